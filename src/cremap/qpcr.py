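"""ChIP-qPCR enrichment quantitation.

The amount of immunoprecipitated DNA at a locus is expressed as the
fraction of the input chromatin,

    fraction of input = E ** (mean Ct_input - mean Ct_ChIP)

where E is the per-cycle amplification efficiency of the amplicon
(E = 2 for ideal doubling), and then normalized to a nonspecific IgG
control immunoprecipitated in parallel:

    enrichment = fraction_of_input(antibody) / fraction_of_input(IgG)

Replicate Ct values are averaged in Ct (log) space by default, the
standard dCt practice; linear-space averaging is available via a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

DEFAULT_EFFICIENCY = 2.0


@dataclass(frozen=True)
class CtMeasurement:
    """Replicate Ct values for one (sample, locus) pair.

    ``efficiency`` is the per-cycle amplification factor, in (1, 2].
    """

    sample: str
    locus: str
    ct_values: tuple[float, ...]
    efficiency: float = DEFAULT_EFFICIENCY

    def __post_init__(self) -> None:
        if not self.ct_values:
            raise ValueError(f"{self.sample}/{self.locus}: no Ct replicates")
        for ct in self.ct_values:
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(
                    f"{self.sample}/{self.locus}: Ct must be finite and > 0, got {ct}"
                )
        if not (1.0 < self.efficiency <= 2.0):
            raise ValueError(
                f"{self.sample}/{self.locus}: efficiency must be in (1, 2], "
                f"got {self.efficiency}"
            )

    def mean_ct(self, linear_space: bool = False) -> float:
        """Mean Ct of the replicates.

        Default: arithmetic mean of Ct. With ``linear_space``, replicates
        are averaged as template quantities E**(-Ct) and converted back.
        """
        if not linear_space:
            return sum(self.ct_values) / len(self.ct_values)
        quantities = [self.efficiency ** (-ct) for ct in self.ct_values]
        return -math.log(sum(quantities) / len(quantities), self.efficiency)


@dataclass(frozen=True)
class EnrichmentResult:
    locus: str
    fraction_of_input: float
    igg_fraction: float
    normalized_enrichment: float


def fraction_of_input(
    ct_chip: CtMeasurement,
    ct_input: CtMeasurement,
    input_dilution_factor: float = 1.0,
    *,
    linear_space: bool = False,
) -> float:
    """E ** (mean Ct_input - mean Ct_ChIP), times the input dilution factor.

    Both measurements must target the same locus with the same assay
    efficiency. ``input_dilution_factor`` multiplies the result when the
    input aliquot was a known fraction of the ChIP chromatin.
    """
    if ct_chip.locus != ct_input.locus:
        raise ValueError(
            f"locus mismatch: ChIP={ct_chip.locus!r} vs input={ct_input.locus!r}"
        )
    if ct_chip.efficiency != ct_input.efficiency:
        raise ValueError(
            f"{ct_chip.locus}: efficiency mismatch "
            f"({ct_chip.efficiency} vs {ct_input.efficiency})"
        )
    if input_dilution_factor <= 0:
        raise ValueError("input_dilution_factor must be > 0")
    delta = ct_input.mean_ct(linear_space) - ct_chip.mean_ct(linear_space)
    return ct_chip.efficiency ** delta * input_dilution_factor


def normalize_to_igg(sample_fraction: float, igg_fraction: float) -> float:
    """Fold enrichment over the IgG control: sample / IgG fraction."""
    if igg_fraction <= 0:
        raise ValueError(f"IgG fraction must be > 0, got {igg_fraction}")
    if sample_fraction < 0:
        raise ValueError(f"sample fraction must be >= 0, got {sample_fraction}")
    return sample_fraction / igg_fraction


def quantify(
    measurements: Sequence[CtMeasurement],
    *,
    chip_sample: str,
    input_sample: str,
    igg_sample: str,
    input_dilution_factor: float = 1.0,
    linear_space: bool = False,
) -> list[EnrichmentResult]:
    """IgG-normalized enrichment for every locus with a full sample trio.

    For each locus having Ct measurements for the antibody, the input and
    the IgG control, computes the antibody and IgG fractions of input and
    their ratio. Loci missing any of the three samples raise.
    """
    by_key = {(m.sample, m.locus): m for m in measurements}
    if len(by_key) != len(measurements):
        raise ValueError("duplicate (sample, locus) measurement")
    loci = sorted({m.locus for m in measurements if m.sample == chip_sample})
    if not loci:
        raise ValueError(f"no measurements for ChIP sample {chip_sample!r}")
    out = []
    for locus in loci:
        try:
            chip = by_key[(chip_sample, locus)]
            inp = by_key[(input_sample, locus)]
            igg = by_key[(igg_sample, locus)]
        except KeyError as exc:
            raise ValueError(f"locus {locus!r}: missing measurement {exc}") from exc
        frac = fraction_of_input(
            chip, inp, input_dilution_factor, linear_space=linear_space
        )
        igg_frac = fraction_of_input(
            igg, inp, input_dilution_factor, linear_space=linear_space
        )
        out.append(
            EnrichmentResult(locus, frac, igg_frac, normalize_to_igg(frac, igg_frac))
        )
    return out


# ---------------------------------------------------------------------------
# I/O


def read_ct_table(path: str | Path) -> list[CtMeasurement]:
    """Read a Ct table TSV: sample, locus, ct [, efficiency].

    One row per replicate; replicates of the same (sample, locus) are
    pooled into one measurement. Efficiency defaults to 2.0 and must be
    consistent across a (sample, locus) group.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "locus", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: Ct table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if "efficiency" not in df.columns:
        df["efficiency"] = DEFAULT_EFFICIENCY
    df["efficiency"] = df["efficiency"].fillna(DEFAULT_EFFICIENCY)
    out = []
    for (sample, locus), grp in df.groupby(["sample", "locus"], sort=True):
        eff = grp["efficiency"].unique()
        if len(eff) > 1:
            raise ValueError(
                f"{path}: inconsistent efficiency for ({sample}, {locus}): {eff}"
            )
        out.append(
            CtMeasurement(
                str(sample),
                str(locus),
                tuple(float(c) for c in grp["ct"]),
                float(eff[0]),
            )
        )
    return out


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("locus\tfraction_of_input\tigg_fraction\tnormalized_enrichment\n")
        for r in results:
            fh.write(
                f"{r.locus}\t{r.fraction_of_input:.10g}\t{r.igg_fraction:.10g}"
                f"\t{r.normalized_enrichment:.10g}\n"
            )
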