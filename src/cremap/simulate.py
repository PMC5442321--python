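"""Synthetic genome, peak calls and loop sets with planted ground truth.

The generator emulates the statistical shape of the pipeline's real
inputs — several cell-line peak sets that partially agree on a common
reference list of binding sites, and promoter-anchored loop lists — at a
scale where every planted fact can be checked exactly:

* genes are spread along each chromosome with generous spacing, so
  promoter windows never collide and every peak has an unambiguous
  closest TSS;
* each reference peak is planted either inside one gene's promoter
  window (a promoter peak) or in a slotted intergenic position far from
  every window (an unambiguous enhancer);
* each dataset independently re-emits each reference peak with a given
  concordance probability, jittering its boundaries within +/-10% of the
  width while always keeping the jittered span inside its slot — so
  concordant copies always merge back into one region and never touch a
  neighbouring peak;
* a subset of enhancer peaks receives loops whose anchor sits inside the
  linked gene's promoter window and whose target is the peak span
  shifted by at most ``loop_target_jitter`` bases (overlap guaranteed).

Ground truth records, per reference peak, the intended class, the
intended closest gene and the per-interaction-set linked genes, so a
pipeline run on the generated files can be scored exactly via
:func:`verify_recovery`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import DEFAULT_PROMOTER_HALFWIDTH, ENHANCER, PROMOTER
from .intervals import GenomicInterval, IntervalIndex
from .peaks import NA_TOKEN
from .table import LIST_DELIM, AnnotationRecord

# Slot geometry: start offsets (relative to the TSS) and widths of the
# positions where peaks may be planted. Chosen so that a span, its
# +/-10%-width jittered dataset copies and its +/-100 bp shifted loop
# target can never cross into a neighbouring slot, window or gene.
_PROMOTER_SLOTS = ((-1800, 1200), (-600, 1200), (600, 1200))
_ENHANCER_SLOTS = ((-8000, 1600), (-6300, 1600), (4700, 1600), (6400, 1600))
_SLOT_MARGIN = 60
_GENE_SPACING = 20_000
_TSS_JITTER = 1000
_ANCHOR_HALFWIDTH = 500


class CapacityError(ValueError):
    """The requested counts do not fit the genome geometry."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs of the synthetic generator.

    Defaults are the intended small-scale conditions: three partially
    concordant cell-line peak sets (concordance 0.8) over one reference
    list of 200 binding sites, a 50-gene model, and two
    promoter-anchored loop sets of 80 loops each.
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 2_000_000
    n_genes: int = 50
    n_reference_peaks: int = 200
    datasets: tuple[str, ...] = ("MDA-MB-231", "SF268", "NCI-H2052")
    peak_width: tuple[int, int] = (200, 600)
    dataset_concordance: float = 0.8
    frac_promoter_peaks: float = 0.3
    interaction_sets: tuple[str, ...] = ("hic", "chic")
    n_loops: int = 80
    frac_enhancers_looped: float = 0.6
    loop_target_jitter: int = 100
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH
    boundary_stress: bool = False

    def __post_init__(self) -> None:
        for name in ("n_chroms", "chrom_length", "n_genes", "n_reference_peaks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.datasets:
            raise ValueError("at least one dataset label required")
        if len(set(self.datasets)) != len(self.datasets):
            raise ValueError("dataset labels must be unique")
        if len(set(self.interaction_sets)) != len(self.interaction_sets):
            raise ValueError("interaction-set labels must be unique")
        for name in (
            "dataset_concordance",
            "frac_promoter_peaks",
            "frac_enhancers_looped",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.peak_width
        if not (0 < lo <= hi):
            raise ValueError(f"invalid peak_width range {self.peak_width}")
        slot_min = min(w for _, w in _PROMOTER_SLOTS + _ENHANCER_SLOTS)
        if hi > slot_min - 2 * _SLOT_MARGIN:
            raise CapacityError(
                f"peak_width {self.peak_width} too wide for the slot geometry"
            )
        if self.interaction_sets and self.loop_target_jitter >= lo:
            raise ValueError(
                "loop_target_jitter must be smaller than the minimum peak "
                "width to guarantee target/peak overlap"
            )
        if self.promoter_halfwidth != DEFAULT_PROMOTER_HALFWIDTH:
            raise ValueError(
                "the planted slot geometry is built for the default "
                f"{DEFAULT_PROMOTER_HALFWIDTH} bp promoter half-width"
            )


#: documented large-scale preset approaching the ">10,000 promoter
#: anchors" scale of real promoter-capture designs; not a test default
LARGE_PRESET = SimConfig(
    n_chroms=10,
    chrom_length=30_000_000,
    n_genes=12_000,
    n_reference_peaks=20_000,
    n_loops=10_000,
)


@dataclass(frozen=True)
class PlantedPeak:
    """One reference binding site and everything planted about it."""

    ref_id: str
    interval: GenomicInterval
    klass: int
    closest_gene: str
    emitted: Mapping[str, str | None]  # dataset -> emitted peak_id or None
    looped_genes: Mapping[str, tuple[str, ...] | None]  # set label -> genes/None

    @property
    def expected_in_output(self) -> bool:
        return any(pid is not None for pid in self.emitted.values())


@dataclass
class SimResult:
    """In-memory products of one generator run."""

    config: SimConfig
    genes: pd.DataFrame  # columns gene, chrom, strand, tss
    peaks: dict[str, pd.DataFrame]  # dataset -> chrom,start,end,name
    loops: dict[str, pd.DataFrame]  # set label -> 6-column BEDPE
    truth: list[PlantedPeak]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row: dict[str, object] = {
                "ref_id": t.ref_id,
                "chrom": t.interval.chrom,
                "start": t.interval.start,
                "end": t.interval.end,
                "klass": t.klass,
                "closest_gene": t.closest_gene,
            }
            for ds, pid in t.emitted.items():
                row[f"src:{ds}"] = pid if pid is not None else NA_TOKEN
            for label, genes in t.looped_genes.items():
                row[f"link:{label}"] = (
                    LIST_DELIM.join(genes) if genes is not None else NA_TOKEN
                )
            rows.append(row)
        return pd.DataFrame(rows)


def generate(config: SimConfig) -> SimResult:
    """Generate gene model, per-dataset peaks, loop sets and ground truth.

    Deterministic for a fixed config: every random draw comes from
    sub-streams spawned from the single config seed.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_place, rng_emit, rng_loops = (np.random.default_rng(s) for s in ss.spawn(3))

    genes = _place_genes(config, rng_place)
    planted = _place_reference_peaks(config, genes, rng_place)
    emitted = _emit_datasets(config, planted, rng_emit)
    looped = _plant_loops(config, genes, planted, rng_loops)

    truth = [
        PlantedPeak(
            ref_id=f"ref_{i + 1:05d}",
            interval=iv,
            klass=klass,
            closest_gene=gene,
            emitted={ds: emitted[ds][i][0] if i in emitted[ds] else None
                     for ds in config.datasets},
            looped_genes={
                label: looped[label]["genes"].get(i)
                for label in config.interaction_sets
            },
        )
        for i, (iv, klass, gene) in enumerate(planted)
    ]

    peak_frames: dict[str, pd.DataFrame] = {}
    for ds in config.datasets:
        rows = [
            (span.chrom, span.start, span.end, pid)
            for pid, span in emitted[ds].values()
        ]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        peak_frames[ds] = df.sort_values(["chrom", "start", "end"]).reset_index(
            drop=True
        )

    loop_frames = {
        label: pd.DataFrame(
            looped[label]["rows"],
            columns=["chrom1", "start1", "end1", "chrom2", "start2", "end2"],
        )
        for label in config.interaction_sets
    }
    return SimResult(config, genes, peak_frames, loop_frames, truth)


def _place_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = -(-config.n_genes // config.n_chroms)  # ceil division
    needed = (per_chrom + 1) * _GENE_SPACING + _TSS_JITTER + 10_000
    if needed > config.chrom_length:
        raise CapacityError(
            f"chrom_length {config.chrom_length} too small for {per_chrom} "
            f"genes per chromosome at {_GENE_SPACING} bp spacing (need {needed})"
        )
    rows = []
    g = 0
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        for k in range(per_chrom):
            if g >= config.n_genes:
                break
            tss = (k + 1) * _GENE_SPACING + int(
                rng.integers(-_TSS_JITTER, _TSS_JITTER + 1)
            )
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"G{g + 1:04d}", chrom, strand, tss))
            g += 1
    return pd.DataFrame(rows, columns=["gene", "chrom", "strand", "tss"])


def _place_reference_peaks(
    config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> list[tuple[GenomicInterval, int, str]]:
    """Plant reference peaks into free slots; returns (span, klass, gene)."""
    if config.boundary_stress:
        return _place_boundary_peaks(config, genes, rng)

    n_prom = round(config.frac_promoter_peaks * config.n_reference_peaks)
    n_enh = config.n_reference_peaks - n_prom
    prom_slots = [
        (row, off, sw)
        for row in genes.itertuples(index=False)
        for off, sw in _PROMOTER_SLOTS
    ]
    enh_slots = [
        (row, off, sw)
        for row in genes.itertuples(index=False)
        for off, sw in _ENHANCER_SLOTS
    ]
    if n_prom > len(prom_slots) or n_enh > len(enh_slots):
        raise CapacityError(
            f"requested {n_prom} promoter / {n_enh} enhancer peaks but only "
            f"{len(prom_slots)} / {len(enh_slots)} slots exist; increase "
            "n_genes or n_chroms"
        )
    lo, hi = config.peak_width
    out: list[tuple[GenomicInterval, int, str]] = []
    for slots, n, klass in (
        (prom_slots, n_prom, PROMOTER),
        (enh_slots, n_enh, ENHANCER),
    ):
        chosen = rng.choice(len(slots), size=n, replace=False)
        for s in chosen:
            gene_row, off, sw = slots[int(s)]
            width = int(rng.integers(lo, hi + 1))
            u = int(rng.integers(_SLOT_MARGIN, sw - width - _SLOT_MARGIN + 1))
            start = int(gene_row.tss) + off + u
            out.append(
                (
                    GenomicInterval(gene_row.chrom, start, start + width),
                    klass,
                    gene_row.gene,
                )
            )
    out.sort(key=lambda t: (t[0].chrom, t[0].start))
    return out


def _place_boundary_peaks(
    config: SimConfig, genes: pd.DataFrame, rng: np.random.Generator
) -> list[tuple[GenomicInterval, int, str]]:
    """Stress mode: peaks swept across the right promoter-window edge.

    The window covers bases tss-w .. tss+w inclusive, so a peak starting
    at tss+w overlaps it by exactly one base (promoter) and a peak
    starting at tss+w+1 misses it by one (enhancer). One peak per gene;
    boundary positions are exact, so dataset emission applies no jitter
    in this mode.
    """
    if config.n_reference_peaks > len(genes):
        raise CapacityError(
            "boundary_stress plants one peak per gene: "
            f"{config.n_reference_peaks} peaks > {len(genes)} genes"
        )
    w = config.promoter_halfwidth
    lo, hi = config.peak_width
    out = []
    for i, row in enumerate(genes.head(config.n_reference_peaks).itertuples(index=False)):
        width = int(rng.integers(lo, hi + 1))
        offset = i % 6 - 2  # sweep starts tss+w-2 .. tss+w+3
        start = int(row.tss) + w + offset
        klass = PROMOTER if offset <= 0 else ENHANCER
        out.append((GenomicInterval(row.chrom, start, start + width), klass, row.gene))
    out.sort(key=lambda t: (t[0].chrom, t[0].start))
    return out


def _emit_datasets(
    config: SimConfig,
    planted: Sequence[tuple[GenomicInterval, int, str]],
    rng: np.random.Generator,
) -> dict[str, dict[int, tuple[str, GenomicInterval]]]:
    """Each dataset re-emits each reference peak with prob concordance,
    jittering both boundaries within +/-10% of the width (skipped in
    boundary-stress mode, where exact positions carry the signal)."""
    out: dict[str, dict[int, tuple[str, GenomicInterval]]] = {}
    for ds in config.datasets:
        emitted: dict[int, tuple[str, GenomicInterval]] = {}
        tag = ds.replace(" ", "")
        for i, (iv, _, _) in enumerate(planted):
            if rng.random() >= config.dataset_concordance:
                continue
            if config.boundary_stress:
                span = iv
            else:
                j = max(1, (iv.end - iv.start) // 10)
                dl = int(rng.integers(-j, j + 1))
                dr = int(rng.integers(-j, j + 1))
                span = GenomicInterval(iv.chrom, iv.start + dl, iv.end + dr)
            emitted[i] = (f"{tag}_{i + 1:05d}", span)
        out[ds] = emitted
    return out


def _plant_loops(
    config: SimConfig,
    genes: pd.DataFrame,
    planted: Sequence[tuple[GenomicInterval, int, str]],
    rng: np.random.Generator,
) -> dict[str, dict]:
    """Per interaction set: BEDPE rows (anchor first) plus the planted
    per-reference-peak gene truth."""
    genes_by_chrom = {c: grp for c, grp in genes.groupby("chrom", sort=True)}
    enh_idx = [i for i, (_, klass, _) in enumerate(planted) if klass == ENHANCER]
    out: dict[str, dict] = {}
    for label in config.interaction_sets:
        rows: list[tuple[str, int, int, str, int, int]] = []
        truth: dict[int, tuple[str, ...]] = {}
        if enh_idx:
            n_looped = min(
                round(config.frac_enhancers_looped * len(enh_idx)),
                config.n_loops,
                len(enh_idx),
            )
            chosen = [int(i) for i in rng.choice(enh_idx, size=n_looped, replace=False)]
            # every chosen enhancer gets one loop; surplus loops go to
            # random chosen enhancers (creating multi-gene assignments)
            schedule = list(chosen)
            for _ in range(config.n_loops - n_looped):
                if not chosen:
                    break
                schedule.append(int(chosen[int(rng.integers(len(chosen)))]))
            gene_sets: dict[int, set[str]] = {}
            for i in schedule:
                iv = planted[i][0]
                cand = genes_by_chrom[iv.chrom]
                g = cand.iloc[int(rng.integers(len(cand)))]
                shift = int(rng.integers(-config.loop_target_jitter,
                                         config.loop_target_jitter + 1))
                anchor = (
                    iv.chrom,
                    int(g.tss) - _ANCHOR_HALFWIDTH,
                    int(g.tss) + _ANCHOR_HALFWIDTH,
                )
                target = (iv.chrom, iv.start + shift, iv.end + shift)
                rows.append(anchor + target)
                gene_sets.setdefault(i, set()).add(str(g.gene))
            truth = {i: tuple(sorted(gs)) for i, gs in gene_sets.items()}
        out[label] = {"rows": rows, "genes": truth}
    return out


# ---------------------------------------------------------------------------
# file emission


def write_outputs(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write the generated inputs in the dialects the pipeline reads.

    Returns a mapping of logical names (``gene_model``, ``peaks:<ds>``,
    ``loops:<set>``, ``truth``) to paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    gene_path = outdir / "gene_model.tsv"
    result.genes.to_csv(gene_path, sep="\t", index=False)
    paths["gene_model"] = gene_path

    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for ds, df in result.peaks.items():
        p = peak_dir / f"{ds.replace(' ', '_')}.bed"
        df.to_csv(p, sep="\t", index=False, header=False)
        paths[f"peaks:{ds}"] = p

    loop_dir = outdir / "loops"
    loop_dir.mkdir(exist_ok=True)
    for label, df in result.loops.items():
        p = loop_dir / f"{label}.bedpe"
        df.to_csv(p, sep="\t", index=False, header=False)
        paths[f"loops:{label}"] = p

    truth_path = outdir / "truth.tsv"
    result.truth_frame().to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


# ---------------------------------------------------------------------------
# recovery scoring


@dataclass(frozen=True)
class RecoveryReport:
    """Exact-match rates of a pipeline run against the planted truth."""

    n_compared: int
    n_enhancers: int
    klass_rate: float
    closest_gene_rate: float
    loop_gene_rate: dict[str, float] = field(default_factory=dict)
    mismatches: tuple[str, ...] = ()

    @property
    def perfect(self) -> bool:
        return (
            self.klass_rate == 1.0
            and self.closest_gene_rate == 1.0
            and all(r == 1.0 for r in self.loop_gene_rate.values())
        )


class AlignmentError(ValueError):
    """Truth and output peaks could not be matched one-to-one."""


def verify_recovery(
    truth: Sequence[PlantedPeak], records: Sequence[AnnotationRecord]
) -> RecoveryReport:
    """Score a pipeline output table against the planted ground truth.

    Each reference peak that was emitted by at least one dataset must
    match exactly one output record by genomic overlap; reference peaks
    emitted by no dataset must be absent. Rates are exact-match
    fractions for the class call, the closest gene, and (over enhancer
    peaks) the per-set linked gene lists.
    """
    index = IntervalIndex([r.interval for r in records])
    matched_records: set[int] = set()
    pairs: list[tuple[PlantedPeak, AnnotationRecord]] = []
    orphans: list[str] = []
    for t in truth:
        hits = index.query(t.interval)
        if not t.expected_in_output:
            if hits:
                orphans.append(
                    f"{t.ref_id}: emitted by no dataset but matched "
                    f"{[records[h].merged_id for h in hits]}"
                )
            continue
        if len(hits) != 1:
            orphans.append(
                f"{t.ref_id}: expected exactly one overlapping output record, "
                f"got {[records[h].merged_id for h in hits]}"
            )
            continue
        matched_records.add(hits[0])
        pairs.append((t, records[hits[0]]))
    unmatched = [
        records[i].merged_id for i in range(len(records)) if i not in matched_records
    ]
    if orphans or unmatched:
        raise AlignmentError(
            "truth/output alignment failed: "
            + "; ".join(orphans + [f"unmatched output record {m}" for m in unmatched])
        )

    mismatches: list[str] = []
    klass_ok = 0
    gene_ok = 0
    loop_ok: dict[str, int] = {}
    n_enh = 0
    labels = list(records[0].links) if records else []
    for t, r in pairs:
        if t.klass == r.klass:
            klass_ok += 1
        else:
            mismatches.append(f"{t.ref_id}: klass {t.klass} != {r.klass}")
        if t.closest_gene == r.closest_gene:
            gene_ok += 1
        else:
            mismatches.append(
                f"{t.ref_id}: closest gene {t.closest_gene} != {r.closest_gene}"
            )
        if t.klass == ENHANCER:
            n_enh += 1
            for label in labels:
                expected = t.looped_genes.get(label)
                got = r.links.get(label)
                got_genes = got if isinstance(got, tuple) else None
                if expected == got_genes:
                    loop_ok[label] = loop_ok.get(label, 0) + 1
                else:
                    mismatches.append(
                        f"{t.ref_id}/{label}: linked genes {expected} != {got_genes}"
                    )
    n = len(pairs)
    return RecoveryReport(
        n_compared=n,
        n_enhancers=n_enh,
        klass_rate=klass_ok / n if n else 1.0,
        closest_gene_rate=gene_ok / n if n else 1.0,
        loop_gene_rate={
            label: (loop_ok.get(label, 0) / n_enh if n_enh else 1.0)
            for label in labels
        },
        mismatches=tuple(mismatches),
    )
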