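"""Stage 2: promoter/enhancer classification and closest-TSS assignment.

A merged peak is a *promoter* peak (class 1) when its span overlaps the
closed +/-2 kb neighbourhood of any transcription start site; otherwise it
is an *enhancer* peak (class 0). Every peak, regardless of class, is also
assigned the gene whose TSS lies closest to the peak midpoint, with a
strand-aware signed distance (negative = upstream of the gene).
"""

from __future__ import annotations

import bisect
import collections
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .intervals import GenomicInterval, IntervalIndex
from .peaks import MergedPeak

PROMOTER = 1
ENHANCER = 0

#: Default promoter window half-width in bp (+/- 2 kb around the TSS).
DEFAULT_PROMOTER_HALFWIDTH = 2000

ProximityMode = Literal["overlap", "midpoint"]


@dataclass(frozen=True)
class GeneModel:
    """One TSS record: gene symbol, chromosome, strand and TSS base.

    A gene with several TSSs contributes one record per TSS, all sharing
    the reported ``gene`` symbol but distinguished by ``record_id``.
    """

    gene: str
    chrom: str
    strand: str
    tss: int
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if not self.record_id:
            object.__setattr__(self, "record_id", self.gene)


@dataclass(frozen=True)
class TssAssignment:
    """Classification and closest-gene assignment for one peak.

    ``gene`` and ``distance`` are ``None`` only when the peak's chromosome
    carries no gene at all; such peaks are enhancers by definition.
    """

    gene: str | None
    distance: int | None
    klass: int

    def __post_init__(self) -> None:
        if self.klass not in (PROMOTER, ENHANCER):
            raise ValueError(f"klass must be 0 or 1, got {self.klass}")
        if (self.gene is None) != (self.distance is None):
            raise ValueError("gene and distance must be None together")
        if self.gene is None and self.klass != ENHANCER:
            raise ValueError("a peak with no gene on its chromosome is an enhancer")


def promoter_window(
    g: GeneModel, w: int = DEFAULT_PROMOTER_HALFWIDTH
) -> GenomicInterval:
    """Closed +/-w bp neighbourhood of the TSS, as a half-open interval.

    ``[max(0, tss - w), tss + w + 1)`` so that every base at distance
    <= w from the TSS (inclusive) is inside. Strand-independent.
    """
    if w <= 0:
        raise ValueError(f"window half-width must be > 0, got {w}")
    return GenomicInterval(g.chrom, max(0, g.tss - w), g.tss + w + 1)


class TssIndex:
    """Sorted-TSS lookup supporting nearest-gene queries per chromosome."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        by_chrom: dict[str, list[GeneModel]] = collections.defaultdict(list)
        for g in self.genes:
            by_chrom[g.chrom].append(g)
        self._tss: dict[str, list[int]] = {}
        self._recs: dict[str, list[GeneModel]] = {}
        for chrom, recs in by_chrom.items():
            recs.sort(key=lambda g: (g.tss, g.gene))
            self._recs[chrom] = recs
            self._tss[chrom] = [g.tss for g in recs]

    def closest(self, chrom: str, pos: int) -> tuple[GeneModel, int] | None:
        """Gene record with TSS nearest ``pos``; ties on |distance| break
        to the lexicographically smallest gene symbol. None if the
        chromosome has no genes."""
        tss = self._tss.get(chrom)
        if not tss:
            return None
        recs = self._recs[chrom]
        i = bisect.bisect_left(tss, pos)
        best_d = None
        for j in (i - 1, i):
            if 0 <= j < len(tss):
                d = abs(tss[j] - pos)
                if best_d is None or d < best_d:
                    best_d = d
        # collect every record at the minimal |distance| (both sides,
        # co-located TSSs) and break the tie by symbol
        candidates = []
        for target in {pos - best_d, pos + best_d}:
            lo = bisect.bisect_left(tss, target)
            while lo < len(tss) and tss[lo] == target:
                candidates.append(recs[lo])
                lo += 1
        best = min(candidates, key=lambda g: (g.gene, g.record_id))
        return best, best_d


def closest_tss(
    peak: MergedPeak | GenomicInterval, genes: Sequence[GeneModel] | TssIndex
) -> tuple[str | None, int | None]:
    """Closest gene to the peak midpoint and the signed distance to it.

    The distance is strand-aware: ``midpoint - tss`` for ``+`` genes and
    ``tss - midpoint`` for ``-`` genes, so a negative value always means
    the peak sits upstream of the gene. Returns ``(None, None)`` when the
    peak's chromosome carries no gene.
    """
    interval = peak.interval if isinstance(peak, MergedPeak) else peak
    index = genes if isinstance(genes, TssIndex) else TssIndex(genes)
    hit = index.closest(interval.chrom, interval.midpoint)
    if hit is None:
        return None, None
    g, _ = hit
    mid = interval.midpoint
    signed = mid - g.tss if g.strand == "+" else g.tss - mid
    return g.gene, signed


def classify_peak(
    peak: MergedPeak | GenomicInterval,
    genes: Sequence[GeneModel] | TssIndex,
    w: int = DEFAULT_PROMOTER_HALFWIDTH,
    proximity_mode: ProximityMode = "overlap",
    _window_index: IntervalIndex | None = None,
) -> TssAssignment:
    """Classify one peak and fill its closest-gene fields.

    Class 1 (promoter) iff the peak is close to *any* TSS: under the
    default ``overlap`` mode, the peak span overlaps the +/-w window;
    under ``midpoint`` mode, the peak midpoint falls inside it. Closest
    gene and distance are reported for every peak regardless of class.
    """
    interval = peak.interval if isinstance(peak, MergedPeak) else peak
    index = genes if isinstance(genes, TssIndex) else TssIndex(genes)
    gene, distance = closest_tss(interval, index)
    if gene is None:
        return TssAssignment(None, None, ENHANCER)
    if proximity_mode == "midpoint":
        hit = index.closest(interval.chrom, interval.midpoint)
        is_promoter = hit is not None and hit[1] <= w
    elif proximity_mode == "overlap":
        if _window_index is None:
            _window_index = IntervalIndex(
                [promoter_window(g, w) for g in index.genes]
            )
        is_promoter = bool(_window_index.query(interval))
    else:
        raise ValueError(f"unknown proximity_mode: {proximity_mode!r}")
    return TssAssignment(gene, distance, PROMOTER if is_promoter else ENHANCER)


def classify_peaks(
    peaks: Sequence[MergedPeak],
    genes: Sequence[GeneModel],
    w: int = DEFAULT_PROMOTER_HALFWIDTH,
    proximity_mode: ProximityMode = "overlap",
) -> dict[str, TssAssignment]:
    """Classify a whole peak list; returns merged_id -> TssAssignment."""
    index = TssIndex(genes)
    window_index = None
    if proximity_mode == "overlap":
        window_index = IntervalIndex([promoter_window(g, w) for g in genes])
    return {
        p.merged_id: classify_peak(
            p, index, w=w, proximity_mode=proximity_mode, _window_index=window_index
        )
        for p in peaks
    }


# ---------------------------------------------------------------------------
# gene-model readers


def read_gene_model(path: str | Path) -> list[GeneModel]:
    """Read a gene model from TSV ``gene, chrom, strand, tss`` (0-based).

    Duplicate gene symbols are rejected unless they represent distinct
    TSSs, in which case each extra TSS becomes a suffixed record
    (``SYM#2``, ``SYM#3``, ...) sharing the base symbol.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene", "chrom", "strand", "tss"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: gene model needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return _build_records(
        [
            (r.gene, r.chrom, r.strand, int(r.tss))
            for r in df.itertuples(index=False)
        ],
        source=str(path),
    )


def read_gene_model_gtf(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Extract TSSs from a GTF subset (1-based; converted to 0-based).

    TSS = start for ``+`` strand, end - 1 for ``-`` strand (0-based).
    Gene symbols come from the ``gene_name`` attribute, falling back to
    ``gene_id``.
    """
    rows: list[tuple[str, str, str, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"{path}:{line_no}: expected 9 GTF columns")
            chrom, _, feat, start, end, _, strand, _, attrs = parts[:9]
            if feat != feature:
                continue
            name = _gtf_attr(attrs, "gene_name") or _gtf_attr(attrs, "gene_id")
            if name is None:
                raise ValueError(f"{path}:{line_no}: no gene_name/gene_id attribute")
            tss = int(start) - 1 if strand == "+" else int(end) - 1
            rows.append((name, chrom, strand, tss))
    return _build_records(rows, source=str(path))


def _gtf_attr(attrs: str, key: str) -> str | None:
    for field in attrs.split(";"):
        field = field.strip()
        if field.startswith(key + " "):
            return field.split(" ", 1)[1].strip().strip('"')
    return None


def _build_records(
    rows: Sequence[tuple[str, str, str, int]], source: str
) -> list[GeneModel]:
    seen: dict[tuple[str, str, str, int], bool] = {}
    per_symbol: collections.Counter[str] = collections.Counter()
    out: list[GeneModel] = []
    for gene, chrom, strand, tss in rows:
        key = (gene, chrom, strand, tss)
        if key in seen:
            raise ValueError(f"{source}: duplicate gene record {key}")
        seen[key] = True
        per_symbol[gene] += 1
        rid = gene if per_symbol[gene] == 1 else f"{gene}#{per_symbol[gene]}"
        out.append(GeneModel(gene, chrom, strand, tss, record_id=rid))
    return out
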