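"""Stage 3: link enhancer peaks to genes via chromatin-interaction loops.

An interaction dataset (Hi-C loop list or promoter-capture Hi-C) supplies
anchor->target pairs where the anchor sits at a gene promoter. Enhancer
peaks overlapping a loop's *target* inherit the gene(s) resolved at that
loop's *anchor*. Each interaction set yields one independent assignment
column; a peak overlapping no target in a set is NA for that set.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

from .annotation import (
    DEFAULT_PROMOTER_HALFWIDTH,
    GeneModel,
    promoter_window,
)
from .intervals import GenomicInterval, IntervalIndex
from .peaks import MergedPeak

logger = logging.getLogger(__name__)

AnchorSide = Literal["first", "second"]


@dataclass(frozen=True)
class Interaction:
    """One promoter-anchored loop, resolved to gene symbol(s)."""

    dataset: str
    anchor: GenomicInterval
    target: GenomicInterval
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("interaction must resolve to >= 1 gene")

    @property
    def is_trans(self) -> bool:
        """True when anchor and target sit on different chromosomes."""
        return self.anchor.chrom != self.target.chrom


@dataclass(frozen=True)
class EnhancerAssignment:
    """Per-interaction-set gene assignment for one enhancer peak.

    ``per_dataset`` maps each loaded interaction-set label to a sorted,
    deduplicated tuple of gene symbols, or ``None`` (NA) when the peak
    overlaps no target of that set.
    """

    merged_id: str
    per_dataset: Mapping[str, tuple[str, ...] | None] = field(default_factory=dict)


class BedpeParseError(ValueError):
    pass


def load_interactions(
    path: str | Path,
    genes: Sequence[GeneModel],
    w: int = DEFAULT_PROMOTER_HALFWIDTH,
    *,
    dataset: str | None = None,
    anchor_side: AnchorSide = "first",
    gene_column: int | None = None,
) -> list[Interaction]:
    """Load a BEDPE loop file and resolve anchors to gene symbols.

    Standard BEDPE columns ``chrom1 start1 end1 chrom2 start2 end2
    [name score strand1 strand2 [genes]]`` are tolerated; gzip input is
    transparent. When an explicit gene column is present (11th column, or
    ``gene_column`` 0-based override) its semicolon-separated symbols are
    used verbatim; otherwise the anchor end (``anchor_side``) is matched
    against the +/-w promoter windows of the gene model and all
    overlapping genes are assigned. Loops resolving to zero genes are
    dropped; the drop count is logged.
    """
    path = Path(path)
    label = dataset if dataset is not None else path.stem
    window_index = IntervalIndex([promoter_window(g, w) for g in genes])
    gene_list = list(genes)

    opener = gzip.open if path.suffix == ".gz" else open
    out: list[Interaction] = []
    dropped = 0
    with opener(path, "rt") as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise BedpeParseError(
                    f"{path}:{line_no}: expected >= 6 BEDPE columns, got {len(parts)}"
                )
            try:
                a = GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
                b = GenomicInterval(parts[3], int(parts[4]), int(parts[5]))
            except ValueError as exc:
                raise BedpeParseError(f"{path}:{line_no}: {exc}") from exc
            anchor, target = (a, b) if anchor_side == "first" else (b, a)

            gcol = gene_column if gene_column is not None else (
                10 if len(parts) > 10 else None
            )
            if gcol is not None and gcol < len(parts) and parts[gcol].strip():
                symbols = tuple(
                    sorted({s for s in parts[gcol].strip().split(";") if s})
                )
            else:
                hits = window_index.query(anchor)
                symbols = tuple(sorted({gene_list[i].gene for i in hits}))
            if not symbols:
                dropped += 1
                continue
            if anchor.chrom != target.chrom:
                logger.debug(
                    "%s:%d: trans contact %s->%s kept",
                    path, line_no, anchor.chrom, target.chrom,
                )
            out.append(Interaction(label, anchor, target, symbols))
    if dropped:
        logger.info(
            "%s: dropped %d interaction(s) resolving to no gene", path, dropped
        )
    if not out:
        logger.warning("%s: zero surviving interactions", path)
    return out


def assign_enhancers(
    peaks: Sequence[MergedPeak],
    interaction_sets: Mapping[str, Sequence[Interaction]],
) -> list[EnhancerAssignment]:
    """Assign each peak, per interaction set, the union of anchor genes of
    every loop whose target overlaps the peak; NA when that union is empty.

    The operation is class-agnostic; the pipeline only feeds it
    enhancer-classified peaks.
    """
    if not interaction_sets:
        raise ValueError("at least one interaction set is required")
    indices = {
        label: (IntervalIndex([i.target for i in loops]), list(loops))
        for label, loops in interaction_sets.items()
    }
    out: list[EnhancerAssignment] = []
    for p in peaks:
        per_ds: dict[str, tuple[str, ...] | None] = {}
        for label, (index, loops) in indices.items():
            hit_genes: set[str] = set()
            for i in index.query(p.interval):
                hit_genes.update(loops[i].genes)
            per_ds[label] = tuple(sorted(hit_genes)) if hit_genes else None
        out.append(EnhancerAssignment(p.merged_id, per_ds))
    return out
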