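"""Stage 1: combine ChIP-seq peak sets from several datasets into one
reference list of merged peaks with per-dataset provenance.

Peaks from all datasets (e.g. different cell lines, or YAP and TAZ pulled
down separately) are pooled and merged by single linkage: any two peaks
sharing at least one base belong to the same merged peak, and chains
A-B, B-C collapse into one region even when A and C themselves do not
touch. Each merged peak records, per declared dataset, which member peak
IDs it absorbed; a dataset contributing no member is marked ABSENT and
rendered "NA" on output.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, span_union

#: Provenance marker for a dataset with no member peak at a merged region.
ABSENT = None

NA_TOKEN = "NA"


@dataclass(frozen=True)
class SourcePeak:
    """One peak call from one dataset."""

    dataset: str
    peak_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class MergedPeak:
    """One row of the reference peak list.

    ``provenance`` maps every declared dataset to the sorted list of its
    member peak IDs, or :data:`ABSENT` (``None``) when that dataset has no
    peak in this region.
    """

    merged_id: str
    interval: GenomicInterval
    provenance: Mapping[str, tuple[str, ...] | None]

    def member_count(self) -> int:
        return sum(len(v) for v in self.provenance.values() if v is not None)


class DuplicatePeakIdError(ValueError):
    """Raised when a dataset reuses a peak_id; carries the offenders."""

    def __init__(self, offenders: Mapping[str, Sequence[str]]):
        self.offenders = {ds: list(ids) for ds, ids in offenders.items()}
        detail = "; ".join(
            f"{ds}: {', '.join(ids)}" for ds, ids in self.offenders.items()
        )
        super().__init__(f"duplicate peak_id within dataset -- {detail}")


def merge_peak_sets(
    peak_sets: Mapping[str, Sequence[SourcePeak]],
    *,
    gap: int = 0,
    min_overlap: int = 1,
    id_prefix: str = "peak_",
) -> list[MergedPeak]:
    """Merge pooled peaks into single-linkage connected components.

    Parameters
    ----------
    peak_sets : mapping of dataset label -> peaks
        Every declared dataset appears in each output peak's provenance,
        ABSENT where it contributed nothing. Datasets may be empty.
    gap : int
        Gaps strictly smaller than this still merge. The default 0
        requires a real overlap; bookended peaks (end == start) are NOT
        merged. ``gap=1`` merges bookended peaks.
    min_overlap : int
        Minimum bases a peak must share with the growing merged region to
        join it (default 1). Values > 1 make the rule stricter than plain
        single linkage.
    id_prefix : str
        Prefix of the deterministic merged IDs, assigned as zero-padded
        ordinals after sorting by (chrom, start).

    Returns
    -------
    list of MergedPeak, sorted by (chrom, start, end).
    """
    if not peak_sets:
        raise ValueError("at least one dataset is required")

    dup: dict[str, list[str]] = {}
    for ds, peaks in peak_sets.items():
        counts = collections.Counter(p.peak_id for p in peaks)
        bad = sorted(pid for pid, n in counts.items() if n > 1)
        if bad:
            dup[ds] = bad
    if dup:
        raise DuplicatePeakIdError(dup)

    pooled: list[SourcePeak] = [p for peaks in peak_sets.values() for p in peaks]
    datasets = list(peak_sets)

    # Single linkage over intervals equals a sweep over sorted starts:
    # a new component starts whenever the next peak begins beyond the
    # running max end (+ gap tolerance).
    pooled.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    components: list[list[SourcePeak]] = []
    cur: list[SourcePeak] = []
    cur_chrom: str | None = None
    cur_end = -1
    # join iff overlap with the running span >= min_overlap, or the gap
    # to it is < gap; with defaults this is "share >= 1 bp".
    threshold = gap - min_overlap + 1 if gap > 0 else 1 - min_overlap
    for p in pooled:
        if p.interval.chrom != cur_chrom or p.interval.start - cur_end >= threshold:
            if cur:
                components.append(cur)
            cur = [p]
            cur_chrom = p.interval.chrom
            cur_end = p.interval.end
        else:
            cur.append(p)
            cur_end = max(cur_end, p.interval.end)
    if cur:
        components.append(cur)

    components.sort(
        key=lambda comp: (
            comp[0].interval.chrom,
            min(m.interval.start for m in comp),
        )
    )
    width = max(4, len(str(len(components))))
    merged: list[MergedPeak] = []
    for ordinal, comp in enumerate(components, start=1):
        by_ds: dict[str, list[str]] = collections.defaultdict(list)
        for m in comp:
            by_ds[m.dataset].append(m.peak_id)
        provenance = {
            ds: tuple(sorted(by_ds[ds])) if ds in by_ds else ABSENT
            for ds in datasets
        }
        merged.append(
            MergedPeak(
                merged_id=f"{id_prefix}{ordinal:0{width}d}",
                interval=span_union(m.interval for m in comp),
                provenance=provenance,
            )
        )
    return merged


# ---------------------------------------------------------------------------
# readers / writers


def read_peaks(path: str | Path, dataset: str | None = None) -> list[SourcePeak]:
    """Read BED4 or ENCODE narrowPeak peak calls for one dataset.

    Only the first four columns (chrom, start, end, name) are used; the
    narrowPeak summit column is parsed but ignored. The dataset label
    defaults to the filename stem.
    """
    path = Path(path)
    label = dataset if dataset is not None else path.stem
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        dtype=str,
        skip_blank_lines=True,
    )
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected >= 3 tab-separated columns")
    peaks = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        chrom, start, end = row[0], int(row[1]), int(row[2])
        name = row[3] if df.shape[1] >= 4 and pd.notna(row[3]) else f"{label}_{row_no}"
        peaks.append(
            SourcePeak(label, str(name), GenomicInterval(chrom, start, end))
        )
    return peaks


def write_merged_bed(merged: Sequence[MergedPeak], path: str | Path) -> None:
    """Write merged peaks as BED4 (chrom, start, end, merged_id)."""
    with open(path, "w") as fh:
        for m in merged:
            fh.write(
                f"{m.interval.chrom}\t{m.interval.start}\t{m.interval.end}\t{m.merged_id}\n"
            )


def write_provenance(merged: Sequence[MergedPeak], path: str | Path) -> None:
    """Write the provenance long table: merged_id, dataset, member_ids|NA."""
    with open(path, "w") as fh:
        fh.write("merged_id\tdataset\tmember_ids\n")
        for m in merged:
            for ds, members in m.provenance.items():
                cell = NA_TOKEN if members is ABSENT else ";".join(members)
                fh.write(f"{m.merged_id}\t{ds}\t{cell}\n")
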