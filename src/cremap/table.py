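"""Assemble, serialize and query the interactome table.

The table mirrors a supplementary-sheet layout: one row per merged peak
with its coordinates, per-dataset provenance, closest gene and signed
distance, promoter(1)/enhancer(0) class, and one gene-assignment column
per interaction set. Two sentinels are distinguished on output:

* ``NA``  — looked for, nothing found (no peak in that dataset / no loop
  matched the enhancer);
* ``.``   — not applicable (interaction columns on promoter rows, which
  are assigned by closest TSS, not by loops).

A strict-compat writer flag collapses ``.`` to ``NA`` for consumers that
do not make the distinction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import ENHANCER, PROMOTER, TssAssignment
from .intervals import GenomicInterval
from .linking import EnhancerAssignment
from .peaks import ABSENT, NA_TOKEN, MergedPeak

#: Sentinel for "not applicable" cells (interaction columns of promoter rows).
NOT_APPLICABLE = "."

LIST_DELIM = ";"


@dataclass(frozen=True)
class AnnotationRecord:
    """One row of the interactome table.

    ``provenance`` values and ``links`` values are tuples of IDs/genes,
    ``None`` for NA, or :data:`NOT_APPLICABLE` for links on promoter rows.
    """

    merged_id: str
    interval: GenomicInterval
    provenance: Mapping[str, tuple[str, ...] | None]
    closest_gene: str | None
    distance: int | None
    klass: int
    links: Mapping[str, tuple[str, ...] | None | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.klass not in (PROMOTER, ENHANCER):
            raise ValueError(f"klass must be 0 or 1, got {self.klass}")
        for label, cell in self.links.items():
            if self.klass == PROMOTER and cell != NOT_APPLICABLE:
                raise ValueError(
                    f"promoter row {self.merged_id}: interaction column "
                    f"{label!r} must be the not-applicable sentinel"
                )
            if self.klass == ENHANCER and isinstance(cell, str):
                raise ValueError(
                    f"enhancer row {self.merged_id}: column {label!r} must "
                    "be a gene tuple or None (NA)"
                )
            if isinstance(cell, tuple) and not cell:
                raise ValueError(
                    f"{self.merged_id}: empty gene tuple in {label!r}; use None"
                )


class TableBuildError(ValueError):
    pass


def build_table(
    merged_peaks: Sequence[MergedPeak],
    tss_assignments: Mapping[str, TssAssignment],
    enhancer_assignments: Sequence[EnhancerAssignment] | Mapping[str, EnhancerAssignment],
    interaction_labels: Sequence[str],
) -> list[AnnotationRecord]:
    """Join the three pipeline stages into one record per merged peak.

    ``enhancer_assignments`` must cover exactly the enhancer-classified
    (klass=0) subset of the peaks; any mismatch between the three ID sets
    is rejected with the symmetric difference spelled out.
    """
    if not isinstance(enhancer_assignments, Mapping):
        enhancer_assignments = {a.merged_id: a for a in enhancer_assignments}

    peak_ids = {p.merged_id for p in merged_peaks}
    tss_ids = set(tss_assignments)
    if peak_ids != tss_ids:
        raise TableBuildError(
            "peak/TSS-assignment ID mismatch: "
            f"only-in-peaks={sorted(peak_ids - tss_ids)}, "
            f"only-in-tss={sorted(tss_ids - peak_ids)}"
        )
    enhancer_ids = {
        pid for pid, a in tss_assignments.items() if a.klass == ENHANCER
    }
    link_ids = set(enhancer_assignments)
    if interaction_labels and enhancer_ids != link_ids:
        raise TableBuildError(
            "enhancer/link-assignment ID mismatch: "
            f"unlinked-enhancers={sorted(enhancer_ids - link_ids)}, "
            f"linked-non-enhancers={sorted(link_ids - enhancer_ids)}"
        )

    records: list[AnnotationRecord] = []
    for p in sorted(merged_peaks, key=lambda m: (m.interval.chrom, m.interval.start)):
        a = tss_assignments[p.merged_id]
        links: dict[str, tuple[str, ...] | None | str]
        if a.klass == PROMOTER:
            links = {label: NOT_APPLICABLE for label in interaction_labels}
        else:
            ea = enhancer_assignments.get(p.merged_id)
            links = {
                label: (ea.per_dataset.get(label) if ea else None)
                for label in interaction_labels
            }
        records.append(
            AnnotationRecord(
                merged_id=p.merged_id,
                interval=p.interval,
                provenance=dict(p.provenance),
                closest_gene=a.gene,
                distance=a.distance,
                klass=a.klass,
                links=links,
            )
        )
    return records


# ---------------------------------------------------------------------------
# serialization

_FIXED_COLS = ("peak_id", "chrom", "start", "end")
_TAIL_COLS = ("closest_gene", "tss_distance", "klass")
_PROV_PREFIX = "src:"
_LINK_PREFIX = "link:"

_HEADER_COMMENT = """\
# Interactome map: one row per merged peak.
# peak_id, chrom/start/end (0-based half-open), per-dataset provenance
# (src:<dataset> = member peak IDs or NA), closest_gene, tss_distance
# (signed bp from peak midpoint to the closest TSS; negative = upstream
# of the gene), klass (1 = promoter, 0 = enhancer), and one gene column
# per interaction set (link:<set> = ;-joined genes, NA = no loop matched,
# . = not applicable on promoter rows).
"""


def write_table(
    records: Sequence[AnnotationRecord],
    path: str | Path,
    *,
    strict_compat: bool = False,
) -> None:
    """Write records as TSV with a commented header.

    ``strict_compat`` renders the promoter-row "." sentinel as "NA",
    collapsing the not-applicable/not-found distinction.
    """
    datasets = list(records[0].provenance) if records else []
    labels = list(records[0].links) if records else []
    cols = (
        list(_FIXED_COLS)
        + [_PROV_PREFIX + d for d in datasets]
        + list(_TAIL_COLS)
        + [_LINK_PREFIX + s for s in labels]
    )
    na_for_dot = NA_TOKEN if strict_compat else NOT_APPLICABLE
    with open(path, "w") as fh:
        fh.write(_HEADER_COMMENT)
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [
                r.merged_id,
                r.interval.chrom,
                str(r.interval.start),
                str(r.interval.end),
            ]
            for d in datasets:
                members = r.provenance[d]
                row.append(NA_TOKEN if members is ABSENT else LIST_DELIM.join(members))
            row.append(NA_TOKEN if r.closest_gene is None else r.closest_gene)
            row.append(NA_TOKEN if r.distance is None else str(r.distance))
            row.append(str(r.klass))
            for s in labels:
                cell = r.links[s]
                if isinstance(cell, str):
                    row.append(na_for_dot)
                elif cell is None:
                    row.append(NA_TOKEN)
                else:
                    row.append(LIST_DELIM.join(cell))
            fh.write("\t".join(row) + "\n")


class TableParseError(ValueError):
    pass


def read_table(path: str | Path) -> list[AnnotationRecord]:
    """Read a table written by :func:`write_table`; inverse on all fields."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    body = [
        (no, ln.rstrip("\n"))
        for no, ln in enumerate(lines, start=1)
        if ln.strip() and not ln.startswith("#")
    ]
    if not body:
        raise TableParseError(f"{path}: no header row found")
    header_no, header = body[0]
    cols = header.split("\t")
    for fixed in _FIXED_COLS + _TAIL_COLS:
        if fixed not in cols:
            raise TableParseError(f"{path}:{header_no}: missing column {fixed!r}")
    known = set(_FIXED_COLS) | set(_TAIL_COLS)
    for c in cols:
        if c not in known and not c.startswith((_PROV_PREFIX, _LINK_PREFIX)):
            raise TableParseError(f"{path}:{header_no}: unknown column {c!r}")
    datasets = [c[len(_PROV_PREFIX):] for c in cols if c.startswith(_PROV_PREFIX)]
    labels = [c[len(_LINK_PREFIX):] for c in cols if c.startswith(_LINK_PREFIX)]
    idx = {c: i for i, c in enumerate(cols)}

    records: list[AnnotationRecord] = []
    for no, ln in body[1:]:
        parts = ln.split("\t")
        if len(parts) != len(cols):
            raise TableParseError(
                f"{path}:{no}: expected {len(cols)} fields, got {len(parts)}"
            )
        try:
            interval = GenomicInterval(
                parts[idx["chrom"]], int(parts[idx["start"]]), int(parts[idx["end"]])
            )
        except ValueError as exc:
            raise TableParseError(f"{path}:{no}: {exc}") from exc
        klass_token = parts[idx["klass"]]
        if klass_token not in ("0", "1"):
            raise TableParseError(f"{path}:{no}: bad klass value {klass_token!r}")
        klass = int(klass_token)
        gene_tok = parts[idx["closest_gene"]]
        dist_tok = parts[idx["tss_distance"]]
        provenance = {
            d: (
                None
                if parts[idx[_PROV_PREFIX + d]] == NA_TOKEN
                else tuple(parts[idx[_PROV_PREFIX + d]].split(LIST_DELIM))
            )
            for d in datasets
        }
        links: dict[str, tuple[str, ...] | None | str] = {}
        for s in labels:
            tok = parts[idx[_LINK_PREFIX + s]]
            if klass == PROMOTER:
                if tok not in (NOT_APPLICABLE, NA_TOKEN):
                    raise TableParseError(
                        f"{path}:{no}: promoter row with gene link {tok!r}"
                    )
                links[s] = NOT_APPLICABLE
            elif tok == NA_TOKEN:
                links[s] = None
            else:
                links[s] = tuple(tok.split(LIST_DELIM))
        try:
            records.append(
                AnnotationRecord(
                    merged_id=parts[idx["peak_id"]],
                    interval=interval,
                    provenance=provenance,
                    closest_gene=None if gene_tok == NA_TOKEN else gene_tok,
                    distance=None if dist_tok == NA_TOKEN else int(dist_tok),
                    klass=klass,
                    links=links,
                )
            )
        except ValueError as exc:
            raise TableParseError(f"{path}:{no}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# gene-set query

CHANNEL_CLOSEST = "closest-promoter"
CHANNEL_PREFIX = "interaction:"


def available_channels(records: Sequence[AnnotationRecord]) -> list[str]:
    labels = list(records[0].links) if records else []
    return [CHANNEL_CLOSEST] + [CHANNEL_PREFIX + s for s in labels]


@dataclass(frozen=True)
class QueryHit:
    record: AnnotationRecord
    gene: str
    channel: str


@dataclass(frozen=True)
class GeneSetQueryResult:
    """Records of the interactome map matching a gene-set query."""

    query: tuple[str, ...]
    channels: tuple[str, ...]
    hits: tuple[QueryHit, ...]

    @property
    def records(self) -> list[AnnotationRecord]:
        seen: dict[str, AnnotationRecord] = {}
        for h in self.hits:
            seen.setdefault(h.record.merged_id, h.record)
        return list(seen.values())

    @property
    def gene_counts(self) -> dict[str, int]:
        """Per query gene, the number of distinct matching records."""
        counts: dict[str, set[str]] = {}
        for h in self.hits:
            counts.setdefault(h.gene, set()).add(h.record.merged_id)
        return {g: len(ids) for g, ids in sorted(counts.items())}

    def to_json(self) -> str:
        return json.dumps(
            {
                "query": list(self.query),
                "channels": list(self.channels),
                "n_records": len(self.records),
                "gene_counts": self.gene_counts,
                "hits": [
                    {
                        "peak_id": h.record.merged_id,
                        "chrom": h.record.interval.chrom,
                        "start": h.record.interval.start,
                        "end": h.record.interval.end,
                        "gene": h.gene,
                        "channel": h.channel,
                    }
                    for h in self.hits
                ],
            },
            indent=2,
        )


def query_geneset(
    records: Sequence[AnnotationRecord],
    genes: Iterable[str],
    channels: Sequence[str] | None = None,
    *,
    fold_case: bool = False,
) -> GeneSetQueryResult:
    """Find all records assigned to any gene of the query set.

    Channels select the assignment routes searched: ``closest-promoter``
    matches the closest gene of promoter-classified rows (the
    closest-TSS assignment rule), ``interaction:<set>`` matches the gene
    column of that interaction set on enhancer rows. Default: all
    channels present in the table. Matching is exact and case-sensitive
    unless ``fold_case``.
    """
    query = tuple(genes)
    if not query:
        raise ValueError("gene set must be non-empty")
    if channels is None:
        channels = available_channels(records)
    channels = tuple(channels)

    def norm(s: str) -> str:
        return s.casefold() if fold_case else s

    wanted = {norm(g): g for g in query}
    hits: list[QueryHit] = []
    for r in records:
        if CHANNEL_CLOSEST in channels and r.klass == PROMOTER:
            if r.closest_gene is not None and norm(r.closest_gene) in wanted:
                hits.append(QueryHit(r, wanted[norm(r.closest_gene)], CHANNEL_CLOSEST))
        for ch in channels:
            if not ch.startswith(CHANNEL_PREFIX):
                continue
            label = ch[len(CHANNEL_PREFIX):]
            cell = r.links.get(label)
            if isinstance(cell, tuple):
                for g in cell:
                    if norm(g) in wanted:
                        hits.append(QueryHit(r, wanted[norm(g)], ch))
    return GeneSetQueryResult(query=query, channels=channels, hits=tuple(hits))


def write_query_bed(result: GeneSetQueryResult, path: str | Path) -> None:
    """Export the matching records as BED4."""
    with open(path, "w") as fh:
        for r in sorted(result.records, key=lambda r: (r.interval.chrom, r.interval.start)):
            fh.write(
                f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{r.merged_id}\n"
            )


def read_geneset(path: str | Path) -> list[str]:
    """Read a newline-delimited gene list; blank lines and # comments skipped."""
    out = []
    with open(path) as fh:
        for ln in fh:
            s = ln.strip()
            if s and not s.startswith("#"):
                out.append(s)
    return out
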