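"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own data paths: they
work on plain tuples/arrays with direct arithmetic, so agreement with
the implementation is a real cross-check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cremap.intervals import GenomicInterval
from cremap.table import NOT_APPLICABLE, AnnotationRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20250921)


def random_intervals(rng, n, chroms=("chr1", "chr2", "chr3"), max_pos=100_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len + 1))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out


# --- independent oracles ---------------------------------------------------


def oracle_overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def oracle_bulk_overlap(query, subject):
    return {
        qi: [si for si, s in enumerate(subject) if oracle_overlaps(q, s)]
        for qi, q in enumerate(query)
    }


def oracle_merge_partition(intervals):
    """Single-linkage connected components via explicit union-find over
    the all-pairs overlap matrix; returns a frozenset of frozensets of
    input indices."""
    n = len(intervals)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if oracle_overlaps(intervals[i], intervals[j]):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return frozenset(frozenset(g) for g in groups.values())


def oracle_closest_tss(mid, chrom, genes):
    """Linear scan over (symbol, chrom, strand, tss) tuples; ties on
    |distance| break to the smallest symbol. None if no same-chrom gene."""
    best = None
    for sym, gchrom, strand, tss in genes:
        if gchrom != chrom:
            continue
        d = abs(mid - tss)
        key = (d, sym)
        if best is None or key < best[0]:
            signed = mid - tss if strand == "+" else tss - mid
            best = (key, sym, signed)
    if best is None:
        return None, None
    return best[1], best[2]


def oracle_assign(peak_intervals, loops):
    """All-pairs scan: loops are (target_interval, genes_tuple) pairs;
    returns per peak the sorted union of genes of overlapping targets,
    or None."""
    out = []
    for p in peak_intervals:
        hit = set()
        for target, genes in loops:
            if oracle_overlaps(p, target):
                hit.update(genes)
        out.append(tuple(sorted(hit)) if hit else None)
    return out


def oracle_query(records, geneset, channels):
    """Row scan over AnnotationRecords mirroring the query contract."""
    geneset = set(geneset)
    matched = []
    for r in records:
        found = False
        if "closest-promoter" in channels and r.klass == 1:
            if r.closest_gene in geneset:
                found = True
        for ch in channels:
            if ch.startswith("interaction:"):
                cell = r.links.get(ch[len("interaction:"):])
                if isinstance(cell, tuple) and any(g in geneset for g in cell):
                    found = True
        if found:
            matched.append(r.merged_id)
    return matched


# --- random table construction ---------------------------------------------

_GENES = [f"G{i}" for i in range(1, 30)]


def random_records(rng, n=None, datasets=("dsA", "dsB"), labels=("hic", "chic")):
    """Random but well-formed AnnotationRecords exercising NA, '.', and
    multi-gene cells."""
    if n is None:
        n = int(rng.integers(0, 40))
    records = []
    pos = 0
    for i in range(n):
        pos += int(rng.integers(1000, 5000))
        width = int(rng.integers(100, 900))
        iv = GenomicInterval(f"chr{int(rng.integers(1, 4))}", pos, pos + width)
        klass = int(rng.random() < 0.4)
        no_gene = rng.random() < 0.05
        if no_gene:
            gene, dist, klass = None, None, 0
        else:
            gene = str(rng.choice(_GENES))
            dist = int(rng.integers(-50_000, 50_000))
        provenance = {
            ds: (
                None
                if rng.random() < 0.3
                else tuple(
                    f"{ds}_p{int(rng.integers(1, 999)):03d}_{k}"
                    for k in range(int(rng.integers(1, 4)))
                )
            )
            for ds in datasets
        }
        if all(v is None for v in provenance.values()):
            provenance[datasets[0]] = (f"{datasets[0]}_p001_0",)
        if klass == 1:
            links = {s: NOT_APPLICABLE for s in labels}
        else:
            links = {
                s: (
                    None
                    if rng.random() < 0.4
                    else tuple(
                        sorted({str(g) for g in rng.choice(_GENES, size=int(rng.integers(1, 4)))})
                    )
                )
                for s in labels
            }
        records.append(
            AnnotationRecord(
                merged_id=f"peak_{i + 1:04d}",
                interval=iv,
                provenance=provenance,
                closest_gene=gene,
                distance=dist,
                klass=klass,
                links=links,
            )
        )
    return records
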