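"""End-to-end orchestration: merge -> classify -> link -> table.

The pipeline is a pure function of its configuration and input files:
identical inputs produce identical output bytes. Every run writes a
manifest recording the config hash, input checksums and per-stage counts
(peaks in/merged, promoters, enhancers, linked/NA per interaction set),
because the NA bookkeeping carries the map's semantics.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .annotation import (
    DEFAULT_PROMOTER_HALFWIDTH,
    ENHANCER,
    PROMOTER,
    classify_peaks,
    read_gene_model,
    read_gene_model_gtf,
)
from .linking import assign_enhancers, load_interactions
from .peaks import merge_peak_sets, read_peaks, write_merged_bed, write_provenance
from .table import build_table, write_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InteractionSetConfig:
    label: str
    path: str
    anchor_side: str = "first"
    gene_column: int | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of one pipeline run."""

    datasets: Mapping[str, str]  # label -> peak file (BED4/narrowPeak)
    gene_model: str
    interaction_sets: tuple[InteractionSetConfig, ...] = ()
    promoter_halfwidth_bp: int = DEFAULT_PROMOTER_HALFWIDTH
    proximity_mode: str = "overlap"
    merge_gap: int = 0
    merge_min_overlap: int = 1
    output_dir: str = "."
    strict_compat: bool = False

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one peak dataset is required")
        labels = [s.label for s in self.interaction_sets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate interaction-set labels: {labels}")

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [self.gene_model, *self.datasets.values()]
            + [s.path for s in self.interaction_sets]
            if not Path(p).is_file()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load from YAML/JSON; keyword overrides win over file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sets = tuple(
            InteractionSetConfig(**s) for s in raw.pop("interaction_sets", [])
        )
        raw.update(overrides)
        return cls(interaction_sets=sets, **raw)


@dataclass
class PipelineResult:
    table_path: Path
    manifest_path: Path
    records: list
    counts: dict[str, object] = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "datasets": dict(config.datasets),
            "gene_model": config.gene_model,
            "interaction_sets": [vars(s) for s in config.interaction_sets],
            "promoter_halfwidth_bp": config.promoter_halfwidth_bp,
            "proximity_mode": config.proximity_mode,
            "merge_gap": config.merge_gap,
            "merge_min_overlap": config.merge_min_overlap,
            "strict_compat": config.strict_compat,
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute merge -> classify -> link -> build -> write.

    Writes ``interactome.tsv``, the merged-peak BED, the provenance
    table and ``manifest.json`` into the output directory. Any stage
    failure removes partial outputs and re-raises with the stage name.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "table": outdir / "interactome.tsv",
        "merged_bed": outdir / "merged_peaks.bed",
        "provenance": outdir / "provenance.tsv",
        "manifest": outdir / "manifest.json",
    }

    stage = "read-inputs"
    try:
        if config.gene_model.endswith((".gtf", ".gtf.gz")):
            genes = read_gene_model_gtf(config.gene_model)
        else:
            genes = read_gene_model(config.gene_model)
        peak_sets = {
            label: read_peaks(path, dataset=label)
            for label, path in config.datasets.items()
        }

        stage = "merge-peaks"
        merged = merge_peak_sets(
            peak_sets, gap=config.merge_gap, min_overlap=config.merge_min_overlap
        )
        write_merged_bed(merged, outputs["merged_bed"])
        write_provenance(merged, outputs["provenance"])

        stage = "classify"
        assignments = classify_peaks(
            merged,
            genes,
            w=config.promoter_halfwidth_bp,
            proximity_mode=config.proximity_mode,  # type: ignore[arg-type]
        )
        enhancer_peaks = [
            p for p in merged if assignments[p.merged_id].klass == ENHANCER
        ]

        stage = "link"
        labels = [s.label for s in config.interaction_sets]
        if config.interaction_sets:
            loops = {
                s.label: load_interactions(
                    s.path,
                    genes,
                    w=config.promoter_halfwidth_bp,
                    dataset=s.label,
                    anchor_side=s.anchor_side,  # type: ignore[arg-type]
                    gene_column=s.gene_column,
                )
                for s in config.interaction_sets
            }
            links = assign_enhancers(enhancer_peaks, loops)
        else:
            links = []

        stage = "build-table"
        records = build_table(merged, assignments, links, labels)

        stage = "write-table"
        write_table(records, outputs["table"], strict_compat=config.strict_compat)
    except Exception:
        for p in outputs.values():
            p.unlink(missing_ok=True)
        logger.error("pipeline failed at stage %r", stage)
        raise

    n_prom = sum(1 for a in assignments.values() if a.klass == PROMOTER)
    n_enh = len(merged) - n_prom
    per_set = {}
    for label in labels:
        linked = sum(
            1
            for a in links
            if a.per_dataset.get(label) is not None
        )
        per_set[label] = {"linked": linked, "na": n_enh - linked}
    counts = {
        "peaks_in": {ds: len(ps) for ds, ps in peak_sets.items()},
        "merged_peaks": len(merged),
        "promoters": n_prom,
        "enhancers": n_enh,
        "interaction_sets": per_set,
    }
    manifest = {
        "tool": "cremap",
        "version": __version__,
        "config_hash": _config_hash(config),
        "inputs": {
            "gene_model": _sha256(config.gene_model),
            **{f"peaks:{ds}": _sha256(p) for ds, p in config.datasets.items()},
            **{
                f"loops:{s.label}": _sha256(s.path)
                for s in config.interaction_sets
            },
        },
        "counts": counts,
    }
    outputs["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return PipelineResult(
        table_path=outputs["table"],
        manifest_path=outputs["manifest"],
        records=records,
        counts=counts,
    )
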