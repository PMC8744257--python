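"""Config-driven orchestration: enrichment -> time course -> integration.

A pipeline run is described by a plain YAML mapping (paths + thresholds).
Every stage logs its inputs, parameters and record counts in/out, so claims
like "N proteins passing the filter" stay auditable, and all intermediates
are files: identical config + inputs give byte-identical outputs.  A stage
failure aborts the run, names the failing stage, and removes partial
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import enrichment, integrate, io_model, timecourse
from .errors import ConfigError, ProximatomeError, StageFailureError


@dataclass
class PipelineConfig:
    counts: str
    design: str
    annotations: str
    late_counts: Optional[str] = None
    late_design: Optional[str] = None
    external_table: Optional[str] = None
    omm_table: Optional[str] = None
    backend: str = "binomial"
    pseudocount: float = 1.0
    fc_min: float = 2.0
    fdr_max: float = 0.1
    ratio_threshold: float = 0.5
    omm_fdr_max: float = 0.1
    omm_log2fc_min: float = 0.0
    seed: int = 0
    outdir: str = "proximatome_out"

    def validate(self) -> None:
        for name in ("fdr_max", "omm_fdr_max"):
            value = getattr(self, name)
            if not 0 < value <= 1:
                raise ConfigError(f"{name} must lie in (0, 1], got {value}")
        if self.fc_min < 0 or self.pseudocount < 0:
            raise ConfigError("fc_min and pseudocount must be nonnegative")
        if self.ratio_threshold <= 0:
            raise ConfigError("ratio_threshold must be positive")
        if self.backend not in ("external", "binomial", "permutation"):
            raise ConfigError(f"unknown backend {self.backend!r}")
        if self.backend == "external" and not self.external_table:
            raise ConfigError("backend 'external' needs external_table")
        required = [self.counts, self.design, self.annotations]
        optional = [self.late_counts, self.late_design,
                    self.external_table, self.omm_table]
        for path in required + [p for p in optional if p]:
            if not Path(path).exists():
                raise ConfigError(f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all applicable stages; returns the JSON-ready summary dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    written: list[Path] = []
    summary: dict = {"parameters": {
        "backend": config.backend, "pseudocount": config.pseudocount,
        "fc_min": config.fc_min, "fdr_max": config.fdr_max,
        "ratio_threshold": config.ratio_threshold,
        "omm_fdr_max": config.omm_fdr_max,
        "omm_log2fc_min": config.omm_log2fc_min, "seed": config.seed,
    }}
    log_lines.append(f"parameters: {json.dumps(summary['parameters'], sort_keys=True)}")

    def _write(frame, name):
        path = outdir / name
        io_model.write_table(frame, path)
        written.append(path)
        return path

    def _stage(name, fn):
        log_lines.append(f"stage {name}: start")
        try:
            result = fn()
        except ProximatomeError:
            raise
        except Exception as exc:  # wrap unexpected errors with the stage name
            raise StageFailureError(name, str(exc)) from exc
        log_lines.append(f"stage {name}: done")
        return result

    try:
        annotations = _stage(
            "read_annotations",
            lambda: io_model.annotation_index(io_model.read_annotations(config.annotations)),
        )

        def _enrich(counts_path, design_path, tag):
            design = io_model.read_design(design_path)
            matrix = io_model.read_counts(counts_path, design)
            external = (
                io_model.read_external_table(config.external_table)
                if config.backend == "external" else None
            )
            records = enrichment.build_records(
                matrix, design, backend=config.backend, external=external,
                pseudocount=config.pseudocount,
                fc_min=config.fc_min, fdr_max=config.fdr_max,
            )
            passing = enrichment.filter_enriched(records, config.fc_min, config.fdr_max)
            _write(records, f"enrichment_{tag}.tsv")
            log_lines.append(
                f"stage enrichment_{tag}: {len(records)} proteins in, "
                f"{len(passing)} passing FC>{config.fc_min}, FDR<{config.fdr_max}"
            )
            summary[f"n_enriched_{tag}"] = int(len(passing))
            return records, passing

        records_early, passing_early = _stage(
            "enrichment_early", lambda: _enrich(config.counts, config.design, "early")
        )

        enriched_set = integrate.make_gene_set("enriched_early",
                                               passing_early["protein_id"])
        _, ann_summary = _stage(
            "annotate_enriched",
            lambda: integrate.annotate_sets(enriched_set, annotations),
        )
        ann_summary.pop("unannotated", None)
        summary["enriched_annotation"] = ann_summary
        log_lines.append(f"stage annotate_enriched: {json.dumps(ann_summary, sort_keys=True)}")

        if config.late_counts and config.late_design:
            records_late, passing_late = _stage(
                "enrichment_late",
                lambda: _enrich(config.late_counts, config.late_design, "late"),
            )

            def _timecourse():
                paired, only_early, only_late = timecourse.pair_timepoints(
                    records_early, records_late
                )
                classified = timecourse.classify_groups(paired, config.ratio_threshold)
                classified["is_mitochondrial"] = [
                    annotations[p].is_mitochondrial if p in annotations else False
                    for p in classified["protein_id"]
                ]
                _write(classified, "groups.tsv")
                composition = timecourse.group_composition(classified, annotations)
                log_lines.append(
                    f"stage timecourse: {len(classified)} classified, "
                    f"{len(only_early)} enriched only early, "
                    f"{len(only_late)} only late"
                )
                return composition, only_early, only_late

            composition, only_early, only_late = _stage("timecourse", _timecourse)
            summary["timecourse"] = {
                "groups": composition["groups"],
                "n_classified": composition["n_total"],
                "n_only_early": len(only_early),
                "n_only_late": len(only_late),
            }

        if config.omm_table:
            def _omm():
                table = io_model.read_omm_table(config.omm_table)
                omm_set = integrate.filter_omm_table(
                    table, config.omm_fdr_max, config.omm_log2fc_min
                )
                mito_members = [
                    p for p in enriched_set.members
                    if p in annotations and annotations[p].is_mitochondrial
                ]
                log_lines.append(
                    f"stage omm_overlap: {len(table)} mRNAs in, "
                    f"{len(omm_set)} passing filter"
                )
                if mito_members:
                    overlap = integrate.set_overlap(
                        integrate.make_gene_set("mito_enriched", mito_members), omm_set
                    )
                    return {
                        "n_omm": overlap.n_b, "n_mito_enriched": overlap.n_a,
                        "n_intersection": overlap.n_intersection,
                        "overlap_percent": overlap.overlap_percent,
                        "jaccard": overlap.jaccard,
                    }
                return {"n_omm": len(omm_set), "n_mito_enriched": 0}

            summary["omm_overlap"] = _stage("omm_overlap", _omm)

        summary_path = outdir / "summary.json"
        summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        written.append(summary_path)
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        return summary
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
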