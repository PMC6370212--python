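"""End-to-end pipeline: identify -> quantify -> express -> integrate.

Runs whichever stages the configuration provides inputs for, writes every
stage's artifacts plus a single JSON report, and records completion state in
a MANIFEST so partial failures leave an auditable trail.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import fileio
from .annotate import AnnotationParams, annotate_dataset
from .masscalc import BuildingBlockLibrary, default_library
from .netstat import build_network, correlation_matrix
from .quantify import DEFAULT_IS_NAME, hcl_rows, normalize_to_is, stage_summary
from .expression import DEFAULT_HOUSEKEEPING, relative_expression

logger = logging.getLogger("anthonet.pipeline")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the MANIFEST records which."""


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run.

    Stages are activated by the presence of their inputs: ``spectra`` for
    annotation, ``areas`` for quantification, ``ct`` + ``curves`` for
    expression; the network stage needs both tables and can be disabled.
    """

    out_dir: str | Path
    spectra: str | Path | None = None
    areas: str | Path | None = None
    ct: str | Path | None = None
    curves: str | Path | None = None
    library: str | Path | None = None  # None -> built-in default library
    seed: int = 0
    params: AnnotationParams = field(default_factory=AnnotationParams)
    is_name: str = DEFAULT_IS_NAME
    housekeeping: str = DEFAULT_HOUSEKEEPING
    alpha: float = 0.05
    edge_threshold: float = 0.65
    run_network: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "params" in raw:
            raw["params"] = AnnotationParams(**raw["params"])
        return cls(**raw)


def _load_library(config: PipelineConfig) -> BuildingBlockLibrary:
    if config.library is None:
        return default_library()
    return BuildingBlockLibrary.from_json(Path(config.library).read_text())


def _library_hash(library: BuildingBlockLibrary) -> str:
    return hashlib.sha1(repr(library.fingerprint()).encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages and return the JSON-ready report.

    Artifacts land under ``config.out_dir``; MANIFEST.json records, for each
    stage, whether it completed, was skipped, or failed.  On failure the
    partial outputs are retained and :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    library = _load_library(config)
    manifest: dict[str, str] = {}
    report: dict = {
        "seed": config.seed,
        "library_hash": _library_hash(library),
    }
    logger.info("pipeline start: seed=%d library=%s", config.seed, report["library_hash"])

    abundance = None
    expr = None

    def finish_manifest() -> None:
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    stage = "annotate"
    try:
        if config.spectra is None:
            manifest[stage] = "skipped"
        else:
            spectra_path = Path(config.spectra)
            if spectra_path.suffix.lower() == ".mgf":
                spectra = fileio.read_mgf(spectra_path)
            else:
                spectra = fileio.read_spectra_csv(spectra_path)
            if not spectra:
                raise ValueError(f"no spectra found in {spectra_path}")
            annotations, summary = annotate_dataset(spectra, library, config.params)
            fileio.write_annotations_tsv(annotations, out / "annotations.tsv")
            fileio.write_annotations_json(annotations, out / "annotations.json")
            report["annotation"] = {
                "n_spectra": summary.n_spectra,
                "per_aglycone": summary.per_aglycone,
                "n_full_composition": summary.n_full_composition,
                "n_class_only": summary.n_class_only,
                "n_unidentified": summary.n_unidentified,
            }
            manifest[stage] = "completed"
            logger.info("annotated %d spectra", summary.n_spectra)

        stage = "quantify"
        if config.areas is None:
            manifest[stage] = "skipped"
        else:
            areas = fileio.read_area_table(config.areas)
            abundance = normalize_to_is(areas, is_name=config.is_name)
            summary = stage_summary(abundance)
            fileio.write_abundance_csv(abundance, out / "abundance.csv")
            fileio.write_stage_summary_csv(summary, out / "stage_summary.csv")
            if len(abundance.values) >= 2:
                hcl = hcl_rows(abundance)
                (out / "metabolite_dendrogram.nwk").write_text(hcl.newick + "\n")
            report["stage_percent"] = {
                stage_id: {
                    compound: round(float(v), 4)
                    for compound, v in summary.percent[stage_id].items()
                }
                for stage_id in summary.percent.columns
            }
            manifest[stage] = "completed"
            logger.info("quantified %d compounds", len(abundance.values))

        stage = "expression"
        if config.ct is None or config.curves is None:
            manifest[stage] = "skipped"
        else:
            ct = fileio.read_ct_table(config.ct)
            curves = fileio.read_curves_csv(config.curves)
            expr = relative_expression(ct, curves, housekeeping=config.housekeeping)
            levels = expr.levels.copy()
            levels.columns = [f"{t}_r{b}" for t, b in levels.columns]
            levels.to_csv(out / "expression.csv", index_label="gene")
            expr.tissue_mean.to_csv(out / "expression_tissue_mean.csv", index_label="gene")
            expr.tissue_sd.to_csv(out / "expression_tissue_sd.csv", index_label="gene")
            manifest[stage] = "completed"
            logger.info("expression for %d genes", len(expr.levels))

        stage = "network"
        if not config.run_network or abundance is None or expr is None:
            manifest[stage] = "skipped" if not config.run_network else "unavailable"
        else:
            levels = expr.levels.drop(index=expr.housekeeping, errors="ignore")
            levels.columns = [f"{t}_r{b}" for t, b in levels.columns]
            common = [c for c in abundance.values.columns if c in levels.columns]
            if len(common) < 3:
                raise ValueError(
                    "network stage needs >= 3 samples shared between the "
                    "metabolite and expression tables"
                )
            merged = pd.concat(
                [abundance.values[common], levels[common]], axis=0
            )
            types = pd.Series(
                ["metabolite"] * len(abundance.values)
                + ["transcript"] * len(levels),
                index=merged.index,
            )
            cr = correlation_matrix(merged, alpha=config.alpha, feature_types=types)
            net = build_network(cr, display_threshold=config.edge_threshold)
            fileio.write_network_outputs(cr, net, out)
            report["network"] = {
                "n_edges": int(len(net.edges)),
                "NS": round(float(net.NS), 4),
                "ns": {k: round(float(v), 4) for k, v in net.ns.items()},
            }
            manifest[stage] = "completed"
            logger.info("network: %d edges, NS=%.3f", len(net.edges), net.NS)
    except Exception as exc:
        manifest[stage] = f"failed: {exc}"
        finish_manifest()
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    finish_manifest()
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
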