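"""Readers and writers for the pipeline's file formats.

MGF (via pyteomics) and a simple CSV dialect carry spectra; long-format CSV
tables carry peak areas and Ct values; annotation reports go out as TSV
(table-style) plus JSON (full candidate lists); networks as edge-list CSV and
GraphML; dendrograms as Newick.  All CSV files are UTF-8, comma-separated,
header row mandatory, decimal point.  m/z values are serialized with six
decimals to preserve ppm-level semantics.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .annotate import Annotation, Spectrum
from .expression import StandardCurve
from .netstat import CorrelationResult, NetworkSummary, to_graphml
from .quantify import AREA_COLUMNS, AbundanceTable, StageSummary

__all__ = [
    "read_mgf",
    "write_mgf",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_area_table",
    "write_area_table",
    "read_ct_table",
    "write_ct_table",
    "read_curves_csv",
    "write_curves_csv",
    "write_annotations_tsv",
    "write_annotations_json",
    "write_abundance_csv",
    "write_stage_summary_csv",
    "write_network_outputs",
]


# --------------------------------------------------------------------------
# spectra


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read singly charged positive-mode spectra from an MGF file.

    TITLE becomes the spectrum id, PEPMASS the precursor m/z, RTINSECONDS
    (optional) the retention time in minutes.  Any charge other than 1+ is
    out of model and rejected.
    """
    spectra: list[Spectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry.get("params", {})
            charges = params.get("charge")
            if charges is not None and list(charges) != [1]:
                raise ValueError(
                    f"spectrum {i}: only singly charged positive ions are "
                    f"supported, got charge {list(charges)}"
                )
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                raise ValueError(f"spectrum {i}: missing PEPMASS")
            title = str(params.get("title", f"spectrum{i}"))
            rt_s = params.get("rtinseconds")
            fragments = tuple(
                (float(mz), float(inten))
                for mz, inten in zip(entry["m/z array"], entry["intensity array"])
            )
            spectra.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=float(pepmass[0]),
                    fragments=fragments,
                    retention_time=float(rt_s) / 60.0 if rt_s is not None else None,
                )
            )
    return spectra


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        params = {"title": s.spectrum_id, "pepmass": s.precursor_mz, "charge": "1+"}
        if s.retention_time is not None:
            params["rtinseconds"] = s.retention_time * 60.0
        entries.append(
            {
                "m/z array": np.array([mz for mz, _ in s.fragments]),
                "intensity array": np.array([i for _, i in s.fragments]),
                "params": params,
            }
        )
    _mgf.write(entries, output=str(path), file_mode="w")


SPECTRA_CSV_COLUMNS = ("spectrum_id", "precursor_mz", "fragment_mz", "fragment_intensity")


def read_spectra_csv(path: str | Path) -> list[Spectrum]:
    """Read the documented CSV spectra dialect (one row per fragment)."""
    df = pd.read_csv(path)
    missing = set(SPECTRA_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spectra CSV missing columns: {sorted(missing)}")
    spectra = []
    for sid, group in df.groupby("spectrum_id", sort=False):
        precursors = group["precursor_mz"].unique()
        if len(precursors) != 1:
            raise ValueError(f"spectrum {sid!r} has conflicting precursor m/z")
        fragments = tuple(
            (float(mz), float(inten))
            for mz, inten in zip(group["fragment_mz"], group["fragment_intensity"])
            if not np.isnan(mz)
        )
        spectra.append(
            Spectrum(
                spectrum_id=str(sid),
                precursor_mz=float(precursors[0]),
                fragments=fragments,
            )
        )
    return spectra


def write_spectra_csv(spectra: list[Spectrum], path: str | Path) -> None:
    rows = []
    for s in spectra:
        for mz, inten in s.fragments:
            rows.append((s.spectrum_id, round(s.precursor_mz, 6), round(mz, 6), inten))
    pd.DataFrame(rows, columns=list(SPECTRA_CSV_COLUMNS)).to_csv(path, index=False)


# --------------------------------------------------------------------------
# tables


def read_area_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(AREA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"area table missing columns: {sorted(missing)}")
    return df


def write_area_table(areas: pd.DataFrame, path: str | Path) -> None:
    areas.to_csv(path, index=False)


CT_CSV_COLUMNS = ("gene", "tissue", "bio_rep", "tech_rep", "ct")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CT_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    return df


def write_ct_table(ct: pd.DataFrame, path: str | Path) -> None:
    ct.to_csv(path, index=False)


def read_curves_csv(path: str | Path) -> dict[str, StandardCurve]:
    df = pd.read_csv(path)
    required = {"gene", "slope", "intercept"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curves CSV missing columns: {sorted(missing)}")
    curves = {}
    for row in df.itertuples(index=False):
        curves[str(row.gene)] = StandardCurve(
            gene=str(row.gene),
            slope=float(row.slope),
            intercept=float(row.intercept),
            r_squared=float(getattr(row, "r_squared", float("nan"))),
        )
    return curves


def write_curves_csv(curves: dict[str, StandardCurve], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene": c.gene,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "efficiency": c.efficiency,
            }
            for c in curves.values()
        ]
    ).to_csv(path, index=False)


# --------------------------------------------------------------------------
# annotation reports


def write_annotations_tsv(annotations: list[Annotation], path: str | Path) -> None:
    """Identification-table-style TSV (one row per spectrum)."""
    rows = []
    for ann in annotations:
        top = ann.top_candidate
        explained = "/".join(
            f"{e.mz:.5f}" for e in ann.fragment_explanations if e.explained
        )
        rows.append(
            {
                "spectrum_id": ann.spectrum_id,
                "rt_min": "" if ann.retention_time is None else f"{ann.retention_time:.2f}",
                "experimental_mz": f"{ann.precursor_mz:.6f}",
                "explained_fragments": explained,
                "formula": top.composition.total_formula.hill() if top else "",
                "assignment": ann.display_name,
                "ppm_error": f"{top.ppm_error:.2f}" if top else "",
                "aglycone": ann.aglycone_detected or "",
                "uv_class": ann.uv_class,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _annotation_to_dict(ann: Annotation) -> dict:
    return {
        "spectrum_id": ann.spectrum_id,
        "precursor_mz": round(ann.precursor_mz, 6),
        "retention_time_min": ann.retention_time,
        "aglycone_detected": ann.aglycone_detected,
        "uv_class": ann.uv_class,
        "display_name": ann.display_name,
        "class_only": ann.is_class_only,
        "candidates": [
            {
                "aglycone": c.composition.aglycone_id,
                "decorations": list(c.composition.decorations),
                "formula": c.composition.total_formula.hill(),
                "theoretical_mz": round(c.composition.cation_mz, 6),
                "ppm_error": round(c.ppm_error, 3),
                "fragments_explained_fraction": round(
                    c.fragments_explained_fraction, 4
                ),
            }
            for c in ann.candidates
        ],
        "fragments": [
            {
                "mz": round(e.mz, 6),
                "kind": e.kind,
                "loss": list(e.loss),
                "residue_id": e.residue_id,
                "ppm_error": None if e.ppm_error is None else round(e.ppm_error, 3),
            }
            for e in ann.fragment_explanations
        ],
    }


def write_annotations_json(annotations: list[Annotation], path: str | Path) -> None:
    payload = [_annotation_to_dict(a) for a in annotations]
    Path(path).write_text(json.dumps(payload, indent=2))


# --------------------------------------------------------------------------
# quantification / network outputs


def write_abundance_csv(ab: AbundanceTable, path: str | Path) -> None:
    ab.values.to_csv(path, index_label="compound_id")


def write_stage_summary_csv(summary: StageSummary, path: str | Path) -> None:
    parts = []
    for name, df in (
        ("mean", summary.mean),
        ("sd", summary.sd),
        ("percent", summary.percent),
    ):
        renamed = df.copy()
        renamed.columns = [f"{stage}_{name}" for stage in df.columns]
        parts.append(renamed)
    pd.concat(parts, axis=1).to_csv(path, index_label="compound_id")


def write_network_outputs(
    cr: CorrelationResult, net: NetworkSummary, out_dir: str | Path
) -> dict[str, str]:
    """Write rho/p matrices, edge list, GraphML and an ns/NS JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "rho": out / "correlation_rho.csv",
        "pval": out / "correlation_pval.csv",
        "edges": out / "edges.csv",
        "graphml": out / "network.graphml",
        "summary": out / "network_summary.json",
    }
    cr.rho.to_csv(paths["rho"], index_label="feature")
    cr.pval.to_csv(paths["pval"], index_label="feature")
    net.edges.to_csv(paths["edges"], index=False)
    nx.write_graphml(to_graphml(cr, net), paths["graphml"])
    summary = {
        "n_features": len(cr.features),
        "n_samples": cr.n_samples,
        "alpha": cr.alpha,
        "display_threshold": net.display_threshold,
        "n_edges": int(len(net.edges)),
        "ns": {k: round(float(v), 6) for k, v in net.ns.items()},
        "NS": round(float(net.NS), 6),
    }
    paths["summary"].write_text(json.dumps(summary, indent=2))
    return {k: str(v) for k, v in paths.items()}
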