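"""Synthetic-data generator with known ground truth.

Emulates the three experimental inputs of a petal-pigmentation study:

* decorated anthocyanin structures and their MS/MS spectra — fragmentation
  produces one ion per single-residue loss plus the aglycone ion (the
  annotator's search model is deliberately more permissive: it also allows
  multi-residue losses, so the generator never mirrors the code under test);
* stage-structured metabolite peak-area tables (stages x biological
  replicates, spiked internal standard, lognormal replicate variation);
* qRT-PCR Ct tables driven by the same latent sample draws, so transcript
  and metabolite levels are coupled the way a shared developmental program
  couples them in real petals.

Cross-feature correlation is induced by a Gaussian copula on the log scale:
a target correlation matrix (or equicorrelation scalar) shapes the joint
replicate noise, while per-stage trend vectors shape the means.  Everything
is reproducible from an integer seed.

Default condition levels mirror the emulated study design: stages S1/S3/S5
with 3 biological and 3 technical replicates, 2 ppm mass error, lognormal
sigma 0.25 on replicate variation, Ct sigma 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotate import Spectrum
from .expression import PERFECT_SLOPE, StandardCurve
from .masscalc import (
    BuildingBlockLibrary,
    Composition,
    ELECTRON_MASS,
    compose,
)

__all__ = [
    "SimulationDesign",
    "SimulatedTables",
    "SyntheticTruth",
    "default_design",
    "ns_recovery_design",
    "sample_structures",
    "simulate_spectrum",
    "simulate_tables",
    "simulate_dilution_series",
]


@dataclass
class SimulationDesign:
    """Study conditions for table simulation.

    Trends are per-stage means of log fold-over-IS (metabolites) or log
    relative quantity (genes), natural-log scale.  ``correlation`` is the
    latent Gaussian-copula correlation across all features (metabolites
    first, then genes, each sorted by name): ``None`` for independence, a
    scalar for equicorrelation, or a full positive-semidefinite matrix.
    """

    metabolite_trends: dict[str, tuple[float, ...]]
    gene_trends: dict[str, tuple[float, ...]]
    stages: tuple[str, ...] = ("S1", "S3", "S5")
    n_reps: int = 3
    correlation: float | np.ndarray | None = None
    lognormal_sigma: float = 0.25
    area_sigma: float = 0.0
    ct_sigma: float = 0.2
    n_tech_reps: int = 3
    is_name: str = "formononetin"
    is_area: float = 1.0e6
    curve_slope: float = PERFECT_SLOPE
    curve_intercept: float = 33.0

    def feature_names(self) -> list[str]:
        return sorted(self.metabolite_trends) + sorted(self.gene_trends)

    def validate(self) -> None:
        n_stages = len(self.stages)
        for name, trend in {**self.metabolite_trends, **self.gene_trends}.items():
            if len(trend) != n_stages:
                raise ValueError(
                    f"trend for {name!r} has {len(trend)} values, expected {n_stages}"
                )
        if self.n_reps < 1 or self.n_tech_reps < 1:
            raise ValueError("replicate counts must be >= 1")
        self.correlation_matrix()  # raises on a non-PSD design

    def correlation_matrix(self) -> np.ndarray:
        p = len(self.feature_names())
        corr = self.correlation
        if corr is None:
            return np.eye(p)
        if np.isscalar(corr):
            r = float(corr)
            mat = np.full((p, p), r)
            np.fill_diagonal(mat, 1.0)
        else:
            mat = np.asarray(corr, dtype=float)
            if mat.shape != (p, p):
                raise ValueError(
                    f"correlation matrix shape {mat.shape} != ({p}, {p})"
                )
        if not np.allclose(mat, mat.T, atol=1e-12):
            raise ValueError("correlation design must be symmetric")
        eigmin = float(np.linalg.eigvalsh(mat).min())
        if eigmin < -1e-10:
            raise ValueError(
                f"correlation design is not positive semidefinite "
                f"(min eigenvalue {eigmin:.3e})"
            )
        return mat


@dataclass
class SyntheticTruth:
    """Ground truth from which every simulated output is derivable."""

    seed: int
    design: SimulationDesign
    true_abundances: pd.DataFrame  # compounds x samples (fold-over-IS)
    true_expression: pd.DataFrame  # genes x (tissue, bio_rep)
    curves: dict[str, StandardCurve]


@dataclass
class SimulatedTables:
    areas: pd.DataFrame  # long format for quantify.normalize_to_is
    ct: pd.DataFrame  # long format for expression.relative_expression
    truth: SyntheticTruth


def default_design() -> SimulationDesign:
    """A petal-development design emulating the study's qualitative trends.

    Most metabolites and the core biosynthetic genes rise from budlet (S1)
    to open flower (S5); the 5-glucosyltransferase declines (as observed for
    its transcript), the 5-acyltransferase stays flat, and the late
    acylated compounds are essentially absent at S1.  Trend values are
    natural-log fold-over-IS / relative quantities at (S1, S3, S5).
    """
    return SimulationDesign(
        metabolite_trends={
            "pel_glc": (0.5, 1.4, 2.2),
            "pel_diglc": (0.4, 1.5, 2.1),
            "pel_rut": (-0.5, 0.8, 1.9),
            "pel_mal_glc": (-0.8, 0.4, 1.5),
            "pel_coum_glc": (-0.7, 0.5, 1.6),
            "pel_rut_glc": (-2.0, 0.2, 1.2),
            "pel_fer_caff_triglc": (-2.5, -0.3, 0.9),
            "pel_fer_coum_triglc": (-2.4, -0.2, 1.0),
            "pel_caff_glc_mal_glc": (-2.2, 0.0, 0.8),
            "pel_coum_glc_mal_glc": (-2.3, 0.3, 0.9),
            "pel_mal_glc_glc": (-2.1, -0.1, 1.1),
        },
        gene_trends={
            "DFR": (0.0, 1.2, 2.0),
            "ANS": (0.2, 1.3, 2.1),
            "GT3": (0.1, 1.1, 1.9),
            "GT5": (1.5, 0.6, 0.2),
            "AT5": (0.8, 0.9, 0.85),
        },
    )


def ns_recovery_design(
    target_mean_abs_rho: float = 0.76,
    n_features: int = 16,
) -> SimulationDesign:
    """Flat-trend equicorrelation design for network-strength recovery.

    With flat stage trends the only cross-feature structure is the copula,
    so the designed unconditional mean pairwise |rho| equals the
    equicorrelation target (0.76 by default) up to the mild lognormal
    attenuation (< 0.01 at sigma 0.25).  Measurement noise is switched off:
    Ct noise attenuates gene-pair correlations by the classical reliability
    product sqrt(lambda_i lambda_j), which is a property of the assay, not
    of the correlation design this experiment calibrates.
    """
    n_genes = 5
    n_met = n_features - n_genes
    flat = (0.0, 0.0, 0.0)
    return SimulationDesign(
        metabolite_trends={f"met{i:02d}": flat for i in range(n_met)},
        gene_trends={f"gene{i}": flat for i in range(n_genes)},
        correlation=target_mean_abs_rho,
        ct_sigma=0.0,
        area_sigma=0.0,
    )


# --------------------------------------------------------------------------
# structures and spectra


def sample_structures(
    n: int,
    library: BuildingBlockLibrary,
    seed: int,
    aglycones: tuple[str, ...] = ("pelargonidin",),
    max_glycosyl: int = 3,
    max_acyl: int = 2,
) -> list[Composition]:
    """Draw ``n`` distinct decorated structures uniformly from the lattice.

    The default aglycone pool is pelargonidin only (an orange-gentian
    scenario); decoration bounds reflect the largest observed compounds
    (three glycosyls, two acyls).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    import itertools

    glycosyl_ids = sorted(b.id for b in library.glycosyls())
    acyl_ids = sorted(b.id for b in library.acyls())

    def multisets(ids, max_total):
        for total in range(max_total + 1):
            yield from itertools.combinations_with_replacement(ids, total)

    pool: list[Composition] = []
    for agl in sorted(aglycones):
        for gly in multisets(glycosyl_ids, max_glycosyl):
            for acyl in multisets(acyl_ids, max_acyl):
                pool.append(compose(agl, gly + acyl, library))
    if n > len(pool):
        raise ValueError(
            f"bounds admit only {len(pool)} distinct compositions, requested {n}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(idx)]


def simulate_spectrum(
    structure: Composition,
    library: BuildingBlockLibrary,
    seed: int,
    mz_sigma_ppm: float = 2.0,
    n_decoys: int = 2,
    include_residue_ions: bool = False,
    spectrum_id: str | None = None,
) -> Spectrum:
    """MS/MS spectrum of a decorated structure with ppm-scale mass error.

    Fragments: one ion per distinct single-residue loss, the aglycone ion
    (full-decoration loss), optional free glycosyl residue ions, and
    ``n_decoys`` uniform-random decoy peaks.  Intensities follow a
    decreasing lognormal profile; every m/z carries independent Gaussian
    relative error of ``mz_sigma_ppm`` ppm.
    """
    rng = np.random.default_rng(seed)
    precursor_theo = structure.cation_mz

    targets: list[float] = []
    seen: set[float] = set()

    def add(mz: float) -> None:
        key = round(mz, 6)
        if key not in seen and mz < precursor_theo - 1.0:
            seen.add(key)
            targets.append(mz)

    for block_id in sorted(set(structure.decorations)):
        add(precursor_theo - library[block_id].residue_mass)
    if structure.decorations:
        aglycone_mz = (
            library[structure.aglycone_id].residue_mass - ELECTRON_MASS
        )
        add(aglycone_mz)
    if include_residue_ions:
        for block_id in sorted(set(structure.decorations)):
            block = library[block_id]
            if block.block_class == "glycosyl":
                add(block.residue_mass)
    targets.sort(reverse=True)

    def jitter(mz: float) -> float:
        return mz * (1.0 + rng.normal(0.0, mz_sigma_ppm * 1e-6))

    precursor = jitter(precursor_theo)
    fragments: list[tuple[float, float]] = []
    for k, mz in enumerate(targets):
        intensity = 1000.0 * np.exp(-0.4 * k) * np.exp(rng.normal(0.0, 0.3))
        fragments.append((jitter(mz), float(intensity)))
    for _ in range(n_decoys):
        if precursor_theo - 10.0 <= 120.0:
            break
        decoy_mz = rng.uniform(120.0, precursor_theo - 10.0)
        fragments.append((decoy_mz, float(rng.uniform(1.0, 50.0))))
    fragments.sort(key=lambda f: -f[1])

    if spectrum_id is None:
        spectrum_id = f"sim-{structure.aglycone_id}-" + "-".join(
            structure.decorations or ("bare",)
        )
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor,
        fragments=tuple(fragments),
    )


# --------------------------------------------------------------------------
# stage-structured tables


def simulate_tables(design: SimulationDesign, seed: int) -> SimulatedTables:
    """Peak-area and Ct tables driven by shared latent per-sample draws.

    For each (stage, replicate) sample a copula-correlated Gaussian vector z
    perturbs the stage trend on the log scale; metabolite fold-over-IS and
    gene quantities are exp(trend + sigma * z).  Areas then follow from the
    (noisy-but-cancelling) internal-standard area, split into two fragment
    ions; Ct values follow each gene's standard curve with additive Gaussian
    cycle noise per technical replicate.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    metabolites = sorted(design.metabolite_trends)
    genes = sorted(design.gene_trends)
    features = metabolites + genes
    p = len(features)

    corr = design.correlation_matrix()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(p))

    samples = [
        (stage, rep)
        for stage in design.stages
        for rep in range(1, design.n_reps + 1)
    ]
    sample_ids = [f"{stage}_r{rep}" for stage, rep in samples]

    latent = np.empty((p, len(samples)))
    for j, (stage, _) in enumerate(samples):
        stage_idx = design.stages.index(stage)
        trend = np.array(
            [design.metabolite_trends[m][stage_idx] for m in metabolites]
            + [design.gene_trends[g][stage_idx] for g in genes]
        )
        z = chol @ rng.standard_normal(p)
        latent[:, j] = trend + design.lognormal_sigma * z
    values = np.exp(latent)

    true_abundances = pd.DataFrame(
        values[: len(metabolites)], index=metabolites, columns=sample_ids
    )
    gene_quantities = pd.DataFrame(
        values[len(metabolites):], index=genes, columns=sample_ids
    )

    # ---- peak-area table --------------------------------------------------
    frag_split = (0.6, 0.4)  # two most abundant fragment ions per compound
    area_rows = []
    for j, ((stage, rep), sample_id) in enumerate(zip(samples, sample_ids)):
        is_total = design.is_area * np.exp(
            rng.normal(0.0, design.lognormal_sigma) if design.lognormal_sigma else 0.0
        )
        for rank, frac in enumerate(frag_split, start=1):
            area_rows.append(
                (design.is_name, sample_id, stage, rep, rank, is_total * frac)
            )
        for compound in metabolites:
            total = true_abundances.at[compound, sample_id] * is_total
            for rank, frac in enumerate(frag_split, start=1):
                area = total * frac
                if design.area_sigma:
                    area *= np.exp(rng.normal(0.0, design.area_sigma))
                area_rows.append((compound, sample_id, stage, rep, rank, area))
    areas = pd.DataFrame(
        area_rows,
        columns=["compound_id", "sample_id", "stage", "replicate", "fragment_rank", "area"],
    )

    # ---- Ct table ---------------------------------------------------------
    curves = {
        g: StandardCurve(
            gene=g,
            slope=design.curve_slope,
            intercept=design.curve_intercept,
            r_squared=1.0,
        )
        for g in genes + ["UBQ"]
    }
    ct_rows = []
    for (stage, rep), sample_id in zip(samples, sample_ids):
        quantities = {g: gene_quantities.at[g, sample_id] for g in genes}
        quantities["UBQ"] = 1.0  # housekeeping reference, constant by design
        for gene, q in quantities.items():
            curve = curves[gene]
            ct_base = curve.intercept + curve.slope * np.log10(q)
            for tech in range(1, design.n_tech_reps + 1):
                noise = rng.normal(0.0, design.ct_sigma) if design.ct_sigma else 0.0
                ct_rows.append((gene, stage, rep, tech, ct_base + noise))
    ct = pd.DataFrame(ct_rows, columns=["gene", "tissue", "bio_rep", "tech_rep", "ct"])

    true_expression = gene_quantities.copy()
    true_expression.columns = pd.MultiIndex.from_tuples(
        samples, names=["tissue", "bio_rep"]
    )
    truth = SyntheticTruth(
        seed=seed,
        design=design,
        true_abundances=true_abundances,
        true_expression=true_expression,
        curves=curves,
    )
    return SimulatedTables(areas=areas, ct=ct, truth=truth)


def simulate_dilution_series(
    curve: StandardCurve,
    dilutions_ng: tuple[float, ...] = (100.0, 10.0, 1.0, 0.16),
    ct_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Ct readings for a serial-dilution standard-curve experiment."""
    rng = np.random.default_rng(seed)
    ng = np.asarray(dilutions_ng, dtype=float)
    ct = curve.intercept + curve.slope * np.log10(ng)
    if ct_sigma:
        ct = ct + rng.normal(0.0, ct_sigma, size=ng.shape)
    return ng, ct
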