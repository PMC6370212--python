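"""qRT-PCR standard-curve quantification with housekeeping normalization.

Transcript levels are interpolated from per-gene dilution standard curves
(Ct regressed on log10 template amount), then normalized to a housekeeping
gene (ubiquitin by default).  This is classical standard-curve relative
quantification, not the delta-delta-Ct shortcut: each gene's own fitted
slope absorbs its amplification efficiency.

Layout conventions: a long-format Ct table with one row per well
(gene, tissue, bio_rep, tech_rep, ct).  Technical replicates are averaged on
the quantity scale before normalization; biological replicates are reported
as mean +/- sample SD per tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_HOUSEKEEPING",
    "StandardCurve",
    "ExpressionResult",
    "fit_standard_curve",
    "relative_expression",
]

DEFAULT_HOUSEKEEPING = "UBQ"

CT_COLUMNS = ("gene", "tissue", "bio_rep", "tech_rep", "ct")

#: Slope of a perfectly efficient (doubling) reaction: -1/log10(2).
PERFECT_SLOPE = -1.0 / np.log10(2.0)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution line Ct = intercept + slope * log10(ng)."""

    gene: str
    slope: float  # Ct per log10 ng; negative for a valid series
    intercept: float  # Ct at 1 ng
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Per-cycle amplification gain minus one: 10**(-1/slope) - 1."""
        return 10.0 ** (-1.0 / self.slope) - 1.0

    def quantity(self, ct: np.ndarray | float) -> np.ndarray | float:
        """Template amount (ng-equivalents) interpolated from the curve."""
        return 10.0 ** ((np.asarray(ct, float) - self.intercept) / self.slope)


@dataclass
class ExpressionResult:
    """Normalized expression levels (housekeeping gene == 1 by construction)."""

    levels: pd.DataFrame  # genes x (tissue, bio_rep) normalized levels
    tissue_mean: pd.DataFrame  # genes x tissues
    tissue_sd: pd.DataFrame  # genes x tissues
    housekeeping: str


def fit_standard_curve(
    gene: str,
    dilution_ng: np.ndarray | list[float],
    ct: np.ndarray | list[float],
    monotone_warn_cycles: float = 0.5,
) -> StandardCurve:
    """Least-squares line of Ct on log10(template ng).

    Requires at least 3 dilution points spanning at least 2 decades (e.g.
    the conventional 100-0.16 ng series).  A Ct series that *decreases* with
    dilution by more than ``monotone_warn_cycles`` anywhere triggers a
    warning (pipetting or inhibition trouble), not an error.
    """
    ng = np.asarray(dilution_ng, dtype=float)
    ct_arr = np.asarray(ct, dtype=float)
    if ng.shape != ct_arr.shape:
        raise ValueError("dilution and Ct arrays must have equal length")
    if ng.size < 3:
        raise ValueError(f"standard curve needs >= 3 dilution points, got {ng.size}")
    if (ng <= 0).any():
        raise ValueError("dilution amounts must be positive")
    log_ng = np.log10(ng)
    if log_ng.max() - log_ng.min() < 2.0:
        raise ValueError("dilution series must span at least 2 log10 units")
    order = np.argsort(log_ng)[::-1]  # most concentrated first
    diffs = np.diff(ct_arr[order])  # Ct should rise as template dilutes
    if (diffs < -monotone_warn_cycles).any():
        warnings.warn(
            f"{gene}: Ct decreases with dilution by more than "
            f"{monotone_warn_cycles} cycles; check the series",
            stacklevel=2,
        )
    fit = stats.linregress(log_ng, ct_arr)
    return StandardCurve(
        gene=gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def relative_expression(
    ct_table: pd.DataFrame,
    curves: dict[str, StandardCurve],
    housekeeping: str = DEFAULT_HOUSEKEEPING,
    detection_floor: float = 1e-6,
) -> ExpressionResult:
    """Standard-curve quantities normalized to the housekeeping gene.

    Per well: quantity = 10**((Ct - intercept)/slope).  Technical replicates
    are averaged on the quantity scale, the housekeeping quantity of the same
    (tissue, biological replicate) divides each gene's quantity, and
    biological replicates are summarized as mean +/- SD per tissue.

    Normalized levels below ``detection_floor`` times the gene's maximum
    level are reported as 0 (tissues genuinely lacking the transcript, e.g.
    leaf for petal-specific genes, otherwise acquire meaningless tiny
    values from late nonspecific Ct).
    """
    missing_cols = set(CT_COLUMNS) - set(ct_table.columns)
    if missing_cols:
        raise ValueError(f"Ct table missing columns: {sorted(missing_cols)}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    genes = sorted(ct_table["gene"].unique())
    if housekeeping not in genes:
        raise ValueError(f"housekeeping gene {housekeeping!r} absent from Ct table")
    missing_curves = [g for g in genes if g not in curves]
    if missing_curves:
        raise ValueError(f"no standard curve for genes: {missing_curves}")

    work = ct_table.copy()
    work["quantity"] = [
        curves[g].quantity(c) for g, c in zip(work["gene"], work["ct"])
    ]
    # Average technical replicates on the quantity scale.
    q = (
        work.groupby(["gene", "tissue", "bio_rep"], sort=True)["quantity"]
        .mean()
        .unstack(["tissue", "bio_rep"])
    )
    hk = q.loc[housekeeping]
    if (hk <= 0).any() or hk.isna().any():
        raise ValueError("housekeeping quantity missing or non-positive in a sample")
    levels = q.div(hk, axis=1)
    if levels.isna().any().any():
        bad = levels.columns[levels.isna().any(axis=0)].tolist()
        raise ValueError(f"missing Ct measurements for samples: {bad}")
    # Detection floor, per gene.
    floor = levels.max(axis=1) * detection_floor
    levels = levels.where(levels.ge(floor, axis=0), 0.0)

    tissue_grouped = levels.T.groupby(level="tissue", sort=False)
    tissue_mean = tissue_grouped.mean().T
    tissue_sd = tissue_grouped.std(ddof=1).fillna(0.0).T
    return ExpressionResult(
        levels=levels,
        tissue_mean=tissue_mean,
        tissue_sd=tissue_sd,
        housekeeping=housekeeping,
    )
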