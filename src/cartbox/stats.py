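"""Threshold-finding ROC grids and mixed-model variance explained.

The ROC layer sweeps a 40 x 40 grid: 40 reference cutoffs (disease
positive when the reference, e.g. infarct transmurality, is >= cutoff)
against 40 predictor thresholds (test positive when the predictor,
e.g. unipolar voltage, is <= threshold; direction configurable).  Per
cutoff the AUC is the trapezoid area of the empirical (1 - specificity,
sensitivity) curve with (0,0) and (1,1) anchors; the optimal operating
point maximizes the Youden index J = sensitivity + specificity - 1
(ties resolved toward the lower threshold).

Variance explained by a predictor in a hierarchical (per-animal)
design is computed from two Gaussian random-intercept models fitted by
maximum likelihood:

    R^2 = 1 - (sigma2_full + tau00_full) / (sigma2_null + tau00_null)

where sigma2 is residual (within-animal) variance and tau00 the
between-animal intercept variance; the full model adds the fixed
predictor to the intercept-only null model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AnalysisError
from .io import EMMMap
from .mesh import SurfaceMesh

__all__ = [
    "DEFAULT_GRID_SPECS",
    "GridSpec",
    "ROCGrid",
    "roc_grid",
    "pair_points_with_reference",
    "MixedModelVariance",
    "mixed_model_r2",
]


@dataclass(frozen=True)
class GridSpec:
    """Evenly spaced sweep: n values of step (max-min)/n over (min, max]
    for predictor thresholds, [min, max) for reference cutoffs."""

    min: float
    max: float
    n: int = 40

    @property
    def step(self) -> float:
        return (self.max - self.min) / self.n

    def thresholds(self) -> np.ndarray:
        """Predictor thresholds: min + step, ..., max."""
        return self.min + self.step * np.arange(1, self.n + 1)

    def cutoffs(self) -> np.ndarray:
        """Reference cutoffs: min, min + step, ..., max - step."""
        return self.min + self.step * np.arange(self.n)


#: Parameter sweep ranges: IT cutoffs 0-100 % step 2.5; UV 0-25 mV
#: (step 25/40 mV), BV 0-12 mV step 0.3, LLS -32-48 % step 2,
#: WT -5-15 mm step 0.5.
DEFAULT_GRID_SPECS = {
    "it": GridSpec(0.0, 100.0),
    "uv": GridSpec(0.0, 25.0),
    "bv": GridSpec(0.0, 12.0),
    "lls": GridSpec(-32.0, 48.0),
    "wt": GridSpec(-5.0, 15.0),
}


@dataclass
class ROCGrid:
    """Sensitivity/specificity over (reference cutoff, predictor threshold).

    Rows where either class is empty are NaN.  ``best`` summarizes the
    cutoff with the largest AUC and its optimal operating point.
    """

    ref_cutoffs: np.ndarray
    pred_thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc_per_cutoff: np.ndarray
    best: dict


def _row_auc(sens_row: np.ndarray, spec_row: np.ndarray) -> float:
    fpr = 1.0 - spec_row
    pts = np.column_stack([fpr, sens_row])
    pts = np.vstack([[0.0, 0.0], pts, [1.0, 1.0]])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def roc_grid(
    pairs: np.ndarray,
    pred_spec: GridSpec,
    ref_spec: GridSpec,
    direction: str = "pred_le_is_positive",
) -> ROCGrid:
    """ROC sweep of predictor thresholds against reference cutoffs.

    ``pairs`` is (n, 2) of (predictor, reference) values per analysis
    point.  For each reference cutoff t_r (positive: ref >= t_r) and
    each predictor threshold t_p (test positive: pred <= t_p, or >=
    with ``direction="pred_ge_is_positive"``), sensitivity and
    specificity are tabulated; rows where the positive or negative
    class is empty are missing.
    """
    pairs = np.asarray(pairs, dtype=float)
    pairs = pairs[np.all(np.isfinite(pairs), axis=1)]
    if len(pairs) < 2:
        raise AnalysisError("need at least 2 (pred, ref) pairs")
    if direction not in ("pred_le_is_positive", "pred_ge_is_positive"):
        raise AnalysisError(f"unknown direction {direction!r}")
    pred, ref = pairs[:, 0], pairs[:, 1]
    cutoffs = ref_spec.cutoffs()
    thresholds = pred_spec.thresholds()
    n_r, n_p = len(cutoffs), len(thresholds)

    if direction == "pred_le_is_positive":
        test_pos = pred[None, :] <= thresholds[:, None]  # (n_p, n)
    else:
        test_pos = pred[None, :] >= thresholds[:, None]

    sens = np.full((n_r, n_p), np.nan)
    spec = np.full((n_r, n_p), np.nan)
    auc = np.full(n_r, np.nan)
    for i, t_r in enumerate(cutoffs):
        pos = ref >= t_r
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            continue
        tp = test_pos[:, pos].sum(axis=1)
        fp = test_pos[:, ~pos].sum(axis=1)
        sens[i] = tp / n_pos
        spec[i] = (n_neg - fp) / n_neg
        auc[i] = _row_auc(sens[i], spec[i])
    if np.all(np.isnan(auc)):
        raise AnalysisError("no reference cutoff yields both classes non-empty")

    i_best = int(np.nanargmax(auc))
    j = sens[i_best] + spec[i_best] - 1.0
    j_best = int(np.argmax(j))  # argmax takes the first (lowest threshold) tie
    best = {
        "ref_cutoff": float(cutoffs[i_best]),
        "pred_threshold": float(thresholds[j_best]),
        "sens": float(sens[i_best, j_best]),
        "spec": float(spec[i_best, j_best]),
        "auc": float(auc[i_best]),
    }
    return ROCGrid(cutoffs, thresholds, sens, spec, auc, best)


def pair_points_with_reference(
    emm: EMMMap, mesh: SurfaceMesh, channel: str, predictor: str = "uv"
) -> tuple[np.ndarray, int]:
    """Pair each included EMM point with a mesh channel value.

    The reference value is the channel at the point's closest mesh
    vertex; the predictor is one of the point's own measurements
    ("uv", "bv", "lls").  Returns ``(pairs (m, 2), n_dropped)`` where
    dropped pairs had a missing channel or predictor value.
    """
    if channel not in mesh.vertex_channels:
        raise AnalysisError(f"mesh has no channel {channel!r}")
    if predictor not in ("uv", "bv", "lls"):
        raise AnalysisError(f"unknown predictor {predictor!r}")
    mask = emm.included
    if not np.any(mask):
        raise AnalysisError("no included points to pair")
    pts = emm.positions[mask]
    nearest = cKDTree(mesh.vertices).query(pts)[1]
    ref = mesh.vertex_channels[channel][nearest]
    pred = getattr(emm, predictor)[mask]
    ok = np.isfinite(ref) & np.isfinite(pred)
    if not np.any(ok):
        raise AnalysisError("no valid (pred, ref) pairs")
    return np.column_stack([pred[ok], ref[ok]]), int((~ok).sum())


@dataclass
class MixedModelVariance:
    """Variance components of the null/full random-intercept models."""

    sigma2_null: float
    tau00_null: float
    sigma2_full: float
    tau00_full: float
    singular_null: bool = False
    singular_full: bool = False

    @property
    def r2(self) -> float:
        return 1.0 - (self.sigma2_full + self.tau00_full) / (
            self.sigma2_null + self.tau00_null
        )


def _fit_random_intercept(df: pd.DataFrame, formula: str) -> tuple[float, float, bool]:
    import statsmodels.formula.api as smf

    model = smf.mixedlm(formula, df, groups=df["group"])
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False)
    sigma2 = float(res.scale)
    tau00 = float(np.asarray(res.cov_re)[0, 0])
    singular = tau00 <= 1e-10
    if not np.isfinite(res.llf):
        raise AnalysisError("non-finite likelihood in mixed-model fit")
    return sigma2, max(tau00, 0.0), singular


def mixed_model_r2(table: pd.DataFrame, covariate_in_full: bool = True) -> MixedModelVariance:
    """Variance explained by a covariate in a random-intercept design.

    ``table`` must have columns ``group`` (animal id), ``outcome`` and
    ``covariate``.  Both models are Gaussian random-intercept models
    fitted by maximum likelihood (not REML, so the two likelihoods are
    comparable): the null model is intercept-only, the full model adds
    the fixed covariate.  With ``covariate_in_full=False`` the full
    model is refitted without the covariate (useful as a degenerate
    check: R^2 is then ~0).
    """
    for col in ("group", "outcome", "covariate"):
        if col not in table.columns:
            raise AnalysisError(f"table lacks column {col!r}")
    df = table.dropna(subset=["group", "outcome", "covariate"]).copy()
    sizes = df.groupby("group").size()
    if len(sizes) < 3:
        raise AnalysisError("need at least 3 groups")
    if (sizes < 2).any():
        raise AnalysisError("every group needs at least 2 rows")
    s2n, t00n, sing_n = _fit_random_intercept(df, "outcome ~ 1")
    # a constant covariate makes the full design singular; it carries no
    # information, so the full model degenerates to the null model
    degenerate = float(df["covariate"].std()) < 1e-12
    full_formula = (
        "outcome ~ covariate" if covariate_in_full and not degenerate else "outcome ~ 1"
    )
    s2f, t00f, sing_f = _fit_random_intercept(df, full_formula)
    return MixedModelVariance(
        sigma2_null=s2n,
        tau00_null=t00n,
        sigma2_full=s2f,
        tau00_full=t00f,
        singular_null=sing_n,
        singular_full=sing_f,
    )
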