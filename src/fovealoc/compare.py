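"""Comparative statistics relating cone peak, PRL, SFL, and raster geometry.

Covers: the normalized-distance paired t-test (is the SFL closer to the
PRL than to the cone density peak, after normalizing both distances by
the PRL-to-peak distance), the correlation between the polar directions
of PRL and SFL displacement from the cone peak, an ordinal (cumulative
logit) regression of the three-category response on stimulus distance
from the raster center and from the PRL, and the region-of-interest
chi-square comparison of "yes" proportions on the PRL side vs the
opposite side of the raster center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "TestResult",
    "OrdinalModelFit",
    "normalized_distance_ttest",
    "displacement_direction_correlation",
    "multinomial_logit",
    "roi_yes_proportion_test",
    "pearson",
]

RESPONSE_ORDER = ("yes", "maybe", "no")


@dataclass
class TestResult:
    """Generic statistic/df/p container for t, chi-square, r, KS outputs."""

    statistic: float
    df: float | tuple
    p: float
    n: int
    kind: str = ""
    effect: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError("p must lie in [0, 1]")


@dataclass
class OrdinalModelFit:
    """Cumulative-logit fit with per-term likelihood-ratio tests.

    ``coefficients`` are reported in the generative sign convention
    (P(Y<=k) = sigmoid(cutpoint_k + x.beta) over yes < maybe < no, so a
    negative distance coefficient means "yes" becomes less likely with
    distance).  Observer enters as fixed intercepts, an approximation of
    a random observer effect.
    """

    coefficients: dict
    se: dict
    cutpoints: np.ndarray
    logL: float
    n: int
    lr_tests: dict  # term -> TestResult
    predicted: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly increasing")


def normalized_distance_ttest(prl, sfl, cone_peak) -> TestResult:
    """Paired t-test of normalized SFL distances to the PRL vs cone peak.

    Per observer: d1 = |PRL-SFL| / |PRL-peak| and
    d2 = |peak-SFL| / |PRL-peak|; the normalization removes the trivial
    dependence on how far apart PRL and peak are (coincident PRL and
    peak would force equal raw distances).  Observers with PRL == peak
    are excluded with a warning.
    """
    prl = np.atleast_2d(np.asarray(prl, float))
    sfl = np.atleast_2d(np.asarray(sfl, float))
    peak = np.atleast_2d(np.asarray(cone_peak, float))
    if not (len(prl) == len(sfl) == len(peak)):
        raise ValueError("per-observer arrays must have equal length")
    denom = np.linalg.norm(prl - peak, axis=1)
    keep = denom > 1e-12
    if not np.all(keep):
        warnings.warn(f"excluding {np.sum(~keep)} observer(s) with PRL == cone peak")
    prl, sfl, peak, denom = prl[keep], sfl[keep], peak[keep], denom[keep]
    n = len(prl)
    if n < 2:
        raise ValueError("need at least 2 usable observers")
    d1 = np.linalg.norm(prl - sfl, axis=1) / denom
    d2 = np.linalg.norm(peak - sfl, axis=1) / denom
    diff = d1 - d2
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return TestResult(
        statistic=float(t), df=n - 1, p=float(p), n=n, kind="paired t",
        effect={"mean_d1": float(d1.mean()), "mean_d2": float(d2.mean()),
                "mean_diff": float(diff.mean()), "sd_diff": float(sd)},
    )


def _circular_mean(angles: np.ndarray) -> float:
    return float(np.arctan2(np.mean(np.sin(angles)), np.mean(np.cos(angles))))


def _wrap(angles: np.ndarray) -> np.ndarray:
    return np.mod(angles + np.pi, 2 * np.pi) - np.pi


def displacement_direction_correlation(angles_prl, angles_sfl) -> TestResult:
    """Pearson correlation of PRL and SFL displacement directions.

    Both angle sets (radians, polar direction from the cone density
    peak) are re-centered so the circular mean of the PRL angles maps to
    0, then wrapped to (-pi, pi], avoiding an arbitrary cut of the
    circle through the data.  df = n - 2.
    """
    a = np.asarray(angles_prl, dtype=float)
    b = np.asarray(angles_sfl, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need matched angle arrays with n >= 3")
    m = _circular_mean(a)
    a = _wrap(a - m)
    b = _wrap(b - m)
    if np.ptp(a) < 1e-12 or np.ptp(b) < 1e-12:
        raise ValueError("degenerate (constant) angle set")
    r, p = sps.pearsonr(a, b)
    return TestResult(statistic=float(r), df=len(a) - 2, p=float(p), n=len(a),
                      kind="pearson r (directions)")


def _design(trials: pd.DataFrame, prl_by_observer: dict, terms, observer_col: str):
    d_raster = np.hypot(trials["s_x"], trials["s_y"]).to_numpy()
    prl = np.array([prl_by_observer[o] for o in trials[observer_col]])
    d_prl = np.linalg.norm(trials[["r_x", "r_y"]].to_numpy() - prl, axis=1)
    cols = {}
    if "raster" in terms:
        cols["d_raster"] = d_raster
    if "prl" in terms:
        cols["d_prl"] = d_prl
    if "interaction" in terms:
        cols["d_raster:d_prl"] = d_raster * d_prl
    X = pd.DataFrame(cols, index=trials.index)
    observers = pd.unique(trials[observer_col])
    if len(observers) > 1:
        dummies = pd.get_dummies(trials[observer_col], prefix="obs", drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    return X


def _fit_ordered(y: pd.Series, X: pd.DataFrame):
    model = OrderedModel(y, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 50:
        raise RuntimeError(
            "ordinal fit diverged (possible separation); consider penalization"
        )
    return res


def multinomial_logit(
    trials: pd.DataFrame,
    prl_by_observer: dict | np.ndarray | tuple,
    observer_col: str = "observer",
    include_interaction: bool = True,
) -> OrdinalModelFit:
    """Ordinal regression of the response on raster and retinal distances.

    Predictors: stimulus distance from the raster center |s|, distance
    from the observer's PRL |r - PRL|, and (optionally) their
    interaction; observer enters as fixed intercepts.  Per-term
    likelihood-ratio chi-square tests come from refits without the term.
    """
    trials = trials.copy()
    if observer_col not in trials.columns:
        trials[observer_col] = 0
    if not isinstance(prl_by_observer, dict):
        prl_by_observer = {o: np.asarray(prl_by_observer, dtype=float)
                           for o in pd.unique(trials[observer_col])}
    present = trials["response"].unique()
    if len(present) < 2:
        raise ValueError("need at least 2 response categories present")
    y = pd.Categorical(trials["response"], categories=list(RESPONSE_ORDER), ordered=True)
    y = pd.Series(y, index=trials.index, name="response")

    terms = ["raster", "prl"] + (["interaction"] if include_interaction else [])
    X_full = _design(trials, prl_by_observer, terms, observer_col)
    res_full = _fit_ordered(y, X_full)

    k_cut = len(RESPONSE_ORDER) - 1
    exog_names = list(X_full.columns)
    params = dict(zip(exog_names, res_full.params[: len(exog_names)]))
    bse = dict(zip(exog_names, res_full.bse[: len(exog_names)]))
    # statsmodels: P(Y<=k) = F(cut_k - x.beta); negate into the generative
    # convention P(Y<=k) = F(cut_k + x.beta)
    coef = {name: -params[name] for name in exog_names if not name.startswith("obs_")}
    se = {name: bse[name] for name in exog_names if not name.startswith("obs_")}

    lr_tests = {}
    for term in terms:
        reduced_terms = [t for t in terms if t != term]
        X_red = _design(trials, prl_by_observer, reduced_terms, observer_col)
        res_red = _fit_ordered(y, X_red)
        lr = 2.0 * (res_full.llf - res_red.llf)
        lr = max(lr, 0.0)
        lr_tests[term] = TestResult(
            statistic=float(lr), df=1, p=float(sps.chi2.sf(lr, 1)), n=len(trials),
            kind="LR chi-square",
        )

    thresholds = res_full.model.transform_threshold_params(res_full.params)[1:-1]
    return OrdinalModelFit(
        coefficients=coef,
        se=se,
        cutpoints=np.asarray(thresholds, dtype=float),
        logL=float(res_full.llf),
        n=len(trials),
        lr_tests=lr_tests,
        predicted=None,
    )


def roi_yes_proportion_test(
    trials: pd.DataFrame, prl, raster_center_retinal=None
) -> TestResult:
    """Chi-square test of "yes" proportions in PRL-side vs opposite ROIs.

    ROI-A is a circle centered on the PRL; ROI-B is displaced from the
    (mean) retinal location of the raster center by the same vector in
    the opposite direction.  Both have diameter equal to the
    raster-center-to-PRL distance (limiting ROI overlap).  Pearson
    chi-square without continuity correction on the 2x2 table
    yes/not-yes x ROI.
    """
    prl = np.asarray(prl, dtype=float)
    r = trials[["r_x", "r_y"]].to_numpy()
    if raster_center_retinal is None:
        raster_center_retinal = trials[["e_x", "e_y"]].to_numpy().mean(axis=0)
    center = np.asarray(raster_center_retinal, dtype=float)
    sep = prl - center
    dist = np.linalg.norm(sep)
    if dist < 1e-9:
        raise ValueError("PRL coincides with the mean raster-center retinal location")
    radius = dist / 2.0  # ROI diameter equals the separation
    roi_a = np.linalg.norm(r - prl, axis=1) <= radius
    roi_b = np.linalg.norm(r - (center - sep), axis=1) <= radius
    yes = (trials["response"] == "yes").to_numpy()
    table = np.array([
        [int(np.sum(yes & roi_a)), int(np.sum(~yes & roi_a))],
        [int(np.sum(yes & roi_b)), int(np.sum(~yes & roi_b))],
    ])
    if np.any(table.sum(axis=1) == 0):
        raise ValueError(f"empty ROI; counts table {table.tolist()}")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    n = int(table.sum())
    return TestResult(
        statistic=float(chi2), df=int(dof), p=float(p), n=n, kind="chi-square",
        effect={
            "table": table.tolist(),
            "prop_yes_prl_roi": table[0, 0] / table[0].sum(),
            "prop_yes_opposite_roi": table[1, 0] / table[1].sum(),
            "n_roi_prl": int(table[0].sum()),
            "n_roi_opposite": int(table[1].sum()),
        },
    )


def pearson(x, y) -> TestResult:
    """Product-moment correlation with df = n - 2 and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matched arrays with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    return TestResult(statistic=float(r), df=len(x) - 2, p=float(p), n=len(x),
                      kind="pearson r")
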