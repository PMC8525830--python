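"""Preferred-retinal-locus estimation and day-to-day stability tests.

The PRL for a day is the mean of a 2D Gaussian fitted by maximum
likelihood to the valid retinal target locations of that day (with the
assumption-free geometric median reported alongside).  Stability across
two days is assessed two ways:

* AIC model comparison between m1 (one Gaussian, shared mean and
  covariance, k = 5 parameters) and m2 (day-specific means, shared
  covariance, k = 7), with P(m1 best) = exp(-dAIC/2)/[1 + exp(-dAIC/2)],
  dAIC = AIC(m1) - AIC(m2), and the evidence ratio
  ER = P(m1 best)/P(m2 best);
* a two-sample 2D Kolmogorov-Smirnov test (Fasano-Franceschini quadrant
  statistic) on per-epoch mean locations, which are approximately
  independent samples (raw 30-Hz frames are strongly autocorrelated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kstwobign, pearsonr

from .gaze import FixationTrace

__all__ = [
    "Gaussian2DFit",
    "ModelComparison",
    "KS2DResult",
    "PRLEstimate",
    "fit_gaussian_2d",
    "fit_two_day_models",
    "geometric_median",
    "epoch_means",
    "ks2d",
    "prl_summary",
]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class Gaussian2DFit:
    """ML fit of a bivariate Gaussian: mean, ML (1/n) covariance, AIC."""

    mu: np.ndarray
    sigma: np.ndarray
    logL: float
    k: int
    n: int

    @property
    def AIC(self) -> float:
        return 2 * self.k - 2 * self.logL


@dataclass
class ModelComparison:
    """AIC comparison of the shared-mean (m1) vs two-mean (m2) models."""

    AIC_m1: float
    AIC_m2: float

    @property
    def delta_AIC(self) -> float:
        return self.AIC_m1 - self.AIC_m2

    @property
    def p_m1(self) -> float:
        return float(1.0 / (1.0 + np.exp(self.delta_AIC / 2.0)))

    @property
    def evidence_ratio(self) -> float:
        # ER = P(m1)/P(m2) = exp(-dAIC/2)
        return float(np.exp(-self.delta_AIC / 2.0))


@dataclass
class KS2DResult:
    D: float
    p: float
    n1: int
    n2: int


@dataclass
class PRLEstimate:
    day: int
    mu: np.ndarray
    geometric_median: np.ndarray
    sigma: np.ndarray
    n: int
    dist_to_peak: float | None = None
    angle_from_peak: float | None = None

    @property
    def mean_median_distance(self) -> float:
        return float(np.linalg.norm(self.mu - self.geometric_median))


def _check_points(points: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    return pts


def _gauss_logl(pts: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("singular covariance")
    d = pts - mu
    maha = np.einsum("ij,jk,ik->i", d, np.linalg.inv(sigma), d)
    return float(-0.5 * (len(pts) * (2 * _LOG_2PI + logdet) + maha.sum()))


def fit_gaussian_2d(points) -> Gaussian2DFit:
    """Closed-form ML fit of a 2D Gaussian (mean + (1/n) scatter matrix).

    AIC uses k = 5 (two mean components, three distinct covariance
    entries).  Degenerate scatter (collinear or duplicated points)
    raises ``numpy.linalg.LinAlgError``.
    """
    pts = _check_points(points)
    n = len(pts)
    if n < 3:
        raise ValueError("need at least 3 points")
    mu = pts.mean(axis=0)
    d = pts - mu
    sigma = d.T @ d / n
    logL = _gauss_logl(pts, mu, sigma)
    return Gaussian2DFit(mu=mu, sigma=sigma, logL=logL, k=5, n=n)


def fit_two_day_models(points_day1, points_day2):
    """Fit the shared (m1) and day-specific-mean (m2) Gaussian models.

    m1 pools both days into a single Gaussian (k = 5).  m2 gives each
    day its own mean but shares the pooled within-day ML covariance
    (k = 7); its log-likelihood is evaluated with day-specific means and
    the shared covariance.  Both solutions are closed-form maximum
    likelihood.  Returns ``(m1, m2, ModelComparison)`` where m2 is a
    pair of :class:`Gaussian2DFit` (one per day, sharing sigma, logL and
    AIC of the joint model).
    """
    p1 = _check_points(points_day1)
    p2 = _check_points(points_day2)
    if len(p1) < 3 or len(p2) < 3:
        raise ValueError("each day needs at least 3 points")
    pooled = np.vstack([p1, p2])
    m1 = fit_gaussian_2d(pooled)

    mu1, mu2 = p1.mean(axis=0), p2.mean(axis=0)
    d1, d2 = p1 - mu1, p2 - mu2
    n = len(pooled)
    sigma_w = (d1.T @ d1 + d2.T @ d2) / n
    logL = _gauss_logl(p1, mu1, sigma_w) + _gauss_logl(p2, mu2, sigma_w)
    m2 = (
        Gaussian2DFit(mu=mu1, sigma=sigma_w, logL=logL, k=7, n=len(p1)),
        Gaussian2DFit(mu=mu2, sigma=sigma_w, logL=logL, k=7, n=len(p2)),
    )
    cmp_ = ModelComparison(AIC_m1=m1.AIC, AIC_m2=m2[0].AIC)
    return m1, m2, cmp_


def geometric_median(points, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Weiszfeld iteration for the point minimizing the sum of distances.

    When an iterate lands on a data point, the standard modified step
    (Vardi-Zhang) decides whether that point is the minimizer.
    """
    pts = _check_points(points)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    if len(pts) == 1:
        return pts[0].copy()
    y = pts.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(pts - y, axis=1)
        on = d < 1e-12
        if on.any():
            others = ~on
            if not others.any():
                return y
            dn = d[others]
            w = 1.0 / dn
            T = (pts[others] * w[:, None]).sum(axis=0) / w.sum()
            Rvec = ((pts[others] - y) / dn[:, None]).sum(axis=0)
            rnorm = np.linalg.norm(Rvec)
            eta = float(on.sum())
            if rnorm <= eta:  # the data point itself is the median
                return y
            # Vardi-Zhang step through the coincident point
            y_new = (1 - eta / rnorm) * T + (eta / rnorm) * y
        else:
            w = 1.0 / d
            y_new = (pts * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    raise RuntimeError(f"geometric median did not converge in {max_iter} iterations; last {y}")


def epoch_means(trace: FixationTrace) -> np.ndarray:
    """One mean retinal location per fixation epoch, over valid frames.

    Averaging within the 2-6-s epochs removes the strong frame-to-frame
    dependence of the 30-Hz samples, giving approximately independent
    observations for the KS test.  Epochs with no valid frames are
    dropped.
    """
    ok = trace.samples[trace.samples["valid"]]
    if len(ok) == 0:
        return np.empty((0, 2))
    g = ok.groupby(["day", "run", "epoch"])[["x_arcmin", "y_arcmin"]].mean()
    return g.to_numpy()


def _quadrant_max_diff(origins: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Max over origins/quadrants of |F_a - F_b| with open-quadrant counts."""
    best = 0.0
    na, nb = len(a), len(b)
    for ox, oy in origins:
        for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            fa = np.mean((sx * (a[:, 0] - ox) > 0) & (sy * (a[:, 1] - oy) > 0))
            fb = np.mean((sx * (b[:, 0] - ox) > 0) & (sy * (b[:, 1] - oy) > 0))
            best = max(best, abs(fa - fb))
    return best


def ks2d(sample_a, sample_b, method: str = "asymptotic",
         n_permutations: int = 2000, seed: int = 0) -> KS2DResult:
    """Two-sample 2D Kolmogorov-Smirnov test (Fasano-Franceschini).

    D is the maximum, over the four quadrant orientations at every data
    point, of the difference between the two samples' quadrant
    fractions, averaged between the maxima obtained using each sample's
    points as origins.  The asymptotic p-value uses
    Z = D sqrt(n1 n2/(n1+n2)) with the correlation correction
    p = Q_KS(Z / (1 + sqrt(1 - rbar^2) (0.25 - 0.75/sqrt(n)))),
    rbar^2 the mean squared Pearson correlation of the two samples.
    ``method='permutation'`` instead permutes the pooled sample labels,
    which is preferable at the n ~ 25-30 epoch-mean sample sizes where
    the asymptotic formula is rough.
    """
    a = _check_points(sample_a)
    b = _check_points(sample_b)
    n1, n2 = len(a), len(b)
    if n1 < 5 or n2 < 5:
        raise ValueError("each sample needs at least 5 points")

    D = _ks2d_stat(a, b)

    if method == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.vstack([a, b])
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(len(pooled))
            if _ks2d_stat(pooled[perm[:n1]], pooled[perm[n1:]]) >= D - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
    elif method == "asymptotic":
        n_eff = n1 * n2 / (n1 + n2)
        r2 = 0.0
        for s in (a, b):
            r, _ = pearsonr(s[:, 0], s[:, 1])
            r2 += r * r / 2.0
        z = D * np.sqrt(n_eff)
        denom = 1.0 + np.sqrt(max(1.0 - r2, 0.0)) * (0.25 - 0.75 / np.sqrt(n_eff))
        p = float(kstwobign.sf(z / denom))
    else:
        raise ValueError("method must be 'asymptotic' or 'permutation'")
    return KS2DResult(D=float(D), p=float(min(max(p, 0.0), 1.0)), n1=n1, n2=n2)


def _ks2d_stat(a: np.ndarray, b: np.ndarray) -> float:
    d1 = _quadrant_max_diff(a, a, b)
    d2 = _quadrant_max_diff(b, a, b)
    return 0.5 * (d1 + d2)


def prl_summary(day_points: list, cone_peak=None) -> dict:
    """Per-day PRL estimates and across-day stability statistics.

    ``day_points`` is a list of (n_i, 2) arrays of valid retinal target
    locations, one per day.  Returns per-day estimates (Gaussian mean,
    geometric median, covariance, distance and polar angle from the cone
    density peak when given), all pairwise day distances, the maximum
    pairwise distance, and — for the pair of days with the largest mean
    difference, as used for 3-day observers — the AIC comparison.
    """
    if len(day_points) < 2:
        raise ValueError("need at least 2 days")
    estimates = []
    for day, pts in enumerate(day_points):
        fit = fit_gaussian_2d(pts)
        g = geometric_median(pts)
        est = PRLEstimate(day=day, mu=fit.mu, geometric_median=g, sigma=fit.sigma, n=fit.n)
        if cone_peak is not None:
            rel = fit.mu - np.asarray(cone_peak, dtype=float)
            est.dist_to_peak = float(np.linalg.norm(rel))
            est.angle_from_peak = float(np.arctan2(rel[1], rel[0]))
        estimates.append(est)

    n_days = len(estimates)
    pair_dist = {}
    for i in range(n_days):
        for j in range(i + 1, n_days):
            pair_dist[(i, j)] = float(np.linalg.norm(estimates[i].mu - estimates[j].mu))
    (i_max, j_max), max_dist = max(pair_dist.items(), key=lambda kv: kv[1])
    m1, m2, comparison = fit_two_day_models(day_points[i_max], day_points[j_max])
    return {
        "per_day": estimates,
        "pairwise_distances": pair_dist,
        "max_pairwise_distance": max_dist,
        "compared_days": (i_max, j_max),
        "m1": m1,
        "m2": m2,
        "comparison": comparison,
        "mean_median_distances": [e.mean_median_distance for e in estimates],
    }
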