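"""Stimulus localization, coordinate transforms, and trace conditioning.

Fixation data are per-frame retinal locations of a fixated target,
recorded at 30 Hz.  This module covers the steps between raw frames and
analysis-ready traces: template localization by normalized
cross-correlation, similarity registration between reference images,
mapping points through transform chains into master-image coordinates,
partitioning a run into fixation epochs at target-shift times, and the
post-shift frame-exclusion rule (the first 20 frames, ~667 ms, after each
shift are dropped, by which time the corrective saccade is complete).

Coordinates are arcmin in master-image space, x rightward, y downward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize as sp_minimize
from skimage.feature import match_template
from skimage.filters import difference_of_gaussians, window as skwindow
from skimage.registration import phase_cross_correlation
from skimage.transform import SimilarityTransform as _SkSimilarity
from skimage.transform import warp, warp_polar

__all__ = [
    "FixationTrace",
    "SimilarityTransform",
    "locate_stimulus",
    "estimate_similarity",
    "apply_transform_chain",
    "segment_epochs",
    "exclude_settling_frames",
    "settling_curve",
]

TRACE_COLUMNS = [
    "day", "run", "frame", "epoch", "t_s", "x_arcmin", "y_arcmin", "valid",
    "target_raster_x", "target_raster_y",
]


@dataclass
class FixationTrace:
    """A day's fixation samples plus the per-epoch target schedule.

    ``samples`` columns: day, run, frame, epoch, t_s, x_arcmin, y_arcmin,
    valid, target_raster_x, target_raster_y.  ``schedule`` columns: day,
    run, epoch, start_frame, target_x, target_y.  Frame indices are
    strictly increasing within a run; every sample belongs to exactly one
    epoch.
    """

    samples: pd.DataFrame
    schedule: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TRACE_COLUMNS) - set(self.samples.columns)
        if missing:
            raise ValueError(f"trace samples missing columns: {sorted(missing)}")
        for (_, _), g in self.samples.groupby(["day", "run"]):
            f = g["frame"].to_numpy()
            if np.any(np.diff(f) <= 0):
                raise ValueError("frame indices must be strictly increasing within a run")

    def valid_points(self) -> np.ndarray:
        ok = self.samples[self.samples["valid"]]
        return ok[["x_arcmin", "y_arcmin"]].to_numpy()

    def copy(self) -> "FixationTrace":
        return FixationTrace(self.samples.copy(), self.schedule.copy())


@dataclass(frozen=True)
class SimilarityTransform:
    """Similarity map p' = scale * R(theta) @ p + (tx, ty)."""

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def rotation_matrix(self) -> np.ndarray:
        c, s = np.cos(self.theta), np.sin(self.theta)
        return np.array([[c, -s], [s, c]])

    def apply(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = self.scale * pts @ self.rotation_matrix.T + np.array([self.tx, self.ty])
        return out

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return T with T(p) = self(other(p)) (``other`` applied first)."""
        t = self.apply([[other.tx, other.ty]])[0]
        return SimilarityTransform(
            tx=float(t[0]), ty=float(t[1]),
            theta=self.theta + other.theta, scale=self.scale * other.scale,
        )

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        c, s = np.cos(-self.theta), np.sin(-self.theta)
        tx = -inv_scale * (c * self.tx - s * self.ty)
        ty = -inv_scale * (s * self.tx + c * self.ty)
        return SimilarityTransform(tx=tx, ty=ty, theta=-self.theta, scale=inv_scale)


def apply_transform_chain(points, chain) -> np.ndarray:
    """Map points through a chain of similarity transforms, first to last.

    ``apply_transform_chain(p, [T1, T2])`` equals ``T2(T1(p))``; composing
    the chain into a single transform gives the same result.
    """
    chain = list(chain)
    if not chain:
        raise ValueError("transform chain must be non-empty")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    for t in chain:
        pts = t.apply(pts)
    return pts


def _quadratic_subpixel(corr: np.ndarray, peak: tuple[int, int]) -> np.ndarray:
    """1D quadratic refinement per axis on the 3x3 peak neighborhood."""
    r, c = peak
    out = np.array([float(r), float(c)])
    for axis, i in ((0, r), (1, c)):
        if i <= 0 or i >= corr.shape[axis] - 1:
            continue
        if axis == 0:
            ym, y0, yp = corr[i - 1, c], corr[i, c], corr[i + 1, c]
        else:
            ym, y0, yp = corr[r, i - 1], corr[r, i], corr[r, i + 1]
        denom = ym - 2 * y0 + yp
        if denom < 0:
            out[axis] = i + 0.5 * (ym - yp) / denom
    return out


def locate_stimulus(frame: np.ndarray, template: np.ndarray, score_threshold: float = 0.5):
    """Locate a template in a frame by normalized cross-correlation.

    Returns ``(offset_yx, score, valid)`` where ``offset_yx`` is the
    sub-pixel (row, col) of the template's top-left corner in the frame
    and ``score`` is the correlation maximum in [-1, 1].  A score below
    ``score_threshold`` flags the sample invalid (the correlation found a
    wrong or absent stimulus).
    """
    frame = np.asarray(frame, dtype=float)
    template = np.asarray(template, dtype=float)
    if template.shape[0] > frame.shape[0] or template.shape[1] > frame.shape[1]:
        raise ValueError("template must be no larger than the frame")
    corr = match_template(frame, template, pad_input=False)
    peak = np.unravel_index(int(np.argmax(corr)), corr.shape)
    score = float(corr[peak])
    offset = _quadratic_subpixel(corr, peak)
    return offset, score, score >= score_threshold


def _translation(moving: np.ndarray, fixed: np.ndarray, upsample: int = 50) -> np.ndarray:
    shift, _, _ = phase_cross_correlation(fixed, moving, upsample_factor=upsample,
                                          normalization=None)
    return shift  # (dy, dx) to apply to moving


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def estimate_similarity(
    moving: np.ndarray,
    fixed: np.ndarray,
    allow_rotation_scale: bool = True,
    quality_threshold: float = 0.2,
):
    """Estimate the similarity transform aligning ``moving`` onto ``fixed``.

    Rotation and log-scale are recovered by phase correlation of the
    log-polar warped Fourier magnitudes (band-pass filtered, windowed);
    translation by phase correlation after undoing rotation/scale.  When
    ``allow_rotation_scale`` is False, only translation is estimated
    (fast path for near-identity chains).

    Returns ``(transform, quality)``; ``transform`` maps moving-image
    pixel coordinates (x, y) to fixed-image coordinates.  Raises
    ``RegistrationError`` when the post-alignment correlation falls below
    ``quality_threshold``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError("images must have identical shape")

    candidates = [(0.0, 1.0)]
    if allow_rotation_scale:
        lo, hi = 1.0, min(moving.shape) * 0.2
        mov_f = difference_of_gaussians(moving, lo, hi)
        fix_f = difference_of_gaussians(fixed, lo, hi)
        wimg = skwindow("hann", moving.shape)
        mov_fs = np.abs(np.fft.fftshift(np.fft.fft2(mov_f * wimg)))
        fix_fs = np.abs(np.fft.fftshift(np.fft.fft2(fix_f * wimg)))
        shape = fix_fs.shape
        radius = shape[0] // 8  # low frequencies carry the geometry
        warped_mov = warp_polar(mov_fs, radius=radius, output_shape=shape,
                                scaling="log", order=0)
        warped_fix = warp_polar(fix_fs, radius=radius, output_shape=shape,
                                scaling="log", order=0)
        warped_mov = warped_mov[: shape[0] // 2]  # FFT magnitude has 180-deg symmetry
        warped_fix = warped_fix[: shape[0] // 2]
        shift, _, _ = phase_cross_correlation(
            warped_fix, warped_mov, upsample_factor=20, normalization=None
        )
        theta_lp = -np.deg2rad((360.0 / shape[0]) * shift[0])
        klog = shape[1] / np.log(radius)
        scale_lp = float(np.exp(shift[1] / klog))
        if abs(theta_lp) > 1e-9 or abs(scale_lp - 1) > 1e-9:
            candidates.append((theta_lp, scale_lp))

    center = (np.array(moving.shape[::-1]) - 1) / 2.0  # (x, y)

    def _aligned(t: SimilarityTransform, order: int = 1) -> np.ndarray:
        sk = _SkSimilarity(scale=t.scale, rotation=t.theta, translation=(t.tx, t.ty))
        return warp(moving, sk.inverse, order=order, cval=np.nan)

    def _score(params) -> float:
        tx, ty, th, logs = params
        img = _aligned(SimilarityTransform(tx, ty, th, float(np.exp(logs))))
        mask = np.isfinite(img)
        if mask.sum() < 100:
            return 1.0
        return 1.0 - _ncc(img[mask], fixed[mask])

    best: SimilarityTransform | None = None
    best_score = np.inf
    for theta, scale in candidates:
        # undo candidate rotation/scale about the center, phase-correlate
        # the translation, then refine all four parameters on NCC (the
        # magnitude-spectrum stage is biased for small rotations and can
        # lock onto spurious peaks, so each candidate is polished and the
        # best final correlation wins)
        pre = _about_center(theta, scale, center)
        if abs(theta) > 1e-12 or abs(scale - 1) > 1e-12:
            moved = _aligned(pre, order=1)
            moved = np.nan_to_num(moved)
        else:
            pre = SimilarityTransform()
            moved = moving
        shift = _translation(moved, fixed)
        post = SimilarityTransform(tx=float(shift[1]), ty=float(shift[0]))
        t0 = post.compose(pre)
        x0 = np.array([t0.tx, t0.ty, t0.theta, np.log(t0.scale)])
        if allow_rotation_scale:
            direc = np.diag([0.5, 0.5, 0.005, 0.005])  # px, px, rad, log-scale
            res = sp_minimize(_score, x0, method="Powell",
                              options={"xtol": 1e-4, "ftol": 1e-7, "maxfev": 400,
                                       "direc": direc})
            x, fun = res.x, res.fun
        else:
            x, fun = x0, _score(x0)
        if fun < best_score:
            best_score = fun
            best = SimilarityTransform(tx=float(x[0]), ty=float(x[1]),
                                       theta=float(x[2]), scale=float(np.exp(x[3])))
    transform = best

    aligned = _aligned(transform, order=3)
    mask = np.isfinite(aligned)
    quality = _ncc(aligned[mask], fixed[mask]) if mask.sum() > 100 else 0.0
    if quality < quality_threshold:
        raise RegistrationError(
            f"registration quality {quality:.3f} below threshold {quality_threshold}"
        )
    return transform, quality


def _about_center(theta: float, scale: float, center: np.ndarray) -> SimilarityTransform:
    """Similarity with rotation/scale applied about ``center`` (x, y)."""
    c, s = np.cos(theta), np.sin(theta)
    R = scale * np.array([[c, -s], [s, c]])
    t = center - R @ center
    return SimilarityTransform(tx=float(t[0]), ty=float(t[1]), theta=theta, scale=scale)


class RegistrationError(RuntimeError):
    pass


def segment_epochs(trace: FixationTrace, schedule: pd.DataFrame | None = None) -> FixationTrace:
    """Assign each frame to the epoch of the most recent target shift.

    ``schedule`` columns: day, run, epoch, start_frame (and optionally
    target positions).  Epoch 0 starts at frame 0.  When ``schedule`` is
    None the trace's own schedule is used.
    """
    sched = trace.schedule if schedule is None else schedule
    samples = trace.samples.copy()
    for (day, run), g in samples.groupby(["day", "run"]):
        s = sched[(sched["day"] == day) & (sched["run"] == run)].sort_values("start_frame")
        starts = s["start_frame"].to_numpy()
        if len(starts) == 0 or starts[0] != 0:
            starts = np.concatenate([[0], starts])
        epoch_ids = np.searchsorted(starts, g["frame"].to_numpy(), side="right") - 1
        samples.loc[g.index, "epoch"] = epoch_ids
    samples["epoch"] = samples["epoch"].astype(int)
    return FixationTrace(samples, sched if schedule is not None else trace.schedule)


def exclude_settling_frames(trace: FixationTrace, n_exclude: int = 20) -> FixationTrace:
    """Invalidate the first ``n_exclude`` frames of every epoch.

    The default of 20 frames (~667 ms at 30 Hz) leaves out the interval
    during which the observer's corrective saccade to the shifted target
    is still pending.  Applies to every epoch including the first of a
    run; previously invalid frames stay invalid.  Idempotent.
    """
    samples = trace.samples.copy()
    rank = samples.groupby(["day", "run", "epoch"]).cumcount()
    samples.loc[rank < n_exclude, "valid"] = False
    return FixationTrace(samples, trace.schedule)


def settling_curve(traces, max_frames: int = 60) -> np.ndarray:
    """Mean distance from the per-epoch median vs frames since shift.

    For each post-shift frame index k < ``max_frames``, averages over all
    epochs (of all traces) the distance |p_k - median(epoch)|, with the
    median taken over the whole epoch.  For noisy fixation the curve
    settles to a positive floor (the eye hovers around the median); for a
    zero-noise, zero-latency trace it is identically 0.  Returns an array
    of length ``max_frames`` (NaN where no epoch is that long).
    """
    if isinstance(traces, FixationTrace):
        traces = [traces]
    sums = np.zeros(max_frames)
    counts = np.zeros(max_frames, dtype=int)
    for tr in traces:
        for _, g in tr.samples.groupby(["day", "run", "epoch"]):
            xy = g[["x_arcmin", "y_arcmin"]].to_numpy()
            med = np.median(xy, axis=0)
            d = np.linalg.norm(xy - med, axis=1)
            k = min(len(d), max_frames)
            sums[:k] += d[:k]
            counts[:k] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
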