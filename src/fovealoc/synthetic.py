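"""Synthetic cone mosaics, fixation sessions, and fixation-judgment trials.

The generator emulates the statistical structure of adaptive-optics
retinal-imaging fixation experiments, with full ground truth:

* a jittered hexagonal cone mosaic whose spacing grows smoothly away from
  a density peak;
* 30-s fixation runs sampled at 30 Hz, in which a fixation target shifts
  to a new random location every 2-6 s (shift distance 5.5-15.6 arcmin,
  inside an 11 x 11-arcmin region) and the recorded retinal location of
  the target combines the observer's preferred retinal locus (PRL),
  slow mean-reverting drift, microsaccadic jumps, frame-to-frame
  fixation scatter, blinks, and a saccadic reaction latency after each
  shift during which the stimulus still sits about a shift-distance away
  from the PRL;
* three-category ("yes"/"maybe"/"no") fixation-judgment trials in which
  a brief stimulus appears at a random offset inside a 22-arcmin square
  of the raster and the ordinal response depends on both the stimulus
  distance from the raster center and its retinal distance from the
  subjective fixation location (SFL), via a cumulative-logit model.

All randomness flows through ``numpy.random.default_rng(seed)``;
identical specs and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gaze import FixationTrace
from .mosaic import ConeMosaic

__all__ = [
    "MosaicSpec",
    "SessionSpec",
    "SFLTrialSpec",
    "make_cone_mosaic",
    "make_fixation_sessions",
    "make_sfl_trials",
]

RESPONSE_CATEGORIES = ("yes", "maybe", "no")


@dataclass
class MosaicSpec:
    """Parameters of a synthetic foveal cone mosaic.

    ``peak_spacing`` is the center-to-center cone spacing at the density
    peak (arcmin); spacing grows with distance r from the peak as
    ``a(r) = peak_spacing * (1 + r/falloff_scale)`` (``falloff_scale``
    may be ``inf`` for a uniform lattice).  ``extent`` is the square
    half-width of the generated region (>= 17.5 arcmin so that a
    35-arcmin-diameter foveal area is covered).
    """

    peak_location: tuple[float, float] = (0.0, 0.0)
    peak_spacing: float = 0.5
    falloff_scale: float = 80.0
    jitter_sd: float = 0.03
    extent: float = 17.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.peak_spacing <= 0:
            raise ValueError("peak_spacing must be > 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.extent < 17.5:
            raise ValueError("extent must be >= 17.5 arcmin (35-arcmin foveal region)")


@dataclass
class SessionSpec:
    """Parameters of a multi-day fixation-session simulation.

    Distances are arcmin, times seconds.  ``fixation_sd`` is the 2x2
    covariance (arcmin^2) of the frame-to-frame fixation scatter;
    ``day_offset`` displaces the true PRL on days after the first (for
    stability power studies).  Drift/microsaccade magnitudes are
    placeholders for real oculomotor statistics and are configurable.
    """

    prl: tuple[float, float] = (0.0, 0.0)
    fixation_sd: np.ndarray = field(default_factory=lambda: 4.0 * np.eye(2))
    n_runs: int = 4
    run_length_s: float = 30.0
    frame_rate_hz: float = 30.0
    shift_interval_s: tuple[float, float] = (2.0, 6.0)
    shift_distance: tuple[float, float] = (5.5, 15.6)
    shift_region: float = 11.0
    latency_frames: int = 8
    latency_jitter_frames: int = 2
    blink_rate_hz: float = 0.1
    blink_duration_s: float = 0.2
    microsaccade_rate_hz: float = 1.2
    microsaccade_landing_sd: float = 0.3
    drift_sd: float = 0.5
    drift_theta: float = 0.15
    day_offset: tuple[float, float] = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.fixation_sd = np.asarray(self.fixation_sd, dtype=float)
        if self.fixation_sd.shape != (2, 2):
            raise ValueError("fixation_sd must be a 2x2 covariance")
        if self.latency_frames < 0:
            raise ValueError("latency_frames must be >= 0")
        for name in ("blink_rate_hz", "microsaccade_rate_hz", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.shift_interval_s
        if not (0 < lo <= hi):
            raise ValueError("shift_interval_s must satisfy 0 < lo <= hi")
        lo, hi = self.shift_distance
        if not (0 < lo <= hi):
            raise ValueError("shift_distance must satisfy 0 < lo <= hi")


@dataclass
class SFLTrialSpec:
    """Parameters of a fixation-judgment trial set.

    The linear predictor of the cumulative-logit response model is
    ``eta = beta_raster*|s| + beta_prl*|r - sfl| + beta_interaction*|s|*|r - sfl|``
    with s the stimulus offset from the raster center, r its retinal
    location, both arcmin; ``P(response <= k) = sigmoid(threshold_k + eta)``
    over the order yes < maybe < no, so negative slopes make "yes" less
    likely with distance.
    """

    sfl: tuple[float, float] = (0.0, 0.0)
    alignment: tuple[float, float] | None = None  # mean raster-center retinal
    # position; defaults to the SFL (the observer centers the raster on it)
    eye_sd: np.ndarray = field(default_factory=lambda: 9.0 * np.eye(2))
    stim_region: float = 22.0
    n_trials: int = 1500
    beta_raster: float = -0.25
    beta_prl: float = -0.35
    beta_interaction: float = 0.0
    thresholds: tuple[float, float] = (2.0, 4.0)
    microsaccade_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.eye_sd = np.asarray(self.eye_sd, dtype=float)
        if self.eye_sd.shape != (2, 2):
            raise ValueError("eye_sd must be a 2x2 covariance")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not self.thresholds[0] < self.thresholds[1]:
            raise ValueError("thresholds must be strictly increasing")
        if not 0 <= self.microsaccade_prob <= 1:
            raise ValueError("microsaccade_prob must be in [0, 1]")
        if self.stim_region != 22.0:
            raise ValueError("stim_region is fixed at 22 arcmin")


def make_cone_mosaic(spec: MosaicSpec) -> ConeMosaic:
    """Generate a jittered hexagonal cone mosaic with a density peak.

    A regular hexagonal lattice with spacing ``peak_spacing`` is laid out
    in an auxiliary plane and warped radially so that local spacing grows
    as ``a0*(1 + R/falloff_scale)`` with distance R from the peak:
    ``R(rho) = falloff_scale*(exp(rho/falloff_scale) - 1)``.  Independent
    Gaussian jitter of SD ``jitter_sd`` is then added per cone, and cones
    outside the square of half-width ``extent`` around the peak are
    dropped.
    """
    rng = np.random.default_rng(spec.seed)
    a0 = spec.peak_spacing
    s = spec.falloff_scale
    r_max = spec.extent * np.sqrt(2.0) + 2 * a0
    rho_max = r_max if not np.isfinite(s) else s * np.log1p(r_max / s)

    nx = int(np.ceil(rho_max / a0)) + 2
    ny = int(np.ceil(rho_max / (a0 * np.sqrt(3) / 2))) + 2
    j = np.arange(-ny, ny + 1)
    i = np.arange(-nx, nx + 1)
    ii, jj = np.meshgrid(i, j)
    u = a0 * (ii + 0.5 * (jj % 2))
    v = a0 * (np.sqrt(3) / 2) * jj
    pts = np.column_stack([u.ravel(), v.ravel()])

    if np.isfinite(s):
        rho = np.linalg.norm(pts, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(rho > 0, s * np.expm1(rho / s) / np.maximum(rho, 1e-300), 1.0)
        pts = pts * factor[:, None]

    pts = pts + np.asarray(spec.peak_location, dtype=float)
    if spec.jitter_sd > 0:
        pts = pts + rng.normal(0.0, spec.jitter_sd, size=pts.shape)

    rel = pts - np.asarray(spec.peak_location, dtype=float)
    keep = np.max(np.abs(rel), axis=1) <= spec.extent
    pts = pts[keep]
    # stable order for determinism independent of float noise in keep mask
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return ConeMosaic(cones=pts[order])


def _sample_target_schedule(spec: SessionSpec, rng: np.random.Generator):
    """Shift times (frames) and target raster positions for one run."""
    half = spec.shift_region / 2.0
    n_frames = int(round(spec.run_length_s * spec.frame_rate_hz))
    targets = [rng.uniform(-half, half, size=2)]
    starts = [0]
    t = 0.0
    while True:
        t += rng.uniform(*spec.shift_interval_s)
        f = int(round(t * spec.frame_rate_hz))
        if f >= n_frames:
            break
        # new target inside the region at a shift distance in range
        for _ in range(10_000):
            cand = rng.uniform(-half, half, size=2)
            d = np.linalg.norm(cand - targets[-1])
            if spec.shift_distance[0] <= d <= spec.shift_distance[1]:
                break
        else:  # pragma: no cover - geometrically impossible for spec ranges
            raise RuntimeError("could not sample a target shift")
        targets.append(cand)
        starts.append(f)
    return np.array(starts), np.array(targets), n_frames


def make_fixation_sessions(spec: SessionSpec, n_days: int = 2):
    """Simulate ``n_days`` of fixation runs; returns traces and ground truth.

    Per day, ``n_runs`` 30-s runs at 30 Hz.  The recorded retinal
    location of the target is ``PRL(+day_offset) + drift + scatter``
    plus, for ``latency`` frames after each target shift, the offset
    ``target_new - target_old`` (the eye still fixates the old target,
    so the shifted stimulus lands a shift-distance away from the PRL
    until the simulated saccade).  Blinks mark frames invalid.

    Returns ``(traces, truth)`` where ``traces`` is a list of
    :class:`~fovealoc.gaze.FixationTrace` (one per day) and ``truth``
    holds per-day true PRLs, epoch boundaries, microsaccade and blink
    frame indices.
    """
    rng = np.random.default_rng(spec.seed)
    chol = np.linalg.cholesky(spec.fixation_sd + 1e-15 * np.eye(2))
    dt = 1.0 / spec.frame_rate_hz
    traces = []
    truth = {"prl_true": [], "epochs": [], "microsaccades": [], "blinks": []}

    for day in range(n_days):
        prl = np.asarray(spec.prl, dtype=float)
        if day > 0:
            prl = prl + np.asarray(spec.day_offset, dtype=float)
        truth["prl_true"].append(prl.copy())
        rows = []
        sched_rows = []
        for run in range(spec.n_runs):
            starts, targets, n_frames = _sample_target_schedule(spec, rng)
            epoch_of = np.searchsorted(starts, np.arange(n_frames), side="right") - 1
            latencies = np.maximum(
                0,
                spec.latency_frames
                + rng.integers(-spec.latency_jitter_frames, spec.latency_jitter_frames + 1,
                               size=len(starts)),
            )
            # drift: mean-reverting (OU-like) walk at stationary SD drift_sd
            theta = spec.drift_theta
            sigma_step = spec.drift_sd * np.sqrt(max(2 * theta - theta**2, 1e-12))
            drift = np.zeros(2)
            ms_p = 1.0 - np.exp(-spec.microsaccade_rate_hz * dt)
            blink_p = 1.0 - np.exp(-spec.blink_rate_hz * dt)
            blink_frames_left = 0
            scatter = rng.normal(size=(n_frames, 2)) @ chol.T
            ms_draws = rng.random(n_frames)
            blink_draws = rng.random(n_frames)
            for e, (f0, tgt) in enumerate(zip(starts, targets)):
                sched_rows.append((day, run, e, int(f0), float(tgt[0]), float(tgt[1])))
            for f in range(n_frames):
                e = epoch_of[f]
                drift = drift * (1 - theta) + rng.normal(0.0, sigma_step, size=2)
                saccaded = e == 0 or (f - starts[e]) >= latencies[e]
                if ms_draws[f] < ms_p:
                    truth["microsaccades"].append((day, run, f))
                    drift = rng.normal(0.0, spec.microsaccade_landing_sd, size=2)
                if not saccaded:
                    offset = targets[e] - targets[e - 1]
                else:
                    offset = np.zeros(2)
                p = prl + drift + scatter[f] + offset
                if blink_frames_left > 0:
                    blink_frames_left -= 1
                    valid = False
                elif blink_draws[f] < blink_p:
                    blink_frames_left = int(round(spec.blink_duration_s / dt)) - 1
                    truth["blinks"].append((day, run, f))
                    valid = False
                else:
                    valid = True
                rows.append(
                    (day, run, f, int(e), f * dt, p[0], p[1], valid,
                     targets[e][0], targets[e][1])
                )
        samples = pd.DataFrame(
            rows,
            columns=["day", "run", "frame", "epoch", "t_s", "x_arcmin", "y_arcmin",
                     "valid", "target_raster_x", "target_raster_y"],
        )
        schedule = pd.DataFrame(
            sched_rows, columns=["day", "run", "epoch", "start_frame", "target_x", "target_y"]
        )
        traces.append(FixationTrace(samples, schedule))
        truth["epochs"].append(schedule)
    return traces, truth


def make_sfl_trials(spec: SFLTrialSpec):
    """Simulate fixation-judgment trials; returns (trials, truth).

    Per trial: stimulus offset s uniform in the 22-arcmin square around
    the raster center; raster-center retinal position
    e ~ N(alignment, eye_sd), where ``alignment`` defaults to the SFL
    (the observer centers the raster on it on average);
    retinal stimulus location r = e + s; ordinal response from the
    cumulative-logit model; independent microsaccade flags.

    ``trials`` is a DataFrame with columns trial, s_x, s_y, e_x, e_y,
    r_x, r_y, response, microsaccade_250ms.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_trials
    half = spec.stim_region / 2.0
    sfl = np.asarray(spec.sfl, dtype=float)
    align = sfl if spec.alignment is None else np.asarray(spec.alignment, float)
    s = rng.uniform(-half, half, size=(n, 2))
    e = align + rng.normal(size=(n, 2)) @ np.linalg.cholesky(spec.eye_sd + 1e-15 * np.eye(2)).T
    r = e + s

    d_raster = np.linalg.norm(s, axis=1)
    d_prl = np.linalg.norm(r - sfl, axis=1)
    eta = (
        spec.beta_raster * d_raster
        + spec.beta_prl * d_prl
        + spec.beta_interaction * d_raster * d_prl
    )
    p_le_yes = _sigmoid(spec.thresholds[0] + eta)
    p_le_maybe = _sigmoid(spec.thresholds[1] + eta)
    u = rng.random(n)
    resp_idx = (u > p_le_yes).astype(int) + (u > p_le_maybe).astype(int)
    response = np.array(RESPONSE_CATEGORIES)[resp_idx]
    ms = rng.random(n) < spec.microsaccade_prob

    trials = pd.DataFrame(
        {
            "trial": np.arange(n),
            "s_x": s[:, 0], "s_y": s[:, 1],
            "e_x": e[:, 0], "e_y": e[:, 1],
            "r_x": r[:, 0], "r_y": r[:, 1],
            "response": response,
            "microsaccade_250ms": ms,
        }
    )
    truth = {
        "sfl_true": sfl,
        "beta_raster": spec.beta_raster,
        "beta_prl": spec.beta_prl,
        "beta_interaction": spec.beta_interaction,
        "thresholds": tuple(spec.thresholds),
        "eta": eta,
    }
    return trials, truth


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x)))
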