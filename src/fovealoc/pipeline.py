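"""End-to-end orchestration: cone density -> PRL -> SFL -> comparisons.

``run_pipeline`` is a pure function of (inputs, config, seed): it either
loads cone/trace/trial CSVs or simulates them with the synthetic
generator, then computes the density peak, per-day PRLs with stability
tests, the SFL fit, and the comparative statistics, writing JSON/CSV
reports (and optional figure analogs) under the output directory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as fio
from .gaze import exclude_settling_frames, settling_curve
from .mosaic import density_at, mosaic_density_map, nyquist_limit
from .prl import epoch_means, ks2d, prl_summary
from .sfl import fit_sfl_model, quadratic_mean_radius, radial_profile
from .compare import multinomial_logit, pearson, roi_yes_proportion_test
from .synthetic import (MosaicSpec, SessionSpec, SFLTrialSpec,
                        make_cone_mosaic, make_fixation_sessions, make_sfl_trials)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("fovealoc")


@dataclass
class PipelineConfig:
    """Paths, analysis parameters, and seed for a pipeline run.

    When a path is None the corresponding input is simulated with the
    synthetic generator (sharing ``seed``).
    """

    cones_csv: str | None = None
    trace_csv: str | None = None
    trials_csv: str | None = None
    out_dir: str = "fovealoc_out"
    window_arcmin: float = 8.0
    n_exclude: int = 20
    ks_method: str = "permutation"
    sfl_starts: int = 8
    n_days: int = 2
    seed: int = 0
    make_plots: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns (and writes) the report bundle."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)

    # --- cone mosaic and density peak -----------------------------------
    if config.cones_csv:
        mosaic = fio.read_cone_csv(config.cones_csv)
    else:
        mosaic = make_cone_mosaic(MosaicSpec(seed=rng_seed))
    log.info("cone mosaic: %d cones", mosaic.n_cones)
    dmap = mosaic_density_map(mosaic, window=config.window_arcmin)
    c_peak = dmap.peak
    log.info("density peak %.2f cones/deg^2 at (%.2f, %.2f) arcmin",
             dmap.peak_density, *c_peak)

    # --- fixation traces and per-day PRLs -------------------------------
    if config.trace_csv:
        traces = [fio.read_trace_csv(config.trace_csv)]
        days = sorted(traces[0].samples["day"].unique())
        traces = [
            type(traces[0])(
                traces[0].samples[traces[0].samples["day"] == d].reset_index(drop=True),
                traces[0].schedule[traces[0].schedule["day"] == d].reset_index(drop=True),
            )
            for d in days
        ]
    else:
        traces, _truth = make_fixation_sessions(SessionSpec(seed=rng_seed + 1),
                                                n_days=config.n_days)
    curve = settling_curve(traces)
    traces = [exclude_settling_frames(t, n_exclude=config.n_exclude) for t in traces]
    day_points = [t.valid_points() for t in traces]
    for i, pts in enumerate(day_points):
        log.info("day %d: %d valid samples", i, len(pts))
    summary = prl_summary(day_points, cone_peak=c_peak)
    i1, i2 = summary["compared_days"]
    ks = ks2d(epoch_means(traces[i1]), epoch_means(traces[i2]),
              method=config.ks_method, seed=rng_seed + 2)

    # --- SFL trials and model -------------------------------------------
    if config.trials_csv:
        trials = fio.read_trial_csv(config.trials_csv)
    else:
        prl_mean = summary["per_day"][0].mu
        trials, _ = make_sfl_trials(SFLTrialSpec(sfl=tuple(prl_mean + np.array([1.0, -0.5])),
                                                 seed=rng_seed + 3))
    findings = fio.validate_inputs(trials=trials)
    if findings:
        raise ValueError(f"trial table failed validation: {findings[:3]}")
    model = fit_sfl_model(trials, n_starts=config.sfl_starts, seed=rng_seed + 4)
    profile = radial_profile(trials, model, seed=rng_seed + 5)

    # --- comparative statistics -----------------------------------------
    prl_xy = summary["per_day"][0].mu
    d_raster = np.hypot(trials["s_x"], trials["s_y"]).to_numpy()
    d_prl = np.linalg.norm(trials[["r_x", "r_y"]].to_numpy() - prl_xy, axis=1)
    corr = pearson(d_raster, d_prl)
    ordinal = multinomial_logit(trials, prl_xy)
    try:
        roi = roi_yes_proportion_test(trials, prl_xy)
        roi_dict = {"chi2": roi.statistic, "df": roi.df, "p": roi.p, "n": roi.n,
                    **roi.effect}
    except ValueError as exc:
        roi_dict = {"error": str(exc)}

    # --- sampling limits and report -------------------------------------
    try:
        nc_prl = nyquist_limit(density_at(dmap, prl_xy))
    except ValueError:
        nc_prl = None
    report = {
        "cone_peak": {
            "location_arcmin": c_peak.tolist(),
            "density_cones_per_deg2": dmap.peak_density,
            "nyquist_cpd": nyquist_limit(dmap.peak_density),
        },
        "prl": {
            "per_day": [
                {
                    "day": e.day,
                    "mu_arcmin": e.mu.tolist(),
                    "geometric_median_arcmin": e.geometric_median.tolist(),
                    "sigma_arcmin2": e.sigma.tolist(),
                    "n": e.n,
                    "dist_to_peak_arcmin": e.dist_to_peak,
                    "angle_from_peak_rad": e.angle_from_peak,
                    "qmr_arcmin": quadratic_mean_radius(e.sigma),
                }
                for e in summary["per_day"]
            ],
            "max_pairwise_distance_arcmin": summary["max_pairwise_distance"],
            "nyquist_at_prl_cpd": nc_prl,
            "aic": {
                "AIC_m1": summary["comparison"].AIC_m1,
                "AIC_m2": summary["comparison"].AIC_m2,
                "delta_AIC": summary["comparison"].delta_AIC,
                "p_m1": summary["comparison"].p_m1,
                "evidence_ratio": summary["comparison"].evidence_ratio,
            },
            "ks": {"D": ks.D, "p": ks.p, "n1": ks.n1, "n2": ks.n2},
            "settling_curve_arcmin": np.asarray(curve).tolist(),
        },
        "sfl": {
            "center_arcmin": model.center.tolist(),
            "sigma_yes_arcmin2": model.sigma_yes.tolist(),
            "sigma_maybe_arcmin2": model.sigma_maybe.tolist(),
            "sigma_in_arcmin2": model.sigma_in.tolist(),
            "kappa": model.kappa,
            "logL": model.logL,
            "counts": model.counts,
            "qmr_yes_arcmin": quadratic_mean_radius(model.sigma_yes),
        },
        "comparisons": {
            "raster_prl_distance_correlation": {
                "r": corr.statistic, "df": corr.df, "p": corr.p,
            },
            "ordinal_model": {
                "coefficients": ordinal.coefficients,
                "se": ordinal.se,
                "lr_tests": {k: {"chi2": v.statistic, "df": v.df, "p": v.p}
                             for k, v in ordinal.lr_tests.items()},
            },
            "roi_yes_test": roi_dict,
        },
        "config": {k: getattr(config, k) for k in
                   ("window_arcmin", "n_exclude", "ks_method", "sfl_starts",
                    "n_days", "seed")},
    }
    fio.write_json(report, out / "report.json")
    fio.write_density_map(dmap, out / "density.tiff", out / "density.json")
    import pandas as pd

    pd.DataFrame(
        [{"day": e.day, "prl_x": e.mu[0], "prl_y": e.mu[1]} for e in summary["per_day"]]
    ).to_csv(out / "prl.csv", index=False)

    if config.make_plots:
        _write_plots(out, curve, summary, model, profile, c_peak)
    log.info("report written to %s", out / "report.json")
    return report


def _write_plots(out: Path, curve, summary, model, profile, c_peak) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(13, 4))
    axes[0].plot(curve)
    axes[0].axvline(20, color="k", ls="--")
    axes[0].set(xlabel="frames since shift", ylabel="distance from epoch median (arcmin)",
                title="settling curve")
    for e in summary["per_day"]:
        axes[1].plot(e.mu[0] - c_peak[0], e.mu[1] - c_peak[1], "o", label=f"day {e.day}")
    axes[1].plot(0, 0, "k+", ms=12)
    axes[1].set(xlabel="x - peak (arcmin)", ylabel="y - peak (arcmin)",
                title="PRL vs cone peak")
    axes[1].legend()
    for cat, color in (("yes", "g"), ("maybe", "b"), ("no", "r")):
        axes[2].plot(profile["r"], profile[cat]["profile"], color=color, label=cat)
        axes[2].fill_between(profile["r"], profile[cat]["lo"], profile[cat]["hi"],
                             color=color, alpha=0.2)
    axes[2].set(xlabel="distance from SFL (arcmin)", ylabel="normalized density",
                title="response radial profiles")
    axes[2].legend()
    fig.tight_layout()
    fig.savefig(out / "figures.png", dpi=120)
    plt.close(fig)
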