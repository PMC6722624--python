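"""End-to-end orchestration: simulate -> preprocess -> fit -> report.

Each (action, mode) dataset gets its own hierarchical-GAM fit; the report
assembles posterior torque-angle curves, the two functional H:Q ratio curves
with equality crossings and extrema, a WAIC comparison of the
with/without-individual-smooth-deviation variants, and optional figures.
Extension outputs are written on the rescaled extension-progress axis
(0 deg = start of the action at 90 deg of knee flexion) for display; all
pairing happens on the anatomical flexion-angle axis.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import data as dmod
from .analysis import (CurveDraws, compare_waic, functional_ratio,
                       posterior_curve)
from .config import RunConfig
from .data import ActionSeries, rescale_extension_angle
from .model import HGAMFit, HGAMSpec, Priors, fit_hgam, save_fit
from .simulate import ACTION_MODES, simulate_dataset

logger = logging.getLogger(__name__)


def _mode_seed(base: int, action: str, mode: str, variant: int = 0) -> int:
    offset = ACTION_MODES.index((action, mode)) + 4 * variant
    return (int(base) * 131 + offset) % (2 ** 31 - 1)


def run_simulate(cfg: RunConfig) -> Path:
    """Write the synthetic dataset CSV and its ground-truth record."""
    out = cfg.resolved_outdir()
    df, truth = simulate_dataset(cfg.generator)
    csv_path = out / "synthetic_trials.csv"
    df.to_csv(csv_path, index=False, float_format="%.17g")
    truth.to_json(out / "truth.json")
    cfg.to_yaml(out / "resolved_config.yaml")
    logger.info("wrote %d rows to %s", len(df), csv_path)
    return csv_path


def load_series(cfg: RunConfig) -> dict[tuple[str, str], list[ActionSeries]]:
    """Read trials (user CSV or previously simulated) and preprocess."""
    out = cfg.resolved_outdir()
    path = Path(cfg.input_csv) if cfg.input_csv else out / "synthetic_trials.csv"
    df, report = dmod.read_trials(path)
    if report.n_rejected:
        logger.warning("validation rejected %d rows: %s", report.n_rejected,
                       report.by_reason)
    return dmod.preprocess(df, cfg.target_velocity_dps, cfg.tolerance_dps)


def _spec(cfg: RunConfig, include_individual: bool) -> HGAMSpec:
    m = cfg.model
    return HGAMSpec.default(
        (0.0, 90.0), k_pop=m.k_pop, k_ind=m.k_ind, degree=m.degree,
        penalty_order=m.penalty_order,
        include_individual_smooths=include_individual,
        priors=Priors(m.variance_prior_shape, m.variance_prior_rate,
                      m.fixed_prior_variance))


def run_fit(cfg: RunConfig) -> dict[tuple[str, str], dict[str, HGAMFit]]:
    """Fit every (action, mode) dataset; optionally also the intercept-only
    variant for WAIC comparison.  Fit artifacts are serialized per fit."""
    out = cfg.resolved_outdir()
    groups = load_series(cfg)
    m = cfg.model
    fits: dict[tuple[str, str], dict[str, HGAMFit]] = {}
    variants = [("full", True)] + ([("intercept_only", False)]
                                   if cfg.compare_models else [])
    for (action, mode), series in sorted(groups.items()):
        fits[(action, mode)] = {}
        for v, (name, include) in enumerate(variants):
            fit = fit_hgam(series, _spec(cfg, include), n_iter=m.n_iter,
                           n_warmup=m.n_warmup,
                           seed=_mode_seed(cfg.seed, action, mode, v),
                           n_chains=m.n_chains)
            fits[(action, mode)][name] = fit
            save_fit(fit, out / f"fit_{action}_{mode}_{name}")
        logger.info("fitted %s %s (%d athletes)", action, mode, len(series))
    return fits


def run_report(cfg: RunConfig,
               fits: dict[tuple[str, str], dict[str, HGAMFit]]) -> dict:
    """Curves, ratios, crossings/extrema, WAIC table and plots."""
    out = cfg.resolved_outdir()
    a = cfg.analysis
    # common grid over the angles every fit's truly-isokinetic data support
    lo = max(f["full"].design.angle_range[0] for f in fits.values())
    hi = min(f["full"].design.angle_range[1] for f in fits.values())
    grid = np.round(np.arange(0.0, 90.0 + 1e-9, a.grid_step_deg), 10)
    grid = grid[(grid >= lo - 1e-9) & (grid <= hi + 1e-9)]
    curves: dict[tuple[str, str], CurveDraws] = {}
    for (action, mode), variants in fits.items():
        cd = posterior_curve(variants["full"], grid)
        cd.source = (action, mode)
        curves[(action, mode)] = cd
        summ = cd.summary(a.credible_level)
        if action == "extension":
            summ = summ.assign(angle=rescale_extension_angle(
                summ["angle"].to_numpy())).sort_values("angle",
                                                       ignore_index=True)
        summ.to_csv(out / f"curve_{action}_{mode}.csv", index=False,
                    float_format="%.17g")

    report: dict = {"curves": {}, "ratios": {}}
    for (action, mode), cd in curves.items():
        report["curves"][f"{action}_{mode}"] = {
            "extrema": posterior_extrema_on_axis(cd, action),
        }

    ratios = {}
    if ("extension", "eccentric") in curves and ("extension", "concentric") in curves:
        ratios["extension"] = functional_ratio(
            curves[("extension", "eccentric")], curves[("extension", "concentric")],
            eps_torque=a.eps_torque, seed=cfg.seed)
    if ("flexion", "concentric") in curves and ("flexion", "eccentric") in curves:
        ratios["flexion"] = functional_ratio(
            curves[("flexion", "concentric")], curves[("flexion", "eccentric")],
            eps_torque=a.eps_torque, seed=cfg.seed)

    for name, rc in ratios.items():
        summ = rc.summary(a.credible_level)
        crossings = rc.crossings(1.0)
        extrema = rc.extrema()
        if name == "extension":
            summ = summ.assign(angle=rescale_extension_angle(
                summ["angle"].to_numpy())).sort_values("angle",
                                                       ignore_index=True)
            crossings = sorted(rescale_extension_angle(c) for c in crossings)
            extrema = sorted((rescale_extension_angle(ang), val, kind)
                             for ang, val, kind in extrema)
        summ.to_csv(out / f"ratio_{name}.csv", index=False, float_format="%.17g")
        report["ratios"][name] = {
            "point_of_equality_crossings_deg": crossings,
            "extrema": [(ang, val, kind) for ang, val, kind in extrema],
            "axis": "extension_progress" if name == "extension" else "flexion_angle",
        }

    if cfg.compare_models:
        tables = []
        for (action, mode), variants in sorted(fits.items()):
            if "intercept_only" not in variants:
                continue
            tab = compare_waic(variants["full"], variants["intercept_only"],
                               names=("intercept+smooth", "intercept-only"))
            tab.insert(0, "dataset", f"{action}_{mode}")
            tables.append(tab)
        if tables:
            waic_table = pd.concat(tables, ignore_index=True)
            waic_table.to_csv(out / "waic_comparison.csv", index=False,
                              float_format="%.17g")
            report["waic"] = waic_table.to_dict(orient="records")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)

    if cfg.make_plots:
        from .plots import plot_curves, plot_ratios
        plot_curves(curves, out / "fig_torque_curves.png", a.credible_level)
        plot_ratios(ratios, out / "fig_hq_ratios.png", a.credible_level)
    return report


def posterior_extrema_on_axis(cd: CurveDraws, action: str) -> list:
    """Interior extrema of the posterior-mean curve, on the display axis."""
    from .analysis import find_extrema

    ext = find_extrema(cd.grid, cd.mean)
    if action == "extension":
        ext = sorted((rescale_extension_angle(ang), val, kind)
                     for ang, val, kind in ext)
    return [(ang, val, kind) for ang, val, kind in ext]


def run_all(cfg: RunConfig) -> dict:
    run_simulate(cfg)
    fits = run_fit(cfg)
    return run_report(cfg, fits)
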