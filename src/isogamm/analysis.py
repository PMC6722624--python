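"""Posterior summaries: predicted curves, functional H:Q ratios, crossings,
extrema and WAIC model comparison.

The functional hamstring:quadriceps ratio for knee extension divides eccentric
hamstring torque by concentric quadriceps torque at each joint angle; for knee
flexion, concentric hamstring by eccentric quadriceps.  A ratio of 1.0 is the
point of equality: the antagonist can exactly brake the agonist there.  Ratio
draws pair MCMC iterations s-by-s across the two independently fitted
posteriors, which is valid because the posteriors are independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .model import HGAMFit

DEFAULT_GRID = np.arange(0.0, 91.0, 1.0)
EPS_TORQUE = 1.0  # N*m; denominator mask threshold against ratio blow-up


@dataclass
class CurveDraws:
    """Posterior draws of a mean torque (or ratio) curve on a common grid."""

    grid: np.ndarray
    draws: np.ndarray            # (S, G)
    axis: str = "flexion_angle"
    source: tuple[str, str] | None = None   # (action, mode)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite curve draws")

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    def band(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise equal-tailed credible band (percentiles of the draws)."""
        a = 100 * (1 - level) / 2
        return (np.percentile(self.draws, a, axis=0),
                np.percentile(self.draws, 100 - a, axis=0))

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = self.band(level)
        return pd.DataFrame({"angle": self.grid, "mean": self.mean,
                             "lower95": lo, "upper95": hi})


def posterior_curve(fit: HGAMFit, grid: np.ndarray | None = None,
                    include_random_variance: bool = False,
                    seed: int = 0) -> CurveDraws:
    """Population-mean torque curve draws: beta0 + f(grid) per iteration.

    Random effects are marginalized at their zero mean; with
    ``include_random_variance`` a fresh athlete's intercept and smooth
    deviation are drawn per iteration from the sampled variance components,
    giving a predictive band for a new individual.  The grid must lie inside
    the fitted basis domain (no extrapolation); the default grid covers the
    whole-degree angles inside the fit's observed data range, because outside
    the truly-isokinetic span the curve is informed by the prior alone.
    """
    d = fit.design
    if grid is None:
        lo_d, hi_d = d.angle_range
        grid = DEFAULT_GRID[(DEFAULT_GRID >= lo_d - 1e-9)
                            & (DEFAULT_GRID <= hi_d + 1e-9)]
    grid = np.asarray(grid, dtype=float)
    lo, hi = d.spec.basis_pop.domain
    if grid.min() < lo or grid.max() > hi:
        raise ValueError(f"grid outside fitted domain [{lo}, {hi}]")
    Xg = np.column_stack([np.ones(len(grid)), d.spec.basis_pop.design_null(grid)])
    Zg = d.spec.basis_pop.design_pen(grid)
    coef = fit.coef_flat()
    sl = d.slices()
    draws = coef[:, sl["fixed"]] @ Xg.T + coef[:, sl["u_pop"]] @ Zg.T
    if include_random_variance and d.n_athletes:
        rng = np.random.default_rng(seed)
        var = fit.variances_flat()
        draws = draws + rng.standard_normal(len(coef))[:, None] * np.sqrt(var[:, [1]])
        if d.n_ind_per_athlete:
            Zi = d.spec.basis_ind.design_pen(grid)
            u = rng.standard_normal((len(coef), Zi.shape[1]))
            draws = draws + (u * np.sqrt(var[:, [2]])) @ Zi.T
    return CurveDraws(grid=grid, draws=draws, source=None)


@dataclass
class RatioCurve:
    """Posterior draws and summaries of a functional H:Q ratio curve."""

    grid: np.ndarray
    ratio_draws: np.ndarray
    mask: np.ndarray = field(default=None)  # True where denominator too small

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.zeros(len(self.grid), dtype=bool)

    @property
    def mean(self) -> np.ndarray:
        m = self.ratio_draws.mean(axis=0)
        return np.where(self.mask, np.nan, m)

    def band(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        a = 100 * (1 - level) / 2
        lo = np.percentile(self.ratio_draws, a, axis=0)
        hi = np.percentile(self.ratio_draws, 100 - a, axis=0)
        return (np.where(self.mask, np.nan, lo), np.where(self.mask, np.nan, hi))

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = self.band(level)
        return pd.DataFrame({"angle": self.grid, "mean": self.mean,
                             "lower95": lo, "upper95": hi})

    def crossings(self, level: float = 1.0) -> list[float]:
        """Angles where the posterior-mean ratio crosses ``level``."""
        return find_level_crossings(self.grid, self.mean, level)

    def extrema(self) -> list[tuple[float, float, str]]:
        return find_extrema(self.grid, self.mean)


def functional_ratio(numerator: CurveDraws, denominator: CurveDraws,
                     eps_torque: float = EPS_TORQUE, seed: int = 0) -> RatioCurve:
    """Pointwise ratio of two curve posteriors, paired iteration-by-iteration.

    If draw counts differ the larger set is subsampled (without replacement,
    fixed seed).  Grid points where the denominator's posterior mean falls
    below ``eps_torque`` are masked; a warning fires if more than 20% of the
    grid is masked.
    """
    if numerator.grid.shape != denominator.grid.shape or \
            not np.allclose(numerator.grid, denominator.grid):
        raise ValueError("numerator and denominator grids differ")
    num, den = numerator.draws, denominator.draws
    if len(num) != len(den):
        rng = np.random.default_rng(seed)
        s = min(len(num), len(den))
        if len(num) > s:
            num = num[np.sort(rng.choice(len(num), s, replace=False))]
        else:
            den = den[np.sort(rng.choice(len(den), s, replace=False))]
    mask = denominator.mean < eps_torque
    if mask.mean() > 0.20:
        warnings.warn(f"{mask.sum()}/{len(mask)} grid points masked "
                      f"(denominator mean < {eps_torque} N*m)", stacklevel=2)
    safe_den = np.where(den == 0, np.nan, den)
    return RatioCurve(grid=numerator.grid, ratio_draws=num / safe_den, mask=mask)


def find_level_crossings(grid, values, level: float = 1.0) -> list[float]:
    """Linear-interpolation crossings of a curve through a reference level.

    Exact grid-point hits are reported once; NaN segments (masked points) are
    skipped; the result is sorted ascending.  An empty list is a valid result.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(grid) < 2:
        raise ValueError("need at least 2 grid points")
    out: list[float] = []
    diff = values - level
    for i, d in enumerate(diff):
        if d == 0.0:
            out.append(float(grid[i]))
    for i in range(len(grid) - 1):
        a, b = diff[i], diff[i + 1]
        if np.isnan(a) or np.isnan(b):
            continue
        if a * b < 0:
            t = a / (a - b)
            out.append(float(grid[i] + t * (grid[i + 1] - grid[i])))
    return sorted(out)


def find_extrema(grid, values) -> list[tuple[float, float, str]]:
    """Interior local maxima/minima of a curve sampled on a grid.

    Detected as sign changes of first differences; a flat plateau reports its
    midpoint; endpoints are never reported; NaN stretches (masked points)
    break the curve into independently scanned segments.  Returns (angle,
    value, kind) tuples with kind in {"max", "min"}, ordered by angle.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(grid) < 3:
        raise ValueError("need at least 3 grid points")
    d = np.diff(values)
    sign = np.sign(d)
    out: list[tuple[float, float, str]] = []
    last_sign = 0.0
    last_change = 0          # index where the current run of equal values began
    for i, s in enumerate(sign):
        if np.isnan(s):
            last_sign = 0.0
            last_change = i + 1
            continue
        if s == 0.0:
            continue
        if last_sign != 0.0 and s != last_sign:
            # extremum spans grid[last_change .. i] (plateau if they differ)
            a = 0.5 * (grid[last_change] + grid[i])
            kind = "max" if last_sign > 0 else "min"
            out.append((float(a), float(values[i]), kind))
        if s != 0.0:
            last_sign = s
        last_change = i + 1
    return out


@dataclass
class WAICResult:
    waic: float
    elpd: float
    p_waic: float
    pointwise: pd.DataFrame

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"WAICResult(waic={self.waic:.2f}, elpd={self.elpd:.2f}, "
                f"p_waic={self.p_waic:.2f})")


def compute_waic(loglik: np.ndarray | HGAMFit) -> WAICResult:
    """Widely applicable information criterion from pointwise log-likelihoods.

    lppd_i = log mean_s exp(l_is) (computed with log-sum-exp), p_waic_i =
    var_s(l_is) (sample variance, ddof=1), waic = -2 * (lppd - p_waic).
    Lower WAIC is better.
    """
    ll = loglik.loglik if isinstance(loglik, HGAMFit) else np.asarray(loglik, dtype=float)
    S = ll.shape[0]
    if S < 2:
        raise ValueError("WAIC needs at least 2 posterior draws")
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = ll.var(axis=0, ddof=1)
    lppd, p_waic = float(lppd_i.sum()), float(p_i.sum())
    elpd = lppd - p_waic
    pointwise = pd.DataFrame({"lppd": lppd_i, "p_waic": p_i,
                              "elpd": lppd_i - p_i})
    return WAICResult(waic=-2.0 * elpd, elpd=elpd, p_waic=p_waic,
                      pointwise=pointwise)


def compare_waic(fit_a, fit_b, names: tuple[str, str] = ("model_a", "model_b")
                 ) -> pd.DataFrame:
    """WAIC comparison table for two fits of the same observations.

    Reports each model's WAIC/elpd/p_waic plus the pairwise elpd difference
    (a - b) and its standard error sqrt(n * var(elpd_i^a - elpd_i^b)).
    """
    wa, wb = compute_waic(fit_a), compute_waic(fit_b)
    da = wa.pointwise["elpd"].to_numpy()
    db = wb.pointwise["elpd"].to_numpy()
    if len(da) != len(db):
        raise ValueError("fits score different observation sets")
    n = len(da)
    diff = da - db
    se = float(np.sqrt(n * diff.var(ddof=1)))
    return pd.DataFrame({
        "model": list(names),
        "waic": [wa.waic, wb.waic],
        "elpd": [wa.elpd, wb.elpd],
        "p_waic": [wa.p_waic, wb.p_waic],
        "elpd_diff_vs_other": [wa.elpd - wb.elpd, wb.elpd - wa.elpd],
        "elpd_diff_se": [se, se],
    })


def peak_torque_ratio(numerator: CurveDraws, denominator: CurveDraws) -> float:
    """Conventional single-number H:Q ratio of posterior-mean peak torques.

    Reported only as a convenience scalar for comparison with the traditional
    peak-moment approach; the angle-specific ratio curve is the modeled object.
    """
    return float(numerator.mean.max() / denominator.mean.max())
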