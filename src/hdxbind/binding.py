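"""Dissociation-constant estimation from FCS titrations and ITC isotherms.

Two FCS routes: the empirical Boltzmann sigmoid in log10-concentration
(the fit the source study used; Kd = 10^x50) and the exact single-site
depletion model, which is unbiased when the labeled concentration is
comparable to Kd. ITC uses the standard one-site isotherm with
volume-displacement dilution and a fitted per-injection baseline.

Confidence intervals are nonparametric bootstrap percentiles (seeded),
chosen over asymptotic intervals because point counts are small.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import DomainError, EmptyTitrationError, FitFailureError
from .simulate import bound_fraction, itc_injection_heats


@dataclass(frozen=True)
class TitrationPoint:
    concentration: float  # nM
    tau: float  # us
    replicate: int = 1
    sd_pct: float | None = None  # within-point SD, percent of tau

    def __post_init__(self):
        if self.concentration < 0:
            raise DomainError("concentration must be >= 0")
        if not self.tau > 0:
            raise DomainError("diffusion time must be positive")


def points_from_frame(frame: pd.DataFrame) -> list[TitrationPoint]:
    """Build points from a titration CSV frame (see simulate module)."""
    sd = frame["sd_pct"] if "sd_pct" in frame.columns else [None] * len(frame)
    return [
        TitrationPoint(float(c), float(t), int(r), None if s is None else float(s))
        for c, t, r, s in zip(
            frame["concentration_nM"], frame["tau_us"], frame["replicate"], sd
        )
    ]


@dataclass
class FcsFitResult:
    kd: float  # nM
    tau_free: float
    tau_bound: float
    model: str  # "boltzmann" | "depletion"
    slope: float | None = None  # log10 units, boltzmann only
    ci95_kd: tuple[float, float] | None = None
    n_points_used: int = 0
    n_points_excluded: int = 0
    residual: float = math.nan
    warnings: list[str] = field(default_factory=list)


@dataclass
class ItcFitResult:
    kd: float  # uM
    delta_h: float  # kcal/mol
    n_sites: float
    baseline: float  # ucal per injection
    ci95_kd: tuple[float, float] | None = None
    residual: float = math.nan
    warnings: list[str] = field(default_factory=list)


def exclude_noisy_points(
    points: Sequence[TitrationPoint], max_cv: float = 8.0
) -> tuple[list[TitrationPoint], list[str]]:
    """Drop points whose within-point SD% strictly exceeds ``max_cv``.

    Points without an SD annotation are kept. Raises when nothing survives.
    """
    if not max_cv > 0:
        raise DomainError("max_cv must be positive")
    kept, log = [], []
    for p in points:
        if p.sd_pct is not None and p.sd_pct > max_cv:
            log.append(
                f"excluded c={p.concentration:g} nM rep {p.replicate}: "
                f"SD {p.sd_pct:.2f}% > {max_cv:g}%"
            )
        else:
            kept.append(p)
    if not kept:
        raise EmptyTitrationError(
            f"all {len(points)} titration points excluded at SD > {max_cv}%"
        )
    return kept, log


# ---------------------------------------------------------------------------
# FCS fits


def _boltzmann_tau(x: np.ndarray, tau_f: float, tau_b: float, x50: float, slope: float):
    return tau_f + (tau_b - tau_f) / (1.0 + np.exp((x50 - x) / slope))


def fit_fcs_boltzmann(
    points: Sequence[TitrationPoint],
    *,
    max_cv: float | None = 8.0,
    n_bootstrap: int = 500,
    seed: int = 0,
) -> FcsFitResult:
    """Global Boltzmann sigmoid fit in log10 concentration; Kd = 10^x50.

    All replicates share all four parameters (a single global parameter
    set). Zero-concentration points cannot enter a log-axis fit and are
    set aside (counted as excluded).
    """
    excluded = 0
    if max_cv is not None:
        points, log = exclude_noisy_points(points, max_cv)
        excluded += len(log)
    positive = [p for p in points if p.concentration > 0]
    excluded += len(points) - len(positive)
    x = np.log10([p.concentration for p in positive])
    y = np.array([p.tau for p in positive])
    if np.unique(x).size < 5:
        raise DomainError("need >= 5 distinct positive concentrations")

    def residuals(params, xx, yy):
        return _boltzmann_tau(xx, *params) - yy

    lo, hi = float(y.min()), float(y.max())
    spread = max(hi - lo, 1e-9)
    # deterministic multi-start grid: x50 at data quantiles, two slopes
    starts = [
        (lo, hi, float(np.quantile(x, q)), s)
        for q in (0.25, 0.4, 0.5, 0.6, 0.75)
        for s in (0.3, 0.8)
    ]
    bounds = (
        [lo - spread, lo - spread, x.min() - 2.0, 1e-3],
        [hi + spread, hi + spread, x.max() + 2.0, 10.0],
    )
    best = _best_fit(residuals, starts, bounds, args=(x, y))
    tau_f, tau_b, x50, slope = best.x
    result = FcsFitResult(
        kd=float(10.0**x50),
        tau_free=float(tau_f),
        tau_bound=float(tau_b),
        slope=float(slope),
        model="boltzmann",
        n_points_used=len(positive),
        n_points_excluded=excluded,
        residual=float(np.sum(best.fun**2)),
    )
    if n_bootstrap:
        result.ci95_kd = _bootstrap_ci(
            residuals, best.x, bounds, x, y,
            kd_of=lambda p: 10.0 ** p[2],
            n_bootstrap=n_bootstrap, seed=seed, point_estimate=result.kd,
        )
    return result


def fit_fcs_depletion(
    points: Sequence[TitrationPoint],
    labeled_conc: float,
    *,
    max_cv: float | None = 8.0,
    n_bootstrap: int = 500,
    seed: int = 0,
) -> FcsFitResult:
    """Exact single-site depletion-model fit (Kd, tau_free, tau_bound).

    Reduces to a hyperbolic binding curve when labeled_conc << Kd. Unlike
    the log-axis sigmoid this model uses zero-concentration points.
    """
    if not labeled_conc > 0:
        raise DomainError("labeled_conc must be positive")
    excluded = 0
    if max_cv is not None:
        points, log = exclude_noisy_points(points, max_cv)
        excluded += len(log)
    c = np.array([p.concentration for p in points])
    y = np.array([p.tau for p in points])
    if np.unique(c[c > 0]).size < 5:
        raise DomainError("need >= 5 distinct positive concentrations")

    def residuals(params, cc, yy):
        log_kd, tau_f, tau_b = params
        f = bound_fraction(cc, 10.0**log_kd, labeled_conc)
        return tau_f + f * (tau_b - tau_f) - yy

    lo, hi = float(y.min()), float(y.max())
    spread = max(hi - lo, 1e-9)
    cmax = float(c.max())
    starts = [
        (lk, lo, hi)
        for lk in np.linspace(
            math.log10(max(c[c > 0].min(), 1e-3)), math.log10(cmax), 5
        )
    ]
    bounds = (
        [math.log10(cmax) - 8.0, lo - spread, lo - spread],
        [math.log10(cmax) + 4.0, hi + spread, hi + spread],
    )
    best = _best_fit(residuals, starts, bounds, args=(c, y))
    log_kd, tau_f, tau_b = best.x
    result = FcsFitResult(
        kd=float(10.0**log_kd),
        tau_free=float(tau_f),
        tau_bound=float(tau_b),
        model="depletion",
        n_points_used=len(points),
        n_points_excluded=excluded,
        residual=float(np.sum(best.fun**2)),
    )
    if n_bootstrap:
        result.ci95_kd = _bootstrap_ci(
            residuals, best.x, bounds, c, y,
            kd_of=lambda p: 10.0 ** p[0],
            n_bootstrap=n_bootstrap, seed=seed, point_estimate=result.kd,
        )
    return result


# ---------------------------------------------------------------------------
# ITC fit


def fit_itc_one_site(
    injections: pd.DataFrame | Sequence[tuple[int, float, float]],
    cell_conc: float,
    syringe_conc: float,
    cell_volume: float,
    *,
    first_injection_weight: float = 0.0,
    fit_baseline: bool = True,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> ItcFitResult:
    """One-site fit of (n_sites, Kd, delta_H, baseline) to injection heats.

    ``injections`` is a frame with columns injection/volume_ul/heat_ucal or
    an equivalent sequence of tuples. The first injection is down-weighted
    (default weight 0 — standard practice for the small pre-injection).
    ``fit_baseline=False`` pins the per-injection dilution-heat offset at 0
    for runs known to carry none (e.g. simulated isotherms), removing a
    nuisance parameter that trades off against Kd.
    """
    if not (cell_conc > 0 and syringe_conc > 0 and cell_volume > 0):
        raise DomainError("concentrations and cell volume must be positive")
    if isinstance(injections, pd.DataFrame):
        vols = injections["volume_ul"].to_numpy(dtype=float)
        heats = injections["heat_ucal"].to_numpy(dtype=float)
    else:
        arr = np.asarray(injections, dtype=float)
        vols, heats = arr[:, 1], arr[:, 2]
    if vols.size < 8:
        raise DomainError("need >= 8 injections")
    weights = np.ones_like(heats)
    weights[0] = first_injection_weight

    scale = max(float(np.abs(heats).max()), 1e-12)

    def residuals(params, v, h, w):
        log_kd, dh, n, base = params
        model = itc_injection_heats(
            10.0**log_kd, dh, n, cell_conc, syringe_conc, cell_volume, v, base
        )
        return (model - h) * w

    dh_guess = float(np.sign(heats[1:].sum()) * max(abs(heats[1:4]).mean(), 0.1) * 5)
    starts = [
        (lk, dh, n, 0.0)
        for lk in np.log10([cell_conc / 100, cell_conc / 10, cell_conc, cell_conc * 10])
        for dh in (dh_guess, dh_guess * 4)
        for n in (1.0,)
    ]
    baseline_cap = scale if fit_baseline else 1e-12
    bounds = (
        [math.log10(cell_conc) - 6.0, -1e4, 0.05, -baseline_cap],
        [math.log10(cell_conc) + 6.0, 1e4, 20.0, baseline_cap],
    )
    best = _best_fit(residuals, starts, bounds, args=(vols, heats, weights))
    log_kd, dh, n, base = best.x
    kd = float(10.0**log_kd)
    result = ItcFitResult(
        kd=kd,
        delta_h=float(dh),
        n_sites=float(n),
        baseline=float(base),
        residual=float(np.sum(best.fun**2)),
    )
    if abs(dh) < 1e-6:
        result.warnings.append("delta_H ~ 0: Kd unidentifiable")
    c_value = n * cell_conc / kd
    if not 0.1 <= c_value <= 1000.0:
        result.warnings.append(
            f"c-value {c_value:.3g} outside [0.1, 1000]; Kd poorly constrained"
        )
    if n_bootstrap:
        idx_all = np.arange(vols.size)
        rng = np.random.default_rng(seed)
        kds = []
        for _ in range(n_bootstrap):
            idx = np.sort(rng.choice(idx_all, size=idx_all.size, replace=True))
            try:
                fit = least_squares(
                    residuals, best.x, bounds=bounds,
                    args=(vols[idx], heats[idx], weights[idx]),
                )
                kds.append(10.0 ** fit.x[0])
            except Exception:
                continue
        if kds:
            lo_ci, hi_ci = np.percentile(kds, [2.5, 97.5])
            result.ci95_kd = (min(float(lo_ci), kd), max(float(hi_ci), kd))
    return result


def kd_fold_change(kd_num: float, kd_den: float) -> tuple[float, int]:
    """Ratio of two dissociation constants, plus nearest-integer field."""
    if not (kd_num > 0 and kd_den > 0):
        raise DomainError("dissociation constants must be positive")
    fold = kd_num / kd_den
    return fold, round(fold)


# ---------------------------------------------------------------------------
# fitting machinery


def _best_fit(residuals, starts, bounds, args):
    best = None
    lo = np.asarray(bounds[0])
    hi = np.asarray(bounds[1])
    for start in starts:
        x0 = np.clip(np.asarray(start, dtype=float), lo + 1e-12, hi - 1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = least_squares(residuals, x0, bounds=bounds, args=args)
            except Exception:
                continue
        if fit.success and (best is None or fit.cost < best.cost):
            best = fit
    if best is None:
        raise FitFailureError("no start converged")
    return best


def _bootstrap_ci(
    residuals, best_params, bounds, x, y, *, kd_of, n_bootstrap, seed,
    point_estimate,
):
    """Percentile bootstrap over points; interval forced to bracket the fit."""
    rng = np.random.default_rng(seed)
    idx_all = np.arange(x.size)
    kds = []
    for _ in range(n_bootstrap):
        idx = rng.choice(idx_all, size=idx_all.size, replace=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = least_squares(
                    residuals, best_params, bounds=bounds, args=(x[idx], y[idx])
                )
            except Exception:
                continue
        if fit.success:
            kds.append(kd_of(fit.x))
    if not kds:
        return None
    lo_ci, hi_ci = np.percentile(kds, [2.5, 97.5])
    return (min(float(lo_ci), point_estimate), max(float(hi_ci), point_estimate))
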