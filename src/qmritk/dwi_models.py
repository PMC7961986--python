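"""Diffusion signal models and voxelwise fitting.

Implements the monoexponential (ADC) decay model and the non-Gaussian
intravoxel incoherent motion (NGIVIM) model that augments the biexponential
IVIM signal equation with a kurtosis correction of the tissue compartment:

    S(b) = S0 * [ f * exp(-b*Dstar) + (1-f) * exp(-b*D + (1/6)*K*(b*D)^2) ]

Fitting is unweighted nonlinear least squares on magnitude signal with box
bounds, using a segmented (high-b first) initialization followed by joint
refinement, which is the standard way to stabilize the ill-conditioned
pseudo-diffusion compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DEFAULT_B_VALUES",
    "BValueSeries",
    "MonoexpFit",
    "NGIVIMFit",
    "ParametricMap",
    "DWIFitConfig",
    "monoexp_signal",
    "ngivim_signal",
    "fit_adc",
    "fit_ngivim",
    "fit_volume",
]

logger = logging.getLogger(__name__)

#: Default 10-point b-value ladder (s/mm^2).
DEFAULT_B_VALUES = np.array([0.0, 20, 50, 80, 200, 300, 500, 800, 1500, 2000])


@dataclass(frozen=True)
class BValueSeries:
    """One voxel's diffusion signal over a b-value ladder.

    Parameters
    ----------
    b_values : array-like
        Diffusion weightings in s/mm^2; strictly increasing, first entry 0.
    signals : array-like
        Non-negative magnitude signals, one per b-value.
    """

    b_values: np.ndarray
    signals: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.b_values, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if b.ndim != 1 or s.shape != b.shape:
            raise ValueError("b_values and signals must be 1-D and equal length")
        if b.size < 2:
            raise ValueError("need at least 2 b-values")
        if b[0] != 0:
            raise ValueError("first b-value must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if np.any(s < 0) or not np.all(np.isfinite(s)):
            raise ValueError("signals must be finite and non-negative")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "signals", s)

    def __len__(self) -> int:
        return self.b_values.size


@dataclass
class MonoexpFit:
    """Result of a monoexponential (ADC) fit."""

    S0: float
    ADC: float
    rss: float
    converged: bool
    message: str = ""


@dataclass
class NGIVIMFit:
    """Result of a non-Gaussian IVIM fit."""

    S0: float
    D: float
    Dstar: float
    f: float
    K: float
    rss: float
    converged: bool
    at_boundary: bool = False
    message: str = ""


@dataclass
class ParametricMap:
    """A per-voxel parameter estimate on the image grid.

    ``values`` holds NaN outside ``mask``; estimates are defined exactly on
    mask voxels (failed fits are also NaN and counted separately).
    """

    name: str
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share a grid")


@dataclass
class DWIFitConfig:
    """Settings for NGIVIM / ADC fitting.

    ``b_split`` separates the perfusion-dominated low-b range from the
    tissue-dominated high-b range used for segmented initialization.
    Bounds enclose physiologic head-and-neck tumor values with wide margins.
    """

    b_split: float = 200.0
    D_bounds: tuple = (1e-5, 3e-3)
    Dstar_max: float = 0.1
    f_bounds: tuple = (0.0, 1.0)
    K_bounds: tuple = (0.0, 3.0)
    S0_max_factor: float = 10.0
    multistart: bool = True
    xtol: float = 1e-14
    ftol: float = 1e-14
    gtol: float = 1e-14
    max_nfev: int = 2000


def _check_scalar_nonneg(**kwargs):
    for name, v in kwargs.items():
        if np.any(np.asarray(v) < 0):
            raise ValueError(f"{name} must be non-negative")


def monoexp_signal(b, S0, ADC):
    """Monoexponential diffusion decay ``S0 * exp(-b * ADC)``.

    Parameters are rejected if negative; ``S0`` must be positive.
    """
    _check_scalar_nonneg(b=b, ADC=ADC)
    if np.any(np.asarray(S0) <= 0):
        raise ValueError("S0 must be positive")
    return S0 * np.exp(-np.asarray(b, dtype=float) * ADC)


def ngivim_signal(b, S0, f, D, Dstar, K):
    """Non-Gaussian IVIM signal.

    ``S0 * [f*exp(-b*Dstar) + (1-f)*exp(-b*D + (1/6)*K*(b*D)**2)]``

    Invariants enforced: 0 <= f <= 1, 0 < D <= Dstar, K >= 0, S0 > 0.
    """
    if np.any(np.asarray(S0) <= 0):
        raise ValueError("S0 must be positive")
    if not (0.0 <= f <= 1.0):
        raise ValueError("f must be in [0, 1]")
    if not (0.0 < D <= Dstar):
        raise ValueError("require 0 < D <= Dstar")
    if K < 0:
        raise ValueError("K must be non-negative")
    b = np.asarray(b, dtype=float)
    _check_scalar_nonneg(b=b)
    bd = b * D
    tissue = np.exp(-bd + K * bd * bd / 6.0)
    perf = np.exp(-b * Dstar)
    return S0 * (f * perf + (1.0 - f) * tissue)


def _subset(series: BValueSeries, b_subset):
    if b_subset is None:
        return series.b_values, series.signals
    b_subset = np.asarray(b_subset, dtype=float)
    idx = np.isin(series.b_values, b_subset)
    return series.b_values[idx], series.signals[idx]


def fit_adc(series: BValueSeries, b_subset=None) -> MonoexpFit:
    """Least-squares monoexponential fit of signal vs b-value.

    Uses a log-linear initializer refined by bounded nonlinear least
    squares on the linear signal. Constant input returns the ADC=0
    boundary estimate with ``converged=False``.
    """
    b, s = _subset(series, b_subset)
    if b.size < 4:
        raise ValueError("monoexponential fit needs >= 4 b-values")

    if np.ptp(s) == 0:
        if s[0] == 0:
            return MonoexpFit(np.nan, np.nan, np.nan, False, "all-zero signal")
        return MonoexpFit(float(s[0]), 0.0, 0.0, False,
                          "constant signal: ADC at zero boundary")

    pos = s > 0
    if pos.sum() >= 2:
        coef = np.polyfit(b[pos], np.log(s[pos]), 1)
        adc0 = float(np.clip(-coef[0], 1e-7, 0.05))
        s0_0 = float(np.clip(np.exp(coef[1]), 1e-12, None))
    else:
        adc0, s0_0 = 1e-3, max(float(s.max()), 1e-12)

    def resid(theta):
        return theta[0] * np.exp(-b * theta[1]) - s

    res = least_squares(
        resid, x0=[s0_0, adc0],
        bounds=([1e-12, 0.0], [10.0 * max(s.max(), 1e-12), 1.0]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=1000,
    )
    rss = float(np.sum(res.fun ** 2))
    return MonoexpFit(float(res.x[0]), float(res.x[1]), rss, bool(res.success))


def _ngivim_stage12_init(b, s, cfg: DWIFitConfig):
    """Segmented initialization: tissue (D, K) from high b, then f, Dstar."""
    hi = b >= cfg.b_split
    bh, sh = b[hi], s[hi]
    d0, k0, a0 = 1e-3, 0.5, s[0] * 0.85
    if bh.size >= 3 and np.all(sh > 0):
        # log S = log[(1-f)S0] - D*b + (K D^2 / 6) b^2  -> quadratic in b
        c2, c1, c0 = np.polyfit(bh, np.log(sh), 2)
        d0 = float(np.clip(-c1, cfg.D_bounds[0], cfg.D_bounds[1]))
        k0 = float(np.clip(6.0 * c2 / d0 ** 2, *cfg.K_bounds))
        a0 = float(np.clip(np.exp(c0), 1e-12, None))
    s0_0 = max(float(s[0]), 1e-12)
    resid0 = s0_0 - a0  # = f * S0 at b=0
    if resid0 <= 0:
        f0, dstar0 = 0.0, d0  # boundary init per degenerate low-b residual
    else:
        f0 = float(np.clip(resid0 / s0_0, 0.0, 0.6))
        lo = (b < cfg.b_split) & (b > 0)
        r = s[lo] - a0 * np.exp(-b[lo] * d0 + k0 * (b[lo] * d0) ** 2 / 6.0)
        good = r > 0
        if good.sum() >= 2:
            slope = np.polyfit(b[lo][good], np.log(r[good]), 1)[0]
            dstar0 = float(np.clip(-slope, d0, cfg.Dstar_max))
        else:
            dstar0 = min(10.0 * d0, cfg.Dstar_max)
    return s0_0 / max(1.0 - f0, 0.4), f0, d0, dstar0, k0


def fit_ngivim(series: BValueSeries, config: DWIFitConfig | None = None) -> NGIVIMFit:
    """Bounded nonlinear least-squares fit of the NGIVIM model.

    Three stages: (1) D, K and amplitude from the high-b segment,
    (2) f and Dstar from the low-b residual, (3) joint refinement of all
    five parameters with bounds (Dstar is parametrized as D + delta,
    delta >= 0, so D <= Dstar always holds). A small deterministic
    multistart guards against local minima.
    """
    cfg = config or DWIFitConfig()
    b, s = series.b_values, series.signals
    if len(series) < 6:
        raise ValueError("NGIVIM fit needs >= 6 b-values")
    if not (np.any(b < cfg.b_split) and np.any(b >= cfg.b_split)):
        raise ValueError("b-values must span both sides of b_split")
    if np.ptp(s) == 0 and s[0] == 0:
        return NGIVIMFit(*([np.nan] * 5), np.nan, False, message="all-zero signal")

    smax = max(float(s.max()), 1e-12)
    lb = np.array([1e-12, cfg.f_bounds[0], cfg.D_bounds[0], 0.0, cfg.K_bounds[0]])
    ub = np.array([cfg.S0_max_factor * smax, cfg.f_bounds[1], cfg.D_bounds[1],
                   cfg.Dstar_max, cfg.K_bounds[1]])

    def resid(theta):
        S0, f, D, delta, K = theta
        bd = b * D
        model = S0 * (f * np.exp(-b * (D + delta))
                      + (1.0 - f) * np.exp(-bd + K * bd * bd / 6.0))
        return model - s

    def solve(x0):
        x0 = np.clip(x0, lb, ub)
        return least_squares(resid, x0, bounds=(lb, ub), xtol=cfg.xtol,
                             ftol=cfg.ftol, gtol=cfg.gtol, max_nfev=cfg.max_nfev)

    s0_0, f0, d0, dstar0, k0 = _ngivim_stage12_init(b, s, cfg)
    best = solve([s0_0, f0, d0, max(dstar0 - d0, 0.0), k0])
    best_rss = float(np.sum(best.fun ** 2))

    if cfg.multistart and best_rss > 1e-16 * smax ** 2 * b.size:
        for f_try, dstar_try, k_try in [(0.05, 2e-3, 0.8), (0.2, 3e-3, 1.0),
                                        (0.15, 1e-2, 0.5), (0.3, 3e-2, 1.5)]:
            alt = solve([s0_0, f_try, d0, max(dstar_try - d0, 1e-5), k_try])
            alt_rss = float(np.sum(alt.fun ** 2))
            if alt_rss < best_rss - 1e-18:
                best, best_rss = alt, alt_rss

    S0, f, D, delta, K = best.x
    at_bound = bool(
        np.isclose(f, cfg.f_bounds[0]) or np.isclose(f, cfg.f_bounds[1])
        or np.isclose(delta, 0.0) or np.isclose(K, cfg.K_bounds[1])
    )
    return NGIVIMFit(float(S0), float(D), float(D + delta), float(f), float(K),
                     best_rss, bool(best.success), at_bound)


_MODEL_PARAMS = {
    "monoexp": ("S0", "ADC"),
    "ngivim": ("S0", "D", "Dstar", "f", "K"),
}


def fit_volume(volume, mask, b_values, model="ngivim", config=None,
               b_subset=None) -> dict:
    """Voxelwise fit over a 4D volume; returns ``{param: ParametricMap}``.

    The 4th axis of ``volume`` must match ``b_values``. Failed voxels are
    left NaN in the maps and counted in the log. Deterministic given the
    inputs and config.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    b_values = np.asarray(b_values, dtype=float)
    if volume.ndim != 4:
        raise ValueError("volume must be 4D")
    if volume.shape[-1] != b_values.size:
        raise ValueError("4th axis must match the b-value ladder")
    if mask.shape != volume.shape[:3]:
        raise ValueError("mask grid does not match volume grid")
    if model not in _MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")

    params = _MODEL_PARAMS[model]
    maps = {p: np.full(mask.shape, np.nan) for p in params}
    conv = np.zeros(mask.shape, dtype=bool)
    n_fail = 0
    idx = np.argwhere(mask)
    if idx.size == 0:
        logger.warning("fit_volume: empty mask, returning empty maps")
    for i, j, k in idx:
        series = BValueSeries(b_values, np.clip(volume[i, j, k], 0, None))
        try:
            if model == "monoexp":
                fit = fit_adc(series, b_subset=b_subset)
                est = {"S0": fit.S0, "ADC": fit.ADC}
            else:
                fit = fit_ngivim(series, config=config)
                est = {"S0": fit.S0, "D": fit.D, "Dstar": fit.Dstar,
                       "f": fit.f, "K": fit.K}
        except ValueError:
            n_fail += 1
            continue
        if not fit.converged:
            n_fail += 1
            continue
        conv[i, j, k] = True
        for p in params:
            maps[p][i, j, k] = est[p]
    logger.info("fit_volume(%s): %d voxels fitted, %d failed",
                model, int(conv.sum()), n_fail)
    out = {p: ParametricMap(p, maps[p], conv.copy()) for p in params}
    return out
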