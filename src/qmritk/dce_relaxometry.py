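"""SPGR relaxometry, VFA T1 mapping, AIF handling, and Tofts / FXR
pharmacokinetic models.

The dynamic-contrast pipeline is: variable-flip-angle (VFA) precontrast
data give the native relaxation rate R10 = 1/T10; dynamic spoiled
gradient-echo (SPGR) signal is inverted to an R1(t) time course; R1(t) is
fitted either with the fast-exchange-limit Tofts model (linear
concentration-relaxation relation) or with the shutter-speed / fast
exchange regime (FXR) model, whose observable R1 is the smaller eigenvalue
of the two-site transcytolemmal water exchange relaxation matrix.

Unit conventions: time in seconds internally; TR in milliseconds at the
API boundary; Ktrans and kep reported in 1/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "R1_RELAXIVITY",
    "VFASeries",
    "T1FitResult",
    "DynamicSeries",
    "AIFCurve",
    "ConcentrationCurve",
    "ToftsParams",
    "FXRParams",
    "FXRFitResult",
    "spgr_signal",
    "fit_t10_vfa",
    "dynamic_signal_to_R1",
    "concentration_from_R1",
    "tofts_concentration",
    "fxr_R1",
    "fxr_R1_from_concentration",
    "fit_tofts",
    "fit_fxr",
    "population_aif",
    "aif_from_roi",
    "fit_t10_volume",
    "fit_dce_volume",
]

#: Contrast-agent longitudinal relaxivity (1/(mM*s)) used throughout.
R1_RELAXIVITY = 4.0

#: Literature defaults for arterial signal conversion at 3T (configurable).
DEFAULT_BLOOD_T10 = 1.65  # s
DEFAULT_HEMATOCRIT = 0.45


@dataclass(frozen=True)
class VFASeries:
    """Steady-state SPGR signals at multiple flip angles (degrees)."""

    flip_angles: np.ndarray
    signals: np.ndarray
    TR: float  # ms

    def __post_init__(self):
        fa = np.asarray(self.flip_angles, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if fa.ndim != 1 or s.shape != fa.shape:
            raise ValueError("flip_angles and signals must be 1-D, equal length")
        if fa.size < 2 or np.unique(fa).size < fa.size:
            raise ValueError("need >= 2 distinct flip angles")
        if np.any(s < 0):
            raise ValueError("signals must be non-negative")
        if self.TR <= 0:
            raise ValueError("TR must be positive")
        object.__setattr__(self, "flip_angles", fa)
        object.__setattr__(self, "signals", s)


@dataclass
class T1FitResult:
    T10: float  # s
    M0: float
    rss: float
    converged: bool
    message: str = ""

    @property
    def R10(self) -> float:
        return 1.0 / self.T10


@dataclass(frozen=True)
class DynamicSeries:
    """Tissue signal time course for one voxel/ROI.

    ``times`` are seconds from the start of the dynamic run, strictly
    increasing; the first ``n_baseline`` phases are precontrast.
    """

    times: np.ndarray
    signals: np.ndarray
    n_baseline: int

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if t.ndim != 1 or s.shape != t.shape:
            raise ValueError("times and signals must be 1-D, equal length")
        if t.size < 10:
            raise ValueError("dynamic series needs >= 10 phases")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (1 <= self.n_baseline < t.size):
            raise ValueError("n_baseline must be >= 1 and < number of phases")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "signals", s)


@dataclass(frozen=True)
class AIFCurve:
    """Arterial input function: plasma contrast concentration vs time."""

    times: np.ndarray
    Cp: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.Cp, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and Cp must be 1-D, equal length")
        if np.any(c < 0):
            raise ValueError("Cp must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "Cp", c)

    def sampled_at(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.times, self.Cp, left=0.0)


@dataclass
class ConcentrationCurve:
    times: np.ndarray
    Ct: np.ndarray


@dataclass
class ToftsParams:
    Ktrans: float  # 1/min
    ve: float

    @property
    def kep(self) -> float:
        """Efflux rate constant, Ktrans/ve (1/min)."""
        return self.Ktrans / self.ve


@dataclass
class FXRParams:
    """Shutter-speed model parameters.

    ``tau_i`` is the mean intracellular water lifetime (s); the exchange
    rates follow detailed balance with water population fractions
    pe = ve, pi = 1 - ve: kie = 1/tau_i, kei = kie*(1-ve)/ve.
    """

    Ktrans: float  # 1/min
    ve: float
    tau_i: float  # s
    R1i: float = 1.0  # 1/s, precontrast intracellular rate
    R10e: float = 1.0  # 1/s, precontrast EES rate
    r1: float = R1_RELAXIVITY

    def __post_init__(self):
        if self.tau_i <= 0:
            raise ValueError("tau_i must be positive")
        if not (0.0 < self.ve <= 1.0):
            raise ValueError("ve must be in (0, 1]")
        if self.r1 <= 0:
            raise ValueError("r1 must be positive")

    @property
    def kie(self) -> float:
        return 1.0 / self.tau_i

    @property
    def kei(self) -> float:
        return self.kie * (1.0 - self.ve) / self.ve


@dataclass
class FXRFitResult:
    params: FXRParams
    rss: float
    converged: bool
    fxl_degenerate: bool = False
    message: str = ""


def spgr_signal(R1, M0, alpha, TR):
    """Steady-state spoiled gradient-echo signal.

    ``M0 * sin(a) * (1 - E1) / (1 - E1*cos(a))`` with ``E1 = exp(-TR*R1)``;
    ``alpha`` in degrees, ``TR`` in ms, ``R1`` in 1/s.
    """
    if np.any(np.asarray(R1) <= 0):
        raise ValueError("R1 must be positive")
    if not (0.0 < alpha < 90.0):
        raise ValueError("alpha must be in (0, 90) degrees")
    if TR <= 0:
        raise ValueError("TR must be positive")
    a = np.deg2rad(alpha)
    e1 = np.exp(-TR / 1000.0 * np.asarray(R1, dtype=float))
    return M0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def fit_t10_vfa(series: VFASeries) -> T1FitResult:
    """VFA T10 fit: linearized initializer refined by nonlinear least squares.

    The linearization regresses S/sin(a) on S/tan(a); the slope is E1.
    A non-positive (or >= 1) slope is reported as non-convergence.
    """
    fa = np.deg2rad(series.flip_angles)
    s = series.signals
    if np.all(s == 0):
        return T1FitResult(np.nan, np.nan, np.nan, False, "all-zero signals")
    y = s / np.sin(fa)
    x = s / np.tan(fa)
    A = np.vstack([x, np.ones_like(x)]).T
    slope, intercept = np.linalg.lstsq(A, y, rcond=None)[0]
    if not (0.0 < slope < 1.0):
        return T1FitResult(np.nan, np.nan, np.nan, False,
                           f"non-physical linearized slope {slope:.3g}")
    tr_s = series.TR / 1000.0
    t1_0 = -tr_s / np.log(slope)
    m0_0 = max(intercept / (1.0 - slope), 1e-12)

    def resid(theta):
        t1, m0 = theta
        e1 = np.exp(-tr_s / t1)
        model = m0 * np.sin(fa) * (1.0 - e1) / (1.0 - e1 * np.cos(fa))
        return model - s

    res = least_squares(resid, [t1_0, m0_0],
                        bounds=([1e-3, 1e-12], [20.0, 1e12]),
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    rss = float(np.sum(res.fun ** 2))
    return T1FitResult(float(res.x[0]), float(res.x[1]), rss, bool(res.success))


def dynamic_signal_to_R1(series: DynamicSeries, R10, alpha, TR):
    """Invert the SPGR equation phase-by-phase to an R1(t) course.

    The equilibrium scale M0 is calibrated from the mean baseline signal
    and the supplied R10. Phases whose signal implies E1 outside (0, 1)
    are flagged False in the returned validity mask (their R1 is NaN).

    Returns
    -------
    (R1t, valid) : tuple of arrays
    """
    if R10 <= 0:
        raise ValueError("R10 must be positive")
    a = np.deg2rad(alpha)
    tr_s = TR / 1000.0
    s = series.signals
    sbase = float(np.mean(s[: series.n_baseline]))
    e10 = np.exp(-tr_s * R10)
    shape0 = np.sin(a) * (1.0 - e10) / (1.0 - e10 * np.cos(a))
    if sbase <= 0 or shape0 <= 0:
        raise ValueError("baseline signal must be positive")
    m0 = sbase / shape0
    denom = m0 * np.sin(a) - s * np.cos(a)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = (m0 * np.sin(a) - s) / denom
    valid = np.isfinite(e1) & (e1 > 0.0) & (e1 < 1.0)
    r1 = np.full_like(s, np.nan)
    r1[valid] = -np.log(e1[valid]) / tr_s
    return r1, valid


def concentration_from_R1(R1t, R10, r1=R1_RELAXIVITY):
    """Linear (fast-exchange-limit) relaxation-to-concentration conversion.

    ``Ct = (R1t - R10) / r1``; negative values are clipped to zero and
    flagged. Returns ``(Ct, clipped)``.
    """
    if r1 <= 0:
        raise ValueError("r1 must be positive")
    ct = (np.asarray(R1t, dtype=float) - R10) / r1
    clipped = ct < 0
    return np.where(clipped, 0.0, ct), clipped


def _kep_per_s(Ktrans_per_min, ve):
    return (Ktrans_per_min / 60.0) / ve


def tofts_concentration(times, Ktrans, ve, aif: AIFCurve) -> ConcentrationCurve:
    """Tofts tissue concentration: causal convolution of the AIF with
    ``Ktrans * exp(-kep * t)``.

    The AIF is linearly interpolated to the (possibly non-uniform) time
    grid and each linear segment is convolved with the exponential kernel
    in closed form, accumulated by the stable first-order recursion
    ``y_i = y_{i-1} * exp(-kep*dt) + segment_integral``. ``Ktrans`` in
    1/min; ``times`` in seconds.
    """
    times = np.asarray(times, dtype=float)
    if Ktrans < 0:
        raise ValueError("Ktrans must be non-negative")
    if not (0.0 < ve <= 1.0):
        raise ValueError("ve must be in (0, 1]")
    cp = aif.sampled_at(times)
    if Ktrans == 0:
        return ConcentrationCurve(times, np.zeros_like(times))
    kt_s = Ktrans / 60.0
    k = _kep_per_s(Ktrans, ve)
    dt = np.diff(times)
    e = np.exp(-k * dt)
    # int_0^dt (c0 + m*u) * exp(-k*(dt-u)) du  for Cp linear on the segment
    c0, c1 = cp[:-1], cp[1:]
    m = (c1 - c0) / dt
    w0 = -np.expm1(-k * dt) / k  # (1 - e)/k
    seg = c0 * w0 + m * (dt - w0) / k
    y = np.empty_like(times)
    y[0] = 0.0
    for i in range(dt.size):
        y[i + 1] = y[i] * e[i] + seg[i]
    ct = kt_s * y
    return ConcentrationCurve(times, np.clip(ct, 0.0, None))


def fxr_R1(times, params: FXRParams, aif: AIFCurve) -> np.ndarray:
    """Observable R1(t) of the two-site transcytolemmal exchange model.

    The tissue concentration follows the Tofts model; the EES relaxation
    rate is ``R10e + r1 * Ce`` with ``Ce = Ct / ve``; the observable rate
    is the smaller eigenvalue of the 2x2 exchange relaxation matrix:

        R1 = 0.5*[(R1i + kie + R1e + kei)
                  - sqrt((R1i + kie - R1e - kei)^2 + 4*kie*kei)]

    In the fast-exchange limit (tau_i -> 0) this reduces to the linear
    relation ``R10 + r1*Ct`` when R1i = R10e.
    """
    times = np.asarray(times, dtype=float)
    ct = tofts_concentration(times, params.Ktrans, params.ve, aif).Ct
    return fxr_R1_from_concentration(ct, params)


def fxr_R1_from_concentration(Ct, params: FXRParams) -> np.ndarray:
    """Two-site-exchange observable R1 at given tissue concentration(s)."""
    ce = np.asarray(Ct, dtype=float) / params.ve
    r1e = params.R10e + params.r1 * ce
    kie, kei = params.kie, params.kei
    a = params.R1i + kie
    b = r1e + kei
    disc = np.sqrt((a - b) ** 2 + 4.0 * kie * kei)
    return 0.5 * ((a + b) - disc)


def fit_tofts(times, Ct, aif: AIFCurve, Ktrans_bounds=(1e-4, 10.0),
              ve_bounds=(0.005, 1.0)):
    """Nonlinear least-squares Tofts fit of a tissue concentration curve.

    Returns ``(ToftsParams, rss, converged)``.
    """
    times = np.asarray(times, dtype=float)
    Ct = np.asarray(Ct, dtype=float)
    if np.allclose(Ct, 0.0):
        return ToftsParams(0.0, 0.5), 0.0, True

    def resid(theta):
        return tofts_concentration(times, theta[0], theta[1], aif).Ct - Ct

    best = None
    for x0 in ([0.2, 0.3], [0.05, 0.1], [1.0, 0.6]):
        res = least_squares(resid, x0,
                            bounds=(np.array([Ktrans_bounds[0], ve_bounds[0]]),
                                    np.array([Ktrans_bounds[1], ve_bounds[1]])),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[1]:
            best = (res, rss)
    res, rss = best
    return ToftsParams(float(res.x[0]), float(res.x[1])), rss, bool(res.success)


@dataclass
class FXRFitConfig:
    Ktrans_bounds: tuple = (1e-4, 10.0)  # 1/min
    ve_bounds: tuple = (0.005, 1.0)
    tau_i_bounds: tuple = (1e-4, 20.0)  # s
    R1i: float | None = None  # default: tissue R10
    R10e: float | None = None
    r1: float = R1_RELAXIVITY


def fit_fxr(times, r1_series, aif: AIFCurve, R10, config: FXRFitConfig | None = None
            ) -> FXRFitResult:
    """Fit the FXR (shutter-speed) model to an R1(t) time course.

    Precontrast intracellular and EES rates default to the measured tissue
    R10. A Tofts fit of the linearly converted concentration initializes
    (Ktrans, ve); tau_i pinned at its lower bound is flagged as
    fast-exchange degenerate.
    """
    cfg = config or FXRFitConfig()
    r1i = R10 if cfg.R1i is None else cfg.R1i
    r10e = R10 if cfg.R10e is None else cfg.R10e
    times = np.asarray(times, dtype=float)
    r1_series = np.asarray(r1_series, dtype=float)
    ok = np.isfinite(r1_series)
    t_fit, r1_fit = times[ok], r1_series[ok]

    ct0, _ = concentration_from_R1(r1_fit, R10, cfg.r1)
    tp, _, _ = fit_tofts(t_fit, ct0, aif,
                         Ktrans_bounds=cfg.Ktrans_bounds, ve_bounds=cfg.ve_bounds)

    lb = np.array([cfg.Ktrans_bounds[0], cfg.ve_bounds[0], cfg.tau_i_bounds[0]])
    ub = np.array([cfg.Ktrans_bounds[1], cfg.ve_bounds[1], cfg.tau_i_bounds[1]])

    def resid(theta):
        p = FXRParams(theta[0], theta[1], theta[2], R1i=r1i, R10e=r10e, r1=cfg.r1)
        return fxr_R1(t_fit, p, aif) - r1_fit

    best = None
    for tau0 in (0.5, 1.0, cfg.tau_i_bounds[0]):
        x0 = np.clip([max(tp.Ktrans, 0.01), min(max(tp.ve, 0.05), 0.95), tau0], lb, ub)
        res = least_squares(resid, x0, bounds=(lb, ub),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=3000)
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[1] - 1e-18:
            best = (res, rss)
    res, rss = best
    params = FXRParams(float(res.x[0]), float(res.x[1]), float(res.x[2]),
                       R1i=r1i, R10e=r10e, r1=cfg.r1)
    degen = bool(np.isclose(params.tau_i, cfg.tau_i_bounds[0], rtol=1e-3))
    return FXRFitResult(params, rss, bool(res.success), fxl_degenerate=degen)


def population_aif(times, t0=40.0, A1=4.0, A2=1.0, m1=2e-3, m2=2e-4,
                   upslope=8.0) -> AIFCurve:
    """Parametric stand-in AIF: linear upslope over one temporal frame,
    then biexponential decay. Defaults give a peak of ~5 mM.

    ``Cp(t) = ramp(t - t0) * [A1*exp(-m1*(t-t0)) + A2*exp(-m2*(t-t0))]``
    """
    times = np.asarray(times, dtype=float)
    if times.size and not (times[0] <= t0 <= times[-1]):
        raise ValueError("bolus arrival t0 must lie within the time range")
    tau = times - t0
    ramp = np.clip(tau / upslope, 0.0, 1.0)
    decay = A1 * np.exp(-m1 * np.clip(tau, 0, None)) \
        + A2 * np.exp(-m2 * np.clip(tau, 0, None))
    cp = np.where(tau < 0, 0.0, ramp * decay)
    return AIFCurve(times, cp)


def aif_from_roi(arterial_series: DynamicSeries, blood_T10=DEFAULT_BLOOD_T10,
                 hematocrit=DEFAULT_HEMATOCRIT, alpha=15.0, TR=7.0,
                 r1=R1_RELAXIVITY) -> AIFCurve:
    """Convert an arterial-ROI mean signal course to a plasma AIF.

    Signal -> R1 (SPGR inversion with blood R10) -> whole-blood
    concentration (linear relation) -> plasma: Cp = Cb / (1 - hematocrit).
    Non-invertible phases are carried as Cp = 0 after baseline.
    """
    if not (0.0 <= hematocrit < 1.0):
        raise ValueError("hematocrit must be in [0, 1)")
    r10b = 1.0 / blood_T10
    r1t, valid = dynamic_signal_to_R1(arterial_series, r10b, alpha, TR)
    cb = np.zeros_like(r1t)
    cb[valid], _ = concentration_from_R1(r1t[valid], r10b, r1)
    cp = cb / (1.0 - hematocrit)
    return AIFCurve(arterial_series.times, np.clip(cp, 0.0, None))


def fit_t10_volume(vfa_volumes, flip_angles, TR, mask):
    """Voxelwise VFA T10 map from a list of per-angle 3D volumes.

    Returns ``(T10_map, converged_mask)`` with NaN outside the mask.
    """
    vols = [np.asarray(v, dtype=float) for v in vfa_volumes]
    mask = np.asarray(mask, dtype=bool)
    t10 = np.full(mask.shape, np.nan)
    conv = np.zeros(mask.shape, dtype=bool)
    for i, j, k in np.argwhere(mask):
        s = np.array([v[i, j, k] for v in vols])
        fit = fit_t10_vfa(VFASeries(flip_angles, np.clip(s, 0, None), TR))
        if fit.converged:
            t10[i, j, k] = fit.T10
            conv[i, j, k] = True
    return t10, conv


def fit_dce_volume(dyn_volume, times, n_baseline, t10_map, mask, aif: AIFCurve,
                   alpha=15.0, TR=7.0, model="fxr", config: FXRFitConfig | None = None):
    """Voxelwise pharmacokinetic fit of a dynamic 4D volume.

    Returns a dict of 3D maps: Ktrans, ve (+ tau_i for the FXR model),
    NaN outside the mask or where the fit failed.
    """
    dyn = np.asarray(dyn_volume, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if dyn.shape[:3] != mask.shape or dyn.shape[-1] != len(times):
        raise ValueError("dynamic volume, mask, and times are inconsistent")
    if model not in ("fxr", "tofts"):
        raise ValueError(f"unknown model {model!r}")
    names = ["Ktrans", "ve"] + (["tau_i"] if model == "fxr" else [])
    maps = {p: np.full(mask.shape, np.nan) for p in names}
    for i, j, k in np.argwhere(mask):
        t10 = t10_map[i, j, k]
        if not np.isfinite(t10) or t10 <= 0:
            continue
        series = DynamicSeries(times, dyn[i, j, k], n_baseline)
        r10 = 1.0 / t10
        r1t, valid = dynamic_signal_to_R1(series, r10, alpha, TR)
        if valid.sum() < 10:
            continue
        if model == "fxr":
            fit = fit_fxr(times, r1t, aif, r10, config)
            if fit.converged:
                maps["Ktrans"][i, j, k] = fit.params.Ktrans
                maps["ve"][i, j, k] = fit.params.ve
                maps["tau_i"][i, j, k] = fit.params.tau_i
        else:
            ct, _ = concentration_from_R1(r1t[valid], r10)
            tp, _, conv = fit_tofts(times[valid], ct, aif)
            if conv:
                maps["Ktrans"][i, j, k] = tp.Ktrans
                maps["ve"][i, j, k] = tp.ve
    return maps
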