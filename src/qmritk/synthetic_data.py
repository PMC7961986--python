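"""Phantom and cohort simulators with known ground truth.

All generators are pure functions of (spec, seed): identical inputs give
identical outputs. DWI phantoms carry Rician noise (magnitude of complex
Gaussian); DCE phantoms carry Gaussian signal noise (contrast-enhanced
SNR is high). Cohorts follow the indirect Fine-Gray simulation scheme so
the true subdistribution coefficient is known, enabling parameter-recovery
tests of the survival machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dce_relaxometry import (
    AIFCurve,
    FXRParams,
    fxr_R1,
    population_aif,
    spgr_signal,
)
from .dwi_models import DEFAULT_B_VALUES, DWIFitConfig, ngivim_signal

__all__ = [
    "AcquisitionConfig",
    "PhantomTruth",
    "CohortSpec",
    "DEFAULT_DWI_TRUTH_RANGES",
    "DEFAULT_DCE_TRUTH_RANGES",
    "DEFAULT_COHORT_METRICS",
    "generate_dwi_phantom",
    "generate_dce_phantom",
    "generate_cohort",
]


@dataclass
class AcquisitionConfig:
    """Acquisition geometry/timing shared by the simulators."""

    b_values: np.ndarray = field(default_factory=lambda: DEFAULT_B_VALUES.copy())
    TR_dce: float = 7.0  # ms
    alpha_dce: float = 15.0  # degrees
    vfa_angles: tuple = (30.0, 15.0, 5.0)
    n_phases: int = 50
    dt: float = 8.0  # s
    n_baseline: int = 5
    noise_sd: float = 0.0
    shape: tuple = (16, 16, 4)
    seed: int = 0

    def __post_init__(self):
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.TR_dce <= 0 or self.alpha_dce <= 0 or self.dt <= 0:
            raise ValueError("acquisition timing parameters must be positive")
        if self.n_phases < 10 or self.n_baseline < 1:
            raise ValueError("need >= 10 phases and >= 1 baseline phase")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.dt


@dataclass
class PhantomTruth:
    """Ground-truth parameter maps paired with a simulated acquisition."""

    maps: dict
    mask: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)


# Per-voxel uniform sampling ranges for phantom truths; chosen to span
# head-and-neck tumor values and stay inside the fitting bounds.
DEFAULT_DWI_TRUTH_RANGES = {
    "S0": (400.0, 600.0),
    "f": (0.10, 0.25),
    "D": (0.5e-3, 1.1e-3),
    "Dstar": (2.0e-3, 2.7e-3),
    "K": (0.6, 1.2),
}

DEFAULT_DCE_TRUTH_RANGES = {
    "T10": (0.8, 1.6),  # s
    "Ktrans": (0.15, 0.55),  # 1/min
    "ve": (0.15, 0.60),
    "tau_i": (0.3, 1.2),  # s
}

# Default two-group metric distributions (mean, sd) for cohort emulation.
DEFAULT_COHORT_METRICS = {
    "ADC": {"with": (0.66e-3, 0.19e-3), "without": (0.76e-3, 0.15e-3)},
    "D": {"with": (0.74e-3, 0.23e-3), "without": (0.87e-3, 0.22e-3)},
    "Dstar": {"with": (2.30e-3, 0.25e-3), "without": (2.40e-3, 0.18e-3)},
    "f": {"with": (0.17, 0.02), "without": (0.19, 0.02)},
    "K": {"with": (0.94, 0.25), "without": (0.82, 0.15)},
    "Ktrans": {"with": (0.29, 0.11), "without": (0.39, 0.16)},
    "ve": {"with": (0.23, 0.13), "without": (0.44, 0.21)},
    "tau_i": {"with": (0.91, 0.15), "without": (0.71, 0.27)},
}


def _default_mask(shape) -> np.ndarray:
    """Central-box tumor mask leaving a background rim for noise checks."""
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(slice(max(1, s // 8), s - max(1, s // 8)) if s > 4 else slice(None)
               for s in shape)
    mask[sl] = True
    return mask


def _draw_truth_maps(rng, shape, mask, ranges, bounds_check=None) -> dict:
    maps = {}
    for name, (lo, hi) in ranges.items():
        vals = np.zeros(shape)
        vals[mask] = rng.uniform(lo, hi, size=int(mask.sum()))
        maps[name] = vals
    if bounds_check:
        for name, (blo, bhi) in bounds_check.items():
            v = maps[name][mask]
            if np.any(v < blo) or np.any(v > bhi):
                raise ValueError(f"truth for {name!r} outside fitting bounds")
    return maps


def add_rician_noise(signal, sd, rng) -> np.ndarray:
    """Magnitude of (signal + complex Gaussian noise)."""
    if sd == 0:
        return np.asarray(signal, dtype=float).copy()
    re = signal + rng.normal(0.0, sd, size=np.shape(signal))
    im = rng.normal(0.0, sd, size=np.shape(signal))
    return np.sqrt(re ** 2 + im ** 2)


def generate_dwi_phantom(config: AcquisitionConfig, truth_ranges=None,
                         mask=None):
    """Simulate a 4D multi-b DWI volume from NGIVIM truth maps.

    Returns ``(volume, PhantomTruth)``. Background (non-mask) voxels have
    zero true signal, so at high noise they sit at the Rician floor
    ``sd * sqrt(pi/2)``.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    mask = _default_mask(shape) if mask is None else np.asarray(mask, dtype=bool)
    ranges = truth_ranges or DEFAULT_DWI_TRUTH_RANGES
    fitcfg = DWIFitConfig()
    maps = _draw_truth_maps(
        rng, shape, mask, ranges,
        bounds_check={"D": fitcfg.D_bounds, "K": fitcfg.K_bounds,
                      "f": fitcfg.f_bounds,
                      "Dstar": (fitcfg.D_bounds[0], fitcfg.Dstar_max)},
    )
    vol = np.zeros(shape + (config.b_values.size,))
    for i, j, k in np.argwhere(mask):
        vol[i, j, k] = ngivim_signal(
            config.b_values, maps["S0"][i, j, k], maps["f"][i, j, k],
            maps["D"][i, j, k], maps["Dstar"][i, j, k], maps["K"][i, j, k])
    vol = add_rician_noise(vol, config.noise_sd, rng)
    return vol, PhantomTruth(maps, mask)


def generate_dce_phantom(config: AcquisitionConfig, truth_ranges=None,
                         mask=None, aif: AIFCurve | None = None, M0=1000.0):
    """Simulate VFA precontrast volumes plus a dynamic contrast series.

    Per voxel: tissue concentration from the Tofts convolution of the AIF,
    observable R1(t) from the two-site-exchange eigenvalue forward model,
    signal via the SPGR equation. Baseline phases are precontrast (the
    AIF bolus arrives at ``n_baseline * dt``). Gaussian noise of
    ``config.noise_sd`` (absolute signal units) is added everywhere.

    Returns ``(vfa_volumes, dynamic_volume, PhantomTruth, AIFCurve)``.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    mask = _default_mask(shape) if mask is None else np.asarray(mask, dtype=bool)
    ranges = truth_ranges or DEFAULT_DCE_TRUTH_RANGES
    maps = _draw_truth_maps(rng, shape, mask, ranges)
    times = config.times
    if aif is None:
        aif = population_aif(times, t0=config.n_baseline * config.dt)

    vfa = [np.zeros(shape) for _ in config.vfa_angles]
    dyn = np.zeros(shape + (config.n_phases,))
    for i, j, k in np.argwhere(mask):
        r10 = 1.0 / maps["T10"][i, j, k]
        for a_idx, angle in enumerate(config.vfa_angles):
            vfa[a_idx][i, j, k] = spgr_signal(r10, M0, angle, config.TR_dce)
        params = FXRParams(maps["Ktrans"][i, j, k], maps["ve"][i, j, k],
                           maps["tau_i"][i, j, k], R1i=r10, R10e=r10)
        r1t = fxr_R1(times, params, aif)
        dyn[i, j, k] = spgr_signal(r1t, M0, config.alpha_dce, config.TR_dce)
    if config.noise_sd > 0:
        for v in vfa:
            v += rng.normal(0.0, config.noise_sd, size=v.shape)
            np.clip(v, 0.0, None, out=v)
        dyn += rng.normal(0.0, config.noise_sd, size=dyn.shape)
        np.clip(dyn, 0.0, None, out=dyn)
    return vfa, dyn, PhantomTruth(maps, mask), aif


@dataclass
class CohortSpec:
    """Two-group competing-risks cohort specification.

    The cause-1 (event of interest) process follows the indirect
    Fine-Gray scheme: with covariate x, the subdistribution is
    ``F1(t|x) = 1 - [1 - p1 * (1 - exp(-rate1 * t))]^exp(beta * x)``,
    so ``beta`` is the true subdistribution log-hazard-ratio. Subjects
    not failing from cause 1 draw an exponential cause-2 time.
    ``covariate`` selects what enters the linear predictor: the group
    indicator ("group") or the standardized metric value ("value").
    """

    n_per_group: tuple = (30, 30)
    metric: str = "ve"
    group_means: tuple = (0.23, 0.44)  # (with-event, without-event) group
    group_sds: tuple = (0.13, 0.21)
    value_range: tuple = (1e-6, None)  # truncation to physical range
    beta: float = 0.0
    covariate: str = "group"
    p1: float = 0.35  # baseline cause-1 cumulative incidence plateau
    rate1: float = 0.15  # 1/month
    rate2: float = 0.03  # 1/month, competing cause
    censor_window: tuple = (3.0, 32.0)  # months
    censor_rate: float = 0.0  # probability of forced early censoring
    seed: int = 0

    def __post_init__(self):
        if min(self.n_per_group) < 2:
            raise ValueError("need n >= 2 per group")
        if min(self.group_sds) <= 0:
            raise ValueError("group SDs must be positive")
        if not (0.0 < self.p1 < 1.0):
            raise ValueError("p1 must be in (0, 1)")
        if self.rate1 <= 0 or self.rate2 <= 0:
            raise ValueError("event rates must be positive")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must be in [0, 1]")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a per-subject cohort table with known ground truth.

    Returns a tidy frame with columns subject_id, metric, value,
    time_months, event (0/1/2), group (0 = with-event-risk profile,
    1 = without). Deterministic given the spec (seed included).
    """
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.n_per_group
    group = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    n = group.size

    values = np.empty(n)
    for g, (m, sd) in enumerate(zip(spec.group_means, spec.group_sds)):
        idx = group == g
        v = rng.normal(m, sd, size=int(idx.sum()))
        lo = spec.value_range[0]
        hi = spec.value_range[1]
        if lo is not None:
            v = np.maximum(v, lo)
        if hi is not None:
            v = np.minimum(v, hi)
        values[idx] = v

    if spec.covariate == "group":
        x = 1.0 - group  # group 0 carries the elevated risk profile
    elif spec.covariate == "value":
        x = (values - values.mean()) / values.std(ddof=0)
    else:
        raise ValueError(f"unknown covariate mode {spec.covariate!r}")

    eta = np.exp(spec.beta * x)
    p1x = 1.0 - (1.0 - spec.p1) ** eta
    u = rng.uniform(size=n)
    is_cause1 = u < p1x
    t_event = np.empty(n)
    # invert the conditional subdistribution for cause-1 times
    uu = rng.uniform(size=n)
    inner = 1.0 - (1.0 - uu * p1x) ** (1.0 / eta)
    with np.errstate(divide="ignore"):
        t1 = -np.log(1.0 - inner / spec.p1) / spec.rate1
    t_event[is_cause1] = t1[is_cause1]
    t_event[~is_cause1] = rng.exponential(1.0 / spec.rate2, size=int((~is_cause1).sum()))
    cause = np.where(is_cause1, 1, 2)

    c_lo, c_hi = spec.censor_window
    censor = rng.uniform(c_lo, c_hi, size=n)
    forced = rng.uniform(size=n) < spec.censor_rate
    censor[forced] = np.minimum(
        censor[forced],
        t_event[forced] * rng.uniform(0.05, 0.95, size=int(forced.sum())))
    time = np.minimum(t_event, censor)
    event = np.where(t_event <= censor, cause, 0)
    time = np.maximum(time, 1e-6)

    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "metric": spec.metric,
        "value": values,
        "time_months": time,
        "event": event,
        "group": group,
    })
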