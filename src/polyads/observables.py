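"""Dynamic and static observables: D_xy, tau_R, R_G^2 and scaling exponents.

Translational diffusion is measured from the mean-square displacement of the
chain centre of mass, averaged over multiple time origins,

    MSD_xy(t) = < |r_cm,xy(t0 + t) - r_cm,xy(t0)|^2 >,

and the parallel diffusion coefficient is the long-time slope over four,
``D_xy = slope/4`` (two in-plane components, 2*d*D*t with d = 2).

Rotational relaxation is measured from the end-to-end vector autocorrelation

    rho(t) = < R(t0 + t) . R(t0) > / < R . R >,

which decays exponentially at long times; tau_R is obtained from a linear
fit of ln rho against t restricted to the band 0.06 < rho < 0.30, where the
decay is reliably single-exponential.

Scaling exponents come from ordinary least squares on log-log axes:
``D_xy ~ N^-alpha`` and ``tau_R ~ N^beta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "TrajectoryRecord",
    "MsdCurve",
    "AcfCurve",
    "DiffusionEstimate",
    "RelaxationEstimate",
    "ScalingFit",
    "CoilGlobuleEstimate",
    "record_trajectory",
    "msd_com",
    "estimate_Dxy",
    "end_to_end_acf",
    "estimate_tau_R",
    "average_msd",
    "average_acf",
    "fit_scaling_exponent",
    "locate_coil_globule",
]


@dataclass
class TrajectoryRecord:
    """Uniformly sampled time series from one production run."""

    times: np.ndarray          # MCS stamps, strictly increasing, uniform
    com: np.ndarray            # (n, 3) unwrapped centre of mass
    end_to_end: np.ndarray     # (n, 3) end-to-end vector R(t)
    rg_sq: np.ndarray          # squared radius of gyration
    n_pp: np.ndarray
    n_ps: np.ndarray
    energy: np.ndarray

    def __post_init__(self):
        n = len(self.times)
        for name in ("com", "end_to_end", "rg_sq", "n_pp", "n_ps", "energy"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch in field {name!r}")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        """Sampling interval in MCS (requires uniform sampling)."""
        if self.n_frames < 2:
            return 1.0
        steps = np.diff(self.times)
        if np.ptp(steps) != 0:
            raise ValueError("trajectory is not uniformly sampled")
        return float(steps[0])

    @property
    def desorbed_fraction(self) -> float:
        """Fraction of frames with no surface contact (slab diagnostics)."""
        return float(np.mean(np.asarray(self.n_ps) == 0))


def record_trajectory(sim, production_mcs: int,
                      sample_interval: int = 1) -> TrajectoryRecord:
    """Run ``sim`` for ``production_mcs`` MCS, recording every interval.

    ``sim`` is a live :class:`~polyads.mc_engine.Simulation`.  The frame at
    the start of production is included, so the record has
    ``production_mcs // sample_interval + 1`` frames.
    """
    n_frames = int(production_mcs) // int(sample_interval) + 1
    times = np.empty(n_frames, dtype=np.int64)
    com = np.empty((n_frames, 3))
    ete = np.empty((n_frames, 3))
    rg_sq = np.empty(n_frames)
    n_pp = np.empty(n_frames, dtype=np.int64)
    n_ps = np.empty(n_frames, dtype=np.int64)
    energy = np.empty(n_frames)
    for k in range(n_frames):
        if k:
            sim.run(sample_interval)
        times[k], com[k], ete[k], rg_sq[k], n_pp[k], n_ps[k], energy[k] = \
            sim.sample_frame()
    return TrajectoryRecord(times, com, ete, rg_sq, n_pp, n_ps, energy)


@dataclass
class MsdCurve:
    lags: np.ndarray           # MCS
    values: np.ndarray         # lattice units^2
    component: str             # "xy" or "xyz"
    origin_counts: np.ndarray  # number of time origins behind each lag

    def __post_init__(self):
        if self.lags[0] != 0 or self.values[0] != 0:
            raise ValueError("MSD must start at lag 0 with value 0")
        if np.any(self.values < 0):
            raise ValueError("MSD values must be non-negative")


@dataclass
class AcfCurve:
    lags: np.ndarray           # MCS
    rho: np.ndarray            # normalized autocorrelation, rho(0) = 1
    cov: np.ndarray            # unnormalized < R(t+tau) . R(t) >
    origin_counts: np.ndarray

    def __post_init__(self):
        if not math.isclose(self.rho[0], 1.0, rel_tol=1e-9):
            raise ValueError("rho(0) must equal 1")


@dataclass
class DiffusionEstimate:
    d_xy: float                # lattice units^2 / MCS
    window: tuple[float, float]
    slope_stderr: float
    r_squared: float

    def __post_init__(self):
        if self.d_xy < 0:
            raise ValueError("negative diffusion coefficient")

    @property
    def d_stderr(self) -> float:
        return self.slope_stderr / 4.0


@dataclass
class RelaxationEstimate:
    tau_r: float               # MCS
    window: tuple[float, float]
    n_points: int
    r_squared: float
    tau_stderr: float

    def __post_init__(self):
        if self.tau_r <= 0:
            raise ValueError("relaxation time must be positive")


@dataclass
class ScalingFit:
    exponent: float            # magnitude of the log-log slope
    sign: int                  # -1 for decreasing (alpha), +1 for increasing
    prefactor: float
    stderr: float
    n_values: tuple


@dataclass
class CoilGlobuleEstimate:
    e_pp: float                # attraction of steepest R_G^2 descent
    resolution: float          # grid spacing
    derivative: float          # central-difference slope at the located point


def _default_lags(n_frames: int, n_lags: int = 120,
                  max_fraction: float = 0.125) -> np.ndarray:
    """0 plus ~n_lags log-spaced integer frame lags.

    Lags are capped at ``max_fraction`` of the trajectory so every reported
    lag retains at least ~1/max_fraction independent time origins.
    """
    max_lag = max(1, int(n_frames * max_fraction))
    raw = np.unique(np.round(np.logspace(0, np.log10(max_lag), n_lags)).astype(int))
    return np.concatenate(([0], raw[raw >= 1]))


def msd_com(traj: TrajectoryRecord, component: str = "xy",
            lags: Optional[Sequence[int]] = None) -> MsdCurve:
    """Multiple-origin MSD of the centre of mass at the given frame lags.

    ``component`` selects the in-plane ("xy") or full ("xyz") displacement.
    ``lags`` are in frames; the default is a log-spaced set capped at 1/8 of
    the trajectory length, which keeps the noisy few-origin tail out of the
    diffusion fit.  Lags are converted to MCS on output.
    """
    cols = {"xy": slice(0, 2), "xyz": slice(0, 3)}[component]
    com = np.asarray(traj.com)[:, cols]
    n = len(com)
    frame_lags = _default_lags(n) if lags is None else np.asarray(lags, dtype=int)
    if np.any(frame_lags >= n):
        raise ValueError("lag exceeds trajectory length")
    values = np.empty(len(frame_lags))
    counts = np.empty(len(frame_lags), dtype=np.int64)
    for k, lag in enumerate(frame_lags):
        if lag == 0:
            values[k], counts[k] = 0.0, n
            continue
        d = com[lag:] - com[:-lag]
        values[k] = float(np.mean(np.sum(d * d, axis=1)))
        counts[k] = n - lag
    return MsdCurve(frame_lags * traj.dt, values, component, counts)


def estimate_Dxy(msd: MsdCurve, window: Optional[tuple[float, float]] = None,
                 min_r2: float = 0.9) -> DiffusionEstimate:
    """Diffusion coefficient from the linear MSD regime: slope / 4.

    The fit window defaults to the last decade of available lags, where the
    centre-of-mass motion is diffusive.  The divisor 4 converts the 2-D
    in-plane slope (2*d*D*t with d = 2); it is applied regardless of the
    component tag so that the estimator is uniform across geometries, as the
    quasi-2D identification MSD_xy ~ MSD requires for adsorbed chains.
    """
    lags, vals = np.asarray(msd.lags, dtype=float), np.asarray(msd.values)
    if window is None:
        window = (lags[-1] / 10.0, lags[-1])
    mask = (lags >= window[0]) & (lags <= window[1]) & (lags > 0)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 lags in the diffusion fit window")
    x, y = lags[mask], vals[mask]
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(len(x) - 2, 1)
    sxx = float(np.sum((x - x.mean()) ** 2))
    stderr = math.sqrt(ss_res / dof / sxx) if sxx > 0 else float("nan")
    if slope < 0 and abs(slope) < 1e-12:
        slope = 0.0
    if ss_tot > 0 and r2 < min_r2:
        raise ValueError(f"MSD fit not linear enough (R^2 = {r2:.3f})")
    return DiffusionEstimate(max(slope, 0.0) / 4.0, tuple(window), stderr, r2)


def end_to_end_acf(traj: TrajectoryRecord,
                   max_lag_frames: Optional[int] = None) -> AcfCurve:
    """FFT-based multiple-origin autocorrelation of the end-to-end vector.

    Normalization uses the time-averaged <R . R> over the whole production
    trajectory (the lag-0 value), an equilibrium estimator that coincides
    with the ensemble definition in expectation.
    """
    R = np.asarray(traj.end_to_end, dtype=float)
    n = len(R)
    if max_lag_frames is None:
        max_lag_frames = n // 2
    max_lag_frames = min(max_lag_frames, n - 1)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    acov = np.zeros(max_lag_frames + 1)
    for c in range(3):
        f = np.fft.rfft(R[:, c], nfft)
        acov += np.fft.irfft(f * np.conj(f), nfft)[: max_lag_frames + 1]
    counts = n - np.arange(max_lag_frames + 1)
    cov = acov / counts
    if cov[0] <= 0:
        raise ValueError("degenerate end-to-end ensemble (zero norm)")
    lags = np.arange(max_lag_frames + 1) * traj.dt
    return AcfCurve(lags, cov / cov[0], cov, counts)


def average_msd(curves: Sequence[MsdCurve]) -> MsdCurve:
    """Origin-count-weighted average of per-replica MSD curves (same lags)."""
    lags = curves[0].lags
    for c in curves[1:]:
        if not np.array_equal(c.lags, lags):
            raise ValueError("curves must share a lag grid")
    w = np.stack([c.origin_counts for c in curves]).astype(float)
    v = np.stack([c.values for c in curves])
    values = np.sum(w * v, axis=0) / np.sum(w, axis=0)
    return MsdCurve(lags, values, curves[0].component,
                    np.sum(w, axis=0).astype(np.int64))


def average_acf(curves: Sequence[AcfCurve]) -> AcfCurve:
    """Ensemble average of ACF curves: average the unnormalized covariance
    (origin-count weighted), then renormalize by the pooled lag-0 value."""
    lags = curves[0].lags
    for c in curves[1:]:
        if not np.array_equal(c.lags, lags):
            raise ValueError("curves must share a lag grid")
    w = np.stack([c.origin_counts for c in curves]).astype(float)
    cv = np.stack([c.cov for c in curves])
    cov = np.sum(w * cv, axis=0) / np.sum(w, axis=0)
    return AcfCurve(lags, cov / cov[0], cov, np.sum(w, axis=0).astype(np.int64))


def estimate_tau_R(acf: AcfCurve, window: tuple[float, float] = (0.06, 0.30),
                   min_points: int = 3) -> RelaxationEstimate:
    """tau_R from the exponential decay of rho(t) inside the fit band.

    A linear, unweighted least-squares fit of ln rho against lag uses only
    lags with ``window[0] < rho < window[1]``, truncated at the first lag at
    which rho falls to the lower edge (later noisy re-entries into the band
    are ignored).  tau_R = -1/slope; an amplitude prefactor different from 1
    does not bias the estimate.
    """
    lo, hi = window
    rho = np.asarray(acf.rho, dtype=float)
    lags = np.asarray(acf.lags, dtype=float)
    below = np.nonzero((rho <= lo) & (lags > 0))[0]
    cut = below[0] if len(below) else len(rho)
    mask = (lags > 0) & (rho > lo) & (rho < hi)
    mask[cut:] = False
    if mask.sum() < min_points:
        raise ValueError(
            f"only {int(mask.sum())} ACF points inside the ({lo}, {hi}) "
            f"window; need {min_points}")
    x, y = lags[mask], np.log(rho[mask])
    slope, intercept = np.polyfit(x, y, 1)
    if slope >= 0:
        raise ValueError("ACF does not decay across the fit window")
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(mask.sum() - 2, 1)
    sxx = float(np.sum((x - x.mean()) ** 2))
    slope_err = math.sqrt(ss_res / dof / sxx) if sxx > 0 else 0.0
    tau = -1.0 / slope
    return RelaxationEstimate(tau, (float(x[0]), float(x[-1])),
                              int(mask.sum()), r2, slope_err / slope ** 2)


def fit_scaling_exponent(n_values: Sequence[float],
                         y_values: Sequence[float]) -> ScalingFit:
    """Power-law exponent by ordinary least squares on (log N, log y).

    The exponent is reported as a magnitude with a separate sign: for a
    decreasing observable (D_xy ~ N^-alpha) ``sign`` is -1 and ``exponent``
    is alpha > 0; for an increasing one (tau_R ~ N^beta) ``sign`` is +1.
    """
    n = np.asarray(n_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if len(n) < 3:
        raise ValueError("need at least 3 chain lengths for a scaling fit")
    if np.any(n <= 0) or np.any(y <= 0):
        raise ValueError("scaling fit requires positive inputs")
    x, ly = np.log(n), np.log(y)
    slope, intercept = np.polyfit(x, ly, 1)
    resid = ly - (slope * x + intercept)
    dof = max(len(n) - 2, 1)
    sxx = float(np.sum((x - x.mean()) ** 2))
    stderr = math.sqrt(float(resid @ resid) / dof / sxx)
    sign = -1 if slope < 0 else 1
    return ScalingFit(abs(float(slope)), sign, float(np.exp(intercept)),
                      stderr, tuple(np.asarray(n_values).tolist()))


def locate_coil_globule(epp_values: Sequence[float],
                        mean_rg_sq: Sequence[float]) -> CoilGlobuleEstimate:
    """Coil-globule transition point: steepest descent of <R_G^2> vs E_PP.

    Central finite differences on the grid locate the interior point of most
    negative slope; the grid spacing is the resolution of the estimate.  A
    curve with no interior slope extremum (e.g. a straight line) is rejected.
    """
    x = np.asarray(epp_values, dtype=float)
    y = np.asarray(mean_rg_sq, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 grid points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    deriv = (y[2:] - y[:-2]) / (x[2:] - x[:-2])
    scale = max(1.0, float(np.max(np.abs(deriv))))
    if np.ptp(deriv) <= 1e-9 * scale:
        raise ValueError("no interior slope extremum: curve too close to linear")
    k = int(np.argmin(deriv))
    spacing = float(np.median(np.diff(x)))
    return CoilGlobuleEstimate(float(x[k + 1]), spacing, float(deriv[k]))
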