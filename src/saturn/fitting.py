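"""Signal models and voxel-wise nonlinear least-squares relaxometry.

The joint 5-parameter truncation model fitted to the 35-sample series is

    S(TS, T2p, TE) = [A (1 - exp(-TS/T1)) exp(-T2p/T2) + B] exp(-TE/T2*)

with amplitude ``A``, offset ``B`` (accounting for the residual signal at
short saturation delays), and the three relaxation times.  ``TS = inf``
(unprepared and T2-prepared images) evaluates the recovery factor exactly as 1.
Late echoes that have sunk into the noise floor are discarded by a suffix-only
truncation rule instead of modeling the Rician offset.

Reference single-parameter models (saturation-recovery T1, T2-prepared
3-parameter, multi-echo T2* truncation) are provided for comparison studies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .sequence import SignalSeries

DEFAULT_BOUNDS = {
    "A": (1e-12, np.inf),
    "B": (-np.inf, np.inf),
    "T1": (100.0, 5000.0),
    "T2": (5.0, 300.0),
    "T2star": (1.0, 300.0),
}

PARAM_NAMES = ("A", "B", "T1", "T2", "T2star")


class DegenerateSeriesError(ValueError):
    """Raised when a series carries no fittable signal variation."""


@dataclass
class FitParams:
    A: float
    B: float
    T1: float
    T2: float
    T2star: float

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.B, self.T1, self.T2, self.T2star])


@dataclass
class FitResult:
    """Estimated parameters plus diagnostics of one voxel-level fit."""

    params: FitParams
    residuals: np.ndarray
    covariance: np.ndarray | None
    converged: bool
    n_truncated_echoes: int
    rss: float
    jacobian: np.ndarray | None = None
    noise_sd: float | None = None  # external noise estimate, if supplied

    @property
    def dof(self) -> int:
        return len(self.residuals) - 5


@dataclass
class ParameterMaps:
    """Per-voxel parameter and precision maps; unfitted voxels are masked."""

    T1: np.ndarray
    T2: np.ndarray
    T2star: np.ndarray
    A: np.ndarray
    B: np.ndarray
    sd_T1: np.ndarray
    sd_T2: np.ndarray
    sd_T2star: np.ndarray
    mask: np.ndarray  # True where a converged fit exists

    def map_dict(self) -> dict[str, np.ndarray]:
        return {
            "T1": self.T1,
            "T2": self.T2,
            "T2star": self.T2star,
            "A": self.A,
            "B": self.B,
            "sd_T1": self.sd_T1,
            "sd_T2": self.sd_T2,
            "sd_T2star": self.sd_T2star,
        }


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def _recovery(TS, T1):
    """1 - exp(-TS/T1) with TS possibly infinite (evaluates exactly to 1)."""
    TS = np.asarray(TS, float)
    out = np.ones_like(TS)
    finite = np.isfinite(TS)
    out[finite] = 1.0 - np.exp(-TS[finite] / T1)
    return out


def eval_signal_model(TS, T2p, TE, p: FitParams) -> np.ndarray | float:
    """Evaluate the 5-parameter model at the given coordinates (ms)."""
    TS = np.asarray(TS, float)
    T2p = np.asarray(T2p, float)
    TE = np.asarray(TE, float)
    rec = _recovery(TS, p.T1)
    sig = (p.A * rec * np.exp(-T2p / p.T2) + p.B) * np.exp(-TE / p.T2star)
    return float(sig) if sig.ndim == 0 else sig


def _model_and_jac(x, TS, T2p, TE):
    A, B, T1, T2, T2s = x
    rec = _recovery(TS, T1)
    e2 = np.exp(-T2p / T2)
    e3 = np.exp(-TE / T2s)
    core = A * rec * e2 + B
    model = core * e3

    finite = np.isfinite(TS)
    drec_dT1 = np.zeros_like(rec)
    drec_dT1[finite] = -np.exp(-TS[finite] / T1) * TS[finite] / T1**2
    J = np.empty((len(TS), 5))
    J[:, 0] = rec * e2 * e3
    J[:, 1] = e3
    J[:, 2] = A * e2 * e3 * drec_dT1
    J[:, 3] = A * rec * e3 * e2 * (T2p / T2**2)
    J[:, 4] = core * e3 * (TE / T2s**2)
    return model, J


# ---------------------------------------------------------------------------
# echo truncation
# ---------------------------------------------------------------------------

def truncate_echoes(
    series: SignalSeries,
    noise_sd: float,
    k: float = 2.0,
    min_echoes: int = 3,
) -> tuple[SignalSeries, int]:
    """Drop trailing noise-floor echoes per contrast (suffix-only rule).

    Within each contrast, echoes after the last one with magnitude
    ``>= k * noise_sd`` are discarded, never leaving fewer than ``min_echoes``
    retained.  ``noise_sd = 0`` leaves the series unchanged.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return series, 0

    keep = np.ones(len(series), bool)
    thresh = k * noise_sd
    for ci in np.unique(series.contrast_index):
        idx = np.where(series.contrast_index == ci)[0]
        order = idx[np.argsort(series.TE[idx])]
        mags = series.magnitude[order]
        above = np.where(mags >= thresh)[0]
        n_keep = (above[-1] + 1) if above.size else 0
        n_keep = max(n_keep, min(min_echoes, len(order)))
        keep[order[n_keep:]] = False

    n_dropped = int((~keep).sum())
    reduced = SignalSeries(
        contrast_index=series.contrast_index[keep],
        TS=series.TS[keep],
        T2p=series.T2p[keep],
        TE=series.TE[keep],
        magnitude=series.magnitude[keep],
    )
    return reduced, n_dropped


# ---------------------------------------------------------------------------
# initialization helpers
# ---------------------------------------------------------------------------

def _loglinear_decay(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit y = A exp(-x / tau) by linear regression of log y; returns (A, tau)."""
    pos = y > 0
    if pos.sum() < 2:
        return float(np.max(y, initial=1.0)), np.nan
    coef = np.polyfit(x[pos], np.log(y[pos]), 1)
    tau = -1.0 / coef[0] if coef[0] < 0 else np.nan
    return float(np.exp(coef[1])), tau


def _initial_guess(series: SignalSeries, bounds: dict) -> np.ndarray:
    """Closed-form sub-fits: T2* from the unprepared echoes, amplitudes at
    TE=0 per contrast, two-point T2, saturation-recovery T1."""
    ci = series.contrast_index
    unprepared = np.isinf(series.TS) & (series.T2p == 0)
    if unprepared.any():
        _, t2s0 = _loglinear_decay(series.TE[unprepared], series.magnitude[unprepared])
    else:
        t2s0 = np.nan
    if not np.isfinite(t2s0) or t2s0 <= 0:
        t2s0 = 25.0
    t2s0 = float(np.clip(t2s0, *bounds["T2star"]))

    # per-contrast amplitude extrapolated to TE = 0 with the T2* estimate
    amp: dict[int, tuple[float, float, float]] = {}
    for c in np.unique(ci):
        sel = ci == c
        d = np.exp(-series.TE[sel] / t2s0)
        s0 = float(np.dot(series.magnitude[sel], d) / np.dot(d, d))
        amp[int(c)] = (float(series.TS[sel][0]), float(series.T2p[sel][0]), s0)

    ts_vals = np.array([v[0] for v in amp.values()])
    s0_vals = np.array([v[2] for v in amp.values()])
    finite_ts = np.isfinite(ts_vals)
    B0 = float(s0_vals[finite_ts][np.argmin(ts_vals[finite_ts])]) if finite_ts.any() else 0.0

    t2p_vals = np.array([v[1] for v in amp.values()])
    t2w = np.isinf(ts_vals)
    A0 = float(np.max(s0_vals[t2w] - B0, initial=np.max(s0_vals) - B0))
    A0 = max(A0, 1e-6 * max(s0_vals.max(), 1e-30), 1e-30)

    if t2w.sum() >= 2:
        _, t20 = _loglinear_decay(
            t2p_vals[t2w], np.clip(s0_vals[t2w] - B0, 1e-30, None)
        )
    else:
        t20 = np.nan
    if not np.isfinite(t20) or t20 <= 0:
        t20 = 45.0
    t20 = float(np.clip(t20, *bounds["T2"]))

    # T1 from the longest finite saturation delay
    t10 = np.nan
    if finite_ts.any():
        i = int(np.argmax(np.where(finite_ts, ts_vals, -np.inf)))
        rec = (s0_vals[i] - B0) / A0
        rec = float(np.clip(rec, 1e-6, 1 - 1e-6))
        t10 = -ts_vals[i] / math.log(1.0 - rec)
    if not np.isfinite(t10) or t10 <= 0:
        t10 = 1400.0
    t10 = float(np.clip(t10, *bounds["T1"]))

    return np.array([A0, max(B0, 0.0), t10, t20, t2s0])


# ---------------------------------------------------------------------------
# the joint fit
# ---------------------------------------------------------------------------

def fit_saturn(
    series: SignalSeries,
    noise_sd: float = 0.0,
    truncation_k: float = 2.0,
    bounds: dict | None = None,
    max_starts: int = 5,
    seed: int = 0,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
) -> FitResult:
    """Fit the 5-parameter model to a (possibly truncated) signal series.

    Requires at least 2 distinct saturation delays, 2 distinct T2-prep
    durations, and 3 distinct echo times.  Initialization comes from
    closed-form sub-fits; on non-convergence up to ``max_starts`` jittered
    restarts are attempted (seeded, reproducible).
    """
    bounds = {**DEFAULT_BOUNDS, **(bounds or {})}
    if len(series) == 0 or np.all(series.magnitude == series.magnitude[0]):
        raise DegenerateSeriesError("series is empty or constant; nothing to fit")
    if len(np.unique(series.TS[np.isfinite(series.TS)])) < 2:
        raise ValueError("need >= 2 distinct finite saturation delays")
    if len(np.unique(series.T2p[series.T2p > 0])) < 2:
        raise ValueError("need >= 2 distinct T2-prep durations")
    if len(np.unique(series.TE)) < 3:
        raise ValueError("need >= 3 distinct echo times")

    reduced, n_dropped = truncate_echoes(series, noise_sd, k=truncation_k)
    TS, T2p, TE, y = reduced.TS, reduced.T2p, reduced.TE, reduced.magnitude

    def residual(x):
        model, _ = _model_and_jac(x, TS, T2p, TE)
        return model - y

    def jac(x):
        _, J = _model_and_jac(x, TS, T2p, TE)
        return J

    lo = np.array([bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([bounds[n][1] for n in PARAM_NAMES])
    x0 = np.clip(_initial_guess(reduced, bounds), lo, hi)
    scale_ref = max(float(np.max(y)), 1e-12)
    x_scale = np.array([scale_ref, scale_ref, 1000.0, 50.0, 30.0])

    rng = np.random.default_rng(seed)
    best = None
    start = x0
    for attempt in range(max_starts):
        res = least_squares(
            residual, start, jac=jac, bounds=(lo, hi), method="trf",
            x_scale=x_scale, ftol=ftol, xtol=xtol, gtol=1e-12, max_nfev=2000,
        )
        if best is None or res.cost < best.cost:
            best = res
        if res.success and res.cost <= best.cost * (1 + 1e-9):
            break
        jitter = rng.lognormal(0.0, 0.3, size=5)
        start = np.clip(x0 * jitter, lo, hi)

    params = FitParams(*best.x)
    result = FitResult(
        params=params,
        residuals=best.fun,
        covariance=None,
        converged=bool(best.success),
        n_truncated_echoes=n_dropped,
        rss=float(2 * best.cost),
        jacobian=jac(best.x),
        noise_sd=noise_sd if noise_sd > 0 else None,
    )
    result.covariance = _covariance(result)
    return result


# ---------------------------------------------------------------------------
# precision (SD) estimation
# ---------------------------------------------------------------------------

def _covariance(fit: FitResult, noise_sd: float | None = None) -> np.ndarray | None:
    J = fit.jacobian
    if J is None:
        return None
    JTJ = J.T @ J
    try:
        inv = np.linalg.inv(JTJ)
    except np.linalg.LinAlgError:
        return None
    sd = noise_sd if noise_sd is not None else fit.noise_sd
    if sd is not None:
        sigma2 = sd**2
    else:
        sigma2 = fit.rss / max(fit.dof, 1)
    return sigma2 * inv


def compute_sd(fit: FitResult, noise_sd: float | None = None) -> dict[str, float]:
    """Per-parameter standard deviations from the fit's local covariance.

    The covariance is ``sigma^2 (J^T J)^{-1}`` with the Jacobian evaluated at
    the optimum; ``sigma^2`` is the dof-corrected residual variance unless an
    external ``noise_sd`` is supplied.  Each parameter's SD is the square root
    of its own diagonal entry.  A singular normal matrix yields NaNs.
    """
    if not fit.converged:
        raise ValueError("SDs are only defined for a converged fit")
    cov = _covariance(fit, noise_sd)
    if cov is None or np.any(np.diag(cov) < -1e-12):
        return {n: float("nan") for n in PARAM_NAMES}
    diag = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return dict(zip(PARAM_NAMES, diag.astype(float)))


# ---------------------------------------------------------------------------
# reference single-parameter fits
# ---------------------------------------------------------------------------

def fit_sasha(
    TS: Sequence[float], S: Sequence[float], T1_bounds=(100.0, 5000.0)
) -> tuple[float, float, float]:
    """Saturation-recovery 3-parameter fit S(TS) = A (1 - B exp(-TS/T1)).

    ``TS`` may contain ``inf`` for the unprepared image (S = A exactly).
    Returns (T1, A, B); requires >= 3 distinct saturation delays.
    """
    TS = np.asarray(TS, float)
    S = np.asarray(S, float)
    if len(np.unique(TS)) < 3:
        raise ValueError("need >= 3 distinct saturation delays")

    finite = np.isfinite(TS)
    A0 = float(S[~finite].mean()) if (~finite).any() else float(S.max())
    A0 = max(A0, 1e-12)
    i_min = np.argmin(np.where(finite, TS, np.inf))
    B0 = float(np.clip(1.0 - S[i_min] / A0, 0.1, 2.0))

    def model(x):
        A, B, T1 = x
        rec = np.ones_like(TS)
        rec[finite] = 1.0 - B * np.exp(-TS[finite] / T1)
        return A * rec

    res = least_squares(
        lambda x: model(x) - S,
        x0=[A0, B0, 1200.0],
        bounds=([1e-12, 0.0, T1_bounds[0]], [np.inf, 2.0, T1_bounds[1]]),
        x_scale=[A0, 1.0, 1000.0],
        ftol=1e-14, xtol=1e-14, gtol=1e-14,
    )
    A, B, T1 = res.x
    return float(T1), float(A), float(B)


def fit_t2prep(
    T2p: Sequence[float], S: Sequence[float], T2_bounds=(5.0, 300.0)
) -> tuple[float, float, float]:
    """T2-prepared 3-parameter fit S(T2p) = A exp(-T2p/T2) + B.

    ``T2p`` may contain ``inf`` for the saturation-mimicked weighting, which
    pins the offset (S = B).  Without an infinite weighting a 2-parameter fit
    (B = 0) is used with a warning; that variant is known to bias T2 upward.
    """
    T2p = np.asarray(T2p, float)
    S = np.asarray(S, float)
    finite = np.isfinite(T2p)
    three_param = (~finite).any()
    if not three_param:
        warnings.warn(
            "no infinite T2 weighting available; falling back to a 2-parameter "
            "fit which biases T2",
            stacklevel=2,
        )
    B0 = float(S[~finite].mean()) if three_param else 0.0
    A0 = max(float(S[finite].max()) - B0, 1e-12)
    _, t20 = _loglinear_decay(T2p[finite], np.clip(S[finite] - B0, 1e-30, None))
    if not np.isfinite(t20) or t20 <= 0:
        t20 = 45.0
    t20 = float(np.clip(t20, *T2_bounds))

    def model(x):
        A, B, T2 = x
        out = np.full_like(T2p, B)
        out[finite] = A * np.exp(-T2p[finite] / T2) + B
        return out

    if three_param:
        x0, lo, hi = [A0, B0, t20], [1e-12, -np.inf, T2_bounds[0]], [np.inf, np.inf, T2_bounds[1]]
    else:
        x0, lo, hi = [A0, 0.0, t20], [1e-12, -1e-30, T2_bounds[0]], [np.inf, 1e-30, T2_bounds[1]]
    res = least_squares(
        lambda x: model(x) - S, x0=x0, bounds=(lo, hi),
        x_scale=[max(A0, 1e-12), max(abs(B0), 1e-3 * A0, 1e-12), 50.0],
        ftol=1e-14, xtol=1e-14, gtol=1e-14,
    )
    A, B, T2 = res.x
    return float(T2), float(A), float(B)


def fit_t2star_multiecho(
    TE: Sequence[float],
    S: Sequence[float],
    noise_sd: float = 0.0,
    truncation_k: float = 2.0,
) -> tuple[float, float]:
    """Mono-exponential 2-parameter truncation fit S(TE) = A exp(-TE/T2*)."""
    TE = np.asarray(TE, float)
    S = np.asarray(S, float)
    if len(TE) != len(S):
        raise ValueError("TE and S must have equal length")
    order = np.argsort(TE)
    TE, S = TE[order], S[order]
    if noise_sd > 0:
        above = np.where(S >= truncation_k * noise_sd)[0]
        n_keep = max((above[-1] + 1) if above.size else 0, min(3, len(S)))
        TE, S = TE[:n_keep], S[:n_keep]
    if len(np.unique(TE)) < 3:
        raise ValueError("need >= 3 retained echoes for the T2* fit")

    A0, t2s0 = _loglinear_decay(TE, S)
    if not np.isfinite(t2s0) or t2s0 <= 0:
        t2s0 = 25.0
    res = least_squares(
        lambda x: x[0] * np.exp(-TE / x[1]) - S,
        x0=[max(A0, 1e-12), float(np.clip(t2s0, 1.0, 300.0))],
        bounds=([1e-12, 1.0], [np.inf, 300.0]),
        ftol=1e-14, xtol=1e-14, gtol=1e-14,
    )
    return float(res.x[1]), float(res.x[0])


# ---------------------------------------------------------------------------
# map fitting
# ---------------------------------------------------------------------------

def fit_maps(
    stack: np.ndarray,
    TS: Sequence[float],
    T2p: Sequence[float],
    TE: Sequence[float],
    mask: np.ndarray | None = None,
    noise_sd: float = 0.0,
    contrast_index: Sequence[float] | None = None,
    **fit_kwargs,
) -> ParameterMaps:
    """Voxel-wise 5-parameter fitting of an image stack.

    ``stack`` is (ny, nx, n_samples) with per-sample coordinates ``TS``,
    ``T2p``, ``TE`` (ms; inf allowed in TS).  Voxels outside ``mask`` or whose
    fit fails are flagged in the output mask, never aborting the map.  The
    result is independent of voxel evaluation order.
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3:
        raise ValueError("stack must be (ny, nx, n_samples)")
    ny, nx, ns = stack.shape
    TS = np.asarray(TS, float)
    T2p = np.asarray(T2p, float)
    TE = np.asarray(TE, float)
    if contrast_index is None:
        # group samples sharing (TS, T2p) into contrasts for truncation
        _, contrast_index = np.unique(
            np.stack([TS, T2p]), axis=1, return_inverse=True
        )
    contrast_index = np.asarray(contrast_index, float)
    if mask is None:
        mask = np.ones((ny, nx), bool)

    maps = {n: np.full((ny, nx), np.nan) for n in
            ("T1", "T2", "T2star", "A", "B", "sd_T1", "sd_T2", "sd_T2star")}
    fitted = np.zeros((ny, nx), bool)
    for iy, ix in zip(*np.nonzero(mask)):
        series = SignalSeries(
            contrast_index=contrast_index,
            TS=TS, T2p=T2p, TE=TE,
            magnitude=np.clip(stack[iy, ix], 0.0, None),
        )
        try:
            fit = fit_saturn(series, noise_sd=noise_sd, **fit_kwargs)
        except (ValueError, DegenerateSeriesError):
            continue
        if not fit.converged:
            continue
        p = fit.params
        maps["T1"][iy, ix] = p.T1
        maps["T2"][iy, ix] = p.T2
        maps["T2star"][iy, ix] = p.T2star
        maps["A"][iy, ix] = p.A
        maps["B"][iy, ix] = p.B
        sds = compute_sd(fit)
        maps["sd_T1"][iy, ix] = sds["T1"]
        maps["sd_T2"][iy, ix] = sds["T2"]
        maps["sd_T2star"][iy, ix] = sds["T2star"]
        fitted[iy, ix] = True

    return ParameterMaps(
        T1=maps["T1"], T2=maps["T2"], T2star=maps["T2star"],
        A=maps["A"], B=maps["B"],
        sd_T1=maps["sd_T1"], sd_T2=maps["sd_T2"], sd_T2star=maps["sd_T2star"],
        mask=fitted,
    )
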