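"""Lognormal bolus model for contrast-ultrasound time–intensity curves.

A bolus of microbubble contrast transiting a tissue bed produces a
time–intensity curve (TIC) that is well described by a shifted, area-scaled
lognormal:

    I(t) = AUC / (sigma * sqrt(2*pi) * (t - t0)) *
           exp(-(ln(t - t0) - mu)**2 / (2 * sigma**2))      for t > t0,
    I(t) = 0                                                otherwise,

with AUC the area under the curve (a.u.·s), ``mu`` (log-s) and ``sigma``
(dimensionless > 0) the lognormal shape parameters, and ``t0`` (s) the bolus
arrival time.  The physiologic read-outs derive in closed form:

* time to peak       TP  = t0 + exp(mu - sigma**2)   (mode of the lognormal)
* mean transit time  MTT = exp(mu + sigma**2 / 2)    (mean, measured from t0)
* peak enhancement   PE  = I(TP)

Fitting is nonlinear least squares.  The default engine is a vectorized,
damped Gauss–Newton (Levenberg–Marquardt) written for batches of curves so
that whole-volume voxel-wise fitting is tractable on a single CPU; it is
deterministic (no randomness, no dependence on batch split).  A
``scipy.optimize.least_squares`` path (``method="trf"``) is provided for
single curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import optimize

__all__ = [
    "TimeIntensityCurve",
    "LognormalFit",
    "FitConfig",
    "lognormal_model",
    "derived_params",
    "fit_tic",
    "fit_curves",
    "roi_conventional_features",
    "ROI_FEATURE_NAMES",
]

_SQRT2PI = float(np.sqrt(2.0 * np.pi))

#: Names of the ROI-level conventional parameter block, in catalog order.
ROI_FEATURE_NAMES = ("PE", "AUC", "TP", "MTT", "T0", "mu", "sigma", "r2")


@dataclass(frozen=True)
class TimeIntensityCurve:
    """One voxel's or one ROI's contrast signal versus time."""

    t_s: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise ValueError("t_s and intensity must be 1-D arrays of equal length")
        if t.size < 8:
            raise ValueError("a TIC needs at least 8 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("TIC values must be finite")
        if np.any(t < 0):
            raise ValueError("negative times are not allowed")
        if np.any(np.diff(t) <= 0):
            raise ValueError("t_s must be strictly increasing")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "intensity", y)

    @classmethod
    def from_csv(cls, path) -> "TimeIntensityCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(arr[:, 0], arr[:, 1])

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.t_s, self.intensity]),
            delimiter=",",
            header="t_s,intensity",
            comments="",
        )


@dataclass(frozen=True)
class LognormalFit:
    """Fitted bolus parameters plus derived perfusion read-outs."""

    auc: float
    mu: float
    sigma: float
    t0: float
    pe: float
    tp: float
    mtt: float
    r2: float
    converged: bool

    def as_dict(self) -> dict[str, float]:
        return {
            "PE": self.pe,
            "AUC": self.auc,
            "TP": self.tp,
            "MTT": self.mtt,
            "T0": self.t0,
            "mu": self.mu,
            "sigma": self.sigma,
            "r2": self.r2,
        }


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the TIC fit.

    r2_floor is the goodness-of-fit floor below which a voxel counts as
    unconverged (keeps noise-only voxels out of the maps); sigma and t0
    bounds keep the optimizer in the physiologic regime.
    """

    sigma_bounds: tuple[float, float] = (0.05, 3.0)
    t0_max_fraction: float = 0.5  # t0 <= t0_max_fraction * t_max
    r2_floor: float = 0.25
    max_iter: int = 60
    subtract_baseline: bool = True
    arrival_threshold: float = 0.10  # fraction of max marking bolus arrival


def lognormal_model(t_s, auc, mu, sigma, t0):
    """Evaluate the shifted area-scaled lognormal bolus model.

    Supports broadcasting: scalar parameters with a time vector, or
    column-vector parameters (n, 1) with a row time grid.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    t = np.asarray(t_s, dtype=float)
    tau = t - np.asarray(t0, dtype=float)
    out = np.zeros(np.broadcast_shapes(tau.shape, np.shape(auc) or (1,)), dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = tau > 0
        ln_tau = np.where(pos, np.log(np.where(pos, tau, 1.0)), 0.0)
        z = (ln_tau - mu) / sigma
        val = np.asarray(auc / (sigma * _SQRT2PI) / np.where(pos, tau, 1.0)
                         * np.exp(-0.5 * z * z))
        out = np.where(pos, val, 0.0)
    return out


def derived_params(auc, mu, sigma, t0):
    """Closed-form (PE, TP, MTT) of the lognormal bolus model.

    TP is the lognormal mode shifted by t0; MTT the lognormal mean measured
    from t0; PE the model height at TP.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    tp = t0 + np.exp(mu - sigma**2)
    mtt = np.exp(mu + sigma**2 / 2.0)
    pe = auc / (sigma * _SQRT2PI) * np.exp(sigma**2 / 2.0 - mu)
    return pe, tp, mtt


# ---------------------------------------------------------------------------
# batched fitting engine
# ---------------------------------------------------------------------------

def _model_only(t, p):
    """Model values for a batch of parameter rows; t: (T,), p: (n, 4)."""
    auc, mu, sigma, t0 = (p[:, i : i + 1] for i in range(4))
    tau = t[None, :] - t0
    pos = tau > 0
    safe_tau = np.where(pos, tau, 1.0)
    z = (np.log(safe_tau) - mu) / sigma
    g = np.exp(-0.5 * z * z) / (sigma * _SQRT2PI * safe_tau)
    return auc * np.where(pos, g, 0.0)


def _model_and_jacobian(t, p):
    """Model values and analytic Jacobian for a batch of parameter rows.

    t: (T,), p: (n, 4) columns (auc, mu, sigma, t0).  Returns f (n, T) and
    J (n, T, 4).
    """
    auc, mu, sigma, t0 = (p[:, i : i + 1] for i in range(4))
    tau = t[None, :] - t0
    pos = tau > 0
    safe_tau = np.where(pos, tau, 1.0)
    ln_tau = np.log(safe_tau)
    z = (ln_tau - mu) / sigma
    g = np.exp(-0.5 * z * z) / (sigma * _SQRT2PI * safe_tau)
    g = np.where(pos, g, 0.0)
    f = auc * g
    J = np.empty(f.shape + (4,), dtype=float)
    J[..., 0] = g
    J[..., 1] = f * z / sigma
    J[..., 2] = f * (z * z - 1.0) / sigma
    # d f / d t0 = f * (1 + z/sigma) / tau   (tau decreases as t0 grows)
    J[..., 3] = np.where(pos, f * (1.0 + z / sigma) / safe_tau, 0.0)
    return f, J


def _initial_guess(t, Y, cfg: FitConfig):
    """Deterministic warm start per curve.

    t0 from the last sample before the curve exceeds ``arrival_threshold``
    of its max; mu/sigma/auc from a signal-weighted quadratic fit of
    ln(I * tau) against ln(tau) (exact for noiseless model curves at the
    true t0).
    """
    n, T = Y.shape
    peak = Y.max(axis=1)
    peak_safe = np.where(peak > 0, peak, 1.0)
    above = Y > (cfg.arrival_threshold * peak_safe)[:, None]
    first_above = np.where(above.any(axis=1), above.argmax(axis=1), 1)
    first_above = np.maximum(first_above, 1)
    t0 = t[first_above - 1]
    # pull the arrival estimate slightly earlier so ln(tau) stays defined
    dt = float(np.median(np.diff(t)))
    t0 = np.maximum(t0 - 0.25 * dt, 0.0)

    tau = t[None, :] - t0[:, None]
    valid = (tau > 1e-9) & (Y > 0.02 * peak_safe[:, None])
    w = np.where(valid, Y * Y, 0.0)
    ln_tau = np.where(tau > 1e-9, np.log(np.maximum(tau, 1e-9)), 0.0)
    z = np.where(valid, np.log(np.maximum(Y, 1e-300)) + ln_tau, 0.0)
    # weighted quadratic regression z ~ c0 + c1*ln_tau + c2*ln_tau^2, batched
    X = np.stack([np.ones_like(ln_tau), ln_tau, ln_tau**2], axis=-1)
    Xw = (X * w[..., None]).transpose(0, 2, 1)
    A = np.matmul(Xw, X)
    b = np.matmul(Xw, z[:, :, None])[..., 0]
    A += 1e-12 * np.eye(3)[None, :, :]
    try:
        c = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        c = np.stack([np.linalg.lstsq(Ai, bi, rcond=None)[0]
                      for Ai, bi in zip(A, b)])
    c2 = np.where(c[:, 2] < -1e-8, c[:, 2], -1.0)
    sigma = np.where(c[:, 2] < -1e-8,
                     np.sqrt(np.maximum(-1.0 / (2.0 * c2), 1e-6)), 0.5)
    sigma = np.clip(sigma, *cfg.sigma_bounds)
    mu = c[:, 1] * sigma**2
    mu = np.clip(mu, np.log(0.1), np.log(max(t[-1], 1.0)) + 1.0)
    auc = np.trapezoid(Y, t, axis=1)
    auc = np.maximum(auc, 1e-9)
    return np.column_stack([auc, mu, sigma, t0])


def _clip_params(p, t_max, cfg: FitConfig):
    p[:, 0] = np.maximum(p[:, 0], 1e-12)
    p[:, 1] = np.clip(p[:, 1], np.log(1e-2), np.log(max(t_max, 1.0)) + 2.0)
    p[:, 2] = np.clip(p[:, 2], *cfg.sigma_bounds)
    p[:, 3] = np.clip(p[:, 3], 0.0, cfg.t0_max_fraction * t_max)
    return p


def fit_curves(t_s: np.ndarray, Y: np.ndarray, config: FitConfig | None = None):
    """Fit the lognormal bolus model to a batch of curves.

    Parameters
    ----------
    t_s : (T,) strictly increasing times in seconds.
    Y : (n, T) nonnegative intensities, one curve per row.
    config : fit tunables.

    Returns
    -------
    params : (n, 4) array of (auc, mu, sigma, t0).
    r2 : (n,) coefficient of determination (NaN for degenerate curves).
    converged : (n,) bool, False where the optimizer failed, the curve was
        flat, or r2 fell below ``config.r2_floor``.

    The engine is a damped Gauss–Newton with per-curve Levenberg damping,
    fully vectorized across curves and free of randomness: results do not
    depend on how curves are batched.
    """
    cfg = config or FitConfig()
    t = np.asarray(t_s, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != t.size:
        raise ValueError("curve length does not match time vector")
    n = Y.shape[0]

    if cfg.subtract_baseline:
        # pre-arrival median: frames before the curve first exceeds 10% of max
        peak = Y.max(axis=1)
        thr = cfg.arrival_threshold * np.where(peak > 0, peak, 1.0)
        above = Y > thr[:, None]
        first = np.where(above.any(axis=1), above.argmax(axis=1), Y.shape[1])
        baseline = np.zeros(n)
        few = np.maximum(first, 3)
        # median over the pre-arrival window, vectorized via masked sort
        idx = np.arange(Y.shape[1])[None, :]
        pre = np.where(idx < few[:, None], Y, np.nan)
        with np.errstate(invalid="ignore"):
            baseline = np.nanmedian(pre, axis=1)
        baseline = np.where(np.isfinite(baseline), baseline, 0.0)
        Y = np.maximum(Y - baseline[:, None], 0.0)

    sst = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    flat = (Y.max(axis=1) <= 0) | (sst <= 0)

    params = _initial_guess(t, np.where(flat[:, None], 1.0, Y), cfg)
    params = _clip_params(params, t[-1], cfg)

    f = _model_only(t, params)
    sse = np.sum((Y - f) ** 2, axis=1)
    lam = np.full(n, 1e-3)
    # active-set compression: iterate only on the curves still improving
    act_idx = np.flatnonzero(~flat)
    eye4 = np.eye(4)[None, :, :]
    for _ in range(cfg.max_iter):
        if act_idx.size == 0:
            break
        p_a, Y_a, lam_a, sse_a = params[act_idx], Y[act_idx], lam[act_idx], sse[act_idx]
        f_a, J = _model_and_jacobian(t, p_a)
        r = Y_a - f_a
        Jt = J.transpose(0, 2, 1)
        g = np.matmul(Jt, r[:, :, None])[..., 0]
        H = np.matmul(Jt, J)
        diag = np.maximum(np.einsum("nkk->nk", H), 1e-12)
        Hd = H + lam_a[:, None, None] * diag[:, None, :] * eye4
        try:
            step = np.linalg.solve(Hd, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            Hd = Hd + 1e-8 * eye4
            step = np.linalg.solve(Hd, g[..., None])[..., 0]
        trial = _clip_params(p_a + step, t[-1], cfg)
        f_trial = _model_only(t, trial)
        sse_trial = np.sum((Y_a - f_trial) ** 2, axis=1)
        better = sse_trial < sse_a
        improvement = (sse_a - sse_trial) / np.maximum(sse_a, 1e-300)
        params[act_idx[better]] = trial[better]
        sse[act_idx] = np.where(better, sse_trial, sse_a)
        lam_new = np.where(better, np.maximum(lam_a * 0.3, 1e-10),
                           np.minimum(lam_a * 4.0, 1e8))
        lam[act_idx] = lam_new
        # drop curves that converged (negligible relative improvement) or
        # stalled at heavy damping
        keep = ~((better & (improvement < 1e-10)) | (~better & (lam_new > 1e6)))
        act_idx = act_idx[keep]

    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(sst > 0, 1.0 - sse / sst, np.nan)
    converged = (~flat) & np.isfinite(r2) & (r2 >= cfg.r2_floor)
    r2 = np.where(flat, np.nan, r2)
    return params, r2, converged


def _fit_from_params(params_row, r2, converged) -> LognormalFit:
    auc, mu, sigma, t0 = (float(v) for v in params_row)
    pe, tp, mtt = derived_params(auc, mu, sigma, t0)
    return LognormalFit(
        auc=auc, mu=mu, sigma=sigma, t0=t0,
        pe=float(pe), tp=float(tp), mtt=float(mtt),
        r2=float(r2), converged=bool(converged),
    )


def fit_tic(
    tic: TimeIntensityCurve,
    config: FitConfig | None = None,
    method: Literal["lm", "trf"] = "lm",
) -> LognormalFit:
    """Fit one time–intensity curve; never raises on a bad curve.

    ``method="lm"`` uses the batched engine (the same code path as the
    voxel-wise maps); ``method="trf"`` delegates to
    scipy.optimize.least_squares with bound constraints and serves as an
    independent route for cross-validation of the engine.
    """
    cfg = config or FitConfig()
    if method == "lm":
        params, r2, conv = fit_curves(tic.t_s, tic.intensity[None, :], cfg)
        return _fit_from_params(params[0], r2[0], conv[0])
    if method != "trf":
        raise ValueError(f"unknown method {method!r}")

    t, y = tic.t_s, tic.intensity.astype(float)
    if cfg.subtract_baseline:
        peak = y.max()
        if peak > 0:
            first = int(np.argmax(y > cfg.arrival_threshold * peak))
            y = np.maximum(y - np.median(y[: max(first, 3)]), 0.0)
    sst = float(np.sum((y - y.mean()) ** 2))
    if y.max() <= 0 or sst <= 0:
        return LognormalFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                            np.nan, np.nan, False)
    p0 = _initial_guess(t, y[None, :], cfg)[0]
    lo = [1e-12, np.log(1e-2), cfg.sigma_bounds[0], 0.0]
    hi = [np.inf, np.log(max(t[-1], 1.0)) + 2.0, cfg.sigma_bounds[1],
          cfg.t0_max_fraction * t[-1]]
    p0 = np.clip(p0, lo, hi)

    def resid(p):
        return lognormal_model(t, *p) - y

    try:
        sol = optimize.least_squares(resid, p0, bounds=(lo, hi),
                                     max_nfev=200 * 4, method="trf")
        sse = float(np.sum(sol.fun**2))
        r2 = 1.0 - sse / sst
        conv = bool(sol.success) and r2 >= cfg.r2_floor
        return _fit_from_params(sol.x, r2, conv)
    except Exception:
        return LognormalFit(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                            np.nan, np.nan, False)


def roi_conventional_features(volume4d, mask, frame_times, config=None) -> dict[str, float]:
    """Conventional bolus parameters from the VOI-averaged TIC.

    Averages the 4D volume over the mask per frame, fits the lognormal
    model, and returns the 8-element ROI block {PE, AUC, TP, MTT, T0, mu,
    sigma, r2}.
    """
    volume4d = np.asarray(volume4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if volume4d.shape[1:] != mask.shape:
        raise ValueError("volume and mask shapes disagree")
    if not mask.any():
        raise ValueError("empty mask")
    tic = TimeIntensityCurve(np.asarray(frame_times, dtype=float),
                             volume4d[:, mask].mean(axis=1))
    return fit_tic(tic, config=config).as_dict()
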