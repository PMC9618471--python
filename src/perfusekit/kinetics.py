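"""One-compartment contrast-kinetic model and voxel-wise fitting.

The tissue time-attenuation curve (TAC) is modelled as

    TAC(t) = A * (AIF (*) exp(-lambda t))(t)

a causal convolution of the arterial input function with a
mono-exponential residue function: ``A`` (1/s) is the inflow rate
constant and ``lambda`` (1/s) the washout rate. Fitting minimises the
sum of squared residuals over (A, lambda) with the bound-constrained
L-BFGS-B optimiser; per-parameter errors follow

    err_i = sqrt(f_stop * (H^-1)_ii),   f_stop = f_tol * max(1, |f|)

with the Hessian ``H`` of the objective evaluated at the optimum by
central finite differences and ``f_stop`` the optimiser's absolute
stopping bound (its ``f_tol`` is relative to the objective scale).

The convolution is evaluated on a uniform auxiliary grid (the exponential
kernel then admits an exact O(n) recursive filter) with trapezoid
end-weights, and linearly interpolated back to the acquisition times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.signal import lfilter
from sklearn.base import BaseEstimator

from .datatypes import AIFCurve, TimeSeriesVolume

__all__ = [
    "FitOptions",
    "CompartmentFit",
    "forward_model",
    "fit_voxel",
    "fit_errors",
    "tac_snr",
    "fit_volume",
    "OneCompartmentModel",
]

# flag bits used in fit_volume's "flags" map
FLAG_LOW_SIGNAL = 1
FLAG_BOUNDARY = 2
FLAG_BAD_HESSIAN = 4


@dataclass
class FitOptions:
    """Options controlling the voxel-wise fit.

    bounds_A, bounds_lam : (low, high) in 1/s. Defaults cover mean transit
        times from 0.1 to 1000 s.
    lam0 : initial washout-rate guess (1/s); the initial A is a moment-based
        volume estimate ``lam0 * area(TAC)/area(AIF)`` clipped to bounds.
    f_tol : L-BFGS-B relative stopping tolerance; also enters the
        parameter-error formula.
    hess_rel_step : relative step for the central-difference Hessian.
    grid_step : uniform resampling step (s) for the convolution; ``None``
        selects min(median sampling interval, 0.25/lam_max).
    subtract_baseline : subtract the first-frame value from TAC and AIF
        before fitting (conventional HU series have a nonzero baseline;
        iodine-density series start at 0 mg/mL).
    """

    bounds_A: tuple[float, float] = (0.0, 10.0)
    bounds_lam: tuple[float, float] = (1e-3, 10.0)
    lam0: float = 0.5
    f_tol: float = 1e-10
    hess_rel_step: float = 1e-4
    grid_step: float | None = None
    subtract_baseline: bool = False
    max_iter: int = 500

    def __post_init__(self) -> None:
        for lo, hi in (self.bounds_A, self.bounds_lam):
            if not (np.isfinite(lo) and np.isfinite(hi) and hi > lo):
                raise ValueError("bounds must be finite with positive measure")
        if self.f_tol <= 0:
            raise ValueError("f_tol must be positive")
        if self.hess_rel_step <= 0:
            raise ValueError("hess_rel_step must be positive")


@dataclass
class CompartmentFit:
    """Result of a single-voxel one-compartment fit."""

    A: float
    lam: float
    err_A: float
    err_lam: float
    residual_sd: float
    objective_value: float
    converged: bool
    n_iter: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def mtt(self) -> float:
        return 1.0 / self.lam


def _resolve_grid_step(times: np.ndarray, lam_max: float,
                       grid_step: float | None) -> float:
    if grid_step is not None:
        if grid_step <= 0:
            raise ValueError("grid_step must be positive")
        return float(grid_step)
    med = float(np.median(np.diff(times)))
    return min(med, 0.25 / lam_max)


class _ConvolutionGrid:
    """Precomputed uniform grid shared by all objective evaluations.

    ``model(lam)`` returns the unit-amplitude model curve m(t; lambda) at
    the requested times and its derivative dm/dlambda. The convolution on
    the uniform grid uses trapezoid end-weights:

        S[i] = dt * (sum_{j<=i} f_j r^(i-j)) - dt/2 * (f_i + f_0 r^i),

    r = exp(-lambda dt), which is the trapezoid-rule quadrature of
    integral f(s) exp(-lambda (t_i - s)) ds and is O(dt^2) accurate.
    """

    def __init__(self, aif: AIFCurve, times: np.ndarray, dt: float) -> None:
        t0, t1 = aif.times[0], max(aif.times[-1], times[-1])
        n = int(np.ceil((t1 - t0) / dt)) + 1
        self.tg = t0 + dt * np.arange(n)
        self.dt = dt
        self.f = np.interp(self.tg, aif.times, aif.values)
        self.trel = self.tg - t0
        self.times = times

    def model(self, lam: float, with_grad: bool = True):
        dt, f = self.dt, self.f
        r = np.exp(-lam * dt)
        F = lfilter([1.0], [1.0, -r], f)           # sum_{j<=i} f_j r^(i-j)
        decay = np.exp(-lam * self.trel)           # r^i
        s = dt * F - 0.5 * dt * (f + f[0] * decay)
        m = np.interp(self.times, self.tg, s)
        if not with_grad:
            return m, None
        # G[i] = sum_j f_j (i-j) r^(i-j) via G[i] = r (G[i-1] + F[i-1])
        v = np.empty_like(F)
        v[0] = 0.0
        v[1:] = r * F[:-1]
        G = lfilter([1.0], [1.0, -r], v)
        ds = -(dt ** 2) * G + 0.5 * dt * f[0] * self.trel * decay
        dm = np.interp(self.times, self.tg, ds)
        return m, dm


def forward_model(
    aif: AIFCurve,
    A: float,
    lam: float,
    times: Sequence[float] | np.ndarray,
    grid_step: float | None = None,
) -> np.ndarray:
    """Evaluate the one-compartment TAC at the given times.

    Parameters are the inflow rate constant ``A`` (1/s) and washout rate
    ``lam`` (1/s); the AIF is resampled to a uniform grid, convolved with
    the exponential residue, and interpolated back to ``times``.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be 1D and strictly increasing")
    if lam <= 0:
        raise ValueError("lam must be positive")
    dt = _resolve_grid_step(aif.times, max(lam, 1e-12), grid_step)
    grid = _ConvolutionGrid(aif, times, dt)
    m, _ = grid.model(lam, with_grad=False)
    return A * m


def fit_errors(
    objective: Callable[[np.ndarray], float],
    optimum: Sequence[float],
    f_tol: float,
    rel_step: float = 1e-4,
) -> tuple[float, float]:
    """Parameter errors from the stopping tolerance and inverse Hessian.

    err_i = sqrt(f_stop * (H^-1)_ii), with H the central-finite-difference
    Hessian of ``objective`` at ``optimum`` and f_stop the optimiser's
    absolute stopping bound ``f_tol * max(1, |f(optimum)|)`` (L-BFGS-B's
    ftol is relative to the objective scale, clamped at 1, so for noisy
    data the bound - and hence the reported error - grows with the
    residual sum of squares). A non-positive-definite H yields NaN
    errors with a warning.
    """
    x = np.asarray(optimum, dtype=float)
    n = x.size
    h = rel_step * np.maximum(np.abs(x), rel_step)
    f0 = objective(x)
    f_stop = f_tol * max(1.0, abs(f0))
    H = np.empty((n, n))
    for i in range(n):
        ei = np.zeros(n); ei[i] = h[i]
        H[i, i] = (objective(x + ei) - 2.0 * f0 + objective(x - ei)) / h[i] ** 2
    for i in range(n):
        for j in range(i + 1, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                objective(x + ei + ej) - objective(x + ei - ej)
                - objective(x - ei + ej) + objective(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    try:
        eigvals = np.linalg.eigvalsh(H)
        if np.any(eigvals <= 0):
            raise np.linalg.LinAlgError("Hessian not positive definite")
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        warnings.warn("Hessian not positive definite; errors set to NaN",
                      RuntimeWarning, stacklevel=2)
        return tuple(np.full(n, np.nan))
    return tuple(np.sqrt(f_stop * np.diag(Hinv)))


def _prepare(tac: np.ndarray, aif: AIFCurve, times: np.ndarray,
             opts: FitOptions) -> tuple[np.ndarray, AIFCurve]:
    if opts.subtract_baseline:
        tac = tac - tac[0]
        aif = AIFCurve(times=aif.times, values=aif.values - aif.values[0],
                       source=aif.source)
    return tac, aif


def fit_voxel(
    tac: Sequence[float] | np.ndarray,
    aif: AIFCurve,
    times: Sequence[float] | np.ndarray,
    opts: FitOptions | None = None,
    _grid: _ConvolutionGrid | None = None,
) -> CompartmentFit:
    """Fit the one-compartment model to a single voxel TAC.

    Least-squares over (A, lambda) with L-BFGS-B within the configured
    bounds; analytic gradient. Flat (zero-signal) TACs short-circuit to
    A at its lower bound with a ``low-signal`` flag; an optimum on a
    bound is flagged ``boundary`` (errors still computed).
    """
    opts = opts or FitOptions()
    tac = np.asarray(tac, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if tac.shape != times.shape:
        raise ValueError("tac and times must have equal length")
    if len(times) < 4:
        raise ValueError("need at least 4 time points to fit 2 parameters")
    if not np.all(np.isfinite(tac)):
        raise ValueError("tac contains non-finite values")

    if _grid is None:
        tac, aif = _prepare(tac, aif, times, opts)
        dt = _resolve_grid_step(aif.times, opts.bounds_lam[1], opts.grid_step)
        _grid = _ConvolutionGrid(aif, times, dt)
    elif opts.subtract_baseline:
        tac = tac - tac[0]

    lo_A, hi_A = opts.bounds_A
    lo_l, hi_l = opts.bounds_lam

    if np.ptp(tac) == 0.0:
        lam_flat = float(np.clip(opts.lam0, lo_l, hi_l))
        m_flat, _ = _grid.model(lam_flat, with_grad=False)
        resid_flat = lo_A * m_flat - tac
        dof_flat = max(len(tac) - 2, 1)
        return CompartmentFit(
            A=lo_A, lam=lam_flat, err_A=np.nan, err_lam=np.nan,
            residual_sd=float(np.sqrt(resid_flat @ resid_flat / dof_flat)),
            objective_value=float(resid_flat @ resid_flat),
            converged=True, n_iter=0, flags=("low-signal",),
        )

    def fun_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        A, lam = x
        m, dm = _grid.model(lam)
        resid = A * m - tac
        f = float(resid @ resid)
        gA = 2.0 * float(m @ resid)
        gl = 2.0 * A * float(dm @ resid)
        return f, np.array([gA, gl])

    def fun(x: np.ndarray) -> float:
        A, lam = x
        m, _ = _grid.model(lam, with_grad=False)
        resid = A * m - tac
        return float(resid @ resid)

    # moment-based initial amplitude: lam0 * area(TAC) / area(AIF)
    area_tac = float(np.trapezoid(tac, times))
    area_aif = float(np.trapezoid(np.interp(times, _grid.tg, _grid.f), times))
    A0 = opts.lam0 * area_tac / area_aif if area_aif > 0 else 0.5 * (lo_A + hi_A)
    x0 = np.array([np.clip(A0, lo_A, hi_A), np.clip(opts.lam0, lo_l, hi_l)])

    res = minimize(
        fun_grad, x0, jac=True, method="L-BFGS-B",
        bounds=[(lo_A, hi_A), (lo_l, hi_l)],
        options={"ftol": opts.f_tol, "gtol": 1e-12, "maxiter": opts.max_iter},
    )
    A_hat, lam_hat = res.x
    flags: list[str] = []
    atol_A = 1e-9 * max(1.0, hi_A)
    atol_l = 1e-9 * max(1.0, hi_l)
    if (abs(A_hat - lo_A) < atol_A or abs(A_hat - hi_A) < atol_A
            or abs(lam_hat - lo_l) < atol_l or abs(lam_hat - hi_l) < atol_l):
        flags.append("boundary")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        err_A, err_lam = fit_errors(fun, res.x, opts.f_tol, opts.hess_rel_step)
    if not (np.isfinite(err_A) and np.isfinite(err_lam)):
        flags.append("bad-hessian")

    m, _ = _grid.model(lam_hat, with_grad=False)
    resid = A_hat * m - tac
    dof = max(len(tac) - 2, 1)
    residual_sd = float(np.sqrt(resid @ resid / dof))

    return CompartmentFit(
        A=float(A_hat), lam=float(lam_hat),
        err_A=float(err_A), err_lam=float(err_lam),
        residual_sd=residual_sd, objective_value=float(res.fun),
        converged=bool(res.success), n_iter=int(res.nit),
        flags=tuple(flags),
    )


def tac_snr(
    fit: CompartmentFit,
    tac: Sequence[float] | np.ndarray,
    aif: AIFCurve,
    times: Sequence[float] | np.ndarray,
    opts: FitOptions | None = None,
) -> float:
    """SNR of a fitted TAC: peak of the fitted curve over residual SD.

    Returns +inf (with a warning) when the residual SD is zero.
    """
    opts = opts or FitOptions()
    tac = np.asarray(tac, dtype=float)
    times = np.asarray(times, dtype=float)
    tac, aif = _prepare(tac, aif, times, opts)
    curve = forward_model(aif, fit.A, fit.lam, times, opts.grid_step)
    if np.ptp(curve) == 0.0:
        raise ValueError("fitted curve is constant; SNR undefined")
    resid = curve - tac
    dof = max(len(tac) - 2, 1)
    sd = float(np.sqrt(resid @ resid / dof))
    if sd == 0.0:
        warnings.warn("zero residual SD; SNR is infinite", RuntimeWarning,
                      stacklevel=2)
        return float("inf")
    return float(curve.max() / sd)


class OneCompartmentModel(BaseEstimator):
    """Voxel-wise one-compartment tracer-kinetic fitter.

    scikit-learn-style estimator: ``X`` is an ``(n_voxels, n_times)``
    matrix of TACs sampled at ``times`` and driven by ``aif``. ``fit``
    estimates per-voxel (A, lambda) by bound-constrained least squares;
    ``predict`` returns the fitted model curves.

    Parameters
    ----------
    aif : AIFCurve
    times : array-like of shape (n_times,)
    bounds_A, bounds_lam, lam0, f_tol, hess_rel_step, grid_step,
    subtract_baseline, max_iter : see :class:`FitOptions`.

    Attributes
    ----------
    A_, lam_ : ndarray of shape (n_voxels,)
        Fitted rate constants (1/s).
    err_A_, err_lam_ : ndarray
        Parameter errors sqrt(f_tol * (H^-1)_ii).
    residual_sd_, objective_value_ : ndarray
    converged_ : ndarray of bool
    n_iter_ : ndarray of int
    flags_ : ndarray of uint8 bitmasks (1 low-signal, 2 boundary,
        4 bad-hessian).
    """

    def __init__(self, aif: AIFCurve | None = None,
                 times: np.ndarray | None = None,
                 bounds_A: tuple[float, float] = (0.0, 10.0),
                 bounds_lam: tuple[float, float] = (1e-3, 10.0),
                 lam0: float = 0.5, f_tol: float = 1e-10,
                 hess_rel_step: float = 1e-4,
                 grid_step: float | None = None,
                 subtract_baseline: bool = False,
                 max_iter: int = 500) -> None:
        self.aif = aif
        self.times = times
        self.bounds_A = bounds_A
        self.bounds_lam = bounds_lam
        self.lam0 = lam0
        self.f_tol = f_tol
        self.hess_rel_step = hess_rel_step
        self.grid_step = grid_step
        self.subtract_baseline = subtract_baseline
        self.max_iter = max_iter

    def _options(self) -> FitOptions:
        return FitOptions(
            bounds_A=self.bounds_A, bounds_lam=self.bounds_lam,
            lam0=self.lam0, f_tol=self.f_tol,
            hess_rel_step=self.hess_rel_step, grid_step=self.grid_step,
            subtract_baseline=self.subtract_baseline, max_iter=self.max_iter,
        )

    def fit(self, X: np.ndarray, y=None) -> "OneCompartmentModel":
        if self.aif is None or self.times is None:
            raise ValueError("aif and times must be set before fitting")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_voxels, n_times)")
        times = np.asarray(self.times, dtype=float)
        if X.shape[1] != len(times):
            raise ValueError("X columns must match len(times)")
        opts = self._options()

        aif = self.aif
        if opts.subtract_baseline:
            aif = AIFCurve(times=aif.times,
                           values=aif.values - aif.values[0],
                           source=aif.source)
        dt = _resolve_grid_step(aif.times, opts.bounds_lam[1], opts.grid_step)
        grid = _ConvolutionGrid(aif, times, dt)

        n = X.shape[0]
        self.A_ = np.empty(n); self.lam_ = np.empty(n)
        self.err_A_ = np.empty(n); self.err_lam_ = np.empty(n)
        self.residual_sd_ = np.empty(n); self.objective_value_ = np.empty(n)
        self.converged_ = np.empty(n, dtype=bool)
        self.n_iter_ = np.empty(n, dtype=int)
        self.flags_ = np.zeros(n, dtype=np.uint8)
        flag_bits = {"low-signal": FLAG_LOW_SIGNAL, "boundary": FLAG_BOUNDARY,
                     "bad-hessian": FLAG_BAD_HESSIAN}
        for i in range(n):
            f = fit_voxel(X[i], aif, times, opts, _grid=grid)
            self.A_[i] = f.A; self.lam_[i] = f.lam
            self.err_A_[i] = f.err_A; self.err_lam_[i] = f.err_lam
            self.residual_sd_[i] = f.residual_sd
            self.objective_value_[i] = f.objective_value
            self.converged_[i] = f.converged
            self.n_iter_[i] = f.n_iter
            for name in f.flags:
                self.flags_[i] |= flag_bits[name]
        self.n_features_in_ = X.shape[1]
        self.grid_step_ = dt
        return self

    def predict(self, X: np.ndarray | None = None) -> np.ndarray:
        """Fitted model curves for the training voxels, shape (n_voxels, n_times)."""
        if not hasattr(self, "A_"):
            raise RuntimeError("estimator is not fitted")
        aif = self.aif
        opts = self._options()
        if opts.subtract_baseline:
            aif = AIFCurve(times=aif.times,
                           values=aif.values - aif.values[0],
                           source=aif.source)
        times = np.asarray(self.times, dtype=float)
        grid = _ConvolutionGrid(aif, times, self.grid_step_)
        out = np.empty((len(self.A_), len(times)))
        for i, (A, lam) in enumerate(zip(self.A_, self.lam_)):
            m, _ = grid.model(lam, with_grad=False)
            out[i] = A * m
        return out


def fit_volume(
    series: TimeSeriesVolume,
    aif: AIFCurve,
    mask: np.ndarray | None = None,
    opts: FitOptions | None = None,
) -> dict[str, np.ndarray]:
    """Fit every masked voxel of a 4D series; thin wrapper over
    :class:`OneCompartmentModel`.

    Returns a dict of (z, y, x) maps: ``A``, ``lam``, ``err_A``,
    ``err_lam``, ``residual_sd``, ``converged`` (bool), ``n_iter`` and
    ``flags`` (uint8 bitmask). Unmasked voxels carry NaN / 0 sentinels.
    """
    opts = opts or FitOptions(
        subtract_baseline=(series.modality == "conventional_hu")
    )
    spatial = series.spatial_shape
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask shape must match the series spatial grid")

    maps: dict[str, np.ndarray] = {
        "A": np.full(spatial, np.nan), "lam": np.full(spatial, np.nan),
        "err_A": np.full(spatial, np.nan), "err_lam": np.full(spatial, np.nan),
        "residual_sd": np.full(spatial, np.nan),
        "converged": np.zeros(spatial, dtype=bool),
        "n_iter": np.zeros(spatial, dtype=int),
        "flags": np.zeros(spatial, dtype=np.uint8),
    }
    if not mask.any():
        warnings.warn("empty mask: no voxels fitted", RuntimeWarning,
                      stacklevel=2)
        return maps

    X = series.data[:, mask].T  # (n_voxels, n_times)
    est = OneCompartmentModel(
        aif=aif, times=series.timestamps,
        bounds_A=opts.bounds_A, bounds_lam=opts.bounds_lam, lam0=opts.lam0,
        f_tol=opts.f_tol, hess_rel_step=opts.hess_rel_step,
        grid_step=opts.grid_step, subtract_baseline=opts.subtract_baseline,
        max_iter=opts.max_iter,
    ).fit(X)
    maps["A"][mask] = est.A_
    maps["lam"][mask] = est.lam_
    maps["err_A"][mask] = est.err_A_
    maps["err_lam"][mask] = est.err_lam_
    maps["residual_sd"][mask] = est.residual_sd_
    maps["converged"][mask] = est.converged_
    maps["n_iter"][mask] = est.n_iter_
    maps["flags"][mask] = est.flags_
    return maps
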