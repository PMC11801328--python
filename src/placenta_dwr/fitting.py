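"""Voxel-wise estimation of T2*-ADC, T2*-IVIM and tensor FA.

All fits minimise ordinary (unweighted) squared residuals against the
magnitude signal with bounded trust-region least squares
(``scipy.optimize.least_squares``).  By default the model predicts the
magnitude directly; when the noise SD is known (``FitConfig.sigma``) the
prediction is replaced by the exact Rician expectation
E[M | S, sigma] = sigma sqrt(pi/2) [(1+x) I0e(x/2) + x I1e(x/2)],
x = S^2 / (2 sigma^2), which removes the noise-floor bias that otherwise
corrupts the most attenuated measurements — without it the fast
compartment's T2* is badly underestimated at realistic SNR.

The T2*-ADC fit is initialised from two log-linear regressions: log-signal
against TE at low b for T2*, and against b at the shortest TE for ADC.
The IVIM fit supports a ``segmented`` strategy (slow compartment on
b >= 200 s/mm^2 first, fast compartment on the remainder) and a ``full``
strategy (joint six-parameter fit seeded by the segmented result plus
randomised multi-starts).  Compartments are relabelled so D* > ADC.

FA is obtained from the shortest-echo-time data by a weighted log-linear
single-tensor fit with eigenvalues clamped at zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares
from scipy.special import i0e, i1e

from .models import (
    DiffusionTensor,
    IvimParams,
    MonoExpParams,
    fractional_anisotropy,
)
from .protocol import AcquisitionScheme

__all__ = [
    "FitResult",
    "FitConfig",
    "ParameterMaps",
    "fit_monoexp",
    "fit_ivim",
    "fit_tensor_fa",
    "fit_volume",
]

# fitting bounds: T2* in (1, 300] ms, ADC in [0, 0.01] mm^2/s, D* in [0, 0.5].
# The physiological >200 ms exclusion is applied downstream (ROI stage), not
# here, so its effect on summaries stays observable.
T2_BOUNDS = (1.0, 300.0)
ADC_BOUNDS = (0.0, 0.01)
DSTAR_BOUNDS = (0.0, 0.5)
IVIM_B_SPLIT = 200.0  # s/mm^2, segmented-fit threshold


@dataclass
class FitResult:
    """Outcome of a single-voxel fit."""

    params: MonoExpParams | IvimParams | DiffusionTensor | None
    residual_norm: float
    converged: bool
    n_iterations: int = 0
    reason: str | None = None
    fa: float | None = None


@dataclass(frozen=True)
class FitConfig:
    """Knobs shared by voxel-wise fitting."""

    strategy: Literal["segmented", "full"] = "full"
    n_starts: int = 5
    seed: int = 0
    max_nfev: int = 200
    #: known Rician noise SD; None fits the magnitude directly
    sigma: float | None = None


@dataclass
class ParameterMaps:
    """3D maps of fitted parameters, defined exactly on the input mask."""

    maps: dict[str, np.ndarray]
    mask: np.ndarray
    model: str
    converged: np.ndarray = None  # boolean map
    summary: dict = field(default_factory=dict)


def rician_expectation(s: np.ndarray, sigma: float) -> np.ndarray:
    """Expected magnitude E[M] of a Rician measurement with true signal s.

    Uses exponentially scaled Bessel functions, stable at any SNR;
    approaches sigma*sqrt(pi/2) as s -> 0 and s as s >> sigma.
    """
    s = np.asarray(s, dtype=float)
    u = s**2 / (4.0 * sigma**2)
    x = 2.0 * u
    return sigma * np.sqrt(np.pi / 2.0) * ((1.0 + x) * i0e(u) + x * i1e(u))


def _rician_dds(s: np.ndarray, sigma: float) -> np.ndarray:
    """d E[M] / d s — chain-rule factor for Rician-corrected jacobians."""
    s = np.asarray(s, dtype=float)
    u = s**2 / (4.0 * sigma**2)
    return np.sqrt(np.pi / 2.0) * (s / (2.0 * sigma)) * (i0e(u) + i1e(u))


def _positive_log(signal: np.ndarray) -> np.ndarray:
    floor = max(np.max(signal), 1.0) * 1e-12
    return np.log(np.clip(signal, floor, None))


def _init_monoexp(signal, te, b, te_min) -> tuple[float, float, float]:
    """Two log-linear regressions for (s0, t2_star, adc) starting values."""
    logs = _positive_log(signal)
    # T2* from TE dependence at low b
    low_b = b <= np.quantile(b, 0.25)
    tau = te[low_b] - te_min
    if np.ptp(tau) > 0:
        slope = np.polyfit(tau, logs[low_b], 1)[0]
        t2 = -1.0 / slope if slope < 0 else T2_BOUNDS[1] / 2
    else:
        t2 = 60.0
    # ADC from b dependence at the shortest TE
    at_te0 = te == te_min
    if np.ptp(b[at_te0]) > 0:
        slope_b, intercept = np.polyfit(b[at_te0], logs[at_te0], 1)
        adc = -slope_b if slope_b < 0 else 0.0
        s0 = float(np.exp(intercept))
    else:
        adc, s0 = 1e-3, float(np.max(signal))
    t2 = float(np.clip(t2, T2_BOUNDS[0] * 1.01, T2_BOUNDS[1] * 0.999))
    adc = float(np.clip(adc, ADC_BOUNDS[0], ADC_BOUNDS[1] * 0.999))
    s0 = float(np.clip(s0, 1e-6, 10 * max(np.max(signal), 1e-6)))
    return s0, t2, adc


def fit_monoexp(signal: np.ndarray, scheme: AcquisitionScheme, config: FitConfig | None = None) -> FitResult:
    """Fit the mono-exponential T2*-ADC model to one voxel's signal.

    Requires at least 3 distinct echo times and 3 distinct b-values.
    A voxel with no positive signal is flagged non-converged rather than
    raising, so volume fits never abort.
    """
    config = config or FitConfig()
    signal = np.asarray(signal, dtype=float)
    if len(signal) != len(scheme):
        raise ValueError(f"signal length {len(signal)} != scheme length {len(scheme)}")
    te, b, te_min = scheme.echo_times, scheme.b_values, scheme.te_min
    if len(np.unique(te)) < 3 or len(np.unique(b)) < 3:
        raise ValueError("need >= 3 distinct echo times and >= 3 distinct b-values")
    if not np.any(signal > 0):
        return FitResult(None, float(np.linalg.norm(signal)), False, reason="no positive signal")

    tau = te - te_min
    sigma = config.sigma

    def residuals(theta):
        s0, t2, adc = theta
        pred = s0 * np.exp(-tau / t2 - b * adc)
        if sigma:
            pred = rician_expectation(pred, sigma)
        return pred - signal

    def jac(theta):
        s0, t2, adc = theta
        e = np.exp(-tau / t2 - b * adc)
        J = np.stack([e, s0 * e * tau / t2**2, -s0 * e * b], axis=1)
        if sigma:
            J = J * _rician_dds(s0 * e, sigma)[:, None]
        return J

    x0 = _init_monoexp(signal, te, b, te_min)
    sol = least_squares(
        residuals, x0, jac=jac,
        bounds=([1e-9, T2_BOUNDS[0], ADC_BOUNDS[0]], [np.inf, T2_BOUNDS[1], ADC_BOUNDS[1]]),
        max_nfev=config.max_nfev,
    )
    params = MonoExpParams(s0=float(sol.x[0]), t2_star=float(sol.x[1]), adc=float(sol.x[2]))
    return FitResult(params, float(np.linalg.norm(sol.fun)), bool(sol.success), int(sol.nfev))


def _fit_decay_subset(signal, tau, b, t2_hint=60.0, d_bounds=ADC_BOUNDS, max_nfev=200,
                      sigma=None, baseline=0.0):
    """Bounded NLLS of baseline + A * exp(-tau/t2 - b*d) on a subset.

    ``baseline`` is a fixed additive prediction (the already-fitted slow
    compartment during segmented IVIM); the Rician expectation, when
    sigma is given, applies to the summed prediction.
    """
    component = np.clip(signal - baseline, 0.0, None)
    logs = _positive_log(component)
    a0 = float(np.max(component))
    design_ok = np.ptp(tau) > 0 and np.ptp(b) > 0
    if design_ok:
        X = np.column_stack([np.ones_like(tau), -tau, -b])
        coef, *_ = np.linalg.lstsq(X, logs, rcond=None)
        a0 = float(np.exp(np.clip(coef[0], -50, 50)))
        t2_hint = 1.0 / coef[1] if coef[1] > 0 else t2_hint
    t2_0 = float(np.clip(t2_hint, T2_BOUNDS[0] * 1.01, T2_BOUNDS[1] * 0.999))
    d_0 = float(np.clip(coef[2] if design_ok else d_bounds[1] / 10, d_bounds[0], d_bounds[1] * 0.999))
    a0 = max(a0, 1e-9)

    def residuals(theta):
        a, t2, d = theta
        pred = baseline + a * np.exp(-tau / t2 - b * d)
        if sigma:
            pred = rician_expectation(pred, sigma)
        return pred - signal

    def jac(theta):
        a, t2, d = theta
        e = np.exp(-tau / t2 - b * d)
        J = np.stack([e, a * e * tau / t2**2, -a * e * b], axis=1)
        if sigma:
            J = J * _rician_dds(baseline + a * e, sigma)[:, None]
        return J

    sol = least_squares(
        residuals, (a0, t2_0, d_0), jac=jac,
        bounds=([1e-12, T2_BOUNDS[0], d_bounds[0]], [np.inf, T2_BOUNDS[1], d_bounds[1]]),
        max_nfev=max_nfev,
    )
    return sol


def _ivim_residual_factory(signal, tau, b, sigma=None):
    def residuals(theta):
        s0, f, t2f, t2s, ds, adc = theta
        fast = f * np.exp(-tau / t2f - b * ds)
        slow = (1.0 - f) * np.exp(-tau / t2s - b * adc)
        pred = s0 * (fast + slow)
        if sigma:
            pred = rician_expectation(pred, sigma)
        return pred - signal

    def jac(theta):
        s0, f, t2f, t2s, ds, adc = theta
        ef = np.exp(-tau / t2f - b * ds)
        es = np.exp(-tau / t2s - b * adc)
        J = np.stack(
            [
                f * ef + (1 - f) * es,
                s0 * (ef - es),
                s0 * f * ef * tau / t2f**2,
                s0 * (1 - f) * es * tau / t2s**2,
                -s0 * f * ef * b,
                -s0 * (1 - f) * es * b,
            ],
            axis=1,
        )
        if sigma:
            J = J * _rician_dds(s0 * (f * ef + (1 - f) * es), sigma)[:, None]
        return J

    return residuals, jac


_IVIM_LO = np.array([1e-9, 0.0, T2_BOUNDS[0], T2_BOUNDS[0], DSTAR_BOUNDS[0], ADC_BOUNDS[0]])
_IVIM_HI = np.array([np.inf, 1.0, T2_BOUNDS[1], T2_BOUNDS[1], DSTAR_BOUNDS[1], ADC_BOUNDS[1]])


def _segmented_ivim(signal, tau, b, max_nfev, sigma=None) -> np.ndarray:
    """Segmented estimate: slow compartment on b >= 200, fast on the rest."""
    high = b >= IVIM_B_SPLIT
    slow_sol = _fit_decay_subset(signal[high], tau[high], b[high], max_nfev=max_nfev, sigma=sigma)
    a_slow, t2s, adc = slow_sol.x
    slow_pred = a_slow * np.exp(-tau / t2s - b * adc)
    low = ~high
    fast_sol = _fit_decay_subset(
        signal[low], tau[low], b[low], t2_hint=t2s + 40.0,
        d_bounds=(ADC_BOUNDS[1], DSTAR_BOUNDS[1]), max_nfev=max_nfev,
        sigma=sigma, baseline=slow_pred[low],
    )
    a_fast, t2f, d_star = fast_sol.x
    s0 = a_slow + a_fast
    f = a_fast / s0 if s0 > 0 else 0.0
    return np.array([s0, f, t2f, t2s, d_star, adc])


def fit_ivim(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    strategy: Literal["full", "segmented"] = "full",
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the two-compartment T2*-IVIM model to one voxel's signal.

    ``segmented`` returns the two-stage estimate directly; ``full``
    refines it by joint bounded least squares with ``config.n_starts``
    randomised restarts (lowest residual wins, ties to the first start).
    The result is relabelled so d_star > adc, with f the fast fraction.
    A fit with f pinned at a bound and indistinguishable compartments is
    flagged non-converged with reason ``"non-identifiable"``.
    """
    config = config or FitConfig()
    signal = np.asarray(signal, dtype=float)
    if len(signal) != len(scheme):
        raise ValueError(f"signal length {len(signal)} != scheme length {len(scheme)}")
    te, b, te_min = scheme.echo_times, scheme.b_values, scheme.te_min
    if len(np.unique(te)) < 3 or len(np.unique(b)) < 3:
        raise ValueError("need >= 3 distinct echo times and >= 3 distinct b-values")
    if np.sum(b >= IVIM_B_SPLIT) < 2 or np.sum(b < IVIM_B_SPLIT) < 2:
        raise ValueError(
            f"need >= 2 b-values on each side of the {IVIM_B_SPLIT:g} s/mm^2 split"
        )
    if not np.any(signal > 0):
        return FitResult(None, float(np.linalg.norm(signal)), False, reason="no positive signal")
    tau = te - te_min
    seg = _segmented_ivim(signal, tau, b, config.max_nfev, sigma=config.sigma)
    seg = np.clip(seg, _IVIM_LO + 1e-12, np.where(np.isinf(_IVIM_HI), np.inf, _IVIM_HI - 1e-12))

    if strategy == "segmented":
        best_x, residual, nit, success = seg, None, 0, True
    elif strategy == "full":
        residuals, jac = _ivim_residual_factory(signal, tau, b, sigma=config.sigma)
        rng = np.random.default_rng(config.seed)
        starts = [seg]
        for _ in range(config.n_starts - 1):
            pert = seg * rng.lognormal(0.0, 0.3, size=6)
            pert[1] = np.clip(seg[1] + rng.normal(0, 0.1), 0.01, 0.99)
            starts.append(np.clip(pert, _IVIM_LO + 1e-9, np.minimum(_IVIM_HI - 1e-9, 1e12)))
        best_x, best_cost, nit, success = None, np.inf, 0, False
        for x0 in starts:
            sol = least_squares(
                residuals, x0, jac=jac, bounds=(_IVIM_LO, _IVIM_HI),
                max_nfev=config.max_nfev,
            )
            nit += sol.nfev
            if sol.cost < best_cost - 1e-15:
                best_x, best_cost, success = sol.x, sol.cost, bool(sol.success)
    else:
        raise ValueError(f"unknown strategy {strategy!r}; expected 'full' or 'segmented'")

    s0, f, t2f, t2s, ds, adc = best_x
    params = IvimParams(
        s0=float(s0), f=float(f), t2_star_fast=float(t2f),
        t2_star_slow=float(t2s), d_star=float(ds), adc=float(adc),
    ).canonical()
    residuals_fn, _ = _ivim_residual_factory(signal, tau, b, sigma=config.sigma)
    res_norm = float(np.linalg.norm(residuals_fn(best_x)))
    reason = None
    converged = bool(success)
    f_pinned = params.f < 1e-3 or params.f > 1 - 1e-3
    degenerate = abs(params.d_star - params.adc) < 1e-6 and abs(
        params.t2_star_fast - params.t2_star_slow
    ) < 1e-3
    if f_pinned and degenerate:
        converged, reason = False, "non-identifiable"
    return FitResult(params, res_norm, converged, int(nit), reason)


def fit_tensor_fa(signal: np.ndarray, scheme: AcquisitionScheme, s0_hint: float | None = None) -> FitResult:
    """Weighted log-linear single-tensor fit on first-TE data, with FA.

    The scheme must contain only shortest-echo-time measurements and at
    least six non-collinear directions plus a low-b reference (checked
    through the rank of the design matrix).  Eigenvalues are clamped at
    zero before FA so that FA lies in [0, 1].
    """
    signal = np.asarray(signal, dtype=float)
    te = scheme.echo_times
    if not np.allclose(te, te[0]):
        raise ValueError("tensor fit expects a first-TE-only scheme")
    if len(signal) != len(scheme):
        raise ValueError(f"signal length {len(signal)} != scheme length {len(scheme)}")
    b = scheme.b_values
    g = scheme.directions
    # unknowns: [log s0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError(
            "rank-deficient tensor design: need >= 6 non-collinear directions "
            "plus a low-b reference at the first TE"
        )
    if not np.any(signal > 0):
        return FitResult(None, float(np.linalg.norm(signal)), False, reason="no positive signal")
    logs = _positive_log(signal)
    w = np.clip(signal, 0.0, None)  # Gaussian noise on S -> weight log-fit by S
    wx = X * w[:, None]
    coef, *_ = np.linalg.lstsq(wx, logs * w, rcond=None)
    tensor = DiffusionTensor(
        dxx=coef[1], dyy=coef[2], dzz=coef[3],
        dxy=coef[4], dxz=coef[5], dyz=coef[6],
        s0=float(np.exp(np.clip(coef[0], -50, 50))),
    )
    lam = np.clip(tensor.eigenvalues(), 0.0, None)
    fa = fractional_anisotropy(lam)
    pred = X @ coef
    res = float(np.linalg.norm(pred - logs))
    return FitResult(tensor, res, True, 1, fa=fa)


_MODEL_PARAMS = {
    "t2adc": ("s0", "t2_star", "adc"),
    "t2ivim": ("s0", "f", "t2_star_fast", "t2_star_slow", "d_star", "adc"),
    "fa": ("s0", "fa"),
}


def fit_volume(
    data_4d: np.ndarray,
    mask: np.ndarray,
    scheme: AcquisitionScheme,
    model: Literal["t2adc", "t2ivim", "fa"],
    config: FitConfig | None = None,
) -> ParameterMaps:
    """Apply a voxel-wise fit to every masked voxel of a 4D volume.

    Non-converged voxels keep NaN parameters and are counted in
    ``summary``; the volume fit itself never aborts on a bad voxel.
    """
    config = config or FitConfig()
    data_4d = np.asarray(data_4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data_4d.ndim != 4:
        raise ValueError(f"expected 4D data, got {data_4d.ndim}D")
    if data_4d.shape[:3] != mask.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume {data_4d.shape[:3]}"
        )
    if data_4d.shape[3] != len(scheme):
        raise ValueError(
            f"4th dimension {data_4d.shape[3]} does not match scheme length {len(scheme)}"
        )
    if model not in _MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    if not mask.any():
        raise ValueError("mask is empty: nothing to fit")

    if model == "fa":
        first = scheme.echo_times == scheme.te_min
        scheme_fit = scheme.subset(first)
        data_fit = data_4d[..., first]
    else:
        scheme_fit, data_fit = scheme, data_4d

    names = _MODEL_PARAMS[model]
    maps = {n: np.full(mask.shape, np.nan) for n in names}
    conv = np.zeros(mask.shape, dtype=bool)
    n_fail = 0
    idx = np.argwhere(mask)
    for ijk in idx:
        sig = data_fit[tuple(ijk)]
        if model == "t2adc":
            res = fit_monoexp(sig, scheme_fit, config)
        elif model == "t2ivim":
            res = fit_ivim(sig, scheme_fit, config.strategy, config)
        else:
            res = fit_tensor_fa(sig, scheme_fit)
        vox = tuple(ijk)
        conv[vox] = res.converged
        if res.params is None:
            n_fail += 1
            continue
        if not res.converged:
            n_fail += 1
        if model == "fa":
            maps["s0"][vox] = res.params.s0
            maps["fa"][vox] = res.fa
        else:
            for n in names:
                maps[n][vox] = getattr(res.params, n)
    n_total = int(mask.sum())
    summary = {
        "model": model,
        "n_voxels": n_total,
        "n_non_converged": n_fail,
        "fraction_non_converged": n_fail / n_total,
        "strategy": config.strategy,
        "seed": config.seed,
    }
    return ParameterMaps(maps=maps, mask=mask, model=model, converged=conv, summary=summary)
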