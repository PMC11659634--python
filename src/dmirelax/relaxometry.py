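"""Relaxation-time fitting and summary statistics.

Three models are fitted by unweighted nonlinear least squares:

- inversion recovery, three parameters:  M(TI) = C1 (1 - C2 exp(-TI/T1))
- spin echo, two parameters:             M(TE) = C1 exp(-TE/T2)
- bi-exponential spin echo with a fixed CSF fraction:
      M(TE) = C1 (f_CSF exp(-TE/T2long) + (1 - f_CSF) exp(-TE/T2short))

IR data are treated as real *signed* values (negative below the null
point); magnitudes are never taken.  Parameter uncertainties are 1-SD
values from the linearized (Jacobian-based) covariance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import OptimizeWarning, curve_fit


def _quiet_curve_fit(*args, **kwargs):
    # noiseless saturated fits legitimately have no residual dof
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", OptimizeWarning)
        return curve_fit(*args, **kwargs)

__all__ = [
    "IRFit",
    "SEFit",
    "BiexpFit",
    "PairedTResult",
    "fit_ir",
    "fit_se",
    "fit_biexp",
    "percent_error",
    "cov_percent",
    "paired_t",
]

IR_T1_STARTS_MS = (50.0, 150.0, 350.0, 700.0)


@dataclass
class IRFit:
    c1: float
    c2: float
    t1_ms: float
    sd_c1: float
    sd_c2: float
    sd_t1_ms: float
    residual_rms: float

    @property
    def physical(self) -> bool:
        """True when the inversion factor is physically meaningful."""
        return 0.0 < self.c2 <= 2.0 + 1e-9

    @property
    def null_time_ms(self) -> float:
        """TI at which the model crosses zero: T1 ln(C2)."""
        return self.t1_ms * math.log(self.c2)


@dataclass
class SEFit:
    c1: float
    t2_ms: float
    sd_c1: float
    sd_t2_ms: float
    residual_rms: float


@dataclass
class BiexpFit:
    c1: float
    t2_long_ms: float
    t2_short_ms: float
    f_csf: float
    sd_c1: float
    sd_t2_long_ms: float
    sd_t2_short_ms: float
    residual_rms: float
    converged_long: bool


def _model_ir(ti, c1, c2, t1):
    return c1 * (1.0 - c2 * np.exp(-ti / t1))


def _model_se(te, c1, t2):
    return c1 * np.exp(-te / t2)


def _check_times(times_ms: np.ndarray, signals: np.ndarray, n_min: int) -> None:
    if times_ms.ndim != 1 or times_ms.shape != signals.shape:
        raise ValueError("times and signals must be 1D arrays of equal length")
    if len(times_ms) < n_min:
        raise ValueError(f"at least {n_min} points required")
    if np.any(np.diff(times_ms) <= 0):
        raise ValueError("times must be strictly increasing")


def _rms(r: np.ndarray) -> float:
    return float(np.sqrt(np.mean(r**2)))


def fit_ir(times_ms, signals) -> IRFit:
    """Three-parameter inversion-recovery fit with multi-start T1 grid.

    Starts are taken from a fixed T1 grid (50/150/350/700 ms) with
    C2 = 2 and C1 from the late-TI amplitude; the best-residual
    converged start wins.
    """
    t = np.asarray(times_ms, dtype=float)
    s = np.asarray(signals, dtype=float)
    _check_times(t, s, 4)
    c1_0 = max(abs(s[-1]), np.max(np.abs(s)) / 2.0, 1e-12)
    best = None
    errors = []
    for t1_0 in IR_T1_STARTS_MS:
        try:
            popt, pcov = _quiet_curve_fit(
                _model_ir, t, s, p0=(c1_0, 2.0, t1_0),
                bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:  # non-convergence
            errors.append(f"start T1={t1_0}: {exc}")
            continue
        ssr = float(np.sum((_model_ir(t, *popt) - s) ** 2))
        if best is None or ssr < best[2]:
            best = (popt, pcov, ssr)
    if best is None:
        raise RuntimeError(
            "IR fit did not converge from any start; " + "; ".join(errors)
        )
    popt, pcov, ssr = best
    resid = _model_ir(t, *popt) - s
    sd = _param_sd(pcov, resid, len(popt))
    return IRFit(
        c1=float(popt[0]), c2=float(popt[1]), t1_ms=float(popt[2]),
        sd_c1=sd[0], sd_c2=sd[1], sd_t1_ms=sd[2], residual_rms=_rms(resid),
    )


def _param_sd(pcov: np.ndarray, resid: np.ndarray, n_params: int) -> np.ndarray:
    # curve_fit already scales the covariance by the residual variance;
    # guard against the noiseless case where dof <= 0 or cov is inf
    with np.errstate(invalid="ignore"):
        sd = np.sqrt(np.diag(pcov))
    return np.where(np.isfinite(sd), sd, 0.0)


def fit_se(times_ms, signals) -> SEFit:
    """Two-parameter spin-echo fit; log-linear solution as the start."""
    t = np.asarray(times_ms, dtype=float)
    s = np.asarray(signals, dtype=float)
    _check_times(t, s, 2)
    if s[0] <= 0:
        raise ValueError("SE fit requires a positive reference amplitude")
    pos = s > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(s[pos]), 1)
        t2_0 = -1.0 / slope if slope < 0 else (t[-1] - t[0])
        c1_0 = math.exp(intercept)
    else:
        t2_0, c1_0 = (t[-1] - t[0]), s[0]
    popt, pcov = _quiet_curve_fit(
        _model_se, t, s, p0=(c1_0, max(t2_0, 1e-3)),
        bounds=([0.0, 1e-6], [np.inf, np.inf]), maxfev=20000,
    )
    resid = _model_se(t, *popt) - s
    sd = _param_sd(pcov, resid, 2)
    return SEFit(c1=float(popt[0]), t2_ms=float(popt[1]),
                 sd_c1=sd[0], sd_t2_ms=sd[1], residual_rms=_rms(resid))


def fit_biexp(times_ms, signals, f_csf: float) -> BiexpFit:
    """Bi-exponential T2 fit with the CSF fraction fixed from anatomy.

    Parameterized as (C1, T2short, delta) with
    T2long = T2short + delta, delta >= 0, so the long component can
    never fall below the short one.  ``converged_long`` is False when
    the relative uncertainty of T2long exceeds 100 % (or the fraction
    degenerates), mirroring the long component's frequent
    non-convergence at short maximum TE.
    """
    if not 0.0 <= f_csf <= 1.0:
        raise ValueError(f"f_csf must lie in [0, 1], got {f_csf}")
    t = np.asarray(times_ms, dtype=float)
    s = np.asarray(signals, dtype=float)
    _check_times(t, s, 4)

    if f_csf == 0.0:
        mono = fit_se(t, s)
        return BiexpFit(mono.c1, math.nan, mono.t2_ms, 0.0,
                        mono.sd_c1, math.nan, mono.sd_t2_ms,
                        mono.residual_rms, converged_long=False)
    if f_csf == 1.0:
        mono = fit_se(t, s)
        return BiexpFit(mono.c1, mono.t2_ms, math.nan, 1.0,
                        mono.sd_c1, mono.sd_t2_ms, math.nan,
                        mono.residual_rms, converged_long=True)

    def model(te, c1, t2_short, delta):
        t2_long = t2_short + delta
        return c1 * (f_csf * np.exp(-te / t2_long)
                     + (1.0 - f_csf) * np.exp(-te / t2_short))

    t_span = t[-1] - t[0]
    best = None
    for t2s_0 in (0.2 * t_span, 0.5 * t_span, t_span):
        for delta_0 in (t_span, 3 * t_span, 10 * t_span):
            try:
                popt, pcov = _quiet_curve_fit(
                    model, t, s, p0=(max(s[0], 1e-12), t2s_0, delta_0),
                    bounds=([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf]),
                    maxfev=40000,
                )
            except (RuntimeError, ValueError):
                continue
            ssr = float(np.sum((model(t, *popt) - s) ** 2))
            if best is None or ssr < best[2]:
                best = (popt, pcov, ssr)
    if best is None:
        raise RuntimeError("bi-exponential fit did not converge from any start")
    popt, pcov, _ = best
    c1, t2_short, delta = popt
    t2_long = t2_short + delta
    resid = model(t, *popt) - s
    sd = _param_sd(pcov, resid, 3)
    # var(T2long) = var(T2short) + var(delta) + 2 cov
    with np.errstate(invalid="ignore"):
        var_long = pcov[1, 1] + pcov[2, 2] + 2.0 * pcov[1, 2]
    sd_long = math.sqrt(var_long) if np.isfinite(var_long) and var_long > 0 else 0.0
    converged = bool(t2_long > 0 and sd_long <= abs(t2_long))
    return BiexpFit(
        c1=float(c1), t2_long_ms=float(t2_long), t2_short_ms=float(t2_short),
        f_csf=float(f_csf), sd_c1=sd[0], sd_t2_long_ms=sd_long,
        sd_t2_short_ms=sd[1], residual_rms=_rms(resid),
        converged_long=converged,
    )


def percent_error(fit_value: float, reference_value: float) -> float:
    """Absolute relative deviation in percent: 100 |fit - ref| / ref."""
    if reference_value == 0:
        raise ValueError("reference value must be nonzero")
    return 100.0 * abs(fit_value - reference_value) / abs(reference_value)


def cov_percent(series) -> float:
    """Coefficient of variation: 100 * sample SD / mean."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("COV requires at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("COV undefined for zero-mean series")
    return float(100.0 * x.std(ddof=1) / abs(mean))


@dataclass
class PairedTResult:
    t: float
    p: float
    n_pairs: int
    zero_variance: bool


def paired_t(a, b) -> PairedTResult:
    """Two-sided paired t-test on the differences a - b.

    Zero-variance differences make the statistic undefined; the result
    is then flagged and t/p are NaN rather than raising.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D arrays of equal length")
    if len(a) < 2:
        raise ValueError("at least 2 pairs required")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        return PairedTResult(math.nan, math.nan, len(a), zero_variance=True)
    res = stats.ttest_rel(a, b)
    return PairedTResult(float(res.statistic), float(res.pvalue), len(a),
                         zero_variance=False)
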