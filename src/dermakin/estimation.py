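"""Parameter estimation from permeation and plasma time series.

Covers the analysis stages of a transdermal study:

* conversion of sequential receptor-chamber concentrations to cumulative
  permeated amount per area, correcting for sample withdrawal/refill;
* nonlinear least-squares fits of the one-compartment skin model to
  infinite-dose (``R0``, ``kout``) and finite-dose (``kin``, ``kout``)
  cumulative or flux data, with asymptotic standard errors;
* the residual-dose shortcut for ``kin``;
* non-compartmental analysis (trapezoidal AUC with log-linear terminal
  extrapolation) and the apparent clearance ``dose/AUC``;
* a two-compartment IV-bolus disposition fit parameterised by
  (CL, V1, VT, CLic).

Standard errors are asymptotic: the residual-variance-scaled inverse of
the Gauss–Newton information matrix at the solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.optimize import least_squares

from .core_models import (
    InvalidParameterError,
    SkinTransportParams,
    finite_dose_profile,
)
from .pk_simulation import PKParams, iv_bolus_concentrations

__all__ = [
    "TimeSeries",
    "FitResult",
    "NCAResult",
    "receptor_concentrations_to_QR",
    "fit_infinite_dose",
    "fit_finite_dose",
    "kin_from_residual_fraction",
    "nca_auc",
    "apparent_clearance",
    "fit_iv_two_compartment",
]

KINDS = {
    "cumulative_per_area",  # µg/cm²
    "receptor_concentration",  # µg/mL
    "plasma_concentration",  # ng/mL
    "amount",  # µg
    "flux",  # µg/cm²/h
}


class InputError(ValueError):
    """Input data violate the declared structure (ordering, kind...)."""


@dataclass(frozen=True)
class TimeSeries:
    """A sampled measurement series with a declared kind.

    ``times`` must be strictly increasing and all values finite.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise InputError("times and values must be 1-D arrays of equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InputError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise InputError("values must be finite")
        if self.kind not in KINDS:
            raise InputError(f"unknown series kind {self.kind!r}; one of {sorted(KINDS)}")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class FitResult:
    """Outcome of a least-squares fit.

    ``standard_errors`` is empty when the fit did not converge or the
    information matrix was singular.  ``alternate`` holds the swapped
    (kin, kout) labelling for fits whose model is symmetric in the two
    rate constants (flip-flop ambiguity).
    """

    estimates: dict[str, float]
    standard_errors: dict[str, float] = field(default_factory=dict)
    residuals: np.ndarray | None = None
    objective: float = math.nan
    converged: bool = False
    n_obs: int = 0
    message: str = ""
    alternate: dict[str, float] | None = None


class NCAResult(NamedTuple):
    """Non-compartmental AUC with optional terminal extrapolation."""

    auc: float
    lambda_z: float | None
    extrapolated: bool


# ---------------------------------------------------------------------------
# receptor sampling correction

def receptor_concentrations_to_QR(
    series: TimeSeries,
    receptor_volume: float,
    sample_volume: float,
    area: float,
) -> TimeSeries:
    """Cumulative permeated amount per area from receptor concentrations.

    At each sampling time a volume ``sample_volume`` is withdrawn and
    replaced with fresh medium, so earlier samples remove drug that the
    cumulative amount must account for::

        Q_n = (C_n * V_R + sum_{i<n} C_i * V_s) / A
    """
    if series.kind != "receptor_concentration":
        raise InputError(f"expected receptor_concentration series, got {series.kind!r}")
    if not 0 <= sample_volume < receptor_volume:
        raise InputError("sample_volume must satisfy 0 <= V_s < receptor_volume")
    if not area > 0:
        raise InputError("area must be positive")
    c = series.values
    removed = np.concatenate([[0.0], np.cumsum(c[:-1] * sample_volume)])
    q = (c * receptor_volume + removed) / area
    return TimeSeries(
        times=series.times.copy(),
        values=q,
        kind="cumulative_per_area",
        replicate_id=series.replicate_id,
    )


def _pool(
    data: TimeSeries | Sequence[TimeSeries], kinds: set[str]
) -> tuple[np.ndarray, np.ndarray, str]:
    """Pool one or several replicate series into (t, y) observation arrays."""
    if isinstance(data, TimeSeries):
        data = [data]
    if not data:
        raise InputError("no data supplied")
    kind = data[0].kind
    if kind not in kinds:
        raise InputError(f"series kind {kind!r} not usable here; expected one of {kinds}")
    t_all, y_all = [], []
    for ts in data:
        if ts.kind != kind:
            raise InputError("all replicate series must share the same kind")
        t_all.append(ts.times)
        y_all.append(ts.values)
    return np.concatenate(t_all), np.concatenate(y_all), kind


def _weights(y: np.ndarray, weighting: str) -> np.ndarray:
    if weighting == "none":
        return np.ones_like(y)
    if weighting == "proportional":
        floor = 1e-3 * max(float(np.max(np.abs(y))), 1e-30)
        return 1.0 / np.maximum(np.abs(y), floor)
    raise InputError(f"unknown weighting {weighting!r}; use 'none' or 'proportional'")


def _finish_fit(res, names, t, y, w) -> FitResult:
    n, p = y.size, len(names)
    ssr = 2.0 * res.cost
    fit = FitResult(
        estimates=dict(zip(names, map(float, res.x))),
        residuals=res.fun / w,  # unweighted residuals
        objective=float(ssr),
        converged=bool(res.success),
        n_obs=int(n),
        message=res.message,
    )
    if res.success and n > p:
        jtj = res.jac.T @ res.jac
        # a (near-)singular information matrix means the parameters are
        # not identifiable from these data; report no standard errors
        if np.linalg.cond(jtj) < 1e12:
            cov = np.linalg.inv(jtj) * ssr / (n - p)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            fit.standard_errors = dict(zip(names, map(float, se)))
    return fit


def fit_infinite_dose(
    data: TimeSeries | Sequence[TimeSeries],
    fit_t0: bool = False,
    weighting: str = "none",
) -> FitResult:
    """Estimate ``R0`` and ``kout`` from infinite-dose cumulative data.

    Fits ``QR(t) = R0*(t-t0) - (R0/kout)*(1 - exp(-kout*(t-t0)))`` by
    least squares.  Starting values come from the pseudo-steady-state
    line through the last third of the observations, whose slope is
    ``R0`` and whose t-axis intercept is ``1/kout``.
    """
    t, y, _ = _pool(data, {"cumulative_per_area"})
    min_pts = 4 if fit_t0 else 3
    if np.unique(t).size < min_pts:
        raise InputError(f"need at least {min_pts} distinct time points")
    w = _weights(y, weighting)

    # pseudo-steady-state line through the last third of the points
    order = np.argsort(t)
    tail = order[-max(2, t.size // 3):]
    slope, intercept = np.polyfit(t[tail], y[tail], 1)
    r0_init = max(slope, 1e-12)
    lag = -intercept / r0_init if intercept < 0 else 0.1 * float(np.max(t))
    kout_init = 1.0 / max(lag, 1e-3 * float(np.max(t)))

    def model(theta, tt):
        r0, kout = theta[0], theta[1]
        t0 = theta[2] if fit_t0 else 0.0
        tau = np.maximum(tt - t0, 0.0)
        return r0 * tau - r0 / kout * -np.expm1(-kout * tau)

    theta0 = [r0_init, kout_init] + ([0.0] if fit_t0 else [])
    lower = [0.0, 1e-12] + ([0.0] if fit_t0 else [])
    res = least_squares(
        lambda th: (model(th, t) - y) * w,
        theta0,
        bounds=(lower, np.inf),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    names = ["R0", "kout"] + (["t0"] if fit_t0 else [])
    return _finish_fit(res, names, t, y, w)


def fit_finite_dose(
    data: TimeSeries | Sequence[TimeSeries],
    Q0: float,
    weighting: str = "none",
) -> FitResult:
    """Estimate ``kin`` and ``kout`` from finite-dose data.

    Accepts cumulative-per-area data (fit of the receptor amount
    ``QR(t)``) or flux data (fit of ``J(t)``).  Both model curves are
    symmetric under exchange of ``kin`` and ``kout``, so the labelling
    is ambiguous (flip-flop); the primary result uses the convention
    ``kin <= kout`` and the swapped labelling is reported in
    ``alternate``.  ``Q0`` is the applied dose per area, µg/cm².
    """
    if not Q0 > 0:
        raise InputError("Q0 must be positive")
    t, y, kind = _pool(data, {"cumulative_per_area", "flux"})
    if np.unique(t).size < 3:
        raise InputError("need at least 3 distinct time points")
    w = _weights(y, weighting)

    def model(theta, tt):
        sp = SkinTransportParams(kin=float(theta[0]), kout=float(theta[1]), Q0=Q0, S=1.0)
        prof = finite_dose_profile(sp, tt)
        return prof.QR if kind == "cumulative_per_area" else prof.J

    # kin heuristic from the apparent residual fraction at the last time
    if kind == "cumulative_per_area":
        frac = float(np.clip(1.0 - np.max(y) / Q0, 1e-6, 1 - 1e-6))
        kin_init = -math.log(frac) / float(np.max(t))
    else:
        kin_init = 1.0 / max(float(t[np.argmax(y)]), 1e-6)
    kout_init = 2.0 * kin_init

    res = least_squares(
        lambda th: (model(th, t) - y) * w,
        [kin_init, kout_init],
        bounds=([1e-12, 1e-12], [1e6, 1e6]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    fit = _finish_fit(res, ["kin", "kout"], t, y, w)
    # diverging rates (instantaneous transfer) leave the model flat in
    # both parameters: detected as an unidentifiable fit — either the
    # rates escaped toward the bound or the information matrix collapsed
    diverged = any(v > 0.99e6 for v in fit.estimates.values()) or (
        fit.converged and not fit.standard_errors
    )
    if diverged:
        fit.converged = False
        fit.standard_errors = {}
        fit.message = "rate constants not identifiable (instantaneous transfer)"
        return fit
    if fit.estimates["kin"] > fit.estimates["kout"]:
        fit.estimates = {"kin": fit.estimates["kout"], "kout": fit.estimates["kin"]}
        fit.standard_errors = {
            "kin": fit.standard_errors.get("kout", math.nan),
            "kout": fit.standard_errors.get("kin", math.nan),
        } if fit.standard_errors else {}
    fit.alternate = {"kin": fit.estimates["kout"], "kout": fit.estimates["kin"]}
    return fit


def kin_from_residual_fraction(fraction_remaining: float, t: float) -> float:
    """Input rate constant from the dose fraction left in the vehicle.

    Inverts the donor depletion ``QD(t)/Q0 = exp(-kin*t)``:
    ``kin = -ln(fraction)/t``.
    """
    if not 0 < fraction_remaining < 1:
        raise InvalidParameterError(
            f"fraction_remaining must lie in (0, 1), got {fraction_remaining}"
        )
    if not t > 0:
        raise InvalidParameterError(f"t must be positive, got {t}")
    return -math.log(fraction_remaining) / t


def nca_auc(
    conc: TimeSeries,
    extrapolate: bool = False,
    n_tail: int = 3,
) -> NCAResult:
    """Trapezoidal AUC of a plasma profile, optionally to infinity.

    The observed-range area uses the linear trapezoidal rule.  With
    ``extrapolate``, the terminal slope λz comes from a log-linear
    regression on the last ``n_tail`` points and the tail area
    ``C_last/λz`` is added.  Extrapolation is refused (flag stays
    False) when the tail contains non-positive concentrations or a
    non-decaying slope.
    """
    if conc.kind != "plasma_concentration":
        raise InputError(f"expected plasma_concentration series, got {conc.kind!r}")
    if len(conc) < 2:
        raise InputError("need at least 2 points for a trapezoid")
    auc = float(np.trapezoid(conc.values, conc.times))
    if not extrapolate:
        return NCAResult(auc=auc, lambda_z=None, extrapolated=False)
    if n_tail < 2:
        raise InputError("n_tail must be >= 2")
    if len(conc) < n_tail:
        raise InputError(f"need at least n_tail={n_tail} points to extrapolate")
    ct, cv = conc.times[-n_tail:], conc.values[-n_tail:]
    if np.any(cv <= 0):
        return NCAResult(auc=auc, lambda_z=None, extrapolated=False)
    slope = np.polyfit(ct, np.log(cv), 1)[0]
    lambda_z = -slope
    if lambda_z <= 0:
        return NCAResult(auc=auc, lambda_z=None, extrapolated=False)
    return NCAResult(
        auc=auc + float(cv[-1]) / lambda_z, lambda_z=float(lambda_z), extrapolated=True
    )


def apparent_clearance(dose: float, auc: float) -> float:
    """Apparent clearance (mL/h) from dose (µg) and AUC (ng·h/mL)."""
    if not dose > 0:
        raise InvalidParameterError(f"dose must be positive, got {dose}")
    if not auc > 0:
        raise InvalidParameterError(f"auc must be positive, got {auc}")
    return dose * 1000.0 / auc


def fit_iv_two_compartment(
    conc: TimeSeries | Sequence[TimeSeries],
    dose: float,
    weighting: str = "none",
) -> FitResult:
    """Fit a two-compartment IV-bolus model to plasma concentrations.

    Least squares on the bi-exponential solution, parameterised by the
    macro constants (CL, V1, VT, CLic) with ``VT = V1 + V2``.  Internally
    optimises (CL, V1, V2, CLic) so that ``VT > V1`` by construction;
    a ``CLic`` estimate pinned at its lower bound signals effectively
    one-compartment data.
    """
    if not dose > 0:
        raise InputError("dose must be positive")
    t, y, _ = _pool(conc, {"plasma_concentration"})
    if np.unique(t).size < 4:
        raise InputError("need at least 4 distinct time points")
    w = _weights(y, weighting)

    # heuristics: back-extrapolated C0 for V1, terminal slope for CL
    c0 = float(np.max(y))
    v1_init = dose * 1000.0 / max(c0, 1e-12)
    tail = slice(-min(3, t.size), None)
    lam = -np.polyfit(t[tail], np.log(np.maximum(y[tail], 1e-12)), 1)[0]
    cl_init = max(lam, 1e-3) * v1_init

    def model(theta, tt):
        cl, v1, v2, clic = theta
        pk = PKParams(CL=cl, V1=v1, VT=v1 + max(v2, 1e-9), CLic=max(clic, 1e-12))
        return iv_bolus_concentrations(pk, dose, tt)

    theta0 = [cl_init, v1_init, v1_init, cl_init]
    res = least_squares(
        lambda th: (model(th, t) - y) * w,
        theta0,
        bounds=([1e-9, 1e-9, 1e-9, 1e-9], np.inf),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=5000,
    )
    fit = _finish_fit(res, ["CL", "V1", "V2", "CLic"], t, y, w)
    v1, v2 = fit.estimates.pop("V1"), fit.estimates.pop("V2")
    fit.estimates = {
        "CL": fit.estimates["CL"],
        "V1": v1,
        "VT": v1 + v2,
        "CLic": fit.estimates["CLic"],
    }
    if fit.standard_errors:
        se = fit.standard_errors
        se_v1, se_v2 = se.pop("V1", math.nan), se.pop("V2", math.nan)
        # VT SE by error propagation ignoring V1–V2 covariance (reported
        # as a plain combination; exact covariance is available from the
        # residual jacobian if needed)
        fit.standard_errors = {
            "CL": se.get("CL", math.nan),
            "V1": se_v1,
            "VT": math.hypot(se_v1, se_v2),
            "CLic": se.get("CLic", math.nan),
        }
    if fit.estimates["CLic"] <= 1e-6:
        fit.message = (fit.message + "; CLic at lower bound: one-compartment data").strip("; ")
    return fit
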