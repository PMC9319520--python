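"""Closed-form models of permeant transport across a membrane (skin).

Two descriptions of a Franz-diffusion-cell experiment are implemented:

* the classical Fickian membrane-diffusion series solution for an
  infinite-dose (constant donor concentration) experiment, with its
  pseudo-steady-state simplification (steady-state flux ``Jss = Kp*CD``
  and lag time ``Tlag``), and
* a one-compartment description of the skin in which permeant enters the
  membrane at a constant rate ``R0`` (infinite dose) or by first-order
  kinetics ``kin`` (finite dose) and leaves it toward the receptor
  chamber by first-order kinetics ``kout``.

All quantities use the canonical internal units µg, mL, cm², h.
Per-area amounts are µg/cm² and fluxes µg/cm²/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "DiffusionParams",
    "SkinTransportParams",
    "SkinProfile",
    "SteadyStateMetrics",
    "fick_cumulative_infinite",
    "fick_flux_fraction",
    "infinite_dose_profile",
    "finite_dose_profile",
    "peak_flux",
    "time_to_flux_fraction",
    "steady_state_metrics",
]

#: relative eigenvalue separation below which the confluent (kin == kout)
#: limit replaces the two-exponential formulas
CONFLUENT_RTOL = 1e-8


class InvalidParameterError(ValueError):
    """A model parameter violates its physical constraints."""


@dataclass(frozen=True)
class DiffusionParams:
    """Fickian membrane parameters.

    Parameters
    ----------
    Kp : float
        Permeability coefficient, cm/h.
    CD : float
        Donor concentration, µg/mL.
    Tlag : float
        Lag time, h.
    K, D, h : float, optional
        Partition coefficient (dimensionless), diffusion coefficient
        (cm²/h) and membrane thickness (cm).  When all three are given
        they must be consistent with ``Kp = K*D/h`` and
        ``Tlag = h**2/(6*D)``.
    """

    Kp: float
    CD: float
    Tlag: float
    K: float | None = None
    D: float | None = None
    h: float | None = None

    def __post_init__(self) -> None:
        if not self.Kp > 0:
            raise InvalidParameterError(f"Kp must be positive, got {self.Kp}")
        if self.CD < 0:
            raise InvalidParameterError(f"CD must be non-negative, got {self.CD}")
        if not self.Tlag > 0:
            raise InvalidParameterError(f"Tlag must be positive, got {self.Tlag}")
        if self.K is not None and self.D is not None and self.h is not None:
            kp = self.K * self.D / self.h
            tlag = self.h**2 / (6.0 * self.D)
            if not math.isclose(kp, self.Kp, rel_tol=1e-9):
                raise InvalidParameterError(
                    f"K*D/h = {kp} inconsistent with Kp = {self.Kp}"
                )
            if not math.isclose(tlag, self.Tlag, rel_tol=1e-9):
                raise InvalidParameterError(
                    f"h**2/(6*D) = {tlag} inconsistent with Tlag = {self.Tlag}"
                )

    @property
    def Jss(self) -> float:
        """Steady-state flux ``Kp*CD``, µg/cm²/h."""
        return self.Kp * self.CD


@dataclass(frozen=True)
class SkinTransportParams:
    """One-compartment skin transport parameters.

    Exactly one input mechanism must be configured: a zero-order rate
    ``R0`` (infinite dose) or a first-order constant ``kin`` together
    with the applied dose ``Q0`` (finite dose).  ``kout`` is the
    first-order output constant shared by both regimens.
    """

    kout: float
    R0: float | None = None
    kin: float | None = None
    Q0: float | None = None
    CD: float | None = None
    S: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not self.kout > 0:
            raise InvalidParameterError(f"kout must be positive, got {self.kout}")
        infinite = self.R0 is not None
        finite = self.kin is not None or self.Q0 is not None
        if infinite and finite:
            raise InvalidParameterError("set either R0 or (kin, Q0), not both")
        if not infinite and not finite:
            raise InvalidParameterError("one of R0 or (kin, Q0) must be set")
        if infinite and self.R0 < 0:
            raise InvalidParameterError(f"R0 must be non-negative, got {self.R0}")
        if finite:
            if self.kin is None or self.Q0 is None:
                raise InvalidParameterError("finite dose requires both kin and Q0")
            if self.kin < 0 or self.Q0 < 0:
                raise InvalidParameterError("kin and Q0 must be non-negative")
        if not self.S > 0:
            raise InvalidParameterError(f"exposed area S must be positive, got {self.S}")
        if self.t0 < 0:
            raise InvalidParameterError(f"onset delay t0 must be non-negative, got {self.t0}")

    @property
    def regimen(self) -> str:
        return "infinite" if self.R0 is not None else "finite"


@dataclass(frozen=True)
class SkinProfile:
    """Time course of the one-compartment skin model (per-area units).

    ``QD`` is the amount remaining in the donor, ``QM`` the amount held
    in the membrane, ``QR`` the cumulative amount in the receptor, and
    ``J`` the instantaneous flux into the receptor.  ``QD`` is ``None``
    for the infinite-dose regimen, where the donor never depletes.
    """

    times: np.ndarray
    QM: np.ndarray
    QR: np.ndarray
    J: np.ndarray
    QD: np.ndarray | None = None


class SteadyStateMetrics(NamedTuple):
    """Permeability coefficient and predicted steady-state plasma level."""

    Kp: float
    Css_ug_per_mL: float | None
    Css_ng_per_mL: float | None


def _as_times(times: Sequence[float] | np.ndarray | float) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise InvalidParameterError("times must be non-negative")
    return t


def fick_cumulative_infinite(
    dp: DiffusionParams,
    t: Sequence[float] | np.ndarray | float,
    n_terms: int = 200,
) -> np.ndarray:
    """Cumulative receptor amount per area under Fickian diffusion.

    Evaluates the series solution of Fick's second law for a membrane
    held at constant donor concentration::

        QR(t) = Kp*CD*t - Kp*CD*Tlag
                - (12*Kp*CD*Tlag/pi^2) * sum_{n>=1} (-1)^n/n^2
                  * exp(-n^2 pi^2 t / (6 Tlag))

    The series is truncated at ``n_terms`` with early exit once a term
    falls below 1e-15 of the running sum.  At ``t = 0`` the series sums
    to ``-pi^2/12`` and cancels the lag term exactly; tiny negative
    truncation residue is clamped to zero.
    """
    if n_terms < 1:
        raise InvalidParameterError("n_terms must be >= 1")
    tt = _as_times(t)
    x = tt / dp.Tlag
    linear = dp.Kp * dp.CD * (tt - dp.Tlag)
    series = np.zeros_like(tt)
    active = np.ones_like(tt, dtype=bool)
    for n in range(1, n_terms + 1):
        term = ((-1.0) ** n / n**2) * np.exp(-(n**2) * math.pi**2 * x[active] / 6.0)
        series[active] += term
        still = np.abs(term) >= 1e-15 * np.maximum(np.abs(series[active]), 1e-300)
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
        if not active.any():
            break
    qr = linear - (12.0 * dp.Kp * dp.CD * dp.Tlag / math.pi**2) * series
    # at t = 0 the series sums to -pi^2/12 analytically; impose the exact
    # cancellation rather than carry the truncation residue
    qr = np.where(tt == 0.0, 0.0, qr)
    qr = np.where(qr < 0, 0.0, qr)  # truncation residue at small t
    return qr if np.ndim(t) else float(qr[0])


def fick_flux_fraction(
    t_over_tlag: float | np.ndarray, n_terms: int = 200
) -> float | np.ndarray:
    """Fraction of the steady-state flux attained at ``t / Tlag``.

    Obtained by differentiating the Fickian cumulative-amount series
    with respect to time::

        J(t)/Jss = 1 + 2 * sum_{n>=1} (-1)^n exp(-n^2 pi^2 (t/Tlag) / 6)

    The result is clipped to [0, 1]; at ``t = 0`` no flux has developed
    and the fraction is exactly zero.
    """
    if n_terms < 1:
        raise InvalidParameterError("n_terms must be >= 1")
    x = np.atleast_1d(np.asarray(t_over_tlag, dtype=float))
    if np.any(x < 0):
        raise InvalidParameterError("t_over_tlag must be non-negative")
    out = np.zeros_like(x)
    pos = x > 0
    if pos.any():
        n = np.arange(1, n_terms + 1)
        terms = ((-1.0) ** n)[None, :] * np.exp(
            -(n**2)[None, :] * math.pi**2 * x[pos, None] / 6.0
        )
        out[pos] = 1.0 + 2.0 * terms.sum(axis=1)
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(t_over_tlag) else float(out[0])


def infinite_dose_profile(
    sp: SkinTransportParams, times: Sequence[float] | np.ndarray
) -> SkinProfile:
    """One-compartment skin profile under constant-rate (infinite) dosing.

    With zero-order input ``R0`` and first-order output ``kout``::

        QM(t) = (R0/kout) * (1 - exp(-kout*(t - t0)))
        QR(t) = R0*(t - t0) - QM(t)
        J(t)  = kout * QM(t)

    so that ``QR + QM = R0*(t - t0)`` (mass balance) and the flux rises
    mono-exponentially to its plateau ``Jss = R0``.
    """
    if sp.regimen != "infinite":
        raise InvalidParameterError("infinite_dose_profile requires R0 to be set")
    t = _as_times(times)
    tau = np.maximum(t - sp.t0, 0.0)
    qm = sp.R0 / sp.kout * -np.expm1(-sp.kout * tau)
    qr = sp.R0 * tau - qm
    return SkinProfile(times=t, QM=qm, QR=qr, J=sp.kout * qm)


def _finite_qm_per_area(q0: float, kin: float, kout: float, tau: np.ndarray) -> np.ndarray:
    # confluent limit: QM = kin*Q0*t*exp(-kin*t) when the rates coincide
    if abs(kin - kout) < CONFLUENT_RTOL * kout:
        return q0 * kin * tau * np.exp(-kin * tau)
    return q0 * kin / (kin - kout) * (np.exp(-kout * tau) - np.exp(-kin * tau))


def finite_dose_profile(
    sp: SkinTransportParams, times: Sequence[float] | np.ndarray
) -> SkinProfile:
    """One-compartment skin profile under depleting (finite) dosing.

    Donor, membrane and receptor amounts per unit area follow::

        QD(t) = Q0 * exp(-kin*(t - t0))
        QM(t) = Q0 * kin/(kin - kout) * (exp(-kout*(t-t0)) - exp(-kin*(t-t0)))
        QR(t) = Q0 - QD(t) - QM(t)
        J(t)  = kout * QM(t)

    with ``Q0`` taken per area (``Q0/S``).  The analytic limit
    ``QM = kin*Q0*t*exp(-kin*t)`` replaces the general formula when
    ``kin`` and ``kout`` coincide to within :data:`CONFLUENT_RTOL`.
    """
    if sp.regimen != "finite":
        raise InvalidParameterError("finite_dose_profile requires kin and Q0 to be set")
    t = _as_times(times)
    tau = np.maximum(t - sp.t0, 0.0)
    q0 = sp.Q0 / sp.S
    qd = q0 * np.exp(-sp.kin * tau)
    qm = _finite_qm_per_area(q0, sp.kin, sp.kout, tau)
    qr = q0 - qd - qm
    return SkinProfile(times=t, QM=qm, QR=np.maximum(qr, 0.0), J=sp.kout * qm, QD=qd)


def peak_flux(sp: SkinTransportParams) -> tuple[float, float]:
    """Time and height of the finite-dose flux maximum.

    ``TJmax = ln(kout/kin) / (kout - kin)`` — symmetric under exchange
    of the two rate constants, with the confluent limit ``1/k`` when
    they coincide.  ``Jmax`` is the flux evaluated at that time.
    """
    if sp.regimen != "finite":
        raise InvalidParameterError("peak_flux applies to the finite-dose regimen")
    if not (sp.kin > 0 and sp.kout > 0):
        raise InvalidParameterError("both rate constants must be positive")
    if abs(sp.kin - sp.kout) < CONFLUENT_RTOL * sp.kout:
        t_jmax = 1.0 / sp.kout
    else:
        t_jmax = math.log(sp.kout / sp.kin) / (sp.kout - sp.kin)
    prof = finite_dose_profile(sp, [t_jmax + sp.t0])
    return t_jmax + sp.t0, float(prof.J[0])


def time_to_flux_fraction(fraction: float, kout: float) -> float:
    """Time for the infinite-dose flux to reach a fraction of its plateau.

    Inverts ``J(t) = R0*(1 - exp(-kout*t))``, giving
    ``t = -ln(1 - fraction)/kout``; for 97.5 % of the plateau the
    multiplier of ``1/kout`` is 3.689.
    """
    if not 0 <= fraction < 1:
        raise InvalidParameterError(f"fraction must lie in [0, 1), got {fraction}")
    if not kout > 0:
        raise InvalidParameterError(f"kout must be positive, got {kout}")
    return -math.log1p(-fraction) / kout


def steady_state_metrics(
    Jss: float,
    CD: float,
    S: float | None = None,
    CL: float | None = None,
) -> SteadyStateMetrics:
    """Permeability coefficient and steady-state plasma concentration.

    ``Kp = Jss/CD`` (cm/h).  When the exposed area ``S`` (cm²) and the
    plasma clearance ``CL`` (mL/h) are supplied, the steady-state plasma
    level ``Css = Jss*S/CL`` is also returned, in µg/mL and ng/mL.  The
    fitted zero-order input rate ``R0`` may stand in for ``Jss``.
    """
    if not CD > 0:
        raise InvalidParameterError(f"CD must be positive, got {CD}")
    kp = Jss / CD
    if S is None or CL is None:
        return SteadyStateMetrics(Kp=kp, Css_ug_per_mL=None, Css_ng_per_mL=None)
    if not S > 0 or not CL > 0:
        raise InvalidParameterError("S and CL must be positive")
    css = Jss * S / CL
    return SteadyStateMetrics(Kp=kp, Css_ug_per_mL=css, Css_ng_per_mL=1000.0 * css)
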