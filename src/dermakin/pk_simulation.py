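"""Coupled skin–plasma simulation of percutaneous dosing.

The skin stages reuse the finite-dose one-compartment transport model
(first-order entry ``kin`` from the applied vehicle into the skin,
first-order exit ``kout`` from the skin) and feed a standard
two-compartment disposition model (central volume ``V1``, peripheral
volume ``V2 = VT - V1``, clearance ``CL``, intercompartmental clearance
``CLic``).  Amounts are tracked in µg; plasma concentrations are
reported in ng/mL (``1000 * A_central / V1``).

The full system is linear, so two independent solution routes are
provided: a stiff-capable ODE integration and the analytic
sum-of-exponentials solution (eigenvalues ``-kin``, ``-kout``, ``-α``,
``-β`` plus the conserved total).  When eigenvalues nearly coincide the
analytic route switches to a matrix-exponential evaluation, which
handles the confluent case exactly without perturbing parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .core_models import InvalidParameterError, _finite_qm_per_area

__all__ = [
    "PKParams",
    "MicroConstants",
    "PlasmaProfile",
    "derive_micro_constants",
    "micro_to_macro",
    "disposition_eigenvalues",
    "iv_bolus_concentrations",
    "simulate_transdermal_pk",
    "simulate_first_order_absorption_pk",
    "skin_residual_fraction",
]


@dataclass(frozen=True)
class PKParams:
    """Two-compartment disposition parameters (macro form).

    CL : total plasma clearance, mL/h
    V1 : central compartment volume, mL
    VT : total distribution volume (``V1 + V2``), mL
    CLic : intercompartmental clearance, mL/h
    """

    CL: float
    V1: float
    VT: float
    CLic: float

    def __post_init__(self) -> None:
        for name in ("CL", "V1", "VT", "CLic"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be positive")
        if not self.VT > self.V1:
            raise InvalidParameterError(
                f"VT ({self.VT}) must exceed V1 ({self.V1})"
            )


@dataclass(frozen=True)
class MicroConstants:
    """Micro rate constants of the two-compartment model.

    k10 = CL/V1, k12 = CLic/V1, k21 = CLic/V2, V2 = VT - V1.
    """

    k10: float
    k12: float
    k21: float
    V2: float


@dataclass(frozen=True)
class PlasmaProfile:
    """Simulated amounts (µg) and plasma concentration (ng/mL)."""

    times: np.ndarray
    conc_ng_per_mL: np.ndarray
    A_vehicle: np.ndarray
    A_skin: np.ndarray
    A_central: np.ndarray
    A_peripheral: np.ndarray
    A_eliminated: np.ndarray
    dose: float


def derive_micro_constants(pk: PKParams) -> MicroConstants:
    """Convert macro parameters (CL, V1, VT, CLic) to micro constants."""
    v2 = pk.VT - pk.V1
    return MicroConstants(
        k10=pk.CL / pk.V1, k12=pk.CLic / pk.V1, k21=pk.CLic / v2, V2=v2
    )


def micro_to_macro(mc: MicroConstants, V1: float) -> PKParams:
    """Inverse of :func:`derive_micro_constants`, given the central volume."""
    return PKParams(CL=mc.k10 * V1, V1=V1, VT=V1 + mc.V2, CLic=mc.k12 * V1)


def disposition_eigenvalues(mc: MicroConstants) -> tuple[float, float]:
    """Hybrid disposition constants (α, β), the bi-exponential slopes."""
    s = mc.k10 + mc.k12 + mc.k21
    disc = np.sqrt(max(s * s - 4.0 * mc.k10 * mc.k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = (mc.k10 * mc.k21 / alpha) if alpha > 0 else 0.0
    return alpha, beta


def _system_matrix(
    mc: MicroConstants, kin: float, kout: float | None
) -> np.ndarray:
    """Build the linear system for [vehicle, skin, central, peripheral,
    eliminated].  ``kout=None`` routes the vehicle directly into the
    central compartment (first-order absorption, no skin stage)."""
    m = np.zeros((5, 5))
    m[0, 0] = -kin
    if kout is None:
        m[2, 0] = kin
    else:
        m[1, 0] = kin
        m[1, 1] = -kout
        m[2, 1] = kout
    m[2, 2] -= mc.k10 + mc.k12
    m[2, 3] = mc.k21
    m[3, 2] = mc.k12
    m[3, 3] = -mc.k21
    m[4, 2] = mc.k10
    return m


def _solve_closed_form(m: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Analytic solution x(t) = V exp(Λt) V⁻¹ x0 of the linear system.

    Falls back to per-time matrix exponentials when the eigenvector
    matrix is ill-conditioned (coincident rate constants)."""
    lam, vec = np.linalg.eig(m)
    cond = np.linalg.cond(vec)
    if np.isfinite(cond) and cond < 1e8 and np.all(np.abs(lam.imag) < 1e-12):
        coef = np.linalg.solve(vec, x0)
        sol = (vec.real @ (coef.real[:, None] * np.exp(np.outer(lam.real, times)))).T
    else:  # confluent branch: exact, no parameter perturbation
        sol = np.empty((times.size, x0.size))
        for i, t in enumerate(times):
            sol[i] = expm(m * t) @ x0
    return np.maximum(sol, 0.0)


def _solve_ode(m: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    t_end = float(times.max()) if times.size else 0.0
    res = solve_ivp(
        lambda _t, x: m @ x,
        (0.0, max(t_end, 1e-12)),
        x0,
        method="LSODA",
        t_eval=times,
        rtol=1e-9,
        atol=1e-12,
    )
    if not res.success:
        raise RuntimeError(f"ODE integration failed: {res.message}")
    return np.maximum(res.y.T, 0.0)


def _simulate(
    pk: PKParams,
    kin: float,
    kout: float | None,
    dose: float,
    times: Sequence[float] | np.ndarray,
    method: str,
) -> PlasmaProfile:
    if not kin > 0:
        raise InvalidParameterError("kin must be positive")
    if kout is not None and not kout > 0:
        raise InvalidParameterError("kout must be positive")
    if not dose > 0:
        raise InvalidParameterError("dose must be positive")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise InvalidParameterError("times must be non-negative")
    mc = derive_micro_constants(pk)
    m = _system_matrix(mc, kin, kout)
    x0 = np.array([dose, 0.0, 0.0, 0.0, 0.0])
    if method == "closed_form":
        sol = _solve_closed_form(m, x0, t)
    elif method == "ode":
        sol = _solve_ode(m, x0, t)
    else:
        raise ValueError(f"unknown method {method!r}; use 'ode' or 'closed_form'")
    return PlasmaProfile(
        times=t,
        conc_ng_per_mL=1000.0 * sol[:, 2] / pk.V1,
        A_vehicle=sol[:, 0],
        A_skin=sol[:, 1],
        A_central=sol[:, 2],
        A_peripheral=sol[:, 3],
        A_eliminated=sol[:, 4],
        dose=dose,
    )


def simulate_transdermal_pk(
    pk: PKParams,
    kin: float,
    kout: float,
    dose: float,
    times: Sequence[float] | np.ndarray,
    method: str = "closed_form",
) -> PlasmaProfile:
    """Three-compartment (skin + central + peripheral) simulation.

    The applied dose leaves the vehicle at rate ``kin``, transits the
    skin compartment, and enters the central circulation at rate
    ``kout * A_skin``.  Plasma concentration is ``1000*A_central/V1``
    in ng/mL.  ``method`` selects the ODE or the analytic route; the
    two agree to high precision and serve as mutual cross-checks.
    """
    return _simulate(pk, kin, kout, dose, times, method)


def simulate_first_order_absorption_pk(
    pk: PKParams,
    kin: float,
    dose: float,
    times: Sequence[float] | np.ndarray,
    method: str = "closed_form",
) -> PlasmaProfile:
    """Comparison model without the skin stage.

    A conventional two-compartment model with first-order absorption:
    the dose enters the central compartment directly at rate ``kin``.
    Used to show what the prediction loses when the skin's output
    constant ``kout`` is omitted.
    """
    return _simulate(pk, kin, None, dose, times, method)


def iv_bolus_concentrations(
    pk: PKParams, dose: float, times: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Bi-exponential plasma concentrations (ng/mL) after an IV bolus.

    ``C(t) = (dose/V1) * [(α-k21)/(α-β) e^{-αt} + (k21-β)/(α-β) e^{-βt}]``
    scaled to ng/mL, with a matrix-exponential fallback when α ≈ β.
    """
    t = np.atleast_1d(np.asarray(times, dtype=float))
    mc = derive_micro_constants(pk)
    alpha, beta = disposition_eigenvalues(mc)
    if alpha - beta > 1e-8 * alpha:
        a = (alpha - mc.k21) / (alpha - beta)
        b = (mc.k21 - beta) / (alpha - beta)
        c = dose / pk.V1 * (a * np.exp(-alpha * t) + b * np.exp(-beta * t))
    else:
        m = np.array(
            [
                [-(mc.k10 + mc.k12), mc.k21],
                [mc.k12, -mc.k21],
            ]
        )
        c = np.array([(expm(m * ti) @ [dose, 0.0])[0] for ti in t]) / pk.V1
    return 1000.0 * c


def skin_residual_fraction(kin: float, kout: float, t: float | np.ndarray) -> float | np.ndarray:
    """Fraction of the applied dose still held in the skin at time ``t``.

    Evaluates the finite-dose membrane amount ``QM(t)/Q0`` with the
    confluent fallback when ``kin`` equals ``kout``.
    """
    if not (kin > 0 and kout > 0):
        raise InvalidParameterError("rate constants must be positive")
    tau = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(tau < 0):
        raise InvalidParameterError("t must be non-negative")
    out = _finite_qm_per_area(1.0, kin, kout, tau)
    return out if np.ndim(t) else float(out[0])
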