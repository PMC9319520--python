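"""Synthetic Franz-cell and plasma datasets for testing the pipeline.

No raw permeation or plasma measurements from the nortriptyline study
are publicly tabulated, so every estimation and simulation stage is
exercised on synthetic data generated here with the statistical
structure the analysis assumes: the true curves come from the
one-compartment skin model (in vitro) or the coupled skin–plasma model
(in vivo), sampled on the study's schedules, with multiplicative
measurement noise.

The fixture bundles in :func:`nortriptyline_fixtures` carry the study's
published parameter values (fitted input rate 229 µg/cm²/h, output
constant 0.10 h⁻¹, donor concentration 50,000 µg/mL, two-compartment
disposition parameters, apparent clearance 3126 mL/h, 20 mg applied
dose) so the whole analysis can be replayed end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core_models import (
    InvalidParameterError,
    SkinTransportParams,
    finite_dose_profile,
    infinite_dose_profile,
)
from .estimation import InputError, TimeSeries, receptor_concentrations_to_QR
from .pk_simulation import PKParams, simulate_transdermal_pk

__all__ = [
    "NoiseModel",
    "ExperimentDesign",
    "FranzCellDataset",
    "PlasmaDataset",
    "InVitroFixture",
    "InVivoFixture",
    "IVFixture",
    "gen_franz_cell_series",
    "gen_plasma_series",
    "nortriptyline_fixtures",
]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-error model applied to generated observations.

    kind: one of none / additive / proportional / combined.
    ``sd_additive`` is in the measurement's own units and
    ``cv_proportional`` is a coefficient of variation.  A fixed seed
    yields bit-identical datasets.
    """

    kind: str = "proportional"
    sd_additive: float = 0.0
    cv_proportional: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"none", "additive", "proportional", "combined"}:
            raise InvalidParameterError(f"unknown noise kind {self.kind!r}")
        if self.sd_additive < 0 or self.cv_proportional < 0:
            raise InvalidParameterError("noise components must be non-negative")

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, int]:
        """Perturb ``values``; returns (noisy values, #truncated-at-zero)."""
        v = np.asarray(values, dtype=float)
        if self.kind == "none":
            return v.copy(), 0
        out = v.copy()
        if self.kind in ("proportional", "combined"):
            out = out * (1.0 + self.cv_proportional * rng.standard_normal(v.shape))
        if self.kind in ("additive", "combined"):
            out = out + self.sd_additive * rng.standard_normal(v.shape)
        truncated = int(np.sum(out < 0))
        return np.maximum(out, 0.0), truncated


@dataclass(frozen=True)
class ExperimentDesign:
    """Sampling design of a permeation or plasma experiment."""

    schedule: tuple[float, ...]
    n_replicates: int
    regimen: str = "infinite"  # infinite | finite
    receptor_volume: float = 9.0  # mL
    sample_volume: float = 0.2  # mL
    area: float = 1.45  # cm²
    refresh_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        sched = tuple(float(s) for s in self.schedule)
        object.__setattr__(self, "schedule", sched)
        object.__setattr__(self, "refresh_times", tuple(float(s) for s in self.refresh_times))
        if len(sched) > 1 and not all(b > a for a, b in zip(sched, sched[1:])):
            raise InvalidParameterError("schedule must be strictly increasing")
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")
        if self.regimen not in {"infinite", "finite"}:
            raise InvalidParameterError(f"unknown regimen {self.regimen!r}")


@dataclass
class FranzCellDataset:
    """Generated in vitro dataset: per-replicate receptor concentrations
    and the cumulative-per-area series derived from them."""

    concentrations: list[TimeSeries]
    cumulative: list[TimeSeries]
    truth: TimeSeries
    metadata: dict = field(default_factory=dict)


@dataclass
class PlasmaDataset:
    """Generated in vivo dataset: per-animal plasma concentrations."""

    series: list[TimeSeries]
    truth: TimeSeries
    metadata: dict = field(default_factory=dict)


def _replicate_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _true_concentrations(
    qr: np.ndarray, design: ExperimentDesign
) -> np.ndarray:
    """Receptor concentrations consistent with the withdrawal/refill
    protocol: the amount removed by earlier samples never re-enters.
    Inverse of :func:`~dermakin.estimation.receptor_concentrations_to_QR`."""
    c = np.empty_like(qr)
    removed = 0.0
    for i, q in enumerate(qr):
        c[i] = (q * design.area - removed) / design.receptor_volume
        removed += c[i] * design.sample_volume
    return c


def gen_franz_cell_series(
    sp: SkinTransportParams,
    design: ExperimentDesign,
    noise: NoiseModel,
) -> FranzCellDataset:
    """Simulate replicate Franz-cell runs.

    The true cumulative curve is evaluated on the design schedule from
    the skin transport model matching the declared regimen, converted
    forward through the sampling dilution to receptor concentrations,
    perturbed per replicate with the noise model, and converted back to
    cumulative-per-area exactly as an analyst would.
    """
    if sp.regimen != design.regimen:
        raise InputError(
            f"design regimen {design.regimen!r} does not match parameters ({sp.regimen})"
        )
    times = np.asarray(design.schedule, dtype=float)
    if design.regimen == "infinite":
        qr_true = infinite_dose_profile(sp, times).QR
    else:
        qr_true = finite_dose_profile(sp, times).QR
    c_true = _true_concentrations(qr_true, design)
    truth = TimeSeries(times=times, values=qr_true, kind="cumulative_per_area")

    concentrations: list[TimeSeries] = []
    cumulative: list[TimeSeries] = []
    n_truncated = 0
    for rep, rng in enumerate(_replicate_rngs(noise.seed, design.n_replicates)):
        noisy, trunc = noise.apply(c_true, rng)
        n_truncated += trunc
        conc = TimeSeries(
            times=times,
            values=noisy,
            kind="receptor_concentration",
            replicate_id=f"cell{rep + 1}",
        )
        concentrations.append(conc)
        cumulative.append(
            receptor_concentrations_to_QR(
                conc, design.receptor_volume, design.sample_volume, design.area
            )
        )
    meta = {
        "regimen": design.regimen,
        "noise": noise,
        "design": design,
        "n_truncated": n_truncated,
        # donor refresh keeps the infinite-dose assumption valid; the
        # constant-CD model is unaffected, recorded for provenance only
        "refresh_times": design.refresh_times,
    }
    return FranzCellDataset(
        concentrations=concentrations, cumulative=cumulative, truth=truth, metadata=meta
    )


def gen_plasma_series(
    pk: PKParams,
    kin: float,
    kout: float,
    dose: float,
    design: ExperimentDesign,
    noise: NoiseModel,
) -> PlasmaDataset:
    """Simulate replicate (per-animal) plasma concentration profiles.

    Truth comes from the three-compartment skin–plasma simulation
    sampled on the design schedule; each animal gets an independent
    noise stream derived from the model seed.
    """
    times = np.asarray(design.schedule, dtype=float)
    prof = simulate_transdermal_pk(pk, kin, kout, dose, times)
    truth = TimeSeries(times=times, values=prof.conc_ng_per_mL, kind="plasma_concentration")
    series: list[TimeSeries] = []
    n_truncated = 0
    for rep, rng in enumerate(_replicate_rngs(noise.seed, design.n_replicates)):
        noisy, trunc = noise.apply(truth.values, rng)
        n_truncated += trunc
        series.append(
            TimeSeries(
                times=times,
                values=noisy,
                kind="plasma_concentration",
                replicate_id=f"rat{rep + 1}",
            )
        )
    meta = {"noise": noise, "design": design, "dose": dose, "n_truncated": n_truncated}
    return PlasmaDataset(series=series, truth=truth, metadata=meta)


@dataclass(frozen=True)
class InVitroFixture:
    """Infinite-dose Franz-cell study conditions and fitted parameters."""

    params: SkinTransportParams
    design: ExperimentDesign
    noise: NoiseModel


@dataclass(frozen=True)
class InVivoFixture:
    """Percutaneous in vivo study conditions (rat)."""

    pk: PKParams
    kin: float
    kout: float
    dose: float
    residual_fraction_in_gel: float
    residual_time: float
    design: ExperimentDesign
    noise: NoiseModel


@dataclass(frozen=True)
class IVFixture:
    """Intravenous disposition study conditions (rat)."""

    pk: PKParams
    dose: float


def nortriptyline_fixtures(seed: int = 0) -> dict[str, object]:
    """Parameter bundles of the nortriptyline transdermal study.

    * ``in_vitro`` — infinite-dose rat-skin Franz-cell experiment:
      fitted input rate R0 = 229 µg/cm²/h and kout = 0.10 h⁻¹, donor
      concentration 50,000 µg/mL, 1.45 cm² exposed area, 9 mL receptor
      sampled 200 µL at {3, 5, 7, 9, 24, 26, 28, 30} h, n = 4 cells,
      donor gel refreshed at 9 h.
    * ``in_vivo`` — percutaneous rat experiment: kin = 0.065 h⁻¹
      (from 3 % of dose left in the gel at 54 h), the same kout,
      apparent clearance 3126 mL/h combined with the IV distribution
      parameters, 20,000 µg dose (0.4 mL of a 5 % m/m gel at density
      1 g/mL), 1.39 cm² area, sampling {8, ..., 54} h, n = 5 rats.
    * ``iv`` — IV bolus disposition study: CL = 1580 mL/h, V1 = 488 mL,
      VT = 1568 mL, CLic = 3340 mL/h, dose 0.5 mg.
    """
    iv_pk = PKParams(CL=1580.0, V1=488.0, VT=1568.0, CLic=3340.0)
    in_vitro = InVitroFixture(
        params=SkinTransportParams(R0=229.0, kout=0.10, CD=50000.0, S=1.45),
        design=ExperimentDesign(
            schedule=(3, 5, 7, 9, 24, 26, 28, 30),
            n_replicates=4,
            regimen="infinite",
            receptor_volume=9.0,
            sample_volume=0.2,
            area=1.45,
            refresh_times=(9.0,),
        ),
        noise=NoiseModel(kind="proportional", cv_proportional=0.05, seed=seed),
    )
    in_vivo = InVivoFixture(
        pk=PKParams(CL=3126.0, V1=488.0, VT=1568.0, CLic=3340.0),
        kin=0.065,
        kout=0.10,
        dose=20000.0,
        residual_fraction_in_gel=0.03,
        residual_time=54.0,
        design=ExperimentDesign(
            schedule=(8, 12, 24, 27, 30, 46, 48, 51, 54),
            n_replicates=5,
            regimen="finite",
            area=1.39,
        ),
        noise=NoiseModel(kind="proportional", cv_proportional=0.15, seed=seed + 1),
    )
    return {
        "in_vitro": in_vitro,
        "in_vivo": in_vivo,
        "iv": IVFixture(pk=iv_pk, dose=500.0),
    }
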