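"""MIRD-style internal dosimetry for ²¹²Pb radiopharmaceuticals.

Pipeline: organ %ID/g time series → time–activity curves (physical decay
re-applied) → time-integrated activity coefficients (TIAC, trapezoid over
observations plus a pure-physical-decay analytic tail) → optional projection
to a human phantom by the relative-concentration method → RBE-weighted
absorbed-dose coefficients

    D_o [Gy/GBq] = TIAC_o[s] · (RBE·E_α + E_e + φ·E_γ)[J per decay] / m_o[kg] · 1e9

→ dose tables at administered activities, the limiting organ, the activity
at which it reaches its dose limit, and safety margins.

Daughters are assumed to decay at the parent's location ("local
equilibrium"), RBE weights α emissions only, and the default photon absorbed
fraction is 0 (photons overwhelmingly escape organ-scale volumes while α and
electron energy is absorbed locally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    MappingError,
)
from .nuclide_chain import LN2, MEV_TO_J, EmissionSummary

__all__ = [
    "TimeActivityCurve",
    "Phantom",
    "DoseCoefficients",
    "DoseReport",
    "build_time_activity_curves",
    "compute_tiac",
    "aggregate_whole_body",
    "extrapolate_to_human",
    "absorbed_dose_coefficients",
    "rescale_rbe",
    "dose_table",
    "activity_limit",
    "safety_margin",
    "reference_dose_coefficients",
]

WHOLE_BODY = "whole_body"


@dataclass
class TimeActivityCurve:
    """Fraction of injected activity in one organ over time (decay included)."""

    organ: str
    times_h: np.ndarray
    activity_fraction: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.activity_fraction = np.asarray(self.activity_fraction, dtype=float)
        if self.times_h.ndim != 1 or self.times_h.shape != self.activity_fraction.shape:
            raise InvalidParameterError("times and fractions must be 1-D and equal length")
        if len(self.times_h) < 2:
            raise InsufficientDataError(f"{self.organ}: need >= 2 timepoints")
        if np.any(np.diff(self.times_h) <= 0):
            raise InvalidParameterError(f"{self.organ}: times must be strictly increasing")
        if np.any(self.activity_fraction < -1e-12) or np.any(self.activity_fraction > 1 + 1e-9):
            raise InvalidParameterError(f"{self.organ}: activity fractions must lie in [0, 1]")


@dataclass
class Phantom:
    """Organ and body masses (kg) with optional per-organ dose limits (Gy)."""

    species: str
    sex: str
    organ_masses_kg: dict[str, float]
    body_mass_kg: float
    dose_limits_gy: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0 or any(m <= 0 for m in self.organ_masses_kg.values()):
            raise InvalidParameterError("all masses must be positive")
        if sum(self.organ_masses_kg.values()) >= self.body_mass_kg:
            raise InvalidParameterError("organ masses must sum to less than body mass")

    @classmethod
    def from_dict(cls, name: str, d: Mapping) -> "Phantom":
        organs = d["organs"]
        return cls(
            species=d.get("species", name),
            sex=d.get("sex", "unspecified"),
            organ_masses_kg={o: float(v["mass_kg"]) for o, v in organs.items()},
            body_mass_kg=float(d["body_mass_kg"]),
            dose_limits_gy={
                o: float(v["dose_limit_Gy"]) for o, v in organs.items() if "dose_limit_Gy" in v
            },
        )

    @classmethod
    def from_yaml(cls, path, name: str | None = None) -> "Phantom":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if name is None:
            if len(data) != 1:
                raise MappingError("phantom file holds several phantoms; pass name=")
            name = next(iter(data))
        return cls.from_dict(name, data[name])

    @classmethod
    def bundled(cls, name: str) -> "Phantom":
        """One of mouse_male, mouse_female, human_male, human_female."""
        ref = resources.files("tapdose.data").joinpath("phantoms.yaml")
        data = yaml.safe_load(ref.read_text())
        if name not in data:
            raise MappingError(f"unknown bundled phantom {name!r}; have {sorted(data)}")
        return cls.from_dict(name, data[name])


@dataclass
class DoseCoefficients:
    """RBE-weighted absorbed dose per administered activity, per organ."""

    rbe: float
    coefficients_gy_per_gbq: dict[str, float]
    alpha_fraction: dict[str, float]
    photon_absorbed_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.rbe <= 0:
            raise InvalidParameterError("rbe must be positive")
        if any(c < 0 for c in self.coefficients_gy_per_gbq.values()):
            raise InvalidParameterError("dose coefficients must be >= 0")


@dataclass
class DoseReport:
    """Organ × administered-activity dose grid with limits and margins."""

    rbe: float
    administered_activities_gbq: list[float]
    doses_gy: pd.DataFrame  # index organ, one column per activity
    dose_limits_gy: dict[str, float]
    limiting_organ: str | None
    activity_limit_gbq: float
    safety_margins: pd.DataFrame  # limit / dose for organs with limits
    exceeded: pd.DataFrame  # bool grid


def build_time_activity_curves(
    summary: pd.DataFrame,
    organ_masses_g: Mapping[str, float],
    half_life_h: float,
    include_t0: bool = True,
    t0_fractions: Mapping[str, float] | None = None,
) -> dict[str, TimeActivityCurve]:
    """Turn a per-organ mean %ID/g summary into time–activity curves.

    ``summary`` needs columns organ, timepoint_h, mean_idg (as produced by
    :func:`tapdose.biodistribution.summarize_biodist`).  %ID/g values are
    decay-corrected to injection, so physical decay is re-applied here:

        A_o(t) = (%ID/g · m_o[g] / 100) · 2^(−t/T½)

    With ``include_t0`` a t = 0 anchor is prepended: 0 for tissues, or the
    value from ``t0_fractions`` (e.g. 1.0 for a whole-body/blood-pool curve).
    """
    lam = LN2 / half_life_h
    t0_fractions = dict(t0_fractions or {})
    out: dict[str, TimeActivityCurve] = {}
    for organ, rows in summary.groupby("organ"):
        if organ not in organ_masses_g:
            raise MappingError(f"no mass for organ {organ!r}")
        rows = rows.sort_values("timepoint_h")
        t = rows["timepoint_h"].to_numpy(dtype=float)
        frac = rows["mean_idg"].to_numpy(dtype=float) * organ_masses_g[organ] / 100.0
        frac = frac * np.exp(-lam * t)
        if include_t0 and t[0] > 0:
            t = np.concatenate([[0.0], t])
            frac = np.concatenate([[t0_fractions.get(organ, 0.0)], frac])
        out[organ] = TimeActivityCurve(organ=organ, times_h=t, activity_fraction=frac)
    return out


def compute_tiac(tac: TimeActivityCurve, half_life_h: float) -> float:
    """Time-integrated activity coefficient (hours per unit administered).

    Trapezoid over the observed points plus an analytic tail
    A(t_last)/λ assuming pure physical decay beyond the last observation.
    """
    if half_life_h <= 0:
        raise InvalidParameterError("half-life must be positive")
    lam = LN2 / half_life_h
    observed = float(np.trapezoid(tac.activity_fraction, tac.times_h))
    tail = float(tac.activity_fraction[-1]) / lam
    return observed + tail


def aggregate_whole_body(tacs: Mapping[str, TimeActivityCurve]) -> TimeActivityCurve:
    """Whole-body curve as the sum of organ activity fractions.

    Curves must share a common time grid.  Include a remainder/carcass organ
    in ``tacs`` if the measured organs do not account for the whole body.
    """
    curves = [c for name, c in tacs.items() if name != WHOLE_BODY]
    if not curves:
        raise InsufficientDataError("no organ curves to aggregate")
    t0 = curves[0].times_h
    for c in curves[1:]:
        if not np.allclose(c.times_h, t0):
            raise MappingError("organ curves must share a common time grid")
    total = np.sum([c.activity_fraction for c in curves], axis=0)
    total = np.minimum(total, 1.0 + 1e-9)
    return TimeActivityCurve(organ=WHOLE_BODY, times_h=t0, activity_fraction=total)


def extrapolate_to_human(
    mouse_tacs: Mapping[str, TimeActivityCurve],
    mouse_phantom: Phantom,
    human_phantom: Phantom,
    whole_body: TimeActivityCurve | None = None,
) -> dict[str, TimeActivityCurve]:
    """Project mouse organ curves onto a human phantom.

    Relative-concentration method: the organ-to-whole-body concentration
    ratio R(t) = (A_o/m_o)/(A_wb/M) measured in the mouse is assumed to hold
    in the human, and the human whole-body fraction curve is taken equal to
    the mouse one:

        A_o^human(t) = R(t) · (m_o^human / M^human) · A_wb(t)

    Organs absent from either phantom raise a mapping error.  The returned
    set includes the shared whole-body curve.
    """
    wb = whole_body if whole_body is not None else aggregate_whole_body(mouse_tacs)
    out: dict[str, TimeActivityCurve] = {}
    for organ, tac in mouse_tacs.items():
        if organ == WHOLE_BODY:
            continue
        if organ not in mouse_phantom.organ_masses_kg:
            raise MappingError(f"organ {organ!r} missing from mouse phantom")
        if organ not in human_phantom.organ_masses_kg:
            raise MappingError(f"organ {organ!r} missing from human phantom")
        if not np.allclose(tac.times_h, wb.times_h):
            raise MappingError("organ and whole-body curves must share time grids")
        m_mouse = mouse_phantom.organ_masses_kg[organ]
        m_human = human_phantom.organ_masses_kg[organ]
        conc_organ = tac.activity_fraction / m_mouse
        conc_wb = wb.activity_fraction / mouse_phantom.body_mass_kg
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(conc_wb > 0, conc_organ / conc_wb, 0.0)
        frac_human = ratio * (m_human / human_phantom.body_mass_kg) * wb.activity_fraction
        out[organ] = TimeActivityCurve(organ=organ, times_h=tac.times_h.copy(),
                                       activity_fraction=frac_human)
    out[WHOLE_BODY] = TimeActivityCurve(
        organ=WHOLE_BODY, times_h=wb.times_h.copy(), activity_fraction=wb.activity_fraction.copy()
    )
    return out


def absorbed_dose_coefficients(
    tiacs: Mapping[str, float],
    phantom: Phantom,
    emissions: EmissionSummary,
    rbe: float,
    photon_absorbed_fraction: float = 0.0,
) -> DoseCoefficients:
    """Gy per administered GBq for every organ with a TIAC and a mass."""
    if rbe <= 0 or photon_absorbed_fraction < 0:
        raise InvalidParameterError("rbe must be > 0 and φ >= 0")
    e_weighted_j = emissions.weighted_energy_mev(rbe, photon_absorbed_fraction) * MEV_TO_J
    alpha_frac = emissions.alpha_fraction(rbe, photon_absorbed_fraction)
    coeffs: dict[str, float] = {}
    fractions: dict[str, float] = {}
    for organ, tiac_h in tiacs.items():
        if organ == WHOLE_BODY:
            mass = phantom.body_mass_kg
        elif organ in phantom.organ_masses_kg:
            mass = phantom.organ_masses_kg[organ]
        else:
            raise MappingError(f"no phantom mass for organ {organ!r}")
        if tiac_h < 0:
            raise InvalidParameterError(f"negative TIAC for {organ!r}")
        decays_per_bq = tiac_h * 3600.0  # decays per administered Bq
        coeffs[organ] = decays_per_bq * e_weighted_j / mass * 1e9  # Gy per GBq
        fractions[organ] = alpha_frac
    return DoseCoefficients(
        rbe=rbe,
        coefficients_gy_per_gbq=coeffs,
        alpha_fraction=fractions,
        photon_absorbed_fraction=photon_absorbed_fraction,
    )


def rescale_rbe(
    coefficient_gy_per_gbq: float,
    from_rbe: float,
    to_rbe: float,
    emissions: EmissionSummary,
    photon_absorbed_fraction: float = 0.0,
) -> float:
    """Re-weight a dose coefficient from one α RBE to another.

    The TIAC and mass cancel; only the weighted energy term changes:
    coeff' = coeff · (RBE'·E_α + E_e + φ·E_γ)/(RBE·E_α + E_e + φ·E_γ).
    """
    num = emissions.weighted_energy_mev(to_rbe, photon_absorbed_fraction)
    den = emissions.weighted_energy_mev(from_rbe, photon_absorbed_fraction)
    return coefficient_gy_per_gbq * num / den


def dose_table(
    coeffs: DoseCoefficients,
    activities_gbq: list[float],
    limits_gy: Mapping[str, float] | None = None,
) -> DoseReport:
    """Organ doses at each administered activity, with limit flags and margins."""
    if any(a <= 0 for a in activities_gbq):
        raise InvalidParameterError("administered activities must be positive")
    limits = dict(limits_gy or {})
    organs = list(coeffs.coefficients_gy_per_gbq)
    doses = pd.DataFrame(
        {a: [coeffs.coefficients_gy_per_gbq[o] * a for o in organs] for a in activities_gbq},
        index=pd.Index(organs, name="organ"),
    )
    exceeded = pd.DataFrame(False, index=doses.index, columns=doses.columns)
    margins = pd.DataFrame(np.inf, index=doses.index, columns=doses.columns)
    for o in organs:
        if o in limits:
            exceeded.loc[o] = doses.loc[o] > limits[o]
            with np.errstate(divide="ignore"):
                margins.loc[o] = np.where(doses.loc[o] > 0, limits[o] / doses.loc[o], np.inf)
    limiting, a_limit = activity_limit(coeffs, limits) if limits else (None, math.inf)
    return DoseReport(
        rbe=coeffs.rbe,
        administered_activities_gbq=list(activities_gbq),
        doses_gy=doses,
        dose_limits_gy=limits,
        limiting_organ=limiting,
        activity_limit_gbq=a_limit,
        safety_margins=margins,
        exceeded=exceeded,
    )


def activity_limit(
    coeffs: DoseCoefficients, limits_gy: Mapping[str, float]
) -> tuple[str | None, float]:
    """Administered activity at which the first organ reaches its dose limit.

    Organs with zero coefficient have unbounded allowance; if every limited
    organ is unbounded the result is (None, inf).
    """
    if not limits_gy:
        raise InvalidParameterError("need at least one organ dose limit")
    best: tuple[str | None, float] = (None, math.inf)
    for organ, limit in limits_gy.items():
        c = coeffs.coefficients_gy_per_gbq.get(organ)
        if c is None:
            continue
        allowance = limit / c if c > 0 else math.inf
        if allowance < best[1]:
            best = (organ, allowance)
    return best


def safety_margin(
    coeffs: DoseCoefficients, organ: str, activity_gbq: float, limit_gy: float
) -> float:
    """Fold factor by which the organ dose at ``activity_gbq`` sits below its limit."""
    if activity_gbq <= 0:
        raise InvalidParameterError("activity must be positive")
    dose = coeffs.coefficients_gy_per_gbq[organ] * activity_gbq
    return math.inf if dose == 0 else limit_gy / dose


def reference_dose_coefficients(
    emissions: EmissionSummary | None = None,
    photon_absorbed_fraction: float = 0.0,
) -> tuple[DoseCoefficients, dict[str, float]]:
    """Bundled published RBE-5 dose coefficients for the GRPR-targeting ²¹²Pb peptide.

    Returns (coefficients in Gy/GBq derived from the reported doses at
    0.111 GBq, organ dose limits in Gy).  When an emission summary is given,
    per-organ α fractions reflect it; otherwise they are left at 1.
    """
    ref = resources.files("tapdose.data").joinpath("grpr1_reference_doses.csv")
    with ref.open("r") as fh:
        df = pd.read_csv(fh, comment="#")
    reference_activity_gbq = 0.111
    coeffs = {
        str(r["organ"]): float(r["dose_gy"]) / reference_activity_gbq for _, r in df.iterrows()
    }
    limits = {
        str(r["organ"]): float(r["dose_limit_gy"])
        for _, r in df.iterrows()
        if not pd.isna(r["dose_limit_gy"])
    }
    rbe = 5.0
    if emissions is not None:
        alpha = {o: emissions.alpha_fraction(rbe, photon_absorbed_fraction) for o in coeffs}
    else:
        alpha = {o: 1.0 for o in coeffs}
    return (
        DoseCoefficients(
            rbe=rbe,
            coefficients_gy_per_gbq=coeffs,
            alpha_fraction=alpha,
            photon_absorbed_fraction=photon_absorbed_fraction,
        ),
        limits,
    )
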