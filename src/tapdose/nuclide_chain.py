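"""Physics of the ²¹²Pb decay chain.

²¹²Pb (T½ = 10.64 h) decays by β⁻ to ²¹²Bi (60.55 min), which branches:
64.06 % β⁻ to ²¹²Po (0.299 µs, 8.785 MeV α) and 35.94 % α to ²⁰⁸Tl
(3.05 min, β⁻), both ending at stable ²⁰⁸Pb.  Every ²¹²Pb decay therefore
eventually yields exactly one α particle of ≈6–8.8 MeV plus β/conversion
electrons and photons; this is what makes the nuclide an in-vivo α-particle
generator for targeted alpha therapy.

This module provides:

* :func:`decay_factor` / :func:`decay_correct_counts` — exponential decay
  arithmetic used throughout counting workflows;
* :func:`bateman_activities` — the analytic Bateman solution for the chain,
  with branching and with effectively-prompt members (²¹²Po) decaying in
  step with their parent;
* :func:`chain_emission_summary` — mean α / electron / photon energy per
  parent decay under the equilibrium assumption, the energy term of all
  downstream dosimetry.

Nuclear data ship as a plain-text CSV (one row per decay mode) and can be
overridden by the caller; :func:`pb212_chain` loads the bundled table.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    IncompleteDataError,
    InvalidChainError,
    InvalidOrderError,
    InvalidParameterError,
)

__all__ = [
    "LN2",
    "MEV_TO_J",
    "PROMPT_HALF_LIFE_H",
    "Emission",
    "DecayMode",
    "Nuclide",
    "DecayChain",
    "EmissionSummary",
    "decay_factor",
    "decay_correct_counts",
    "bateman_activities",
    "chain_emission_summary",
    "load_chain_csv",
    "pb212_chain",
]

LN2 = math.log(2.0)

#: exact SI conversion, 1 MeV in joules
MEV_TO_J = 1.602176634e-13

SECONDS_PER_HOUR = 3600.0

#: nuclides with half-life below this (hours) are treated as decaying in step
#: with their parent; ²¹²Po (8.3e-11 h) is the only chain member affected
PROMPT_HALF_LIFE_H = 1e-6


@dataclass(frozen=True)
class Emission:
    """Mean emitted energy (MeV) per decay via one decay mode."""

    e_alpha: float = 0.0
    e_electron: float = 0.0
    e_photon: float = 0.0

    def __post_init__(self) -> None:
        if min(self.e_alpha, self.e_electron, self.e_photon) < 0:
            raise InvalidParameterError("emission energies must be >= 0")


@dataclass(frozen=True)
class DecayMode:
    """One decay branch: daughter (or terminal), branching fraction, emissions."""

    daughter: str | None
    branching: float
    emission: Emission | None = None


@dataclass(frozen=True)
class Nuclide:
    name: str
    half_life_h: float
    modes: tuple[DecayMode, ...] = ()

    def __post_init__(self) -> None:
        if not self.half_life_h > 0:
            raise InvalidParameterError(
                f"half-life of {self.name} must be positive, got {self.half_life_h}"
            )
        if self.modes:
            total = sum(m.branching for m in self.modes)
            if abs(total - 1.0) > 1e-9:
                raise InvalidChainError(
                    f"branching fractions of {self.name} sum to {total}, expected 1"
                )

    @property
    def decay_constant(self) -> float:
        """λ in 1/h."""
        return LN2 / self.half_life_h

    @property
    def is_prompt(self) -> bool:
        return self.half_life_h < PROMPT_HALF_LIFE_H


@dataclass(frozen=True)
class EmissionSummary:
    """Mean energy (MeV) emitted per decay of the chain head, at equilibrium."""

    e_alpha: float
    e_electron: float
    e_photon: float

    def weighted_energy_mev(self, rbe: float, photon_absorbed_fraction: float = 0.0) -> float:
        """RBE-weighted energy term rbe·E_α + E_e + φ·E_γ in MeV per decay."""
        if rbe <= 0 or photon_absorbed_fraction < 0:
            raise InvalidParameterError("rbe must be > 0 and φ >= 0")
        return rbe * self.e_alpha + self.e_electron + photon_absorbed_fraction * self.e_photon

    def alpha_fraction(self, rbe: float, photon_absorbed_fraction: float = 0.0) -> float:
        """Fraction of the weighted energy carried by α emissions."""
        total = self.weighted_energy_mev(rbe, photon_absorbed_fraction)
        return rbe * self.e_alpha / total if total > 0 else 0.0


class DecayChain:
    """Ordered, acyclic decay chain starting at its head nuclide.

    Daughters must appear after their parent; a daughter name not present in
    the chain is treated as terminal/stable and is not tracked.
    """

    def __init__(self, nuclides: list[Nuclide], source: str = ""):
        names = [n.name for n in nuclides]
        if len(set(names)) != len(names):
            raise InvalidChainError(f"duplicate nuclide names in chain: {names}")
        index = {name: i for i, name in enumerate(names)}
        for nuc in nuclides:
            for mode in nuc.modes:
                if mode.daughter is not None and mode.daughter in index:
                    if index[mode.daughter] <= index[nuc.name]:
                        raise InvalidChainError(
                            f"{nuc.name} -> {mode.daughter} violates chain ordering"
                        )
        self.nuclides: tuple[Nuclide, ...] = tuple(nuclides)
        self.source = source
        self._index = index

    def __iter__(self):
        return iter(self.nuclides)

    def __len__(self) -> int:
        return len(self.nuclides)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __getitem__(self, name: str) -> Nuclide:
        return self.nuclides[self._index[name]]

    @property
    def head(self) -> Nuclide:
        return self.nuclides[0]

    def decays_per_head_decay(self) -> dict[str, float]:
        """Expected number of decays of each member per decay of the head."""
        n: dict[str, float] = defaultdict(float)
        n[self.head.name] = 1.0
        for nuc in self.nuclides:
            for mode in nuc.modes:
                if mode.daughter is not None and mode.daughter in self._index:
                    n[mode.daughter] += n[nuc.name] * mode.branching
        return dict(n)


def decay_factor(half_life_h: float, elapsed_h: float) -> float:
    """Surviving fraction exp(−ln2 · elapsed/half_life), in (0, 1]."""
    if not half_life_h > 0:
        raise InvalidParameterError(f"half-life must be positive, got {half_life_h}")
    if elapsed_h < 0:
        raise InvalidParameterError(f"elapsed time must be >= 0, got {elapsed_h}")
    return math.exp(-LN2 * elapsed_h / half_life_h)


def _hours_between(later, earlier) -> float:
    """Difference in hours between two timestamps (numbers in hours, or datetimes)."""
    delta = later - earlier
    if hasattr(delta, "total_seconds"):
        return delta.total_seconds() / SECONDS_PER_HOUR
    return float(delta)


def decay_correct_counts(raw_counts: float, count_time, reference_time, half_life_h: float) -> float:
    """Back-correct counts measured at ``count_time`` to ``reference_time``.

    Times may be numbers (hours) or datetime-likes; counting must not precede
    the reference.
    """
    elapsed = _hours_between(count_time, reference_time)
    if elapsed < 0:
        raise InvalidOrderError("count_time precedes reference_time")
    return raw_counts / decay_factor(half_life_h, elapsed)


def bateman_activities(
    chain: DecayChain,
    initial_activity: Mapping[str, float],
    t,
) -> dict[str, np.ndarray | float]:
    """Activities of every chain member at time(s) ``t`` (hours).

    Analytic Bateman solution as a sum of exponentials, propagated down the
    chain with branching.  Members with half-life below
    :data:`PROMPT_HALF_LIFE_H` carry no inventory of their own: their
    activity equals their instantaneous production rate (e.g. ²¹²Po decays
    in step with ²¹²Bi at the 64.06 % branching fraction).

    Parameters
    ----------
    initial_activity
        Activity (any consistent unit) of each nuclide at t = 0; omitted
        nuclides start at zero.
    t
        Scalar or array of times ≥ 0 in hours.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    if np.any(t_arr < 0):
        raise InvalidParameterError("t must be >= 0")
    for name, a0 in initial_activity.items():
        if name not in chain:
            raise InvalidChainError(f"initial activity given for unknown nuclide {name!r}")
        if a0 < 0:
            raise InvalidParameterError(f"initial activity of {name} must be >= 0")
        if chain[name].is_prompt and a0 > 0:
            raise InvalidParameterError(
                f"{name} is treated as prompt; it cannot hold initial activity"
            )

    # Per nuclide, its activity A(t) = sum(c * exp(-lam * t)) as {lam: c}.
    activity_terms: dict[str, dict[float, float]] = {}
    # Production-rate terms feeding each nuclide, same representation.
    feed: dict[str, dict[float, float]] = defaultdict(lambda: defaultdict(float))

    for nuc in chain:
        if nuc.is_prompt:
            terms = dict(feed[nuc.name])  # activity mirrors production
        else:
            lam = nuc.decay_constant
            n0 = initial_activity.get(nuc.name, 0.0) / lam
            particular: dict[float, float] = defaultdict(float)
            for mu, p in feed[nuc.name].items():
                if abs(lam - mu) <= 1e-12 * max(lam, mu):
                    raise InvalidChainError(
                        f"degenerate decay constants for {nuc.name}; Bateman solution undefined"
                    )
                particular[mu] += p / (lam - mu)
            c_self = n0 - sum(particular.values())
            atom_terms = dict(particular)
            atom_terms[lam] = atom_terms.get(lam, 0.0) + c_self
            terms = {mu: lam * c for mu, c in atom_terms.items()}
        activity_terms[nuc.name] = terms
        for mode in nuc.modes:
            if mode.daughter is not None and mode.daughter in chain:
                for mu, c in terms.items():
                    feed[mode.daughter][mu] += mode.branching * c

    out: dict[str, np.ndarray | float] = {}
    for name, terms in activity_terms.items():
        a = np.zeros_like(t_arr, dtype=float)
        for mu, c in terms.items():
            a = a + c * np.exp(-mu * t_arr)
        a = np.where(np.abs(a) < 1e-15, 0.0, a)  # clip solver-scale negatives
        out[name] = float(a) if scalar else a
    return out


def chain_emission_summary(chain: DecayChain, assume_equilibrium: bool = True) -> EmissionSummary:
    """Mean α / electron / photon energy (MeV) per decay of the chain head.

    Under the equilibrium assumption each head decay is followed by the full
    cascade of daughter decays weighted by branching; with
    ``assume_equilibrium=False`` only the head's own emissions are counted.
    """
    weights = chain.decays_per_head_decay() if assume_equilibrium else {chain.head.name: 1.0}
    e_alpha = e_electron = e_photon = 0.0
    for nuc in chain:
        w = weights.get(nuc.name, 0.0)
        if w == 0.0:
            continue
        for mode in nuc.modes:
            if mode.emission is None:
                raise IncompleteDataError(
                    f"decay mode {nuc.name} -> {mode.daughter} has no emission record"
                )
            e_alpha += w * mode.branching * mode.emission.e_alpha
            e_electron += w * mode.branching * mode.emission.e_electron
            e_photon += w * mode.branching * mode.emission.e_photon
    return EmissionSummary(e_alpha=e_alpha, e_electron=e_electron, e_photon=e_photon)


def load_chain_csv(path_or_buffer, source: str | None = None) -> DecayChain:
    """Load a decay chain from a per-mode CSV table.

    Columns: nuclide, half_life_s, mode, daughter, branching, e_alpha_MeV,
    e_electron_MeV, e_photon_MeV.  Rows sharing a nuclide are its branches;
    first appearance fixes chain order.  Lines starting with '#' are comments.
    """
    df = pd.read_csv(path_or_buffer, comment="#")
    required = {
        "nuclide", "half_life_s", "daughter", "branching",
        "e_alpha_MeV", "e_electron_MeV", "e_photon_MeV",
    }
    missing = required - set(df.columns)
    if missing:
        raise IncompleteDataError(f"chain table missing columns: {sorted(missing)}")
    nuclides: list[Nuclide] = []
    for name in df["nuclide"].drop_duplicates():
        rows = df[df["nuclide"] == name]
        half_life_h = float(rows["half_life_s"].iloc[0]) / SECONDS_PER_HOUR
        modes = tuple(
            DecayMode(
                daughter=None if pd.isna(r["daughter"]) else str(r["daughter"]),
                branching=float(r["branching"]),
                emission=Emission(
                    e_alpha=float(r["e_alpha_MeV"]),
                    e_electron=float(r["e_electron_MeV"]),
                    e_photon=float(r["e_photon_MeV"]),
                ),
            )
            for _, r in rows.iterrows()
        )
        nuclides.append(Nuclide(name=str(name), half_life_h=half_life_h, modes=modes))
    return DecayChain(nuclides, source=source or "user CSV")


def pb212_chain() -> DecayChain:
    """The bundled ²¹²Pb chain (NNDC half-lives, ICRP-107-style mean energies)."""
    ref = resources.files("tapdose.data").joinpath("pb212_chain.csv")
    with ref.open("r") as fh:
        return load_chain_csv(fh, source="tapdose bundled pb212_chain.csv (NNDC/ICRP-107 derived)")
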