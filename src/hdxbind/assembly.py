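"""Oligomeric-composition inference from measured masses, plus coiled-coil
register and rod-length helpers.

Stoichiometry is an exhaustive enumeration over integer copy numbers under
explicit constraints (e.g. an obligate homodimer contributes in multiples of
two). Constraints are always user input: mass alone can rank a wrong
composition first, which is exactly why the prior matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

from .errors import DomainError, NoDataError

#: default upper bound on copies of any one component
DEFAULT_MAX_COPIES = 4
#: default relative mass tolerance; generous enough to accept real SEC-MALS
#: deviations of ~9% while rejecting unrelated compositions. Our choice.
DEFAULT_TOLERANCE = 0.10


@dataclass(frozen=True)
class StoichConstraint:
    """Copy-number constraint for one component."""

    multiple: int = 1  # copies must be a multiple of this (obligate dimer: 2)
    max_copies: int = DEFAULT_MAX_COPIES

    def __post_init__(self):
        if self.multiple < 1:
            raise DomainError("multiple must be >= 1")
        if self.max_copies < self.multiple:
            raise DomainError("max_copies must be >= multiple")


@dataclass
class StoichiometrySolution:
    composition: dict[str, int]
    theoretical_mass: float  # kDa
    deviation: float  # |theoretical - measured| / measured
    rank: int

    @property
    def total_copies(self) -> int:
        return sum(self.composition.values())


@dataclass
class StoichiometryResult:
    solutions: list[StoichiometrySolution]  # within tolerance, ranked
    best_out_of_tolerance: StoichiometrySolution | None = None

    @property
    def best(self) -> StoichiometrySolution | None:
        return self.solutions[0] if self.solutions else None


def composition_mass(
    composition: Mapping[str, int], monomer_masses: Mapping[str, float]
) -> float:
    """Theoretical mass (kDa) of an integer composition."""
    return sum(monomer_masses[name] * n for name, n in composition.items())


def infer_stoichiometry(
    measured_mass: float,
    monomer_masses: Mapping[str, float],
    constraints: Mapping[str, StoichConstraint] | None = None,
    tolerance: float = DEFAULT_TOLERANCE,
    max_copies: int = DEFAULT_MAX_COPIES,
) -> StoichiometryResult:
    """Enumerate every constraint-satisfying composition and rank by fit.

    Ranking: relative deviation, then fewer total copies, then lexicographic
    component order. Solutions within ``tolerance`` are returned; when none
    qualifies, the best out-of-tolerance candidate is attached instead.
    """
    if not measured_mass > 0:
        raise DomainError("measured mass must be positive")
    if not monomer_masses:
        raise NoDataError("need at least one component")
    if not 0 < tolerance <= 0.5:
        raise DomainError("tolerance must be in (0, 0.5]")
    constraints = constraints or {}
    names = sorted(monomer_masses)
    ranges = []
    for name in names:
        con = constraints.get(name, StoichConstraint(max_copies=max_copies))
        ranges.append(range(0, con.max_copies + 1, con.multiple))

    candidates = []
    for copies in product(*ranges):
        if not any(copies):
            continue
        comp = dict(zip(names, copies))
        mass = composition_mass(comp, monomer_masses)
        deviation = abs(mass - measured_mass) / measured_mass
        candidates.append((deviation, sum(copies), copies, comp, mass))
    if not candidates:
        raise NoDataError("constraints admit no non-empty composition")
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))

    solutions = [
        StoichiometrySolution(comp, mass, dev, rank)
        for rank, (dev, _, _, comp, mass) in enumerate(candidates, start=1)
        if dev <= tolerance
    ]
    best_oot = None
    if not solutions:
        dev, _, _, comp, mass = candidates[0]
        best_oot = StoichiometrySolution(comp, mass, dev, 1)
    return StoichiometryResult(solutions, best_oot)


_HEPTAD = "abcdefg"


def heptad_register(
    anchor_residue: int, anchor_letter: str, query_residue: int
) -> str:
    """Heptad letter of ``query_residue`` given an anchored register.

    The a-g alphabet is cyclic with period 7, so the letter is the anchor's
    letter advanced by (query - anchor) mod 7.
    """
    if anchor_letter not in _HEPTAD:
        raise DomainError(f"heptad letter must be one of {_HEPTAD!r}")
    if anchor_residue < 1 or query_residue < 1:
        raise DomainError("residue indices are 1-based and positive")
    offset = (query_residue - anchor_residue) % 7
    return _HEPTAD[(_HEPTAD.index(anchor_letter) + offset) % 7]


@dataclass(frozen=True)
class RodExtension:
    extension_nm: float
    negative: bool  # flagged when the complex is shorter than the reference


def rod_extension(
    complex_mean_length: float, reference_mean_length: float
) -> RodExtension:
    """Length added to a coiled-coil rod by a bound partner, nm."""
    if not (complex_mean_length > 0 and reference_mean_length > 0):
        raise DomainError("lengths must be positive")
    diff = complex_mean_length - reference_mean_length
    return RodExtension(diff, negative=diff < 0)
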