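"""Forward simulators for every input the analysis chain consumes.

Three generators with seeded randomness and exported ground truth:

* peptide-level HDX centroid tables with state-dependent per-residue
  protection factors,
* FCS titrations (diffusion time vs titrant concentration) from the exact
  single-site depletion model,
* ITC injection-heat series from the one-site isotherm with
  volume-displacement dilution.

The HDX forward model is first-order exchange per observable amide: the
expected deuterium content of residue *i* after exposure *t* is
``d2o_fraction * (1 - exp(-k_int * t / P_i))`` with protection factor
``P_i >= 1`` (``inf`` = never exchanges). A peptide's centroid mass is its
undeuterated average mass plus the deuterium mass shift times the summed
expected content of its observable amides, plus Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import DEUTERIUM_MASS_SHIFT, OUT_EXCHANGE_EXPOSURE, PROTON_MASS
from .errors import InvalidDesignError
from .peptides import (
    COLUMNS,
    ExchangeDataset,
    average_mass,
    exchangeable_positions,
    validate_sequence,
)

# ---------------------------------------------------------------------------
# designs


@dataclass
class GroundTruthProtein:
    """A protein with known per-residue protection factors per state."""

    name: str
    sequence: str
    intrinsic_rate: float = 1.0  # per minute, single rate for all amides
    protection: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = validate_sequence(self.sequence)
        if not self.intrinsic_rate > 0:
            raise InvalidDesignError("intrinsic_rate must be positive")
        for state, vec in list(self.protection.items()):
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (len(self.sequence),):
                raise InvalidDesignError(
                    f"protection vector for {state!r} has length {vec.size}, "
                    f"sequence has {len(self.sequence)}"
                )
            if np.any(vec < 1):
                raise InvalidDesignError("protection factors must be >= 1")
            self.protection[state] = vec

    @property
    def length(self) -> int:
        return len(self.sequence)


def protection_profile(
    length: int,
    windows: Sequence[tuple[int, int, float]] = (),
    baseline: float = 1.0,
) -> np.ndarray:
    """Build a per-residue protection vector from (start, end, P) windows.

    Coordinates are 1-based inclusive; later windows override earlier ones.
    """
    vec = np.full(length, float(baseline))
    for start, end, p in windows:
        if not (1 <= start <= end <= length):
            raise InvalidDesignError(f"window {start}-{end} outside 1..{length}")
        vec[start - 1 : end] = p
    return vec


@dataclass(frozen=True)
class PeptideDesign:
    """How to generate a peptide map: seeded random digestion or tiling."""

    mode: str = "random"  # "random" | "tiling"
    n_peptides: int = 100
    min_length: int = 6
    max_length: int = 18
    tile_length: int = 10
    tile_offset: int = 5

    def __post_init__(self):
        if self.mode not in ("random", "tiling"):
            raise InvalidDesignError(f"unknown peptide map mode {self.mode!r}")
        if self.min_length < 4 or self.max_length < self.min_length:
            raise InvalidDesignError("peptide lengths must satisfy 4 <= min <= max")


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic HDX experiment."""

    timepoints: tuple[float, ...] = (10.0, 60.0, 300.0, 1800.0, 9000.0)
    replicates_per_state: int = 3
    d2o_fraction: float = 0.9
    noise_sd: float = 0.05  # Da on peptide centroid mass
    seed: int = 0
    peptide_design: PeptideDesign = PeptideDesign()
    charges: tuple[int, ...] = (2,)
    fast_loss: int = 1
    out_exchange_time_s: float = 86400.0  # 24 h control incubation

    def __post_init__(self):
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0 or np.any(tp <= 0) or np.any(np.diff(tp) <= 0):
            raise InvalidDesignError("timepoints must be positive, strictly increasing")
        if self.replicates_per_state < 2:
            raise InvalidDesignError("replicates_per_state must be >= 2")
        if not 0 < self.d2o_fraction <= 1:
            raise InvalidDesignError("d2o_fraction must be in (0, 1]")
        if self.noise_sd < 0:
            raise InvalidDesignError("noise_sd must be >= 0")
        if any(z < 1 for z in self.charges):
            raise InvalidDesignError("charges must be >= 1")


@dataclass(frozen=True)
class TitrationDesign:
    """Parameters of one synthetic FCS titration."""

    true_kd: float = 47.0  # nM
    labeled_conc: float = 10.0  # nM
    tau_free: float = 150.0  # us
    tau_bound: float = 350.0  # us
    conc_grid: tuple[float, ...] = tuple(np.geomspace(1.0, 10_000.0, 12))
    replicates: int = 3
    noise_cv: float = 0.03
    n_consecutive: int = 6  # consecutive measurements averaged per entry
    seed: int = 0

    def __post_init__(self):
        if not self.true_kd > 0:
            raise InvalidDesignError("true_kd must be positive")
        if not self.tau_bound > self.tau_free > 0:
            raise InvalidDesignError("require tau_bound > tau_free > 0")
        grid = np.asarray(self.conc_grid, dtype=float)
        if np.any(grid < 0):
            raise InvalidDesignError("concentrations must be non-negative")
        if np.any(np.diff(grid) < 0):
            raise InvalidDesignError("conc_grid must be sorted")
        if self.replicates < 1:
            raise InvalidDesignError("replicates must be >= 1")
        if not self.labeled_conc > 0:
            raise InvalidDesignError("labeled_conc must be positive")
        if self.n_consecutive < 1:
            raise InvalidDesignError("n_consecutive must be >= 1")


def default_injection_volumes() -> tuple[float, ...]:
    """1 injection of 0.2 ul followed by 18 injections of 2 ul."""
    return (0.2,) + (2.0,) * 18


@dataclass(frozen=True)
class ItcDesign:
    """Parameters of one synthetic ITC run."""

    true_kd: float = 2.24  # uM
    delta_h: float = -10.0  # kcal/mol
    n_sites: float = 1.0
    cell_conc: float = 20.0  # uM
    syringe_conc: float = 270.0  # uM
    cell_volume: float = 200.0  # ul
    injection_volumes: tuple[float, ...] = field(
        default_factory=default_injection_volumes
    )
    noise_sd: float = 0.2  # ucal per injection
    seed: int = 0

    def __post_init__(self):
        if not self.true_kd > 0:
            raise InvalidDesignError("true_kd must be positive")
        for name in ("cell_conc", "syringe_conc", "cell_volume"):
            if not getattr(self, name) > 0:
                raise InvalidDesignError(f"{name} must be positive")
        if any(v <= 0 for v in self.injection_volumes):
            raise InvalidDesignError("injection volumes must be positive")
        if self.noise_sd < 0:
            raise InvalidDesignError("noise_sd must be >= 0")


# ---------------------------------------------------------------------------
# peptide maps


@dataclass(frozen=True)
class Peptide:
    start: int
    end: int
    sequence: str


@dataclass
class PeptideMap:
    peptides: list[Peptide]
    coverage: float


def _coverage(peptides: Sequence[Peptide], length: int) -> float:
    covered = np.zeros(length, dtype=bool)
    for p in peptides:
        covered[p.start - 1 : p.end] = True
    return float(covered.sum() / length)


def generate_peptide_map(
    protein: GroundTruthProtein, design: SimulationDesign
) -> PeptideMap:
    """Emulate protease digestion coverage of the protein sequence."""
    pd_ = design.peptide_design
    seq, length = protein.sequence, protein.length
    if length < pd_.min_length:
        raise InvalidDesignError(
            f"sequence length {length} shorter than minimum peptide length"
        )
    peptides: list[Peptide] = []
    if pd_.mode == "tiling":
        if length < pd_.tile_length:
            raise InvalidDesignError("sequence shorter than tile length")
        start = 1
        while start + pd_.tile_length - 1 <= length:
            end = start + pd_.tile_length - 1
            peptides.append(Peptide(start, end, seq[start - 1 : end]))
            start += pd_.tile_offset
        # ensure the C-terminus is tiled when the offset overshoots
        if peptides and peptides[-1].end < length:
            end = length
            start = end - pd_.tile_length + 1
            peptides.append(Peptide(start, end, seq[start - 1 : end]))
    else:
        rng = np.random.default_rng(design.seed)
        max_len = min(pd_.max_length, length)
        for _ in range(pd_.n_peptides):
            plen = int(rng.integers(pd_.min_length, max_len + 1))
            start = int(rng.integers(1, length - plen + 2))
            end = start + plen - 1
            peptides.append(Peptide(start, end, seq[start - 1 : end]))
        peptides.sort(key=lambda p: (p.start, p.end))
    return PeptideMap(peptides, _coverage(peptides, length))


# ---------------------------------------------------------------------------
# HDX forward model


def expected_uptake_fraction(
    protein: GroundTruthProtein,
    peptide: Peptide,
    state: str,
    exposure_s: float,
    fast_loss: int = 1,
) -> float:
    """Noise-free expected deuterated fraction of one peptide (0..1).

    Fraction is relative to the theoretical maximum (all observable amides
    exchanged at the buffer D2O fraction), so the D2O fraction cancels.
    """
    positions = exchangeable_positions(peptide.sequence, peptide.start, fast_loss)
    if not positions:
        return 0.0
    pvec = protein.protection.get(state)
    t_min = exposure_s / 60.0
    total = 0.0
    for pos in positions:
        p = 1.0 if pvec is None else pvec[pos - 1]
        rate = 0.0 if math.isinf(p) else protein.intrinsic_rate * t_min / p
        total += 1.0 - math.exp(-rate) if rate > 0 else 0.0
    return total / len(positions)


def ground_truth_uptake(
    protein: GroundTruthProtein,
    peptides: Sequence[Peptide],
    design: SimulationDesign,
    states: Sequence[str],
) -> pd.DataFrame:
    """Noise-free per-peptide uptake fractions for every state/timepoint."""
    rows = []
    for pep in peptides:
        for state in states:
            for t in design.timepoints:
                rows.append(
                    (
                        protein.name, pep.start, pep.end, pep.sequence, state,
                        float(t),
                        expected_uptake_fraction(
                            protein, pep, state, t, design.fast_loss
                        ),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=["protein", "start", "end", "sequence", "state", "exposure", "d_true"],
    )


def simulate_uptake_dataset(
    protein: GroundTruthProtein,
    peptides: Sequence[Peptide],
    design: SimulationDesign,
    states: Sequence[str] | None = None,
) -> ExchangeDataset:
    """Simulate a full centroid table: states x timepoints x replicates.

    Each peptide additionally gets an undeuterated record (exposure 0) and an
    out-exchange control record (exposure ``inf``, simulated as the forward
    model evaluated at the 24 h control incubation) per state and replicate.
    """
    if states is None:
        states = sorted(protein.protection) or ["apo"]
    for pep in peptides:
        if not (1 <= pep.start <= pep.end <= protein.length):
            raise InvalidDesignError(f"peptide {pep} outside sequence")
        if protein.sequence[pep.start - 1 : pep.end] != pep.sequence:
            raise InvalidDesignError(f"peptide {pep} mismatches protein sequence")

    rng = np.random.default_rng(design.seed)
    shift = DEUTERIUM_MASS_SHIFT * design.d2o_fraction
    exposures = [0.0, *map(float, design.timepoints), OUT_EXCHANGE_EXPOSURE]
    rows = []
    for pep in peptides:
        mex0 = average_mass(pep.sequence)
        n_amides = len(
            exchangeable_positions(pep.sequence, pep.start, design.fast_loss)
        )
        for state in states:
            for exposure in exposures:
                t_eff = (
                    design.out_exchange_time_s
                    if math.isinf(exposure)
                    else exposure
                )
                frac = expected_uptake_fraction(
                    protein, pep, state, t_eff, design.fast_loss
                )
                mass = mex0 + shift * frac * n_amides
                # undeuterated rows carry the identification-stage parent
                # mass, which is high-accuracy: no centroid noise on them
                # (the 10 ppm read-time rule judges exactly these rows)
                noisy_row = design.noise_sd > 0 and exposure != 0.0
                for rep in range(1, design.replicates_per_state + 1):
                    noisy = mass + rng.normal(0.0, design.noise_sd) if noisy_row else mass
                    for z in design.charges:
                        rows.append(
                            (
                                protein.name, pep.start, pep.end, pep.sequence,
                                z, state, exposure, rep,
                                (noisy + z * PROTON_MASS) / z, np.nan,
                            )
                        )
    return ExchangeDataset(pd.DataFrame(rows, columns=COLUMNS))


# ---------------------------------------------------------------------------
# FCS titration


def bound_fraction(
    titrant_total: float | np.ndarray, kd: float, labeled_total: float
) -> float | np.ndarray:
    """Fraction of the labeled species bound, exact single-site depletion.

    Solves the quadratic mass balance for total titrant ``L``, total labeled
    species ``R`` and dissociation constant ``K`` (all same units).
    """
    L = np.asarray(titrant_total, dtype=float)
    s = L + kd + labeled_total
    disc = s * s - 4.0 * L * labeled_total
    f = (s - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * labeled_total)
    return f if f.ndim else float(f)


def expected_diffusion_time(
    conc: float | np.ndarray, design: TitrationDesign
) -> float | np.ndarray:
    f = bound_fraction(conc, design.true_kd, design.labeled_conc)
    return design.tau_free + f * (design.tau_bound - design.tau_free)


@dataclass
class TitrationDataset:
    """Frame columns: concentration_nM, tau_us, replicate, sd_pct."""

    frame: pd.DataFrame
    design: TitrationDesign


def simulate_fcs_titration(design: TitrationDesign) -> TitrationDataset:
    """Each entry is the mean of ``n_consecutive`` noisy measurements.

    ``noise_cv`` is the multiplicative CV of one measurement; the reported
    ``sd_pct`` is the realized SD of the consecutive draws as a percentage
    of their mean, mirroring how titration entries are produced and then
    screened by the SD-percentage exclusion rule.
    """
    rng = np.random.default_rng(design.seed)
    rows = []
    for rep in range(1, design.replicates + 1):
        for conc in design.conc_grid:
            tau_true = float(expected_diffusion_time(conc, design))
            if design.noise_cv:
                draws = tau_true * (
                    1.0 + rng.normal(0.0, design.noise_cv, design.n_consecutive)
                )
                tau = float(draws.mean())
                sd_pct = (
                    float(draws.std(ddof=1) / abs(tau) * 100.0)
                    if design.n_consecutive > 1
                    else 0.0
                )
            else:
                tau, sd_pct = tau_true, 0.0
            rows.append((float(conc), tau, rep, sd_pct))
    frame = pd.DataFrame(
        rows, columns=["concentration_nM", "tau_us", "replicate", "sd_pct"]
    )
    return TitrationDataset(frame, design)


# ---------------------------------------------------------------------------
# ITC isotherm


def itc_injection_heats(
    kd_uM: float,
    delta_h_kcal: float,
    n_sites: float,
    cell_conc_uM: float,
    syringe_conc_uM: float,
    cell_volume_ul: float,
    injection_volumes_ul: Sequence[float],
    baseline_ucal: float = 0.0,
) -> np.ndarray:
    """Noise-free per-injection heats (ucal) for the one-site model.

    Cell contents are diluted by perfusion (instantaneous mixing, displaced
    volume leaves at current composition); the measured heat of injection j
    is the change in cell heat content plus the mean heat content carried
    out with the displaced volume.
    """
    v0 = cell_volume_ul
    vols = np.asarray(injection_volumes_ul, dtype=float)
    cum = np.cumsum(vols)
    dil = np.exp(-cum / v0)
    mt = cell_conc_uM * dil  # macromolecule total in cell, uM
    xt = syringe_conc_uM * (1.0 - dil)  # titrant total in cell, uM

    # fraction of sites occupied, one-site isotherm:
    # theta^2 - theta*(1 + Xt/(n*Mt) + Kd/(n*Mt)) + Xt/(n*Mt) = 0
    r = xt / (n_sites * mt)
    term = 1.0 + r + kd_uM / (n_sites * mt)
    theta = 0.5 * (term - np.sqrt(term * term - 4.0 * r))

    # heat content of the cell after each injection, ucal:
    # uM * ul * kcal/mol * 1e-3 = ucal
    q = n_sites * theta * mt * v0 * delta_h_kcal * 1e-3
    q_prev = np.concatenate(([0.0], q[:-1]))
    dq = q - q_prev + (vols / v0) * 0.5 * (q + q_prev)
    return dq + baseline_ucal


@dataclass
class ItcDataset:
    """Frame columns: injection, volume_ul, heat_ucal."""

    frame: pd.DataFrame
    design: ItcDesign


def simulate_itc_isotherm(design: ItcDesign) -> ItcDataset:
    heats = itc_injection_heats(
        design.true_kd,
        design.delta_h,
        design.n_sites,
        design.cell_conc,
        design.syringe_conc,
        design.cell_volume,
        design.injection_volumes,
    )
    rng = np.random.default_rng(design.seed)
    if design.noise_sd:
        heats = heats + rng.normal(0.0, design.noise_sd, size=heats.size)
    frame = pd.DataFrame(
        {
            "injection": np.arange(1, heats.size + 1),
            "volume_ul": list(design.injection_volumes),
            "heat_ucal": heats,
        }
    )
    return ItcDataset(frame, design)


# convenience used by tests and the CLI

def with_seed(design, seed: int):
    """Return a copy of any frozen design with a different seed."""
    return replace(design, seed=seed)


_RESIDUE_POOL = "ACDEFGHIKLMNQRSTVWY"  # proline left out of random sequences


def random_protein_sequence(length: int, seed: int = 0, proline_every: int = 0) -> str:
    """Seeded random sequence; optional proline sprinkled every N residues."""
    rng = np.random.default_rng(seed)
    residues = list(rng.choice(list(_RESIDUE_POOL), size=length))
    if proline_every:
        for i in range(proline_every, length, proline_every):
            residues[i] = "P"
    return "".join(residues)
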