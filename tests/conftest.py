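"""Shared fixtures: small ground-truth proteins and simulation designs."""

import math

import numpy as np
import pytest

from hdxbind.simulate import (
    GroundTruthProtein,
    PeptideDesign,
    SimulationDesign,
    protection_profile,
    random_protein_sequence,
)

#: windows used by the recovery simulations (1-based inclusive, P factor)
SAS6_WINDOW = (440, 460)
GORAB_PROTECTED = (230, 260)
GORAB_DESTABILIZED = (270, 315)


@pytest.fixture(scope="session")
def sas6_like() -> GroundTruthProtein:
    """472-residue protein, strong extra protection at 440-460 in complex."""
    length = 472
    seq = random_protein_sequence(length, seed=1234)
    return GroundTruthProtein(
        "sas6",
        seq,
        protection={
            "apo": protection_profile(length),
            "complex": protection_profile(length, [(*SAS6_WINDOW, 200.0)]),
        },
    )


@pytest.fixture(scope="session")
def sas6_null() -> GroundTruthProtein:
    """Same protein with no state-dependent protection at all."""
    length = 472
    seq = random_protein_sequence(length, seed=1234)
    return GroundTruthProtein(
        "sas6",
        seq,
        protection={
            "apo": protection_profile(length),
            "complex": protection_profile(length),
        },
    )


@pytest.fixture(scope="session")
def gorab_like() -> GroundTruthProtein:
    """338-residue protein: protection gained at 230-260 and lost at 270-315
    in the complexed state (opposite directions)."""
    length = 338
    seq = random_protein_sequence(length, seed=4321)
    return GroundTruthProtein(
        "gorab",
        seq,
        protection={
            "apo": protection_profile(length, [(*GORAB_DESTABILIZED, 200.0)]),
            "complex": protection_profile(length, [(*GORAB_PROTECTED, 200.0)]),
        },
    )


@pytest.fixture()
def recovery_design() -> SimulationDesign:
    return SimulationDesign(
        replicates_per_state=2,
        noise_sd=0.05,
        seed=11,
        peptide_design=PeptideDesign(n_peptides=120),
    )


@pytest.fixture()
def tiny_protein() -> GroundTruthProtein:
    length = 60
    seq = random_protein_sequence(length, seed=7)
    return GroundTruthProtein(
        "tiny",
        seq,
        protection={
            "apo": protection_profile(length),
            "holo": protection_profile(length, [(20, 30, math.inf)]),
        },
    )


@pytest.fixture()
def tiling_design() -> SimulationDesign:
    return SimulationDesign(
        noise_sd=0.0,
        seed=3,
        peptide_design=PeptideDesign(mode="tiling", tile_length=10, tile_offset=5),
    )


def interval_union_coverage(intervals, length: int) -> float:
    """Independent brute-force interval-union oracle (1-based inclusive)."""
    covered = set()
    for start, end in intervals:
        covered.update(range(start, end + 1))
    return len([r for r in covered if 1 <= r <= length]) / length


def jaccard(region_start, region_end, window_start, window_end) -> float:
    inter = max(0, min(region_end, window_end) - max(region_start, window_start) + 1)
    union = (window_end - window_start + 1) + (region_end - region_start + 1) - inter
    return inter / union
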