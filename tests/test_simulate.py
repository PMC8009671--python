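"""Tests for the forward simulators (HDX tables, FCS titrations, ITC)."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from conftest import interval_union_coverage
from hdxbind.constants import DEUTERIUM_MASS_SHIFT, PROTON_MASS
from hdxbind.errors import InvalidDesignError
from hdxbind.peptides import average_mass, exchangeable_positions
from hdxbind.simulate import (
    GroundTruthProtein,
    ItcDesign,
    Peptide,
    PeptideDesign,
    SimulationDesign,
    TitrationDesign,
    bound_fraction,
    default_injection_volumes,
    expected_diffusion_time,
    expected_uptake_fraction,
    generate_peptide_map,
    itc_injection_heats,
    protection_profile,
    random_protein_sequence,
    simulate_fcs_titration,
    simulate_itc_isotherm,
    simulate_uptake_dataset,
    with_seed,
)


class TestPeptideMap:
    def test_deterministic_tiling(self):
        seq = random_protein_sequence(30, 0)
        prot = GroundTruthProtein("p", seq)
        design = SimulationDesign(
            peptide_design=PeptideDesign(mode="tiling", tile_length=10, tile_offset=5)
        )
        pmap = generate_peptide_map(prot, design)
        spans = [(p.start, p.end) for p in pmap.peptides]
        assert spans == [(1, 10), (6, 15), (11, 20), (16, 25), (21, 30)]
        assert pmap.coverage == 1.0
        for p in pmap.peptides:
            assert p.sequence == seq[p.start - 1 : p.end]

    def test_seed_determinism(self):
        prot = GroundTruthProtein("p", random_protein_sequence(100, 1))
        design = SimulationDesign(peptide_design=PeptideDesign(n_peptides=40), seed=9)
        assert generate_peptide_map(prot, design) == generate_peptide_map(prot, design)

    def test_random_coverage_matches_union_oracle(self):
        prot = GroundTruthProtein("p", random_protein_sequence(472, 2))
        design = SimulationDesign(
            peptide_design=PeptideDesign(n_peptides=120, min_length=6, max_length=18),
            seed=7,
        )
        pmap = generate_peptide_map(prot, design)
        oracle = interval_union_coverage(
            [(p.start, p.end) for p in pmap.peptides], 472
        )
        assert pmap.coverage == pytest.approx(oracle)

    def test_sequence_too_short(self):
        prot = GroundTruthProtein("p", "GAK")
        with pytest.raises(InvalidDesignError):
            generate_peptide_map(prot, SimulationDesign())


def _noise_free(seed=0, **kw):
    return SimulationDesign(
        noise_sd=0.0, seed=seed,
        peptide_design=PeptideDesign(mode="tiling", tile_length=10, tile_offset=5),
        **kw,
    )


class TestUptakeSimulation:
    def test_t0_equals_undeuterated_mass(self, tiny_protein):
        design = _noise_free()
        pmap = generate_peptide_map(tiny_protein, design)
        ds = simulate_uptake_dataset(tiny_protein, pmap.peptides, design)
        zero = ds.frame[ds.frame["exposure"] == 0.0]
        for _, row in zero.iterrows():
            neutral = row["charge"] * (row["centroid_mz"] - PROTON_MASS)
            assert neutral == pytest.approx(average_mass(row["sequence"]), abs=1e-9)

    def test_saturation_reaches_theoretical_maximum(self):
        length = 40
        prot = GroundTruthProtein(
            "p", random_protein_sequence(length, 3),
            protection={"apo": protection_profile(length)},
        )
        design = _noise_free(timepoints=(10.0, 1e9))
        pmap = generate_peptide_map(prot, design)
        ds = simulate_uptake_dataset(prot, pmap.peptides, design)
        sat = ds.frame[ds.frame["exposure"] == 1e9]
        for _, row in sat.iterrows():
            n = len(exchangeable_positions(row["sequence"], row["start"], 1))
            expected = (
                average_mass(row["sequence"])
                + n * 0.9 * DEUTERIUM_MASS_SHIFT
            )
            neutral = row["charge"] * (row["centroid_mz"] - PROTON_MASS)
            assert neutral == pytest.approx(expected, abs=1e-8)

    def test_infinite_protection_window(self):
        # ground-truth window 278-284 fully protected; peptides inside exchange
        # nothing, peptides outside match a per-residue brute-force sum
        length = 300
        seq = random_protein_sequence(length, 4)
        prot = GroundTruthProtein(
            "p", seq,
            protection={"apo": protection_profile(length, [(278, 284, math.inf)])},
        )
        inside = Peptide(279, 284, seq[278:284])
        outside = Peptide(100, 112, seq[99:112])
        for t in (10.0, 300.0, 9000.0):
            assert expected_uptake_fraction(prot, inside, "apo", t) == 0.0
            # brute force: every observable amide is unprotected
            positions = exchangeable_positions(outside.sequence, outside.start, 1)
            brute = sum(
                1.0 - math.exp(-1.0 * (t / 60.0)) for _ in positions
            ) / len(positions)
            assert expected_uptake_fraction(prot, outside, "apo", t) == pytest.approx(
                brute, abs=1e-12
            )

    def test_uptake_monotone_in_time(self, tiny_protein):
        design = _noise_free()
        pmap = generate_peptide_map(tiny_protein, design)
        for pep in pmap.peptides:
            for state in ("apo", "holo"):
                fracs = [
                    expected_uptake_fraction(tiny_protein, pep, state, t)
                    for t in design.timepoints
                ]
                assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_record_count(self, tiny_protein):
        design = SimulationDesign(
            noise_sd=0.01, seed=1, replicates_per_state=3,
            peptide_design=PeptideDesign(mode="tiling", tile_length=10, tile_offset=10),
        )
        pmap = generate_peptide_map(tiny_protein, design)
        ds = simulate_uptake_dataset(tiny_protein, pmap.peptides, design)
        n_pep, n_states, n_t = len(pmap.peptides), 2, len(design.timepoints)
        # timepoints plus undeuterated and out-exchange records, per replicate
        assert len(ds) == n_pep * n_states * (n_t + 2) * 3

    def test_seed_determinism(self, tiny_protein):
        design = SimulationDesign(
            seed=5, peptide_design=PeptideDesign(mode="tiling", tile_length=10,
                                                 tile_offset=5)
        )
        pmap = generate_peptide_map(tiny_protein, design)
        a = simulate_uptake_dataset(tiny_protein, pmap.peptides, design)
        b = simulate_uptake_dataset(tiny_protein, pmap.peptides, design)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_peptide_outside_sequence_rejected(self, tiny_protein):
        bad = Peptide(58, 65, "AAAAAAAA")
        with pytest.raises(InvalidDesignError):
            simulate_uptake_dataset(tiny_protein, [bad], _noise_free())


class TestFcsSimulation:
    def test_zero_concentration_gives_tau_free(self):
        design = TitrationDesign(noise_cv=0.0, conc_grid=(0.0, 10.0, 100.0))
        assert expected_diffusion_time(0.0, design) == design.tau_free

    def test_saturation_approaches_tau_bound(self):
        design = TitrationDesign(true_kd=47.0, labeled_conc=10.0, noise_cv=0.0)
        tau = expected_diffusion_time(1e9, design)
        assert tau == pytest.approx(design.tau_bound, rel=1e-6)

    def test_quadratic_against_root_finding_oracle(self):
        # K = 47 nM, R = 10 nM, L = 47 nM: solve the mass balance numerically
        K, R, L = 47.0, 10.0, 47.0

        def balance(fb):
            # free ligand = L - fb*R; Kd relation: fb/(1-fb) = free/K
            return (L - fb * R) * (1.0 - fb) - K * fb

        oracle = brentq(balance, 0.0, 1.0, xtol=1e-14)
        assert bound_fraction(L, K, R) == pytest.approx(oracle, abs=1e-10)

    def test_tau_monotone_in_concentration(self):
        design = TitrationDesign(noise_cv=0.0)
        taus = expected_diffusion_time(np.geomspace(0.1, 1e6, 50), design)
        assert np.all(np.diff(taus) >= 0)

    def test_row_count(self):
        data = simulate_fcs_titration(TitrationDesign(replicates=3))
        assert len(data.frame) == 12 * 3

    def test_seed_determinism(self):
        d = TitrationDesign(seed=42)
        pd.testing.assert_frame_equal(
            simulate_fcs_titration(d).frame, simulate_fcs_titration(d).frame
        )

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidDesignError):
            TitrationDesign(conc_grid=(-1.0, 10.0))

    def test_sd_pct_reflects_noise_scale(self):
        data = simulate_fcs_titration(TitrationDesign(noise_cv=0.05, seed=8))
        # realized SD% of 6 consecutive draws at CV 5% centers near 5
        assert 2.0 < data.frame["sd_pct"].median() < 8.0


class TestItcSimulation:
    def test_default_schedule_gives_19_records(self):
        data = simulate_itc_isotherm(ItcDesign())
        assert len(data.frame) == 19
        assert data.frame["volume_ul"].iloc[0] == pytest.approx(0.2)
        assert data.frame["volume_ul"].iloc[1:].tolist() == [2.0] * 18

    def test_zero_enthalpy_zero_heats(self):
        design = ItcDesign(delta_h=0.0, noise_sd=0.0)
        assert np.allclose(simulate_itc_isotherm(design).frame["heat_ucal"], 0.0)

    def test_tight_binding_equivalence_point(self):
        # K -> 0: constant heat per mole until the cell macromolecule is
        # saturated, then ~0. Mole-balance oracle with perfusion dilution:
        # X_syr*(1-e^(-v/V0)) >= n*M0*e^(-v/V0)
        design = ItcDesign(true_kd=1e-9, noise_sd=0.0)
        heats = simulate_itc_isotherm(design).frame["heat_ucal"].to_numpy()
        vols = np.asarray(design.injection_volumes)
        cum = np.cumsum(vols)
        saturated = design.syringe_conc * (1 - np.exp(-cum / design.cell_volume)) >= (
            design.n_sites * design.cell_conc * np.exp(-cum / design.cell_volume)
        )
        oracle_idx = int(np.argmax(saturated))  # first saturated injection
        per_mole = heats / (vols * design.syringe_conc)
        # injections well before the equivalence point: constant heat per mole
        early = per_mole[: oracle_idx - 1]
        assert np.allclose(early, early[0], rtol=1e-3)
        # injections after: essentially zero
        assert np.all(np.abs(heats[oracle_idx + 1 :]) < 1e-6 * np.abs(heats[0] / vols[0] * 2.0))

    def test_cumulative_heat_monotone_single_sign(self):
        design = ItcDesign(noise_sd=0.0)
        heats = simulate_itc_isotherm(design).frame["heat_ucal"].to_numpy()
        assert np.all(heats <= 0)  # exothermic design
        cumulative = np.cumsum(heats)
        assert np.all(np.diff(cumulative) <= 1e-12)

    def test_heat_conservation_under_saturation(self):
        # saturating excess: total heat -> n * dH * M0 * V0, to 2%
        design = ItcDesign(
            true_kd=0.001, syringe_conc=2000.0, noise_sd=0.0,
            injection_volumes=(2.0,) * 30,
        )
        total = simulate_itc_isotherm(design).frame["heat_ucal"].sum()
        expected = design.n_sites * design.delta_h * design.cell_conc * design.cell_volume * 1e-3
        assert total == pytest.approx(expected, rel=0.02)

    def test_seed_determinism_and_with_seed(self):
        d = ItcDesign(seed=3)
        pd.testing.assert_frame_equal(
            simulate_itc_isotherm(d).frame, simulate_itc_isotherm(d).frame
        )
        assert with_seed(d, 4).seed == 4

    def test_invalid_design(self):
        with pytest.raises(InvalidDesignError):
            ItcDesign(cell_conc=-1.0)


class TestGroundTruthProtein:
    def test_protection_vector_length_checked(self):
        with pytest.raises(InvalidDesignError):
            GroundTruthProtein("p", "GAGAGA", protection={"apo": np.ones(5)})

    def test_protection_below_one_rejected(self):
        with pytest.raises(InvalidDesignError):
            GroundTruthProtein("p", "GAGAGA", protection={"apo": np.full(6, 0.5)})

    def test_window_profile(self):
        vec = protection_profile(10, [(3, 5, 7.0)])
        assert vec[1] == 1.0 and vec[2] == 7.0 and vec[4] == 7.0 and vec[5] == 1.0
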