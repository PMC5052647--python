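import numpy as np
import pytest

import btpcorr as b
from btpcorr.distributions import count_peaks_1d, histogram_1d
from btpcorr.synthetic import (
    ProteinLayout,
    StateModel,
    SyntheticPairSpec,
    planted_design,
    sample_heterogeneous_pair,
    sample_pair,
    sample_protein,
    single_state,
    state_mi,
    two_state,
    write_dssp_codes,
    write_pdb,
)


class TestStateModel:
    def test_weights_default_uniform(self):
        m = StateModel(means=(0.0, 90.0), kappas=(5.0, 5.0))
        assert m.weights == (0.5, 0.5)

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            StateModel(means=(0.0, 90.0), kappas=(5.0, 5.0), weights=(0.7, 0.7))

    def test_transition_matrix_stationarity_enforced(self):
        t = np.array([[0.9, 0.1], [0.1, 0.9]])  # stationary (0.5, 0.5)
        StateModel(means=(0.0, 90.0), kappas=(5.0, 5.0),
                   weights=(0.5, 0.5), transition_matrix=t)
        with pytest.raises(ValueError, match="stationary"):
            StateModel(means=(0.0, 90.0), kappas=(5.0, 5.0),
                       weights=(0.8, 0.2), transition_matrix=t)

    def test_too_many_states_rejected(self):
        with pytest.raises(ValueError):
            StateModel(means=(0.0, 1.0, 2.0, 3.0), kappas=(1.0,) * 4)


class TestSamplePair:
    def test_seeded_determinism_bit_identical(self):
        spec = SyntheticPairSpec(
            state_x=two_state(-60, 60), state_y=single_state(0.0),
            coupling="copula", rho=0.3, M=5000, seed=99, mean_dwell=100)
        x1, y1, _ = sample_pair(spec)
        x2, y2, _ = sample_pair(spec)
        assert np.array_equal(x1.angles, x2.angles)
        assert np.array_equal(y1.angles, y2.angles)

    def test_angles_in_convention_range(self):
        spec = SyntheticPairSpec(
            state_x=two_state(170, -170), state_y=single_state(180.0),
            coupling="copula", rho=0.5, M=20_000, seed=1)
        x, y, _ = sample_pair(spec)
        for a in (x.angles, y.angles):
            assert a.min() > -180.0 and a.max() <= 180.0

    def test_invalid_joint_table_rejected(self):
        spec = SyntheticPairSpec(
            state_x=two_state(-60, 60), state_y=two_state(0, 90),
            coupling="state_coupled",
            joint_state_probs=np.array([[0.9, 0.0], [0.0, 0.1]]),  # wrong marginals
            M=100, seed=0)
        with pytest.raises(ValueError, match="marginals"):
            sample_pair(spec)

    def test_uncoupled_single_state_pair_is_null(self):
        spec = SyntheticPairSpec(
            state_x=single_state(-60, 8), state_y=single_state(60, 8),
            coupling="independent", M=50_000, seed=4)
        x, y, gt = sample_pair(spec)
        r, _ = b.circular_correlation(x, y)
        assert abs(r) < 0.05
        assert b.mutual_information(x, y) < 0.04
        assert gt.analytic_state_mi == 0.0

    def test_state_occupancy_matches_weights(self):
        m = 100_000
        spec = SyntheticPairSpec(
            state_x=two_state(-90, 90, kappa=50, weight_a=0.3),
            state_y=single_state(0.0),
            coupling="independent", M=m, seed=8, mean_dwell=10)
        x, _, _ = sample_pair(spec)
        frac = np.mean(np.abs((x.angles - (-90) + 180) % 360 - 180) < 90)
        sigma = np.sqrt(0.3 * 0.7 / m)
        # Markov dwell inflates the binomial sigma by ~sqrt(2*dwell)
        assert abs(frac - 0.3) < 3 * sigma * np.sqrt(2 * 10)

    def test_copula_r_monotone_in_rho(self):
        rhos = [-0.8, -0.4, 0.0, 0.4, 0.8]
        medians = []
        for rho in rhos:
            rs = []
            for seed in range(5):
                spec = SyntheticPairSpec(
                    state_x=single_state(-60, 8), state_y=single_state(60, 8),
                    coupling="copula", rho=rho, M=20_000, seed=seed)
                x, y, _ = sample_pair(spec)
                rs.append(b.circular_correlation(x, y)[0])
            medians.append(np.median(rs))
        assert all(b2 > a2 for a2, b2 in zip(medians, medians[1:]))

    def test_separated_two_state_mi_matches_analytic(self):
        table = np.array([[0.4, 0.1], [0.1, 0.4]])
        analytic = 0.8 * np.log(1.6) + 0.2 * np.log(0.4)
        spec = SyntheticPairSpec(
            state_x=two_state(-60, 60, kappa=20),
            state_y=two_state(-60, 60, kappa=20),
            coupling="state_coupled", joint_state_probs=table,
            M=200_000, seed=0, mean_dwell=10)
        x, y, gt = sample_pair(spec)
        assert gt.analytic_state_mi == pytest.approx(analytic)
        assert gt.analytic_state_mi == pytest.approx(0.1927, abs=5e-5)
        assert b.mutual_information(x, y) == pytest.approx(analytic, abs=0.02)

    def test_state_mi_formula(self):
        assert state_mi(np.array([[0.25, 0.25], [0.25, 0.25]])) == 0.0
        assert state_mi(np.array([[0.5, 0.0], [0.0, 0.5]])) == pytest.approx(np.log(2))


class TestHeterogeneousPair:
    def spec(self, seed=0, m=100_000):
        return SyntheticPairSpec(
            state_x=two_state(-60, 60, kappa=20),
            state_y=two_state(-45, 120, kappa=20),
            coupling="copula",
            rho={(0, 0): 0.8, (0, 1): 0.8, (1, 0): -0.8, (1, 1): -0.8},
            M=m, seed=seed, mean_dwell=5000)

    def test_expected_verdict_recorded(self):
        _, _, gt = sample_heterogeneous_pair(self.spec())
        assert gt.expected_linearity == "nonlinear"

    def test_classified_nonlinear(self):
        x, y, _ = sample_heterogeneous_pair(self.spec(seed=3))
        mi = b.mutual_information(x, y)
        r, _ = b.circular_correlation(x, y)
        assert b.classify_linearity(mi, r) == "nonlinear"

    def test_identical_rho_rejected(self):
        s = self.spec()
        s.rho = {(0, 0): 0.8, (0, 1): 0.8, (1, 0): 0.8, (1, 1): 0.8}
        with pytest.raises(ValueError, match="differ"):
            sample_heterogeneous_pair(s)

    def test_single_state_rejected(self):
        s = self.spec()
        s.state_x = single_state(0.0)
        with pytest.raises(ValueError):
            sample_heterogeneous_pair(s)


class TestPlantedDesign:
    def test_structure_and_truth_labels(self):
        series, truths = planted_design(M=2000, seed=0)
        assert len(series) == 12 and len(truths) == 6
        labels = [t["truth"].expected_linearity for t in truths]
        assert labels == ["linear"] * 2 + ["nonlinear"] * 4

    def test_deterministic(self):
        s1, _ = planted_design(M=1000, seed=5)
        s2, _ = planted_design(M=1000, seed=5)
        for a, c in zip(s1, s2):
            assert np.array_equal(a.angles, c.angles)


class TestSampleProtein:
    def test_alpha_torsions_are_single_peak(self):
        for seed in range(5):
            series, *_ = sample_protein(6, M=20_000, seed=seed,
                                        layout=ProteinLayout(ss_labels="HHHHHH"))
            for s in series:
                assert count_peaks_1d(histogram_1d(s.angles)).n_peaks == 1

    def test_loop_torsions_can_switch_states(self):
        series, *_ = sample_protein(4, M=50_000, seed=2, mean_dwell=200,
                                    layout=ProteinLayout(ss_labels="LLLL"))
        counts = [count_peaks_1d(histogram_1d(s.angles)).n_peaks for s in series]
        assert max(counts) >= 2

    def test_planted_pair_out_of_range_rejected(self):
        layout = ProteinLayout(ss_labels="LLLL",
                               coupled_pairs=[{"i": 1, "j": 99, "mode": "copula"}])
        with pytest.raises(ValueError, match="range"):
            sample_protein(4, M=100, layout=layout)

    def test_geometry_and_files_round_trip(self, tmp_path):
        from btpcorr.geometry import (build_torsion_index, inter_torsion_distance,
                                      read_dssp_codes, read_pdb_frames)

        series, frame, codes, truths, imap = sample_protein(
            8, M=500, seed=0,
            layout=ProteinLayout(ss_labels="HHLLEELL",
                                 coupled_pairs=[{"i": 2, "j": 13, "mode": "copula",
                                                 "rho": 0.5}]))
        assert len(series) == 14
        assert truths[0]["pair"] == (2, 13)
        # distant torsion indices realize a long-range pseudo-distance
        d = inter_torsion_distance(frame, imap, 2, 13)
        assert d > 8.0
        pdb = tmp_path / "synth.pdb"
        write_pdb(pdb, frame)
        back = read_pdb_frames(pdb)[0]
        assert back.residue_numbers == frame.residue_numbers
        np.testing.assert_allclose(back.atom(3, "CA"), frame.atom(3, "CA"), atol=1e-3)
        dssp = tmp_path / "ss.tsv"
        write_dssp_codes(dssp, codes)
        assert read_dssp_codes(dssp) == codes

    def test_extracted_dihedrals_match_mdtraj(self, tmp_path):
        """Cross-check phi/psi extraction against mdtraj on a generated PDB."""
        import mdtraj

        from btpcorr.geometry import (build_torsion_index, extract_torsion_series,
                                      read_pdb_frames)

        _, frame, *_ = sample_protein(5, M=10, seed=3)
        pdb = tmp_path / "chain.pdb"
        write_pdb(pdb, frame)
        frames = read_pdb_frames(pdb)
        imap = build_torsion_index(5)
        ours = {(s.residue_number, s.kind): s.angles[0]
                for s in extract_torsion_series(frames, imap)}
        traj = mdtraj.load(str(pdb))
        phi_idx, phi = mdtraj.compute_phi(traj)
        psi_idx, psi = mdtraj.compute_psi(traj)
        for k, ang in enumerate(np.degrees(phi[0])):
            res = traj.topology.atom(phi_idx[k][1]).residue.resSeq
            assert ours[(res, "phi")] == pytest.approx(ang, abs=1e-2)
        for k, ang in enumerate(np.degrees(psi[0])):
            res = traj.topology.atom(psi_idx[k][0]).residue.resSeq
            assert ours[(res, "psi")] == pytest.approx(ang, abs=1e-2)
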