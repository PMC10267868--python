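import numpy as np
import pytest

import linkmap as lm
from linkmap import estimate
from conftest import make_family


class TestTransmittedAlleles:
    def test_definitional_cases(self):
        fam = make_family([1, 1, 0], [[2, 1, 0]])
        t = estimate.infer_transmitted_alleles(fam)
        assert t[0, 0] == 1      # sire het, progeny hom 2 -> paternal allele 1
        assert t[0, 1] == -1     # heterozygous progeny reveals nothing
        assert t[0, 2] == -1     # sire homozygous: non-informative

    def test_hand_worked_toy_family(self):
        # sire het at all 3 markers; 4 progeny written out by hand
        fam = make_family(
            [1, 1, 1],
            [[0, 0, 0],
             [2, 2, np.nan],
             [1, 0, 2],
             [2, 0, 0]],
        )
        t = estimate.infer_transmitted_alleles(fam)
        expected = np.array([
            [0, 0, 0],
            [1, 1, -1],
            [-1, 0, 1],
            [1, 0, 0],
        ], dtype=np.int8)
        np.testing.assert_array_equal(t, expected)


class TestPhasing:
    def test_majority_links_in_phase(self):
        # 10 progeny, 9 transmit equal alleles at the two markers
        prog = np.array([[0, 0]] * 9 + [[0, 2]], dtype=float)
        fam = make_family([1, 1], prog)
        t = estimate.infer_transmitted_alleles(fam)
        hap1, hap2, blocks = estimate.phase_sire(t, np.array([0, 1]))
        assert hap1.tolist() == [0, 0] and hap2.tolist() == [1, 1]
        assert blocks.tolist() == [0, 0]

    def test_unresolved_link_splits_blocks(self):
        # no progeny informative at both markers -> two phase blocks
        prog = np.array([[0, 1], [1, 2]], dtype=float)
        fam = make_family([1, 1], prog)
        t = estimate.infer_transmitted_alleles(fam)
        _, _, blocks = estimate.phase_sire(t, np.array([0, 1]))
        assert blocks.tolist() == [0, 1]

    def test_single_informative_marker(self):
        fam = make_family([1, 0], [[0, 0]])
        t = estimate.infer_transmitted_alleles(fam)
        hap1, hap2, blocks = estimate.phase_sire(t, np.array([0]))
        assert hap1.size == 1 and blocks.tolist() == [0]

    def test_zero_theta_family_phases_consistently(self):
        # with no recombination every progeny matches one haplotype end-to-end
        cfg = lm.SimulationConfig(
            n_families=3, n_progeny_per_family=30, p=15, seed=8,
            true_adjacent_theta=np.zeros(14),
        )
        data, _, _ = lm.simulate_dataset(cfg)
        origins = lm.infer_origins(data)
        for fo in origins.families:
            for row in fo.origins:
                labels = set(row[row > 0].tolist())
                assert len(labels) <= 1


class TestOrigins:
    def test_gauge_flip_leaves_rates_unchanged(self, small_sim):
        _, data, _, _ = small_sim
        origins = lm.infer_origins(data)
        adj = lm.adjacent_rates(origins)
        pw = lm.pairwise_rates(origins)
        fo = origins.families[0]
        flipped = estimate.FamilyOrigins(
            fo.sire_id, fo.chrom, fo.het_idx,
            np.where(fo.origins > 0, 3 - fo.origins, 0).astype(np.int8),
            fo.blocks, fo.hap2, fo.hap1,
        )
        mutated = estimate.OriginMatrix(origins.marker_map,
                                        [flipped] + origins.families[1:])
        assert lm.adjacent_rates(mutated) == adj
        assert lm.pairwise_rates(mutated) == pw

    def test_unknown_stays_unknown(self):
        fam = make_family([1, 1], [[1, np.nan]])
        t = estimate.infer_transmitted_alleles(fam)
        origins = estimate.paternal_origins(t, np.array([0, 1]), np.array([0, 0], np.int8))
        assert (origins == 0).all()

    def test_origin_recovery_against_truth(self):
        # with theta=0 and many progeny, inferred origins match the truth
        # up to a per-family global flip
        cfg = lm.SimulationConfig(
            n_families=5, n_progeny_per_family=40, p=10, seed=21,
            true_adjacent_theta=np.zeros(9),
        )
        data, truth, _ = lm.simulate_dataset(cfg)
        origins = lm.infer_origins(data)
        for fo in origins.families:
            true = truth[fo.sire_id][:, fo.het_idx]
            known = fo.origins > 0
            if not known.any():
                continue
            agree = (fo.origins == true)[known]
            assert agree.all() or (~agree).all()


class TestAdjacentRates:
    def test_pooling_arithmetic(self):
        # counts (2 rec / 20 inf) and (1 rec / 30 inf) pool to 3/50 = 0.06
        def fam_with_counts(n_inf, n_rec, sire_id):
            prog = np.zeros((n_inf, 2))
            prog[:n_rec, 1] = 2.0  # these progeny switch haplotype
            return make_family([1, 1], prog, sire_id=sire_id)

        mmap = lm.default_marker_map(2)
        data = lm.HalfSibDataset(mmap, [fam_with_counts(20, 2, "s1"),
                                        fam_with_counts(30, 1, "s2")])
        adj = lm.adjacent_rates(lm.infer_origins(data))
        row = adj.table.iloc[0]
        assert row["n_inf"] == 50 and row["n_rec"] == 3
        assert row["theta"] == pytest.approx(0.06)

    def test_binomial_recovery_single_interval(self):
        cfg = lm.SimulationConfig(
            n_families=200, n_progeny_per_family=50, p=2, seed=13,
            true_adjacent_theta=np.array([0.1]),
        )
        data, _, _ = lm.simulate_dataset(cfg)
        adj = lm.adjacent_rates(lm.infer_origins(data))
        row = adj.table.iloc[0]
        se = np.sqrt(0.1 * 0.9 / row["n_inf"])
        assert abs(row["theta"] - 0.1) < 3 * se

    def test_no_switches_gives_zero_rates(self):
        cfg = lm.SimulationConfig(
            n_families=10, n_progeny_per_family=20, p=8, seed=4,
            true_adjacent_theta=np.zeros(7),
        )
        data, _, _ = lm.simulate_dataset(cfg)
        adj = lm.adjacent_rates(lm.infer_origins(data))
        theta = adj.table["theta"].to_numpy()
        assert np.nanmax(theta) == 0.0

    def test_globally_noninformative_gap_attributed_to_last_interval(self):
        # middle marker homozygous in every sire: its two intervals form one
        # gap whose pooled rate lands on the second interval (map length is
        # conserved); the first interval stays NA
        prog = np.zeros((30, 3))
        prog[:3, 2] = 2.0  # 3 recombinants across the gap
        fam = make_family([1, 0, 1], prog)
        data = lm.HalfSibDataset(lm.default_marker_map(3), [fam])
        with pytest.warns(UserWarning, match="without informative"):
            adj = lm.adjacent_rates(lm.infer_origins(data))
        assert np.isnan(adj.table.loc[0, "theta"])
        assert adj.table.loc[1, "theta"] == pytest.approx(0.1)
        assert adj.table.loc[1, "n_inf"] == 30


class TestPairwiseRates:
    def test_candidate_pair_count_identity(self):
        assert lm.candidate_pair_count(4) == 6
        assert lm.candidate_pair_count(1415) == 1415 * 1414 // 2

    def test_composition_on_three_markers(self):
        cfg = lm.SimulationConfig(
            n_families=150, n_progeny_per_family=60, p=3, seed=17,
            true_adjacent_theta=np.array([0.12, 0.18]),
        )
        data, _, _ = lm.simulate_dataset(cfg)
        pw = lm.pairwise_rates(lm.infer_origins(data)).table
        th = {(r["i_id"], r["j_id"]): r["theta"] for _, r in pw.iterrows()}
        t12, t23 = th[("c1m1", "c1m2")], th[("c1m2", "c1m3")]
        t13 = th[("c1m1", "c1m3")]
        expected = t12 * (1 - t23) + (1 - t12) * t23
        n13 = pw.set_index(["i_id", "j_id"]).loc[("c1m1", "c1m3"), "n_inf"]
        se = np.sqrt(expected * (1 - expected) / n13)
        assert abs(t13 - expected) < 3 * se

    def test_pair_cap_guard(self, small_sim):
        _, data, _, _ = small_sim
        origins = lm.infer_origins(data)
        with pytest.raises(ValueError, match="max_pairs"):
            lm.pairwise_rates(origins, max_pairs=10)

    def test_column_major_pair_order(self, small_results):
        pw = small_results.pairwise.table
        ids = small_results.qc_data.marker_map.marker_ids
        pos = {m: k for k, m in enumerate(ids)}
        j_idx = pw["j_id"].map(pos).to_numpy()
        i_idx = pw["i_id"].map(pos).to_numpy()
        keys = j_idx * len(ids) + i_idx
        assert (np.diff(keys) > 0).all()
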