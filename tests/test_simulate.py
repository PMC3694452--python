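import math

import numpy as np
import pytest

from sisterrates.clade_rates import clade_branch_sum, extract_pair_subtree
from sisterrates.models import CodonModel, NucModel
from sisterrates.simulate import (
    SimulationConfig,
    generate_study,
    simulate_alignment,
    simulate_pair_tree,
)
from sisterrates.trees import parse_newick, write_newick


class TestSimulatePairTree:
    def test_balanced_clades_and_disjoint_sets(self):
        cfg = SimulationConfig(tips_per_clade=4, seed=1)
        tree, pair = simulate_pair_tree(cfg, 1)
        assert len(pair.parasite) == len(pair.nonparasite) == 4
        assert set(tree.tip_labels) == set(pair.all_tips)

    def test_multiplier_scales_parasite_sum_exactly(self):
        """Same seed with and without the multiplier: the P-clade sum is
        exactly m times its unscaled draw; the NP clade is untouched."""
        base_tree, pair = simulate_pair_tree(
            SimulationConfig(tips_per_clade=4, multiplier=1.0, seed=2), 1
        )
        fast_tree, _ = simulate_pair_tree(
            SimulationConfig(tips_per_clade=4, multiplier=3.0, seed=2), 1
        )
        base = extract_pair_subtree(base_tree, pair)
        fast = extract_pair_subtree(fast_tree, pair)
        assert clade_branch_sum(fast, "P") == pytest.approx(
            3.0 * clade_branch_sum(base, "P"), abs=1e-10
        )
        assert clade_branch_sum(fast, "NP") == pytest.approx(
            clade_branch_sum(base, "NP"), abs=1e-12
        )

    def test_fixed_seed_reproducible(self):
        cfg = SimulationConfig(seed=42)
        t1, p1 = simulate_pair_tree(cfg, 3)
        t2, p2 = simulate_pair_tree(cfg, 3)
        assert write_newick(t1) == write_newick(t2)
        assert p1 == p2

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(tips_per_clade=10)
        with pytest.raises(ValueError):
            SimulationConfig(multiplier=-1)
        with pytest.raises(ValueError):
            SimulationConfig(outgroup_depth=0.1, clade_height=0.15)


class TestSimulateAlignment:
    def test_jc_divergence_matches_closed_form(self):
        t = 0.1
        tree = parse_newick(f"(A:{t},B:0.0);")
        rng = np.random.default_rng(8)
        aln = simulate_alignment(tree, NucModel(ncat=1), 100000, rng)
        diff = sum(
            a != b for a, b in zip(aln.records["A"], aln.records["B"])
        ) / 100000
        expected = 0.75 * (1 - math.exp(-4 * t / 3))
        assert diff == pytest.approx(expected, abs=0.003)

    def test_zero_lengths_give_identical_sequences(self):
        tree = parse_newick("((A:0,B:0):0,C:0);")
        aln = simulate_alignment(tree, NucModel(ncat=1), 500, np.random.default_rng(1))
        assert aln.records["A"] == aln.records["B"] == aln.records["C"]

    def test_root_frequencies_match_model(self):
        freqs = np.array([0.1, 0.2, 0.3, 0.4])
        tree = parse_newick("(A:0.0,B:0.0);")
        n = 30000
        aln = simulate_alignment(
            tree, NucModel(freqs=freqs, ncat=1), n, np.random.default_rng(3)
        )
        counts = np.array([aln.records["A"].count(c) for c in "ACGT"]) / n
        sigma = np.sqrt(freqs * (1 - freqs) / n)
        assert np.all(np.abs(counts - freqs) < 3.5 * sigma)

    def test_codon_alignment_is_coding_and_stop_free(self):
        cfg = SimulationConfig(
            tips_per_clade=2, model=CodonModel(), seq_length=200, seed=4
        )
        rng = np.random.default_rng(4)
        tree, pair = simulate_pair_tree(cfg, 1, rng)
        aln = simulate_alignment(tree, cfg.model, 200, rng)
        assert aln.n_columns == 600
        assert aln.partitions[0].coding
        for seq in aln.records.values():
            for k in range(0, 600, 3):
                assert seq[k : k + 3] not in {"TAA", "TAG", "TGA"}


class TestGenerateStudy:
    def test_manifest_matches_clade_sums_on_true_tree(self):
        cfg = SimulationConfig(
            n_pairs=3, tips_per_clade=3, multiplier=2.5, seq_length=50, seed=6
        )
        study = generate_study(cfg)
        for pair, tree, row in zip(
            study.pairs, study.trees, study.manifest.itertuples()
        ):
            sub = extract_pair_subtree(tree, pair)
            assert clade_branch_sum(sub, "P") == pytest.approx(
                row.true_P_sum, abs=1e-9
            )
            assert clade_branch_sum(sub, "NP") == pytest.approx(
                row.true_NP_sum, abs=1e-9
            )

    def test_study_bit_reproducible(self):
        cfg = SimulationConfig(n_pairs=2, seq_length=100, seed=77)
        s1 = generate_study(cfg)
        s2 = generate_study(cfg)
        for a1, a2 in zip(s1.alignments, s2.alignments):
            assert a1.records == a2.records
        for t1, t2 in zip(s1.trees, s2.trees):
            assert write_newick(t1) == write_newick(t2)

    def test_written_study_round_trips(self, tmp_path):
        from sisterrates.alignments import read_alignment
        from sisterrates.pairs import read_pair_config

        cfg = SimulationConfig(n_pairs=2, tips_per_clade=2, seq_length=60, seed=9)
        study = generate_study(cfg)
        cfg_path = study.write(tmp_path)
        pairs, _ = read_pair_config(cfg_path)
        assert [p.pair_id for p in pairs] == [1, 2]
        aln = read_alignment(tmp_path / pairs[0].alignment_path)
        assert aln.records == study.alignments[0].records
        tree = parse_newick((tmp_path / pairs[0].tree_path).read_text())
        assert sorted(tree.tip_labels) == sorted(study.trees[0].tip_labels)
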