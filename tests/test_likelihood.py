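import math

import numpy as np
import pytest

from sisterrates.alignments import Alignment
from sisterrates.likelihood import (
    _TreeIndex,
    log_likelihood,
    optimize_branch_lengths,
)
from sisterrates.models import NucModel, ReversibleEigen
from sisterrates.simulate import SimulationConfig, simulate_alignment, simulate_pair_tree
from sisterrates.trees import parse_newick

JC = NucModel(ncat=1)
_STATE = {"A": 0, "C": 1, "G": 2, "T": 3}


def brute_force_loglik(tree, aln, model):
    """Enumerate all internal-node state assignments; independent of pruning."""
    ix = _TreeIndex(tree)
    eig = ReversibleEigen(model.rate_matrix(), model.freqs)
    rates = model.category_rates()
    internals = [i for i in range(ix.n_nodes) if not ix.is_tip[i]]
    total = 0.0
    ncol = aln.n_columns
    for col in range(ncol):
        site_like = 0.0
        for r in rates:
            P = {i: eig.transition_matrix(ix.lengths[i] * r) for i in range(ix.n_nodes)}
            for assign in np.ndindex(*([4] * len(internals))):
                state = dict(zip(internals, assign))
                like = model.freqs[state[ix.root]]
                for i in range(ix.n_nodes):
                    if i == ix.root:
                        continue
                    parent_state = state[ix.parent[i]]
                    if ix.is_tip[i]:
                        ch = aln.records[ix.labels[i]][col]
                        if ch in _STATE:
                            like *= P[i][parent_state, _STATE[ch]]
                    else:
                        like *= P[i][parent_state, state[i]]
                site_like += like
        total += math.log(site_like / len(rates))
    return total


def test_jc_closed_form_two_tips():
    for t, chars in [(0.05, "AA"), (0.3, "AC"), (1.2, "GG")]:
        tree = parse_newick(f"(A:{t / 2},B:{t / 2});")
        aln = Alignment({"A": chars[0], "B": chars[1]})
        ll = log_likelihood(tree, aln, JC)
        e = math.exp(-4 * t / 3)
        if chars[0] == chars[1]:
            closed = math.log(0.25 * (0.25 + 0.75 * e))
        else:
            closed = math.log(0.25 * (0.25 - 0.25 * e))
        assert ll == pytest.approx(closed, abs=1e-12)


def test_pruning_matches_enumeration_small_trees(rng):
    """Exhaustive check on 3- and 4-tip trees with gamma rates and gaps."""
    cases = [
        ("((A:0.1,B:0.25):0.08,C:0.4);", ["ACGT", "AAG-", "TCGN"]),
        ("((A:0.15,B:0.3):0.1,(C:0.2,D:0.05):0.12);", ["ACGTAC", "A-GTAA", "CCGTNN", "ACTTAC"]),
    ]
    for nwk, seqs in cases:
        tree = parse_newick(nwk)
        labels = sorted(tree.tip_labels)
        aln = Alignment(dict(zip(labels, seqs)))
        model = NucModel(
            rates=rng.uniform(0.5, 2.0, 6),
            freqs=[0.1, 0.2, 0.3, 0.4],
            alpha=0.7,
            ncat=3,
        )
        assert log_likelihood(tree, aln, model) == pytest.approx(
            brute_force_loglik(tree, aln, model), abs=1e-10
        )


def test_all_gap_column_contributes_zero():
    tree = parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
    base = Alignment({"A": "AC", "B": "AG", "C": "AT"})
    padded = Alignment({"A": "AC-", "B": "AG-", "C": "AT-"})
    assert log_likelihood(tree, padded, JC) == pytest.approx(
        log_likelihood(tree, base, JC), abs=1e-12
    )


def test_likelihood_invariant_to_rerooting(rng):
    cfg = SimulationConfig(
        tips_per_clade=3, model=NucModel(ncat=1), seq_length=200, seed=5
    )
    local = np.random.default_rng(5)
    tree, _ = simulate_pair_tree(cfg, 1, local)
    aln = simulate_alignment(tree, cfg.model, 200, local)
    model = NucModel(rates=[1.5, 2.0, 0.7, 1.2, 2.4, 1.0], freqs=[0.3, 0.2, 0.25, 0.25], ncat=1)
    ll = log_likelihood(tree, aln, model)
    re = tree.clone()
    inner = [
        nd
        for nd in re.dtree.preorder_node_iter()
        if nd.parent_node is not None and not nd.is_leaf()
    ]
    edge = inner[len(inner) // 2].edge
    half = edge.length / 2
    re.dtree.reroot_at_edge(edge, length1=half, length2=half)
    assert log_likelihood(re, aln, model) == pytest.approx(ll, abs=1e-9)


def test_tip_without_sequence_raises():
    tree = parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
    aln = Alignment({"A": "AC", "B": "AG"})
    with pytest.raises(ValueError, match="without sequences"):
        log_likelihood(tree, aln, JC)


class TestOptimizeBranchLengths:
    def test_identical_sequences_shrink_to_zero(self):
        tree = parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        aln = Alignment({l: "ACGTACGT" for l in "ABC"})
        fit = optimize_branch_lengths(tree, aln, JC, fixed_params=True)
        assert fit.total_length < 1e-5

    def test_recovers_simulated_lengths(self):
        cfg = SimulationConfig(
            tips_per_clade=2, model=NucModel(ncat=1), seq_length=20000, seed=9
        )
        local = np.random.default_rng(9)
        tree, _ = simulate_pair_tree(cfg, 1, local)
        aln = simulate_alignment(tree, cfg.model, 20000, local)
        fit = optimize_branch_lengths(tree, aln, JC, fixed_params=True)
        assert fit.total_length == pytest.approx(tree.total_length(), rel=0.05)

    def test_trace_monotone_and_restart_is_fixed_point(self):
        cfg = SimulationConfig(
            tips_per_clade=2, model=NucModel(ncat=1), seq_length=500, seed=13
        )
        local = np.random.default_rng(13)
        tree, _ = simulate_pair_tree(cfg, 1, local)
        aln = simulate_alignment(tree, cfg.model, 500, local)
        fit = optimize_branch_lengths(tree, aln, JC, fixed_params=True)
        assert all(b >= a - 1e-9 for a, b in zip(fit.trace, fit.trace[1:]))
        fit2 = optimize_branch_lengths(fit.tree, aln, JC, fixed_params=True)
        assert abs(fit2.logL - fit.logL) < 1e-6
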