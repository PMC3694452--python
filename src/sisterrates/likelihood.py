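"""Maximum-likelihood branch-length estimation under GTR+G and GY94.

The engine computes exact log-likelihoods by Felsenstein pruning over
compressed site patterns, with per-node rescaling to avoid underflow, and
fits branch lengths by coordinate-wise Brent line searches.  Each edge's
one-dimensional likelihood profile is evaluated cheaply from "inside"
(below-edge) and "outside" (rest-of-tree) conditional likelihoods, which are
maintained incrementally during a pre-order sweep; this is the standard
one-branch-at-a-time scheme used by ML phylogenetics programs.

Free model parameters (GTR exchangeabilities and gamma shape; kappa and the
omega set for codon fits) are interleaved with branch-length sweeps until the
log-likelihood converges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .alignments import Alignment, Partition
from .models import (
    CODON_INDEX,
    CodonModel,
    NucModel,
    ReversibleEigen,
    build_gy94_matrix,
    empirical_nucleotide_frequencies,
    f3x4_frequencies,
    flux_fractions,
)
from .trees import Tree

__all__ = [
    "BranchRates",
    "FitResult",
    "log_likelihood",
    "optimize_branch_lengths",
    "fit_codon_model",
    "dn_ds_decompose",
]

MAX_BRANCH_LENGTH = 20.0
OMEGA_BOUNDS = (1e-4, 99.0)
_TINY = 1e-300


# ---------------------------------------------------------------------------
# tree indexing
# ---------------------------------------------------------------------------


class _TreeIndex:
    """Array view of a tree: nodes in postorder, root last."""

    def __init__(self, tree: Tree):
        nodes = list(tree.dtree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self.node_of = {id(nd): i for i, nd in enumerate(nodes)}
        self.nodes = nodes
        self.root = self.n_nodes - 1
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.lengths = np.zeros(self.n_nodes)
        self.is_tip = np.zeros(self.n_nodes, dtype=bool)
        self.labels: list[str | None] = [None] * self.n_nodes
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self.node_of[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.lengths[i] = nd.edge.length if nd.edge.length else 0.0
            if nd.is_leaf():
                self.is_tip[i] = True
                self.labels[i] = nd.taxon.label
        self.tip_ids = {
            self.labels[i]: i for i in range(self.n_nodes) if self.is_tip[i]
        }
        self.postorder = list(range(self.n_nodes))
        self.edge_nodes = [i for i in range(self.n_nodes) if i != self.root]

    def descendant_tips(self) -> list[set[str]]:
        out: list[set[str]] = [set() for _ in range(self.n_nodes)]
        for i in self.postorder:
            if self.is_tip[i]:
                out[i] = {self.labels[i]}
            for c in self.children[i]:
                out[i] |= out[c]
        return out

    def write_lengths(self, lengths: np.ndarray) -> None:
        for i, nd in enumerate(self.nodes):
            if nd.parent_node is not None:
                nd.edge.length = float(lengths[i])


# ---------------------------------------------------------------------------
# data encoding
# ---------------------------------------------------------------------------

_NUC_STATE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _compress(mat: np.ndarray):
    """Column-pattern compression: unique columns + multiplicities."""
    patterns, counts = np.unique(mat, axis=1, return_counts=True)
    return patterns, counts.astype(float)


def encode_nucleotide(aln: Alignment, labels):
    """Tip partial-likelihood arrays over compressed nucleotide patterns."""
    mat = np.array(
        [[_NUC_STATE.get(ch, -1) for ch in aln.records[l]] for l in labels],
        dtype=np.int8,
    )
    patterns, weights = _compress(mat)
    partials = {}
    for r, label in enumerate(labels):
        part = np.ones((patterns.shape[1], 4))
        known = patterns[r] >= 0
        part[known] = 0.0
        part[np.flatnonzero(known), patterns[r, known]] = 1.0
        partials[label] = part
    return partials, weights


def codon_columns(aln: Alignment, partition: Partition | None = None) -> slice:
    if partition is not None:
        if not partition.coding:
            raise ValueError(f"partition {partition.name!r} is not coding")
        return slice(partition.start + partition.frame, partition.end)
    if aln.n_columns % 3:
        raise ValueError("alignment length not divisible by 3")
    return slice(0, aln.n_columns)


def encode_codon(aln: Alignment, labels, partition: Partition | None = None):
    """Tip partials over compressed codon patterns (61 sense-codon states).

    Codons containing gaps or ambiguity, and stop codons, are treated as
    fully missing data.
    """
    sl = codon_columns(aln, partition)
    rows = []
    for l in labels:
        seq = aln.records[l][sl]
        states = [
            CODON_INDEX.get(seq[k : k + 3], -1) for k in range(0, len(seq), 3)
        ]
        rows.append(states)
    mat = np.array(rows, dtype=np.int16)
    patterns, weights = _compress(mat)
    partials = {}
    for r, label in enumerate(labels):
        part = np.ones((patterns.shape[1], 61))
        known = patterns[r] >= 0
        part[known] = 0.0
        part[np.flatnonzero(known), patterns[r, known]] = 1.0
        partials[label] = part
    return partials, weights


# ---------------------------------------------------------------------------
# pruning engine
# ---------------------------------------------------------------------------


class PruningEngine:
    """Pruning likelihood with per-edge profile evaluation.

    Holds the indexed topology, tip partials over compressed patterns, the
    stationary distribution, and a transition-matrix provider (a shared
    eigendecomposition with per-category rates, or per-edge decompositions
    for free-ratio codon fits).
    """

    def __init__(self, index: _TreeIndex, tip_partials, weights, pi, cat_rates=None):
        self.ix = index
        self.w = np.asarray(weights, dtype=float)
        self.pi = np.asarray(pi, dtype=float)
        self.cat_rates = (
            np.ones(1) if cat_rates is None else np.asarray(cat_rates, dtype=float)
        )
        self.ncat = len(self.cat_rates)
        self.npat = len(self.w)
        self.ns = len(self.pi)
        self.tipD = {
            index.tip_ids[lab]: part for lab, part in tip_partials.items()
        }
        self.eigen: ReversibleEigen | None = None
        self.edge_eigens: list[ReversibleEigen | None] | None = None

    # -- transition matrices ------------------------------------------
    def set_shared_eigen(self, eigen: ReversibleEigen):
        self.eigen = eigen
        self.edge_eigens = None

    def set_edge_eigens(self, eigens):
        self.edge_eigens = list(eigens)
        self.eigen = None

    def edge_P(self, node: int, t: float) -> np.ndarray:
        eig = self.eigen if self.edge_eigens is None else self.edge_eigens[node]
        return eig.transition_matrices(self.cat_rates * t)

    # -- partials ------------------------------------------------------
    def _edge_contrib(self, node, t, D, S):
        """P(t) applied to the below-node partial; returns (value, log-scaler)."""
        P = self.edge_P(node, t)
        if self.ix.is_tip[node]:
            val = np.einsum("kij,pj->kpi", P, self.tipD[node])
            sc = np.zeros((self.ncat, self.npat))
        else:
            val = np.einsum("kij,kpj->kpi", P, D[node])
            sc = S[node]
        return val, sc

    def _node_partial(self, v, lengths, D, S):
        """Recompute the below partial of internal node v from its children."""
        prod = np.ones((self.ncat, self.npat, self.ns))
        sc = np.zeros((self.ncat, self.npat))
        for c in self.ix.children[v]:
            val, s = self._edge_contrib(c, lengths[c], D, S)
            prod = prod * val
            sc = sc + s
        m = prod.max(axis=2)
        m = np.where(m > 0, m, 1.0)
        return prod / m[:, :, None], sc + np.log(m)

    def _uppass(self, lengths):
        D: dict[int, np.ndarray] = {}
        S: dict[int, np.ndarray] = {}
        for v in self.ix.postorder:
            if not self.ix.is_tip[v]:
                D[v], S[v] = self._node_partial(v, lengths, D, S)
        return D, S

    def loglik(self, lengths) -> float:
        D, S = self._uppass(lengths)
        root = self.ix.root
        site = np.einsum("i,kpi->kp", self.pi, D[root])
        M = S[root].max(axis=0)
        tot = (site * np.exp(S[root] - M[None, :])).sum(axis=0) / self.ncat
        return float((self.w * (np.log(np.maximum(tot, _TINY)) + M)).sum())

    # -- one-branch-at-a-time optimization ----------------------------
    def _edge_profile(self, v, U_pi, Dv, B):
        """Return f(t) = log-likelihood of the tree as a function of edge v's
        length, up to an additive constant shared across t."""
        tip = self.ix.is_tip[v]

        def f(t):
            P = self.edge_P(v, t)
            if tip:
                contrib = np.einsum("kij,pj->kpi", P, Dv)
            else:
                contrib = np.einsum("kij,kpj->kpi", P, Dv)
            site = np.einsum("kpi,kpi->kp", U_pi, contrib)
            tot = (site * B).sum(axis=0)
            return float((self.w * np.log(np.maximum(tot, _TINY))).sum())

        return f

    def _optimize_edge(self, f, t0):
        best = f(t0)
        res = minimize_scalar(
            lambda t: -f(t),
            bounds=(0.0, MAX_BRANCH_LENGTH),
            method="bounded",
            options={"xatol": 1e-7},
        )
        if -res.fun > best:
            return float(res.x)
        return float(t0)

    def sweep(self, lengths, omega_step=None):
        """One pre-order pass optimizing every edge length in place.

        ``omega_step(node, U_pi, Dv, B, lengths)`` is an optional hook called
        per edge after the length update (used by free-ratio codon fits to
        re-optimize that edge's omega with the same cached partials).
        """
        ix = self.ix
        D, S = self._uppass(lengths)
        O: dict[int, np.ndarray] = {
            ix.root: np.ones((self.ncat, self.npat, self.ns))
        }
        SO: dict[int, np.ndarray] = {ix.root: np.zeros((self.ncat, self.npat))}

        def visit(u):
            kids = ix.children[u]
            for v in kids:
                U = O[u].copy()
                SU = SO[u].copy()
                for s2 in kids:
                    if s2 == v:
                        continue
                    val, sc = self._edge_contrib(s2, lengths[s2], D, S)
                    U = U * val
                    SU = SU + sc
                m = U.max(axis=2)
                m = np.where(m > 0, m, 1.0)
                U /= m[:, :, None]
                SU = SU + np.log(m)
                if ix.is_tip[v]:
                    Dv, SDv = self.tipD[v], np.zeros((self.ncat, self.npat))
                else:
                    Dv, SDv = D[v], S[v]
                SC = SU + SDv
                B = np.exp(SC - SC.max(axis=0)[None, :])
                U_pi = U * self.pi[None, None, :]
                f = self._edge_profile(v, U_pi, Dv, B)
                lengths[v] = self._optimize_edge(f, lengths[v])
                if omega_step is not None:
                    omega_step(v, U_pi, Dv, B, lengths)
                if not ix.is_tip[v]:
                    P = self.edge_P(v, lengths[v])
                    Ov = np.einsum("kij,kpj->kpi", P, U)
                    m2 = Ov.max(axis=2)
                    m2 = np.where(m2 > 0, m2, 1.0)
                    O[v] = Ov / m2[:, :, None]
                    SO[v] = SU + np.log(m2)
                    visit(v)
                    del O[v], SO[v]
                    D[v], S[v] = self._node_partial(v, lengths, D, S)

        visit(ix.root)
        return lengths


# ---------------------------------------------------------------------------
# public API: nucleotide fits
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """An ML fit: tree with fitted lengths, fitted model, log-likelihood."""

    tree: Tree
    model: object
    logL: float
    trace: list[float] = field(default_factory=list)
    n_patterns: int = 0

    @property
    def total_length(self) -> float:
        return self.tree.total_length()


def _init_lengths(index: _TreeIndex) -> np.ndarray:
    lengths = index.lengths.copy()
    missing = ~index.is_tip & (lengths <= 0)
    lengths[lengths <= 0] = 0.05
    lengths[index.root] = 0.0
    return lengths


def _nuc_engine(tree: Tree, aln: Alignment, model: NucModel):
    index = _TreeIndex(tree)
    missing = [l for l in index.tip_ids if l not in aln.records]
    if missing:
        raise ValueError(f"tree tips without sequences: {sorted(missing)}")
    partials, weights = encode_nucleotide(aln, list(index.tip_ids))
    eng = PruningEngine(
        index, partials, weights, model.freqs, model.category_rates()
    )
    eng.set_shared_eigen(ReversibleEigen(model.rate_matrix(), model.freqs))
    return index, eng


def log_likelihood(tree: Tree, aln: Alignment, model, partition=None) -> float:
    """Exact log-likelihood of the alignment on the tree under the model.

    Dispatches on model type: :class:`NucModel` (with discrete-gamma mixing)
    or :class:`CodonModel` (single omega).  Branch lengths are read from the
    tree; missing lengths count as 0.
    """
    if isinstance(model, NucModel):
        index, eng = _nuc_engine(tree, aln, model)
        return eng.loglik(index.lengths.copy())
    if isinstance(model, CodonModel):
        index = _TreeIndex(tree)
        partials, weights = encode_codon(aln, list(index.tip_ids), partition)
        eng = PruningEngine(index, partials, weights, model.freqs)
        eng.set_shared_eigen(
            ReversibleEigen(model.rate_matrix(), model.freqs)
        )
        return eng.loglik(index.lengths.copy())
    raise TypeError(f"unsupported model type: {type(model).__name__}")


def optimize_branch_lengths(
    tree: Tree,
    aln: Alignment,
    model: NucModel | None = None,
    fixed_params: bool = False,
    tol: float = 1e-6,
    max_rounds: int = 50,
) -> FitResult:
    """ML branch lengths (and optionally GTR+G parameters) for an alignment.

    Coordinate-wise Brent optimization over each edge length in ``[0, 20]``
    interleaved (unless ``fixed_params``) with Nelder-Mead optimization of
    the exchangeabilities and gamma shape, iterated until the log-likelihood
    improves by less than ``tol``.  Base frequencies are the empirical
    frequencies of the alignment.  The returned trace is non-decreasing.
    """
    if model is None:
        model = NucModel(freqs=empirical_nucleotide_frequencies(aln.records.values()))
    index, eng = _nuc_engine(tree, aln, model)
    lengths = _init_lengths(index)
    trace = [eng.loglik(lengths)]
    params_converged = fixed_params
    for round_i in range(max_rounds):
        eng.sweep(lengths)
        if not params_converged:
            model, gain = _optimize_gtr_params(
                eng, model, lengths, budget=60 if round_i == 0 else 25
            )
            if gain < 0.1 * tol:
                params_converged = True
        cur = eng.loglik(lengths)
        trace.append(max(cur, trace[-1]))
        if trace[-1] - trace[-2] < tol:
            break
    fitted = tree.clone()
    fidx = _TreeIndex(fitted)
    fidx.write_lengths(lengths)
    return FitResult(fitted, model, trace[-1], trace, eng.npat)


def _optimize_gtr_params(
    eng: PruningEngine, model: NucModel, lengths, budget: int = 40
):
    """Quasi-Newton step over log exchangeabilities (GT fixed at 1) and log
    alpha, with finite-difference gradients.  Returns (model, logL gain)."""
    free_alpha = model.ncat > 1
    x0 = np.log(model.rates[:5])
    if free_alpha:
        x0 = np.append(x0, np.log(model.alpha))

    def rebuild(x) -> NucModel:
        rates = np.append(np.exp(np.clip(x[:5], -12, 12)), 1.0)
        alpha = float(np.exp(np.clip(x[5], -7, 14))) if free_alpha else model.alpha
        return NucModel(
            rates=rates, freqs=model.freqs, alpha=min(alpha, 1e6), ncat=model.ncat
        )

    def apply(m: NucModel):
        eng.set_shared_eigen(ReversibleEigen(m.rate_matrix(), m.freqs))
        eng.cat_rates = m.category_rates()
        eng.ncat = len(eng.cat_rates)

    def nll(x):
        apply(rebuild(x))
        return -eng.loglik(lengths)

    base = nll(x0)
    res = minimize(
        nll,
        x0,
        method="L-BFGS-B",
        options={"maxiter": budget, "ftol": 1e-11, "eps": 1e-5},
    )
    x = res.x if res.fun < base else x0
    best = rebuild(x)
    apply(best)
    return best, max(0.0, base - min(res.fun, base))


# ---------------------------------------------------------------------------
# codon fits
# ---------------------------------------------------------------------------


def dn_ds_decompose(t: float, omega: float, model: CodonModel):
    """Split a codon branch length into (dN, dS).

    The fitted matrix's equilibrium substitution flux is partitioned into
    nonsynonymous and synonymous fractions (rho_N, rho_S); site proportions
    (pi_N, pi_S) come from the same model with omega set to 1 (the
    mutational-opportunity convention).  Then dN = t rho_N / (3 pi_N) and
    dS = t rho_S / (3 pi_S), so t = 3 (dN pi_N + dS pi_S) by construction.
    """
    rhoN, rhoS = flux_fractions(model.kappa, omega, model.freqs)
    piN, piS = flux_fractions(model.kappa, 1.0, model.freqs)
    if piN <= 0 or piS <= 0:
        raise ValueError("degenerate codon frequencies: no syn or nonsyn sites")
    return t * rhoN / (3 * piN), t * rhoS / (3 * piS)


@dataclass
class BranchRates:
    """Per-edge codon-model rates plus shared model quantities.

    ``edges`` has one row per edge (child node label or internal id) with
    columns t, omega, dN, dS and the clade class used in per-clade fits.
    ``site_proportions`` holds (pi_N, pi_S); N and S sites per codon are
    3 pi_N and 3 pi_S.
    """

    edges: pd.DataFrame
    kappa: float
    omega_by_class: dict[str, float]
    site_proportions: tuple[float, float]
    logL: float
    tree: Tree
    model: CodonModel

    def clade_sum(self, column: str, cls: str) -> float:
        sel = self.edges[self.edges["clade"] == cls]
        return float(sel[column].sum())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# kappa\t{self.kappa:.6g}\n")
            piN, piS = self.site_proportions
            fh.write(f"# N_sites_per_codon\t{3 * piN:.6g}\n")
            fh.write(f"# S_sites_per_codon\t{3 * piS:.6g}\n")
            for cls, w in sorted(self.omega_by_class.items()):
                fh.write(f"# omega[{cls}]\t{w:.6g}\n")
            fh.write(f"# logL\t{self.logL:.6f}\n")
            self.edges.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _classify_edges(index: _TreeIndex, pair) -> np.ndarray:
    """Label every edge P / NP / other by its descendant tip set."""
    desc = index.descendant_tips()
    classes = np.array(["other"] * index.n_nodes, dtype=object)
    for i in index.edge_nodes:
        if desc[i] <= pair.parasite:
            classes[i] = "P"
        elif desc[i] <= pair.nonparasite:
            classes[i] = "NP"
    return classes


def fit_codon_model(
    tree: Tree,
    aln: Alignment,
    parameterization: str = "free",
    pair=None,
    partition: Partition | None = None,
    kappa0: float = 2.0,
    omega0: float = 0.4,
    tol: float = 1e-5,
    max_rounds: int = 30,
) -> BranchRates:
    """Fit GY94 by maximum likelihood and decompose branch lengths.

    ``parameterization`` is ``"single"`` (one omega), ``"free"`` (an
    independent omega on every edge) or ``"per-clade"`` (one omega for the
    parasitic clade's edges, one for the non-parasitic clade's, one for the
    rest; requires ``pair``).  Codon frequencies are F3x4 from the data;
    kappa is estimated; branch lengths are expected substitutions per codon.
    """
    if parameterization not in {"single", "free", "per-clade"}:
        raise ValueError(f"unknown parameterization: {parameterization!r}")
    if parameterization == "per-clade" and pair is None:
        raise ValueError("per-clade fit needs a ComparisonPair")

    index = _TreeIndex(tree)
    labels = list(index.tip_ids)
    missing = [l for l in labels if l not in aln.records]
    if missing:
        raise ValueError(f"tree tips without sequences: {sorted(missing)}")
    sl = codon_columns(aln, partition)
    freqs = f3x4_frequencies(
        np.array([list(aln.records[l][sl]) for l in labels])
    )
    partials, weights = encode_codon(aln, labels, partition)
    if len(weights) < 2:
        import warnings

        warnings.warn("fewer than 2 codon patterns: degenerate fit")
    eng = PruningEngine(index, partials, weights, freqs)

    if parameterization == "per-clade":
        classes = _classify_edges(index, pair)
    elif parameterization == "single":
        classes = np.array(["all"] * index.n_nodes, dtype=object)
    else:
        classes = np.array(
            [f"edge{i}" for i in range(index.n_nodes)], dtype=object
        )
    class_names = sorted({classes[i] for i in index.edge_nodes})
    omega_of = {cls: omega0 for cls in class_names}
    kappa = kappa0

    eig_cache: dict[tuple[float, float], ReversibleEigen] = {}

    def eigen_for(om: float) -> ReversibleEigen:
        key = (kappa, om)
        if key not in eig_cache:
            eig_cache[key] = ReversibleEigen(
                build_gy94_matrix(kappa, om, freqs), freqs
            )
        return eig_cache[key]

    def refresh_eigens():
        eng.set_edge_eigens(
            [eigen_for(omega_of[classes[i]]) if i != index.root else None
             for i in range(index.n_nodes)]
        )

    refresh_eigens()
    lengths = _init_lengths(index)
    trace = [eng.loglik(lengths)]

    def free_omega_step(v, U_pi, Dv, B, lens):
        # re-optimize this edge's omega with partials fixed, then its length
        tip = index.is_tip[v]

        def g(logw):
            om = float(np.exp(logw))
            P = eigen_for(om).transition_matrices(np.array([lens[v]]))
            if tip:
                contrib = np.einsum("kij,pj->kpi", P, Dv)
            else:
                contrib = np.einsum("kij,kpj->kpi", P, Dv)
            site = np.einsum("kpi,kpi->kp", U_pi, contrib)
            tot = (site * B).sum(axis=0)
            return -float((eng.w * np.log(np.maximum(tot, _TINY))).sum())

        cur = np.log(omega_of[classes[v]])
        res = minimize_scalar(
            g,
            bounds=np.log(OMEGA_BOUNDS),
            method="bounded",
            options={"xatol": 1e-4},
        )
        if res.fun < g(cur):
            omega_of[classes[v]] = float(np.exp(res.x))
        eng.edge_eigens[v] = eigen_for(omega_of[classes[v]])
        f = eng._edge_profile(v, U_pi, Dv, B)
        lens[v] = eng._optimize_edge(f, lens[v])

    def full_nll_omega(cls, logw):
        saved = omega_of[cls]
        omega_of[cls] = float(np.exp(logw))
        refresh_eigens()
        val = -eng.loglik(lengths)
        omega_of[cls] = saved
        return val

    def full_nll_kappa(logk):
        nonlocal kappa
        saved = kappa
        kappa = float(np.exp(logk))
        eig_cache.clear()
        refresh_eigens()
        val = -eng.loglik(lengths)
        kappa = saved
        eig_cache.clear()
        return val

    for _ in range(max_rounds):
        if parameterization == "free":
            eng.sweep(lengths, omega_step=free_omega_step)
        else:
            eng.sweep(lengths)
            current = -eng.loglik(lengths)
            for cls in class_names:
                res = minimize_scalar(
                    lambda lw: full_nll_omega(cls, lw),
                    bounds=np.log(OMEGA_BOUNDS),
                    method="bounded",
                    options={"xatol": 1e-5},
                )
                if res.fun < current:
                    omega_of[cls] = float(np.exp(res.x))
                    current = res.fun
                refresh_eigens()
        # kappa step (shared by all parameterizations)
        current = -eng.loglik(lengths)
        res = minimize_scalar(
            full_nll_kappa,
            bounds=(np.log(0.05), np.log(100.0)),
            method="bounded",
            options={"xatol": 1e-5},
        )
        if res.fun < current:
            kappa = float(np.exp(res.x))
        eig_cache.clear()
        refresh_eigens()
        cur = eng.loglik(lengths)
        trace.append(max(cur, trace[-1]))
        if trace[-1] - trace[-2] < tol:
            break

    model = CodonModel(kappa=kappa, omega=1.0, freqs=freqs)
    piN, piS = flux_fractions(kappa, 1.0, freqs)
    rows = []
    clade_classes = (
        _classify_edges(index, pair) if pair is not None else None
    )
    for i in index.edge_nodes:
        om = omega_of[classes[i]]
        dN, dS = dn_ds_decompose(lengths[i], om, model)
        rows.append(
            {
                "child": index.labels[i] or f"node{i}",
                "clade": clade_classes[i] if clade_classes is not None else classes[i],
                "t": lengths[i],
                "omega": om,
                "dN": dN,
                "dS": dS,
            }
        )
    fitted = tree.clone()
    fitted.unit = "codon"
    fidx = _TreeIndex(fitted)
    fidx.write_lengths(lengths)
    return BranchRates(
        edges=pd.DataFrame(rows),
        kappa=kappa,
        omega_by_class=dict(omega_of),
        site_proportions=(piN, piS),
        logL=trace[-1],
        tree=fitted,
        model=model,
    )
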