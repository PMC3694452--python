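"""Synthetic sister-pair studies with known ground truth.

Each simulated comparison is a balanced pair of ultrametric Yule clades of
equal tip count joined at a shared node, plus an outgroup, with every edge on
the "parasitic" side (stem included) multiplied by a rate factor m.
Sequences evolve along the true tree under GTR+G or GY94 by drawing the root
state from the stationary distribution and transitioning edge-wise with the
model's matrix exponential.  A fixed seed makes the whole study
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignments import Alignment, Partition
from .likelihood import _classify_edges, _TreeIndex
from .models import (
    CodonModel,
    NucModel,
    ReversibleEigen,
    SENSE_CODONS,
    build_gy94_matrix,
)
from .pairs import ComparisonPair, write_pair_config
from .trees import Tree, parse_newick, write_newick

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "simulate_pair_tree",
    "simulate_alignment",
    "generate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study design for the synthetic generator.

    Tips per clade is capped at 9 and the two sister clades always have the
    same tip count, mirroring the balanced design that controls the
    node-density effect.  Heights and lengths are expected substitutions per
    site (or per codon for a codon model).  ``multiplier`` scales every
    parasite-side edge including the stem.  Clade-specific omegas for codon
    simulation default to the model's omega when unset.
    """

    n_pairs: int = 12
    tips_per_clade: int = 4
    n_outgroup: int = 1
    clade_height: float = 0.15
    stem_length: float = 0.05
    outgroup_depth: float = 0.35
    multiplier: float = 1.0
    model: object = field(default_factory=NucModel)
    seq_length: int = 2000
    omega_parasite: float | None = None
    omega_nonparasite: float | None = None
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.tips_per_clade <= 9):
            raise ValueError("tips per clade must be between 1 and 9")
        if self.multiplier < 0:
            raise ValueError("rate multiplier must be non-negative")
        if min(self.clade_height, self.stem_length) <= 0:
            raise ValueError("heights and lengths must be positive")
        if self.outgroup_depth <= self.clade_height + self.stem_length:
            raise ValueError(
                "outgroup depth must exceed clade height + stem length"
            )
        if self.n_pairs < 1 or self.n_outgroup < 1 or self.seq_length < 1:
            raise ValueError("counts must be positive")


class _Lineage:
    __slots__ = ("start", "end", "children", "label")

    def __init__(self, start: float):
        self.start = start
        self.end = None
        self.children = None
        self.label = None

    def walk(self):
        yield self
        if self.children:
            for c in self.children:
                yield from c.walk()


def _simulate_yule(labels, height: float, rng) -> _Lineage:
    """Ultrametric Yule clade: the crown split is the clade root (time 0),
    later splits follow exponential waits, and the whole history is scaled
    so every tip sits at depth ``height``."""
    labels = list(labels)
    n = len(labels)
    root = _Lineage(0.0)
    if n == 1:
        root.label = labels[0]
        root.end = height
        return root
    rel = [0.0]
    t = 0.0
    for k in range(2, n):
        t += rng.exponential(1.0 / k)
        rel.append(t)
    total = t + rng.exponential(1.0 / n)
    scale = height / total
    active = [root]
    for s in rel:
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.end = s * scale
        parent.children = (_Lineage(parent.end), _Lineage(parent.end))
        active.extend(parent.children)
    for lab, idx in zip(labels, rng.permutation(len(active))):
        active[idx].label = lab
        active[idx].end = height
    return root


def _render(node: _Lineage, factor: float, root_length: float) -> str:
    def rec(nd: _Lineage, length: float) -> str:
        if nd.children is None:
            return f"{nd.label}:{length:.10g}"
        inner = ",".join(
            rec(c, (c.end - c.start) * factor) for c in nd.children
        )
        return f"({inner}):{length:.10g}"

    return rec(node, root_length)


def _clade_edge_sum(root: _Lineage) -> float:
    """Total branch length inside the clade, excluding the stem.

    A single-tip clade has no internal edges; its height is carried on the
    stem-plus-terminal edge (see :func:`_clade_text`)."""
    if root.children is None:
        return root.end - root.start
    return sum(nd.end - nd.start for nd in root.walk() if nd is not root)


def _clade_text(root: _Lineage, factor: float, stem: float, height: float) -> str:
    if root.children is None:
        return f"{root.label}:{(stem + height) * factor:.10g}"
    return _render(root, factor, stem * factor)


def _simulate_pair(cfg: SimulationConfig, pair_id: int, rng):
    k = cfg.tips_per_clade
    p_tips = [f"P{pair_id}t{i + 1}" for i in range(k)]
    np_tips = [f"N{pair_id}t{i + 1}" for i in range(k)]
    og_tips = [f"OG{pair_id}x{i + 1}" for i in range(cfg.n_outgroup)]
    m = cfg.multiplier

    p_root = _simulate_yule(p_tips, cfg.clade_height, rng)
    np_root = _simulate_yule(np_tips, cfg.clade_height, rng)
    p_txt = _clade_text(p_root, m, cfg.stem_length, cfg.clade_height)
    np_txt = _clade_text(np_root, 1.0, cfg.stem_length, cfg.clade_height)
    d0 = cfg.outgroup_depth - cfg.clade_height - cfg.stem_length
    if cfg.n_outgroup == 1:
        og_txt = f"{og_tips[0]}:{cfg.outgroup_depth:.10g}"
    else:
        og_root = _simulate_yule(og_tips, cfg.clade_height, rng)
        og_txt = _render(
            og_root, 1.0, cfg.outgroup_depth - cfg.clade_height
        )
    newick = f"({og_txt},({p_txt},{np_txt}):{d0:.10g});"
    tree = parse_newick(newick)
    pair = ComparisonPair(
        pair_id=pair_id,
        parasite=frozenset(p_tips),
        nonparasite=frozenset(np_tips),
        outgroup=frozenset(og_tips),
    )
    # independent bookkeeping of the true clade sums (stem included)
    true_p = m * (cfg.stem_length + _clade_edge_sum(p_root))
    true_np = cfg.stem_length + _clade_edge_sum(np_root)
    return tree, pair, true_p, true_np


def simulate_pair_tree(cfg: SimulationConfig, pair_id: int = 1, rng=None):
    """One comparison's true tree and pair definition.

    Under multiplier m the parasite clade's true branch-length sum is exactly
    m times the non-parasite sum in expectation (and exactly m times its own
    unscaled sum by construction).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    tree, pair, _, _ = _simulate_pair(cfg, pair_id, rng)
    return tree, pair


def _sample_children(P: np.ndarray, parents: np.ndarray, rng) -> np.ndarray:
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(parents.size)
    return (u[:, None] > cum[parents]).sum(axis=1)


def simulate_alignment(
    tree: Tree,
    model,
    length: int,
    rng=None,
    seed: int | None = None,
    pair: ComparisonPair | None = None,
    omega_parasite: float | None = None,
    omega_nonparasite: float | None = None,
) -> Alignment:
    """Evolve sequences along the tree under the model.

    ``length`` counts sites for a nucleotide model, codons for a codon model.
    The root state is drawn from the stationary distribution; a gamma rate
    category is drawn per site when the model has one; codon simulation runs
    over the 61 sense codons.  Clade-specific omegas (stems included) apply
    when a pair definition is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    ix = _TreeIndex(tree)
    is_codon = isinstance(model, CodonModel)

    if is_codon:
        edge_eigens = _codon_edge_eigens(
            ix, model, pair, omega_parasite, omega_nonparasite
        )
        rates = np.ones(1)
        cat_of_site = np.zeros(length, dtype=int)
    else:
        shared_eigen = ReversibleEigen(model.rate_matrix(), model.freqs)
        edge_eigens = [shared_eigen] * ix.n_nodes
        rates = model.category_rates()
        cat_of_site = rng.integers(0, len(rates), size=length)

    states = {ix.root: rng.choice(model.n_states, size=length, p=model.freqs)}
    seqs: dict[str, np.ndarray] = {}
    for v in reversed(ix.postorder):  # preorder
        if v == ix.root:
            continue
        P = edge_eigens[v].transition_matrices(rates * ix.lengths[v])
        parent_states = states[ix.parent[v]]
        child = np.empty(length, dtype=int)
        for c in range(len(rates)):
            sel = np.flatnonzero(cat_of_site == c)
            if sel.size:
                child[sel] = _sample_children(P[c], parent_states[sel], rng)
        states[v] = child
        if ix.is_tip[v]:
            seqs[ix.labels[v]] = child

    if is_codon:
        records = {
            lab: "".join(SENSE_CODONS[s] for s in st) for lab, st in seqs.items()
        }
        ncol = 3 * length
    else:
        records = {
            lab: "".join("ACGT"[s] for s in st) for lab, st in seqs.items()
        }
        ncol = length
    return Alignment(
        records, partitions=[Partition("sim", 0, ncol, coding=is_codon)]
    )


def _codon_edge_eigens(ix, model, pair, omega_p, omega_np):
    base = ReversibleEigen(model.rate_matrix(), model.freqs)
    if pair is None or (omega_p is None and omega_np is None):
        return [base] * ix.n_nodes
    classes = _classify_edges(ix, pair)
    clade_omega = {
        "P": model.omega if omega_p is None else omega_p,
        "NP": model.omega if omega_np is None else omega_np,
    }
    cache: dict[float, ReversibleEigen] = {model.omega: base}
    eigens = []
    for i in range(ix.n_nodes):
        om = clade_omega.get(classes[i], model.omega)
        if om not in cache:
            cache[om] = ReversibleEigen(
                build_gy94_matrix(model.kappa, om, model.freqs), model.freqs
            )
        eigens.append(cache[om])
    return eigens


@dataclass
class SyntheticStudy:
    """A full synthetic dataset: per-pair true trees, alignments, manifest."""

    config: SimulationConfig
    pairs: list[ComparisonPair]
    trees: list[Tree]
    alignments: list[Alignment]
    manifest: pd.DataFrame

    def write(self, outdir) -> Path:
        """Write the study in the pipeline's input dialects; returns the
        pair-config path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cfg_pairs = []
        for pair, tree, aln in zip(self.pairs, self.trees, self.alignments):
            stem = f"pair{pair.pair_id:02d}"
            (outdir / f"{stem}.nwk").write_text(write_newick(tree) + "\n")
            aln.write_fasta(outdir / f"{stem}.fasta")
            cfg_pairs.append(
                ComparisonPair(
                    pair_id=pair.pair_id,
                    parasite=pair.parasite,
                    nonparasite=pair.nonparasite,
                    outgroup=pair.outgroup,
                    mode=pair.mode,
                    tree_path=f"{stem}.nwk",
                    alignment_path=f"{stem}.fasta",
                )
            )
        write_pair_config(outdir / "pairs.cfg", cfg_pairs)
        self.manifest.to_csv(
            outdir / "manifest.tsv", sep="\t", index=False, float_format="%.10g"
        )
        return outdir / "pairs.cfg"


def generate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Simulate every pair of a study from one seeded generator."""
    rng = np.random.default_rng(cfg.seed)
    is_codon = isinstance(cfg.model, CodonModel)
    pairs, trees, alns, rows = [], [], [], []
    for pid in range(1, cfg.n_pairs + 1):
        tree, pair, true_p, true_np = _simulate_pair(cfg, pid, rng)
        aln = simulate_alignment(
            tree,
            cfg.model,
            cfg.seq_length,
            rng,
            pair=pair if is_codon else None,
            omega_parasite=cfg.omega_parasite,
            omega_nonparasite=cfg.omega_nonparasite,
        )
        pairs.append(pair)
        trees.append(tree)
        alns.append(aln)
        rows.append(
            {
                "pair": pid,
                "true_P_sum": true_p,
                "true_NP_sum": true_np,
                "multiplier": cfg.multiplier,
                "omega_P": cfg.omega_parasite if is_codon else np.nan,
                "omega_NP": cfg.omega_nonparasite if is_codon else np.nan,
            }
        )
    return SyntheticStudy(cfg, pairs, trees, alns, pd.DataFrame(rows))
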