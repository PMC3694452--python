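"""Nucleotide and codon substitution models.

Implements the general time-reversible nucleotide model with discrete-gamma
rate variation (GTR+G) and the Goldman–Yang codon model (GY94) over the 61
sense codons of the universal genetic code.  Rate matrices are scaled so that
branch lengths are expected substitutions per site (nucleotide) or per codon
(codon model) at equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.linalg import eigh
from scipy.special import gammainc
from Bio.Data.CodonTable import unambiguous_dna_by_id

__all__ = [
    "NUCLEOTIDES",
    "SENSE_CODONS",
    "CODON_INDEX",
    "NucModel",
    "CodonModel",
    "build_gtr_matrix",
    "build_gy94_matrix",
    "discrete_gamma",
    "ReversibleEigen",
    "flux_fractions",
    "f3x4_frequencies",
    "empirical_nucleotide_frequencies",
]

NUCLEOTIDES = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
# exchangeability order follows the usual convention
GTR_PAIRS = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]  # AC AG AT CG CT GT

_TABLE = unambiguous_dna_by_id[1]  # universal code
SENSE_CODONS = tuple(
    sorted(c for c in _TABLE.forward_table if set(c) <= set(NUCLEOTIDES))
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)
N_CODONS = len(SENSE_CODONS)  # 61

_PURINES = {"A", "G"}


def _codon_pair_tables():
    """Index arrays over single-nucleotide-difference sense-codon pairs."""
    I, J, is_ts, is_syn = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            I.append(i)
            J.append(j)
            is_ts.append((ci[k] in _PURINES) == (cj[k] in _PURINES))
            is_syn.append(CODON_AA[i] == CODON_AA[j])
    return (
        np.array(I),
        np.array(J),
        np.array(is_ts, dtype=bool),
        np.array(is_syn, dtype=bool),
    )


_PAIR_I, _PAIR_J, _PAIR_TS, _PAIR_SYN = _codon_pair_tables()


@dataclass
class NucModel:
    """GTR+G nucleotide model.

    ``rates`` are the six exchangeabilities in order AC, AG, AT, CG, CT, GT
    (GT conventionally fixed to 1 for identifiability); ``freqs`` the
    equilibrium base frequencies (A, C, G, T); ``alpha`` the gamma shape and
    ``ncat`` the number of equal-weight discrete rate categories.
    """

    rates: np.ndarray = field(default_factory=lambda: np.ones(6))
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    alpha: float = 0.5
    ncat: int = 4

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.rates.shape != (6,) or np.any(self.rates <= 0):
            raise ValueError("need 6 positive exchangeabilities")
        if self.freqs.shape != (4,) or np.any(self.freqs <= 0):
            raise ValueError("need 4 positive base frequencies")
        self.freqs = self.freqs / self.freqs.sum()
        if self.alpha <= 0:
            raise ValueError("gamma shape must be positive")
        if self.ncat < 1:
            raise ValueError("need at least one rate category")

    @property
    def n_states(self) -> int:
        return 4

    def rate_matrix(self) -> np.ndarray:
        return build_gtr_matrix(self)

    def category_rates(self) -> np.ndarray:
        return discrete_gamma(self.alpha, self.ncat)


@dataclass
class CodonModel:
    """GY94 codon model: kappa, omega, and 61 sense-codon frequencies.

    ``omega`` is the model's single ratio; free-ratio and per-clade fits hold
    one :class:`CodonModel` and supply per-edge omegas externally.
    """

    kappa: float = 2.0
    omega: float = 0.5
    freqs: np.ndarray = field(
        default_factory=lambda: np.full(N_CODONS, 1.0 / N_CODONS)
    )

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.kappa <= 0 or self.omega < 0:
            raise ValueError("kappa must be positive, omega non-negative")
        if self.freqs.shape != (N_CODONS,) or np.any(self.freqs < 0):
            raise ValueError(f"need {N_CODONS} non-negative codon frequencies")
        if self.freqs.sum() <= 0:
            raise ValueError("codon frequencies sum to zero")
        self.freqs = self.freqs / self.freqs.sum()

    @property
    def n_states(self) -> int:
        return N_CODONS

    def rate_matrix(self, omega: float | None = None) -> np.ndarray:
        w = self.omega if omega is None else omega
        return build_gy94_matrix(self.kappa, w, self.freqs)


def build_gtr_matrix(model: NucModel) -> np.ndarray:
    """GTR rate matrix with rows summing to 0 and mean rate 1 at equilibrium."""
    pi = model.freqs
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(model.rates, GTR_PAIRS):
        Q[i, j] = r * pi[j]
        Q[j, i] = r * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def build_gy94_matrix(kappa: float, omega: float, freqs: np.ndarray) -> np.ndarray:
    """GY94 rate matrix over sense codons, scaled to mean rate 1.

    Instantaneous change is permitted only between codons differing at a
    single position; transitions are weighted by ``kappa`` and nonsynonymous
    changes by ``omega``; the target-codon frequency multiplies every rate.
    """
    freqs = np.asarray(freqs, dtype=float)
    Q = np.zeros((N_CODONS, N_CODONS))
    w = np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_SYN, 1.0, omega)
    Q[_PAIR_I, _PAIR_J] = w * freqs[_PAIR_J]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(freqs * np.diag(Q)).sum()
    if mu <= 0:
        raise ValueError("degenerate codon model: zero total rate")
    return Q / mu


def flux_fractions(kappa: float, omega: float, freqs: np.ndarray):
    """Proportions (rho_N, rho_S) of equilibrium substitution flux that is
    nonsynonymous vs. synonymous under GY94."""
    freqs = np.asarray(freqs, dtype=float)
    w = np.where(_PAIR_TS, kappa, 1.0) * np.where(_PAIR_SYN, 1.0, omega)
    flux = freqs[_PAIR_I] * w * freqs[_PAIR_J]
    total = flux.sum()
    if total <= 0:
        raise ValueError("degenerate codon model: zero total flux")
    syn = flux[_PAIR_SYN].sum() / total
    return 1.0 - syn, syn


def discrete_gamma(alpha: float, k: int) -> np.ndarray:
    """Mean rates of ``k`` equal-probability discrete-gamma categories.

    The gamma has shape ``alpha`` and mean 1; category rates are the
    conditional means within equiprobable quantile bins, renormalized so the
    average rate is exactly 1.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    if k == 1:
        return np.ones(1)
    from scipy.stats import gamma as gamma_dist

    edges = gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], edges, [np.inf]])
    # E[X; X<=b] for X ~ Gamma(shape a, rate a) is regularized P(a+1, a*b)
    upper = np.where(np.isinf(edges), 1.0, gammainc(alpha + 1, alpha * edges))
    rates = k * np.diff(upper)
    return rates / rates.mean()


class ReversibleEigen:
    """Spectral decomposition of a reversible rate matrix.

    For reversible Q with stationary distribution pi, the similarity transform
    diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric, so transition matrices
    P(t) = exp(Qt) come from a single real eigendecomposition.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        sp = np.sqrt(pi)
        B = (sp[:, None] * Q) / sp[None, :]
        B = 0.5 * (B + B.T)
        lam, V = eigh(B)
        self.lam = lam
        self._left = V / sp[:, None]  # diag(1/sqrt(pi)) V
        self._right = (V * sp[:, None]).T  # V^T diag(sqrt(pi))
        self.pi = pi

    def transition_matrix(self, t: float) -> np.ndarray:
        P = (self._left * np.exp(self.lam * t)) @ self._right
        return np.clip(P, 0.0, None)

    def transition_matrices(self, ts: np.ndarray) -> np.ndarray:
        """Stacked P(t) for a vector of ``ts`` (e.g. per-category rates x t)."""
        ts = np.atleast_1d(np.asarray(ts, dtype=float))
        E = np.exp(np.outer(ts, self.lam))  # (k, s)
        P = np.einsum("ij,kj,jl->kil", self._left, E, self._right)
        return np.clip(P, 0.0, None)


def empirical_nucleotide_frequencies(seqs) -> np.ndarray:
    """Base frequencies pooled over sequences, ignoring gaps/ambiguity."""
    counts = np.zeros(4)
    for s in seqs:
        for i, nuc in enumerate(NUCLEOTIDES):
            counts[i] += s.count(nuc)
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases")
    # small floor avoids zero-frequency states on sparse data
    counts = np.maximum(counts, 0.5)
    return counts / counts.sum()


def f3x4_frequencies(codon_columns: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from observed positional base composition.

    ``codon_columns`` is a character matrix whose width is a multiple of 3
    (sequences x in-frame columns).  Stop codons receive zero probability and
    the sense-codon frequencies are renormalized.
    """
    mat = np.asarray(codon_columns)
    if mat.shape[1] % 3:
        raise ValueError("column count not divisible by 3")
    pos_freqs = np.zeros((3, 4))
    for pos in range(3):
        cols = mat[:, pos::3]
        for i, nuc in enumerate(NUCLEOTIDES):
            pos_freqs[pos, i] = np.count_nonzero(cols == nuc)
        s = pos_freqs[pos].sum()
        pos_freqs[pos] = (
            np.full(4, 0.25) if s == 0 else np.maximum(pos_freqs[pos], 0.5) / max(s, 1)
        )
        pos_freqs[pos] /= pos_freqs[pos].sum()
    freqs = np.array(
        [
            pos_freqs[0, _NUC_INDEX[c[0]]]
            * pos_freqs[1, _NUC_INDEX[c[1]]]
            * pos_freqs[2, _NUC_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return freqs / freqs.sum()
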