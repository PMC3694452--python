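"""Paired nonparametric tests across phylogenetically independent comparisons.

The Wilcoxon signed-ranks test is computed with midranks for tied absolute
differences, the tie-corrected variance, and a 0.5 continuity correction
toward the mean in the normal approximation — the convention of classic
statistics packages, which reproduces published Z values from rounded table
entries.  An exact-distribution option enumerates the signed-rank null by
dynamic programming.  The sign test is the exact two-tailed binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clade_rates import CladeRateSummary, sign_of

__all__ = [
    "DifferenceVector",
    "PairedTestResult",
    "wilcoxon_signed_rank",
    "sign_test",
    "combined_gene_sign",
    "summarize_study",
    "StudyResult",
]


@dataclass(frozen=True)
class PairedTestResult:
    """Result of one paired test over the comparisons.

    ``n_used`` excludes zero differences; ``w_plus`` is the sum of positive
    midranks (Wilcoxon only); ``z`` the signed normal deviate (NaN for the
    exact sign test); ``p`` two-tailed.
    """

    n_used: int
    n_pos: int
    n_neg: int
    w_plus: float
    z: float
    p: float
    method: str  # "wilcoxon" | "wilcoxon-exact" | "sign-test"


@dataclass(frozen=True)
class DifferenceVector:
    """Ordered signed differences P_i - NP_i for one genome x rate class."""

    pair_ids: tuple[int, ...]
    diffs: tuple[float, ...]
    rate_class: str
    genome: str

    @classmethod
    def from_summaries(cls, rows: list[CladeRateSummary]) -> "DifferenceVector":
        rows = sorted(rows, key=lambda r: r.pair_id)
        if not rows:
            raise ValueError("no summaries supplied")
        genomes = {r.genome for r in rows}
        classes = {r.rate_class for r in rows}
        if len(genomes) > 1 or len(classes) > 1:
            raise ValueError("summaries span multiple genomes or rate classes")
        return cls(
            tuple(r.pair_id for r in rows),
            tuple(r.difference for r in rows),
            rows[0].rate_class,
            rows[0].genome,
        )

    @property
    def n_pos(self) -> int:
        return sum(1 for d in self.diffs if d > 0)

    @property
    def n_neg(self) -> int:
        return sum(1 for d in self.diffs if d < 0)


def _as_array(d) -> np.ndarray:
    if isinstance(d, DifferenceVector):
        return np.asarray(d.diffs, dtype=float)
    return np.asarray(d, dtype=float)


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-tailed p for W+ by DP over all 2^n sign assignments.

    Midranks are doubled to make integer weights, so ties are handled
    exactly.  Two-tailed p doubles the smaller tail and caps at 1.
    """
    weights = np.rint(2 * ranks).astype(int)
    total = weights.sum()
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for w in weights:
        counts[w:] += counts[:-w].copy()
    counts /= counts.sum()
    w2 = int(round(2 * w_plus))
    upper = counts[w2:].sum()
    lower = counts[: w2 + 1].sum()
    return float(min(1.0, 2 * min(upper, lower)))


def wilcoxon_signed_rank(d, exact: bool = False) -> PairedTestResult:
    """Wilcoxon signed-ranks test on paired differences.

    Zero differences are dropped; absolute values are ranked with midranks
    for ties; W+ is the positive-rank sum.  The default normal approximation
    uses Z = (W+ - n(n+1)/4 -/+ 0.5) / sigma with the continuity correction
    of 0.5 toward the mean and the tie-corrected variance
    n(n+1)(2n+1)/24 - sum(t^3 - t)/48.  ``exact=True`` replaces the p value
    with the exact permutation tail (Z still reported for reference).
    """
    arr = _as_array(d)
    if not np.all(np.isfinite(arr)):
        raise ValueError("differences must be finite")
    nz = arr[arr != 0]
    if nz.size == 0:
        raise ValueError("all differences are zero")
    n = nz.size
    ranks = sps.rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(nz), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
    dev = w_plus - mean
    z = 0.0 if var == 0 else (dev - 0.5 * np.sign(dev)) / np.sqrt(var)
    if exact:
        p = _exact_signed_rank_p(ranks, w_plus)
        method = "wilcoxon-exact"
    else:
        p = float(2 * sps.norm.sf(abs(z)))
        method = "wilcoxon"
    return PairedTestResult(
        n_used=n,
        n_pos=int((nz > 0).sum()),
        n_neg=int((nz < 0).sum()),
        w_plus=w_plus,
        z=float(z),
        p=min(1.0, p),
        method=method,
    )


def sign_test(n_pos: int, n_neg: int) -> PairedTestResult:
    """Exact two-tailed sign test: p = min(1, 2 P[Bin(n, 1/2) >= max(k+, k-)])."""
    if n_pos < 0 or n_neg < 0 or n_pos + n_neg < 1:
        raise ValueError("need at least one nonzero difference")
    n = n_pos + n_neg
    k = max(n_pos, n_neg)
    p = min(1.0, 2 * float(sps.binom.sf(k - 1, n, 0.5)))
    return PairedTestResult(
        n_used=n,
        n_pos=n_pos,
        n_neg=n_neg,
        w_plus=float("nan"),
        z=float("nan"),
        p=p,
        method="sign-test",
    )


def combined_gene_sign(per_gene: dict[str, CladeRateSummary]) -> str:
    """Combine one pair's signs across whichever genes are available.

    If every available gene agrees the shared sign is returned; on conflict
    the sign of the summed per-gene differences decides.  Only the sign, not
    the magnitude, feeds the downstream sign test.
    """
    if not per_gene:
        raise ValueError("no genes available for this pair")
    signs = {row.sign for row in per_gene.values() if row.sign != "0"}
    if len(signs) == 1:
        return signs.pop()
    if not signs:
        return "0"
    return sign_of(sum(row.difference for row in per_gene.values()))


@dataclass
class StudyResult:
    """Study-level tables and test results."""

    table: pd.DataFrame
    tests: dict[tuple[str, str], PairedTestResult]
    diffs: dict[tuple[str, str], DifferenceVector]
    combined_signs: dict[str, dict[int, str]] = field(default_factory=dict)
    combined_tests: dict[str, PairedTestResult] = field(default_factory=dict)

    def write_tsv(self, table_path, tests_path) -> None:
        self.table.to_csv(table_path, sep="\t", index=False, float_format="%.6g")
        rows = []
        for (genome, rate_class), res in sorted(self.tests.items()):
            rows.append(
                {
                    "genome": genome,
                    "rate_class": rate_class,
                    "n": res.n_used,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                    "w_plus": res.w_plus,
                    "z": res.z,
                    "p": res.p,
                    "method": res.method,
                }
            )
        for genome, res in sorted(self.combined_tests.items()):
            rows.append(
                {
                    "genome": genome,
                    "rate_class": "combined-sign",
                    "n": res.n_used,
                    "n_pos": res.n_pos,
                    "n_neg": res.n_neg,
                    "w_plus": res.w_plus,
                    "z": res.z,
                    "p": res.p,
                    "method": res.method,
                }
            )
        pd.DataFrame(rows).to_csv(
            tests_path, sep="\t", index=False, float_format="%.6g"
        )


def summarize_study(
    summaries: list[CladeRateSummary],
    combine_classes: dict[str, tuple[str, ...]] | None = None,
    exact: bool = False,
) -> StudyResult:
    """Run the paired tests for every genome x rate class.

    Branch-sum and omega classes get the Wilcoxon signed-ranks test; ``GC``
    rows get the exact sign test (base-composition differences are tested on
    sign only).  ``combine_classes`` maps a genome to the gene classes whose
    per-pair signs are merged by :func:`combined_gene_sign` and fed to one
    exact sign test — the treatment of genomes with heterogeneous gene
    availability.
    """
    table = pd.DataFrame(
        [
            {
                "pair": r.pair_id,
                "genome": r.genome,
                "rate_class": r.rate_class,
                "P": r.P,
                "NP": r.NP,
                "sign": r.sign,
            }
            for r in sorted(summaries, key=lambda r: (r.genome, r.rate_class, r.pair_id))
        ]
    )
    groups: dict[tuple[str, str], list[CladeRateSummary]] = {}
    for r in summaries:
        groups.setdefault((r.genome, r.rate_class), []).append(r)

    tests: dict[tuple[str, str], PairedTestResult] = {}
    diffs: dict[tuple[str, str], DifferenceVector] = {}
    for key, rows in groups.items():
        vec = DifferenceVector.from_summaries(rows)
        diffs[key] = vec
        if key[1] == "GC":
            tests[key] = sign_test(vec.n_pos, vec.n_neg)
        else:
            tests[key] = wilcoxon_signed_rank(vec, exact=exact)

    result = StudyResult(table=table, tests=tests, diffs=diffs)
    for genome, classes in (combine_classes or {}).items():
        per_pair: dict[int, dict[str, CladeRateSummary]] = {}
        for r in summaries:
            if r.genome == genome and r.rate_class in classes:
                per_pair.setdefault(r.pair_id, {})[r.rate_class] = r
        signs = {
            pid: combined_gene_sign(genes) for pid, genes in sorted(per_pair.items())
        }
        n_pos = sum(1 for s in signs.values() if s == "+")
        n_neg = sum(1 for s in signs.values() if s == "-")
        result.combined_signs[genome] = signs
        result.combined_tests[genome] = sign_test(n_pos, n_neg)
    return result
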