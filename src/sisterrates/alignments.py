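"""Multiple sequence alignments with gene partitions.

An :class:`Alignment` is an immutable-by-convention mapping of tip label to an
equal-length nucleotide string over ``A C G T - N``, together with a partition
map assigning column intervals to named genes and a genome tag (nuclear,
mitochondrial or chloroplast).  Coding partitions carry a reading-frame offset
and must span a whole number of codons.

Column coordinates in user-facing interfaces (config files, masking) are
1-based inclusive, following the NEXUS charset convention; internally all
intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "AlignmentError",
    "Partition",
    "read_alignment",
    "mask_columns",
    "flag_pseudogenes",
    "concatenate",
]

STOP_CODONS = {"TAA", "TAG", "TGA"}
_VALID = set("ACGT-N")
# IUPAC ambiguity codes collapse to N: the likelihood engine treats any
# partial ambiguity as fully missing data.
_AMBIG = set("RYSWKMBDHVU?X.")


class AlignmentError(ValueError):
    """Raised for malformed alignments or partition maps."""


@dataclass(frozen=True)
class Partition:
    """A named column interval, 0-based half-open ``[start, end)``."""

    name: str
    start: int
    end: int
    coding: bool = False
    frame: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start

    @classmethod
    def from_one_based(cls, name, first, last, coding=False, frame=0):
        """Build from a 1-based inclusive interval (config-file convention)."""
        return cls(name, first - 1, last, coding=coding, frame=frame)


def _normalize(seq: str) -> str:
    s = seq.upper()
    out = []
    for ch in s:
        if ch in _VALID:
            out.append(ch)
        elif ch in _AMBIG:
            out.append("N")
        else:
            raise AlignmentError(f"invalid character {ch!r} in sequence")
    return "".join(out)


@dataclass
class Alignment:
    """Equal-length sequence records plus partition map and genome tag."""

    records: dict[str, str]
    partitions: list[Partition] = field(default_factory=list)
    genome: str = "nuclear"

    def __post_init__(self):
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) > 1:
            raise AlignmentError(
                f"unequal sequence lengths: {sorted(lengths)}"
            )
        self.records = {k: _normalize(v) for k, v in self.records.items()}
        self._check_partitions()

    # -- invariants ----------------------------------------------------
    def _check_partitions(self):
        ncol = self.n_columns
        spans = sorted((p.start, p.end, p.name) for p in self.partitions)
        prev_end = 0
        for start, end, name in spans:
            if start < 0 or end > ncol or start >= end:
                raise AlignmentError(
                    f"partition {name!r} interval [{start + 1},{end}] out of "
                    f"bounds for {ncol}-column alignment"
                )
            if start < prev_end:
                raise AlignmentError(f"partition {name!r} overlaps a previous one")
            prev_end = end
        for p in self.partitions:
            if p.coding and (p.length - p.frame) % 3 != 0:
                raise AlignmentError(
                    f"coding partition {p.name!r}: length {p.length} minus frame "
                    f"{p.frame} not divisible by 3"
                )

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.records.values()))) if self.records else 0

    @property
    def labels(self) -> list[str]:
        return list(self.records)

    def subset(self, labels) -> "Alignment":
        missing = [l for l in labels if l not in self.records]
        if missing:
            raise AlignmentError(f"labels not in alignment: {missing}")
        return Alignment(
            {l: self.records[l] for l in labels},
            partitions=list(self.partitions),
            genome=self.genome,
        )

    def columns(self, partition: Partition | None = None) -> np.ndarray:
        """Character matrix (n_seqs x n_cols), optionally one partition's
        in-frame columns."""
        mat = np.array([list(s) for s in self.records.values()])
        if partition is None:
            return mat
        return mat[:, partition.start + partition.frame : partition.end]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, seq in self.records.items():
                fh.write(f">{label}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def read_alignment(path, partitions=None, genome="nuclear") -> Alignment:
    """Read a FASTA alignment and attach a partition map.

    ``partitions`` may be a list of :class:`Partition` or of tuples
    ``(name, first, last[, coding[, frame]])`` with 1-based inclusive columns.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise AlignmentError(f"duplicate FASTA label: {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    parts = []
    for p in partitions or []:
        if isinstance(p, Partition):
            parts.append(p)
        else:
            parts.append(Partition.from_one_based(*p))
    return Alignment(records, partitions=parts, genome=genome)


def mask_columns(aln: Alignment, intervals) -> Alignment:
    """Remove the columns in ``intervals`` (1-based inclusive pairs).

    The partition map is re-indexed to the surviving columns.  Masking that
    would leave a coding partition with a non-codon length is rejected unless
    the masked block is itself codon-aligned within that partition.
    """
    ncol = aln.n_columns
    drop = np.zeros(ncol, dtype=bool)
    for first, last in intervals:
        if first < 1 or last > ncol or first > last:
            raise AlignmentError(
                f"mask interval [{first},{last}] out of bounds (1..{ncol})"
            )
        drop[first - 1 : last] = True
    if not drop.any():
        return Alignment(dict(aln.records), list(aln.partitions), aln.genome)

    for p in aln.partitions:
        if not p.coding:
            continue
        sel = drop[p.start : p.end].copy()
        sel[: p.frame] = False  # frame-offset columns are non-codon anyway
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            continue
        rel = idx - p.frame
        # each masked run must start on a codon boundary and span whole codons
        runs = np.split(rel, np.flatnonzero(np.diff(rel) != 1) + 1)
        for run in runs:
            if run[0] % 3 != 0 or len(run) % 3 != 0:
                raise AlignmentError(
                    f"mask breaks codon structure of partition {p.name!r}"
                )

    keep = ~drop
    new_records = {
        lab: "".join(np.array(list(seq))[keep]) for lab, seq in aln.records.items()
    }
    # re-index partitions: new coordinate = old - (#dropped before)
    shift = np.cumsum(drop)  # dropped count up to and including column i

    def newpos(old: int) -> int:
        return old - int(shift[old - 1]) if old > 0 else 0

    new_parts = []
    for p in aln.partitions:
        ns, ne = newpos(p.start), newpos(p.end)
        if ne > ns:
            new_parts.append(replace(p, start=ns, end=ne))
    return Alignment(new_records, new_parts, aln.genome)


def flag_pseudogenes(aln: Alignment, partition: Partition) -> list[tuple[str, str]]:
    """Flag likely pseudogenes in one coding partition.

    A sequence is flagged when it contains an in-frame internal stop codon
    (TAA/TAG/TGA before the final codon) or a gap run whose length is not a
    multiple of 3 (a frameshift).  Returns ``(label, reason)`` pairs; an empty
    list means no sequence looks pseudogenized.
    """
    if not partition.coding:
        raise AlignmentError(f"partition {partition.name!r} is not coding")
    out: list[tuple[str, str]] = []
    for label, seq in aln.records.items():
        sub = seq[partition.start + partition.frame : partition.end]
        # frameshift gaps
        run = 0
        flagged = False
        for ch in sub + "X":  # sentinel flushes the final run
            if ch == "-":
                run += 1
            else:
                if run and run % 3 != 0:
                    out.append((label, f"frameshift gap of length {run}"))
                    flagged = True
                    break
                run = 0
        if flagged:
            continue
        ncodon = len(sub) // 3
        for k in range(ncodon - 1):  # exclude the final codon
            codon = sub[3 * k : 3 * k + 3]
            if codon in STOP_CODONS:
                out.append((label, f"internal stop at codon {k + 1}"))
                break
    return out


def concatenate(alns, drop_uncovered_for=None) -> Alignment:
    """Concatenate gene alignments sharing a genome tag.

    The label set is the union of the inputs'; tips missing a gene are filled
    with gap characters (treated as missing data downstream).  Each input's
    partitions are carried over at shifted coordinates; inputs with no
    partition map contribute one anonymous partition spanning their columns.

    When ``drop_uncovered_for`` is a pair of tip collections ``(side_a,
    side_b)``, any input alignment with no unambiguous data in either side is
    excluded — only gene regions covered in both the parasitic and the
    non-parasitic clade enter the analysis.
    """
    alns = list(alns)
    if not alns:
        raise AlignmentError("nothing to concatenate")
    genomes = {a.genome for a in alns}
    if len(genomes) > 1:
        raise AlignmentError(f"conflicting genome tags: {sorted(genomes)}")

    if drop_uncovered_for is not None:
        side_a, side_b = (set(s) for s in drop_uncovered_for)

        def covered(a: Alignment, side) -> bool:
            return any(
                set(a.records[l]) - {"-", "N"} for l in side if l in a.records
            )

        alns = [a for a in alns if covered(a, side_a) and covered(a, side_b)]
        if not alns:
            raise AlignmentError("no gene has coverage in both clades")

    labels: list[str] = []
    for a in alns:
        for l in a.labels:
            if l not in labels:
                labels.append(l)
    pieces: dict[str, list[str]] = {l: [] for l in labels}
    parts: list[Partition] = []
    offset = 0
    for i, a in enumerate(alns):
        ncol = a.n_columns
        for l in labels:
            pieces[l].append(a.records.get(l, "-" * ncol))
        src = a.partitions or [Partition(f"gene{i + 1}", 0, ncol)]
        for p in src:
            parts.append(replace(p, start=p.start + offset, end=p.end + offset))
        offset += ncol
    return Alignment(
        {l: "".join(chunks) for l, chunks in pieces.items()},
        partitions=parts,
        genome=alns[0].genome,
    )
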