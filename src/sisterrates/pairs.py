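"""Comparison-pair definitions and the flat-text study configuration format.

A :class:`ComparisonPair` names one phylogenetically independent contrast: a
set of parasitic tips, an equal-or-different-sized set of non-parasitic sister
tips, and at least one outgroup tip used to root the extracted subtree.

Study configuration files use INI syntax, one ``[pair:<id>]`` section per
comparison::

    [pair:1]
    parasite = P1_t1 P1_t2
    nonparasite = N1_t1 N1_t2
    outgroup = OG1
    mode = holoparasitic
    tree = pair01.nwk          ; optional per-pair input paths
    alignment = pair01.fasta

Partition maps live in a ``[partitions]`` section with 1-based inclusive
intervals: ``matR = 1-1200 coding frame=0``.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass
from pathlib import Path

from .alignments import Partition

__all__ = ["ComparisonPair", "PairConfigError", "read_pair_config", "write_pair_config"]


class PairConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ComparisonPair:
    """One parasite / non-parasite sister contrast plus outgroup."""

    pair_id: int
    parasite: frozenset[str]
    nonparasite: frozenset[str]
    outgroup: frozenset[str]
    mode: str = "holoparasitic"  # or hemiparasitic
    tree_path: str | None = None
    alignment_path: str | None = None

    def __post_init__(self):
        for name, s in [
            ("parasite", self.parasite),
            ("nonparasite", self.nonparasite),
            ("outgroup", self.outgroup),
        ]:
            if not s:
                raise PairConfigError(f"pair {self.pair_id}: empty {name} tip set")
        if (
            self.parasite & self.nonparasite
            or self.parasite & self.outgroup
            or self.nonparasite & self.outgroup
        ):
            raise PairConfigError(
                f"pair {self.pair_id}: tip sets must be pairwise disjoint"
            )

    @property
    def all_tips(self) -> frozenset[str]:
        return self.parasite | self.nonparasite | self.outgroup


def _parse_tips(raw: str) -> frozenset[str]:
    return frozenset(raw.replace(",", " ").split())


def read_pair_config(path) -> tuple[list[ComparisonPair], list[Partition]]:
    """Read pairs and (optionally) a partition map from a config file."""
    cp = configparser.ConfigParser()
    read = cp.read(str(path))
    if not read:
        raise PairConfigError(f"cannot read config file: {path}")
    pairs: list[ComparisonPair] = []
    partitions: list[Partition] = []
    for section in cp.sections():
        if section.lower().startswith("pair"):
            pid_txt = section.split(":", 1)[-1].strip()
            try:
                pid = int(pid_txt)
            except ValueError as exc:
                raise PairConfigError(f"bad pair id in [{section}]") from exc
            sec = cp[section]
            try:
                pairs.append(
                    ComparisonPair(
                        pair_id=pid,
                        parasite=_parse_tips(sec["parasite"]),
                        nonparasite=_parse_tips(sec["nonparasite"]),
                        outgroup=_parse_tips(sec["outgroup"]),
                        mode=sec.get("mode", "holoparasitic"),
                        tree_path=sec.get("tree"),
                        alignment_path=sec.get("alignment"),
                    )
                )
            except KeyError as exc:
                raise PairConfigError(f"[{section}] missing key {exc}") from exc
        elif section.lower() == "partitions":
            for gene, spec in cp[section].items():
                tokens = spec.split()
                first, last = (int(x) for x in tokens[0].split("-"))
                coding = "coding" in tokens[1:]
                frame = 0
                for tok in tokens[1:]:
                    if tok.startswith("frame="):
                        frame = int(tok.split("=", 1)[1])
                partitions.append(
                    Partition.from_one_based(gene, first, last, coding, frame)
                )
    pairs.sort(key=lambda p: p.pair_id)
    return pairs, partitions


def write_pair_config(path, pairs, partitions=()) -> None:
    lines: list[str] = []
    for p in sorted(pairs, key=lambda q: q.pair_id):
        lines.append(f"[pair:{p.pair_id}]")
        lines.append("parasite = " + " ".join(sorted(p.parasite)))
        lines.append("nonparasite = " + " ".join(sorted(p.nonparasite)))
        lines.append("outgroup = " + " ".join(sorted(p.outgroup)))
        lines.append(f"mode = {p.mode}")
        if p.tree_path:
            lines.append(f"tree = {p.tree_path}")
        if p.alignment_path:
            lines.append(f"alignment = {p.alignment_path}")
        lines.append("")
    if partitions:
        lines.append("[partitions]")
        for part in partitions:
            spec = f"{part.start + 1}-{part.end}"
            if part.coding:
                spec += f" coding frame={part.frame}"
            lines.append(f"{part.name} = {spec}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
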