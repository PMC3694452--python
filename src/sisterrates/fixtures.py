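"""Embedded published clade branch-length tables for the 12 comparisons.

These are the printed per-pair clade statistics for nuclear and mitochondrial
sequences (total branch length; mitochondrial dN, dS and dN/dS) and for
chloroplast sequences (16S rRNA and protein-coding totals, dN, dS, dN/dS,
plus the combined per-pair sign), exactly as published, together with the
printed test statistics they imply.  The comparative-test layer reproduces
those statistics from these values; the branch lengths themselves are inputs
here, not recomputed from sequence data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clade_rates import CladeRateSummary

__all__ = ["StudyFixture", "load_table_fixture", "PAIR_NAMES"]

PAIR_NAMES = {
    1: ("Apodanthaceae", "Malvaceae"),
    2: ("Cytinaceae", "Thymelaeaceae"),
    3: ("Rafflesiaceae", "Passifloraceae/Euphorbiaceae"),
    4: ("Cynomoriaceae", "Hamamelidaceae/Peridiscaceae"),
    5: ("Krameriaceae", "Zygophyllaceae"),
    6: ("Mitrastemonaceae", "Vaccinieae"),
    7: ("Boraginaceae", "Boraginaceae"),
    8: ("Orobanchaceae/Rhinantheae", "Lamiales/Plantaginaceae"),
    9: ("Convolvulaceae", "Ipomoeeae"),
    10: ("Lauraceae", "Lauraceae"),
    11: ("Hydnoraceae", "Aristolochiaceae"),
    12: ("Balanophoraceae/Loranthaceae/Schoepfiaceae/Olacaceae", "Olacaceae"),
}

# (P, NP) per pair 1..12
_NUCLEAR_TOTAL = {
    1: (0.513, 0.072), 2: (0.121, 0.028), 3: (1.093, 0.052), 4: (0.087, 0.012),
    5: (0.019, 0.025), 6: (0.075, 0.013), 7: (0.036, 0.028), 8: (0.042, 0.043),
    9: (0.080, 0.016), 10: (0.323, 0.230), 11: (0.296, 0.057), 12: (0.384, 0.120),
}
_MITO_TOTAL = {
    1: (0.380, 0.037), 2: (0.070, 0.035), 3: (0.631, 0.141), 4: (0.030, 0.011),
    5: (0.015, 0.011), 6: (0.026, 0.017), 7: (0.029, 0.020), 8: (0.007, 0.022),
    9: (0.061, 0.021), 10: (0.012, 0.005), 11: (0.152, 0.042), 12: (0.131, 0.014),
}
_MITO_DN = {
    1: (0.466, 0.055), 2: (0.077, 0.032), 3: (0.577, 0.114), 4: (0.017, 0.007),
    5: (0.012, 0.007), 6: (0.021, 0.005), 7: (0.020, 0.013), 8: (0.002, 0.006),
    9: (0.052, 0.008), 10: (0.010, 0.004), 11: (0.072, 0.014), 12: (0.101, 0.005),
}
_MITO_DS = {
    1: (0.739, 0.024), 2: (0.094, 0.043), 3: (0.660, 0.241), 4: (0.060, 0.024),
    5: (0.023, 0.025), 6: (0.039, 0.048), 7: (0.049, 0.044), 8: (0.023, 0.072),
    9: (0.096, 0.054), 10: (0.018, 0.008), 11: (0.152, 0.042), 12: (0.180, 0.040),
}
_MITO_OMEGA = {
    1: (0.628, 1.287), 2: (0.960, 0.742), 3: (0.726, 0.520), 4: (0.276, 0.282),
    5: (0.529, 0.289), 6: (0.529, 0.108), 7: (0.389, 0.343), 8: (0.133, 0.054),
    9: (0.562, 0.249), 10: (0.540, 0.530), 11: (0.418, 0.330), 12: (0.493, 0.773),
}
# chloroplast: 16S rRNA available for pairs 1-4, 6, 8, 9, 11
_CP_RRN16 = {
    1: (1.637, 0.013), 2: (0.091, 0.008), 3: (0.150, 0.091), 4: (0.083, 0.002),
    6: (0.196, 0.940), 8: (0.027, 0.001), 9: (0.014, 0.001), 11: (0.336, 0.000),
}
# protein-coding totals available for pairs 5, 7-10, 12
_CP_PROTEIN = {
    5: (0.098, 0.164), 7: (0.076, 0.019), 8: (0.561, 0.366), 9: (0.724, 0.052),
    10: (0.344, 0.122), 12: (0.125, 0.049),
}
_CP_DN = {
    5: (0.032, 0.070), 7: (0.040, 0.017), 8: (0.413, 0.206), 9: (0.115, 0.027),
    10: (0.235, 0.116), 12: (0.068, 0.039),
}
_CP_DS = {
    5: (0.296, 0.360), 7: (0.133, 0.040), 8: (0.960, 0.743), 9: (1.938, 0.151),
    10: (0.526, 0.137), 12: (0.241, 0.069),
}
_CP_OMEGA = {
    5: (0.112, 0.220), 7: (0.297, 0.423), 8: (0.409, 0.268), 9: (0.047, 0.102),
    10: (0.320, 0.721), 12: (0.239, 0.585),
}
# the published combined chloroplast sign per pair
_CP_COMBINED_SIGN = {
    1: "+", 2: "+", 3: "+", 4: "+", 5: "-", 6: "-",
    7: "+", 8: "+", 9: "+", 10: "+", 11: "+", 12: "+",
}

# printed footer statistics: (genome, rate_class) -> (Z, p)
PRINTED_TESTS = {
    ("nuclear", "total"): (2.786, 0.005),
    ("mitochondrial", "total"): (2.628, 0.009),
    ("mitochondrial", "dN"): (2.942, 0.003),
    ("mitochondrial", "dS"): (2.157, 0.031),
    ("mitochondrial", "omega"): (1.294, 0.196),
    ("chloroplast", "rrn16"): (1.47, 0.14),
    ("chloroplast", "protein"): (1.68, 0.09),
    ("chloroplast", "dN"): (1.47, 0.14),
    ("chloroplast", "dS"): (1.89, 0.06),
    ("chloroplast", "omega"): (-1.26, 0.21),
}
PRINTED_COMBINED_SIGN_P = 0.039


@dataclass(frozen=True)
class StudyFixture:
    """The published per-pair clade statistics and footer test values."""

    summaries: tuple[CladeRateSummary, ...]
    combined_sign: dict[int, str]
    printed_tests: dict[tuple[str, str], tuple[float, float]]
    printed_combined_sign_p: float

    def rows(self, genome: str, rate_class: str) -> list[CladeRateSummary]:
        return [
            r
            for r in self.summaries
            if r.genome == genome and r.rate_class == rate_class
        ]

    def values(self, genome: str, rate_class: str, pair_id: int):
        for r in self.summaries:
            if (
                r.genome == genome
                and r.rate_class == rate_class
                and r.pair_id == pair_id
            ):
                return (r.P, r.NP)
        raise KeyError((genome, rate_class, pair_id))


def load_table_fixture() -> StudyFixture:
    """The published tables as :class:`CladeRateSummary` rows."""
    rows: list[CladeRateSummary] = []

    def add(genome, rate_class, data):
        for pid, (p, np_) in sorted(data.items()):
            rows.append(CladeRateSummary(pid, genome, rate_class, p, np_))

    add("nuclear", "total", _NUCLEAR_TOTAL)
    add("mitochondrial", "total", _MITO_TOTAL)
    add("mitochondrial", "dN", _MITO_DN)
    add("mitochondrial", "dS", _MITO_DS)
    add("mitochondrial", "omega", _MITO_OMEGA)
    add("chloroplast", "rrn16", _CP_RRN16)
    add("chloroplast", "protein", _CP_PROTEIN)
    add("chloroplast", "dN", _CP_DN)
    add("chloroplast", "dS", _CP_DS)
    add("chloroplast", "omega", _CP_OMEGA)
    return StudyFixture(
        summaries=tuple(rows),
        combined_sign=dict(_CP_COMBINED_SIGN),
        printed_tests=dict(PRINTED_TESTS),
        printed_combined_sign_p=PRINTED_COMBINED_SIGN_P,
    )
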