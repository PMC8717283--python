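"""Umami/sweet functional prediction from intact Tas1r counts.

Umami perception needs a Tas1r1--Tas1r3 heterodimer and sweet perception a
Tas1r2--Tas1r3 heterodimer, so a species is predicted to retain umami iff
it has at least one intact Tas1r1 AND one intact Tas1r3, and sweet iff at
least one intact Tas1r2 AND one intact Tas1r3.  Count entries written as
"2(1PS)" mean two loci of which one is a pseudogene: intact = 2 - 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

FAMILIES = ("Tas1r1", "Tas1r2", "Tas1r3")

_COUNT_RE = re.compile(r"^\s*(\d+)\s*(?:\(\s*(\d+)\s*PS\s*\))?\s*$")


@dataclass
class FamilyCount:
    total: int
    pseudo: int = 0

    @property
    def intact(self) -> int:
        return self.total - self.pseudo

    def __post_init__(self) -> None:
        if self.total < 0 or self.pseudo < 0 or self.pseudo > self.total:
            raise ValueError(f"bad family count: {self.total}({self.pseudo}PS)")


def parse_count(text: str | int) -> FamilyCount:
    """Parse a repertoire-table entry like '1', '2(1PS)' or '2 (1PS)'."""
    if isinstance(text, int):
        return FamilyCount(text)
    m = _COUNT_RE.match(str(text))
    if not m:
        raise ValueError(f"unparseable count entry: {text!r}")
    return FamilyCount(int(m.group(1)), int(m.group(2) or 0))


@dataclass
class TasteProfile:
    species: str
    tas1r1: FamilyCount
    tas1r2: FamilyCount
    tas1r3: FamilyCount

    @property
    def umami(self) -> bool:
        return self.tas1r1.intact >= 1 and self.tas1r3.intact >= 1

    @property
    def sweet(self) -> bool:
        return self.tas1r2.intact >= 1 and self.tas1r3.intact >= 1

    @property
    def pseudo_or_absent(self) -> int:
        """Pseudogene loci plus families with no locus at all."""
        return sum(
            c.pseudo + (1 if c.total == 0 else 0)
            for c in (self.tas1r1, self.tas1r2, self.tas1r3)
        )


def predict_taste(counts, species: str = "") -> TasteProfile:
    """Build a TasteProfile from (Tas1r1, Tas1r2, Tas1r3) counts.

    Each count may be an int, a FamilyCount, or a string like '2(1PS)'.
    """
    c1, c2, c3 = (
        c if isinstance(c, FamilyCount) else parse_count(c) for c in counts
    )
    return TasteProfile(species=species, tas1r1=c1, tas1r2=c2, tas1r3=c3)


@dataclass
class CohortSummary:
    n_species: int
    lost_both: int  # neither umami nor sweet
    lost_sweet_only: int  # umami retained, sweet lost
    intact_totals: dict  # family -> summed intact count
    pseudo_or_absent_total: int


def summarize_cohort(profiles: list[TasteProfile]) -> CohortSummary:
    totals = {f: 0 for f in FAMILIES}
    lost_both = lost_sweet_only = pa = 0
    for p in profiles:
        totals["Tas1r1"] += p.tas1r1.intact
        totals["Tas1r2"] += p.tas1r2.intact
        totals["Tas1r3"] += p.tas1r3.intact
        pa += p.pseudo_or_absent
        if not p.umami and not p.sweet:
            lost_both += 1
        elif p.umami and not p.sweet:
            lost_sweet_only += 1
    return CohortSummary(
        n_species=len(profiles),
        lost_both=lost_both,
        lost_sweet_only=lost_sweet_only,
        intact_totals=totals,
        pseudo_or_absent_total=pa,
    )


# ---------------------------------------------------------------------------
# packaged amphibian repertoire fixture
# ---------------------------------------------------------------------------


def load_reference_table() -> list[dict]:
    """The packaged 14-species amphibian Tas1r repertoire table
    (species, order, per-family count strings, published umami/sweet calls)."""
    text = (
        resources.files("tastemine.data")
        .joinpath("amphibian_tas1r_repertoire.tsv")
        .read_text()
    )
    lines = [l for l in text.strip().splitlines() if not l.startswith("#")]
    header = lines[0].split("\t")
    return [dict(zip(header, l.split("\t"))) for l in lines[1:]]


def reference_profiles() -> list[TasteProfile]:
    return [
        predict_taste(
            (row["Tas1r1"], row["Tas1r2"], row["Tas1r3"]),
            species=row["species"],
        )
        for row in load_reference_table()
    ]


def profiles_to_tsv(profiles: list[TasteProfile]) -> str:
    lines = ["species\tTas1r1\tTas1r2\tTas1r3\tumami\tsweet"]
    for p in profiles:
        lines.append(
            f"{p.species}\t{p.tas1r1.intact}\t{p.tas1r2.intact}\t"
            f"{p.tas1r3.intact}\t{int(p.umami)}\t{int(p.sweet)}"
        )
    return "\n".join(lines) + "\n"
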