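"""Synteny-based gene presence/absence calls from flanking marker genes.

A receptor gene that cannot be found in an assembly may be truly lost or
merely unassembled.  If the two marker genes that conservedly flank it
(e.g. NOL9 and ZBTB48 around Tas1r1) sit together on one contig with no
receptor hit between them, the locus was assembled and empty: the gene is
called ABSENT.  If the markers are split across contigs or missing, the
evidence is insufficient and the call is UNDETERMINED.
"""

from __future__ import annotations

from dataclasses import dataclass

PRESENT = "PRESENT"
PSEUDOGENE = "PSEUDOGENE"
ABSENT = "ABSENT"
UNDETERMINED = "UNDETERMINED"


@dataclass
class MarkerRule:
    family: str  # target gene family, e.g. Tas1r1
    upstream: str  # marker gene symbol
    downstream: str

    def __post_init__(self) -> None:
        if self.family in (self.upstream, self.downstream):
            raise ValueError("markers must be distinct from the target")


#: conserved flanking markers of the three umami/sweet receptor genes
DEFAULT_RULES = (
    MarkerRule("Tas1r1", "NOL9", "ZBTB48"),
    MarkerRule("Tas1r2", "MIB2", "GOLIM4"),
    MarkerRule("Tas1r3", "DVL1", "CPTP"),
)


@dataclass
class MarkerAnnotation:
    marker: str
    contig_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 0:
            raise ValueError(
                f"malformed marker interval for {self.marker}: "
                f"[{self.start}, {self.end})"
            )


def call_gene_status(
    models,
    hits,
    markers: list[MarkerAnnotation],
    rule: MarkerRule,
    max_span: int = 1_000_000,
    strict: bool = True,
) -> str:
    """Presence/absence call for one target family in one assembly.

    ``models`` are annotated GeneModels of the target family, ``hits`` any
    raw search hits for it (used to check the inter-marker gap is truly
    empty).  In ``strict`` mode co-located markers without a target give
    ABSENT; in permissive mode the same evidence gives UNDETERMINED (loss
    only "perhaps"), reserving ABSENT for when both markers are directly
    adjacent (< 10 kb apart).
    """
    intact = [m for m in models if m.category == "INTACT"]
    if intact:
        return PRESENT
    if models and all(m.category in ("PSEUDO", "PARTIAL", "SHORT") for m in models):
        if any(m.category == "PSEUDO" for m in models):
            return PSEUDOGENE
        return UNDETERMINED  # only fragments: cannot distinguish loss
    up = [m for m in markers if m.marker == rule.upstream]
    down = [m for m in markers if m.marker == rule.downstream]
    for u in up:
        for d in down:
            if u.contig_id != d.contig_id:
                continue
            lo = min(u.start, d.start)
            hi = max(u.end, d.end)
            if hi - lo > max_span:
                continue
            gap_hit = any(
                h.contig_id == u.contig_id and h.start < hi and lo < h.end
                for h in hits
            )
            if gap_hit:
                continue
            if strict or hi - lo < 10_000:
                return ABSENT
    return UNDETERMINED


def status_table_tsv(calls: dict) -> str:
    """calls: {(species, family): status} -> TSV."""
    lines = ["species\tfamily\tstatus"]
    for (species, family), status in sorted(calls.items()):
        lines.append(f"{species}\t{family}\t{status}")
    return "\n".join(lines) + "\n"
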