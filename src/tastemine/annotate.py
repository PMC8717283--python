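"""Gene-model construction and classification for candidate receptor loci.

Each extended candidate locus is aligned to its best-scoring query protein
with the frame-aware guided aligner, the maximal ORF is extracted, ORF
disruptions (premature stops, frameshifts) are called from the alignment,
the protein is screened for seven transmembrane segments by Kyte--Doolittle
hydropathy, and the locus is classified:

INTACT   complete clean ORF, >270 aa, start + stop, >=7 TM segments
PARTIAL  ORF truncated by a contig end (missing start or stop)
PSEUDO   any ORF disruption, or a complete ORF failing the TM screen,
         or a start/stop lost away from any contig edge
SHORT    complete clean ORF of <=270 aa (reported, not counted intact)

Pseudogene evidence outranks truncation: a contig-edge fragment that also
carries a frameshift is PSEUDO.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from ._codons import revcomp, translate, translate_codon
from .align import Disruption, guided_align
from .search import CandidateLocus, blosum62_score

logger = logging.getLogger(__name__)

INTACT_MIN_AA = 270  # strict: a 270-aa ORF is SHORT, not intact
MIN_TM_SEGMENTS = 7
FLOOR_SCORE = 60.0  # guided-alignment score below which a locus is dropped

CATEGORIES = ("INTACT", "PARTIAL", "PSEUDO", "SHORT")


@dataclass
class GeneModel:
    contig_id: str
    strand: str
    locus_start: int  # extended locus, forward-strand 0-based half-open
    locus_end: int
    coding_start: int  # forward-strand coords of the extracted gene region
    coding_end: int
    protein: str  # translation up to the first disruption/stop
    raw_translation: str
    category: str
    disruptions: list = field(default_factory=list)
    tm_count: int = 0
    has_start: bool = False
    has_stop: bool = False
    family: str = ""
    gene_name: str = ""
    guide_id: str = ""
    guide_interval: tuple = (0, 0)  # guide residues covered by the alignment
    score: float = 0.0


# ---------------------------------------------------------------------------
# transmembrane screen
# ---------------------------------------------------------------------------


def count_tm_segments(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    min_gap: int = 3,
) -> int:
    """Count transmembrane segments by sliding-window mean hydropathy.

    Windows of Kyte--Doolittle mean above ``threshold`` are collected;
    maximal runs of above-threshold windows separated by at least
    ``min_gap`` below-threshold windows count as one segment each.
    """
    if len(protein) < window:
        return 0
    vals = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in protein])
    means = np.convolve(vals, np.ones(window) / window, mode="valid")
    above = means > threshold
    segments = 0
    gap = min_gap  # so the first above-run always opens a segment
    in_run = False
    for a in above:
        if a:
            if not in_run and gap >= min_gap:
                segments += 1
            in_run = True
            gap = 0
        else:
            in_run = False
            gap += 1
    return segments


# ---------------------------------------------------------------------------
# ORF extraction and disruption detection
# ---------------------------------------------------------------------------


@dataclass
class _Extraction:
    coding_start: int  # locus-local, strand-oriented
    coding_end: int
    protein: str
    raw_translation: str
    has_start: bool
    has_stop: bool
    disruptions: list
    q_start: int
    q_end: int
    score: float


def _extract(locus_seq: str, guide: str, floor_score: float = FLOOR_SCORE):
    aln = guided_align(locus_seq, guide)
    if aln is None or aln.score < floor_score:
        return None
    # --- upstream: locate the start codon in the initial frame ---
    p0 = aln.nt_start
    has_start = False
    coding_start = p0
    if translate_codon(locus_seq[p0 : p0 + 3]) == "M":
        has_start = True
    else:
        pos = p0 - 3
        steps = 0
        while pos >= 0 and steps < 40:
            codon = translate_codon(locus_seq[pos : pos + 3])
            if codon == "*":
                break
            if codon == "M":
                coding_start = pos
                has_start = True
                break
            pos -= 3
            steps += 1
    # --- downstream: run to the stop codon in the final frame ---
    pL = aln.nt_end
    has_stop = False
    coding_end = pL
    pos = pL - 3  # last consumed codon start (frame anchor)
    pos += 3
    while pos + 3 <= len(locus_seq):
        codon = translate_codon(locus_seq[pos : pos + 3])
        pos += 3
        coding_end = pos
        if codon == "*":
            has_stop = True
            break
    raw = translate(locus_seq[coding_start:coding_end])
    clean = raw[:-1] if raw.endswith("*") else raw
    protein = clean.split("*")[0]
    return _Extraction(
        coding_start=coding_start,
        coding_end=coding_end,
        protein=protein,
        raw_translation=raw,
        has_start=has_start,
        has_stop=has_stop,
        disruptions=list(aln.disruptions),
        q_start=aln.q_start,
        q_end=aln.q_end,
        score=aln.score,
    )


def extract_gene_model(locus_seq: str, guide: str, floor_score: float = FLOOR_SCORE):
    """(coding interval, protein, raw translation) for a locus, or None.

    The reading frame and ORF are chosen by maximising the guided-alignment
    score to the guide; coordinates are local to ``locus_seq``.
    """
    ext = _extract(locus_seq, guide, floor_score)
    if ext is None:
        return None
    return (ext.coding_start, ext.coding_end), ext.protein, ext.raw_translation


def detect_disruptions(locus_seq: str, guide: str) -> list[Disruption]:
    """Premature stops and net-frameshift indels in a locus, guide-aligned."""
    ext = _extract(locus_seq, guide, floor_score=0.0)
    return [] if ext is None else ext.disruptions


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_gene(
    protein: str,
    has_start: bool,
    has_stop: bool,
    disruptions: list,
    tm_count: int,
    truncated_at_edge: bool = False,
) -> str:
    """Apply the intact/partial/pseudo/short rules (see module docstring)."""
    if disruptions:
        return "PSEUDO"
    if not (has_start and has_stop):
        return "PARTIAL" if truncated_at_edge else "PSEUDO"
    if len(protein) <= INTACT_MIN_AA:
        return "SHORT"
    if tm_count < MIN_TM_SEGMENTS:
        return "PSEUDO"
    return "INTACT"


def build_gene_model(
    genome_contigs: dict,
    locus: CandidateLocus,
    queries: dict,
    family: str = "Tas2r",
    floor_score: float = FLOOR_SCORE,
) -> GeneModel | None:
    """Full annotation of one extended candidate locus; None if dropped."""
    contig = genome_contigs[locus.contig_id]
    seq = contig[locus.start : locus.end]
    if locus.strand == "-":
        seq = revcomp(seq)
    guide = queries[locus.best_query]
    ext = _extract(seq, guide, floor_score)
    if ext is None:
        logger.info(
            "locus %s:%d-%d dropped (no alignment above floor)",
            locus.contig_id, locus.start, locus.end,
        )
        return None
    # map strand-oriented local coding coords to forward-strand contig coords
    if locus.strand == "+":
        cstart = locus.start + ext.coding_start
        cend = locus.start + ext.coding_end
        edge5 = locus.start <= 0
        edge3 = locus.end >= len(contig)
    else:
        cstart = locus.end - ext.coding_end
        cend = locus.end - ext.coding_start
        edge5 = locus.end >= len(contig)
        edge3 = locus.start <= 0
    truncated = (not ext.has_start and edge5) or (not ext.has_stop and edge3)
    tm = count_tm_segments(ext.protein)
    category = classify_gene(
        ext.protein, ext.has_start, ext.has_stop, ext.disruptions, tm, truncated
    )
    return GeneModel(
        contig_id=locus.contig_id,
        strand=locus.strand,
        locus_start=locus.start,
        locus_end=locus.end,
        coding_start=cstart,
        coding_end=cend,
        protein=ext.protein,
        raw_translation=ext.raw_translation,
        category=category,
        disruptions=ext.disruptions,
        tm_count=tm,
        has_start=ext.has_start,
        has_stop=ext.has_stop,
        family=family,
        guide_id=locus.best_query,
        guide_interval=(ext.q_start, ext.q_end),
        score=ext.score,
    )


def annotate_loci(
    genome, loci, queries: dict, family: str = "Tas2r",
    floor_score: float = FLOOR_SCORE,
) -> list[GeneModel]:
    contigs = getattr(genome, "contigs", genome)
    models = []
    for locus in loci:
        m = build_gene_model(contigs, locus, queries, family, floor_score)
        if m is not None:
            models.append(m)
    return models


# ---------------------------------------------------------------------------
# partial-locus disambiguation
# ---------------------------------------------------------------------------


def deduplicate_partials(partials: list[GeneModel]) -> list[list[GeneModel]]:
    """Group partial models of one species into inferred gene loci.

    Fragments whose guide-aligned regions overlap must come from different
    gene copies and stay separate; fragments covering complementary,
    non-overlapping parts of the guide are fused into one inferred locus.
    """
    frags = sorted(partials, key=lambda m: m.guide_interval)
    groups: list[list[GeneModel]] = []  # each with a current right edge
    edges: list[int] = []
    for m in frags:
        qs, qe = m.guide_interval
        placed = False
        for gi in range(len(groups)):
            if qs >= edges[gi]:  # complementary: same inferred locus
                groups[gi].append(m)
                edges[gi] = qe
                placed = True
                break
        if not placed:
            groups.append([m])
            edges.append(qe)
    return groups


# ---------------------------------------------------------------------------
# reciprocal verification and naming
# ---------------------------------------------------------------------------


def _quick_protein_score(a: str, b: str) -> float:
    """Best ungapped local alignment score between two proteins (exact for
    the substitution-only panel comparisons this is used for)."""
    best = 0.0
    for diag in range(-(len(b) - 1), len(a)):
        score = run_best = 0.0
        for i in range(max(0, diag), min(len(a), len(b) + diag)):
            score = max(0.0, score + blosum62_score(a[i], b[i - diag]))
            run_best = max(run_best, score)
        best = max(best, run_best)
    return best


def reciprocal_verify(
    protein: str,
    panel: dict,
    decoy_families: set | frozenset = frozenset({"V1R", "V2R"}),
) -> str:
    """Family of the best-scoring panel member, or 'REJECTED' for decoys.

    ``panel`` maps member id -> (family, protein sequence).
    """
    if not panel:
        raise ValueError("reference panel must not be empty")
    best_family, best_score = None, -1.0
    for _, (fam, seq) in panel.items():
        s = _quick_protein_score(protein, seq)
        if s > best_score:
            best_family, best_score = fam, s
    return "REJECTED" if best_family in decoy_families else best_family


def species_prefix(binomial: str) -> str:
    """Four-letter Xxxx prefix: Genus[:2] + epithet[:2]."""
    parts = binomial.replace("_", " ").split()
    if len(parts) < 2:
        raise ValueError(f"need a binomial species name, got {binomial!r}")
    return (parts[0][:2] + parts[1][:2]).capitalize()


def assign_gene_names(
    models: list[GeneModel], species: str, family: str,
    _taken: set | None = None,
) -> list[GeneModel]:
    """Name genes Xxxx_FamilyN in genomic order (contig, then position)."""
    prefix = species_prefix(species)
    ordered = sorted(models, key=lambda m: (m.contig_id, m.coding_start))
    for i, m in enumerate(ordered, start=1):
        name = f"{prefix}_{family}{i}"
        if _taken is not None:
            if name in _taken:
                raise ValueError(f"gene name collision: {name}")
            _taken.add(name)
        m.gene_name = name
        m.family = family
    return ordered


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def models_to_tsv(models: list[GeneModel]) -> str:
    lines = [
        "gene\tcontig\tstart\tend\tstrand\tcategory\tprotein_len\t"
        "tm_count\tdisruptions\tguide"
    ]
    for m in models:
        dis = ";".join(f"{d.kind}@{d.position}" for d in m.disruptions) or "."
        lines.append(
            f"{m.gene_name or '.'}\t{m.contig_id}\t{m.coding_start}\t"
            f"{m.coding_end}\t{m.strand}\t{m.category}\t{len(m.protein)}\t"
            f"{m.tm_count}\t{dis}\t{m.guide_id}"
        )
    return "\n".join(lines) + "\n"


def models_to_gff3(models: list[GeneModel]) -> str:
    lines = ["##gff-version 3"]
    for m in models:
        attrs = (
            f"ID={m.gene_name or m.contig_id + ':' + str(m.coding_start)};"
            f"category={m.category};tm_count={m.tm_count}"
        )
        lines.append(
            "\t".join(
                [
                    m.contig_id,
                    "tastemine",
                    "gene",
                    str(m.coding_start + 1),
                    str(m.coding_end),
                    f"{m.score:.0f}",
                    m.strand,
                    ".",
                    attrs,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def models_to_protein_fasta(models: list[GeneModel]) -> str:
    return "".join(
        f">{m.gene_name or m.contig_id} {m.category}\n{m.protein}\n"
        for m in models
        if m.protein
    )
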