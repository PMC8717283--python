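"""Translated homology search: six-frame translation, seeded word matching
with X-drop extension, and the hit filtering / merging / flank-extension
rules used for receptor-gene mining.

The search is a deterministic TBLASTN-like procedure: protein queries are
matched against all six reading frames of each contig via exact word seeds,
each seed is extended without gaps under BLOSUM62 with an X-drop rule, and
hits are reported in forward-strand genomic coordinates (0-based,
half-open).  The e-value cutoff of the original protocol is replaced by a
raw-score threshold; hits shorter than ``min_hit_len`` nt (default 100) are
discarded, overlapping hits are merged into candidate loci, and loci are
extended by ``flank`` nt (default 500) on both sides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices

from ._codons import revcomp, translate

logger = logging.getLogger(__name__)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_B62_ALPHA = _BLOSUM62.alphabet
_B62_INDEX = {aa: i for i, aa in enumerate(_B62_ALPHA)}
_B62 = np.array(_BLOSUM62)


def blosum62_score(a: str, b: str) -> float:
    ia = _B62_INDEX.get(a, _B62_INDEX["X"])
    ib = _B62_INDEX.get(b, _B62_INDEX["X"])
    return float(_B62[ia, ib])


@dataclass
class SearchParams:
    """Search thresholds.  ``score_threshold`` stands in for the classical
    e-value cutoff (1e-10 in the mining protocol); it is a raw BLOSUM62
    score floor calibrated so that genuine receptor hits pass and chance
    word matches in ~megabase random sequence do not."""

    score_threshold: float = 60.0
    min_hit_len: int = 100  # nt, "<100 bp discarded" rule
    flank: int = 500  # nt extension on both sides of a merged locus
    word_size: int = 4
    matrix: str = "BLOSUM62"
    xdrop: float = 18.0
    frameshift_gap: int = 50  # nt; merge split-frame hits this close
    max_n_frac: float = 0.5

    def __post_init__(self) -> None:
        if self.min_hit_len <= 0:
            raise ValueError("min_hit_len must be > 0")
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass
class SearchHit:
    query_id: str
    contig_id: str
    strand: str  # + / -
    frame: int  # 0..2 within the strand
    start: int  # forward-strand nt, 0-based half-open
    end: int
    score: float
    aln_len: int  # nt

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CandidateLocus:
    contig_id: str
    strand: str
    start: int
    end: int
    hit_indices: list = field(default_factory=list)
    best_query: str = ""


@dataclass
class Frame:
    """One reading frame of a contig with its coordinate map."""

    strand: str
    frame: int
    protein: str
    contig_len: int

    def nt_interval(self, p_start: int, p_end: int) -> tuple[int, int]:
        """Forward-strand nt interval for protein positions [p_start, p_end)."""
        if self.strand == "+":
            return self.frame + 3 * p_start, self.frame + 3 * p_end
        L = self.contig_len
        return L - self.frame - 3 * p_end, L - self.frame - 3 * p_start


def sixframe_translate(contig: str) -> list[Frame]:
    """All six reading frames with coordinate maps (stops as '*')."""
    contig = contig.upper()
    L = len(contig)
    frames = []
    rc = revcomp(contig)
    for f in range(3):
        frames.append(Frame("+", f, translate(contig[f:]), L))
    for f in range(3):
        frames.append(Frame("-", f, translate(rc[f:]), L))
    return frames


def _extend_seed(q, s, qi, si, k, xdrop):
    """Ungapped X-drop extension of an exact word match.

    Returns (score, q_start, q_end, s_start, s_end)."""
    score = sum(blosum62_score(q[qi + j], s[si + j]) for j in range(k))
    # right
    best, best_r = score, 0
    cur, r = score, 0
    while qi + k + r < len(q) and si + k + r < len(s):
        cur += blosum62_score(q[qi + k + r], s[si + k + r])
        r += 1
        if cur > best:
            best, best_r = cur, r
        if best - cur > xdrop:
            break
    # left
    cur, l = best, 0
    best_l = 0
    while qi - l > 0 and si - l > 0:
        cur += blosum62_score(q[qi - l - 1], s[si - l - 1])
        l += 1
        if cur > best:
            best, best_l = cur, l
        if best - cur > xdrop:
            break
    return best, qi - best_l, qi + k + best_r, si - best_l, si + k + best_r


def search_genome(queries: dict, genome, params: SearchParams | None = None):
    """Search protein queries against all six frames of every contig.

    ``queries`` maps query id -> protein sequence; ``genome`` is a
    GenomeAssembly or a plain {contig_id: sequence} dict.  Returns a list of
    SearchHit sorted by (contig, start, query).  Contigs that are more than
    ``max_n_frac`` N are skipped with a warning.
    """
    params = params or SearchParams()
    contigs = getattr(genome, "contigs", genome)
    if not queries or not contigs:
        raise ValueError("queries and genome must be non-empty")
    k = params.word_size
    hits: list[SearchHit] = []
    for contig_id, seq in contigs.items():
        if len(seq) and seq.upper().count("N") / len(seq) > params.max_n_frac:
            logger.warning("contig %s skipped: >%.0f%% N", contig_id,
                           100 * params.max_n_frac)
            continue
        for fr in sixframe_translate(seq):
            index: dict[str, list[int]] = {}
            prot = fr.protein
            for i in range(len(prot) - k + 1):
                word = prot[i : i + k]
                if "*" in word or "X" in word:
                    continue
                index.setdefault(word, []).append(i)
            for qid, qseq in queries.items():
                covered: dict[int, list[tuple[int, int]]] = {}
                for qi in range(len(qseq) - k + 1):
                    for si in index.get(qseq[qi : qi + k], ()):
                        diag = si - qi
                        if any(a <= si < b for a, b in covered.get(diag, ())):
                            continue
                        score, qs, qe, ss, se = _extend_seed(
                            qseq, prot, qi, si, k, params.xdrop
                        )
                        covered.setdefault(diag, []).append((ss, se))
                        if score < params.score_threshold:
                            continue
                        # clip trailing stop columns from hit boundaries
                        while ss < se and prot[se - 1] == "*":
                            se -= 1
                            qe -= 1
                        while ss < se and prot[ss] == "*":
                            ss += 1
                            qs += 1
                        if ss >= se:
                            continue
                        start, end = fr.nt_interval(ss, se)
                        hits.append(
                            SearchHit(
                                query_id=qid,
                                contig_id=contig_id,
                                strand=fr.strand,
                                frame=fr.frame,
                                start=start,
                                end=end,
                                score=score,
                                aln_len=3 * (se - ss),
                            )
                        )
    hits = _dedupe(hits)
    hits.sort(key=lambda h: (h.contig_id, h.start, h.query_id, -h.score))
    return hits


def _dedupe(hits):
    """Drop identical-interval duplicates from overlapping seeds, keeping
    the best score per (query, contig, strand, frame, interval)."""
    best: dict[tuple, SearchHit] = {}
    for h in hits:
        key = (h.query_id, h.contig_id, h.strand, h.frame, h.start, h.end)
        if key not in best or h.score > best[key].score:
            best[key] = h
    return list(best.values())


def filter_hits(hits, params: SearchParams | None = None):
    """Discard hits spanning fewer than ``min_hit_len`` genomic nt."""
    params = params or SearchParams()
    return [h for h in hits if h.aln_len >= params.min_hit_len]


def merge_hits(hits, params: SearchParams | None = None):
    """Union overlapping hits (same contig and strand) into candidate loci.

    Hits in different reading frames separated by at most
    ``frameshift_gap`` nt are merged too: a frameshifted pseudogene
    presents as split hits and must become one locus.  Merging is
    transitive; loci are maximal and mutually disjoint per contig-strand.
    """
    params = params or SearchParams()
    groups: dict[tuple, list[tuple[int, SearchHit]]] = {}
    for i, h in enumerate(hits):
        groups.setdefault((h.contig_id, h.strand), []).append((i, h))
    loci = []
    for (contig_id, strand), members in sorted(groups.items()):
        members.sort(key=lambda ih: (ih[1].start, ih[1].end))
        cur: list[tuple[int, SearchHit]] = []
        cur_end = None
        cur_frames: set[int] = set()
        for i, h in members:
            joins = False
            if cur:
                if h.start < cur_end:
                    joins = True
                elif (
                    h.start - cur_end <= params.frameshift_gap
                    and h.frame not in cur_frames
                ):
                    joins = True
            if joins:
                cur.append((i, h))
                cur_end = max(cur_end, h.end)
                cur_frames.add(h.frame)
            else:
                if cur:
                    loci.append(_make_locus(contig_id, strand, cur))
                cur = [(i, h)]
                cur_end = h.end
                cur_frames = {h.frame}
        if cur:
            loci.append(_make_locus(contig_id, strand, cur))
    loci.sort(key=lambda l: (l.contig_id, l.start, l.strand))
    return loci


def _make_locus(contig_id, strand, members):
    best = max(members, key=lambda ih: ih[1].score)
    return CandidateLocus(
        contig_id=contig_id,
        strand=strand,
        start=min(h.start for _, h in members),
        end=max(h.end for _, h in members),
        hit_indices=[i for i, _ in members],
        best_query=best[1].query_id,
    )


def extend_locus(
    locus: CandidateLocus, params: SearchParams, contig_len: int
) -> CandidateLocus:
    """Extend a locus by ``flank`` nt both ways, clipped to the contig."""
    return CandidateLocus(
        contig_id=locus.contig_id,
        strand=locus.strand,
        start=max(0, locus.start - params.flank),
        end=min(contig_len, locus.end + params.flank),
        hit_indices=list(locus.hit_indices),
        best_query=locus.best_query,
    )


def hits_to_tsv(hits) -> str:
    lines = ["query\tcontig\tstrand\tframe\tstart\tend\tscore\taln_len"]
    for h in hits:
        lines.append(
            f"{h.query_id}\t{h.contig_id}\t{h.strand}\t{h.frame}\t"
            f"{h.start}\t{h.end}\t{h.score:.1f}\t{h.aln_len}"
        )
    return "\n".join(lines) + "\n"


def loci_to_bed(loci) -> str:
    return (
        "".join(
            f"{l.contig_id}\t{l.start}\t{l.end}\t{l.best_query}\t0\t{l.strand}\n"
            for l in loci
        )
    )
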