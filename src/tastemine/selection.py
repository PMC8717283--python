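"""Counting-based selective-pressure estimation.

Pairwise dN/dS follows Nei & Gojobori (1986): synonymous and nonsynonymous
site counts are the per-position fractions of single-nucleotide changes
that are synonymous (changes to stop codons excluded from the denominator,
positions renormalised so every codon contributes three sites), observed
differences are averaged over all shortest mutational pathways that avoid
stop codons, and proportions are Jukes--Cantor corrected,
d = -3/4 ln(1 - 4p/3).  omega = dN/dS (flagged undefined when dS = 0).

The site-wise scan is a counting stand-in for likelihood site models:
per-codon-site synonymous/nonsynonymous change counts are compared with
the neutral expectation from the site's codon composition by a binomial
tail probability; sites whose score (1 - tail probability) reaches the
threshold are labelled POSITIVE (nonsynonymous excess) or NEGATIVE
(nonsynonymous deficit).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from ._codons import CODON_TO_AA, SENSE_CODONS

POSITIVE, NEGATIVE, NEUTRAL = "POSITIVE", "NEGATIVE", "NEUTRAL"


# ---------------------------------------------------------------------------
# site counting
# ---------------------------------------------------------------------------


def count_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position, the fraction of the three single-nucleotide changes that
    is synonymous; changes creating a stop codon are excluded from the
    denominator and the position renormalised to weight 1, so
    syn + nonsyn == 3 for every codon.
    """
    codon = codon.upper()
    aa = CODON_TO_AA.get(codon)
    if aa is None or aa == "*":
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            alt_aa = CODON_TO_AA[alt]
            if alt_aa == "*":
                continue
            n_valid += 1
            if alt_aa == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


_SITE_CACHE = {c: count_sites(c) for c in SENSE_CODONS}


# ---------------------------------------------------------------------------
# pathway-averaged differences
# ---------------------------------------------------------------------------


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    uniformly over all shortest mutational pathways avoiding stops."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == "*":
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        # all pathways traverse stops; count every change nonsynonymous
        return 0.0, float(len(diff_pos))
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


_PATH_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def codon_differences(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    if key not in _PATH_CACHE:
        _PATH_CACHE[key] = _pathway_counts(c1, c2)
    return _PATH_CACHE[key]


# ---------------------------------------------------------------------------
# pairwise dN/dS
# ---------------------------------------------------------------------------


@dataclass
class DnDsResult:
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    dN: float | None
    dS: float | None
    omega: float | None
    undefined: bool
    n_codons: int


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def pairwise_dnds(seq1: str, seq2: str) -> DnDsResult:
    """Nei--Gojobori dN/dS between two aligned codon sequences.

    Codons containing a gap or ambiguity in either sequence are dropped
    (pairwise deletion).  omega is None (undefined flag set) when dS = 0
    or a Jukes--Cantor correction is out of range.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must be aligned (equal length)")
    if len(seq1) % 3:
        raise ValueError("alignment length must be a multiple of 3")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3].upper(), seq2[i : i + 3].upper()
        if c1 not in _SITE_CACHE or c2 not in _SITE_CACHE:
            continue  # gap / ambiguity / stop: pairwise deletion
        n_codons += 1
        s1, n1 = _SITE_CACHE[c1]
        s2, n2 = _SITE_CACHE[c2]
        S += (s1 + s2) / 2.0
        N += (n1 + n2) / 2.0
        sd, nd = codon_differences(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = _jukes_cantor(pS)
    dN = _jukes_cantor(pN)
    undefined = dS is None or dN is None or dS == 0.0
    omega = None if undefined else dN / dS
    return DnDsResult(
        N=N, S=S, Nd=Nd, Sd=Sd, pN=pN, pS=pS, dN=dN, dS=dS,
        omega=omega, undefined=undefined, n_codons=n_codons,
    )


def mean_family_omega(alignment) -> tuple[float | None, int, int]:
    """(mean omega, defined pairs, undefined pairs) over all sequence pairs.

    ``alignment`` is a CodonAlignment or a list of equal-length sequences.
    """
    seqs = getattr(alignment, "seqs", alignment)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    omegas = []
    undefined = 0
    for a, b in itertools.combinations(seqs, 2):
        r = pairwise_dnds(a, b)
        if r.undefined:
            undefined += 1
        else:
            omegas.append(r.omega)
    mean = float(np.mean(omegas)) if omegas else None
    return mean, len(omegas), undefined


def dnds_table(alignment) -> "object":
    """Pairwise dN/dS table as a pandas DataFrame."""
    import pandas as pd

    names = getattr(alignment, "names", None)
    seqs = getattr(alignment, "seqs", alignment)
    if names is None:
        names = [f"seq{i + 1}" for i in range(len(seqs))]
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(seqs), 2):
        r = pairwise_dnds(a, b)
        rows.append(
            {
                "seq1": names[i], "seq2": names[j],
                "N": r.N, "S": r.S, "Nd": r.Nd, "Sd": r.Sd,
                "dN": r.dN, "dS": r.dS, "omega": r.omega,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# site-wise selection scan
# ---------------------------------------------------------------------------


@dataclass
class SiteResult:
    site: int  # codon index
    nd: float
    sd: float
    expected_pn: float
    score: float  # 1 - binomial tail probability of the observed direction
    classification: str


@dataclass
class SiteScanResult:
    sites: list = field(default_factory=list)
    threshold: float = 0.9

    @property
    def positive_sites(self):
        return [s.site for s in self.sites if s.classification == POSITIVE]

    @property
    def negative_sites(self):
        return [s.site for s in self.sites if s.classification == NEGATIVE]


def _consensus_codon(codons: list[str]) -> str:
    counts: dict[str, int] = {}
    for c in codons:
        counts[c] = counts.get(c, 0) + 1
    return max(sorted(counts), key=lambda c: counts[c])


def site_selection_scan(
    alignment, tree=None, threshold: float = 0.9
) -> SiteScanResult:
    """Classify each codon column as POSITIVE / NEGATIVE / NEUTRAL.

    Changes per column are counted against the column's consensus codon
    (a star-tree parsimony: each mutation is counted roughly once, unlike
    all-pairs pooling which counts it up to n-1 times).  The observed
    nonsynonymous fraction is compared with the neutral expectation from
    the column's site composition by binomial tails; ``tree`` is accepted
    for interface compatibility and currently ignored beyond validation.
    """
    seqs = getattr(alignment, "seqs", alignment)
    if not seqs or len(seqs) < 2:
        raise ValueError("need at least two sequences")
    L = len(seqs[0]) // 3
    out = SiteScanResult(threshold=threshold)
    for site in range(L):
        codons = [s[3 * site : 3 * site + 3].upper() for s in seqs]
        codons = [c for c in codons if c in _SITE_CACHE]
        if len(codons) < 2:
            out.sites.append(
                SiteResult(site, 0, 0, 0.0, 0.0, NEUTRAL)
            )
            continue
        cons = _consensus_codon(codons)
        nd = sd = 0.0
        for c in codons:
            if c != cons:
                s_, n_ = codon_differences(cons, c)
                sd += s_
                nd += n_
        s_sites = np.mean([_SITE_CACHE[c][0] for c in codons])
        n_sites = 3.0 - s_sites
        p_n = n_sites / 3.0
        n_changes = int(round(nd + sd))
        if n_changes == 0:
            out.sites.append(SiteResult(site, nd, sd, p_n, 0.0, NEUTRAL))
            continue
        k = int(round(nd))
        # tail probabilities of the observed direction under neutrality
        p_excess = float(binom.sf(k - 1, n_changes, p_n))  # P(X >= k)
        p_deficit = float(binom.cdf(k, n_changes, p_n))  # P(X <= k)
        if 1.0 - p_excess >= threshold:
            cls, score = POSITIVE, 1.0 - p_excess
        elif 1.0 - p_deficit >= threshold:
            cls, score = NEGATIVE, 1.0 - p_deficit
        else:
            cls = NEUTRAL
            score = max(1.0 - p_excess, 1.0 - p_deficit)
        out.sites.append(SiteResult(site, nd, sd, p_n, score, cls))
    return out


def site_table_tsv(scan: SiteScanResult) -> str:
    lines = ["site\tnd\tsd\tscore\tclassification"]
    for s in scan.sites:
        lines.append(
            f"{s.site}\t{s.nd:.2f}\t{s.sd:.2f}\t{s.score:.3f}\t{s.classification}"
        )
    return "\n".join(lines) + "\n"
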