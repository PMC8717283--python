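"""Frame-aware guided alignment of a protein against a nucleotide locus.

A local dynamic program aligns a guide protein to a genomic locus at the
nucleotide level: the usual move consumes one codon (3 nt) per guide
residue, but 1- and 2-nt moves are allowed at a frameshift penalty, so a
single pass aligns across the ORF-disrupting indels that characterise
pseudogenes.  Premature stop codons are alignable columns (BLOSUM62 scores
'*' against everything) and are reported from the traceback, as are
coalesced frameshift events.

Coordinates are local to the supplied (strand-oriented) locus sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._codons import translate_codon
from .search import _B62, _B62_INDEX

# move codes stored in the pointer matrix
_NONE, _MATCH, _DEL3, _FS1, _FS2, _FSM1, _FSM2 = range(7)

# (nt consumed, query consumed) per move
_MOVE_SHAPE = {
    _MATCH: (3, 1),
    _DEL3: (3, 0),
    _FS1: (1, 0),
    _FS2: (2, 0),
    _FSM1: (1, 1),
    _FSM2: (2, 1),
}

DEL3_PENALTY = -10.0
FRAMESHIFT_PENALTY = -14.0
_NEG = -1e9


@dataclass
class Disruption:
    kind: str  # PREMATURE_STOP | FRAMESHIFT
    position: int  # codon index (stops) or nt offset in locus (frameshifts)
    length_mod3: int = 0  # net indel length mod 3, frameshifts only


@dataclass
class GuidedAlignment:
    score: float
    nt_start: int  # locus-local nt interval covered by the alignment
    nt_end: int
    q_start: int  # guide residue interval covered
    q_end: int
    path: list = field(default_factory=list)  # (move, nt_pos_after, q_pos_after)
    disruptions: list = field(default_factory=list)
    frame_at_start: int = 0
    frame_at_end: int = 0


def guided_align(locus: str, guide: str) -> GuidedAlignment | None:
    """Best local frame-aware alignment of ``guide`` to ``locus``.

    Returns None for empty inputs or when nothing aligns with positive
    score.
    """
    L, m = len(locus), len(guide)
    if L < 3 or m == 0:
        return None
    x_idx = _B62_INDEX["X"]
    q_idx = np.array([_B62_INDEX.get(a, x_idx) for a in guide])
    aa_idx = np.full(L, -1, dtype=np.int64)  # aa of codon starting at i
    for i in range(L - 2):
        aa_idx[i] = _B62_INDEX.get(translate_codon(locus[i : i + 3]), x_idx)

    H = np.zeros((L + 1, m + 1), dtype=np.float32)
    P = np.zeros((L + 1, m + 1), dtype=np.uint8)
    cand = np.empty((7, m + 1), dtype=np.float32)
    for i in range(1, L + 1):
        cand[_NONE] = 0.0
        for code in (_MATCH, _DEL3, _FS1, _FS2, _FSM1, _FSM2):
            dn, dq = _MOVE_SHAPE[code]
            row = cand[code]
            if i < dn:
                row[:] = _NEG
                continue
            if code == _MATCH:
                if aa_idx[i - 3] < 0:
                    row[:] = _NEG
                    continue
                row[0] = _NEG
                row[1:] = H[i - 3, :-1] + _B62[aa_idx[i - 3]][q_idx]
            elif code == _DEL3:
                row[:] = H[i - 3] + DEL3_PENALTY
            elif dq == 0:
                row[:] = H[i - dn] + FRAMESHIFT_PENALTY
            else:
                row[0] = _NEG
                row[1:] = H[i - dn, :-1] + FRAMESHIFT_PENALTY
        best = cand.argmax(axis=0)
        H[i] = cand[best, np.arange(m + 1)]
        P[i] = best
        np.maximum(H[i], 0.0, out=H[i])
        P[i][H[i] <= 0.0] = _NONE

    end_flat = int(H.argmax())
    i, j = divmod(end_flat, m + 1)
    score = float(H[i, j])
    if score <= 0.0:
        return None
    nt_end, q_end = i, j
    path = []
    while H[i, j] > 0.0 and P[i, j] != _NONE:
        code = int(P[i, j])
        path.append((code, i, j))
        dn, dq = _MOVE_SHAPE[code]
        i, j = i - dn, j - dq
    path.reverse()
    if not path:
        return None
    nt_start, q_start = i, j
    aln = GuidedAlignment(
        score=score,
        nt_start=nt_start,
        nt_end=nt_end,
        q_start=q_start,
        q_end=q_end,
        path=path,
        frame_at_start=nt_start % 3,
        frame_at_end=(nt_end - 3) % 3 if path else nt_start % 3,
    )
    aln.disruptions = _call_disruptions(path, aa_idx)
    # frame at the final matched codon
    for code, pi, _ in reversed(path):
        if code == _MATCH:
            aln.frame_at_end = (pi - 3) % 3
            break
    return aln


_STOP_IDX = _B62_INDEX["*"]


def _call_disruptions(path, aa_idx) -> list[Disruption]:
    out: list[Disruption] = []
    run_net = 0  # nt - 3*query consumed over a frameshift run
    run_start = None
    for code, i, j in path:
        dn, dq = _MOVE_SHAPE[code]
        if code in (_FS1, _FS2, _FSM1, _FSM2):
            if run_start is None:
                run_start = i - dn
            run_net += dn - 3 * dq
        else:
            if run_start is not None and run_net % 3 != 0:
                out.append(_frameshift(run_start, run_net))
            run_start, run_net = None, 0
            if code == _MATCH and aa_idx[i - 3] == _STOP_IDX:
                out.append(Disruption("PREMATURE_STOP", j - 1))
    if run_start is not None and run_net % 3 != 0:
        out.append(_frameshift(run_start, run_net))
    return out


def _frameshift(start: int, net: int) -> Disruption:
    # net > 0: insertion in the locus; net < 0: deletion.  The reported
    # value is the indel length mod 3, not the signed frame offset.
    length = net if net > 0 else -net
    return Disruption("FRAMESHIFT", start, length % 3)
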