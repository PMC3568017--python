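"""Frame-shift candidate enumeration and query-profile precomputation.

A frame-shifted match aligns 1, 2, 4 or 5 query nucleotides to one amino
acid by inserting 2 or 1, or deleting 1 or 2, nucleotides to recover a
triplet.  For a window of width ``w`` ending at query position ``j`` the
composite match score is

    m_w(a, window) = max_k [ m3(a, T_k) - P_k ]

over all candidate triplets ``T_k`` with their frame-shift penalties
``P_k``.  Since m_w does not depend on the protein, all five widths are
precomputed per query position into a :class:`QueryProfile`, which makes
each DP cell as cheap as in a standard Smith-Waterman-Gotoh scan.

Candidate spaces (window of 4 nucleotides: 4 single deletions; window of 5:
10 double deletions, 4 adjacent/grouped and 6 split; window of 2: 12 single
insertions over 10 distinct triplets; window of 1: 48 double insertions over
37 distinct triplets) follow the combinatorics of the frame-shift model.

Penalty pricing: a deletion is charged the single penalty discounted by the
deleted base's flowpeak deviation; a grouped double deletion is discounted
only when both bases come from the same flow (same run for FASTA input); an
insertion is discounted when it extends a flanking homopolymer or (with raw
flow data) when a matching zero flow lies between the flanking peaks; every
other event pays the full ``S`` (or ``D``).  Split doubles price their two
events independently and sum.  In neutral mode every event pays the full
penalty.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .flowspace import (
    AlignParams,
    FlowRead,
    deviation,
    flowpeak_call,
    frameshift_penalty,
    insertion_flowpeak,
    penalty_factor,
    valid_insertions,
)
from .scoring import AA_ALPHABET, NT_ALPHABET, encode_nt, triplet_score_table

__all__ = [
    "Candidate",
    "QueryProfile",
    "Pricing",
    "enumerate_deletions",
    "enumerate_insertions",
    "build_profile",
]

NEG = -np.inf


@dataclasses.dataclass(frozen=True)
class Candidate:
    """One way of resolving a window to a triplet by a frame-shift event."""

    triplet: str
    event: str  # del1 | del2-grouped | del2-split | ins1 | ins2-grouped | ins2-split
    positions: tuple[int, ...]  # deleted read positions, or insertion gap positions
    inserted: str  # inserted nucleotide(s), "" for deletions
    penalty: float

    @property
    def n_events(self) -> int:
        return 2 if self.event.endswith("split") else 1


class Pricing:
    """Per-read precomputed event prices under one parameter set.

    Arrays:
      del1[b]        single deletion of base b
      del2g[b]       grouped deletion of bases (b, b+1)
      ins1[g, c]     single insertion of nucleotide code c at gap g (0..L)
      ins2g[g, c]    grouped double insertion "cc" at gap g
      valid[g, c]    insertion validation mask (all True when V is off)
    """

    def __init__(self, read: FlowRead, params: AlignParams):
        self.read = read
        self.params = params
        L = len(read)
        S, D = params.S, params.D
        h, k = params.effective_h, params.k
        mode = params.mode
        seq = read.sequence
        codes = encode_nt(seq)
        self.codes = codes

        self.del1 = np.full(L, S, dtype=np.float64)
        self.del2g = np.full(max(L - 1, 0), D, dtype=np.float64)
        self.ins1 = np.full((L + 1, 4), S, dtype=np.float64)
        self.ins2g = np.full((L + 1, 4), D, dtype=np.float64)
        self.valid = np.ones((L + 1, 4), dtype=bool)

        if mode != "neutral":
            flow = mode == "flow454" and read.has_flow_data
            peaks = read.flowpeaks
            if peaks is None:
                peaks = read.run_length.astype(np.float64)
            # per-base called length: flow data -> call of its own peak
            # (robust when undercalls merge two runs); FASTA -> run length
            if flow:
                calls = np.maximum(1, np.floor(peaks + 0.5).astype(np.int64))
            else:
                calls = read.run_length
            self._peaks, self._calls = peaks, calls

            for b in range(L):
                f = penalty_factor(peaks[b], int(calls[b]), int(calls[b]) - 1, k)
                self.del1[b] = frameshift_penalty(S, h, f)
            same = (read.flow_index[:-1] == read.flow_index[1:]) if flow else (
                (codes[:-1] == codes[1:])
            )
            for b in range(L - 1):
                if same[b] and calls[b] >= 2:
                    f = penalty_factor(peaks[b], int(calls[b]), int(calls[b]) - 2, k)
                    self.del2g[b] = frameshift_penalty(D, h, f)

            for g in range(L + 1):
                for c in range(4):
                    nt = NT_ALPHABET[c]
                    fbest = None
                    for b in (g - 1, g):  # flanking bases matching nt extend a run
                        if 0 <= b < L and seq[b] == nt:
                            f1 = penalty_factor(peaks[b], int(calls[b]), int(calls[b]) + 1, k)
                            f2 = penalty_factor(peaks[b], int(calls[b]), int(calls[b]) + 2, k)
                            fbest = (f1, f2) if fbest is None else (
                                max(fbest[0], f1), max(fbest[1], f2))
                    if fbest is None and flow:
                        p0 = insertion_flowpeak(read, g, nt)
                        if p0 is not None:
                            fbest = (
                                penalty_factor(p0, 0, 1, k),
                                penalty_factor(p0, 0, 2, k),
                            )
                    if fbest is not None:
                        self.ins1[g, c] = frameshift_penalty(S, h, fbest[0])
                        self.ins2g[g, c] = frameshift_penalty(D, h, fbest[1])

        if params.V and mode != "neutral":
            for g in range(L + 1):
                ok = valid_insertions(read, g)
                for c in range(4):
                    self.valid[g, c] = NT_ALPHABET[c] in ok


# ---------------------------------------------------------------------------
# explicit candidate enumeration (public API; also used by traceback)


def enumerate_deletions(window: str, read: FlowRead, params: AlignParams,
                        start: int, pricing: Pricing | None = None) -> list[Candidate]:
    """All deletion candidates for a 4- or 5-nucleotide window starting at
    read position ``start``: exactly 4 for a single deletion, 10 for a
    double (4 grouped + 6 split)."""
    pricing = pricing or Pricing(read, params)
    w = len(window)
    out: list[Candidate] = []
    if w == 4:
        for d in range(4):
            trip = window[:d] + window[d + 1 :]
            out.append(Candidate(trip, "del1", (start + d,), "",
                                 float(pricing.del1[start + d])))
    elif w == 5:
        for d1 in range(5):
            for d2 in range(d1 + 1, 5):
                trip = "".join(window[i] for i in range(5) if i not in (d1, d2))
                if d2 == d1 + 1:
                    out.append(Candidate(trip, "del2-grouped",
                                         (start + d1, start + d2), "",
                                         float(pricing.del2g[start + d1])))
                else:
                    pen = float(pricing.del1[start + d1] + pricing.del1[start + d2])
                    out.append(Candidate(trip, "del2-split",
                                         (start + d1, start + d2), "", pen))
    else:
        raise ValueError(f"deletion window must have length 4 or 5, got {w}")
    return out


def enumerate_insertions(window: str, read: FlowRead, params: AlignParams,
                         start: int, pricing: Pricing | None = None) -> list[Candidate]:
    """All insertion candidates for a 2-nucleotide window (single insertion,
    up to 12 combinations) or 1-nucleotide window (double insertion, up to
    48).  With validation on, inserted nucleotides are restricted to those
    plausible at each gap position."""
    pricing = pricing or Pricing(read, params)
    w = len(window)
    use_valid = params.V and params.mode != "neutral"
    out: list[Candidate] = []

    def ok(g: int, c: int) -> bool:
        return (not use_valid) or bool(pricing.valid[g, c])

    if w == 2:
        gaps = (start, start + 1, start + 2)  # before, between, after
        for gi, g in enumerate(gaps):
            for c, nt in enumerate(NT_ALPHABET):
                if not ok(g, c):
                    continue
                trip = window[:gi] + nt + window[gi:]
                out.append(Candidate(trip, "ins1", (g,), nt,
                                     float(pricing.ins1[g, c])))
    elif w == 1:
        q = window
        gl, gr = start, start + 1
        for c1, a in enumerate(NT_ALPHABET):
            for c2, b in enumerate(NT_ALPHABET):
                # both before the base (grouped at gap gl)
                if ok(gl, c1) and ok(gl, c2):
                    pen = (pricing.ins2g[gl, c1] if c1 == c2
                           else params.D)
                    out.append(Candidate(a + b + q, "ins2-grouped",
                                         (gl,), a + b, float(pen)))
                # both after the base (grouped at gap gr)
                if ok(gr, c1) and ok(gr, c2):
                    pen = (pricing.ins2g[gr, c1] if c1 == c2
                           else params.D)
                    out.append(Candidate(q + a + b, "ins2-grouped",
                                         (gr,), a + b, float(pen)))
                # one on each side (split)
                if ok(gl, c1) and ok(gr, c2):
                    pen = pricing.ins1[gl, c1] + pricing.ins1[gr, c2]
                    out.append(Candidate(a + q + b, "ins2-split",
                                         (gl, gr), a + b, float(pen)))
    else:
        raise ValueError(f"insertion window must have length 1 or 2, got {w}")
    return out


def candidates_for(read: FlowRead, params: AlignParams, j: int, w: int,
                   pricing: Pricing | None = None) -> list[Candidate]:
    """Candidates for the width-``w`` window ending at read position ``j``
    (0-based, inclusive).  Width 3 has the single penalty-free candidate."""
    start = j - w + 1
    if start < 0:
        return []
    window = read.sequence[start : j + 1]
    if w == 3:
        return [Candidate(window, "match", (), "", 0.0)]
    if w in (4, 5):
        return enumerate_deletions(window, read, params, start, pricing)
    return enumerate_insertions(window, read, params, start, pricing)


def best_candidate(cands: Sequence[Candidate], aa_scores) -> tuple[Candidate, float]:
    """Deterministic argmax of ``m3(aa, T_k) - P_k``: ties break by fewer
    frame-shift events, then leftmost event position, then alphabetically
    smaller inserted nucleotides (TACG order is *not* used here; plain
    lexicographic order keeps output predictable)."""
    best = None
    best_score = NEG
    for cand in cands:
        s = aa_scores(cand.triplet) - cand.penalty
        key = (cand.n_events, cand.positions, cand.inserted)
        if best is None or s > best_score or (s == best_score and key < best[1]):
            best, best_score = (cand, key), s
    return best[0], best_score


# ---------------------------------------------------------------------------
# vectorised profile build


class QueryProfile:
    """Precomputed composite match scores.

    ``M[w-1, j, a]`` is the best width-``w`` score for the window ending at
    query position ``j`` against amino-acid index ``a`` (-inf when the
    window would run past the read start, or when validation removes every
    candidate).  Candidate detail is re-derived on demand during traceback.
    """

    def __init__(self, read: FlowRead, params: AlignParams, M: np.ndarray,
                 pricing: Pricing):
        self.read = read
        self.params = params
        self.M = M
        self.pricing = pricing

    def __len__(self) -> int:
        return len(self.read)


def build_profile(read: FlowRead, params: AlignParams,
                  matrix_name: str | None = None) -> QueryProfile:
    """Build the query profile for all widths 1..5 and all residues.

    Every cell equals the maximum over that window's candidates of
    ``m3(aa, T_k) - P_k`` (verifiable by re-enumeration); width 3 is the
    plain codon score.
    """
    pricing = Pricing(read, params)
    L = len(read)
    x = pricing.codes
    trip_aa = triplet_score_table(matrix_name or params.matrix.name)
    nA = trip_aa.shape[1]
    M = np.full((5, L, nA), NEG, dtype=np.float64)
    use_valid = params.V and params.mode != "neutral"
    validf = np.where(pricing.valid, 0.0, NEG) if use_valid else None

    def stackmax(trips: list[np.ndarray], pens: list[np.ndarray], w: int, j0: int):
        """M[w-1, j0:, :] = max over combos of trip_aa[trip] - pen."""
        best = np.full((L - j0, nA), NEG)
        for t, p in zip(trips, pens):
            np.maximum(best, trip_aa[t] + p[:, None], out=best)
        M[w - 1, j0:, :] = best

    # width 3: plain codon
    if L >= 3:
        t3 = 25 * x[:-2] + 5 * x[1:-1] + x[2:]
        M[2, 2:, :] = trip_aa[t3]

    # width 4: single deletion, windows ending at j >= 3
    if L >= 4:
        a, b, c, d = x[:-3], x[1:-2], x[2:-1], x[3:]
        pos = np.arange(L - 3)
        trips = [25 * b + 5 * c + d, 25 * a + 5 * c + d,
                 25 * a + 5 * b + d, 25 * a + 5 * b + c]
        pens = [-pricing.del1[pos + i] for i in range(4)]
        stackmax(trips, pens, 4, 3)

    # width 5: double deletion, windows ending at j >= 4
    if L >= 5:
        v = [x[i : L - 4 + i] for i in range(5)]
        pos = np.arange(L - 4)
        trips, pens = [], []
        for d1 in range(5):
            for d2 in range(d1 + 1, 5):
                keep = [i for i in range(5) if i not in (d1, d2)]
                trips.append(25 * v[keep[0]] + 5 * v[keep[1]] + v[keep[2]])
                if d2 == d1 + 1:
                    pens.append(-pricing.del2g[pos + d1])
                else:
                    pens.append(-(pricing.del1[pos + d1] + pricing.del1[pos + d2]))
        stackmax(trips, pens, 5, 4)

    # width 2: single insertion, windows ending at j >= 1
    if L >= 2:
        q1, q2 = x[:-1], x[1:]
        pos = np.arange(L - 1)  # window start
        trips, pens = [], []
        for gi in range(3):  # gap offset within window
            g = pos + gi
            for c in range(4):
                if gi == 0:
                    trips.append(25 * c + 5 * q1 + q2)
                elif gi == 1:
                    trips.append(25 * q1 + 5 * c + q2)
                else:
                    trips.append(25 * q1 + 5 * q2 + c)
                p = -pricing.ins1[g, c]
                if validf is not None:
                    p = p + validf[g, c]
                pens.append(p)
        stackmax(trips, pens, 2, 1)

    # width 1: double insertion
    q = x
    pos = np.arange(L)
    trips, pens = [], []
    for c1 in range(4):
        for c2 in range(4):
            grouped = (-pricing.ins2g[:, c1] if c1 == c2
                       else np.full(L + 1, -params.D))
            if validf is not None:
                vg = validf[:, c1] + validf[:, c2]
                grouped = grouped + vg
            # both before base (gap = pos), both after (gap = pos + 1)
            trips.append(25 * c1 + 5 * c2 + q)
            pens.append(grouped[pos])
            trips.append(25 * q + 5 * c1 + c2)
            pens.append(grouped[pos + 1])
            # split: c1 before, c2 after
            p = -(pricing.ins1[pos, c1] + pricing.ins1[pos + 1, c2])
            if validf is not None:
                p = p + validf[pos, c1] + validf[pos + 1, c2]
            trips.append(25 * c1 + 5 * q + c2)
            pens.append(p)
    stackmax(trips, pens, 1, 0)

    return QueryProfile(read, params, M, pricing)
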