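"""Frame-shift-capable Smith-Waterman-Gotoh alignment of a nucleotide read
(columns) against a protein (rows).

Cell recurrence::

    S[i,j] = max( S[i-1,j-1] + m1, S[i-1,j-2] + m2, S[i-1,j-3] + m3,
                  S[i-1,j-4] + m4, S[i-1,j-5] + m5, E[i,j], H[i,j], 0 )
    E[i,j] = max( S[i-1,j] - G0, E[i-1,j] - Ge )      # residue vs gap
    H[i,j] = max( S[i,j-3] - G0, H[i,j-3] - Ge )      # codon vs gap

where ``m_w`` comes from the precomputed query profile.  Traceback starts at
the global maximum and stops at the local-alignment floor.  Ties in the cell
maximum resolve in the order listed above, which together with the
profile's deterministic candidate order makes the traceback reproducible.

``H`` is undefined for ``j < 3`` at gap opening; those cells hold the floor.
Frame-shift events exist only inside the width-1/2/4/5 matches, so protein
gaps and frame-shifts never merge into one event.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from .flowspace import (
    AlignParams,
    FlowRead,
    frameshift_penalty,
    insertion_flowpeak,
    penalty_factor,
    valid_insertions,
    validate_params,
)
from .profile import (
    Candidate,
    QueryProfile,
    best_candidate,
    build_profile,
    candidates_for,
)
from .scoring import AA_ALPHABET, NT_ALPHABET, encode_protein, m3_score, translate_codon

__all__ = [
    "AlignmentResult",
    "Column",
    "align",
    "align_read",
    "brute_force_align",
    "alignment_stats",
    "format_alignment",
]

NEG = -np.inf


# ---------------------------------------------------------------------------
# DP kernel


def _dp_py(M, prot, G0, Ge):
    P = prot.shape[0]
    L = M.shape[1]
    S = np.zeros((P + 1, L + 1))
    E = np.full((P + 1, L + 1), -np.inf)
    H = np.full((P + 1, L + 1), -np.inf)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, P + 1):
        ai = prot[i - 1]
        for j in range(1, L + 1):
            e = S[i - 1, j] - G0
            if E[i - 1, j] - Ge > e:
                e = E[i - 1, j] - Ge
            E[i, j] = e
            h = -np.inf
            if j >= 3:
                h = S[i, j - 3] - G0
                if H[i, j - 3] - Ge > h:
                    h = H[i, j - 3] - Ge
            H[i, j] = h
            s = 0.0
            for w in range(1, 6):
                if j - w >= 0:
                    m = M[w - 1, j - 1, ai]
                    if m > -np.inf:
                        v = S[i - 1, j - w] + m
                        if v > s:
                            s = v
            if e > s:
                s = e
            if h > s:
                s = h
            S[i, j] = s
            if s > best:
                best = s
                bi = i
                bj = j
    return S, E, H, best, bi, bj


try:  # pragma: no cover - exercised implicitly
    import numba

    _dp = numba.njit(cache=True, fastmath=False)(_dp_py)
except Exception:  # pragma: no cover
    _dp = _dp_py


# ---------------------------------------------------------------------------
# result containers


@dataclasses.dataclass
class Column:
    """One alignment column: an amino acid vs a (possibly frame-shifted)
    codon chunk, or a gap on either side."""

    kind: str  # "match" | "pgap" | "qgap"
    aa: str = ""
    width: int = 0  # query nucleotides consumed
    window: str = ""  # original query nucleotides in this column
    candidate: Candidate | None = None
    gap_open: bool = False
    score: float = 0.0


@dataclasses.dataclass
class AlignmentResult:
    """Traceback product of one read-vs-protein alignment.

    Ranges are 0-based half-open.  ``events`` lists every frame-shifted
    nucleotide as ``(kind, position, nucleotide)`` where *position* is the
    deleted read position for ``"del"`` and the insertion gap index (between
    read bases ``g-1`` and ``g``) for ``"ins"``.
    """

    query_id: str
    target_id: str
    score: float
    prot_range: tuple[int, int]
    query_range: tuple[int, int]
    columns: list[Column]
    query_length: int
    protein_length: int

    @property
    def events(self) -> list[tuple[str, int, str]]:
        out = []
        for col in self.columns:
            cand = col.candidate
            if cand is None or cand.event == "match":
                continue
            if cand.event.startswith("del"):
                for pos in cand.positions:
                    out.append(("del", pos, self.query_sequence_at(pos)))
            elif cand.event == "ins1":
                out.append(("ins", cand.positions[0], cand.inserted))
            elif cand.event == "ins2-grouped":
                g = cand.positions[0]
                out.append(("ins", g, cand.inserted[0]))
                out.append(("ins", g, cand.inserted[1]))
            else:  # ins2-split
                out.append(("ins", cand.positions[0], cand.inserted[0]))
                out.append(("ins", cand.positions[1], cand.inserted[1]))
        return out

    _query_seq: str = ""

    def query_sequence_at(self, pos: int) -> str:
        return self._query_seq[pos] if self._query_seq else "N"

    @property
    def n_gaps(self) -> int:
        """Number of frame-shifting gap events (grouped doubles count once,
        split doubles twice)."""
        return sum(c.candidate.n_events for c in self.columns
                   if c.candidate is not None and c.candidate.event != "match")

    @property
    def is_empty(self) -> bool:
        return not self.columns


# ---------------------------------------------------------------------------
# alignment + traceback


def align(profile: QueryProfile, protein: str, target_id: str = "target") -> AlignmentResult:
    """Optimal local alignment of the profiled read against ``protein``."""
    if len(protein) < 1:
        raise ValueError("protein must contain at least one residue")
    params = validate_params(profile.params)
    read = profile.read
    prot_idx = encode_protein(protein)
    S, E, H, best, bi, bj = _dp(profile.M, prot_idx, params.G0, params.Ge)

    columns: list[Column] = []
    if best <= 0:
        res = AlignmentResult(read.id, target_id, 0.0, (0, 0), (0, 0), [],
                              len(read), len(protein))
        res._query_seq = read.sequence
        return res

    i, j = bi, bj
    state = "S"
    while True:
        if state == "S":
            s = S[i, j]
            if s <= 0:
                break
            ai = prot_idx[i - 1]
            moved = False
            for w in range(1, 6):
                if j - w < 0:
                    continue
                m = profile.M[w - 1, j - 1, ai]
                if m == NEG:
                    continue
                if S[i - 1, j - w] + m == s:
                    cands = candidates_for(read, params, j - 1, w, profile.pricing)
                    matrix = params.matrix
                    aa = protein[i - 1]
                    cand, cscore = best_candidate(
                        cands, lambda t: m3_score(aa, t, matrix))
                    columns.append(Column("match", aa, w,
                                          read.sequence[j - w : j], cand,
                                          score=cscore))
                    i -= 1
                    j -= w
                    moved = True
                    break
            if moved:
                continue
            if E[i, j] == s:
                state = "E"
            elif H[i, j] == s:
                state = "H"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback: no predecessor matches cell score")
        elif state == "E":
            opened = S[i - 1, j] - params.G0 == E[i, j]
            columns.append(Column("pgap", protein[i - 1], 0, "", None,
                                  gap_open=opened,
                                  score=-(params.G0 if opened else params.Ge)))
            i -= 1
            state = "S" if opened else "E"
            if state == "E":
                # continue consuming the extension chain
                continue
        elif state == "H":
            opened = S[i, j - 3] - params.G0 == H[i, j]
            columns.append(Column("qgap", "", 3, read.sequence[j - 3 : j], None,
                                  gap_open=opened,
                                  score=-(params.G0 if opened else params.Ge)))
            j -= 3
            state = "S" if opened else "H"

    columns.reverse()
    res = AlignmentResult(read.id, target_id, float(best), (i, bi), (j, bj),
                          columns, len(read), len(protein))
    res._query_seq = read.sequence
    return res


def align_read(read: FlowRead, protein: str, params: AlignParams,
               target_id: str = "target") -> AlignmentResult:
    """Convenience wrapper: build the profile and align."""
    return align(build_profile(read, params), protein, target_id)


# ---------------------------------------------------------------------------
# statistics & formatting


def alignment_stats(result: AlignmentResult) -> dict:
    """Identities, positives, coverage, protein-space gaps and frame-shift
    count of an alignment."""
    identities = positives = 0
    ncols = len(result.columns)
    for col in result.columns:
        if col.kind != "match":
            continue
        trans = translate_codon(col.candidate.triplet)
        if trans == col.aa and trans != "X":
            identities += 1
        if col.score + col.candidate.penalty > 0:
            positives += 1
    gaps = sum(1 for c in result.columns if c.kind in ("pgap", "qgap"))
    j0, j1 = result.query_range
    covered = j1 - j0

    def frac(a, b):
        pct = int(round(100.0 * a / b)) if b else 0
        return f"{a}/{b} ({pct}%)"

    return {
        "score": result.score,
        "length": ncols,
        "identities": identities,
        "positives": positives,
        "identities_str": frac(identities, ncols),
        "positives_str": frac(positives, ncols),
        "coverage_str": frac(covered, result.query_length),
        "gaps": gaps,
        "nGaps": result.n_gaps,
    }


def _column_chunks(col: Column) -> tuple[str, str, str]:
    """(query, match, protein) strings for one column; frame-shifted and
    inserted nucleotides are lowercase."""
    if col.kind == "pgap":
        return "---", "   ", col.aa + "  "
    if col.kind == "qgap":
        return col.window, "   ", "-  "
    cand = col.candidate
    if cand.event == "match":
        q = col.window
    elif cand.event.startswith("del"):
        q = _mark_deleted(col)
    else:
        q = _mark_inserted(col)
    sym = " "
    trans = translate_codon(cand.triplet)
    if trans == col.aa and trans != "X":
        sym = "|"
    elif col.score + cand.penalty > 0:
        sym = "+"
    width = len(q)
    mid = sym.center(3).ljust(width)
    prot = col.aa.ljust(width)
    return q, mid, prot


def _mark_deleted(col: Column) -> str:
    """Window with the deleted nucleotides lowercase.

    Deleted offsets are recovered by matching the kept triplet against the
    window; homopolymer-equivalent choices are indistinguishable in print,
    so the leftmost consistent marking is used.
    """
    w = col.width
    window = col.window
    npos = len(col.candidate.positions)
    for offs in itertools.combinations(range(w), npos):
        kept = "".join(window[i] for i in range(w) if i not in offs)
        if kept == col.candidate.triplet:
            return "".join(c.lower() if i in offs else c
                           for i, c in enumerate(window))
    return window  # pragma: no cover


def _mark_inserted(col: Column) -> str:
    cand = col.candidate
    window = col.window
    if cand.event == "ins1":
        # triplet is window with one lowercase char inserted
        for gi in range(len(window) + 1):
            trip = window[:gi] + cand.inserted + window[gi:]
            if trip == cand.triplet:
                return window[:gi] + cand.inserted.lower() + window[gi:]
    elif cand.event == "ins2-grouped":
        ins = cand.inserted
        if cand.triplet == ins + window:
            return ins.lower() + window
        return window + ins.lower()
    else:  # ins2-split
        a, b = cand.inserted
        return a.lower() + window + b.lower()
    return window  # pragma: no cover


def format_alignment(result: AlignmentResult, line_width: int = 60) -> str:
    """Human-readable three-row alignment block with a stats header.

    Frame-shifted nucleotides print lowercase; inserted nucleotides are the
    maximum-likelihood predictions substituted into the query row.
    """
    stats = alignment_stats(result)
    lines = [
        f"Query: {result.query_id} ({result.query_length} nt)",
        f"Target: {result.target_id} ({result.protein_length} aa)",
        (f"Score: {stats['score']:g}  Identities: {stats['identities_str']}  "
         f"Positives: {stats['positives_str']}"),
        (f"Coverage: {stats['coverage_str']}  Gaps: {stats['gaps']}  "
         f"nGaps: {stats['nGaps']}"),
        "",
    ]
    if result.is_empty:
        lines.append("(no alignment)")
        return "\n".join(lines) + "\n"

    chunks = [_column_chunks(c) for c in result.columns]
    qpos = result.query_range[0] + 1  # 1-based display
    ppos = result.prot_range[0] + 1
    idx = 0
    while idx < len(chunks):
        qrow = mrow = prow = ""
        q0, p0 = qpos, ppos
        while idx < len(chunks) and len(qrow) + len(chunks[idx][0]) <= line_width:
            q, m, p = chunks[idx]
            col = result.columns[idx]
            qrow += q
            mrow += m
            prow += p
            qpos += col.width
            if col.kind != "qgap":
                ppos += 1
            idx += 1
        lines.append(f"Query  {q0:>5} {qrow} {qpos - 1}")
        lines.append(f"       {'':>5} {mrow}")
        lines.append(f"Target {p0:>5} {prow} {ppos - 1}")
        lines.append("")
    return "\n".join(lines) + "\n"


def parse_header(text: str) -> dict:
    """Recover the stats record from a formatted alignment header."""
    import re

    out = {}
    m = re.search(r"Score: ([\d.eE+-]+)\s+Identities: (\d+)/(\d+) \((\d+)%\)\s+"
                  r"Positives: (\d+)/(\d+)", text)
    out["score"] = float(m.group(1))
    out["identities"] = int(m.group(2))
    out["length"] = int(m.group(3))
    out["positives"] = int(m.group(5))
    m = re.search(r"Coverage: (\d+)/(\d+) \((\d+)%\)\s+Gaps: (\d+)\s+nGaps: (\d+)", text)
    out["coverage"] = (int(m.group(1)), int(m.group(2)))
    out["gaps"] = int(m.group(4))
    out["nGaps"] = int(m.group(5))
    return out


# ---------------------------------------------------------------------------
# independent small-instance oracle


_ORACLE_MAX = (6, 20)  # protein residues, read nucleotides


def brute_force_align(read: FlowRead, protein: str, params: AlignParams) -> float:
    """Exhaustive reference scorer for tiny instances.

    Re-derives every candidate triplet by direct combinatorial enumeration
    (no query profile) and evaluates the alignment recurrences by plain
    recursion over cell states, independent of the production DP kernel and
    traceback.  Refuses inputs beyond ~6 residues x ~20 nucleotides.
    """
    if len(protein) > _ORACLE_MAX[0] or len(read) > _ORACLE_MAX[1]:
        raise ValueError("brute_force_align is restricted to tiny instances")
    params = validate_params(params)
    matrix = params.matrix
    seq = read.sequence
    L = len(seq)
    mode = params.mode
    S0, D0 = params.S, params.D
    h, k = params.effective_h, params.k
    flow = mode == "flow454" and read.has_flow_data
    use_valid = params.V and mode != "neutral"

    peaks = read.flowpeaks
    if peaks is None:
        peaks = read.run_length.astype(float)

    def call_of(b):
        if flow:
            return max(1, int(np.floor(peaks[b] + 0.5)))
        return int(read.run_length[b])

    def price_del1(b):
        if mode == "neutral":
            return S0
        n = call_of(b)
        return frameshift_penalty(S0, h, penalty_factor(peaks[b], n, n - 1, k))

    def price_del2(b1, b2):
        if b2 == b1 + 1:
            if mode != "neutral":
                same = (read.flow_index[b1] == read.flow_index[b2]) if flow \
                    else seq[b1] == seq[b2]
                n = call_of(b1)
                if same and n >= 2:
                    return frameshift_penalty(
                        D0, h, penalty_factor(peaks[b1], n, n - 2, k))
            return D0
        return price_del1(b1) + price_del1(b2)

    def price_ins1(g, nt):
        if mode == "neutral":
            return S0
        f = None
        for b in (g - 1, g):
            if 0 <= b < L and seq[b] == nt:
                n = call_of(b)
                fb = penalty_factor(peaks[b], n, n + 1, k)
                f = fb if f is None else max(f, fb)
        if f is None and flow:
            p0 = insertion_flowpeak(read, g, nt)
            if p0 is not None:
                f = penalty_factor(p0, 0, 1, k)
        return frameshift_penalty(S0, h, f) if f is not None else S0

    def price_ins2g(g, nt):
        if mode == "neutral":
            return D0
        f = None
        for b in (g - 1, g):
            if 0 <= b < L and seq[b] == nt:
                n = call_of(b)
                fb = penalty_factor(peaks[b], n, n + 2, k)
                f = fb if f is None else max(f, fb)
        if f is None and flow:
            p0 = insertion_flowpeak(read, g, nt)
            if p0 is not None:
                f = penalty_factor(p0, 0, 2, k)
        return frameshift_penalty(D0, h, f) if f is not None else D0

    def allowed(g, nt):
        return (not use_valid) or nt in valid_insertions(read, g)

    def m_w(aa, j, w):
        """Best composite score, window of width w ending at read pos j-1
        (1-based j nucleotides consumed)."""
        start = j - w
        if start < 0:
            return NEG
        window = seq[start:j]
        best = NEG
        if w == 3:
            return m3_score(aa, window, matrix)
        if w == 4:
            for d in range(4):
                trip = window[:d] + window[d + 1 :]
                best = max(best, m3_score(aa, trip, matrix) - price_del1(start + d))
        elif w == 5:
            for d1, d2 in itertools.combinations(range(5), 2):
                trip = "".join(window[i] for i in range(5) if i not in (d1, d2))
                best = max(best, m3_score(aa, trip, matrix)
                           - price_del2(start + d1, start + d2))
        elif w == 2:
            for gi, g in enumerate((start, start + 1, start + 2)):
                for nt in NT_ALPHABET:
                    if not allowed(g, nt):
                        continue
                    trip = window[:gi] + nt + window[gi:]
                    best = max(best, m3_score(aa, trip, matrix) - price_ins1(g, nt))
        else:  # w == 1
            gl, gr = start, start + 1
            for a in NT_ALPHABET:
                for b in NT_ALPHABET:
                    if allowed(gl, a) and allowed(gl, b):
                        pen = price_ins2g(gl, a) if a == b else D0
                        best = max(best, m3_score(aa, a + b + window, matrix) - pen)
                    if allowed(gr, a) and allowed(gr, b):
                        pen = price_ins2g(gr, a) if a == b else D0
                        best = max(best, m3_score(aa, window + a + b, matrix) - pen)
                    if allowed(gl, a) and allowed(gr, b):
                        best = max(best, m3_score(aa, a + window + b, matrix)
                                   - price_ins1(gl, a) - price_ins1(gr, b))
        return best

    from functools import lru_cache

    P = len(protein)

    @lru_cache(maxsize=None)
    def cell(i, j, state):
        if state == "E":
            if i < 1:
                return NEG
            return max(cell(i - 1, j, "S") - params.G0,
                       cell(i - 1, j, "E") - params.Ge)
        if state == "H":
            if j < 3:
                return NEG
            return max(cell(i, j - 3, "S") - params.G0,
                       cell(i, j - 3, "H") - params.Ge)
        # S state
        if i == 0 or j < 0:
            return 0.0 if i >= 0 and j >= 0 else NEG
        if j == 0:
            return 0.0
        best = 0.0
        aa = protein[i - 1]
        for w in range(1, 6):
            if j - w >= 0:
                m = m_w(aa, j, w)
                if m > NEG:
                    best = max(best, cell(i - 1, j - w, "S") + m)
        best = max(best, cell(i, j, "E"), cell(i, j, "H"))
        return best

    return max(cell(i, j, "S") for i in range(P + 1) for j in range(L + 1))
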