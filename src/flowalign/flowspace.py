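"""Flow-space data model for pyrosequencing reads.

454-style pyrosequencing cycles nucleotide reagents over the template in a
fixed flow order (default ``TACG``) and records one signal intensity — a
*flowpeak* — per flow.  The rounded flowpeak is the called homopolymer
length, so base-calling errors concentrate at homopolymer boundaries and
appear as insertions (undercalls of the peak) or deletions (overcalls) in
the read.  This module holds the read container carrying that per-base
flowpeak annotation, the SFF reader/writer, and the position-specific
frame-shift penalty model driven by flowpeak deviations.

Penalty model
-------------
A frame-shift gap normally costs the full single (``S``) or double (``D``)
penalty, but at a homopolymer it is discounted according to how far the
flowpeak ``p`` sits from the alternative call ``m``:

``Dev_m(p, n) = p - (m + 0.5)`` for a down-call (``m < n``), ``(m - 0.5) - p``
for an up-call (``m > n``), and ``0`` for ``m = n``; deviations are clamped
at zero.  The discount factor is ``f = 1 - Dev / (k * max(n, 1))`` clamped
to [0, 1], and the penalty paid is ``P0 - P0*(1-h)*f`` — i.e. the full
penalty at ``f = 0`` falling linearly to the floor ``P0*h`` at ``f = 1``.
``k`` is thus the relative deviation at which the full penalty applies.

Without flowpeak data (FASTA input) the flowpeak of a base is taken to be
its homopolymer run length, which makes insertion and deletion discounts at
a run equal and monotone in run length.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

from .scoring import NT_ALPHABET, SubstitutionMatrix, load_matrix

__all__ = [
    "FlowRead",
    "AlignParams",
    "ParameterError",
    "annotate_fasta",
    "read_sff",
    "write_sff",
    "deviation",
    "penalty_factor",
    "frameshift_penalty",
    "flowpeak_call",
    "valid_insertions",
    "insertion_flowpeak",
    "validate_params",
    "MODES",
]

DEFAULT_FLOW_ORDER = "TACG"
MODES = ("neutral", "fasta454", "flow454")


class ParameterError(ValueError):
    """An alignment-parameter combination the model rejects."""


# ---------------------------------------------------------------------------
# read container


@dataclasses.dataclass
class FlowRead:
    """A nucleotide query with optional per-base flowpeak annotation.

    ``flowpeaks[b]`` is the signal of the flow that called base ``b`` (1.0 =
    one incorporation); ``run_length[b]`` is the length of the maximal
    homopolymer run containing ``b`` and ``run_end[b]`` flags its last base.
    ``flow_index[b]`` indexes into ``flow_values`` (the full flowgram,
    including zero flows) when raw flow data are available.
    """

    id: str
    sequence: str
    flowpeaks: np.ndarray | None = None
    run_length: np.ndarray | None = None
    run_end: np.ndarray | None = None
    flow_index: np.ndarray | None = None
    flow_order: str = DEFAULT_FLOW_ORDER
    flow_values: np.ndarray | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        for c in self.sequence:
            if c not in "TACGN":
                raise ValueError(f"read {self.id!r}: invalid nucleotide {c!r}")
        if self.run_length is None:
            self.run_length, self.run_end = _runs(self.sequence)
        if self.flowpeaks is not None:
            self.flowpeaks = np.asarray(self.flowpeaks, dtype=np.float64)
            if len(self.flowpeaks) != len(self.sequence):
                raise ValueError("flowpeaks length != sequence length")
            if not np.all(np.isfinite(self.flowpeaks)) or np.any(self.flowpeaks < 0):
                raise ValueError("flowpeaks must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_flow_data(self) -> bool:
        return self.flow_index is not None and self.flow_values is not None

    def reverse_complement(self) -> "FlowRead":
        """The read on the opposite strand, with its flowgram reversed and
        complemented so that per-base flowpeaks and zero-flow lookups stay
        meaningful."""
        comp = str.maketrans("TACGN", "ATGCN")
        seq = self.sequence.translate(comp)[::-1]
        fp = None if self.flowpeaks is None else self.flowpeaks[::-1].copy()
        fi = fv = None
        order = self.flow_order
        if self.has_flow_data:
            n_fl = len(self.flow_values)
            fv = self.flow_values[::-1].copy()
            fi = (n_fl - 1 - self.flow_index)[::-1].copy()
            # flow characters reverse and complement; keep explicit order
            chars = _flow_chars(self.flow_order, n_fl).translate(comp)[::-1]
            order = chars  # non-cyclic explicit flow string
        return FlowRead(self.id, seq, flowpeaks=fp, flow_index=fi,
                        flow_order=order, flow_values=fv)


def _runs(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-base homopolymer run length and run-end flag."""
    L = len(sequence)
    run_length = np.empty(L, dtype=np.int64)
    run_end = np.zeros(L, dtype=bool)
    i = 0
    while i < L:
        j = i
        while j + 1 < L and sequence[j + 1] == sequence[i]:
            j += 1
        run_length[i : j + 1] = j - i + 1
        run_end[j] = True
        i = j + 1
    return run_length, run_end


def _flow_chars(flow_order: str, n_flows: int) -> str:
    reps = -(-n_flows // len(flow_order))
    return (flow_order * reps)[:n_flows]


def annotate_fasta(sequence: str, id: str = "query") -> FlowRead:
    """Build a :class:`FlowRead` from a bare nucleotide string.

    Without flow data the flowpeak of every base is its homopolymer run
    length, so integer peaks make insertion and deletion discounts coincide.
    """
    read = FlowRead(id, sequence)
    read.flowpeaks = read.run_length.astype(np.float64)
    return read


# ---------------------------------------------------------------------------
# SFF I/O (Roche SFF v1.00 via Biopython)


def read_sff(path) -> list[FlowRead]:
    """Read an SFF v1.00 file into :class:`FlowRead` objects.

    Flow values are decoded to signal units (stored value / 100); per-base
    flow indices are reconstructed from the cumulative index-per-flow bytes
    and quality/adapter clipping is applied so that ``sequence`` covers only
    the clipped region.
    """
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(str(path), "sff"):
        flow_values = np.asarray(rec.annotations["flow_values"], dtype=np.float64) / 100.0
        offsets = np.asarray(rec.annotations["flow_index"], dtype=np.int64)
        flow_index = np.cumsum(offsets) - 1
        flow_chars = rec.annotations["flow_chars"]
        seq = str(rec.seq).upper()
        left = max(rec.annotations.get("clip_qual_left", 0),
                   rec.annotations.get("clip_adapter_left", 0))
        rights = [v for v in (rec.annotations.get("clip_qual_right", 0),
                              rec.annotations.get("clip_adapter_right", 0)) if v]
        start = left - 1 if left > 0 else 0
        stop = min(rights) if rights else len(seq)
        seq_c = seq[start:stop]
        fi = flow_index[start:stop]
        if not seq_c:
            raise ValueError(f"SFF record {rec.id!r}: clipping removed all bases")
        reads.append(
            FlowRead(
                rec.id,
                seq_c,
                flowpeaks=flow_values[fi],
                flow_index=fi,
                flow_order=flow_chars,
                flow_values=flow_values,
            )
        )
    return reads


def write_sff(path, reads: Iterable[FlowRead], flow_order: str | None = None) -> None:
    """Write :class:`FlowRead` objects with flow data to an SFF v1.00 file.

    A minimal writer used to build test fixtures and to persist simulated
    reads; reads must carry ``flow_values`` and ``flow_index``.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    n_flows = None
    for read in reads:
        if not read.has_flow_data:
            raise ValueError(f"read {read.id!r} has no flow data")
        if n_flows is None:
            n_flows = len(read.flow_values)
        elif len(read.flow_values) != n_flows:
            raise ValueError("all reads in one SFF file must share the flow count")
        rec = SeqRecord(Seq(read.sequence), id=read.id, description="")
        rec.annotations["flow_values"] = [int(round(v * 100)) for v in read.flow_values]
        offs = np.diff(np.concatenate([[-1], read.flow_index])) .astype(int)
        if np.any(offs < 0) or np.any(offs > 255):
            raise ValueError("flow_index offsets out of SFF range")
        rec.annotations["flow_index"] = [int(o) for o in offs]
        rec.annotations["flow_chars"] = _flow_chars(read.flow_order, n_flows)
        rec.annotations["flow_key"] = "TCAG"
        for k in ("clip_qual_left", "clip_qual_right",
                  "clip_adapter_left", "clip_adapter_right"):
            rec.annotations[k] = 0
        rec.letter_annotations["phred_quality"] = [30] * len(read.sequence)
        records.append(rec)
    with open(path, "wb") as handle:
        SeqIO.write(records, handle, "sff")


# ---------------------------------------------------------------------------
# penalty model


def flowpeak_call(p: float) -> int:
    """Called homopolymer length of a flowpeak: the nearest integer, with the
    call interval ``n - 0.5 <= p < n + 0.5``."""
    return int(np.floor(p + 0.5))


def deviation(p: float, n: int, m: int) -> float:
    """Relative flowpeak deviation required for an ``n``-mer peak ``p`` to be
    called as an ``m``-mer; clamped at zero so boundary peaks never go
    negative."""
    if m < n:
        d = p - (m + 0.5)
    elif m == n:
        d = 0.0
    else:
        d = (m - 0.5) - p
    return max(0.0, d)


def penalty_factor(p: float, n: int, m: int, k: float) -> float:
    """Discount factor ``f in [0, 1]``: 1 at zero deviation, 0 once the
    deviation reaches ``k * max(n, 1)``."""
    if k <= 0:
        raise ParameterError("k must be > 0")
    f = 1.0 - deviation(p, n, m) / (k * max(n, 1))
    return min(1.0, max(0.0, f))


def frameshift_penalty(P0: float, h: float, f: float) -> float:
    """Position-specific frame-shift penalty ``P0 - P0*(1-h)*f``.

    Equals the full ``P0`` at ``f = 0`` and the homopolymer floor ``P0*h``
    at ``f = 1``.
    """
    return P0 - P0 * (1.0 - h) * f


# ---------------------------------------------------------------------------
# insertion validation


def _fasta_flow_indices(read: FlowRead) -> np.ndarray:
    """Reconstruct per-base flow indices by simulating the default flow order
    over the called sequence (used when raw flow data are absent)."""
    order = read.flow_order or DEFAULT_FLOW_ORDER
    cyc = len(order)
    fi = np.empty(len(read), dtype=np.int64)
    pos = -1
    prev = None
    for b, c in enumerate(read.sequence):
        if c == prev:
            fi[b] = fi[b - 1]
            continue
        t = pos + 1
        while order[t % cyc] != c:
            t += 1
            if t - pos > cyc + 1:  # N or unknown base: park on next flow
                t = pos + 1
                break
        fi[b] = t
        pos = t
        prev = c
    return fi


def _flow_char(read: FlowRead, t: int) -> str:
    order = read.flow_order or DEFAULT_FLOW_ORDER
    return order[t % len(order)] if len(order) <= 8 else order[t]


def valid_insertions(read: FlowRead, gap_position: int) -> set[str]:
    """Nucleotides plausibly insertable between bases ``gap_position - 1``
    and ``gap_position``.

    A nucleotide is plausible if its reagent was flowed strictly between the
    flows of the two flanking bases (it could hide a false-negative peak), or
    if it extends either flanking base's homopolymer.  Read ends permit all
    four nucleotides.
    """
    L = len(read)
    if gap_position <= 0 or gap_position >= L:
        return set(NT_ALPHABET)
    fi = read.flow_index if read.flow_index is not None else _fasta_flow_indices(read)
    t0, t1 = int(fi[gap_position - 1]), int(fi[gap_position])
    allowed = {read.sequence[gap_position - 1], read.sequence[gap_position]}
    for t in range(t0 + 1, t1):
        allowed.add(_flow_char(read, t))
    allowed.discard("N")
    return allowed


def insertion_flowpeak(read: FlowRead, gap_position: int, nucleotide: str) -> float | None:
    """Flowpeak of the zero-call flow of ``nucleotide`` between the flanking
    bases' flows, or ``None`` when no such flow exists (or without raw flow
    data).  When several qualify the strongest peak is returned."""
    if not read.has_flow_data:
        return None
    L = len(read)
    if gap_position <= 0 or gap_position >= L:
        return None
    t0 = int(read.flow_index[gap_position - 1])
    t1 = int(read.flow_index[gap_position])
    best = None
    for t in range(t0 + 1, t1):
        if _flow_char(read, t) == nucleotide:
            v = float(read.flow_values[t])
            if best is None or v > best:
                best = v
    return best


# ---------------------------------------------------------------------------
# parameters


@dataclasses.dataclass
class AlignParams:
    """All alignment tunables.

    ``S``/``D`` are the single and double (grouped) frame-shift gap
    penalties; ``h`` sets the homopolymer penalty floor ``S*h``/``D*h``;
    ``k`` the relative flowpeak deviation at which the full penalty applies;
    ``V`` switches flow-order insertion validation; ``G0``/``Ge`` are the
    protein-space gap open/extension costs.
    """

    mode: str = "fasta454"
    S: float = 12.0
    D: float = 24.0
    h: float = 0.5
    k: float = 0.6
    V: bool = False
    G0: float = 8.0
    Ge: float = 2.0
    matrix: SubstitutionMatrix | None = None

    _MODE_DEFAULTS = {
        "neutral": dict(S=8.0, D=15.0, h=1.0, k=1.0, V=False),
        "fasta454": dict(S=12.0, D=24.0, h=0.5, k=0.6, V=False),
        "flow454": dict(S=20.0, D=40.0, h=0.3, k=0.4, V=True),
    }

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "AlignParams":
        """Default parameter set for one of the three operating modes."""
        if mode not in MODES:
            raise ParameterError(f"unknown mode {mode!r}")
        kw = dict(cls._MODE_DEFAULTS[mode])
        kw.update(overrides)
        return cls(mode=mode, **kw)

    def __post_init__(self):
        if self.matrix is None:
            self.matrix = load_matrix("BLOSUM62")

    @property
    def effective_h(self) -> float:
        """In neutral mode the penalty is constant (no discount)."""
        return 1.0 if self.mode == "neutral" else self.h


def validate_params(params: AlignParams) -> AlignParams:
    """Reject penalty combinations under which the model degenerates.

    ``D > 2*S`` would make two single gaps cheaper than one grouped double
    (and the DP cannot track repeated corrections of one homopolymer), and a
    minimum single-plus-double frame-shift cost at or below the protein gap
    open cost would let homopolymer corrections substitute for protein gaps.
    """
    if params.mode not in MODES:
        raise ParameterError(f"unknown mode {params.mode!r}")
    if params.S < 0 or params.D < 0:
        raise ParameterError("gap penalties must be >= 0")
    if not (0.0 < params.h <= 1.0):
        raise ParameterError("h must be in (0, 1]")
    if params.k <= 0:
        raise ParameterError("k must be > 0")
    if params.D > 2 * params.S:
        raise ParameterError(
            f"D > 2*S (D={params.D}, S={params.S}): two single frame-shift "
            "gaps would be favoured over one grouped double"
        )
    h = params.effective_h
    if params.S * h + params.D * h <= params.G0:
        raise ParameterError(
            f"S*h + D*h = {params.S * h + params.D * h} <= G0 = {params.G0}: "
            "frame-shift corrections must cost more than opening a protein gap"
        )
    return params
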