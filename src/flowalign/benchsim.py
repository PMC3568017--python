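"""Synthetic benchmark for homopolymer indel recovery.

The benchmark emulates the evaluation design used for flow-space aligners:
a random coding seed sequence is generated and translated; protein targets
are derived from it by BLOSUM-guided mutation down to fixed identity levels;
flow-space reads are simulated from the nucleotide seed with homopolymer
over/undercalls as the only error type; reads are aligned against each
target under each operating mode; and the predicted frame-shift corrections
are scored against the simulated ground truth with the Matthews correlation
coefficient (MCC).

Read simulator
--------------
The template is decomposed into flows over the cycle ``TACG``.  Each
positive flow of an ``n``-mer draws its peak from ``Normal(n, sigma(n))``
truncated at zero with ``sigma(n) = sigma_a + sigma_b * n``; each zero flow
draws ``|Normal(0, sigma0)|``.  The called length is the rounded peak, and
every call that differs from the template length is recorded as a truth
overcall (surplus bases in the read) or undercall (missing bases).  The
defaults (``sigma = 0.08 + 0.05 n``, ``sigma0 = 0.12``) give on the order of
one homopolymer indel per ~350-base read, the error-rate scale of 454
Titanium data; they are not a model of any specific instrument.

Scoring
-------
A true positive is a predicted deletion inside the read span of an
overcalled flow with the right nucleotide, or a predicted insertion of the
right nucleotide at a gap position adjacent to (or inside) the remaining
span of an undercalled flow.  Any other prediction is a false positive;
unrecovered truth events inside the aligned region are false negatives
(truth events outside the aligned region are ignored); every other aligned
read position is a true negative.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentResult, align, build_profile
from .flowspace import DEFAULT_FLOW_ORDER, AlignParams, FlowRead, annotate_fasta
from .scoring import CODON_TABLE, STOP, load_matrix

__all__ = [
    "BenchmarkTruth",
    "ConfusionCounts",
    "TruthEvent",
    "random_coding_sequence",
    "translate_sequence",
    "mutate_protein",
    "simulate_read",
    "score_predictions",
    "mcc",
    "run_benchmark",
]

_SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != STOP)
_BLOSUM_LEVELS = (45, 50, 62, 80, 90)


@dataclasses.dataclass(frozen=True)
class TruthEvent:
    """One homopolymer miscall: ``kind`` is ``"over"`` (surplus bases in the
    read, to be deleted) or ``"under"`` (missing bases, to be inserted);
    ``start:end`` is the read-coordinate span of the affected flow's called
    bases and ``count`` the number of surplus/missing nucleotides."""

    kind: str
    nt: str
    start: int
    end: int
    count: int


@dataclasses.dataclass
class BenchmarkTruth:
    """A simulated read together with its ground-truth homopolymer events."""

    template: str
    read: FlowRead
    events: list[TruthEvent]


@dataclasses.dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __iadd__(self, other: "ConfusionCounts"):
        self.TP += other.TP
        self.FP += other.FP
        self.TN += other.TN
        self.FN += other.FN
        return self

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


# ---------------------------------------------------------------------------
# target construction


def random_coding_sequence(length_nt: int, rng: np.random.Generator) -> str:
    """Uniform-random coding sequence (sense codons only, no internal
    stops); length is rounded down to a multiple of three."""
    n_codons = length_nt // 3
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def translate_sequence(nt: str) -> str:
    return "".join(CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt) - 2, 3))


def _blosum_level(identity: float) -> int:
    return min(_BLOSUM_LEVELS, key=lambda lv: abs(lv - identity))


def mutate_protein(protein: str, target_identity: float,
                   rng: np.random.Generator | int) -> str:
    """Substitute exactly ``round((1 - identity) * length)`` uniformly chosen
    positions; the replacement residue is drawn proportionally to the
    off-diagonal substitution probabilities implied by the BLOSUM matrix
    whose clustering level is nearest the target identity (half-bit log-odds
    ``s`` is inverted as ``P(b|a) ∝ 2**(s/2)``)."""
    if not (0 < target_identity <= 100):
        raise ValueError("target identity must be in (0, 100]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    n_sub = int(round((1.0 - target_identity / 100.0) * len(protein)))
    if n_sub == 0:
        return protein
    matrix = load_matrix(f"BLOSUM{_blosum_level(target_identity)}")
    aas = "ACDEFGHIKLMNPQRSTVWY"
    positions = rng.choice(len(protein), size=n_sub, replace=False)
    out = list(protein)
    for pos in positions:
        orig = out[pos]
        cands = [b for b in aas if b != orig]
        w = np.array([2.0 ** (matrix.score(orig, b) / 2.0) for b in cands])
        out[pos] = cands[rng.choice(len(cands), p=w / w.sum())]
    return "".join(out)


# ---------------------------------------------------------------------------
# read simulation


def simulate_read(template: str, rng: np.random.Generator | int,
                  sigma: tuple[float, float] = (0.08, 0.05),
                  sigma0: float = 0.12,
                  flow_order: str = DEFAULT_FLOW_ORDER) -> BenchmarkTruth:
    """Simulate one flow-space read covering ``template`` entirely.

    ``sigma = (a, b)`` gives the positive-flow peak standard deviation
    ``a + b*n``; ``sigma0`` the zero-flow sd.  With all sigmas zero the read
    equals the template and the truth list is empty.
    """
    if not template:
        raise ValueError("template must be non-empty")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    a, b = sigma
    cyc = len(flow_order)
    peaks: list[float] = []
    read_chars: list[str] = []
    flow_index: list[int] = []
    events: list[TruthEvent] = []
    ptr = 0
    t = 0
    while ptr < len(template):
        nt = flow_order[t % cyc]
        n = 0
        while ptr + n < len(template) and template[ptr + n] == nt:
            n += 1
        ptr += n
        if n > 0:
            peak = max(0.0, rng.normal(n, a + b * n))
        else:
            peak = abs(rng.normal(0.0, sigma0)) if sigma0 > 0 else 0.0
        m = int(np.floor(peak + 0.5))
        rs = len(read_chars)
        read_chars.extend(nt * m)
        flow_index.extend([t] * m)
        peaks.append(peak)
        if m > n:
            events.append(TruthEvent("over", nt, rs, rs + m, m - n))
        elif m < n:
            events.append(TruthEvent("under", nt, rs, rs + m, n - m))
        t += 1
    if not read_chars:
        raise ValueError("simulated read is empty; template too short or noise too high")
    flow_values = np.asarray(peaks, dtype=np.float64)
    fi = np.asarray(flow_index, dtype=np.int64)
    read = FlowRead("sim", "".join(read_chars), flowpeaks=flow_values[fi],
                    flow_index=fi, flow_order=flow_order, flow_values=flow_values)
    return BenchmarkTruth(template, read, events)


# ---------------------------------------------------------------------------
# scoring


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; zero denominator factors give 0 by
    convention (all-zero counts additionally warn)."""
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    if tp == fp == tn == fn == 0:
        warnings.warn("MCC of all-zero confusion counts is undefined; returning 0")
        return 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / float(np.sqrt(denom))


def score_predictions(alignment: AlignmentResult, truth: BenchmarkTruth) -> ConfusionCounts:
    """Confusion counts of the alignment's frame-shift predictions against
    the simulated truth of its read."""
    if alignment.query_id != truth.read.id:
        raise ValueError("alignment was not produced from this truth's read")
    j0, j1 = alignment.query_range
    counts = ConfusionCounts()
    if j1 <= j0:
        return counts

    def in_region(ev: TruthEvent) -> bool:
        if ev.kind == "over":
            return ev.start < j1 and ev.end > j0
        return j0 <= ev.end and ev.start <= j1

    open_events = [[ev, ev.count] for ev in truth.events if in_region(ev)]
    for kind, pos, nt in alignment.events:
        matched = False
        for rec in open_events:
            ev, remaining = rec
            if remaining <= 0 or ev.nt != nt:
                continue
            if kind == "del" and ev.kind == "over" and ev.start <= pos < ev.end:
                pass
            elif kind == "ins" and ev.kind == "under" and ev.start <= pos <= ev.end:
                pass
            else:
                continue
            rec[1] -= 1
            counts.TP += 1
            matched = True
            break
        if not matched:
            counts.FP += 1
    counts.FN = sum(rec[1] for rec in open_events)
    counts.TN = max(0, (j1 - j0) - counts.TP - counts.FP - counts.FN)
    return counts


# ---------------------------------------------------------------------------
# benchmark driver


def run_benchmark(identities: Sequence[float] = (100, 80, 60, 40),
                  n_reads: int = 1000,
                  modes: Sequence[str] = ("neutral", "fasta454", "flow454"),
                  seed: int = 0,
                  params_by_mode: dict[str, AlignParams] | None = None,
                  read_length: int = 350,
                  template: str | None = None,
                  template_length_nt: int = 1950,
                  sigma: tuple[float, float] = (0.08, 0.05),
                  sigma0: float = 0.12) -> pd.DataFrame:
    """Simulate, align and score; one row per (mode, identity).

    A single random coding seed is generated (unless ``template`` is given,
    e.g. a real ORF), translated, and mutated to each identity level; the
    same ``n_reads`` simulated reads are aligned under every mode.  Fully
    deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    if template is None:
        template = random_coding_sequence(template_length_nt, rng)
    protein = translate_sequence(template)
    targets = {ident: mutate_protein(protein, ident, rng) for ident in identities}

    truths: list[BenchmarkTruth] = []
    for _ in range(n_reads):
        start = int(rng.integers(0, max(1, len(template) - read_length + 1)))
        window = template[start : start + read_length]
        truths.append(simulate_read(window, rng, sigma=sigma, sigma0=sigma0))

    params_by_mode = params_by_mode or {}
    counts: dict[tuple[str, float], ConfusionCounts] = {
        (mode, ident): ConfusionCounts() for mode in modes for ident in identities
    }
    for truth in truths:
        for mode in modes:
            params = params_by_mode.get(mode) or AlignParams.for_mode(mode)
            if mode == "flow454":
                read = truth.read
            else:
                read = annotate_fasta(truth.read.sequence, id=truth.read.id)
            profile = build_profile(read, params)
            for ident in identities:
                result = align(profile, targets[ident], target_id=f"id{ident}")
                counts[(mode, ident)] += score_predictions(result, truth)

    rows = []
    columns = ["mode", "identity", "S", "D", "h", "k", "V", "n_reads",
               "TP", "FP", "TN", "FN", "MCC"]
    if n_reads == 0:
        return pd.DataFrame(columns=columns)
    for mode in modes:
        params = params_by_mode.get(mode) or AlignParams.for_mode(mode)
        for ident in identities:
            c = counts[(mode, ident)]
            rows.append({
                "mode": mode, "identity": ident,
                "S": params.S, "D": params.D, "h": params.h, "k": params.k,
                "V": params.V, "n_reads": n_reads,
                "TP": c.TP, "FP": c.FP, "TN": c.TN, "FN": c.FN,
                "MCC": mcc(c) if c.total else float("nan"),
            })
    return pd.DataFrame(rows)


def plot_benchmark(table: pd.DataFrame, path=None):  # pragma: no cover
    """MCC versus identity, one line per mode (optional matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for mode, sub in table.groupby("mode"):
        sub = sub.sort_values("identity")
        ax.plot(sub["identity"], sub["MCC"], marker="o", label=mode)
    ax.set_xlabel("target identity (%)")
    ax.set_ylabel("MCC")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path)
    return fig
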