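"""Synthetic benchmark: mutation, read simulation, truth scoring, MCC."""

import numpy as np
import pytest
from scipy import stats as sps

from flowalign.benchsim import (
    BenchmarkTruth,
    ConfusionCounts,
    TruthEvent,
    mcc,
    mutate_protein,
    random_coding_sequence,
    run_benchmark,
    score_predictions,
    simulate_read,
    translate_sequence,
)
from flowalign.align import align_read
from flowalign.flowspace import AlignParams, FlowRead


# ---------------------------------------------------------------------------
# target mutation


def test_mutate_identity_100_unchanged(rng):
    prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 80))
    assert mutate_protein(prot, 100, rng) == prot


def test_mutate_exact_substitution_count(rng):
    prot = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 200))
    mut = mutate_protein(prot, 90, rng)
    assert sum(a != b for a, b in zip(prot, mut)) == 20
    mut = mutate_protein(prot, 40, rng)
    assert sum(a != b for a, b in zip(prot, mut)) == 120


def test_mutate_never_keeps_original_at_chosen_site(rng):
    prot = "K" * 50
    mut = mutate_protein(prot, 50, rng)
    assert sum(c != "K" for c in mut) == 25


def test_mutate_deterministic():
    prot = "MKWLLDEHARNDCEQGHILKF" * 5
    assert mutate_protein(prot, 60, 42) == mutate_protein(prot, 60, 42)


def test_mutate_rejects_bad_identity(rng):
    with pytest.raises(ValueError):
        mutate_protein("MKW", 0, rng)
    with pytest.raises(ValueError):
        mutate_protein("MKW", 120, rng)


# ---------------------------------------------------------------------------
# read simulation


def test_noiseless_simulation_is_exact(rng):
    template = random_coding_sequence(300, rng)
    truth = simulate_read(template, rng, sigma=(0.0, 0.0), sigma0=0.0)
    assert truth.read.sequence == template
    assert truth.events == []
    assert np.array_equal(np.round(truth.read.flow_values),
                          truth.read.flow_values)


def test_simulation_deterministic(rng):
    template = random_coding_sequence(300, rng)
    a = simulate_read(template, 99)
    b = simulate_read(template, 99)
    assert a.read.sequence == b.read.sequence
    assert np.array_equal(a.read.flow_values, b.read.flow_values)
    assert a.events == b.events


def test_truth_events_reconstruct_template(rng):
    """Applying the truth events to the read recovers the template."""
    template = random_coding_sequence(600, rng)
    truth = simulate_read(template, rng, sigma=(0.15, 0.08), sigma0=0.2)
    seq = truth.read.sequence
    out = []
    cursor = 0
    for ev in sorted(truth.events, key=lambda e: e.start):
        out.append(seq[cursor : ev.start])
        called = seq[ev.start : ev.end]
        if ev.kind == "over":
            out.append(called[: len(called) - ev.count])
        else:
            out.append(called + ev.nt * ev.count)
        cursor = ev.end
    out.append(seq[cursor:])
    assert "".join(out) == template


def test_overcall_rate_matches_normal_tail(rng):
    """Empirical overcall frequency of a 3-mer tracks the closed-form
    normal tail probability."""
    sigma = (0.10, 0.05)
    sd3 = sigma[0] + sigma[1] * 3
    p_over = sps.norm.sf(3.5, loc=3, scale=sd3)
    n = 10_000
    hits = 0
    for _ in range(n):
        truth = simulate_read("AAA", rng, sigma=sigma, sigma0=0.0)
        hits += any(e.kind == "over" for e in truth.events)
    se = np.sqrt(p_over * (1 - p_over) / n)
    assert abs(hits / n - p_over) < 5 * se + 1e-4


# ---------------------------------------------------------------------------
# prediction scoring


def _flow_read(seq, flow_values, flow_index):
    fv = np.asarray(flow_values, float)
    fi = np.asarray(flow_index)
    return FlowRead("sim", seq, flowpeaks=fv[fi], flow_index=fi,
                    flow_order="TACG", flow_values=fv)


def _overcalled_read():
    """Template ATG GAC TTT AAA TGG with the T-run overcalled to TTTT:
    read ATGGACTTTTAAATGG, consistent TACG flowgram.  The two-codon MD
    anchor upstream makes recovering the deletion optimal."""
    fv = [0, 1.0, 0, 0, 1.0, 0, 0, 1.95, 0, 1.0,
          0.98, 0, 3.55, 2.95, 0, 0, 1.0, 0, 0, 1.95]
    fi = [1, 4, 7, 7, 9, 10, 12, 12, 12, 12, 13, 13, 13, 16, 19, 19]
    return _flow_read("ATGGACTTTTAAATGG", fv, fi)


def test_perfect_recovery_scores_mcc_one():
    read = _overcalled_read()
    truth = BenchmarkTruth("ATGGACTTTAAATGG", read, [TruthEvent("over", "T", 6, 10, 1)])
    res = align_read(read, "MDFKW", AlignParams.for_mode("flow454"))
    counts = score_predictions(res, truth)
    assert counts.TP == 1
    assert (counts.FP, counts.FN) == (0, 0)
    assert mcc(counts) == 1.0
    assert counts.total == res.query_range[1] - res.query_range[0]


def test_adjacent_homopolymer_correction_counts_fp_and_fn():
    """Deleting from the neighbouring run instead of the truth's run gives
    one FP and one FN (the deletion lands in the sharper T-peak, not the
    A-run the truth names)."""
    read = _overcalled_read()
    truth = BenchmarkTruth("ATGGACTTTTAATGG", read, [TruthEvent("over", "A", 10, 13, 1)])
    res = align_read(read, "MDFKW", AlignParams.for_mode("flow454"))
    counts = score_predictions(res, truth)
    assert counts.FP == 1 and counts.FN == 1


def test_truth_outside_alignment_ignored():
    read = _overcalled_read()
    truth = BenchmarkTruth("ATGGACTTTAAATGG", read, [TruthEvent("over", "T", 6, 10, 1)])
    # protein matching only the tail: alignment covers AAA TGG only
    res = align_read(read, "KW", AlignParams.for_mode("flow454"))
    assert res.query_range[0] >= 10
    counts = score_predictions(res, truth)
    assert counts.FN == 0 and counts.TP == 0


def test_score_predictions_id_mismatch():
    read = _overcalled_read()
    truth = BenchmarkTruth("ATGGACTTTAAATGG", read, [])
    res = align_read(read, "MDFKW", AlignParams.for_mode("flow454"))
    truth.read.id = "other"
    with pytest.raises(ValueError):
        score_predictions(res, truth)


# ---------------------------------------------------------------------------
# MCC


@pytest.mark.parametrize(
    "tp,fp,tn,fn,expected",
    [(5, 0, 95, 0, 1.0), (1, 1, 1, 1, 0.0),
     (3, 1, 90, 2, 268 / np.sqrt(20 * 8372))],
)
def test_mcc_values(tp, fp, tn, fn, expected):
    assert mcc(ConfusionCounts(tp, fp, tn, fn)) == pytest.approx(expected)


def test_mcc_zero_factor_convention():
    assert mcc(ConfusionCounts(0, 0, 10, 0)) == 0.0
    with pytest.warns(UserWarning):
        assert mcc(ConfusionCounts(0, 0, 0, 0)) == 0.0


def test_mcc_bounds(rng):
    for _ in range(200):
        tp, fp, tn, fn = rng.integers(0, 50, 4)
        if tp + fp + tn + fn == 0:
            continue
        assert -1.0 <= mcc(ConfusionCounts(int(tp), int(fp), int(tn), int(fn))) <= 1.0


# ---------------------------------------------------------------------------
# benchmark driver


def test_benchmark_empty_when_no_reads():
    assert run_benchmark(n_reads=0, seed=1).empty


def test_benchmark_deterministic():
    a = run_benchmark(identities=(100, 60), n_reads=8, seed=7)
    b = run_benchmark(identities=(100, 60), n_reads=8, seed=7)
    assert a.equals(b)


def test_benchmark_noiseless_has_no_positives():
    tab = run_benchmark(identities=(100,), n_reads=5, seed=3,
                        sigma=(0.0, 0.0), sigma0=0.0)
    assert (tab["TP"] == 0).all() and (tab["FP"] == 0).all() and (tab["FN"] == 0).all()
    assert (tab["MCC"] == 0.0).all()


def test_benchmark_columns_and_counts():
    tab = run_benchmark(identities=(100, 40), n_reads=5, seed=13)
    assert set(tab["mode"]) == {"neutral", "fasta454", "flow454"}
    assert len(tab) == 6
    assert (tab[["TP", "FP", "TN", "FN"]] >= 0).all().all()
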