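"""Flow-space model: runs, flowpeak deviations, penalties, validation, SFF."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flowalign.flowspace import (
    AlignParams,
    FlowRead,
    ParameterError,
    annotate_fasta,
    deviation,
    frameshift_penalty,
    insertion_flowpeak,
    penalty_factor,
    read_sff,
    valid_insertions,
    validate_params,
    write_sff,
)


# ---------------------------------------------------------------------------
# FASTA annotation


def test_annotate_fasta_runs():
    read = annotate_fasta("TTTAA")
    assert list(read.run_length) == [3, 3, 3, 2, 2]
    assert list(read.flowpeaks) == [3, 3, 3, 2, 2]
    assert list(read.run_end) == [False, False, True, False, True]


def test_annotate_fasta_all_singletons():
    read = annotate_fasta("ACGT")
    assert list(read.flowpeaks) == [1, 1, 1, 1]


def test_annotate_fasta_rejects_bad_input():
    with pytest.raises(ValueError):
        annotate_fasta("")
    with pytest.raises(ValueError):
        annotate_fasta("ACGU")


# ---------------------------------------------------------------------------
# deviation / penalty factor / penalty


def test_deviation_examples():
    assert deviation(0.49, 0, 1) == pytest.approx(0.01)
    assert deviation(1.50, 2, 1) == 0.0
    assert deviation(1.50, 2, 3) == pytest.approx(1.0)
    for n in range(6):
        assert deviation(float(n), n, n) == 0.0


def test_penalty_factor_examples():
    # FASTA (p = n), 1-mer, k = 0.6: up-call factor 1 - 0.5/0.6
    assert penalty_factor(1.0, 1, 2, 0.6) == pytest.approx(1 - 0.5 / 0.6)
    # full penalty once the deviation reaches k * n (0.4 for a 2-mer, k=0.2)
    assert penalty_factor(1.5 + 0.4, 2, 1, 0.2) == pytest.approx(0.0, abs=1e-12)
    assert penalty_factor(1.95, 2, 1, 0.2) == 0.0  # beyond the threshold
    assert penalty_factor(1.5 + 0.39, 2, 1, 0.2) > 1e-3
    with pytest.raises(ParameterError):
        penalty_factor(1.0, 1, 2, 0.0)


def test_frameshift_penalty_endpoints():
    assert frameshift_penalty(20.0, 0.3, 1.0) == pytest.approx(6.0)  # P0*h
    assert frameshift_penalty(20.0, 0.3, 0.0) == 20.0
    assert frameshift_penalty(20.0, 0.3, 0.5) == pytest.approx(13.0)


@given(n=st.integers(1, 8), k=st.floats(0.1, 1.0))
def test_integer_peak_insertion_deletion_symmetry(n, k):
    """At integer flowpeaks the up-call and down-call discounts coincide."""
    up = penalty_factor(float(n), n, n + 1, k)
    down = penalty_factor(float(n), n, n - 1, k)
    assert up == pytest.approx(down)


@given(p=st.floats(0.0, 8.0), n=st.integers(0, 8), dm=st.integers(-2, 2),
       k=st.floats(0.05, 2.0), h=st.floats(0.05, 1.0))
def test_penalty_bounds(p, n, dm, k, h):
    f = penalty_factor(p, n, n + dm, k)
    assert 0.0 <= f <= 1.0
    pen = frameshift_penalty(10.0, h, f)
    assert 10.0 * h - 1e-12 <= pen <= 10.0 + 1e-12


def test_fasta_penalty_monotone_in_run_length():
    """Longer homopolymers get cheaper (or equal) frame-shifts in FASTA mode."""
    k, h, S = 0.6, 0.5, 12.0
    pens = [frameshift_penalty(S, h, penalty_factor(float(n), n, n - 1, k))
            for n in range(1, 10)]
    assert all(b <= a + 1e-12 for a, b in zip(pens, pens[1:]))


# ---------------------------------------------------------------------------
# insertion validation


def _flow_read_tttccc():
    # flows: T=3.05, A=0.49, C=2.95  ->  read TTTCCC
    fv = np.array([3.05, 0.49, 2.95, 0.0])
    fi = np.array([0, 0, 0, 2, 2, 2])
    return FlowRead("r", "TTTCCC", flowpeaks=fv[fi], flow_index=fi,
                    flow_order="TACG", flow_values=fv)


def test_valid_insertions_between_runs():
    read = _flow_read_tttccc()
    assert valid_insertions(read, 3) == {"A", "T", "C"}


def test_valid_insertions_fasta_reconstruction():
    read = annotate_fasta("TTTCCC")
    assert valid_insertions(read, 3) == {"A", "T", "C"}


def test_valid_insertions_mid_homopolymer():
    read = _flow_read_tttccc()
    assert valid_insertions(read, 1) == {"T"}


def test_valid_insertions_read_ends():
    read = _flow_read_tttccc()
    assert valid_insertions(read, 0) == set("TACG")
    assert valid_insertions(read, 6) == set("TACG")


def test_insertion_flowpeak():
    read = _flow_read_tttccc()
    assert insertion_flowpeak(read, 3, "A") == pytest.approx(0.49)
    assert insertion_flowpeak(read, 3, "G") is None
    assert insertion_flowpeak(read, 1, "A") is None  # same flow, nothing between
    k = 0.4
    f = penalty_factor(insertion_flowpeak(read, 3, "A"), 0, 1, k)
    assert f == pytest.approx(1 - 0.01 / k)


def test_insertion_flowpeak_zero_flow():
    fv = np.array([1.0, 0.0, 1.0])
    fi = np.array([0, 2])
    read = FlowRead("r", "TC", flowpeaks=fv[fi], flow_index=fi,
                    flow_order="TACG", flow_values=fv)
    p0 = insertion_flowpeak(read, 1, "A")
    assert p0 == 0.0
    assert deviation(p0, 0, 1) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# parameter validation


@pytest.mark.parametrize("mode", ["neutral", "fasta454", "flow454"])
def test_default_params_accepted(mode):
    validate_params(AlignParams.for_mode(mode))


def test_reject_double_cheaper_than_two_singles():
    with pytest.raises(ParameterError, match="2\\*S"):
        validate_params(AlignParams.for_mode("neutral", S=8, D=20))


def test_reject_frameshifts_cheaper_than_protein_gap():
    with pytest.raises(ParameterError, match="G0"):
        validate_params(AlignParams.for_mode("fasta454", S=4, D=8, h=0.5))


def test_mode_defaults():
    p = AlignParams.for_mode("flow454")
    assert (p.S, p.D, p.h, p.k, p.V) == (20.0, 40.0, 0.3, 0.4, True)
    p = AlignParams.for_mode("fasta454")
    assert (p.S, p.D, p.h, p.k, p.V) == (12.0, 24.0, 0.5, 0.6, False)
    p = AlignParams.for_mode("neutral")
    assert (p.S, p.D) == (8.0, 15.0)
    assert (p.G0, p.Ge) == (8.0, 2.0)


# ---------------------------------------------------------------------------
# SFF round trip


def test_sff_round_trip(tmp_path, rng):
    from flowalign.benchsim import random_coding_sequence, simulate_read

    reads = []
    template = random_coding_sequence(300, rng)
    for i in range(3):
        truth = simulate_read(template, rng)
        truth.read.id = f"read{i}"
        reads.append(truth.read)
    path = tmp_path / "sim.sff"
    write_sff(path, reads)
    back = read_sff(path)
    assert [r.id for r in back] == [r.id for r in reads]
    for orig, rt in zip(reads, back):
        assert rt.sequence == orig.sequence
        assert np.allclose(rt.flow_values, orig.flow_values, atol=0.005)
        assert np.array_equal(rt.flow_index, orig.flow_index)
        assert np.allclose(rt.flowpeaks, orig.flowpeaks, atol=0.005)


def test_sff_clipping(tmp_path):
    """Quality clipping removes leading bases from the decoded sequence."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq("TTACGGCA"), id="clipped")
    rec.annotations["flow_values"] = [200, 100, 100, 100, 0, 100, 0, 100, 100, 0]
    rec.annotations["flow_index"] = [1, 0, 1, 1, 1, 2, 2, 1]
    rec.annotations["flow_chars"] = "TACGTACGTA"
    rec.annotations["flow_key"] = "TCAG"
    rec.annotations["clip_qual_left"] = 5
    rec.annotations["clip_qual_right"] = 0
    rec.annotations["clip_adapter_left"] = 0
    rec.annotations["clip_adapter_right"] = 0
    rec.letter_annotations["phred_quality"] = [30] * 8
    path = tmp_path / "clip.sff"
    with open(path, "wb") as fh:
        SeqIO.write([rec], fh, "sff")
    read = read_sff(path)[0]
    assert read.sequence == "GGCA"
    assert len(read.flowpeaks) == 4


def test_sff_bad_magic(tmp_path):
    path = tmp_path / "bad.sff"
    path.write_bytes(b"not an sff file at all")
    with pytest.raises(ValueError):
        read_sff(path)


def test_reverse_complement_round_trip():
    read = _flow_read_tttccc()
    rc = read.reverse_complement()
    assert rc.sequence == "GGGAAA"
    assert np.allclose(rc.flowpeaks, read.flowpeaks[::-1])
    back = rc.reverse_complement()
    assert back.sequence == read.sequence
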