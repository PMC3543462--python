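import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acanthoflux.qc import (
    QCConfig,
    Read,
    primer_match_and_trim,
    primer_matches,
    read_fastq,
    run_qc,
    window_error_filter,
    worst_window_error,
    write_fastq,
)

from conftest import FWD, REV, REV_RC


def make_read(insert: str, q: int = 40, read_id: str = "r", primers: bool = True) -> Read:
    seq = (FWD + insert + REV_RC) if primers else insert
    return Read(id=read_id, sequence=seq, qualities=(q,) * len(seq))


class TestPrimerMatching:
    def test_trim_removes_both_primer_spans(self, qc_cfg):
        trimmed, reason = primer_match_and_trim(make_read("ACGTACGT"), qc_cfg)
        assert reason is None
        assert trimmed.sequence == "ACGTACGT"
        assert len(trimmed.qualities) == 8

    def test_missing_reverse_primer_rejected(self, qc_cfg):
        read = Read(id="r", sequence=FWD + "ACGTACGT" + "TTTT",
                    qualities=(40,) * 16)
        trimmed, reason = primer_match_and_trim(read, qc_cfg)
        assert trimmed is None and reason == "no-rev-primer"

    def test_missing_forward_primer_rejected(self, qc_cfg):
        read = Read(id="r", sequence="TTTT" + "ACGTACGT" + REV_RC,
                    qualities=(40,) * 16)
        trimmed, reason = primer_match_and_trim(read, qc_cfg)
        assert trimmed is None and reason == "no-fwd-primer"

    def test_primer_longer_than_read_is_too_short(self, qc_cfg):
        read = Read(id="r", sequence="ACG", qualities=(40,) * 3)
        trimmed, reason = primer_match_and_trim(read, qc_cfg)
        assert trimmed is None and reason == "too-short"

    @pytest.mark.parametrize("base,expected", [("C", True), ("T", True), ("A", False)])
    def test_iupac_y_degeneracy(self, base, expected):
        assert primer_matches("Y", base) is expected

    def test_n_in_read_matches_nothing(self):
        # degeneracy is honored in the primer only; an uncalled read base
        # cannot satisfy an exact primer match
        assert primer_matches("A", "N") is False
        assert primer_matches("N", "N") is False


class TestWindowFilter:
    def test_uniform_high_quality_passes(self, qc_cfg):
        read = make_read("A" * 100, q=40, primers=False)
        passed, worst, reason = window_error_filter(read, qc_cfg)
        assert passed and reason is None
        assert worst == pytest.approx(1e-4)

    def test_exact_boundary_passes_strict_inequality(self, qc_cfg):
        # 30 bp all Q20: one full-length window with mean exactly 0.01
        read = make_read("A" * 30, q=20, primers=False)
        passed, worst, _ = window_error_filter(read, qc_cfg)
        assert passed
        assert worst == pytest.approx(0.01)

    def test_low_quality_run_fails(self, qc_cfg):
        # 10 consecutive Q3 bases (p≈0.5012) amid Q40: worst 50-bp window
        # mean ≈ (10×0.5012 + 40×1e-4)/50 ≈ 0.1003 > 0.01
        quals = [40] * 45 + [3] * 10 + [40] * 45
        read = Read(id="r", sequence="A" * 100, qualities=tuple(quals))
        passed, worst, reason = window_error_filter(read, qc_cfg)
        assert not passed and reason == "window"
        expected = (10 * 10 ** (-0.3) + 40 * 1e-4) / 50
        assert worst == pytest.approx(expected, rel=1e-9)

    def test_window_count_for_long_reads(self, qc_cfg):
        # len - window + 1 sliding windows, step 1: verified indirectly by
        # placing the bad stretch at the very end of the read
        quals = [40] * 80 + [3] * 20
        read = Read(id="r", sequence="A" * 100, qualities=tuple(quals))
        passed, _, _ = window_error_filter(read, qc_cfg)
        assert not passed

    def test_empty_read_fails_with_reason(self, qc_cfg):
        passed, worst, reason = window_error_filter(
            Read(id="r", sequence="", qualities=()), qc_cfg
        )
        assert not passed and reason == "empty"

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        quals=st.lists(st.integers(min_value=0, max_value=45), min_size=1, max_size=120),
        bump=st.integers(min_value=0, max_value=10),
    )
    def test_raising_quality_never_flips_pass_to_fail(self, quals, bump):
        cfg = QCConfig(window_length=50, max_window_error=0.01)
        read = Read(id="r", sequence="A" * len(quals), qualities=tuple(quals))
        better = Read(id="r", sequence="A" * len(quals),
                      qualities=tuple(q + bump for q in quals))
        if window_error_filter(read, cfg)[0]:
            assert window_error_filter(better, cfg)[0]


class TestRunQC:
    def test_clean_reads_fully_retained(self, qc_cfg):
        reads = [make_read("ACGTACGT" * 3, read_id=f"r{i}") for i in range(10)]
        retained, counts = run_qc(reads, qc_cfg)
        assert len(retained) == 10
        assert counts["retained"] == counts["input"] == 10

    def test_partition_of_mixed_fixture(self, qc_cfg):
        good = make_read("ACGTACGT", read_id="good")
        no_primer = Read(id="nop", sequence="T" * 20, qualities=(40,) * 20)
        bad_window = Read(
            id="badq",
            sequence=FWD + "A" * 60 + REV_RC,
            qualities=(40,) * 4 + (3,) * 60 + (40,) * 4,
        )
        retained, counts = run_qc([good, no_primer, bad_window], qc_cfg)
        assert [r.id for r in retained] == ["good"]
        assert counts["no-fwd-primer"] == 1
        assert counts["window"] == 1
        rejected = sum(
            counts[k] for k in
            ("too-short", "no-fwd-primer", "no-rev-primer", "window", "empty", "chimera")
        )
        assert counts["retained"] + rejected == counts["input"] == 3

    def test_empty_input(self, qc_cfg):
        retained, counts = run_qc([], qc_cfg)
        assert retained == [] and counts["input"] == 0 and counts["retained"] == 0

    def test_chimera_hook_removals_are_counted(self, qc_cfg):
        reads = [make_read("ACGTACGT", read_id=f"r{i}") for i in range(4)]
        retained, counts = run_qc(
            reads, qc_cfg, chimera_hook=lambda rs: [r for r in rs if r.id != "r2"]
        )
        assert counts["chimera"] == 1
        assert counts["retained"] == 3
        assert counts["retained"] + counts["chimera"] == counts["input"]

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(data=st.lists(
        st.tuples(st.booleans(), st.integers(min_value=0, max_value=42)),
        max_size=20,
    ))
    def test_partition_identity_holds_for_random_inputs(self, data):
        cfg = QCConfig(fwd_primer=FWD, rev_primer=REV)
        reads = [
            make_read("ACGTACGTACGT", q=q, read_id=f"r{i}", primers=with_primers)
            for i, (with_primers, q) in enumerate(data)
        ]
        _, counts = run_qc(reads, cfg)
        rejected = sum(
            counts[k] for k in
            ("too-short", "no-fwd-primer", "no-rev-primer", "window", "empty", "chimera")
        )
        assert counts["retained"] + rejected == counts["input"] == len(reads)


class TestFastqIO:
    def test_round_trip(self, tmp_path):
        reads = [make_read("ACGTAACC", q=q, read_id=f"r{q}") for q in (2, 20, 40)]
        path = tmp_path / "reads.fastq"
        write_fastq(reads, path)
        back = read_fastq(path)
        assert [(r.id, r.sequence, r.qualities) for r in back] == [
            (r.id, r.sequence, r.qualities) for r in reads
        ]

    def test_quality_length_mismatch_is_rejected(self):
        with pytest.raises(ValueError, match="qualities"):
            Read(id="r", sequence="ACGT", qualities=(40,) * 3)
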