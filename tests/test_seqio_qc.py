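"""Read QC rules, contamination screen, and tabular hit parsing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from viromeco import simgen
from viromeco.seqio_qc import (
    QCReport,
    Read,
    ReadSet,
    qc_filter,
    read_fastq,
    read_hit_table,
    screen_contamination,
    write_fastq,
)


def _read(seq, qual=40, read_id="r1"):
    quals = [qual] * len(seq) if isinstance(qual, int) else list(qual)
    return Read(read_id, seq, quals)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestQCFilter:
    def test_clean_read_retained_unchanged(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(rng, 150)
        kept, rep = qc_filter(ReadSet("s", [_read(seq)]))
        assert rep.surviving_reads == 1
        assert kept.reads[0].sequence == seq

    def test_eight_base_homopolymer_removed(self):
        seq = "ACGTACGT" + "A" * 8 + "CGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACGTACG"
        kept, rep = qc_filter(ReadSet("s", [_read(seq)]))
        assert rep.surviving_reads == 0
        assert rep.removed_by["homopolymer"] == 1

    def test_seven_base_run_survives(self):
        seq = "CGTC" * 10 + "A" * 7 + "CGTC" * 10
        kept, rep = qc_filter(ReadSet("s", [_read(seq)]))
        assert rep.surviving_reads == 1

    def test_trim_then_length_rule(self):
        # 60-nt read whose last 15 bases are Q20: trimmed to 45, then too short
        rng = np.random.default_rng(2)
        seq = _random_seq(rng, 60)
        qual = [40] * 45 + [20] * 15
        kept, rep = qc_filter(ReadSet("s", [_read(seq, qual)]))
        assert rep.surviving_reads == 0
        assert rep.removed_by["too_short"] == 1

    def test_adversarial_fixture_reconciles(self):
        rng = np.random.default_rng(3)
        reads = [
            _read(_random_seq(rng, 49), read_id="short"),
            _read(_random_seq(rng, 301), read_id="long"),
            _read(_random_seq(rng, 80) + "G" * 8 + _random_seq(rng, 20), read_id="homo"),
            _read(_random_seq(rng, 70) + "N" + _random_seq(rng, 30), read_id="ambig"),
            _read(_random_seq(rng, 100), qual=10, read_id="allbad"),
            _read(_random_seq(rng, 150), read_id="clean"),
        ]
        kept, rep = qc_filter(ReadSet("s", reads))
        assert rep.surviving_reads == 1
        assert rep.removed_by["too_short"] == 1
        assert rep.removed_by["too_long"] == 1
        assert rep.removed_by["homopolymer"] == 1
        assert rep.removed_by["ambiguous"] == 1
        assert rep.removed_by["quality_trim_to_empty"] == 1
        assert rep.surviving_reads + sum(rep.removed_by.values()) == rep.input_reads

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        reads = [
            _read(_random_seq(rng, n), qual=[40] * (n - 5) + [25] * 5, read_id=f"r{n}")
            for n in (60, 100, 150, 200)
        ]
        once, rep1 = qc_filter(ReadSet("s", reads))
        twice, rep2 = qc_filter(once)
        assert [(r.read_id, r.sequence) for r in once] == [
            (r.read_id, r.sequence) for r in twice
        ]
        assert rep2.surviving_reads == rep2.input_reads

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.text(alphabet="ACGTN", min_size=1, max_size=80),
                st.integers(min_value=0, max_value=45),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_report_always_reconciles(self, specs):
        reads = [
            _read(seq, qual=q, read_id=f"r{i}") for i, (seq, q) in enumerate(specs)
        ]
        _, rep = qc_filter(ReadSet("s", reads))
        assert rep.surviving_reads + sum(rep.removed_by.values()) == rep.input_reads

    def test_inconsistent_report_rejected(self):
        with pytest.raises(ValueError):
            QCReport(input_reads=5, surviving_reads=5, removed_by={"too_short": 1})


class TestScreen:
    def test_positive_control(self):
        decoy = simgen.decoy_genome(1, 20_000)
        rng = np.random.default_rng(5)
        reads = []
        for i in range(50):
            start = rng.integers(0, len(decoy) - 150)
            reads.append(_read(decoy[start : start + 150], read_id=f"r{i}"))
        res = screen_contamination(ReadSet("s", reads), {"decoy": decoy})
        assert res.mapped_fraction == 1.0
        assert res.decision == "contaminated"

    def test_negative_control(self):
        decoy = simgen.decoy_genome(1, 20_000)
        rng = np.random.default_rng(6)
        reads = [_read(_random_seq(rng, 150), read_id=f"r{i}") for i in range(50)]
        res = screen_contamination(ReadSet("s", reads), {"decoy": decoy})
        assert res.mapped_fraction < 0.05
        assert res.decision == "pass"

    def test_mixture_recovers_planted_fraction(self):
        decoy = simgen.decoy_genome(2, 30_000)
        rng = np.random.default_rng(7)
        n, frac = 400, 0.15
        reads = []
        planted = 0
        for i in range(n):
            if rng.random() < frac:
                start = rng.integers(0, len(decoy) - 150)
                seq = decoy[start : start + 150]
                planted += 1
            else:
                seq = _random_seq(rng, 150)
            reads.append(_read(seq, read_id=f"r{i}"))
        res = screen_contamination(ReadSet("s", reads), {"decoy": decoy})
        sigma = np.sqrt(frac * (1 - frac) / n)
        assert abs(planted / n - frac) <= 3 * sigma  # the planted draw itself
        assert abs(res.mapped_fraction - planted / n) <= 0.02  # screen recovers it
        assert res.decision == "contaminated"

    def test_empty_inputs_rejected(self):
        decoy = {"d": "ACGT" * 100}
        with pytest.raises(ValueError):
            screen_contamination(ReadSet("s", []), decoy)
        with pytest.raises(ValueError):
            screen_contamination(ReadSet("s", [_read("ACGT" * 40)]), {})


class TestHitTable:
    def test_parse_and_coordinate_convention(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "q1\ts1\t98.00\t100\t2\t0\t1\t100\t1\t100\t3e-27\t180.0\n"
        )
        hits = read_hit_table(path)
        assert len(hits) == 1
        h = hits[0]
        assert h.evalue == pytest.approx(3e-27)
        assert (h.query_start, h.query_end) == (0, 100)
        assert h.identity == pytest.approx(0.98)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert read_hit_table(path) == []

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("q1\ts1\t98.0\n")
        with pytest.raises(ValueError, match=":1:"):
            read_hit_table(path)

    def test_fastq_roundtrip(self, tmp_path):
        rng = np.random.default_rng(8)
        reads = ReadSet(
            "s",
            [
                Read(f"r{i}", _random_seq(rng, 100), list(rng.integers(2, 41, 100)))
                for i in range(5)
            ],
        )
        path = tmp_path / "reads.fastq"
        write_fastq(path, reads)
        back = read_fastq(path, "s")
        assert [(r.read_id, r.sequence, list(r.quality)) for r in back] == [
            (r.read_id, r.sequence, list(r.quality)) for r in reads
        ]
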