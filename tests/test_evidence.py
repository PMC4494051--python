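"""Footprint filtering, densities, evidence tiers and the readthrough null."""

import numpy as np
import pytest

from ctermx.evidence import (
    EvidenceCall,
    FootprintProfile,
    FootprintRead,
    categorize,
    combine_total_evidence,
    filter_reads,
    orf_density,
    readthrough_length,
    reads_to_hits,
)
from ctermx.model import first_stop_pos


def _read(score=36, unique=True, length=20):
    return FootprintRead(position=0, score=score, unique=unique, length=length)


class TestFilterReads:
    @pytest.mark.parametrize(
        "read,high,relaxed",
        [
            (_read(36, True, 20), True, True),
            (_read(34, False, 25), False, True),
            (_read(31, True, 25), False, False),
            (_read(36, False, 20), False, True),  # nonunique fails only at high
            (_read(36, True, 17), False, True),  # short read fails only at high
        ],
    )
    def test_stringency_tiers(self, read, high, relaxed):
        assert (read in filter_reads([read], "high")) == high
        assert (read in filter_reads([read], "relaxed")) == relaxed

    def test_unknown_tier_rejected(self):
        with pytest.raises(ValueError):
            filter_reads([], "medium")


class TestDensity:
    def test_uniform_track(self):
        p = FootprintProfile("g", "r1", [2.0] * 50, mrna_abundance=10.0)
        assert orf_density(p, (0, 50)) == pytest.approx(0.2)

    def test_all_zero(self):
        p = FootprintProfile("g", "r1", [0.0] * 30, mrna_abundance=4.0)
        assert orf_density(p, (0, 30)) == 0.0

    def test_matches_hand_sum_on_subwindow(self, rng):
        hits = list(rng.integers(0, 9, size=120).astype(float))
        p = FootprintProfile("g", "r1", hits, mrna_abundance=7.0)
        lo, hi = 30, 90
        assert orf_density(p, (lo, hi)) == pytest.approx(sum(hits[lo:hi]) / (hi - lo) / 7.0)

    def test_reads_accumulate(self):
        reads = [FootprintRead(3, 36, True, 20), FootprintRead(3, 36, True, 20), FootprintRead(5, 36, True, 20)]
        assert reads_to_hits(reads, 8) == [0, 0, 0, 2, 0, 1, 0, 0]

    def test_bad_span_rejected(self):
        p = FootprintProfile("g", "r1", [1.0] * 10, mrna_abundance=1.0)
        with pytest.raises(ValueError):
            orf_density(p, (5, 5))


class TestCategorize:
    @pytest.mark.parametrize(
        "mean,category",
        [
            (0.05, "strong"), (0.031, "strong"),
            (0.03, "moderate"), (0.02, "moderate"), (0.016, "moderate"),
            (0.015, "low"), (0.01, "low"), (0.006, "low"),
            (0.005, "none"), (0.001, "none"), (0.0, "none"),
        ],
    )
    def test_threshold_tiers(self, mean, category):
        assert categorize([mean]).category == category

    def test_replicates_averaged(self):
        assert categorize([0.04, 0.02]).category == "moderate"  # mean 0.03

    def test_monotone_in_density(self, rng):
        order = ["none", "low", "moderate", "strong"]
        cats = [categorize([d]).category for d in sorted(rng.uniform(0, 0.05, 60))]
        ranks = [order.index(c) for c in cats]
        assert ranks == sorted(ranks)


class TestTotalEvidence:
    @pytest.mark.parametrize(
        "ribo,lit,total",
        [
            ("none", "strong_support", "strong"),
            ("strong", "none", "strong"),
            ("low", "moderate_support", "moderate"),
            ("moderate", "moderate_support", "moderate"),
        ],
    )
    def test_join_on_ordered_scale(self, ribo, lit, total):
        call = EvidenceCall("g", 0.0, ribo)
        assert combine_total_evidence(call, lit) == total
        assert call.total_evidence == total

    def test_join_is_idempotent_and_commutative(self):
        levels = ["none", "low", "moderate", "strong"]
        for a in levels:
            assert combine_total_evidence(EvidenceCall("g", 0, a), a) == a
            for b in levels:
                ab = combine_total_evidence(EvidenceCall("g", 0, a), b)
                ba = combine_total_evidence(EvidenceCall("g", 0, b), a)
                assert ab == ba


class TestReadthrough:
    def test_next_stop_one_codon_away(self):
        seq = "ATGAAATAA" + "AAATAG" + "CCC"
        assert readthrough_length(seq, stop_pos=6, utr_boundary=len(seq)) == 1

    def test_no_stop_before_boundary_excluded(self):
        seq = "ATGAAATAA" + "CCCCCCCCC" + "TAG"
        assert readthrough_length(seq, 6, utr_boundary=15) is None
        assert readthrough_length(seq, 6, utr_boundary=len(seq)) == 3

    def test_boundary_upstream_of_stop_rejected(self):
        with pytest.raises(ValueError):
            readthrough_length("ATGAAATAAAAA", 6, 7)

    def test_equals_brute_force_scan(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(300):
            utr = "".join(bases[rng.integers(0, 4, size=60)])
            seq = "ATGCCATAA" + utr
            got = readthrough_length(seq, 6, len(seq))
            nxt = first_stop_pos(seq, 9)
            expect = None if nxt is None else (nxt - 6) // 3 - 1
            assert got == expect

    def test_mean_matches_geometric_expectation(self, rng):
        """Under uniform bases each codon is a stop w.p. 3/64; the readthrough
        length is geometric, so its mean is near (1-p)/p for long windows."""
        p = 3 / 64
        bases = np.array(list("ACGT"))
        vals = []
        for _ in range(4000):
            utr = "".join(bases[rng.integers(0, 4, size=900)])
            rt = readthrough_length("ATGTAA" + utr, 3, 906)
            if rt is not None:
                vals.append(rt)
        mean = np.mean(vals)
        expect = (1 - p) / p
        assert abs(mean - expect) / expect < 0.1


class TestTrackTables:
    def _write_inputs(self, tmp_path):
        (tmp_path / "tracks.tsv").write_text(
            "gene_id\treplicate\ttranscript_pos\thits\n"
            + "".join(f"gA\tr1\t{i}\t4\n" for i in range(10))
            + "".join(f"gA\tr2\t{i}\t2\n" for i in range(10))
            + "".join(f"gB\tr1\t{i}\t0\n" for i in range(10))
        )
        (tmp_path / "abund.tsv").write_text("gene_id\tmrna_abundance\ngA\t100\ngB\t50\n")
        (tmp_path / "spans.tsv").write_text("gene_id\torf_start\torf_end\ngA\t0\t10\ngB\t0\t10\n")
        (tmp_path / "lit.tsv").write_text("gene_id\tliterature_flag\ngB\tstrong_support\n")

    def test_evidence_from_tracks(self, tmp_path):
        from ctermx.evidence import evidence_from_tracks, read_abundance, read_footprint_track, read_literature

        self._write_inputs(tmp_path)
        calls = evidence_from_tracks(
            read_footprint_track(tmp_path / "tracks.tsv"),
            read_abundance(tmp_path / "abund.tsv"),
            {"gA": (0, 10), "gB": (0, 10)},
            read_literature(tmp_path / "lit.tsv"),
        )
        # gA: replicate densities 0.04 and 0.02 -> mean 0.03 -> moderate
        assert calls["gA"].density == pytest.approx(0.03)
        assert calls["gA"].category == "moderate"
        assert calls["gA"].total_evidence == "moderate"
        # gB: zero footprints but strong literature support
        assert calls["gB"].category == "none"
        assert calls["gB"].total_evidence == "strong"

    def test_cli_evidence_subcommand(self, tmp_path):
        from click.testing import CliRunner

        from ctermx.cli import main as cli_main

        self._write_inputs(tmp_path)
        out = tmp_path / "evidence.tsv"
        res = CliRunner().invoke(cli_main, [
            "evidence", "--tracks", str(tmp_path / "tracks.tsv"),
            "--abundance", str(tmp_path / "abund.tsv"),
            "--orf-spans", str(tmp_path / "spans.tsv"),
            "--literature", str(tmp_path / "lit.tsv"),
            "--out", str(out)])
        assert res.exit_code == 0, res.output
        lines = out.read_text().splitlines()
        assert lines[0] == "gene_id\tdensity\tribo_evidence\ttotal_evidence"
        assert len(lines) == 3
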