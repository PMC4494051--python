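"""Aligned-stop check, walkback, allele partitioning, singleton exclusion."""

import numpy as np
import pytest

from ctermx.alignprep import builtin_align
from ctermx.model import GeneAlignment, StrainSequence, ValidationError, first_stop_pos
from ctermx.scan import (
    drop_singletons,
    locate_aligned_stop,
    mutation_fingerprint,
    partition_alleles,
    walkback,
)


def _family(seqs: dict[str, str], gene="g1"):
    out = []
    for i, (sid, s) in enumerate(seqs.items()):
        out.append(StrainSequence(gene, sid, "scer", s, 0, is_reference=(i == 0)))
    return out


REF = "ATGCAGTTCGATACCGGATTGCAAGCATAA" + "CCAGAGTAGGCTAAC"  # ORF + UTR with in-frame stop


class TestLocateAlignedStop:
    def test_identical_strains_all_have_stop(self):
        aln = builtin_align(_family({"ref": REF, "a": REF, "b": REF}))
        assert all(locate_aligned_stop(aln).values())

    def test_point_loss_flagged(self):
        mutant = REF[:27] + "CAA" + REF[30:]
        aln = builtin_align(_family({"ref": REF, "a": REF, "b": mutant}))
        flags = locate_aligned_stop(aln)
        assert flags == {"ref": True, "a": True, "b": False}

    def test_upstream_deletion_flagged_consistently_with_translation(self):
        mutant = REF[:17] + REF[18:]  # 1-nt deletion 10 nt upstream of the stop
        aln = builtin_align(_family({"ref": REF, "a": mutant}))
        flags = locate_aligned_stop(aln)
        # oracle: naive translation of the mutant from its start
        pos = first_stop_pos(mutant, 0)
        assert pos != 27 - 1 or not flags["a"]
        assert flags["ref"]

    def test_reference_without_stop_is_annotation_error(self):
        rows = [("ref", "ATGCCCAAA"), ("a", "ATGCCCAAA")]
        aln = GeneAlignment("g1", rows, "ref", start_col=0, stop_col=6)
        with pytest.raises(ValidationError, match="annotation error"):
            locate_aligned_stop(aln)


class TestWalkback:
    def test_clean_orf(self):
        aln = builtin_align(_family({"ref": REF, "a": REF}))
        res = walkback(aln, "a")
        assert res.premature_stop_positions == []
        assert res.frame_offset == 0
        assert res.reached_start
        assert res.effective_stop == 27

    def test_insertion_shifts_frame(self):
        mutant = REF[:12] + "T" + REF[12:]
        aln = builtin_align(_family({"ref": REF, "a": mutant}))
        res = walkback(aln, "a")
        assert res.frame_offset == 1
        assert res.effective_stop == first_stop_pos(mutant, 0)

    def test_subtraction_allele_has_one_premature_stop(self):
        mutant = REF[:18] + "TAA" + REF[21:]
        aln = builtin_align(_family({"ref": REF, "a": mutant}))
        res = walkback(aln, "a")
        assert res.frame_offset == 0
        assert res.premature_stop_positions == [3]  # 3 codons upstream of the stop
        assert res.effective_stop == 18

    def test_oracle_equivalence_random_sequences(self):
        """Walkback effective stop == naive start-anchored translation."""
        rng = np.random.default_rng(1234)
        bases = np.array(list("ACGT"))
        checked = 0
        for _ in range(2000):
            n_codons = int(rng.integers(10, 25))
            seq = "ATG" + "".join(bases[rng.integers(0, 4, size=3 * n_codons)]) + "TAA" \
                + "".join(bases[rng.integers(0, 4, size=30)])
            if first_stop_pos(seq, 0) is None:
                continue
            kind = rng.integers(3)
            p = int(rng.integers(4, len(seq) - 8))
            if kind == 0:
                mutant = seq[:p] + "ACGT"[rng.integers(4)] + seq[p + 1:]
            elif kind == 1:
                mutant = seq[:p] + seq[p + 1:]
            else:
                mutant = seq[:p] + "ACGT"[rng.integers(4)] + seq[p:]
            aln = builtin_align(_family({"ref": seq, "a": mutant}))
            flags = locate_aligned_stop(aln)
            if not flags["a"]:
                continue  # walkback runs on stop-bearing strains
            res = walkback(aln, "a")
            assert res.effective_stop == first_stop_pos(mutant, 0)
            checked += 1
        assert checked > 1000


class TestPartitionAlleles:
    def test_monomorphic_not_scp(self):
        aln = builtin_align(_family({f"s{i}": REF for i in range(10)}))
        rec = partition_alleles(aln)
        assert not rec.is_scp and len(rec.alleles) == 1

    def test_two_alleles_partitioned(self):
        mutant = REF[:27] + "CAA" + REF[30:]  # reads through to the UTR stop
        fam = {f"s{i}": REF for i in range(8)}
        fam.update({"m1": mutant, "m2": mutant})
        rec = partition_alleles(builtin_align(_family(fam)))
        assert rec.is_scp
        assert sorted(len(a.strains) for a in rec.alleles) == [2, 8]

    def test_invariant_to_strain_order(self):
        mutant = REF[:27] + "CAA" + REF[30:]
        fam = {"ref": REF, "a": REF, "m": mutant}
        fam_rev = dict(reversed(list(fam.items())))
        seqs1 = _family(fam)
        seqs2 = _family(fam_rev)
        seqs2[0].is_reference = False  # keep the same reference strain
        for s in seqs2:
            if s.strain_id == "ref":
                s.is_reference = True
        r1 = partition_alleles(builtin_align(seqs1))
        r2 = partition_alleles(builtin_align(seqs2))
        assert {a.strains for a in r1.alleles} == {a.strains for a in r2.alleles}


class TestDropSingletons:
    def _record(self, fam):
        aln = builtin_align(_family(fam))
        rec = partition_alleles(aln)
        fps = {s: mutation_fingerprint(aln, s, a.stop_col) for a in rec.alleles for s in a.strains}
        return rec, fps

    def test_singleton_allele_removed(self):
        mutant = REF[:27] + "CAA" + REF[30:]
        fam = {f"s{i}": REF for i in range(5)}
        fam["m"] = mutant
        rec, fps = self._record(fam)
        out = drop_singletons(rec, fps)
        assert not out.is_scp
        assert out.singleton_excluded["m"] == "singleton"

    def test_shared_mutation_retained(self):
        mutant = REF[:12] + "T" + REF[12:]
        fam = {f"s{i}": REF for i in range(5)}
        fam.update({"m1": mutant, "m2": mutant})
        rec, fps = self._record(fam)
        out = drop_singletons(rec, fps)
        assert out.is_scp
        assert all(len(a.strains) >= 2 for a in out.alleles)

    def test_double_singleton_removed(self):
        # independent 1-nt insertions at different positions, same stop
        m1 = REF[:12] + "T" + REF[12:]
        m2 = REF[:15] + "C" + REF[15:]
        if first_stop_pos(m1, 0) != first_stop_pos(m2, 0):
            pytest.skip("constructed pair must share a stop")
        fam = {f"s{i}": REF for i in range(5)}
        fam.update({"m1": m1, "m2": m2})
        rec, fps = self._record(fam)
        same_allele = [a for a in rec.alleles if {"m1", "m2"} <= a.strains]
        assert same_allele, "both carriers must partition into one allele"
        out = drop_singletons(rec, fps)
        assert out.singleton_excluded["m1"] == "double-singleton"
        assert out.singleton_excluded["m2"] == "double-singleton"
        assert not out.is_scp

    def test_retained_alleles_share_fingerprints(self, small_cohort):
        _, families, _, _ = small_cohort
        for gene_id in list(families)[:6]:
            focal = [s for s in families[gene_id] if s.species == "scer"]
            aln = builtin_align(focal)
            rec = partition_alleles(aln)
            fps = {s: mutation_fingerprint(aln, s, a.stop_col) for a in rec.alleles for s in a.strains}
            out = drop_singletons(rec, fps)
            for allele in out.alleles:
                groups = {}
                for s in allele.strains:
                    groups.setdefault(fps[s], []).append(s)
                assert max(len(g) for g in groups.values()) >= 2
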