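"""Simulator invariants: locus construction, event planting, determinism."""

import numpy as np
import pytest

from ctermx.model import first_stop_pos, is_stop, translate_to_stop
from ctermx.simulate import (
    EventInfeasible,
    EventSpec,
    _make_ancestral,
    pair_from_catalog_row,
    plant_event,
    read_truth,
    simulate_cohort,
    simulate_locus,
    write_cohort,
)

SPECIES = {"scer": 6, "spar": 4}


def _locus(seed=3, orf_codons=60, **kw):
    rng = np.random.default_rng(seed)
    anc = _make_ancestral("g1", orf_codons, 150, 0.4, rng, **kw)
    strains, _ = simulate_locus(SPECIES, orf_codons, 150, 0.4, rng, ancestral=anc,
                                protected=set(range(len(anc.seq))))
    return strains, anc


class TestLocus:
    def test_orf_structure(self):
        _, anc = _locus()
        assert anc.seq.startswith("ATG")
        assert first_stop_pos(anc.seq, 0) == anc.stop_pos
        utr_stop = first_stop_pos(anc.seq, anc.stop_pos + 3)
        assert utr_stop is not None and utr_stop < anc.stop_pos + 3 + anc.utr_len

    def test_zero_rate_strains_identical_to_ancestor(self):
        rng = np.random.default_rng(5)
        strains, anc = simulate_locus(SPECIES, 40, 150, 0.4, rng, sub_rate=0.0)
        assert all(s.seq == anc.seq for s in strains)

    def test_substitutions_preserve_stop_structure(self):
        rng = np.random.default_rng(11)
        strains, anc = simulate_locus(SPECIES, 60, 150, 0.4, rng, sub_rate=0.02)
        for s in strains:
            assert len(s.seq) == len(anc.seq)
            for frame in range(3):
                for i in range(frame, len(anc.seq) - 2, 3):
                    assert is_stop(s.seq[i:i + 3]) == is_stop(anc.seq[i:i + 3])

    def test_gc_one_infeasible(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            _make_ancestral("g", 20, 150, 1.0, rng)

    def test_determinism_same_seed_byte_identical(self):
        a1, _ = simulate_locus(SPECIES, 50, 150, 0.4, np.random.default_rng(77), sub_rate=0.01)
        a2, _ = simulate_locus(SPECIES, 50, 150, 0.4, np.random.default_rng(77), sub_rate=0.01)
        assert [(s.strain_id, s.seq) for s in a1] == [(s.strain_id, s.seq) for s in a2]


class TestPlantEvent:
    def test_point_added_equals_distance_to_next_utr_stop(self):
        strains, anc = _locus(seed=9)
        carriers = ("scer_s01", "scer_s02")
        truth = plant_event(strains, anc, EventSpec("point_stop_loss", carriers),
                            np.random.default_rng(1))
        carrier = next(s for s in strains if s.strain_id == "scer_s01")
        dist = (first_stop_pos(carrier.seq, 0) - anc.stop_pos) // 3
        assert truth.added_aa == truth.new_aa == dist
        assert truth.mutation_class == "point"

    def test_frameshift_truth_from_brute_force_translation(self):
        strains, anc = _locus(seed=13)
        carriers = ("scer_s01", "scer_s03")
        truth = plant_event(strains, anc, EventSpec("frameshift_indel", carriers),
                            np.random.default_rng(2))
        carrier = next(s for s in strains if s.strain_id == "scer_s01")
        ld = translate_to_stop(carrier.seq, 0)
        assert truth.added_aa == ld - anc.protein_len
        assert truth.new_aa >= truth.added_aa
        assert truth.mutation_class == "frameshift"

    def test_fusion_requires_downstream_orf(self):
        strains, anc = _locus(seed=15)
        with pytest.raises(EventInfeasible):
            plant_event(strains, anc, EventSpec("fusion_deletion", ("scer_s01", "scer_s02")),
                        np.random.default_rng(3))

    def test_fusion_deletion_extends_into_downstream_orf(self):
        rng = np.random.default_rng(21)
        anc = _make_ancestral("g1", 60, 150, 0.4, rng, downstream_codons=40)
        strains, _ = simulate_locus(SPECIES, 60, 150, 0.4, rng, ancestral=anc,
                                    protected=set(range(len(anc.seq))))
        truth = plant_event(strains, anc, EventSpec("fusion_deletion", ("scer_s01", "scer_s02")), rng)
        assert truth.mutation_class == "deletion_fusion"
        carrier = next(s for s in strains if s.strain_id == "scer_s01")
        assert translate_to_stop(carrier.seq, 0) > anc.protein_len
        # the ancestral stop codon and the whole 3' flank are gone
        assert len(carrier.seq) < anc.downstream_start

    def test_double_singleton_same_stop_different_positions(self):
        strains, anc = _locus(seed=17)
        truth = plant_event(strains, anc, EventSpec("double_singleton", ("scer_s01", "scer_s02")),
                            np.random.default_rng(4))
        c1 = next(s for s in strains if s.strain_id == "scer_s01")
        c2 = next(s for s in strains if s.strain_id == "scer_s02")
        assert c1.seq != c2.seq
        assert len(c1.seq) == len(c2.seq) == len(anc.seq) + 1
        assert translate_to_stop(c1.seq, 0) == translate_to_stop(c2.seq, 0)
        assert not truth.nonsingleton

    def test_unknown_carrier_rejected(self):
        strains, anc = _locus()
        with pytest.raises(ValueError):
            plant_event(strains, anc, EventSpec("point_stop_loss", ("nope",)),
                        np.random.default_rng(0))


class TestCohort:
    def test_truth_table_bookkeeping(self, small_cohort):
        cfg, families, truth, _ = small_cohort
        assert len(families) == cfg.n_genes
        nonsing = truth.nonsingleton_events
        assert len(nonsing) == cfg.additions + cfg.subtractions + cfg.fusions
        for t in truth.genes:
            assert t.new_aa >= t.added_aa
            if t.mutation_class == "point":
                assert t.new_aa == t.added_aa
            if t.kind == "singleton_error":
                assert len(t.carriers) == 1
            if t.kind == "double_singleton":
                assert len(t.carriers) == 2

    def test_replay_reproduces_truth_exactly(self, small_cohort, tmp_path):
        cfg, families, truth, _ = small_cohort
        fam2, truth2 = simulate_cohort(cfg, 7)
        assert truth2 == truth
        assert {g: [(s.strain_id, s.seq) for s in fam] for g, fam in fam2.items()} == \
               {g: [(s.strain_id, s.seq) for s in fam] for g, fam in families.items()}

    def test_cohort_round_trips_through_disk(self, small_cohort, tmp_path):
        cfg, families, truth, _ = small_cohort
        fam2, truth2 = simulate_cohort(cfg, 7)
        write_cohort(fam2, truth2, tmp_path, cfg)
        back = read_truth(tmp_path / "truth.tsv")
        assert back == truth2
        assert sorted(p.name for p in tmp_path.glob("*.fasta")) == \
               sorted(f"{g}.fasta" for g in families)


class TestCatalogPairSynthesis:
    def test_infeasible_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            pair_from_catalog_row(100, 5, 3, "frameshift", rng)  # new < added
        with pytest.raises(ValueError):
            pair_from_catalog_row(10, 5, 20, "frameshift", rng)  # new > la + added
        with pytest.raises(ValueError):
            pair_from_catalog_row(100, 3, 5, "point", rng)  # point must have new == added

    def test_pairs_realize_requested_lengths(self, rng):
        for la, added, new, cls in [(30, 1, 1, "point"), (30, 1, 4, "frameshift"),
                                    (50, 10, 10, "frameshift"), (40, 12, 20, "deletion_fusion")]:
            anc, der, _ = pair_from_catalog_row(la, added, new, cls, rng)
            assert translate_to_stop(anc, 0) == la
            assert translate_to_stop(der, 0) == la + added
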