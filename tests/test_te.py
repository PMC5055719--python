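"""TE identification: two-step criterion, prefilter, classification tables."""

import random

import pytest

from httscan import (assign_family, assign_superfamily,
                     build_classifications, check_family_consistency,
                     classify_te_transcripts, load_family_catalog,
                     prefilter_known_species, tabulate_classifications,
                     tally_totals, te_flags_from_descriptions)
from httscan.te import TEClassification

from conftest import make_hit


def brute_force_te(cdd_hits, repeat_hits, flags, e_cut):
    """Direct evaluation of the written predicate, hit by hit."""
    def best(hits):
        return min(hits, key=lambda h: (h.e_value, -h.bitscore,
                                        h.subject_id))
    te = set()
    for q in {h.query_id for h in cdd_hits}:
        c = [h for h in cdd_hits if h.query_id == q]
        r = [h for h in repeat_hits if h.query_id == q]
        if not any(flags.get(h.subject_id, False) for h in c):
            continue
        if not r:
            continue
        if best(r).e_value < e_cut and best(r).e_value < best(c).e_value:
            te.add(q)
    return te


def random_micro_table(rng):
    """A tiny random hit world with deliberate E-value ties and boundary
    values."""
    e_grid = [1e-30, 1e-12, 1e-8, 1e-6, 1e-5, 1e-5, 1e-4, 1e-2, 1.0]
    queries = [f"q{i}" for i in range(rng.randint(2, 6))]
    subjects = [f"s{i}" for i in range(4)]
    flags = {s: rng.random() < 0.5 for s in subjects}
    cdd, repeat = [], []
    for q in queries:
        for _ in range(rng.randint(0, 3)):
            cdd.append(make_hit(query=q, subject=rng.choice(subjects),
                                e_value=rng.choice(e_grid),
                                bitscore=rng.choice([50.0, 100.0]),
                                program="blastx", tag="cdd"))
        for _ in range(rng.randint(0, 3)):
            repeat.append(make_hit(query=q, subject=rng.choice(subjects),
                                   e_value=rng.choice(e_grid),
                                   bitscore=rng.choice([50.0, 100.0]),
                                   program="tblastx", tag="repeat_lib"))
    return cdd, repeat, flags


class TestTwoStepCriterion:
    def test_te_when_repeat_top_beats_cdd_top_and_cutoff(self):
        cdd = [make_hit(query="t1", subject="dom", e_value=1e-10,
                        program="blastx", tag="cdd")]
        repeat = [make_hit(query="t1", subject="rep", e_value=1e-30,
                           program="tblastx", tag="repeat_lib")]
        assert classify_te_transcripts(cdd, repeat, {"dom": True}) == {"t1"}

    def test_single_copy_gene_with_te_domain_rejected(self):
        # the elongation-factor failure mode: a TE-like conserved domain
        # but a repeat hit weaker than the domain hit
        cdd = [make_hit(query="ef2", subject="tetm", e_value=1e-12,
                        program="blastx", tag="cdd")]
        repeat = [make_hit(query="ef2", subject="rep", e_value=1e-8,
                           program="tblastx", tag="repeat_lib")]
        assert classify_te_transcripts(cdd, repeat, {"tetm": True}) == set()

    def test_cutoff_is_a_strict_inequality(self):
        cdd = [make_hit(query="t1", subject="dom", e_value=1e-3,
                        program="blastx", tag="cdd")]
        repeat = [make_hit(query="t1", subject="rep", e_value=1e-5,
                           program="tblastx", tag="repeat_lib")]
        assert classify_te_transcripts(cdd, repeat, {"dom": True}) == set()

    def test_transcript_without_cdd_hits_is_not_te(self):
        repeat = [make_hit(query="t1", subject="rep", e_value=1e-30,
                           program="tblastx", tag="repeat_lib")]
        assert classify_te_transcripts([], repeat, {}) == set()

    def test_agrees_with_brute_force_on_random_micro_tables(self):
        rng = random.Random(20160767)
        for _ in range(1000):
            cdd, repeat, flags = random_micro_table(rng)
            expected = brute_force_te(cdd, repeat, flags, 1e-5)
            got = classify_te_transcripts(cdd, repeat, flags)
            assert got == expected

    def test_relaxing_cutoff_never_shrinks_te_set(self):
        rng = random.Random(7)
        for _ in range(100):
            cdd, repeat, flags = random_micro_table(rng)
            sets = [classify_te_transcripts(cdd, repeat, flags,
                                            e_te_candidate=e)
                    for e in (1e-8, 1e-5, 1e-2)]
            assert sets[0] <= sets[1] <= sets[2]

    def test_row_order_never_changes_the_answer(self):
        rng = random.Random(13)
        cdd, repeat, flags = random_micro_table(rng)
        reference = classify_te_transcripts(cdd, repeat, flags)
        for _ in range(10):
            rng.shuffle(cdd)
            rng.shuffle(repeat)
            assert classify_te_transcripts(cdd, repeat, flags) == reference


class TestPrefilter:
    def test_strong_self_hit_retained_no_hit_dropped(self):
        hits = [make_hit(query="keep", e_value=1e-40)]
        kept = prefilter_known_species({"keep", "drop"}, hits)
        assert kept == {"keep"}

    def test_weak_self_hit_dropped_at_threshold(self):
        hits = [make_hit(query="t", e_value=1e-3)]
        assert prefilter_known_species({"t"}, hits) == set()
        assert prefilter_known_species({"t"}, hits, e_nt_hit=1e-2) == {"t"}

    def test_empty_hit_list_yields_empty_set(self):
        assert prefilter_known_species({"a", "b"}, []) == set()


class TestSuperfamilyAndFamily:
    def test_superfamily_follows_top_hit_with_group_lookup(self):
        repeat = [make_hit(query="t1", subject="gypsy_cons", e_value=1e-30,
                           program="tblastx", tag="repeat_lib"),
                  make_hit(query="t1", subject="rte_cons", e_value=1e-10,
                           program="tblastx", tag="repeat_lib")]
        out = assign_superfamily(repeat, {"gypsy_cons": ("Gypsy", ""),
                                          "rte_cons": ("RTE", "")})
        assert out["t1"] == ("Gypsy", "LTR retrotransposon")

    def test_no_annotated_hit_gives_unknown(self):
        out = assign_superfamily([], {}, transcript_ids={"t1"})
        assert out["t1"] == ("Unknown", "Unknown")

    def test_equal_e_values_resolved_by_bitscore(self):
        hits = [make_hit(query="t1", subject="a", e_value=1e-20,
                         bitscore=80.0, program="tblastx",
                         tag="repeat_lib"),
                make_hit(query="t1", subject="b", e_value=1e-20,
                         bitscore=120.0, program="tblastx",
                         tag="repeat_lib")]
        annotation = {"a": ("Gypsy", ""), "b": ("RTE", "")}
        for order in (hits, hits[::-1]):
            assert assign_superfamily(order, annotation)["t1"][0] == "RTE"

    def test_family_requires_focal_species_and_threshold(self, catalog):
        focal = "Litopenaeus vannamei"
        strong = [make_hit(query="t1", subject="RTE-3_LVa",
                           organism=focal, e_value=1e-60,
                           program="blastn", tag="repeat_lib")]
        assert assign_family(strong, catalog, focal)["t1"] == "RTE-3_LVa"
        weak = [make_hit(query="t1", subject="RTE-3_LVa", organism=focal,
                         e_value=1e-15, program="blastn",
                         tag="repeat_lib")]
        assert assign_family(weak, catalog, focal)["t1"] is None
        alien = [make_hit(query="t1", subject="RTE-3_LVa",
                          organism="Danio rerio", e_value=1e-80,
                          program="blastn", tag="repeat_lib")]
        assert assign_family(alien, catalog, "Danio rerio")["t1"] is None

    def test_uncataloged_top_hit_logs_and_returns_none(self, catalog,
                                                       caplog):
        hits = [make_hit(query="t1", subject="mystery_consensus",
                         organism="Litopenaeus vannamei", e_value=1e-60,
                         program="blastn", tag="repeat_lib")]
        import logging
        with caplog.at_level(logging.WARNING, logger="httscan.te"):
            out = assign_family(hits, catalog, "Litopenaeus vannamei")
        assert out["t1"] is None
        assert any("mystery_consensus" in r.message for r in caplog.records)


class TestConsistencyAndTally:
    def cls(self, tid, superfamily, family, group="Non-LTR retrotransposon"):
        return TEClassification(transcript_id=tid, is_te=True, group=group,
                                superfamily=superfamily, family=family)

    def test_discordant_family_reported_once_sorted(self, catalog):
        classifications = [
            self.cls("a", "RTE", "Gypsy-3_LVa-LTR"),
            self.cls("b", "CR1", "Penelope-6_LVa"),
            self.cls("c", "CR1", "Penelope-6_LVa"),
            self.cls("d", "RTE", "RTE-3_LVa"),
        ]
        assert check_family_consistency(classifications, catalog) == \
            ["Gypsy-3_LVa-LTR", "Penelope-6_LVa"]

    def test_all_concordant_is_empty(self, catalog):
        classifications = [self.cls("a", "RTE", "RTE-1_LVa"),
                           self.cls("b", "Penelope", "Penelope-2_LVa")]
        assert check_family_consistency(classifications, catalog) == []

    def test_family_split_across_superfamilies_reported_once(self, catalog):
        classifications = [self.cls("a", "RTE", "RTE-1_LVa"),
                           self.cls("b", "Gypsy", "RTE-1_LVa",
                                    group="LTR retrotransposon")]
        assert check_family_consistency(classifications, catalog) == \
            ["RTE-1_LVa"]

    def test_tally_totals_are_conserved(self, catalog):
        classifications = [
            self.cls("a", "RTE", "RTE-1_LVa"),
            self.cls("b", "RTE", None),
            self.cls("c", "Gypsy", None, group="LTR retrotransposon"),
        ]
        totals = tally_totals(tabulate_classifications(classifications))
        assert totals["total"] == 3
        assert totals["n_family_assigned"] == 1
        assert sum(totals["per_group"].values()) == 3

    def test_empty_input_gives_zero_tally(self):
        assert tabulate_classifications([]) == {}
        totals = tally_totals({})
        assert totals["total"] == 0 and totals["n_distinct_families"] == 0


def test_te_flags_from_descriptions_matches_substring():
    flags = te_flags_from_descriptions({
        "cd1": "reverse transcriptase of LTR Transposon",
        "cd2": "ATP synthase subunit",
        "cd3": None})
    assert flags == {"cd1": True, "cd2": False, "cd3": False}


def test_family_on_non_te_classification_rejected():
    with pytest.raises(ValueError, match="non-TE"):
        TEClassification(transcript_id="x", is_te=False,
                         family="RTE-1_LVa")
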