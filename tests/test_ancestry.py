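"""Origin registry, null inference, pair classification and counting."""

import itertools

import numpy as np
import pytest

from meiodrive import ancestry
from meiodrive.ancestry import (
    AMBIG,
    AMBIGUOUS,
    AUS,
    EXCLUDED,
    FULLY_INFORMATIVE,
    PARTIAL_ABXAB,
    TIM,
    UNINFORMATIVE,
    OriginRegistry,
    RegistryError,
    build_origin_registry,
    classify_pair,
    count_transmissions,
    deduce_transmission,
    infer_null_alleles,
    subset_transmissions,
)
from meiodrive.simulate import simulate_cross

from conftest import build_dataset, toy_config
import oracles

REGISTRY = OriginRegistry(
    origins={("m1", a): o for a, o in
             [(200, AUS), (220, AUS), (210, TIM), (230, TIM)]}
)
ORIGIN_OF = {200: "AUS", 220: "AUS", 210: "TIM", 230: "TIM"}


class TestRegistry:
    def test_pool_exclusive_alleles_labelled(self):
        ds = build_dataset(
            [
                ("A1", "F", None, None, "FOUNDER_AUS", "adult"),
                ("A2", "M", None, None, "FOUNDER_AUS", "adult"),
                ("T1", "M", None, None, "FOUNDER_TIM", "adult"),
            ],
            {
                ("A1", "m1"): (200, 202), ("A2", "m1"): (200, 200),
                ("T1", "m1"): (210, 210),
            },
        )
        reg = build_origin_registry(ds)
        assert reg.origin("m1", 200) == AUS
        assert reg.origin("m1", 202) == AUS
        assert reg.origin("m1", 210) == TIM

    def test_shared_length_is_ambiguous(self):
        ds = build_dataset(
            [
                ("A1", "F", None, None, "FOUNDER_AUS", "adult"),
                ("T1", "M", None, None, "FOUNDER_TIM", "adult"),
            ],
            {("A1", "m1"): (204, 204), ("T1", "m1"): (204, 210)},
        )
        assert build_origin_registry(ds).origin("m1", 204) == AMBIG

    def test_marker_without_founder_genotypes_errors(self):
        ds = build_dataset(
            [("A1", "F", None, None, "FOUNDER_AUS", "adult")], {},
        )
        with pytest.raises(RegistryError, match="m1"):
            build_origin_registry(ds)

    def test_descendant_only_allele_warns_ambiguous(self):
        ds = build_dataset(
            [
                ("A1", "F", None, None, "FOUNDER_TIM", "adult"),
                ("A2", "M", None, None, "FOUNDER_AUS", "adult"),
                ("O", "U", "A1", "A2", "F1", "sampled_embryo"),
            ],
            {("A1", "m1"): (210, 210), ("A2", "m1"): (200, 200),
             ("O", "m1"): (200, 999)},
        )
        reg = build_origin_registry(ds)
        assert reg.origin("m1", 999) == AMBIG
        assert any("999" in w for w in reg.warnings)

    def test_simulated_overlap_fraction_reflected(self):
        cfg = toy_config(allele_overlap_fraction=0.5, rng_seed=61)
        ds, _ = simulate_cross(cfg)
        reg = build_origin_registry(ancestry.apply_w_coding(ds))
        shared = sum(1 for o in reg.origins.values() if o == AMBIG)
        assert shared > 0


class TestNullInference:
    def _trio(self, dam, sire, off):
        return build_dataset(
            [
                ("D", "F", None, None, "FOUNDER_TIM", "adult"),
                ("S", "M", None, None, "FOUNDER_AUS", "adult"),
                ("O", "U", "D", "S", "F1", "sampled_embryo"),
            ],
            {("D", "m1"): dam, ("S", "m1"): sire, ("O", "m1"): off},
        )

    def test_forced_offspring_null_rewritten(self):
        """Apparent homozygote {220,220} whose dam cannot provide 220:
        the dam transmitted an unamplified allele -> slot becomes NULL."""
        ds = self._trio((200, 210), (220, 230), (220, 220))
        out, calls = infer_null_alleles(ds)
        assert [(c.individual_id, c.marker_id) for c in calls] == [("O", "m1")]
        assert out.genotype_lookup()[("O", "m1")] == (0, 220)

    def test_consistent_homozygote_untouched(self):
        ds = self._trio((200, 210), (200, 230), (200, 200))
        out, calls = infer_null_alleles(ds)
        assert calls == []
        assert out.genotype_lookup()[("O", "m1")] == (200, 200)

    def test_parent_null_inferred_from_offspring(self):
        """Heterozygous offspring carrying an allele absent from an
        apparently homozygous parent reveals that parent's dropout."""
        ds = self._trio((210, 210), (220, 230), (200, 220))
        out, calls = infer_null_alleles(ds)
        assert [(c.individual_id, c.marker_id) for c in calls] == [("D", "m1")]
        assert out.genotype_lookup()[("D", "m1")] == (0, 210)

    def test_precision_one_against_injected_dropouts(self):
        """Every null call on a simulated dataset corresponds to an
        injected dropout (precision 1); recall is below 1 by design."""
        cfg = toy_config(null_allele_rate=0.05, genotype_missing_rate=0.0,
                         founder_introgression=0.0, abnormality_rates={},
                         bc1_samples=300, bc2_samples=400, rng_seed=71)
        ds, truth = simulate_cross(cfg)
        ds = ancestry.apply_w_coding(ds)
        _, calls = infer_null_alleles(ds)
        injected = set(
            truth.nuisance.loc[truth.nuisance["event"] == "null_masked",
                               ["individual_id", "marker_id"]]
            .itertuples(index=False, name=None)
        )
        called = {(c.individual_id, c.marker_id) for c in calls}
        assert called, "no null calls made"
        assert called <= injected  # precision = 1
        recall = len(called) / len(injected)
        assert 0 < recall < 1


class TestClassification:
    # registry where the partner's alleles are both Australian (the
    # study design: pure Australian partners)
    PURE = OriginRegistry(
        origins={("m1", a): o for a, o in
                 [(200, AUS), (210, TIM), (220, AUS), (230, AUS)]}
    )

    def test_disjoint_partner_fully_informative(self):
        (pc,) = classify_pair((200, 210), (220, 230), "m1", self.PURE)
        assert pc.focal == "dam" and pc.status == FULLY_INFORMATIVE

    def test_abxab_partial(self):
        pcs = classify_pair((200, 210), (200, 210), "m1", REGISTRY)
        assert {p.focal for p in pcs} == {"dam", "sire"}
        assert all(p.status == PARTIAL_ABXAB for p in pcs)

    def test_both_hybrid_parents_each_classified(self):
        """Two AUS/TIM heterozygous parents with different allele pairs:
        both are focal, one classification each."""
        pcs = classify_pair((200, 210), (220, 230), "m1", REGISTRY)
        assert {p.focal for p in pcs} == {"dam", "sire"}

    def test_partner_sharing_one_allele_still_fully_informative(self):
        """Partner {210, 220}: any offspring with 200 took it from the
        focal parent; any without took the focal 210."""
        pcs = {p.focal: p for p in
               classify_pair((200, 210), (210, 220), "m1", self.PURE)}
        assert pcs["dam"].status == FULLY_INFORMATIVE

    def test_focal_with_null_not_classified(self):
        assert classify_pair((0, 210), (220, 230), "m1", self.PURE) == []

    def test_ambiguous_origin_not_classified(self):
        reg = OriginRegistry(origins={("m1", 200): AMBIG, ("m1", 210): TIM,
                                      ("m1", 220): AUS, ("m1", 230): AUS})
        assert classify_pair((200, 210), (220, 230), "m1", reg) == []


class TestDeduction:
    def test_abxab_homozygote_counts_for_each_parent(self):
        pcs = classify_pair((200, 210), (200, 210), "m1", REGISTRY)
        for pc in pcs:
            assert deduce_transmission(pc, (200, 200)) == 1
            assert deduce_transmission(pc, (210, 210)) == 0
            assert deduce_transmission(pc, (200, 210)) == AMBIGUOUS

    def test_fully_informative_pair_deduces_each_offspring(self):
        (pc,) = classify_pair((200, 210), (220, 230), "m1",
                              TestClassification.PURE)
        assert deduce_transmission(pc, (200, 220)) == 1
        assert deduce_transmission(pc, (210, 230)) == 0

    def test_missing_and_inconsistent_offspring_excluded(self):
        (pc,) = classify_pair((200, 210), (220, 230), "m1",
                              TestClassification.PURE)
        assert deduce_transmission(pc, None) == EXCLUDED
        assert deduce_transmission(pc, (240, 250)) == EXCLUDED
        assert deduce_transmission(pc, (200, 210, 220)) == EXCLUDED


class TestExhaustiveOracle:
    def test_classifier_and_deduction_match_brute_force(self):
        """Exhaustive agreement with gamete-assignment enumeration over
        all parental genotype pairs from a 4-allele registry including
        NULL and W placeholders."""
        dam_genos = oracles.all_genotypes([200, 210, 220, 230],
                                          with_null=True, with_w=True)
        sire_genos = oracles.all_genotypes([200, 210, 220, 230],
                                           with_null=True)
        observations = oracles.all_genotypes([200, 210, 220, 230],
                                             with_null=False, with_w=True)
        n_checked = 0
        for dam, sire in itertools.product(dam_genos, sire_genos):
            expected = oracles.oracle_classify(dam, sire, ORIGIN_OF)
            got = {p.focal: p for p in classify_pair(dam, sire, "m1", REGISTRY)}
            assert set(got) == set(expected), (dam, sire)
            for focal, (status, mapping) in expected.items():
                pc = got[focal]
                assert pc.status == status, (dam, sire, focal)
                for obs in observations:
                    verdict = oracles.oracle_deduce(mapping, status, obs)
                    assert deduce_transmission(pc, obs) == verdict, (
                        dam, sire, focal, obs
                    )
                    n_checked += 1
        assert n_checked > 1500

    def test_abxab_heterozygotes_never_counted(self):
        """Structural property of the AB x AB exception."""
        for a, b in itertools.combinations([200, 210, 220, 230], 2):
            if {ORIGIN_OF[a], ORIGIN_OF[b]} != {"AUS", "TIM"}:
                continue
            for pc in classify_pair((a, b), (a, b), "m1", REGISTRY):
                assert deduce_transmission(pc, (a, b)) == AMBIGUOUS
                assert deduce_transmission(pc, (a, a)) in (0, 1)


def _toy_family(offspring):
    individuals = [
        ("TD", "F", None, None, "FOUNDER_TIM", "adult"),
        ("AS", "M", None, None, "FOUNDER_AUS", "adult"),
        ("A2", "F", None, None, "FOUNDER_AUS", "adult"),
        ("F1a", "M", "TD", "AS", "F1", "adult"),
        ("AP", "F", None, None, "FOUNDER_AUS", "adult"),
    ]
    genotypes = {
        ("TD", "m1"): (210, 210), ("AS", "m1"): (200, 200),
        ("A2", "m1"): (220, 230), ("F1a", "m1"): (200, 210),
        ("AP", "m1"): (220, 230),
    }
    for i, off in enumerate(offspring):
        individuals.append((f"B{i}", "U", "AP", "F1a", "BC1", "sampled_embryo"))
        genotypes[(f"B{i}", "m1")] = off
    return build_dataset(individuals, genotypes)


class TestCounting:
    def test_toy_pair_counts(self):
        """Four offspring, three Australian transmissions deduced."""
        ds = _toy_family([(200, 220), (200, 230), (200, 220), (210, 230)])
        reg = build_origin_registry(ds)
        res = count_transmissions(ds, reg)
        assert res.ledger["total"] == 4
        assert res.ledger["informative"] == 4
        assert res.summary.iloc[0]["n"] == 4
        assert res.summary.iloc[0]["successes"] == 3

    def test_marginals_additive(self, toy_run):
        ds, _, _ = toy_run
        ds = ancestry.apply_w_coding(ds)
        ds, _ = infer_null_alleles(ds)
        reg = build_origin_registry(ds)
        res = count_transmissions(ds, reg)
        assert res.summary["n"].sum() == len(res.records)
        assert res.summary["successes"].sum() == res.records["transmitted"].sum()
        assert set(res.records["transmitted"].unique()) <= {0, 1}

    def test_ledger_conserves_every_transmission(self, toy_run):
        ds, _, _ = toy_run
        ds = ancestry.apply_w_coding(ds)
        reg = build_origin_registry(ds)
        led = count_transmissions(ds, reg).ledger
        cats = [k for k in led
                if k not in ("total", "informative_percent")]
        assert sum(led[k] for k in cats) == led["total"]


class TestSubsets:
    def test_heterozygous_parents_keeps_abxab(self):
        ds = _toy_family([(200, 200)])
        # make the partner share the focal lengths: AB x AB
        gen = ds.genotypes.copy()
        gen.loc[(gen["individual_id"] == "AP"), ["allele1", "allele2"]] = (200, 210)
        ds = build_dataset(
            ds.individuals.itertuples(index=False, name=None),
            {(r.individual_id, r.marker_id): (r.allele1, r.allele2)
             for r in gen.itertuples()},
        )
        reg = REGISTRY
        recs = count_transmissions(ds, reg).records
        sub = subset_transmissions(recs, ds, reg, "heterozygous_parents")
        assert len(sub) == len(recs) > 0

    def test_no_inbreeding_drops_shared_aus_allele_pairs(self):
        ds = _toy_family([(200, 220)])
        gen_map = {(r.individual_id, r.marker_id): (r.allele1, r.allele2)
                   for r in ds.genotypes.itertuples()}
        gen_map[("AP", "m1")] = (200, 220)  # can produce {200,200}: AUS hom
        ds2 = build_dataset(ds.individuals.itertuples(index=False, name=None),
                            gen_map)
        recs = count_transmissions(ds2, REGISTRY).records
        assert len(recs) > 0
        sub = subset_transmissions(recs, ds2, REGISTRY, "no_inbreeding")
        assert len(sub) == 0

    def test_no_inbreeding_keeps_non_aus_sharing_pairs(self):
        ds = _toy_family([(200, 220)])
        gen_map = {(r.individual_id, r.marker_id): (r.allele1, r.allele2)
                   for r in ds.genotypes.itertuples()}
        gen_map[("B0", "m1")] = (200, 230)  # consistent with the new pair
        gen_map[("AP", "m1")] = (210, 230)  # shares only the TIM length
        ds2 = build_dataset(ds.individuals.itertuples(index=False, name=None),
                            gen_map)
        recs = count_transmissions(ds2, REGISTRY).records
        sub = subset_transmissions(recs, ds2, REGISTRY, "no_inbreeding")
        assert len(sub) == len(recs) > 0

    def test_unknown_subset_rejected(self, toy_run):
        ds, _, _ = toy_run
        reg = build_origin_registry(ancestry.apply_w_coding(ds))
        with pytest.raises(ValueError, match="unknown subset"):
            subset_transmissions(
                count_transmissions(ds, reg).records, ds, reg, "nope"
            )
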