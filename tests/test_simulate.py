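"""ZW meiosis simulator: drive semantics, crossover models, nuisance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meiodrive import ancestry
from meiodrive.simulate import (
    ConfigError,
    CrossConfig,
    default_marker_map,
    gamete_batch,
    simulate_cross,
    simulate_meiosis,
)

from conftest import toy_config
import oracles

AUS, TIM = 0, 1
HAP_A = (200, AUS, 201, AUS)  # AUS-origin homolog
HAP_B = (300, TIM, 301, TIM)  # TIM-origin homolog


def _freq_aus(g, key):
    return float(np.mean(np.asarray(g[key]) == AUS))


class TestMeiosisDrive:
    def test_mi_drive_passthrough_at_centromere(self):
        """d_MI = 0.8 at a 0-cM marker transmits the focal allele at 0.8."""
        rng = np.random.default_rng(0)
        g = gamete_batch(HAP_A, HAP_B, 100_000, rng, female=True, d_mi=0.8,
                         centro_cm=0.0, distal_cm=50.0)
        se = np.sqrt(0.8 * 0.2 / 100_000)
        assert abs(_freq_aus(g, "c_org") - 0.8) < 3 * se

    @pytest.mark.parametrize("cm", [18.0, 34.0, 50.0])
    def test_mi_drive_diluted_by_recombination_at_distal_marker(self, cm):
        """Focal distal-allele frequency = d(1-r) + (1-d)r with
        r = cm/(2L); exactly 0.5 at r = 0.5 (50-cM marker)."""
        rng = np.random.default_rng(1)
        g = gamete_batch(HAP_A, HAP_B, 100_000, rng, female=True, d_mi=0.8,
                         centro_cm=0.0, distal_cm=cm)
        expect = oracles.obligate_one_centromeric_k(0.8, cm)
        se = np.sqrt(expect * (1 - expect) / 100_000)
        assert abs(_freq_aus(g, "d_org") - expect) < 3.5 * se

    @pytest.mark.parametrize("cm", [25.0, 50.0])
    def test_mii_drive_distorts_distal_but_not_centromere(self, cm):
        rng = np.random.default_rng(2)
        g = gamete_batch(HAP_A, HAP_B, 100_000, rng, female=True, d_mii=0.8,
                         centro_cm=0.0, distal_cm=cm)
        expect = oracles.obligate_one_mii_distal_k(0.8, cm)
        se = np.sqrt(0.25 / 100_000)
        assert abs(_freq_aus(g, "d_org") - expect) < 3.5 * se
        assert abs(_freq_aus(g, "c_org") - 0.5) < 3.5 * se

    def test_centromere_only_drive_leaves_50cm_marker_fair(self):
        rng = np.random.default_rng(3)
        g = gamete_batch(HAP_A, HAP_B, 50_000, rng, female=True, d_mi=0.9,
                         centro_cm=0.0, distal_cm=50.0)
        se = np.sqrt(0.25 / 50_000)
        assert abs(_freq_aus(g, "d_org") - 0.5) < 3 * se

    def test_drive_silent_in_males(self):
        """The same d parameter must not bias a male meiosis (drive is
        female-specific; the simulator forces d = 0.5 in males)."""
        rng = np.random.default_rng(4)
        g = gamete_batch(HAP_A, HAP_B, 50_000, rng, female=False, d_mi=0.9,
                         centro_cm=0.0, distal_cm=50.0)
        se = np.sqrt(0.25 / 50_000)
        assert abs(_freq_aus(g, "c_org") - 0.5) < 3 * se

    def test_male_drive_request_is_config_error(self):
        with pytest.raises(ConfigError, match="female"):
            CrossConfig(drive={("all", "M", "MI_centromere"): 0.8})

    def test_poisson_model_reproduces_haldane_map_function(self):
        """Bundle rate L/50 with random chromatid pairs gives
        r(m) = (1 - exp(-2m/100)) / 2."""
        rng = np.random.default_rng(5)
        m = 20.0
        g = gamete_batch(HAP_A, HAP_B, 20_000, rng, female=True,
                         centro_cm=0.0, distal_cm=m, model="poisson")
        # recombinant = centromere origin differs from distal origin
        rec = np.mean(np.asarray(g["c_org"]) != np.asarray(g["d_org"]))
        expect = (1 - np.exp(-2 * m / 100)) / 2
        se = np.sqrt(expect * (1 - expect) / 20_000)
        assert abs(rec - expect) < 3.5 * se

    def test_single_meiosis_wrapper(self):
        cfg = toy_config()
        _, specs = default_marker_map(cfg.n_chromosomes, cfg.include_z)
        rng = np.random.default_rng(6)
        genome = {
            s.name: (HAP_A, HAP_B) if not s.is_z else (HAP_A, ("W",))
            for s in specs
        }
        gamete = simulate_meiosis(genome, "F", cfg, specs, rng)
        assert set(gamete) == {s.name for s in specs}
        for s in specs:
            assert "c_len" in gamete[s.name]


class TestMarkerMap:
    def test_default_map_matches_study_layout(self):
        markers, specs = default_marker_map()
        cen = markers[markers["position_class"] == "centromeric"]
        dis = markers[markers["position_class"] == "distal"]
        assert len(cen) == 29 and len(dis) == 27
        assert cen["cm_from_centromere"].median() == 0.0
        assert cen["cm_from_centromere"].max() <= 27
        assert dis["cm_from_centromere"].median() == 50.0
        assert dis["cm_from_centromere"].min() >= 18
        # minimum inter-marker distance on shared chromosomes
        merged = cen.merge(dis, on="chromosome", suffixes=("_c", "_d"))
        gap = merged["cm_from_centromere_d"] - merged["cm_from_centromere_c"]
        assert (gap >= 17).all()


class TestCrossInvariants:
    def test_fair_cross_markers_binomial_over_seeds(self):
        """With d = 0.5 everywhere, per-marker transmission counts are
        Binomial(n, 0.5): the per-seed goodness-of-fit (number of markers
        rejected by the exact binomial test at 5%) is unremarkable in
        >= 95% of seeds."""
        from meiodrive.inference import binomial_p_two_sided

        nonsig = 0
        n, n_markers, seeds = 200, 56, 20
        # 95th percentile of rejections under fairness
        crit = stats.binom.ppf(0.95, n_markers, 0.05)
        for seed in range(seeds):
            rng = np.random.default_rng(100 + seed)
            s = np.array([
                int(np.sum(np.asarray(
                    gamete_batch(HAP_A, HAP_B, n, rng, female=True,
                                 centro_cm=0.0, distal_cm=50.0)["c_org"]
                ) == AUS))
                for _ in range(n_markers)
            ])
            pvals = binomial_p_two_sided(s, n, 0.5)
            if np.sum(pvals <= 0.05) <= crit:
                nonsig += 1
        assert nonsig >= seeds - 1

    def test_truth_log_reconciles_exactly_on_clean_run(self, clean_run):
        """Nuisance-free: deduced transmission counts equal the truth log
        for every (parent, marker) with an informative pair."""
        ds, truth, _ = clean_run
        ds = ancestry.apply_w_coding(ds)
        reg = ancestry.build_origin_registry(ds)
        res = ancestry.count_transmissions(ds, reg)
        recs = res.records
        tt = truth.transmissions.set_index(
            ["offspring_id", "parent_id", "marker_id"]
        )["origin"]
        assert len(recs) > 500
        for r in recs.itertuples():
            true_org = tt.loc[(r.offspring_id, r.parent_id, r.marker_id)]
            assert r.transmitted == (1 if true_org == "AUS" else 0)

    def test_fair_cross_pooled_k_near_half(self, clean_run):
        ds, _, _ = clean_run
        ds = ancestry.apply_w_coding(ds)
        reg = ancestry.build_origin_registry(ds)
        recs = ancestry.count_transmissions(ds, reg).records
        k = recs["transmitted"].mean()
        se = np.sqrt(0.25 / len(recs))
        assert abs(k - 0.5) < 3.5 * se

    def test_sex_ratio_binomial_under_fair_w_transmission(self, toy_run):
        ds, _, _ = toy_run
        bc = ds.individuals[ds.individuals["cohort"].isin(("BC1", "BC2"))]
        sexed = bc[bc["sex"].isin(("F", "M"))]
        nf = int((sexed["sex"] == "F").sum())
        n = len(sexed)
        assert abs(nf - n / 2) < 4 * np.sqrt(n / 4)

    def test_infertile_egg_rate_binomial(self):
        """~12% of eggs are apparently infertile (3 SE band)."""
        cfg = toy_config(bc1_samples=400, bc2_samples=600, rng_seed=21)
        ds, _ = simulate_cross(cfg)
        eggs = ds.individuals[ds.individuals["cohort"].isin(("BC1", "BC2"))]
        rate = (eggs["fate"] == "infertile_egg").mean()
        se = np.sqrt(0.12 * 0.88 / len(eggs))
        assert abs(rate - 0.12) < 3.5 * se

    def test_determinism_same_seed_same_dataset(self):
        cfg = toy_config(rng_seed=31)
        ds1, _ = simulate_cross(cfg)
        ds2, _ = simulate_cross(toy_config(rng_seed=31))
        pd.testing.assert_frame_equal(ds1.genotypes, ds2.genotypes)
        pd.testing.assert_frame_equal(ds1.individuals, ds2.individuals)

    def test_inbreeding_penalty_biases_survivors_not_truth(self):
        """With drive off and an inbreeding penalty on, the naive k among
        surviving offspring drops below 0.5 while all-conceptus counts
        stay fair (survivorship bias, not drive)."""
        cfg = toy_config(
            inbreeding_penalty=0.6, null_allele_rate=0.0,
            genotype_missing_rate=0.0, founder_introgression=0.0,
            abnormality_rates={}, bc1_samples=400, bc2_samples=700,
            rng_seed=41,
        )
        ds, truth = simulate_cross(cfg)
        ds = ancestry.apply_w_coding(ds)
        reg = ancestry.build_origin_registry(ds)
        recs = ancestry.count_transmissions(ds, reg).records
        alive = set(
            ds.individuals.loc[ds.individuals["fate"] != "dead_chick",
                               "individual_id"]
        )
        k_all = recs["transmitted"].mean()
        k_alive = recs[recs["offspring_id"].isin(alive)]["transmitted"].mean()
        assert k_alive < k_all
        assert k_alive < 0.5

    def test_founder_introgression_marks_markers(self):
        cfg = toy_config(founder_introgression=0.25, rng_seed=51)
        _, truth = simulate_cross(cfg)
        n_markers = len(default_marker_map(cfg.n_chromosomes)[0])
        frac = len(truth.introgressed_markers) / n_markers
        # marker-level probability is twice the diploid fraction
        assert 0.1 < frac < 0.9

    def test_impossible_cohort_sizes_rejected(self):
        with pytest.raises(ConfigError, match="mothers|adults|samples"):
            toy_config(bc1_adult_males=200, bc1_adult_females=200)
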