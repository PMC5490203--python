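"""Wildtype sex-as-a-biological-variable analyses."""

import numpy as np
import pandas as pd
import pytest

from dimorph.io import AssembledDataset, WILDTYPE_KEY, assemble_wildtype_datasets
from dimorph.generate import GeneratorConfig, generate_controls
from dimorph.wildtype import (
    WildtypeSexResult,
    analyze_wt_categorical,
    analyze_wt_continuous,
    cross_centre_concordance,
    results_frame,
    summarize_prevalence,
)
from dimorph.stats import Interval

from conftest import make_obs


def categorical_wt_dataset(xf, nf, xm, nm, **key_over):
    rows = []
    for sex, x, n in (("female", xf, nf), ("male", xm, nm)):
        rows += [
            dict({"sex": sex, "trait_kind": "categorical",
                  "category": "not_as_expected" if i < x else "as_expected"}, **key_over)
            for i in range(n)
        ]
    obs = make_obs(rows)
    key = tuple(obs.iloc[0][k] for k in WILDTYPE_KEY)
    return AssembledDataset(key=key, trait_kind="categorical", data=obs,
                            key_fields=tuple(WILDTYPE_KEY))


class TestCategorical:
    def test_equal_rates_not_significant(self):
        r = analyze_wt_categorical(categorical_wt_dataset(5, 200, 5, 200))
        assert r.raw_p > 0.5
        assert r.effect_interval.point == 0.0

    def test_female_excess_detected(self):
        r = analyze_wt_categorical(categorical_wt_dataset(20, 200, 2, 200))
        assert r.raw_p < 0.05
        assert r.effect_direction == "female_greater"
        assert r.effect_interval.lower > 0

    def test_all_as_expected_degenerate(self):
        r = analyze_wt_categorical(categorical_wt_dataset(0, 150, 0, 150))
        assert r.raw_p == 1.0

    def test_effect_bounds_within_unit_interval(self):
        r = analyze_wt_categorical(categorical_wt_dataset(200, 200, 0, 200))
        assert -1.0 <= r.effect_interval.lower <= r.effect_interval.upper <= 1.0


def continuous_wt_dataset(seed, sex_effect=0.0, weight_slope=0.0, n_batches=20,
                          controls_per_batch_per_sex=10, **cfg_over):
    cfg = GeneratorConfig(seed=seed, sex_effect=sex_effect, weight_slope=weight_slope,
                          n_batches=n_batches,
                          controls_per_batch_per_sex=controls_per_batch_per_sex, **cfg_over)
    obs, _, _ = generate_controls(cfg)
    return assemble_wildtype_datasets(obs, "continuous")[0]


class TestContinuous:
    def test_null_size_close_to_nominal(self):
        # no sex effect: raw p < 0.05 should occur at ~5% over seeded replicates
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            ds = continuous_wt_dataset(seed, n_batches=20, controls_per_batch_per_sex=6)
            hits += analyze_wt_continuous(ds, "absolute").raw_p < 0.05
        rate = hits / n_rep
        mc_se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 3 * mc_se

    def test_weight_mediated_effect_separates_variants(self):
        # trait driven purely by weight; males heavier: the absolute analysis
        # sees a male shift, the weight-adjusted analysis should not
        ok_abs, ok_adj = 0, 0
        n_rep = 20
        for seed in range(1000, 1000 + n_rep):
            ds = continuous_wt_dataset(seed, weight_slope=0.5, n_batches=25,
                                       controls_per_batch_per_sex=12)
            r_abs = analyze_wt_continuous(ds, "absolute")
            r_adj = analyze_wt_continuous(ds, "weight_adjusted")
            ok_abs += (r_abs.raw_p < 0.05) and r_abs.effect_direction == "male_greater"
            ok_adj += r_adj.raw_p >= 0.05
        assert ok_abs >= 0.9 * n_rep
        assert ok_adj >= 0.9 * n_rep

    def test_direct_sex_effect_detected_by_both_variants(self):
        ds = continuous_wt_dataset(7, sex_effect=1.0, n_batches=25, controls_per_batch_per_sex=8)
        r_abs = analyze_wt_continuous(ds, "absolute")
        r_adj = analyze_wt_continuous(ds, "weight_adjusted")
        # weight is collinear with sex (males heavier), so the adjusted
        # variant loses some precision but both remain clearly significant
        assert r_abs.raw_p < 1e-6 and r_adj.raw_p < 1e-3
        assert r_abs.effect_direction == r_adj.effect_direction == "male_greater"

    def test_direction_invariant_to_sex_recoding(self):
        ds = continuous_wt_dataset(8, sex_effect=-0.8, n_batches=25, controls_per_batch_per_sex=8)
        r = analyze_wt_continuous(ds, "absolute")
        flipped_data = ds.data.copy()
        flipped_data["sex"] = flipped_data["sex"].map({"female": "male", "male": "female"})
        flipped = AssembledDataset(key=ds.key, trait_kind="continuous", data=flipped_data,
                                   key_fields=ds.key_fields)
        r_flip = analyze_wt_continuous(flipped, "absolute")
        assert r.raw_p == pytest.approx(r_flip.raw_p, rel=1e-6)
        assert {r.effect_direction, r_flip.effect_direction} == {"female_greater", "male_greater"}


def _mk_result(param, centre, p, direction, variant="continuous_absolute"):
    key = (centre, "B6N", "pipe", param, "mg")
    return WildtypeSexResult(
        key=key, key_fields=tuple(WILDTYPE_KEY), trait_kind="continuous",
        analysis_variant=variant, raw_p=p,
        effect_interval=Interval(0.1 if direction == "female_greater" else -0.1, -1, 1),
        effect_direction=direction, procedure="proc",
    )


class TestSummaries:
    def test_all_null_gives_zero_prevalence(self):
        results = [_mk_result(f"t{i}", "A", 1.0, "none") for i in range(100)]
        s = summarize_prevalence(results)
        assert s["overall"]["n_significant"] == 0
        assert all(r.direction == "none" for r in results)

    def test_mixed_variants_rejected(self):
        results = [_mk_result("t", "A", 0.5, "none"),
                   _mk_result("t2", "A", 0.5, "none", variant="categorical")]
        with pytest.raises(ValueError, match="variants"):
            summarize_prevalence(results)

    def test_per_centre_counts_sum_to_overall(self):
        rng = np.random.default_rng(0)
        results = [
            _mk_result(f"t{i}", c, p, "female_greater")
            for i, (c, p) in enumerate(zip(rng.choice(["A", "B", "C"], 60), rng.random(60) ** 4))
        ]
        s = summarize_prevalence(results)
        assert s["per_centre"]["n_significant"].sum() == s["overall"]["n_significant"]
        assert s["per_centre"]["n"].sum() == s["overall"]["n"]

    def test_prevalence_recovery_with_true_effects(self):
        # 30% of data sets get a 1.5 residual-SD sex effect at n=150/sex
        results = []
        for i in range(40):
            effect = 1.5 if i < 12 else 0.0
            ds = continuous_wt_dataset(3000 + i, sex_effect=effect, n_batches=25,
                                       controls_per_batch_per_sex=6, parameter=f"t{i}")
            results.append(analyze_wt_continuous(ds, "absolute"))
        s = summarize_prevalence(results)
        assert abs(s["overall"]["percent_significant"] - 30.0) <= 10.0

    def test_adjustment_is_study_wide_not_per_centre(self):
        # one strong hit among many nulls: per-centre adjustment would rescue
        # borderline hits that the study-wide family correctly suppresses
        results = [_mk_result("t0", "A", 0.01, "female_greater")] + [
            _mk_result(f"t{i}", "B", 0.3, "none") for i in range(1, 20)
        ]
        summarize_prevalence(results)
        assert not any(r.significant for r in results)  # 20 * 0.01 > 0.05 study-wide
        single = [_mk_result("t0", "A", 0.01, "female_greater")]
        summarize_prevalence(single)
        assert single[0].significant


class TestConcordance:
    def test_concordant_and_discordant_and_excluded(self):
        results = (
            [_mk_result("p1", c, 0.001, "female_greater") for c in "ABC"]
            + [_mk_result("p2", c, 0.001, "female_greater") for c in "AB"]
            + [_mk_result("p2", "C", 0.001, "male_greater")]
            + [_mk_result("p3", c, 0.001, "female_greater") for c in "AB"]  # 2 centres only
        )
        summarize_prevalence(results)
        table, pct = cross_centre_concordance(results)
        verdict = table.set_index("parameter")["discordant"]
        assert not verdict["p1"]
        assert verdict["p2"]
        assert "p3" not in verdict.index
        assert pct == pytest.approx(50.0)

    def test_nonsignificant_disagreement_is_not_discordant(self):
        results = (
            [_mk_result("p1", "A", 0.001, "female_greater")]
            + [_mk_result("p1", "B", 0.9, "male_greater")]
            + [_mk_result("p1", "C", 0.9, "male_greater")]
        )
        summarize_prevalence(results)
        table, _ = cross_centre_concordance(results)
        assert not table["discordant"].iloc[0]
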