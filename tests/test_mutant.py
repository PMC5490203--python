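"""Two-stage mutant pipelines and the SD classification taxonomy."""

import numpy as np
import pandas as pd
import pytest

from dimorph.generate import GeneratorConfig, generate_controls, generate_mutant_line
from dimorph.io import AssembledDataset, assemble_mutant_datasets
from dimorph.mutant import (
    SD_LABELS,
    classify_sd_continuous,
    run_categorical_pipeline,
    run_continuous_pipeline,
    stage_results_frame,
    summarize_by_gene,
    summarize_by_screen,
)
from dimorph.stats import Interval

from conftest import categorical_dataset


class TestCategoricalPipeline:
    def test_strong_genotype_no_sex_effect(self):
        # knockouts abnormal in both sexes equally: stage 1 fires, stage 2 does not
        ds = categorical_dataset(
            ctrl={"female": (1, 200), "male": (1, 200)},
            ko={"female": (6, 7), "male": (6, 7)},
        )
        (r,) = run_categorical_pipeline([ds])
        assert r.stage1 is not None and r.stage1_pass
        assert r.classification == "genotype_no_sex_effect"

    def test_female_specific_effect(self):
        ds = categorical_dataset(
            ctrl={"female": (0, 200), "male": (0, 200)},
            ko={"female": (7, 7), "male": (0, 7)},
        )
        (r,) = run_categorical_pipeline([ds])
        assert r.stage1_pass and r.stage2_pass
        assert r.classification == "female_greater"
        assert r.abnormality_diff.point == 1.0

    def test_zero_abnormal_filtered_without_testing(self):
        ds = categorical_dataset(
            ctrl={"female": (0, 100), "male": (0, 100)},
            ko={"female": (0, 7), "male": (0, 7)},
        )
        (r,) = run_categorical_pipeline([ds])
        assert r.filter_alpha_star == 1.0
        assert r.stage1 is None and not r.stage1_pass

    def test_wildtype_dataset_rejected(self):
        ds = categorical_dataset(ctrl={"female": (0, 10), "male": (0, 10)}, ko={"female": (1, 7), "male": (1, 7)})
        ds.key = ds.key[:-1] + ("",)
        with pytest.raises(ValueError, match="mutant"):
            run_categorical_pipeline([ds])

    def test_filters_only_shrink_the_family(self):
        # disabling the alpha-star filter must not change any surviving p-value
        strong = categorical_dataset(
            ctrl={"female": (1, 150), "male": (1, 150)},
            ko={"female": (5, 7), "male": (6, 7)}, colony="c_strong",
        )
        empty = categorical_dataset(
            ctrl={"female": (0, 150), "male": (0, 150)},
            ko={"female": (0, 7), "male": (0, 7)}, colony="c_empty",
        )
        filtered = run_categorical_pipeline([strong, empty])
        unfiltered = run_categorical_pipeline([strong, empty], alpha_star_threshold=1.1)
        assert filtered[0].stage1.p_value == unfiltered[0].stage1.p_value
        assert filtered[1].stage1 is None and unfiltered[1].stage1 is not None

    def test_stage2_never_without_stage1(self):
        datasets = [
            categorical_dataset(
                ctrl={"female": (1, 100), "male": (2, 100)},
                ko={"female": (f, 7), "male": (m, 7)}, colony=f"c{f}{m}",
            )
            for f, m in [(0, 0), (2, 1), (7, 0), (6, 6), (1, 5)]
        ]
        results = run_categorical_pipeline(datasets)
        for r in results:
            if r.stage2 is not None:
                assert r.stage1_pass
            if not r.stage1_pass:
                assert r.stage2 is None


def continuous_dataset(seed, genotype_effect, workflow="multi_batch", n_batches=30,
                       controls_per_batch_per_sex=7, ko_cohort_per_sex=7, colony="col1",
                       **cfg_over):
    cfg = GeneratorConfig(seed=seed, genotype_effect=genotype_effect, n_batches=n_batches,
                          controls_per_batch_per_sex=controls_per_batch_per_sex,
                          ko_cohort_per_sex=ko_cohort_per_sex, **cfg_over)
    controls, _, ctx = generate_controls(cfg)
    ko, truth = generate_mutant_line(cfg, workflow, context=ctx, colony_id=colony)
    obs = pd.concat([controls, ko], ignore_index=True)
    return assemble_mutant_datasets(obs, "continuous"), truth


class TestContinuousPipeline:
    def test_male_only_effect_recovered(self):
        # 3 residual-SD male-only effect, 7/sex knockouts: recovered in >= 80%
        hits, n_rep = 0, 60
        for seed in range(n_rep):
            datasets, truth = continuous_dataset(seed, (0.0, 3.0))
            (r,) = run_continuous_pipeline(datasets)
            hits += r.classification == "male_only"
        assert hits >= 0.8 * n_rep

    def test_equal_effect_classified_no_sex_effect(self):
        calls = []
        for seed in range(100, 130):
            datasets, _ = continuous_dataset(seed, (2.5, 2.5))
            (r,) = run_continuous_pipeline(datasets)
            calls.append(r.classification)
        assert calls.count("genotype_no_sex_effect") >= 0.7 * len(calls)

    def test_null_stage1_rate_near_nominal(self):
        raw = []
        for seed in range(200, 320):
            datasets, _ = continuous_dataset(seed, (0.0, 0.0))
            (r,) = run_continuous_pipeline(datasets)
            raw.append(r.stage1.p_value)
        rate = np.mean(np.array(raw) < 0.05)
        mc_se = np.sqrt(0.05 * 0.95 / len(raw))
        assert abs(rate - 0.05) <= 3 * mc_se

    def test_workflow_filter_excludes_low_batch(self):
        datasets, _ = continuous_dataset(5, (0.0, 3.0), workflow="one_batch")
        (r,) = run_continuous_pipeline(datasets, workflow_filter="multi_batch")
        assert r.stage1 is None
        assert "excluded_by_workflow_filter" in r.flags

    def test_classification_swaps_with_sex_relabelling(self):
        datasets, _ = continuous_dataset(9, (3.5, 0.0))
        (r,) = run_continuous_pipeline(datasets)
        swapped_data = datasets[0].data.copy()
        swapped_data["sex"] = swapped_data["sex"].map({"female": "male", "male": "female"})
        swapped = [AssembledDataset(key=datasets[0].key, trait_kind="continuous",
                                    data=swapped_data, key_fields=datasets[0].key_fields)]
        (r2,) = run_continuous_pipeline(swapped)
        mapping = {"female_only": "male_only", "male_only": "female_only",
                   "female_greater": "male_greater", "male_greater": "female_greater"}
        assert r2.classification == mapping.get(r.classification, r.classification)


class TestClassifySdContinuous:
    def iv(self, lo, hi):
        return Interval(point=(lo + hi) / 2, lower=lo, upper=hi)

    def test_not_significant_is_no_sex_effect(self):
        assert classify_sd_continuous(self.iv(-0.2, 0.1), self.iv(-0.4, -0.1), False) == "genotype_no_sex_effect"

    @pytest.mark.parametrize(
        "female,male,expected",
        [
            ((-0.2, 0.1), (-0.4, -0.1), "male_only"),
            ((0.1, 0.4), (-0.2, 0.1), "female_only"),
            ((0.1, 0.3), (-0.3, -0.1), "opposing_directions"),
            ((0.5, 0.9), (0.1, 0.3), "female_greater"),
            ((0.1, 0.3), (0.5, 0.9), "male_greater"),
            ((-0.2, 0.1), (-0.1, 0.2), "cannot_classify"),
        ],
    )
    def test_taxonomy(self, female, male, expected):
        assert classify_sd_continuous(self.iv(*female), self.iv(*male), True) == expected

    def test_missing_intervals_rejected(self):
        with pytest.raises(ValueError):
            classify_sd_continuous(None, self.iv(0, 1), True)


class TestSummaries:
    def _fake_results(self):
        datasets, _ = continuous_dataset(33, (0.0, 3.0))
        (r,) = run_continuous_pipeline(datasets)
        return r

    def test_gene_summary_arithmetic(self):
        r = self._fake_results()
        results = []
        for i in range(10):
            import copy

            ri = copy.deepcopy(r)
            ri.stage1_pass = True
            ri.stage2_pass = i < 4
            ri.classification = "male_only" if i < 4 else "genotype_no_sex_effect"
            results.append(ri)
        table = summarize_by_gene(results)
        assert table.loc[0, "n_genotype_hits"] == 10
        assert table.loc[0, "sd_fraction"] == pytest.approx(0.4)

    def test_gene_summary_excludes_lines_without_hits(self):
        r = self._fake_results()
        r.stage1_pass = False
        r.stage2_pass = False
        assert len(summarize_by_gene([r])) == 0

    def test_screen_summary_threshold(self):
        import copy

        r = self._fake_results()
        results = []
        for proc, n_hits, n_sd in [("proc_small", 34, 5), ("proc_big", 40, 5)]:
            for i in range(n_hits):
                ri = copy.deepcopy(r)
                ri.procedure = proc
                ri.stage1_pass = True
                ri.stage2_pass = i < n_sd
                results.append(ri)
        table = summarize_by_screen(results, min_hits=35)
        assert list(table["procedure"]) == ["proc_big"]
        assert table.loc[0, "sd_hit_rate_percent"] == pytest.approx(12.5)

    def test_empty_input_empty_tables(self):
        assert len(summarize_by_screen([])) == 0
        assert len(summarize_by_gene([])) == 0
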