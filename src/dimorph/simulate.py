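"""Type-I-error validation of the continuous two-stage pipeline.

Two study designs: (i) resampling wildtype observations into mock
knockout/control splits whose batch pattern mimics a named phenotyping
workflow, so both stages are run under an exact null; (ii) a parametric
stage-2 study where an equal-in-both-sexes genotype shift ("main effect")
is added to mock knockouts, checking that a pure main effect does not
masquerade as a sex-by-genotype interaction.

Mock knockouts are a relabelling of existing control rows, never a
redraw, so resampling preserves the marginal distribution of the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import mixed_lr_test, mixed_model_fit
from .mutant import _prepare_continuous

__all__ = [
    "SimulationDesign",
    "TraitSpec",
    "resample_workflow_null",
    "simulate_stage2_null_with_main_effect",
    "default_trait_panel",
]

_EQ3 = ["genotype", "sex_male", "genotype_x_sex", "body_weight"]
_EQ4 = ["sex_male", "body_weight"]
_EQ5 = ["genotype", "sex_male", "body_weight"]


@dataclass(frozen=True)
class TraitSpec:
    """Signal characteristics of one simulated trait."""

    name: str
    mean: float
    sd: float
    sex_effect: float = 0.0


def default_trait_panel() -> list[TraitSpec]:
    """A small panel emulating the scale diversity of clinical-chemistry
    style screens (very different means/SDs and sex effects)."""
    return [
        TraitSpec("albumin", 30.0, 2.0, 1.0),
        TraitSpec("alt", 50.0, 20.0, -8.0),
        TraitSpec("glucose", 9.0, 1.5, 0.8),
        TraitSpec("total_protein", 55.0, 3.0, 0.0),
        TraitSpec("calcium", 2.3, 0.1, 0.02),
    ]


@dataclass(frozen=True)
class SimulationDesign:
    mode: str  # "resample_wildtype" | "parametric_stage2"
    workflow: str = "random"
    iterations: int = 500
    cohort_per_sex: int = 7
    n_batches: int = 300
    controls_per_batch_per_sex: int = 2
    batch_sd_fraction: float = 0.25
    signal_levels: tuple = (0.0, 0.5, 1.0, 1.5, 2.0)
    thresholds: tuple = (0.01, 0.05, 0.10, 0.20)
    traits: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if any(not (0.0 < t < 1.0) for t in self.thresholds):
            raise ValueError("thresholds must lie in (0, 1)")


def _stage_ps(d: pd.DataFrame) -> tuple[float, float]:
    """Stage-1 and stage-2 LR p-values on one prepared data frame."""
    full = mixed_model_fit(d, "value", _EQ3, residual_group="genotype_class")
    structure = (full.residual_structure,)
    null1 = mixed_model_fit(d, "value", _EQ4, residual_group="genotype_class", candidates=structure)
    null2 = mixed_model_fit(d, "value", _EQ5, residual_group="genotype_class", candidates=structure)
    return mixed_lr_test(full, null1).p_value, mixed_lr_test(full, null2).p_value


def _sample_counts(total: int, parts: int, rng: np.random.Generator) -> list[int]:
    base, extra = divmod(total, parts)
    counts = [base + (1 if i < extra else 0) for i in range(parts)]
    rng.shuffle(counts)
    return counts


def _mock_ko_indices(
    by_sex_batch: dict, workflow: str, cohort: int, rng: np.random.Generator
) -> np.ndarray:
    """Row indices to relabel as mock knockouts under a workflow pattern."""

    def from_batches(sex: str, batches: list, counts: list[int]) -> list[int]:
        picked: list[int] = []
        for b, c in zip(batches, counts):
            idx = by_sex_batch[sex][b]
            picked.extend(rng.choice(idx, size=c, replace=False))
        return picked

    def batches_with(sex: str, min_rows: int) -> list:
        return [b for b, idx in by_sex_batch[sex].items() if len(idx) >= min_rows]

    def distinct(sex: str, k: int, min_rows: int, exclude=()) -> list:
        ok = [b for b in batches_with(sex, min_rows) if b not in exclude]
        if len(ok) < k:
            raise ValueError(f"insufficient controls to realize workflow {workflow!r}")
        return list(rng.choice(ok, size=k, replace=False))

    if workflow == "one_batch":
        both = [b for b in batches_with("female", cohort) if b in batches_with("male", cohort)]
        if not both:
            raise ValueError("insufficient controls to realize workflow 'one_batch'")
        b = both[rng.integers(len(both))]
        return np.array(from_batches("female", [b], [cohort]) + from_batches("male", [b], [cohort]))
    if workflow == "two_batch":
        bf = distinct("female", 1, cohort)
        bm = distinct("male", 1, cohort, exclude=bf)
        return np.array(from_batches("female", bf, [cohort]) + from_batches("male", bm, [cohort]))
    if workflow == "three_batch":
        cf = _sample_counts(cohort, 2, rng)
        bf = distinct("female", 2, max(cf))
        bm = distinct("male", 1, cohort, exclude=bf)
        return np.array(from_batches("female", bf, cf) + from_batches("male", bm, [cohort]))
    if workflow == "multi_batch":
        cf = _sample_counts(cohort, 3, rng)
        cm = _sample_counts(cohort, 2, rng)
        bf = distinct("female", 3, max(cf))
        bm = distinct("male", 2, max(cm), exclude=bf)
        return np.array(from_batches("female", bf, cf) + from_batches("male", bm, cm))
    if workflow == "random":
        picked = []
        for sex in ("female", "male"):
            allidx = np.concatenate(list(by_sex_batch[sex].values()))
            if len(allidx) < cohort:
                raise ValueError("insufficient controls to realize workflow 'random'")
            picked.extend(rng.choice(allidx, size=cohort, replace=False))
        return np.array(picked)
    raise ValueError(f"unknown workflow {workflow!r}")


def _surface_rows(ps: np.ndarray, thresholds, **labels) -> list[dict]:
    rows = []
    n = len(ps)
    for thr in thresholds:
        r = float(np.mean(ps < thr))
        rows.append(
            dict(labels, threshold=thr, n_iterations=n, rejection_rate=r,
                 mc_se=float(np.sqrt(r * (1.0 - r) / n)))
        )
    return rows


def resample_workflow_null(controls: pd.DataFrame, design: SimulationDesign) -> pd.DataFrame:
    """Empirical stage-1/stage-2 rejection rates under resampled nulls.

    Per iteration, a per-sex cohort of control animals is relabelled as
    mock knockouts following the workflow's batch pattern and both stages
    of the continuous pipeline run without multiplicity adjustment. The
    returned surface has one row per trait x stage x threshold.
    """
    if (controls["genotype_class"] != "control").any():
        raise ValueError("resampling expects control-only observations")
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []
    for param, g in controls.groupby("parameter", sort=True):
        g = g.reset_index(drop=True)
        by_sex_batch = {
            sex: {b: idx.to_numpy() for b, idx in gg.groupby("batch_label").groups.items()}
            for sex, gg in ((s, g[g["sex"] == s]) for s in ("female", "male"))
        }
        p1s, p2s = np.empty(design.iterations), np.empty(design.iterations)
        for it in range(design.iterations):
            ko_idx = _mock_ko_indices(by_sex_batch, design.workflow, design.cohort_per_sex, rng)
            d = g.copy()
            d.loc[ko_idx, "genotype_class"] = "mutant"
            d.loc[ko_idx, "colony_id"] = "mock"
            p1s[it], p2s[it] = _stage_ps(_prepare_continuous(d))
        rows += _surface_rows(p1s, design.thresholds, parameter=param,
                              workflow=design.workflow, stage=1, signal=0.0)
        rows += _surface_rows(p2s, design.thresholds, parameter=param,
                              workflow=design.workflow, stage=2, signal=0.0)
    return pd.DataFrame(rows)


def simulate_stage2_null_with_main_effect(design: SimulationDesign) -> pd.DataFrame:
    """Stage-2 size when knockouts carry a pure (sex-equal) main effect.

    Per iteration a wildtype population is simulated over ``n_batches``
    batches with batch SD = ``batch_sd_fraction`` x residual SD; a random-
    workflow mock-knockout cohort is drawn, the same cohort is shifted by
    each signal level x SD in both sexes (body weight sampled from the
    wildtype female distribution), and the interaction test runs. A pure
    main effect should leave the rejection rate at nominal for every
    signal level.
    """
    if design.mode != "parametric_stage2":
        raise ValueError("design.mode must be 'parametric_stage2'")
    traits = list(design.traits) or [TraitSpec("clinical_chemistry_trait", 30.0, 2.0, 1.0)]
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []
    per = design.controls_per_batch_per_sex
    nb = design.n_batches
    n_ctrl = nb * per * 2
    c = design.cohort_per_sex
    for trait in traits:
        ps = {lvl: np.empty(design.iterations) for lvl in design.signal_levels}
        for it in range(design.iterations):
            batch = np.repeat(np.arange(nb), per * 2)
            sex_male = np.tile(np.r_[np.zeros(per), np.ones(per)], nb)
            bdev = rng.normal(0.0, design.batch_sd_fraction * trait.sd, nb)
            value = (
                trait.mean + trait.sex_effect * sex_male + bdev[batch]
                + rng.normal(0.0, trait.sd, n_ctrl)
            )
            # body weight sampled from the wildtype female signal
            weight = rng.normal(22.0, 2.0, n_ctrl + 2 * c)
            ko_batch = rng.integers(nb, size=2 * c)
            ko_sex = np.r_[np.zeros(c), np.ones(c)]
            ko_base = (
                trait.mean + trait.sex_effect * ko_sex + bdev[ko_batch]
                + rng.normal(0.0, trait.sd, 2 * c)
            )
            for lvl in design.signal_levels:
                d = pd.DataFrame(
                    {
                        "value": np.r_[value, ko_base + lvl * trait.sd],
                        "sex_male": np.r_[sex_male, ko_sex],
                        "genotype": np.r_[np.zeros(n_ctrl), np.ones(2 * c)],
                        "body_weight": weight,
                        "batch_label": np.r_[batch, ko_batch],
                        "genotype_class": ["control"] * n_ctrl + ["mutant"] * 2 * c,
                    }
                )
                d["genotype_x_sex"] = d["genotype"] * d["sex_male"]
                full = mixed_model_fit(d, "value", _EQ3, residual_group="genotype_class")
                null2 = mixed_model_fit(
                    d, "value", _EQ5, residual_group="genotype_class",
                    candidates=(full.residual_structure,),
                )
                ps[lvl][it] = mixed_lr_test(full, null2).p_value
        for lvl in design.signal_levels:
            rows += _surface_rows(ps[lvl], design.thresholds, parameter=trait.name,
                                  workflow="random", stage=2, signal=lvl)
    return pd.DataFrame(rows)
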