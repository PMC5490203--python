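"""Synthetic phenotyping data with known ground truth.

Emulates the structure of high-throughput phenotyping data: control
animals accumulate over time in measurement batches (calendar dates),
knockout cohorts of ~7 animals per sex are phenotyped alongside them, a
batch-level random deviate is shared by every animal measured on the same
date, body weight is sexually dimorphic (males heavier) and may feed into
the trait, and genotype effects can differ by sex. Every generated table
passes the data-model validation and carries a truth record for
generator-truth recovery tests.

All randomness flows from one explicit seed through spawned substreams,
so individual lines are regenerable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import COLUMNS, validate_observations

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "generate_controls",
    "generate_mutant_line",
    "generate_categorical_line",
    "true_sd_category",
]

_EPOCH = pd.Timestamp("2014-01-06")


@dataclass(frozen=True)
class GeneratorConfig:
    """World description for one synthetic centre/trait.

    Defaults mirror the stated experimental conditions: knockout cohorts
    of 7 per sex, batch standard deviation 25% of the residual SD, and a
    sexually dimorphic body weight (female 22 g, male 28 g, SD 2 g).
    """

    seed: int
    centre: str = "centre_A"
    genetic_background: str = "C57BL/6N"
    pipeline: str = "pipeline_1"
    procedure: str = "clinical_chemistry"
    parameter: str = "trait_1"
    metadata_group: str = "mg0"
    n_batches: int = 50
    batch_spacing_days: int = 7
    controls_per_batch_per_sex: int = 3
    ko_cohort_per_sex: int = 7
    trait_mean: float = 10.0
    residual_sd: float = 1.0
    #: batch SD as a fraction of the residual SD
    batch_sd: float = 0.25
    #: male minus female shift in trait units
    sex_effect: float = 0.0
    weight_mean_female: float = 22.0
    weight_mean_male: float = 28.0
    weight_sd: float = 2.0
    #: trait change per gram of body weight
    weight_slope: float = 0.0
    #: per-sex genotype effects in trait units (female, male)
    genotype_effect: tuple[float, float] = (0.0, 0.0)
    #: abnormality probabilities per (sex, genotype_class)
    categorical_rates: dict = field(
        default_factory=lambda: {
            ("female", "control"): 0.01,
            ("male", "control"): 0.01,
            ("female", "mutant"): 0.01,
            ("male", "mutant"): 0.01,
        }
    )

    def __post_init__(self) -> None:
        if self.n_batches < 1 or self.controls_per_batch_per_sex < 0 or self.ko_cohort_per_sex < 1:
            raise ValueError("counts must be positive")
        if any(not (0.0 <= p <= 1.0) for p in self.categorical_rates.values()):
            raise ValueError("categorical rates must lie in [0, 1]")
        if self.residual_sd <= 0 or self.weight_sd <= 0 or self.batch_sd < 0:
            raise ValueError("scales must be positive (batch_sd may be zero)")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth behind one generated line/trait."""

    parameter: str
    colony_id: str | None
    sex_effect: float
    genotype_effect_female: float
    genotype_effect_male: float
    sd_category: str


def true_sd_category(effect_female: float, effect_male: float) -> str:
    """SD category implied by a pair of per-sex genotype effects."""
    f, m = effect_female, effect_male
    if f == 0.0 and m == 0.0:
        return "no_genotype_effect"
    if f == m:
        return "genotype_no_sex_effect"
    if m == 0.0:
        return "female_only"
    if f == 0.0:
        return "male_only"
    if np.sign(f) != np.sign(m):
        return "opposing_directions"
    return "female_greater" if abs(f) > abs(m) else "male_greater"


class ControlContext:
    """Batch dates and shared batch deviates for one generated centre."""

    def __init__(self, config: GeneratorConfig, rng: np.random.Generator):
        self.dates = [
            _EPOCH + pd.Timedelta(days=config.batch_spacing_days * b)
            for b in range(config.n_batches)
        ]
        self.deviates = rng.normal(0.0, config.batch_sd * config.residual_sd, config.n_batches)


def _empty_obs(n: int) -> pd.DataFrame:
    return pd.DataFrame({c: [None] * n for c in COLUMNS})


def _continuous_value(
    cfg: GeneratorConfig, rng: np.random.Generator, sex_male: np.ndarray,
    weight: np.ndarray, batch_dev: np.ndarray, geno_eff: np.ndarray,
) -> np.ndarray:
    return (
        cfg.trait_mean
        + cfg.sex_effect * sex_male
        + cfg.weight_slope * weight
        + batch_dev
        + geno_eff
        + rng.normal(0.0, cfg.residual_sd, len(sex_male))
    )


def _rows(
    cfg: GeneratorConfig, ids: list[str], sexes: np.ndarray, genotype: str, colony: str,
    zygosity: str, batch_ids: np.ndarray, ctx: ControlContext, values=None, categories=None,
    weights=None,
) -> pd.DataFrame:
    n = len(ids)
    df = _empty_obs(n)
    df["animal_id"] = ids
    df["sex"] = np.where(sexes == 1, "male", "female")
    df["genotype_class"] = genotype
    df["zygosity"] = zygosity
    df["colony_id"] = colony
    df["centre"] = cfg.centre
    df["genetic_background"] = cfg.genetic_background
    df["pipeline"] = cfg.pipeline
    df["procedure"] = cfg.procedure
    df["parameter"] = cfg.parameter
    df["metadata_group"] = cfg.metadata_group
    df["batch_label"] = [ctx.dates[b] for b in batch_ids]
    if values is not None:
        df["trait_kind"] = "continuous"
        df["value"] = values
        df["category"] = ""
        df["body_weight"] = weights
        df["weight_offset_days"] = 0
    else:
        df["trait_kind"] = "categorical"
        df["value"] = np.nan
        df["category"] = categories
        df["body_weight"] = weights if weights is not None else np.nan
        df["weight_offset_days"] = 0 if weights is not None else np.nan
    return df


def generate_controls(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, TruthRecord, ControlContext]:
    """Generate batch-structured wildtype observations for one trait.

    Returns the observation table, the truth record (no genotype effect)
    and the :class:`ControlContext` whose batch deviates must be shared
    with any knockout line phenotyped in the same batches.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_ctx, rng_obs = (np.random.default_rng(s) for s in ss.spawn(2))
    ctx = ControlContext(config, rng_ctx)
    per = config.controls_per_batch_per_sex
    n = config.n_batches * per * 2
    batch_ids = np.repeat(np.arange(config.n_batches), per * 2)
    sexes = np.tile(np.r_[np.zeros(per), np.ones(per)], config.n_batches).astype(int)
    weights = np.where(
        sexes == 1,
        rng_obs.normal(config.weight_mean_male, config.weight_sd, n),
        rng_obs.normal(config.weight_mean_female, config.weight_sd, n),
    )
    values = _continuous_value(
        config, rng_obs, sexes, weights, ctx.deviates[batch_ids], np.zeros(n)
    )
    ids = [f"wt_{config.centre}_{config.parameter}_{i}" for i in range(n)]
    obs = _rows(config, ids, sexes, "control", "", "wildtype", batch_ids, ctx,
                values=values, weights=weights)
    truth = TruthRecord(config.parameter, None, config.sex_effect, 0.0, 0.0, "no_genotype_effect")
    return validate_observations(obs), truth, ctx


def _workflow_batches(
    workflow: str, n_per_sex: int, n_batches: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Batch assignment (female, male) realizing a requested workflow class."""
    if workflow == "one_batch":
        b = int(rng.integers(n_batches))
        return np.full(n_per_sex, b), np.full(n_per_sex, b)
    if workflow == "low_batch":
        if n_batches < 2:
            raise ValueError("low_batch needs >= 2 batches available")
        b1, b2 = rng.choice(n_batches, size=2, replace=False)
        return np.full(n_per_sex, b1), np.full(n_per_sex, b2)
    if workflow == "multi_batch":
        if n_per_sex < 3 or n_batches < 5:
            raise ValueError("multi_batch unrealizable with this cohort/batch count")
        # batches are calendar dates, so the number of collection dates grows
        # with cohort size (roughly five animals per sex per date); the
        # canonical 7/sex cohort keeps the minimal 3 + 2 disjoint pattern
        k = int(np.ceil(n_per_sex / 5))
        if k <= 3:
            chosen = rng.choice(n_batches, size=5, replace=False)
            f = rng.choice(chosen[:3], size=n_per_sex)
            f[:3] = chosen[:3]  # guarantee three distinct female batches
            m = rng.choice(chosen[3:], size=n_per_sex)
            m[:2] = chosen[3:]  # and two distinct male batches
            return f, m
        k_f = k_m = min(k, n_batches)
        f_b = rng.choice(n_batches, size=k_f, replace=False)
        m_b = rng.choice(n_batches, size=k_m, replace=False)
        # round-robin so every chosen date actually receives animals
        f = f_b[np.arange(n_per_sex) % k_f]
        m = m_b[np.arange(n_per_sex) % k_m]
        return f, m
    if workflow == "random":
        return rng.integers(n_batches, size=n_per_sex), rng.integers(n_batches, size=n_per_sex)
    raise ValueError(f"unknown workflow {workflow!r}")


def generate_mutant_line(
    config: GeneratorConfig,
    workflow: str = "multi_batch",
    context: ControlContext | None = None,
    colony_id: str = "colony_1",
    seed_offset: int = 1,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate one knockout cohort on top of the control model.

    The cohort is placed into batches realizing the requested workflow
    class and the per-sex genotype effects are added to the control signal.
    Pass the ``context`` returned by :func:`generate_controls` so mutants
    share batch deviates with controls measured on the same date.
    """
    ss = np.random.SeedSequence(config.seed)
    spawned = ss.spawn(2 + seed_offset)
    rng = np.random.default_rng(spawned[1 + seed_offset])
    if context is None:
        context = ControlContext(config, np.random.default_rng(spawned[0]))
    n = config.ko_cohort_per_sex
    fb, mb = _workflow_batches(workflow, n, config.n_batches, rng)
    batch_ids = np.concatenate([fb, mb])
    sexes = np.r_[np.zeros(n), np.ones(n)].astype(int)
    weights = np.where(
        sexes == 1,
        rng.normal(config.weight_mean_male, config.weight_sd, 2 * n),
        rng.normal(config.weight_mean_female, config.weight_sd, 2 * n),
    )
    eff_f, eff_m = config.genotype_effect
    geno_eff = np.where(sexes == 1, eff_m, eff_f)
    values = _continuous_value(config, rng, sexes, weights, context.deviates[batch_ids], geno_eff)
    ids = [f"ko_{colony_id}_{config.parameter}_{i}" for i in range(2 * n)]
    obs = _rows(config, ids, sexes, "mutant", colony_id, "homozygote", batch_ids, context,
                values=values, weights=weights)
    truth = TruthRecord(
        config.parameter, colony_id, config.sex_effect, eff_f, eff_m,
        true_sd_category(eff_f, eff_m),
    )
    return validate_observations(obs), truth


def generate_categorical_line(
    config: GeneratorConfig,
    colony_id: str = "colony_1",
    n_controls_per_sex: int | None = None,
    seed_offset: int = 1,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a categorical knockout line plus its matched controls.

    Per-animal Bernoulli abnormality draws at the configured sex x
    genotype rates; the truth category compares the knockout rates of the
    two sexes relative to the control rates.
    """
    ss = np.random.SeedSequence(config.seed)
    spawned = ss.spawn(2 + seed_offset)
    rng = np.random.default_rng(spawned[1 + seed_offset])
    ctx = ControlContext(config, np.random.default_rng(spawned[0]))
    n_ctrl = (
        n_controls_per_sex
        if n_controls_per_sex is not None
        else config.n_batches * config.controls_per_batch_per_sex
    )
    rows = []
    for genotype, n_per_sex, colony, zyg, prefix in (
        ("control", n_ctrl, "", "wildtype", "wt"),
        ("mutant", config.ko_cohort_per_sex, colony_id, "homozygote", "ko"),
    ):
        sexes = np.r_[np.zeros(n_per_sex), np.ones(n_per_sex)].astype(int)
        rates = np.where(
            sexes == 1,
            config.categorical_rates[("male", genotype)],
            config.categorical_rates[("female", genotype)],
        )
        abn = rng.random(2 * n_per_sex) < rates
        batch_ids = rng.integers(config.n_batches, size=2 * n_per_sex)
        ids = [f"{prefix}_{colony_id}_{config.parameter}_{i}" for i in range(2 * n_per_sex)]
        rows.append(
            _rows(config, ids, sexes, genotype, colony, zyg, batch_ids, ctx,
                  categories=np.where(abn, "not_as_expected", "as_expected"))
        )
    obs = pd.concat(rows, ignore_index=True)
    # the pipeline tests one-sided toward higher knockout abnormality, so the
    # truth effect is the abnormality-rate increase floored at zero
    pf = max(0.0, config.categorical_rates[("female", "mutant")]
             - config.categorical_rates[("female", "control")])
    pm = max(0.0, config.categorical_rates[("male", "mutant")]
             - config.categorical_rates[("male", "control")])
    truth = TruthRecord(
        config.parameter, colony_id, 0.0, pf, pm, true_sd_category(pf, pm)
    )
    return validate_observations(obs), truth
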