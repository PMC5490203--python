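"""Sex as a modifier of the knockout (genotype) effect.

Two-stage pipelines: stage 1 asks whether genotype affects the trait at
all; stage 2, only among stage-1 hits, asks whether sex modifies that
effect. Discrete-data stages are preceded by minimal-attainable-p
("alpha star") filters so data sets that could never reach significance
do not inflate the multiplicity burden. Stage-2 hits are classified into
a taxonomy of sex-modified effects (one sex only, one sex greater,
opposing directions, cannot classify) from per-sex standardized genotype
estimates and their intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AssembledDataset, classify_workflow
from .lmm import mixed_lr, mixed_model_fit, mixed_lr_test
from .stats import (
    Interval,
    StratumTable,
    TestOutcome,
    cmh_midp_onesided,
    firth_lr_test,
    lrko_alpha_star,
    mh_alpha_star,
    multiplicity_adjust,
    newcombe_diff_ci,
    standardize_effect,
)

__all__ = [
    "StageResult",
    "run_categorical_pipeline",
    "run_continuous_pipeline",
    "classify_sd_continuous",
    "summarize_by_gene",
    "summarize_by_screen",
    "stage_results_frame",
    "SD_LABELS",
]

#: labels that are only reachable when the stage-2 interaction is significant
SD_LABELS = (
    "female_only",
    "male_only",
    "female_greater",
    "male_greater",
    "opposing_directions",
    "cannot_classify",
)

Z95 = 1.959963984540054


@dataclass
class StageResult:
    key: tuple
    key_fields: tuple
    trait_kind: str
    procedure: str = ""
    colony_id: str = ""
    workflow: str | None = None
    filter_alpha_star: float | None = None
    stage1: TestOutcome | None = None
    stage1_adjusted_p: float = float("nan")
    stage1_pass: bool = False
    lrko_filter: float | None = None
    stage2: TestOutcome | None = None
    stage2_adjusted_p: float = float("nan")
    stage2_pass: bool = False
    classification: str | None = None
    #: per-sex standardized genotype effect with 95% Wald interval (continuous)
    female_effect: Interval | None = None
    male_effect: Interval | None = None
    #: per-sex knockout abnormality proportions (categorical)
    female_abnormality: float | None = None
    male_abnormality: float | None = None
    abnormality_diff: Interval | None = None
    flags: list[str] = field(default_factory=list)


def _ko_counts(d: pd.DataFrame) -> dict:
    ko = d[d["genotype_class"] == "mutant"]
    ctrl = d[d["genotype_class"] == "control"]
    out = {}
    for sex in ("female", "male"):
        ks = ko[ko["sex"] == sex]
        cs = ctrl[ctrl["sex"] == sex]
        out[sex] = {
            "ko_n": len(ks),
            "ko_abn": int((ks["category"] == "not_as_expected").sum()),
            "ctrl_n": len(cs),
            "ctrl_abn": int((cs["category"] == "not_as_expected").sum()),
        }
    return out


def run_categorical_pipeline(
    datasets: list[AssembledDataset],
    fdr_stage1: float = 0.05,
    fdr_stage2: float = 0.20,
    fdr_method: str = "hochberg_stepup",
    alpha_star_threshold: float = 0.05,
) -> list[StageResult]:
    """Two-stage categorical pipeline with attainability filters.

    (i) Mantel–Haenszel alpha star filters out data sets whose margins
    cannot reach ``alpha_star_threshold``; (ii) the one-sided CMH mid-p
    (sex-stratified, knockout-vs-control abnormality) is adjusted at
    ``fdr_stage1`` over the retained family; (iii) stage-1 hits pass
    through the LR-KO alpha-star filter, then the knockout-only penalized
    LR test of sex is adjusted at ``fdr_stage2``; (iv) stage-2 hits are
    classed female/male greater by the per-sex knockout abnormality rates.
    """
    results: list[StageResult] = []
    for ds in datasets:
        if ds.trait_kind != "categorical":
            raise ValueError("categorical pipeline fed a non-categorical data set")
        if ds.colony_id in (None, ""):
            raise ValueError("categorical pipeline requires mutant data sets")
        c = _ko_counts(ds.data)
        margins = [
            (c[s]["ctrl_n"], c[s]["ko_n"], c[s]["ctrl_abn"] + c[s]["ko_abn"])
            for s in ("female", "male")
        ]
        r = StageResult(
            key=ds.key,
            key_fields=ds.key_fields,
            trait_kind="categorical",
            procedure=str(ds.data["procedure"].iloc[0]),
            colony_id=ds.colony_id or "",
            filter_alpha_star=mh_alpha_star(margins),
            female_abnormality=c["female"]["ko_abn"] / c["female"]["ko_n"],
            male_abnormality=c["male"]["ko_abn"] / c["male"]["ko_n"],
        )
        if r.filter_alpha_star < alpha_star_threshold:
            strata = [
                StratumTable(s, (c[s]["ctrl_abn"], c[s]["ctrl_n"]), (c[s]["ko_abn"], c[s]["ko_n"]))
                for s in ("female", "male")
            ]
            r.stage1 = cmh_midp_onesided(strata, direction="mutant_higher")
        results.append(r)

    tested = [r for r in results if r.stage1 is not None]
    adj, flags = multiplicity_adjust([r.stage1.p_value for r in tested], fdr_method, fdr_stage1)
    for r, a, s in zip(tested, adj, flags):
        r.stage1_adjusted_p, r.stage1_pass = float(a), bool(s)

    stage2_candidates = []
    for r in (r for r in tested if r.stage1_pass):
        c = _ko_counts(_data_by_key(datasets, r.key))
        nf, nm = c["female"]["ko_n"], c["male"]["ko_n"]
        xf, xm = c["female"]["ko_abn"], c["male"]["ko_abn"]
        r.lrko_filter = lrko_alpha_star(xf + xm, nf, nm)
        r.abnormality_diff = newcombe_diff_ci(xf, nf, xm, nm)
        if r.lrko_filter < alpha_star_threshold:
            X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
            y = np.array([1.0, 1.0, 0.0, 0.0])
            w = np.array([xf, xm, nf - xf, nm - xm], dtype=float)
            keep = w > 0
            r.stage2 = firth_lr_test(y[keep], X[keep], X[keep][:, :1], sample_weight=w[keep])
            stage2_candidates.append(r)
        else:
            r.classification = "genotype_no_sex_effect"

    adj, flags = multiplicity_adjust(
        [r.stage2.p_value for r in stage2_candidates], fdr_method, fdr_stage2
    )
    for r, a, s in zip(stage2_candidates, adj, flags):
        r.stage2_adjusted_p, r.stage2_pass = float(a), bool(s)
        if not s:
            r.classification = "genotype_no_sex_effect"
        else:
            r.classification = (
                "female_greater" if r.female_abnormality > r.male_abnormality else "male_greater"
            )
    return results


def _data_by_key(datasets: list[AssembledDataset], key: tuple) -> pd.DataFrame:
    for ds in datasets:
        if ds.key == key:
            return ds.data
    raise KeyError(key)


def _prepare_continuous(d: pd.DataFrame) -> pd.DataFrame:
    d = d.copy()
    d["sex_male"] = (d["sex"] == "male").astype(float)
    d["genotype"] = (d["genotype_class"] == "mutant").astype(float)
    d["genotype_x_sex"] = d["genotype"] * d["sex_male"]
    d["genotype_female"] = d["genotype"] * (1.0 - d["sex_male"])
    d["genotype_male"] = d["genotype_x_sex"]
    return d


def run_continuous_pipeline(
    datasets: list[AssembledDataset],
    fdr_stage1: float = 0.05,
    fdr_stage2: float = 0.05,
    fdr_method: str = "hochberg_stepup",
    workflow_filter: str = "all",
) -> list[StageResult]:
    """Two-stage continuous pipeline with per-sex effect classification.

    Stage 1 LR-tests all genotype terms: trait ~ genotype + sex +
    genotype:sex + weight + (1|batch) against the model without genotype
    terms. Stage 2, among adjusted stage-1 hits, LR-tests the interaction
    alone. A final reparametrized model with genotype nested within sex
    yields directly interpretable per-sex genotype estimates, standardized
    by the average wildtype signal, from which stage-2 hits are classified.
    """
    if workflow_filter not in ("all", "multi_batch"):
        raise ValueError(f"unknown workflow filter {workflow_filter!r}")
    results: list[StageResult] = []
    frames: dict[tuple, pd.DataFrame] = {}
    for ds in datasets:
        if ds.trait_kind != "continuous":
            raise ValueError("continuous pipeline fed a non-continuous data set")
        if ds.data["body_weight"].isna().any():
            raise ValueError("continuous mutant pipeline requires a weight on every animal")
        wf = classify_workflow(ds)
        r = StageResult(
            key=ds.key,
            key_fields=ds.key_fields,
            trait_kind="continuous",
            procedure=str(ds.data["procedure"].iloc[0]),
            colony_id=ds.colony_id or "",
            workflow=wf,
        )
        if workflow_filter == "multi_batch" and wf != "multi_batch":
            r.flags.append("excluded_by_workflow_filter")
            results.append(r)
            continue
        d = _prepare_continuous(ds.data)
        frames[ds.key] = d
        full_terms = ["genotype", "sex_male", "genotype_x_sex", "body_weight"]
        outcome, full, _ = mixed_lr(
            d, "value", full_terms, ["sex_male", "body_weight"], residual_group="genotype_class"
        )
        r.stage1 = outcome
        r._structure = full.residual_structure  # reuse for stage 2 / final model
        results.append(r)

    tested = [r for r in results if r.stage1 is not None]
    adj, flags = multiplicity_adjust([r.stage1.p_value for r in tested], fdr_method, fdr_stage1)
    for r, a, s in zip(tested, adj, flags):
        r.stage1_adjusted_p, r.stage1_pass = float(a), bool(s)

    stage2_candidates = [r for r in tested if r.stage1_pass]
    for r in stage2_candidates:
        d = frames[r.key]
        structure = (r._structure,)
        full = mixed_model_fit(
            d, "value", ["genotype", "sex_male", "genotype_x_sex", "body_weight"],
            residual_group="genotype_class", candidates=structure,
        )
        null = mixed_model_fit(
            d, "value", ["genotype", "sex_male", "body_weight"],
            residual_group="genotype_class", candidates=structure,
        )
        r.stage2 = mixed_lr_test(full, null)

    adj, flags = multiplicity_adjust(
        [r.stage2.p_value for r in stage2_candidates], fdr_method, fdr_stage2
    )
    for r, a, s in zip(stage2_candidates, adj, flags):
        r.stage2_adjusted_p, r.stage2_pass = float(a), bool(s)
        d = frames[r.key]
        try:
            final = mixed_model_fit(
                d, "value", ["sex_male", "body_weight", "genotype_female", "genotype_male"],
                residual_group="genotype_class", candidates=(r._structure,),
            )
        except (ValueError, np.linalg.LinAlgError):
            final = None
        if final is None or not final.converged:
            r.flags.append("final_model_not_converged")
            r.classification = "cannot_classify" if s else "genotype_no_sex_effect"
            continue
        wt = d[d["genotype_class"] == "control"]
        wt_means = wt.groupby("sex")["value"].mean()
        try:
            per_sex = {}
            for sex, term in (("female", "genotype_female"), ("male", "genotype_male")):
                est, se = standardize_effect(
                    final.estimates[term],
                    final.standard_errors[term],
                    float(wt_means.get("female", np.nan)),
                    float(wt_means.get("male", np.nan)),
                )
                per_sex[sex] = Interval(point=est, lower=est - Z95 * se, upper=est + Z95 * se)
        except ValueError:
            r.flags.append("standardization_refused")
            r.classification = "cannot_classify" if s else "genotype_no_sex_effect"
            continue
        r.female_effect, r.male_effect = per_sex["female"], per_sex["male"]
        r.classification = classify_sd_continuous(r.female_effect, r.male_effect, s)
    return results


def classify_sd_continuous(
    female: Interval, male: Interval, stage2_significant: bool
) -> str:
    """Classify a sex-modified genotype effect from per-sex intervals.

    Without a significant interaction the call is genotype-with-no-sex-
    effect. Otherwise: one interval excluding zero -> that sex only; both
    excluding zero with opposite signs -> opposing directions; same sign
    -> whichever standardized magnitude is larger; neither -> the model
    cannot localize the interaction ("cannot classify").
    """
    if female is None or male is None:
        raise ValueError("per-sex intervals required for classification")
    if not stage2_significant:
        return "genotype_no_sex_effect"
    f_sig, m_sig = female.excludes_zero(), male.excludes_zero()
    if f_sig and not m_sig:
        return "female_only"
    if m_sig and not f_sig:
        return "male_only"
    if f_sig and m_sig:
        if np.sign(female.point) != np.sign(male.point):
            return "opposing_directions"
        return "female_greater" if abs(female.point) > abs(male.point) else "male_greater"
    return "cannot_classify"


def summarize_by_gene(results: list[StageResult], grouping: str = "colony_id") -> pd.DataFrame:
    """Per knockout line: genotype hits, SD calls and effect magnitudes.

    The effect magnitude of an SD call is the larger absolute per-sex
    standardized estimate. Lines with no genotype hit are excluded from
    the SD-fraction ranking.
    """
    df = stage_results_frame(results)
    rows = []
    for colony, g in df.groupby(grouping):
        n_hits = int(g["stage1_pass"].sum())
        if n_hits == 0:
            continue
        sd = g[g["stage2_pass"]]
        mags = np.nanmax(
            np.abs(sd[["female_effect", "male_effect"]].to_numpy(dtype=float)), axis=1
        ) if len(sd) else np.array([])
        mags = mags[~np.isnan(mags)]
        rows.append(
            {
                grouping: colony,
                "n_genotype_hits": n_hits,
                "n_sd": len(sd),
                "sd_fraction": len(sd) / n_hits,
                "mean_effect_magnitude": float(np.mean(mags)) if len(mags) else float("nan"),
                "sd_effect_magnitude": float(np.std(mags, ddof=1)) if len(mags) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[grouping, "n_genotype_hits", "n_sd", "sd_fraction",
                 "mean_effect_magnitude", "sd_effect_magnitude"],
    ).sort_values("sd_fraction", ascending=False, ignore_index=True) if rows else pd.DataFrame(
        columns=[grouping, "n_genotype_hits", "n_sd", "sd_fraction",
                 "mean_effect_magnitude", "sd_effect_magnitude"]
    )


def summarize_by_screen(results: list[StageResult], min_hits: int = 35) -> pd.DataFrame:
    """Per procedure SD hit rate among genotype-significant calls.

    Procedures with fewer than ``min_hits`` genotype-significant data sets
    are excluded (hit-rate estimates would be too noisy to compare).
    """
    df = stage_results_frame(results)
    rows = []
    for proc, g in df.groupby("procedure"):
        n_hits = int(g["stage1_pass"].sum())
        if n_hits < min_hits:
            continue
        n_sd = int(g["stage2_pass"].sum())
        rows.append(
            {"procedure": proc, "n_genotype_hits": n_hits, "n_sd": n_sd,
             "sd_hit_rate_percent": 100.0 * n_sd / n_hits}
        )
    return pd.DataFrame(rows, columns=["procedure", "n_genotype_hits", "n_sd", "sd_hit_rate_percent"])


def stage_results_frame(results: list[StageResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = dict(zip(r.key_fields, r.key))
        row.update(
            trait_kind=r.trait_kind,
            procedure=r.procedure,
            colony_id=r.colony_id,
            workflow=r.workflow,
            filter_alpha_star=r.filter_alpha_star,
            stage1_p=r.stage1.p_value if r.stage1 else float("nan"),
            stage1_adjusted_p=r.stage1_adjusted_p,
            stage1_pass=r.stage1_pass,
            lrko_filter=r.lrko_filter,
            stage2_p=r.stage2.p_value if r.stage2 else float("nan"),
            stage2_adjusted_p=r.stage2_adjusted_p,
            stage2_pass=r.stage2_pass,
            classification=r.classification,
            female_effect=r.female_effect.point if r.female_effect else float("nan"),
            female_lower=r.female_effect.lower if r.female_effect else float("nan"),
            female_upper=r.female_effect.upper if r.female_effect else float("nan"),
            male_effect=r.male_effect.point if r.male_effect else float("nan"),
            male_lower=r.male_effect.lower if r.male_effect else float("nan"),
            male_upper=r.male_effect.upper if r.male_effect else float("nan"),
            female_abnormality=r.female_abnormality,
            male_abnormality=r.male_abnormality,
            flags=";".join(r.flags),
        )
        rows.append(row)
    if not rows:
        return pd.DataFrame(
            columns=["centre", "genetic_background", "pipeline", "parameter",
                     "metadata_group", "colony_id", "trait_kind", "procedure",
                     "workflow", "filter_alpha_star", "stage1_p", "stage1_adjusted_p",
                     "stage1_pass", "lrko_filter", "stage2_p", "stage2_adjusted_p",
                     "stage2_pass", "classification", "female_effect", "female_lower",
                     "female_upper", "male_effect", "male_lower", "male_upper",
                     "female_abnormality", "male_abnormality", "flags"]
        )
    return pd.DataFrame(rows)
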