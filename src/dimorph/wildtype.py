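"""Sex as a biological variable in control (wildtype) data.

For each wildtype data set, tests whether sex explains variation in the
trait: a penalized-likelihood-ratio test of abnormality rates for
categorical traits, and a mixed-model LR test (with or without body
weight as a covariate) for continuous traits. Significance is decided
study-wide per analysis variant with step-up multiplicity control, and
reproducibility across centres is summarized by a direction-concordance
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AssembledDataset
from .lmm import mixed_lr
from .stats import (
    Interval,
    TestOutcome,
    firth_lr_test,
    multiplicity_adjust,
    newcombe_diff_ci,
)

__all__ = [
    "WildtypeSexResult",
    "analyze_wt_categorical",
    "analyze_wt_continuous",
    "summarize_prevalence",
    "cross_centre_concordance",
    "results_frame",
]

VARIANTS = ("categorical", "continuous_weight_adjusted", "continuous_absolute")


@dataclass
class WildtypeSexResult:
    key: tuple
    key_fields: tuple
    trait_kind: str
    analysis_variant: str
    raw_p: float
    effect_interval: Interval
    #: sign of the raw effect: which sex shows the larger value/abnormality rate
    effect_direction: str
    procedure: str = ""
    adjusted_p: float = float("nan")
    significant: bool = False
    #: set by summarize_prevalence; "none" unless significant
    direction: str = "none"
    n_female: int = 0
    n_male: int = 0

    @property
    def centre(self) -> str:
        return dict(zip(self.key_fields, self.key))["centre"]

    @property
    def parameter(self) -> str:
        return dict(zip(self.key_fields, self.key))["parameter"]


def _sex_counts(data: pd.DataFrame) -> tuple[int, int]:
    n = data.groupby("sex").size()
    return int(n.get("female", 0)), int(n.get("male", 0))


def analyze_wt_categorical(dataset: AssembledDataset) -> WildtypeSexResult:
    """Penalized LR test of sex on the abnormality rate of a control data set.

    Outcomes are recoded as-expected -> 0, not-as-expected -> 1 and the
    model Y ~ sex is compared with Y ~ 1. The biological effect is the
    difference in per-sex abnormality proportions (female minus male) with
    a Newcombe interval.
    """
    d = dataset.data
    abn = (d["category"] == "not_as_expected").astype(float)
    fem = d["sex"] == "female"
    nf, nm = int(fem.sum()), int((~fem).sum())
    if nf == 0 or nm == 0:
        raise ValueError("both sexes required (assembly violation)")
    xf, xm = int(abn[fem].sum()), int(abn[~fem].sum())
    if abn.nunique() <= 1:
        # degenerate: every animal in the same category
        outcome = TestOutcome(0.0, 1, 1.0, "two_sided", "br_logistic_lr")
    else:
        # weighted 2x2 fit: rows (sex, outcome) with frequency weights
        X_full = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        y = np.array([1.0, 1.0, 0.0, 0.0])
        w = np.array([xf, xm, nf - xf, nm - xm], dtype=float)
        keep = w > 0
        outcome = firth_lr_test(y[keep], X_full[keep], X_full[keep][:, :1], sample_weight=w[keep])
    ci = newcombe_diff_ci(xf, nf, xm, nm)
    direction = "female_greater" if ci.point > 0 else ("male_greater" if ci.point < 0 else "none")
    return WildtypeSexResult(
        key=dataset.key,
        key_fields=dataset.key_fields,
        trait_kind="categorical",
        analysis_variant="categorical",
        raw_p=outcome.p_value,
        effect_interval=ci,
        effect_direction=direction,
        procedure=str(d["procedure"].iloc[0]),
        n_female=nf,
        n_male=nm,
    )


def analyze_wt_continuous(dataset: AssembledDataset, variant: str = "weight_adjusted") -> WildtypeSexResult:
    """Mixed-model LR test of sex on a continuous control data set.

    weight_adjusted: trait ~ sex + weight + (1|batch) against
    trait ~ weight + (1|batch) — the role of sex after accounting for the
    dimorphic body size. absolute: trait ~ sex + (1|batch) against
    trait ~ (1|batch). Residual variance may be stratified by sex
    (AIC-selected).
    """
    if variant not in ("weight_adjusted", "absolute"):
        raise ValueError(f"unknown variant {variant!r}")
    d = dataset.data.copy()
    d["sex_male"] = (d["sex"] == "male").astype(float)
    if variant == "weight_adjusted":
        if d["body_weight"].isna().any():
            raise ValueError("weight_adjusted analysis requires a weight on every animal")
        full_terms, null_terms = ["sex_male", "body_weight"], ["body_weight"]
    else:
        full_terms, null_terms = ["sex_male"], []
    outcome, full, _ = mixed_lr(d, "value", full_terms, null_terms, residual_group="sex")
    est = full.estimates["sex_male"]
    se = full.standard_errors["sex_male"]
    ci = Interval(point=est, lower=est - 1.959963984540054 * se, upper=est + 1.959963984540054 * se)
    nf, nm = _sex_counts(d)
    return WildtypeSexResult(
        key=dataset.key,
        key_fields=dataset.key_fields,
        trait_kind="continuous",
        analysis_variant=f"continuous_{variant}",
        raw_p=outcome.p_value,
        effect_interval=ci,
        # the sex coefficient is the male minus female shift
        effect_direction="male_greater" if est > 0 else ("female_greater" if est < 0 else "none"),
        procedure=str(d["procedure"].iloc[0]),
        n_female=nf,
        n_male=nm,
    )


def summarize_prevalence(
    results: list[WildtypeSexResult],
    level: float = 0.05,
    method: str = "hochberg_stepup",
) -> dict:
    """Study-wide multiplicity adjustment and prevalence summary.

    Adjustment is applied once over all data sets of one analysis variant
    (never per centre). Mutates the results in place (adjusted_p,
    significant, direction) and returns overall / per-centre /
    per-procedure summary tables.
    """
    if not results:
        return {"overall": {"n": 0, "n_significant": 0, "percent_significant": float("nan")}}
    variants = {r.analysis_variant for r in results}
    if len(variants) > 1:
        raise ValueError(f"results mix analysis variants: {sorted(variants)}")
    adj, flags = multiplicity_adjust([r.raw_p for r in results], method=method, level=level)
    for r, a, s in zip(results, adj, flags):
        r.adjusted_p = float(a)
        r.significant = bool(s)
        r.direction = r.effect_direction if s else "none"
    df = results_frame(results)
    overall = {
        "n": len(df),
        "n_significant": int(df["significant"].sum()),
        "percent_significant": 100.0 * df["significant"].mean(),
    }

    def by(col: str) -> pd.DataFrame:
        g = df.groupby(col)["significant"]
        out = g.agg(n="size", n_significant="sum")
        out["percent_significant"] = 100.0 * out["n_significant"] / out["n"]
        dirs = df[df["significant"]].groupby([col, "direction"]).size().unstack(fill_value=0)
        return out.join(dirs, how="left").fillna(0)

    return {"overall": overall, "per_centre": by("centre"), "per_procedure": by("procedure")}


def cross_centre_concordance(results: list[WildtypeSexResult]) -> tuple[pd.DataFrame, float]:
    """Direction concordance of significant sex effects across centres.

    Restricted to parameters measured at three or more centres; a
    parameter is discordant iff at least two centres show significant
    effects of opposite direction. Mixed significant/non-significant calls
    are not discordant (sensitivity differs across centres). Returns the
    per-parameter table and the overall discordance percentage.
    """
    df = results_frame(results)
    rows = []
    for param, g in df.groupby("parameter"):
        n_centres = g["centre"].nunique()
        if n_centres < 3:
            continue
        dirs = set(g.loc[g["significant"], "direction"]) - {"none"}
        rows.append(
            {
                "parameter": param,
                "n_centres": n_centres,
                "n_significant": int(g["significant"].sum()),
                "discordant": dirs >= {"female_greater", "male_greater"},
            }
        )
    table = pd.DataFrame(rows, columns=["parameter", "n_centres", "n_significant", "discordant"])
    pct = 100.0 * table["discordant"].mean() if len(table) else float("nan")
    return table, float(pct)


def results_frame(results: list[WildtypeSexResult]) -> pd.DataFrame:
    """Flatten results into the stable tabular form used for TSV output."""
    rows = []
    for r in results:
        row = dict(zip(r.key_fields, r.key))
        row.update(
            trait_kind=r.trait_kind,
            analysis_variant=r.analysis_variant,
            procedure=r.procedure,
            n_female=r.n_female,
            n_male=r.n_male,
            raw_p=r.raw_p,
            adjusted_p=r.adjusted_p,
            significant=r.significant,
            direction=r.direction,
            effect=r.effect_interval.point,
            effect_lower=r.effect_interval.lower,
            effect_upper=r.effect_interval.upper,
        )
        rows.append(row)
    return pd.DataFrame(rows)
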