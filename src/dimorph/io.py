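"""Observation tables, data-set assembly and classification rules.

The unit of raw input is one animal x trait measurement ("observation")
carrying its full experimental provenance: phenotyping centre, genetic
background, pipeline/procedure/parameter identifiers, metadata group,
measurement batch (a calendar date), sex, genotype class and, where
available, a body weight measured within four days of the trait.

The unit of statistical analysis is an :class:`AssembledDataset`: all
observations of one trait in one centre/background/pipeline/metadata
context, either controls only (wildtype analyses) or one knockout colony
joined with its matched controls (mutant analyses).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "Dialect",
    "ValidationError",
    "read_observations",
    "validate_observations",
    "attach_weights",
    "AssembledDataset",
    "AssemblyLog",
    "assemble_wildtype_datasets",
    "assemble_mutant_datasets",
    "classify_workflow",
    "classify_viability",
    "write_observations",
    "write_results",
    "read_results",
]

#: Canonical observation-table columns, in stable order.
COLUMNS = [
    "animal_id",
    "sex",
    "genotype_class",
    "zygosity",
    "colony_id",
    "centre",
    "genetic_background",
    "pipeline",
    "procedure",
    "parameter",
    "metadata_group",
    "batch_label",
    "trait_kind",
    "value",
    "category",
    "body_weight",
    "weight_offset_days",
]

SEXES = ("female", "male")
GENOTYPE_CLASSES = ("control", "mutant")
ZYGOSITIES = ("wildtype", "heterozygote", "homozygote", "hemizygote")
TRAIT_KINDS = ("continuous", "categorical")
CATEGORIES = ("as_expected", "not_as_expected")

#: Key fields shared by all observations of a wildtype data set.
WILDTYPE_KEY = ["centre", "genetic_background", "pipeline", "parameter", "metadata_group"]
#: Mutant data sets additionally key on the knockout colony.
MUTANT_KEY = WILDTYPE_KEY + ["colony_id"]

MAX_WEIGHT_OFFSET_DAYS = 4


class ValidationError(ValueError):
    """Raised when an observation table violates the data model.

    Carries the full list of row-level problems so a caller can report
    every defective row at once instead of failing on the first.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} validation problem(s):\n" + "\n".join(self.problems)
        )


@dataclass(frozen=True)
class Dialect:
    """Column mapping from an input file's headers onto canonical names.

    ``columns`` maps canonical name -> header in the file; canonical
    names absent from the mapping are assumed to appear verbatim.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    sep: str = ","

    def rename_map(self) -> dict[str, str]:
        return {src: canon for canon, src in self.columns.items()}


def read_observations(path: str | Path, dialect: Dialect | None = None) -> pd.DataFrame:
    """Read and validate an observation table from CSV/TSV.

    Rows failing validation are reported collectively via
    :class:`ValidationError`, never silently dropped.
    """
    dialect = dialect or Dialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    df = df.rename(columns=dialect.rename_map())
    missing = [c for c in COLUMNS if c not in df.columns and c not in ("body_weight", "weight_offset_days")]
    if missing:
        raise ValidationError([f"missing mandatory column(s): {', '.join(missing)}"])
    for c in ("body_weight", "weight_offset_days"):
        if c not in df.columns:
            df[c] = ""
    df = df[COLUMNS].copy()
    for c in ("value", "body_weight", "weight_offset_days"):
        df[c] = pd.to_numeric(df[c].mask(df[c] == ""), errors="coerce")
    df["batch_label"] = pd.to_datetime(df["batch_label"], errors="coerce")
    validate_observations(df)
    return df


def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Check observation-table invariants; raise ValidationError listing rows."""
    problems: list[str] = []
    missing = [c for c in COLUMNS if c not in obs.columns]
    if missing:
        raise ValidationError([f"missing mandatory column(s): {', '.join(missing)}"])

    def bad(mask: pd.Series, reason: str) -> None:
        for idx in obs.index[np.asarray(mask, dtype=bool)]:
            problems.append(f"row {idx}: {reason}")

    bad(~obs["sex"].isin(SEXES), "sex must be 'female' or 'male'")
    bad(~obs["genotype_class"].isin(GENOTYPE_CLASSES), "genotype_class must be control/mutant")
    bad(~obs["trait_kind"].isin(TRAIT_KINDS), "trait_kind must be continuous/categorical")
    bad(obs["batch_label"].isna(), "batch_label must parse as a date")

    cont = obs["trait_kind"] == "continuous"
    value_num = pd.to_numeric(obs["value"], errors="coerce")
    bad(cont & value_num.isna(), "continuous observation lacks a numeric value")
    bad(cont & (obs["category"].astype(str).str.len() > 0), "continuous observation must not carry a category")
    cat = obs["trait_kind"] == "categorical"
    bad(cat & ~obs["category"].isin(CATEGORIES), "categorical observation needs category as_expected/not_as_expected")
    bad(cat & value_num.notna(), "categorical observation must not carry a value")

    ctrl = obs["genotype_class"] == "control"
    bad(ctrl & (obs["colony_id"].astype(str).str.len() > 0), "controls must have empty colony_id")
    bad((~ctrl) & (obs["colony_id"].astype(str).str.len() == 0), "mutants must carry a colony_id")

    has_w = pd.to_numeric(obs["body_weight"], errors="coerce").notna()
    off = pd.to_numeric(obs["weight_offset_days"], errors="coerce")
    bad(has_w & (off.abs() > MAX_WEIGHT_OFFSET_DAYS), f"weight offset exceeds +/-{MAX_WEIGHT_OFFSET_DAYS} days")

    if problems:
        raise ValidationError(problems)
    return obs


def attach_weights(obs: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Attach the nearest-in-time body weight to each observation.

    ``weights`` has columns (animal_id, date, grams). A weight is attached
    only when its measurement date is within +/-4 days of the observation's
    batch date; at an exact |offset| tie the earlier date wins. Duplicate
    (animal_id, date) entries with conflicting grams are a data error.
    """
    w = weights.copy()
    w["date"] = pd.to_datetime(w["date"])
    dup = w.groupby(["animal_id", "date"])["grams"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        raise ValidationError(
            [f"conflicting weights for {a} on {d:%Y-%m-%d}" for a, d in conflicts.index]
        )
    w = w.drop_duplicates(["animal_id", "date"])
    out = obs.copy()
    out["body_weight"] = np.nan
    out["weight_offset_days"] = np.nan
    by_animal = {a: g for a, g in w.groupby("animal_id")}
    batch = pd.to_datetime(out["batch_label"])
    for i in out.index:
        g = by_animal.get(out.at[i, "animal_id"])
        if g is None:
            continue
        offs = (g["date"] - batch[i]).dt.days
        ok = offs.abs() <= MAX_WEIGHT_OFFSET_DAYS
        if not ok.any():
            continue
        cand = g[ok].assign(_off=offs[ok])
        # nearest in time; tie on |offset| -> earlier date
        cand = cand.sort_values(["_off"], key=lambda s: s.abs() * 10 + (s > 0).astype(int))
        best = cand.iloc[0]
        out.at[i, "body_weight"] = best["grams"]
        out.at[i, "weight_offset_days"] = int(best["_off"])
    return out


@dataclass
class AssembledDataset:
    """One trait/context data set: the unit of statistical analysis."""

    key: tuple
    trait_kind: str
    data: pd.DataFrame
    key_fields: tuple = tuple(WILDTYPE_KEY)

    @property
    def colony_id(self) -> str | None:
        return dict(zip(self.key_fields, self.key)).get("colony_id")

    def counts(self) -> pd.Series:
        """Observation counts per sex x genotype_class."""
        return self.data.groupby(["sex", "genotype_class"], observed=True).size()

    def batches(self, genotype_class: str | None = None) -> pd.Series:
        d = self.data
        if genotype_class is not None:
            d = d[d["genotype_class"] == genotype_class]
        return d.groupby("sex")["batch_label"].nunique()

    def mutants(self) -> pd.DataFrame:
        return self.data[self.data["genotype_class"] == "mutant"]

    def controls(self) -> pd.DataFrame:
        return self.data[self.data["genotype_class"] == "control"]

    def label(self) -> str:
        return "/".join("-" if v in (None, "") else str(v) for v in self.key)


@dataclass
class AssemblyLog:
    """Record of retained and excluded candidate keys with reasons."""

    retained: list[tuple] = field(default_factory=list)
    excluded: list[tuple[tuple, str]] = field(default_factory=list)

    def summary(self) -> dict:
        reasons: dict[str, int] = {}
        for _, reason in self.excluded:
            reasons[reason] = reasons.get(reason, 0) + 1
        return {
            "retained": len(self.retained),
            "excluded": len(self.excluded),
            "excluded_by_reason": reasons,
        }


def assemble_wildtype_datasets(
    obs: pd.DataFrame,
    trait_kind: str,
    min_per_sex: int = 100,
    log: AssemblyLog | None = None,
) -> list[AssembledDataset]:
    """Group control observations into wildtype data sets.

    A candidate key is retained only if both sexes are present with
    strictly more than ``min_per_sex`` observations each.
    """
    log = log if log is not None else AssemblyLog()
    ctrl = obs[(obs["genotype_class"] == "control") & (obs["trait_kind"] == trait_kind)]
    out: list[AssembledDataset] = []
    for key, g in ctrl.groupby(WILDTYPE_KEY, sort=True):
        n = g.groupby("sex").size().reindex(SEXES, fill_value=0)
        if (n <= min_per_sex).any():
            log.excluded.append((key, f"fewer than {min_per_sex + 1} observations in at least one sex"))
            continue
        log.retained.append(key)
        out.append(AssembledDataset(key=key, trait_kind=trait_kind, data=g.copy(),
                                    key_fields=tuple(WILDTYPE_KEY)))
    return out


def assemble_mutant_datasets(
    obs: pd.DataFrame,
    trait_kind: str,
    min_mutants_per_sex: int = 5,
    log: AssemblyLog | None = None,
) -> list[AssembledDataset]:
    """Join each knockout colony with its matched controls.

    Retention requires both sexes present with strictly more than
    ``min_mutants_per_sex`` mutant readings each, matched controls from the
    same centre/background/pipeline/metadata context, and — for continuous
    traits — body weight on every analysed animal (animals lacking weight
    are dropped with a logged count before the count rule is applied).
    """
    log = log if log is not None else AssemblyLog()
    sub = obs[obs["trait_kind"] == trait_kind]
    mut = sub[sub["genotype_class"] == "mutant"]
    ctrl = sub[sub["genotype_class"] == "control"]
    ctrl_groups = {key: g for key, g in ctrl.groupby(WILDTYPE_KEY, sort=True)}
    out: list[AssembledDataset] = []
    for key, g in mut.groupby(MUTANT_KEY, sort=True):
        ctx = key[: len(WILDTYPE_KEY)]
        matched = ctrl_groups.get(ctx)
        if matched is None or not len(matched):
            log.excluded.append((key, "no matched controls in the same context"))
            continue
        if trait_kind == "continuous":
            n_dropped = int(g["body_weight"].isna().sum()) + int(matched["body_weight"].isna().sum())
            g = g[g["body_weight"].notna()]
            matched = matched[matched["body_weight"].notna()]
            if n_dropped:
                log.excluded.append((key, f"dropped {n_dropped} weightless animal(s) (kept data set)"))
            if not len(matched):
                log.excluded.append((key, "no weighted controls available"))
                continue
        n = g.groupby("sex").size().reindex(SEXES, fill_value=0)
        if (n <= min_mutants_per_sex).any():
            log.excluded.append((key, f"fewer than {min_mutants_per_sex + 1} mutant readings in at least one sex"))
            continue
        data = pd.concat([g, matched], ignore_index=True)
        log.retained.append(key)
        out.append(AssembledDataset(key=key, trait_kind=trait_kind, data=data,
                                    key_fields=tuple(MUTANT_KEY)))
    return out


def classify_workflow(dataset: AssembledDataset) -> str:
    """Classify how a knockout cohort was spread over measurement batches.

    multi_batch: >= 4 distinct mutant batches overall with >= 3 batches in
    one sex and >= 2 in the other. one_batch: all mutants share one batch.
    Everything else is low_batch. Multi-batch designs decouple genotype
    from batch and give the best type-I-error control.
    """
    mut = dataset.mutants()
    if not len(mut):
        raise ValueError("workflow classification requires a mutant data set")
    n_total = mut["batch_label"].nunique()
    per_sex = mut.groupby("sex")["batch_label"].nunique().reindex(SEXES, fill_value=0)
    if n_total == 1:
        return "one_batch"
    hi, lo = per_sex.max(), per_sex.min()
    if n_total >= 4 and hi >= 3 and lo >= 2:
        return "multi_batch"
    return "low_batch"


def classify_viability(n_homozygote: int, n_offspring: int) -> str:
    """Breeding-outcome viability call for a knockout line.

    non_viable: no homozygotes among >= 28 offspring of het intercrosses;
    subviable: homozygote fraction < 13%; otherwise viable.
    """
    if n_offspring < 1 or n_homozygote < 0 or n_homozygote > n_offspring:
        raise ValueError("counts must satisfy 0 <= n_homozygote <= n_offspring, n_offspring >= 1")
    if n_homozygote == 0 and n_offspring >= 28:
        return "non_viable"
    if n_homozygote / n_offspring < 0.13:
        return "subviable"
    return "viable"


def write_observations(obs: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    out = obs.copy()
    out["batch_label"] = pd.to_datetime(out["batch_label"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as TSV with full float precision.

    Floats are serialized with 17 significant digits so that p-values
    round-trip bit-stably and downstream rankings are reproducible.
    """
    results.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so serialized p-values come back bit-identical
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_run_summary(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=str) + "\n")
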