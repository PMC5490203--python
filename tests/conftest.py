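"""Shared fixtures: tiny observation tables built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dimorph.io import COLUMNS, AssembledDataset, MUTANT_KEY, WILDTYPE_KEY


def make_obs(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical observation frame from sparse row dicts."""
    defaults = {
        "animal_id": "",
        "sex": "female",
        "genotype_class": "control",
        "zygosity": "wildtype",
        "colony_id": "",
        "centre": "A",
        "genetic_background": "B6N",
        "pipeline": "pipe",
        "procedure": "proc",
        "parameter": "trait",
        "metadata_group": "mg",
        "batch_label": "2014-01-06",
        "trait_kind": "continuous",
        "value": np.nan,
        "category": "",
        "body_weight": np.nan,
        "weight_offset_days": np.nan,
    }
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults, **r)
        if not d["animal_id"]:
            d["animal_id"] = f"a{i}"
        full.append(d)
    df = pd.DataFrame(full, columns=COLUMNS)
    df["batch_label"] = pd.to_datetime(df["batch_label"])
    return df


def categorical_counts_obs(
    ctrl: dict[str, tuple[int, int]],
    ko: dict[str, tuple[int, int]],
    colony: str = "col1",
) -> pd.DataFrame:
    """Observation table from (n_abnormal, n_total) per sex for each group."""
    rows = []
    for sex, (x, n) in ctrl.items():
        for i in range(n):
            rows.append({"sex": sex, "trait_kind": "categorical",
                         "category": "not_as_expected" if i < x else "as_expected"})
    for sex, (x, n) in ko.items():
        for i in range(n):
            rows.append({"sex": sex, "trait_kind": "categorical", "genotype_class": "mutant",
                         "colony_id": colony, "zygosity": "homozygote",
                         "category": "not_as_expected" if i < x else "as_expected"})
    return make_obs(rows)


def categorical_dataset(ctrl, ko, colony: str = "col1") -> AssembledDataset:
    obs = categorical_counts_obs(ctrl, ko, colony)
    key = ("A", "B6N", "pipe", "trait", "mg", colony)
    return AssembledDataset(key=key, trait_kind="categorical", data=obs,
                            key_fields=tuple(MUTANT_KEY))


@pytest.fixture
def obs_factory():
    return make_obs


@pytest.fixture
def categorical_dataset_factory():
    return categorical_dataset
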