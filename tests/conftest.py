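"""Shared fixtures: small synthetic studies and toy tables built in-process."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from microtrace.data_io import OtuTable, preprocess_study
from microtrace.synthetic_household import GeneratorConfig, generate_study


def small_config(**overrides) -> GeneratorConfig:
    """A reduced study design that keeps every mechanism of the generator."""
    base = dict(
        n_residences=4,
        occupants_per_residence=[1, 1, 2, 2],
        n_seasons=3,
        skin_sites=["forehead", "palm", "forearm"],
        surface_sites=["desk", "tv", "sink"],
        air_sites=["bedroom"],
        n_controls=3,
        read_depth_range=(800, 1200),
        n_common_core_otus=25,
        n_core_otus_per_individual=4,
        n_shared_household_otus=5,
        n_transient_otus_per_season=8,
        n_identifying_otus_per_individual=3,
        n_environment_otus=40,
        n_contaminant_otus=5,
        rng_seed=5,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


def generate_clean(config: GeneratorConfig):
    """Generate a study and run the standard preprocessing."""
    table, meta, tree, truth = generate_study(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clean, meta2 = preprocess_study(table, meta)
    return clean, meta2, tree, truth


@pytest.fixture(scope="session")
def small_study():
    """One preprocessed small study shared across read-only tests."""
    return generate_clean(small_config())


@pytest.fixture(scope="session")
def full_study():
    """The full cohort design at generator defaults, preprocessed."""
    return generate_clean(GeneratorConfig(rng_seed=17))


@pytest.fixture()
def toy_table() -> OtuTable:
    """Tiny hand-written counts table with taxonomy."""
    data = pd.DataFrame(
        [[10, 0, 5, 1], [0, 20, 5, 0], [2, 2, 2, 2]],
        index=["s1", "s2", "s3"],
        columns=["otuA", "otuB", "otuC", "otuD"],
    )
    taxonomy = {
        "otuA": "k__Bacteria;p__;c__;o__;f__Moraxellaceae;g__Acinetobacter",
        "otuB": "k__Bacteria;p__;c__;o__;f__Sphingomonadaceae;g__",
        "otuC": "k__Bacteria;p__;c__;o__;f__Staphylococcaceae;g__",
        "otuD": "k__Bacteria;p__;c__;o__;f__Moraxellaceae;g__",
    }
    return OtuTable(data, "counts", taxonomy)
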