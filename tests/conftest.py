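"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cfpreg import qpcr_io
from cfpreg import synthetic_cohort as sc


@pytest.fixture(scope="session")
def mini_panel() -> list[sc.GeneModel]:
    """Four genes covering all trajectory shapes and tissue groups."""
    return [
        sc.GeneModel("PLA1", "placental", "rise", 2.0, 22.0, 0.3,
                     baseline=-1.2, noise_sd=0.15),
        sc.GeneModel("CGB", "placental", "early_peak", 2.5, 9.0, 2.2,
                     baseline=-1.2, noise_sd=0.15),
        sc.GeneModel("IMM1", "immune", "rise_with_baseline", 0.6, 20.0, 0.2,
                     baseline=0.8, noise_sd=0.15),
        sc.GeneModel("OTH1", "other", "rise_with_baseline", 0.1, 20.0, 0.2,
                     baseline=1.0, noise_sd=0.15),
    ]


@pytest.fixture(scope="session")
def weekly_config() -> sc.SimulationConfig:
    return sc.SimulationConfig(
        seed=42,
        cohorts=(sc.CohortDesign("weekly", 8, scheme="weekly",
                                 preterm_fraction=0.0),))


@pytest.fixture(scope="session")
def weekly_cohort(weekly_config, mini_panel):
    return sc.simulate_cohort(weekly_config, mini_panel)


@pytest.fixture(scope="session")
def weekly_matrix(weekly_cohort, mini_panel):
    samples, _ = weekly_cohort
    groups = {m.gene: m.group for m in mini_panel}
    return qpcr_io.from_long_frame(samples, groups)


@pytest.fixture(scope="session")
def risk_cohort():
    """Sparse-sampled two-cohort design with an injected preterm effect."""
    panel = sc.make_screen_panel()
    config = sc.SimulationConfig(
        seed=7,
        cohorts=(
            sc.CohortDesign("discovery", 34, scheme="sparse", n_draws=1,
                            window=(17.0, 35.0), preterm_fraction=8 / 34),
            sc.CohortDesign("validation", 23, scheme="sparse", n_draws=1,
                            window=(22.0, 34.0), preterm_fraction=5 / 23),
        ))
    samples, outcomes = sc.simulate_cohort(config, panel)
    samples = sc.inject_preterm_effect(samples, outcomes,
                                       list(sc.PRETERM_SEVEN), 1.2, lod=0.0)
    groups = {m.gene: m.group for m in panel}
    return qpcr_io.from_long_frame(samples, groups), outcomes
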