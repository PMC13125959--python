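"""Shared fixtures: synthetic landscapes, virtual species, fitted members.

The expensive end-to-end objects (100x100 landscape, 300-presence training
table, cross-validated members, gated ensemble) are session-scoped so the
ground-truth-recovery checks and the interpretation tests reuse one fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ensdm import (
    PREDICTOR_NAMES,
    build_ensemble,
    build_training_table,
    aggregate_to_grid,
    clean_occurrences,
    cross_validate,
    make_grid,
    sample_presences,
    sample_pseudo_absences,
    simulate_coastline,
    simulate_predictor_stack,
    thin_occurrences,
)
from ensdm import models as md
from ensdm import simulate as sim

EXTENT = (110.0, 120.0, 20.0, 30.0)
SEED = 20240915


@pytest.fixture(scope="session")
def grid():
    return make_grid(EXTENT, 0.1)


@pytest.fixture(scope="session")
def coast(grid):
    return simulate_coastline(grid, seed=1)


@pytest.fixture(scope="session")
def stack(grid, coast):
    return simulate_predictor_stack(grid, correlation_length=8.0, seed=1, coast=coast)


@pytest.fixture(scope="session")
def species(stack):
    return sim.default_inland_species(stack)


@pytest.fixture(scope="session")
def training_table(grid, coast, stack, species):
    occ = sample_presences(species, 300, seed=SEED)
    cleaned, _ = clean_occurrences(occ, EXTENT, land=coast)
    thinned = thin_occurrences(cleaned)
    cells = aggregate_to_grid(thinned, grid, stack.valid_mask)
    absences = sample_pseudo_absences(stack.valid_mask, cells, grid, seed=SEED + 1)
    return build_training_table(cells, absences, stack)


@pytest.fixture(scope="session")
def cv_members(training_table):
    cv_mx = cross_validate(
        lambda t, s: md.fit_maxent(t, seed=s), training_table, seed=SEED, algorithm="maxent-style"
    )
    cv_rf = cross_validate(
        lambda t, s: md.fit_forest(t, seed=s), training_table, seed=SEED, algorithm="forest"
    )
    return cv_mx, cv_rf


@pytest.fixture(scope="session")
def fitted_members(training_table):
    mx = md.fit_maxent(training_table, seed=SEED)
    rf = md.fit_forest(training_table, seed=SEED)
    return mx, rf


@pytest.fixture(scope="session")
def ensemble_sdm(training_table, fitted_members, cv_members):
    presence_X = training_table.loc[training_table["label"] == 1, list(PREDICTOR_NAMES)]
    return build_ensemble(list(fitted_members), list(cv_members), presence_X)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


def toy_training_table(n: int = 200, seed: int = 0, signal: bool = True) -> pd.DataFrame:
    """A 7-predictor table; label = indicator(BIO1 > median) when signal."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 7))
    df = pd.DataFrame(X, columns=PREDICTOR_NAMES)
    if signal:
        label = (df["BIO1"] > df["BIO1"].median()).astype(int)
    else:
        label = rng.integers(0, 2, size=n)
    df.insert(0, "cell", np.arange(n))
    df.insert(0, "label", label)
    return df
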