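"""Shared fixtures: synthetic populations and a planted-island screen."""

from __future__ import annotations

import numpy as np
import pytest

from phenoscreen import phenotyping as ph
from phenoscreen import synthetic as syn
from phenoscreen.growth import fit_gompertz


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def wt_spec():
    return syn.StrainSpec(strain_id="WT")


@pytest.fixture(scope="session")
def wt_population(wt_spec):
    """A single large WT-like population (5,000 cells)."""
    return syn.generate_cell_population(wt_spec, 5000, seed=42)


@pytest.fixture(scope="session")
def planted_screen():
    """The canonical planted-archipelago screen, fully summarised.

    Returns a dict with the cell tables, growth curves, realized truth,
    plate-uncorrected feature matrix and the WT-referenced ScoreMatrix.
    """
    truth = syn.planted_archipelago_truth(seed=11)
    cells, curves, realized = syn.generate_screen(truth)
    fits = {s: fit_gompertz(c) for s, c in curves.items()}
    feats = ph.features_table(cells, fits).drop(columns="low_n")
    score_mat = ph.compute_scores(feats, sorted(truth.wt_ids))
    return {
        "cells": cells,
        "curves": curves,
        "truth": realized,
        "features": feats,
        "scores": score_mat,
        "wt_ids": sorted(truth.wt_ids),
    }
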