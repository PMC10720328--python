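"""Shared fixtures: seeded synthetic cohorts reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import strainpheno as sp
from strainpheno.synthetic import cohort_table


@pytest.fixture(scope="session")
def small_cohort():
    """240 subjects under the default four-group study conditions."""
    cfg = sp.default_config(n_subjects=240, seed=11)
    subjects = sp.generate_cohort(cfg)
    return cfg, subjects


@pytest.fixture(scope="session")
def featurized(small_cohort):
    _, subjects = small_cohort
    kept, _ = sp.qc_filter([s.trace for s in subjects])
    aligned, _ = sp.align_and_resample(kept)
    features = sp.build_feature_matrix(aligned)
    truth = {s.subject_id: s.true_cluster for s in subjects}
    return aligned, features, truth


@pytest.fixture(scope="session")
def fitted(featurized):
    aligned, features, truth = featurized
    model = sp.fit_gmm(features, k=4, seed=0)
    assignments = sp.assign(model, features)
    model, assignments = sp.relabel_canonical(model, assignments)
    labels = np.array([a.label for a in assignments])
    return model, assignments, labels


@pytest.fixture(scope="session")
def outcome_table(small_cohort):
    _, subjects = small_cohort
    return cohort_table(subjects)
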