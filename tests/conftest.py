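"""Shared fixtures: small synthetic cohorts and fitted pipelines.

The expensive artifacts (a default 15+15-subject cohort preprocessed and
fitted end to end) are session-scoped so the whole suite pays for them
once.
"""

import dataclasses

import numpy as np
import pytest

import ramanmuscle as rm


@pytest.fixture(scope="session")
def default_cohort():
    """Default-config two-group mouse cohort at seed 1 (120 spectra)."""
    cohort, truth = rm.generate_cohort(
        rm.default_config(seed=1), ["unexercised", "exercised"]
    )
    return cohort, truth


@pytest.fixture(scope="session")
def default_matrix(default_cohort):
    cohort, _ = default_cohort
    return rm.preprocess_cohort(cohort)


@pytest.fixture(scope="session")
def default_fit(default_matrix):
    return rm.fit_pipeline(default_matrix)


@pytest.fixture(scope="session")
def three_group_matrix():
    """Cohort including the synthetic human group, preprocessed."""
    cohort, _ = rm.generate_cohort(
        rm.default_config(seed=1), ["unexercised", "exercised", "human"]
    )
    return rm.preprocess_cohort(cohort)


@pytest.fixture()
def tiny_cohort():
    """A hand-built 3-spectrum cohort on a short axis (io round-trips)."""
    wn = np.linspace(900.0, 1800.0, 10)
    spectra = []
    for i, (grp, cov) in enumerate(
        [("unexercised", None), ("exercised", 6.5), ("exercised", 12.25)]
    ):
        meta = rm.SpectrumMetadata(
            subject_id=f"m{i}",
            group=grp,
            site="gastrocnemius-medial-left",
            covariate=cov,
            acquisition_id=f"a{i + 1}",
        )
        spectra.append(rm.RamanSpectrum(wn, np.sin(wn / 100.0) + i, meta))
    return rm.Cohort(spectra, name="tiny")


@pytest.fixture()
def noiseless_config():
    cfg = rm.default_config(seed=7)
    return dataclasses.replace(cfg, noise_sd=0.0)
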