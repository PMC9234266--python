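"""Shared fixtures: tiny volumes and a small prebuilt atlas database.

Everything is generated programmatically; expensive artifacts (the small
atlas database, the full experiment report) are session-scoped so the whole
suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from striatseg.imgio import LabelVolume, Volume
from striatseg.phantom import default_spec, synthesize_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    return Volume(rng.random((8, 8, 8)).astype(np.float32), np.eye(4))


@pytest.fixture
def small_labels(rng):
    return LabelVolume(rng.integers(0, 3, (8, 8, 8)), np.eye(4), {1: "a", 2: "b"})


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free, blur-free, undeformed conditions (exactness tests)."""
    return default_spec(noise_sd=0.0, psf_fwhm=0.0, deform_amplitude=0.0,
                        uptake_jitter_sd=0.0)


@pytest.fixture(scope="session")
def default_hc_subject():
    return synthesize_subject(default_spec(), "HC", 11)


@pytest.fixture(scope="session")
def default_pd_subject():
    return synthesize_subject(default_spec(), "PD", 12)


@pytest.fixture(scope="session")
def small_db():
    """A 6-subject atlas database at default geometry (shared, ~1 min).

    Built from a mild-variability cohort (4 mm deformation, low noise) so
    near-identity examples probe pipeline correctness rather than cohort
    difficulty.
    """
    from striatseg.atlasdb import AtlasBuildSettings, build_database

    spec = default_spec(deform_amplitude=4.0, noise_sd=0.05)
    subjects = [synthesize_subject(spec, g, s, f"{g.lower()}{s}")
                for g, s in [("HC", 101), ("HC", 102), ("HC", 103),
                             ("PD", 104), ("PD", 105), ("PD", 106)]]
    settings = AtlasBuildSettings(template_iterations=2)
    db = build_database(
        [(s.pet, s.truth, s.group) for s in subjects], settings,
        ids=[s.subject_id for s in subjects],
    )
    return db
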