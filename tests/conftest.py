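"""Shared fixtures: the phantom, its sensitivity maps and a synthetic cohort.

The expensive objects (three quasi-static phantom solves, the seeded
8-subject cohort) are computed once per session and shared across tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from impedyn import synthetic, workflow


@pytest.fixture(scope="session")
def phantom():
    return synthetic.make_phantom(synthetic.PhantomSpec())


@pytest.fixture(scope="session")
def smaps(phantom):
    return workflow.compute_sensitivity_maps(phantom)


@pytest.fixture(scope="session")
def cohort_spec():
    return synthetic.CohortSpec()


@pytest.fixture(scope="session")
def cohort_study(phantom, cohort_spec, smaps):
    return workflow.run_cohort_study(phantom, cohort_spec, smaps=smaps)


def _subject(phantom, cohort_spec, noise_free):
    params = synthetic.subject_parameters(cohort_spec)[0]
    rng = np.random.default_rng(np.random.SeedSequence(cohort_spec.seed).spawn(1)[0])
    return synthetic.make_pulsation(
        phantom.spec, params, cohort_spec, rng, surfaces=phantom.surfaces,
        noise_free=noise_free,
    )


@pytest.fixture(scope="session")
def noise_free_subject(phantom, cohort_spec):
    return _subject(phantom, cohort_spec, noise_free=True)


@pytest.fixture(scope="session")
def noisy_subject(phantom, cohort_spec):
    return _subject(phantom, cohort_spec, noise_free=False)
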