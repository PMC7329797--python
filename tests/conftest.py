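"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from meropk.dataset import (
    CovariateSet,
    DoseEvent,
    Observation,
    PKDataset,
    SubjectRecord,
)
from meropk.popmodel import meropenem_crrt_model
from meropk.structural import InfusionSchedule, StructuralParams, concentration_profile


@pytest.fixture(scope="session")
def published_model():
    return meropenem_crrt_model()


@pytest.fixture(scope="session")
def typical_params():
    return StructuralParams(v1=27.9, v2=33.7, cl_crrt=15.1, q=21.1)


@pytest.fixture
def single_infusion():
    return InfusionSchedule(doses=(DoseEvent(start_time=0.0, amount=1000.0, duration=1.0),))


def make_subject(sid, times, concs, doses=None, covariates=None, **obs_kwargs):
    doses = doses if doses is not None else (DoseEvent(0.0, 1000.0, 1.0),)
    return SubjectRecord(
        subject_id=sid,
        doses=tuple(doses),
        observations=tuple(
            Observation(time=float(t), concentration=float(c), **obs_kwargs)
            for t, c in zip(times, concs)
        ),
        covariates=CovariateSet(covariates or {"albumin": 24.6}),
    )


def quad_ofv_one_eta(subject, model, param="V1"):
    """-2 log marginal likelihood by adaptive quadrature over a single eta.

    Independent oracle for the Laplace OFV: integrates the exact joint
    density of (observations, eta) numerically.  Only valid for models with
    exactly one random effect.
    """
    (name,) = model.iiv.eta_names
    assert name == param
    om = model.iiv.omega2[param]
    obs = subject.active_observations()
    times = np.array([o.time for o in obs])
    y = np.array([o.concentration for o in obs])
    sched = InfusionSchedule(doses=subject.doses)
    sa, sp = model.residual.sigma_add, model.residual.sigma_prop

    def log_joint(eta):
        p = model.individual_params(eta={param: eta}, cov=subject.covariates)
        f = concentration_profile(p, sched, times)
        g = sa**2 + (sp * f) ** 2
        ll = -0.5 * np.sum(np.log(2 * np.pi * g) + (y - f) ** 2 / g)
        return ll - 0.5 * (math.log(2 * math.pi * om) + eta * eta / om)

    w = math.sqrt(om)
    shift = max(log_joint(e) for e in np.linspace(-4 * w, 4 * w, 81))
    val, _ = quad(lambda e: math.exp(log_joint(e) - shift), -8 * w, 8 * w, limit=400)
    return -2.0 * (math.log(val) + shift)


def random_params(rng, scale=1.0):
    """Physiologically plausible random structural parameters."""
    return StructuralParams(
        v1=float(rng.uniform(5, 80) * scale),
        v2=float(rng.uniform(5, 120) * scale),
        cl_crrt=float(rng.uniform(2, 40)),
        q=float(rng.uniform(2, 60)),
    )
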