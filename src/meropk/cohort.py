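"""Virtual study cohorts with known ground truth.

The generator reproduces the trial design that produced the clinical
dataset: 19 critically ill adults on CRRT, 1 g meropenem infused over 1 h
every 8 h, arterial samples at 0, 15, 30, 45, 60, 75, 90, 120, 180, 240 and
480 min after the start of an infusion.  Nine of the nineteen subjects are
sampled around their first dose, the remainder at steady state after
several days of therapy.  Covariates are drawn to match the reported
demographics (albumin median 24.6 g/l over 15.6-31.8; weight 60-100 kg; age
36-79 y), and sepsis probability decreases with albumin, mirroring the
observed confounding between the two.  Every cohort carries its true
subject-level random effects and kinetic parameters for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import CovariateSet, DoseEvent, Observation, PKDataset, SubjectRecord
from .popmodel import PopulationModel, draw_etas, meropenem_crrt_model, residual_variance
from .structural import InfusionSchedule, concentration_profile

__all__ = ["CohortConfig", "SimulatedDataset", "generate_cohort", "design_summary"]

#: nominal sampling times, hours after the start of the monitored infusion
DEFAULT_SAMPLING_TIMES = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 3.0, 4.0, 8.0)


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 19
    model: PopulationModel = field(default_factory=meropenem_crrt_model)
    dose: float = 1000.0
    tau: float = 8.0
    infusion_duration: float = 1.0
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    first_dose_fraction: float = 9.0 / 19.0
    #: prior doses given to steady-state subjects before the sampled interval
    n_prior_doses: int = 12
    albumin_range: tuple[float, float] = (15.6, 31.8)
    #: Beta(a, b) shape for albumin on its range; median ~24.6 g/l
    albumin_beta: tuple[float, float] = (2.5, 2.07)
    weight_range: tuple[float, float] = (60.0, 100.0)
    age_range: tuple[float, float] = (36.0, 79.0)
    age_beta: tuple[float, float] = (3.0, 1.3)
    #: expected fraction of all scheduled observations contaminated with a
    #: spurious positive predose value (only time-zero samples of first-dose
    #: subjects are eligible)
    contamination_rate: float = 0.0
    lloq: float = 0.1
    with_residual: bool = True

    def __post_init__(self):
        if not (0.0 <= self.first_dose_fraction <= 1.0):
            raise ValueError("first_dose_fraction must lie in [0, 1]")
        if not (0.0 <= self.contamination_rate <= 1.0):
            raise ValueError("contamination_rate must lie in [0, 1]")
        if any(t < 0 or t > self.tau for t in self.sampling_times):
            raise ValueError("sampling times must lie within one dosing interval")


@dataclass(frozen=True)
class SimulatedDataset:
    dataset: PKDataset
    true_etas: dict       # subject_id -> {param: eta}
    true_params: dict     # subject_id -> StructuralParams
    config: CohortConfig

    def __post_init__(self):
        ids = {s.subject_id for s in self.dataset.subjects}
        if set(self.true_etas) != ids or set(self.true_params) != ids:
            raise ValueError("truth records must align with subject ids")


def _scaled_beta(rng, a, b, lo, hi, n):
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def generate_cohort(config: CohortConfig | None = None, rng=None) -> SimulatedDataset:
    """Draw one virtual cohort under ``config`` (bit-reproducible given rng)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(rng)
    model = config.model
    n = config.n_subjects
    n_first = int(round(config.first_dose_fraction * n))

    albumin = _scaled_beta(rng, *config.albumin_beta, *config.albumin_range, n)
    weight = rng.uniform(*config.weight_range, size=n)
    age = _scaled_beta(rng, *config.age_beta, *config.age_range, n)
    # lower albumin -> higher sepsis probability (logistic, 50% at the median)
    p_sepsis = 1.0 / (1.0 + np.exp((albumin - 24.6) / 2.0))
    sepsis = (rng.uniform(size=n) < p_sepsis).astype(float)
    creatinine = rng.uniform(0.6, 3.7, size=n)

    etas = draw_etas(model, n, rng)
    eta_names = model.iiv.eta_names

    n_obs_total = n * len(config.sampling_times)
    n_contam = rng.binomial(n_obs_total, config.contamination_rate)

    subjects, true_etas, true_params = [], {}, {}
    contaminated: set[int] = set()
    if n_contam and n_first:
        contaminated = set(
            rng.choice(np.arange(n_first), size=min(n_contam, n_first), replace=False)
        )
    for i in range(n):
        sid = f"S{i + 1:02d}"
        first_dose = i < n_first
        eta = dict(zip(eta_names, etas[i]))
        params = model.individual_params(eta=eta, cov={"albumin": albumin[i]})
        n_doses = 1 if first_dose else config.n_prior_doses + 1
        doses = tuple(
            DoseEvent(start_time=k * config.tau, amount=config.dose, duration=config.infusion_duration)
            for k in range(n_doses)
        )
        t0 = (n_doses - 1) * config.tau
        times = t0 + np.asarray(config.sampling_times)
        conc = concentration_profile(params, InfusionSchedule(doses=doses), times)
        if config.with_residual:
            sd = np.sqrt(residual_variance(conc, model.residual))
            conc = conc + rng.normal(size=conc.shape) * sd
        obs = []
        for t, c in zip(times, conc):
            is_predose = first_dose and t == 0.0
            contaminated_here = is_predose and i in contaminated
            if is_predose:
                # no drug on board before the very first dose; a clean predose
                # sample is an exact zero that carries no information (and
                # would degenerate the additive-error likelihood), so it is
                # stored excluded unless contamination makes it positive
                c = float(rng.uniform(config.lloq, 2.0)) if contaminated_here else 0.0
            c = float(c)
            # the assay cannot report a negative value: clip and exclude
            negative = c < 0.0
            c = max(c, 0.0)
            flag_out = negative or (is_predose and not contaminated_here)
            reason = (
                "negative-simulated"
                if negative
                else "predose-zero" if flag_out else ""
            )
            obs.append(
                Observation(
                    time=float(t),
                    concentration=c,
                    below_lloq=bool(0 < c < config.lloq),
                    excluded=flag_out,
                    exclusion_reason=reason,
                )
            )
        cov = CovariateSet(
            {
                "albumin": float(albumin[i]),
                "weight": float(weight[i]),
                "age": float(age[i]),
                "sepsis": float(sepsis[i]),
                "creatinine": float(creatinine[i]),
                "therapy_day": 1.0 if first_dose else float(1 + rng.integers(1, 12)),
            }
        )
        subjects.append(
            SubjectRecord(subject_id=sid, doses=doses, observations=tuple(obs), covariates=cov)
        )
        true_etas[sid] = eta
        true_params[sid] = params

    ds = PKDataset(
        subjects=tuple(subjects),
        lloq=config.lloq,
        metadata={"generator": "meropk.cohort", "n_first_dose": n_first},
    )
    return SimulatedDataset(dataset=ds, true_etas=true_etas, true_params=true_params, config=config)


def design_summary(dataset: PKDataset) -> dict:
    """Deterministic design/covariate summary of an event-record dataset."""
    n_sub = len(dataset.subjects)
    n_obs = dataset.n_observations()
    n_first = sum(1 for s in dataset.subjects if len(s.doses) == 1)
    cov_rows = {}
    names = sorted({k for s in dataset.subjects for k in s.covariates.values})
    for name in names:
        vals = np.array(
            [s.covariates.get(name) for s in dataset.subjects if s.covariates.get(name) is not None],
            float,
        )
        cov_rows[name] = {
            "median": float(np.median(vals)) if vals.size else np.nan,
            "min": float(vals.min()) if vals.size else np.nan,
            "max": float(vals.max()) if vals.size else np.nan,
        }
    return {
        "n_subjects": n_sub,
        "n_observations": n_obs,
        "n_observations_active": dataset.n_observations(active_only=True),
        "n_first_dose_subjects": n_first,
        "n_steady_state_subjects": n_sub - n_first,
        "covariates": cov_rows,
    }
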