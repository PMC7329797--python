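"""Deterministic kinetics: two-compartment disposition with zero-order infusion.

The model is the linear mammillary system

    V1 dC1/dt = -Q*C1 + Q*C2 - Cl_CRRT*C1 + R(t)
    V2 dC2/dt =  Q*C1 - Q*C2

with elimination exclusively by continuous renal replacement therapy
(clearance ``Cl_CRRT``) and infusion input ``R(t)`` into the central
compartment.  The production path is the closed-form bi-exponential
solution (superposition over infusions, geometric accumulation for steady
state); numerical ODE integration is provided only as an independent test
oracle.

All functions accept and return the package units: hours, mg, l, mg/l.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .dataset import DoseEvent

__all__ = [
    "StructuralParams",
    "MacroConstants",
    "InfusionSchedule",
    "macro_constants",
    "concentration_profile",
    "steady_state_profile",
    "ode_oracle",
]

# relative root separation below which the bi-exponential form degenerates;
# roots closer than this are split apart by the same amount (error O(1e-9),
# far below every tolerance used in this package)
_REPEATED_ROOT_EPS = 1e-9


@dataclass(frozen=True)
class StructuralParams:
    """Kinetic constants of one individual.

    v1, v2 : l
        Central / peripheral volumes of distribution.
    cl_crrt : l/h
        Systemic clearance (entirely via CRRT in this population).
    q : l/h
        Inter-compartmental clearance.
    """

    v1: float
    v2: float
    cl_crrt: float
    q: float

    def __post_init__(self):
        for name in ("v1", "v2", "cl_crrt", "q"):
            v = getattr(self, name)
            if not (v > 0) or not np.isfinite(v):
                raise ValueError(f"{name} must be strictly positive, got {v}")

    @property
    def vss(self) -> float:
        """Steady-state volume of distribution V1 + V2 (l)."""
        return self.v1 + self.v2


@dataclass(frozen=True)
class MacroConstants:
    """Bi-exponential macro-constants of the central unit-bolus response.

    C1(t) = coef_alpha * exp(-alpha*t) + coef_beta * exp(-beta*t) after a
    1 mg bolus, with alpha > beta > 0.
    """

    alpha: float
    beta: float
    coef_alpha: float
    coef_beta: float

    @property
    def half_life_beta(self) -> float:
        """Terminal half-life ln(2)/beta (h)."""
        return np.log(2.0) / self.beta


@dataclass(frozen=True)
class InfusionSchedule:
    doses: tuple[DoseEvent, ...]
    steady_state: bool = False
    tau: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "doses", tuple(self.doses))
        if self.steady_state:
            if self.tau is None or self.tau <= 0:
                raise ValueError("steady-state schedule requires a positive tau")
            if len(self.doses) != 1:
                raise ValueError("steady-state schedule holds the single repeated dose")
            if self.doses[0].duration >= self.tau:
                raise ValueError("infusion duration must be shorter than tau")


def _exp_terms(v1, v2, cl, q):
    """Decay rates and unit-bolus coefficients, vectorized over leading axes.

    Returns ``(lam, coef)`` of shape ``(..., 2)`` such that the central
    response to a 1 mg bolus is ``sum_k coef_k * exp(-lam_k * t)``.
    """
    v1, v2, cl, q = np.broadcast_arrays(
        np.asarray(v1, float), np.asarray(v2, float), np.asarray(cl, float), np.asarray(q, float)
    )
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    s = k10 + k12 + k21
    prod = k10 * k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * prod, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    # guard the (measure-zero) repeated root by nudging beta downward, and
    # keep beta strictly positive when Q -> 0 drives the roots apart
    near = (alpha - beta) <= _REPEATED_ROOT_EPS * alpha
    beta = np.where(near, alpha * (1.0 - _REPEATED_ROOT_EPS), beta)
    beta = np.maximum(beta, alpha * 1e-14)
    denom = (alpha - beta) * v1
    coef_a = (alpha - k21) / denom
    coef_b = (k21 - beta) / denom
    lam = np.stack([alpha, beta], axis=-1)
    coef = np.stack([coef_a, coef_b], axis=-1)
    return lam, coef


def _exp_terms_1c(v1, cl):
    """One-compartment limit: a single exponential."""
    v1 = np.asarray(v1, float)
    cl = np.asarray(cl, float)
    lam = (cl / v1)[..., None]
    coef = (1.0 / v1)[..., None]
    return lam, coef


def macro_constants(p: StructuralParams) -> MacroConstants:
    """Hybrid rate constants alpha/beta and bolus coefficients.

    alpha and beta are the roots of x^2 - (k10+k12+k21) x + k10*k21 = 0 with
    k10 = Cl_CRRT/V1, k12 = Q/V1, k21 = Q/V2.
    """
    lam, coef = _exp_terms(p.v1, p.v2, p.cl_crrt, p.q)
    return MacroConstants(
        alpha=float(lam[0]), beta=float(lam[1]), coef_alpha=float(coef[0]), coef_beta=float(coef[1])
    )


def _superposition_numpy(lam, coef, d_start, d_rate, d_dur, times):
    te = times[:, :, None] - d_start[:, None, :]  # (S,T,D)
    te = np.maximum(te, 0.0)[..., None]  # (S,T,D,1)
    lam_ = lam[:, None, None, :]
    coef_ = coef[:, None, None, :]
    dur_ = d_dur[:, None, :, None]
    tin = np.minimum(te, dur_)
    term = (coef_ / lam_) * (-np.expm1(-lam_ * tin)) * np.exp(-lam_ * (te - tin))
    rate_ = d_rate[:, None, :, None]
    return (rate_ * term).sum(axis=(2, 3))


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _superposition_jit(lam, coef, d_start, d_rate, d_dur, times):  # pragma: no cover
        S, T = times.shape
        D = d_start.shape[1]
        K = lam.shape[1]
        out = np.zeros((S, T))
        for s in range(S):
            for t in range(T):
                acc = 0.0
                for d in range(D):
                    rate = d_rate[s, d]
                    if rate == 0.0:
                        continue
                    te = times[s, t] - d_start[s, d]
                    if te <= 0.0:
                        continue
                    dur = d_dur[s, d]
                    tin = te if te < dur else dur
                    for k in range(K):
                        lk = lam[s, k]
                        acc += (
                            rate
                            * (coef[s, k] / lk)
                            * (-np.expm1(-lk * tin))
                            * np.exp(-lk * (te - tin))
                        )
                out[s, t] = acc
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _superposition(lam, coef, d_start, d_rate, d_dur, times):
    """Central concentration by superposition of zero-order infusions.

    Shapes: ``lam``/``coef`` (S, K); dose arrays (S, D); ``times`` (S, T) or
    (T,).  Padded dose slots are encoded by ``d_rate == 0``.  Returns (S, T).

    One expression covers both branches: with te = t - start and
    tin = min(te, dur),

        c = R * sum_k (coef_k/lam_k) * (1 - e^{-lam_k tin}) * e^{-lam_k (te - tin)}

    which is the during-infusion solution for te <= dur and the post-infusion
    washout beyond, continuous at the infusion end.
    """
    times = np.atleast_2d(np.asarray(times, float))
    lam = np.ascontiguousarray(lam, float)
    coef = np.ascontiguousarray(coef, float)
    d_start = np.ascontiguousarray(d_start, float)
    d_rate = np.ascontiguousarray(d_rate, float)
    d_dur = np.ascontiguousarray(d_dur, float)
    if times.shape[0] == 1 and lam.shape[0] > 1:
        times = np.broadcast_to(times, (lam.shape[0], times.shape[1]))
    times = np.ascontiguousarray(times, float)
    if _HAVE_NUMBA:
        return _superposition_jit(lam, coef, d_start, d_rate, d_dur, times)
    return _superposition_numpy(lam, coef, d_start, d_rate, d_dur, times)


def _ss_superposition(lam, coef, dose, dur, tau, times):
    """Steady-state central concentration within one dosing interval.

    Accumulation of the single-dose exponential terms as a geometric series
    over infinitely many prior doses.  ``times`` must lie in [0, tau]
    measured from the start of an infusion.  Shapes: ``lam``/``coef``
    (S, K); ``times`` (T,).  Returns (S, T).
    """
    times = np.asarray(times, float)
    t = times[None, :, None]
    lam_ = lam[:, None, :]
    coef_ = coef[:, None, :]
    rate = dose / dur
    e_dur = -np.expm1(-lam_ * dur)          # 1 - exp(-lam*dur)
    e_tau = -np.expm1(-lam_ * tau)          # 1 - exp(-lam*tau)
    carry = np.exp(-lam_ * tau) / e_tau     # sum over completed prior doses
    decay = np.exp(-lam_ * (t - dur))       # may exceed 1 while the infusion runs
    during = -np.expm1(-lam_ * np.minimum(t, dur)) + e_dur * decay * carry
    post = e_dur * decay / e_tau
    branch = np.where(t <= dur, during, post)
    return rate * ((coef_ / lam_) * branch).sum(axis=-1)


def concentration_profile(p: StructuralParams, schedule: InfusionSchedule, times) -> np.ndarray:
    """Central concentration (mg/l) at ``times`` (h) under ``schedule``.

    Closed-form superposition over the schedule's infusions; for a
    steady-state schedule the geometric accumulation within one interval.
    """
    times = np.asarray(times, float)
    if np.any(times < 0):
        raise ValueError("times must be non-negative")
    if schedule.steady_state:
        return steady_state_profile(
            p, schedule.doses[0].amount, schedule.tau, schedule.doses[0].duration, times
        )
    lam, coef = _exp_terms(p.v1, p.v2, p.cl_crrt, p.q)
    if not schedule.doses:
        return np.zeros_like(times)
    d_start = np.array([[d.start_time for d in schedule.doses]])
    d_rate = np.array([[d.rate for d in schedule.doses]])
    d_dur = np.array([[d.duration for d in schedule.doses]])
    return _superposition(lam[None, :], coef[None, :], d_start, d_rate, d_dur, times[None, :])[0]


def steady_state_profile(
    p: StructuralParams,
    dose: float,
    tau: float,
    duration: float,
    times,
    method: str = "accumulation",
) -> np.ndarray:
    """Periodic steady-state concentrations over one dosing interval.

    Parameters
    ----------
    dose, tau, duration : mg, h, h
        Repeated dose, dosing interval and infusion length (duration < tau).
    times : array of h in [0, tau]
        Measured from the start of an infusion at steady state.
    method : {"accumulation", "simulate"}
        Closed-form geometric accumulation (production path) or explicit
        superposition of enough repeated doses to decay ten terminal
        half-lives (cross-check path); the two agree to < 1e-6 relative.
    """
    if duration >= tau:
        raise ValueError(f"infusion duration {duration} h must be < tau {tau} h")
    times = np.asarray(times, float)
    if np.any(times < 0) or np.any(times > tau + 1e-12):
        raise ValueError("steady-state times must lie within [0, tau]")
    if method == "accumulation":
        lam, coef = _exp_terms(p.v1, p.v2, p.cl_crrt, p.q)
        return _ss_superposition(lam[None, :], coef[None, :], dose, duration, tau, times)[0]
    if method == "simulate":
        mc = macro_constants(p)
        # residual accumulation decays as exp(-beta * n * tau); run it below 1e-8
        n_doses = max(2, int(np.ceil(18.5 / (mc.beta * tau))) + 1)
        doses = tuple(
            DoseEvent(start_time=i * tau, amount=dose, duration=duration)
            for i in range(n_doses)
        )
        return concentration_profile(
            p, InfusionSchedule(doses=doses), (n_doses - 1) * tau + times
        )
    raise ValueError(f"unknown method {method!r}")


def ode_oracle(
    p: StructuralParams, schedule: InfusionSchedule, times, rel_tol: float = 1e-10
) -> np.ndarray:
    """Reference solution by piecewise high-accuracy ODE integration.

    Test oracle only: integrates the mass-balance system across every
    infusion on/off boundary with DOP853.  ``rel_tol`` must be <= 1e-8.
    """
    if rel_tol > 1e-8:
        raise ValueError("rel_tol must be <= 1e-8 for the oracle")
    times = np.asarray(times, float)
    if schedule.steady_state:
        raise ValueError("the oracle integrates explicit schedules only")
    doses = schedule.doses
    if not doses:
        return np.zeros_like(times)

    def rate_at(t):
        return sum(
            d.rate for d in doses if d.start_time <= t < d.start_time + d.duration
        )

    breakpoints = sorted(
        {0.0, *(d.start_time for d in doses), *(d.start_time + d.duration for d in doses)}
    )
    t_end = float(max(times.max(), breakpoints[-1]))
    segs = [b for b in breakpoints if b < t_end] + [t_end]

    def rhs_factory(r):
        def rhs(_t, y):
            c1, c2 = y
            return (
                (-(p.q + p.cl_crrt) * c1 + p.q * c2 + r) / p.v1,
                (p.q * c1 - p.q * c2) / p.v2,
            )

        return rhs

    y = np.zeros(2)
    out = np.full(times.shape, np.nan)
    out[times == 0.0] = 0.0
    for a, b in zip(segs, segs[1:]):
        mask = (times > a) & (times <= b)
        t_eval = np.unique(np.append(times[mask], b))
        sol = solve_ivp(
            rhs_factory(rate_at(0.5 * (a + b))),
            (a, b),
            y,
            method="DOP853",
            rtol=rel_tol,
            atol=rel_tol * 1e-2,
            # keep steps short: the dense-output interpolant between giant
            # steps is less accurate than the step error itself
            max_step=0.25,
            t_eval=t_eval,
        )
        if not sol.success:
            raise RuntimeError(f"ODE oracle failed on [{a}, {b}]: {sol.message}")
        lookup = dict(zip(sol.t, sol.y[0]))
        for i in np.where(mask)[0]:
            out[i] = lookup[times[i]]
        y = sol.y[:, -1]
    return out
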