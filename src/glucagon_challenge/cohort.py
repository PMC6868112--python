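"""Forward simulation of the challenge test and seeded synthetic cohorts.

The generator emulates the study design: eight subjects, sixteen sampling
times between 135 and 360 min, a 3 h baseline steady state followed by a
3 h somatostatin-clamped infusion phase, two visits per subject (before and
after treatment), and a treatment effect that reduces the total receptor
number — expressed identifiably as a roughly 2.2-fold increase of the
apparent dissociation constant K'1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    BaselineState,
    FixedKinetics,
    Protocol,
    SubjectParameters,
    _clearance,
    _hill,
    apply_baseline_constraints,
    hgp_rate,
    make_baseline,
    receptor_steady_state,
    system_rhs,
)

__all__ = [
    "ObservationSchedule",
    "NoiseModel",
    "SubjectRecord",
    "CohortSpec",
    "SubjectPair",
    "SimulationError",
    "GenerationError",
    "SimulatedTrajectory",
    "simulate_subject",
    "observe",
    "generate_paired_cohort",
    "TABLE_MEANS",
    "TABLE_SDS",
]

# Population means / SDs of the fitted parameters (before-treatment cohort
# averages); used as the default sampling distribution for synthetic subjects.
TABLE_MEANS = {
    "V_1": 5.63, "K1_prime": 0.00501, "V_id": 1.52, "K_id": 11.0,
    "k_degI": 30.5, "k_degE": 5.73, "k_in": 21.5, "V_h": 4.65, "b_G": 0.0804,
}
TABLE_SDS = {
    "V_1": 1.97, "K1_prime": 0.00257, "V_id": 0.963, "K_id": 6.62,
    "k_degI": 8.27, "k_degE": 1.84, "k_in": 15.2, "V_h": 2.28, "b_G": 0.228,
}

DEFAULT_TIMES_MIN = (135, 150, 165, 179, 195, 210, 225, 240,
                     255, 270, 285, 300, 315, 330, 345, 360)


class SimulationError(RuntimeError):
    """The ODE integrator failed; carries solver diagnostics."""


class GenerationError(RuntimeError):
    """Could not draw a valid (positive, consistent) synthetic subject."""


@dataclass(frozen=True)
class ObservationSchedule:
    """Sampling times of the challenge test, in minutes."""

    times_min: tuple = DEFAULT_TIMES_MIN

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("times_min must be strictly increasing")

    @property
    def times_h(self) -> np.ndarray:
        return np.asarray(self.times_min, dtype=float) / 60.0


@dataclass(frozen=True)
class NoiseModel:
    """Independent multiplicative Gaussian noise, value * (1 + CV * z).

    Proportional (constant-CV) errors match assay behaviour and keep the
    channels positive at the default CVs (5% glucose, 10% hormones and
    tracer-derived rates).
    """

    cv_G: float = 0.05
    cv_I: float = 0.10
    cv_E: float = 0.10
    cv_Fhgp: float = 0.10
    cv_Rd: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if min(self.cv_G, self.cv_I, self.cv_E, self.cv_Fhgp, self.cv_Rd) < 0:
            raise ValueError("noise CVs must be >= 0")


@dataclass
class SubjectRecord:
    """Sampled (noisy) observation series for one subject and one visit."""

    subject_id: str
    visit: str  # "before" | "after"
    times_min: np.ndarray
    glucose: np.ndarray
    insulin: np.ndarray
    glucagon: np.ndarray
    fhgp: np.ndarray
    rd: np.ndarray
    true_params: Optional[SubjectParameters] = None
    true_baseline: Optional[BaselineState] = None

    def __post_init__(self):
        n = len(self.times_min)
        for name in ("glucose", "insulin", "glucagon", "fhgp", "rd"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if len(arr) != n:
                raise ValueError(f"channel {name} length {len(arr)} != schedule length {n}")
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.visit not in ("before", "after"):
            raise ValueError("visit must be 'before' or 'after'")

    @property
    def times_h(self) -> np.ndarray:
        return self.times_min / 60.0


@dataclass
class SubjectPair:
    before: SubjectRecord
    after: SubjectRecord


@dataclass(frozen=True)
class CohortSpec:
    """Population recipe for a paired synthetic cohort.

    The treatment multiplies K'1 by ``treatment_K1prime_multiplier``
    (default 0.0109 / 0.00501, the cohort-average after/before ratio, i.e. a
    roughly halved receptor number); other parameters are untouched unless
    listed in ``treatment_effects`` (multipliers by parameter name).
    Basal glucose and insulin get mild between-subject spread; basal
    glucagon defaults to the reported physiological 14.3 pmol/L.
    """

    n_subjects: int = 8
    param_means: dict = field(default_factory=lambda: dict(TABLE_MEANS))
    param_sds: dict = field(default_factory=lambda: dict(TABLE_SDS))
    treatment_K1prime_multiplier: float = 0.0109 / 0.00501
    treatment_effects: dict = field(default_factory=dict)
    G_bar_mean: float = 0.9      # g/L
    G_bar_sd: float = 0.045
    I_bar_mean: float = 10.0     # mU/L; near the insulin clamp plateau Q_I/(V_I k_degI)
    I_bar_sd: float = 1.0
    E_bar_mean: float = 14.3     # pmol/L
    E_bar_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.treatment_K1prime_multiplier <= 0:
            raise ValueError("treatment multiplier must be > 0")


@dataclass
class SimulatedTrajectory:
    """Noiseless solution of one challenge test.

    Phase 1 is the constant baseline; phase 2 is the ODE solution with
    dense output.  ``sample`` evaluates every observable channel at
    arbitrary times in [0, t_end] hours.
    """

    params: SubjectParameters
    baseline: BaselineState
    protocol: Protocol
    fixed: FixedKinetics
    _sol: object  # scipy OdeSolution over [t_switch, t_end]

    def states(self, t_h):
        """State arrays (G, I, E, r, r_e) at times ``t_h`` (hours)."""
        t = np.atleast_1d(np.asarray(t_h, dtype=float))
        b = self.baseline
        base = np.array([b.G_bar, b.I_bar, b.E_bar, b.r_bar, b.re_bar])
        out = np.repeat(base[:, None], len(t), axis=1)
        in2 = t >= self.protocol.t_switch
        if np.any(in2):
            out[:, in2] = self._sol(t[in2])
        return out

    def sample(self, t_h) -> dict:
        """Observable channels at times ``t_h`` (hours)."""
        G, I, E, r, r_e = self.states(t_h)
        r_e = np.maximum(r_e, 0.0)
        return {
            "glucose": G,
            "insulin": I,
            "glucagon": E,
            "r": r,
            "r_e": r_e,
            "fhgp": hgp_rate(r_e, self.params),
            "rd": _clearance(G, I, self.params, self.fixed),
        }


def simulate_subject(params: SubjectParameters, protocol: Protocol = Protocol(),
                     fixed: FixedKinetics = FixedKinetics(),
                     baseline: Optional[BaselineState] = None,
                     rtol: float = 1e-9, atol: float = 1e-11) -> SimulatedTrajectory:
    """Simulate one challenge test from its baseline steady state.

    If no baseline is supplied it is built self-consistently from the
    default basal concentrations in ``CohortSpec``.  The receptor subsystem
    mixes rates from 0.18/h to ~36/h, so a stiff-capable adaptive
    integrator (LSODA) at tight tolerance is used.
    """
    if baseline is None:
        baseline = make_baseline(0.9, 10.0, 14.3, params, fixed)
    y0 = np.array([baseline.G_bar, baseline.I_bar, baseline.E_bar,
                   baseline.r_bar, baseline.re_bar])
    sol = solve_ivp(
        lambda t, y: system_rhs(y, t, params, protocol, fixed),
        (protocol.t_switch, protocol.t_end), y0,
        method="LSODA", rtol=rtol, atol=atol, dense_output=True,
    )
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}")
    return SimulatedTrajectory(params=params, baseline=baseline,
                               protocol=protocol, fixed=fixed, _sol=sol.sol)


def observe(trajectory: SimulatedTrajectory, schedule: ObservationSchedule,
            noise: NoiseModel, subject_id: str = "S1", visit: str = "before",
            rng: Optional[np.random.Generator] = None) -> SubjectRecord:
    """Sample a trajectory at the schedule times and apply measurement noise.

    Zero CVs reproduce the model exactly; an explicit ``rng`` overrides the
    noise model's seed (used by the cohort generator to stream draws).
    """
    t_h = schedule.times_h
    if t_h[0] < 0 or t_h[-1] > trajectory.protocol.t_end:
        raise ValueError("schedule extends outside the simulated span")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    clean = trajectory.sample(t_h)
    cvs = {"glucose": noise.cv_G, "insulin": noise.cv_I, "glucagon": noise.cv_E,
           "fhgp": noise.cv_Fhgp, "rd": noise.cv_Rd}
    noisy = {}
    for ch, cv in cvs.items():
        z = rng.standard_normal(len(t_h))
        noisy[ch] = clean[ch] * (1.0 + cv * z)
    return SubjectRecord(
        subject_id=subject_id, visit=visit, times_min=np.asarray(schedule.times_min, float),
        glucose=noisy["glucose"], insulin=noisy["insulin"], glucagon=noisy["glucagon"],
        fhgp=noisy["fhgp"], rd=noisy["rd"],
        true_params=trajectory.params, true_baseline=trajectory.baseline,
    )


def _draw_positive(rng, mean, sd, max_retries=100):
    if sd == 0.0:
        if mean <= 0:
            raise GenerationError(f"non-positive fixed value {mean}")
        return mean
    for _ in range(max_retries):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise GenerationError(f"could not draw positive value (mean={mean}, sd={sd})")


def _draw_subject(rng, spec: CohortSpec, fixed: FixedKinetics):
    """One self-consistent synthetic subject: free parameters + baseline.

    Two joint-consistency rejections are applied to the independent
    truncated-normal draws: the eliminated V_ii must come out positive for
    the baseline balance to hold, and the baseline Hill occupancy
    r̄e²/(K'1² + r̄e²) must be below half-max — a subject whose receptor
    response is already saturated at baseline could not show the glucose
    excursion (and its reduction under receptor loss) that defines the
    challenge test.  The cohort-average regime has occupancy ~0.35.
    """
    for _ in range(500):
        vals = {k: _draw_positive(rng, spec.param_means[k], spec.param_sds[k])
                for k in spec.param_means}
        G_bar = _draw_positive(rng, spec.G_bar_mean, spec.G_bar_sd)
        I_bar = _draw_positive(rng, spec.I_bar_mean, spec.I_bar_sd)
        E_bar = _draw_positive(rng, spec.E_bar_mean, spec.E_bar_sd)
        params = SubjectParameters(V_ii=1.0, **vals)  # V_ii placeholder
        baseline = make_baseline(G_bar, I_bar, E_bar, params, fixed)
        occupancy = _hill(baseline.re_bar, 1.0, params.K1_prime, params.hill_n)
        if occupancy >= 0.5:
            continue
        id_term = params.V_id * I_bar * G_bar / (params.K_id + G_bar)
        V_ii = (baseline.Fhgp_bar - id_term) * (fixed.K_ii + G_bar) / G_bar
        if V_ii <= 0:
            continue
        params = replace(params, V_ii=V_ii)
        return params, baseline
    raise GenerationError("no consistent subject after 500 attempts")


def _after_visit(params: SubjectParameters, baseline: BaselineState,
                 spec: CohortSpec, fixed: FixedKinetics):
    """Treatment-modified parameters and the matching consistent baseline.

    K'1 is scaled by the treatment multiplier (receptor loss); the subject's
    basal state, basal HGP and clearance traits are carried over unchanged,
    and b_G re-balances the basal production so the after-visit steady state
    still holds.
    """
    after = replace(params, K1_prime=params.K1_prime * spec.treatment_K1prime_multiplier)
    for name, mult in spec.treatment_effects.items():
        after = replace(after, **{name: getattr(after, name) * mult})
    r_bar, re_bar = receptor_steady_state(baseline.E_bar, after, fixed)
    b_G = baseline.Fhgp_bar - _hill(re_bar, after.V_1, after.K1_prime, after.hill_n)
    if b_G <= 0:
        raise GenerationError("after-visit b_G non-positive; treatment effect inconsistent")
    after = replace(after, b_G=b_G)
    after_baseline = BaselineState(G_bar=baseline.G_bar, I_bar=baseline.I_bar,
                                   E_bar=baseline.E_bar, r_bar=r_bar, re_bar=re_bar,
                                   Fhgp_bar=baseline.Fhgp_bar)
    return after, after_baseline


def generate_paired_cohort(spec: CohortSpec, protocol: Protocol = Protocol(),
                           fixed: FixedKinetics = FixedKinetics(),
                           noise: NoiseModel = NoiseModel(),
                           schedule: ObservationSchedule = ObservationSchedule()):
    """Generate a seeded paired cohort: per subject one before and one after
    visit, both simulated from ground-truth parameters and observed with
    noise.  Returns a list of :class:`SubjectPair` with ground truth stored
    on each record."""
    rng = np.random.default_rng(spec.seed)
    noise_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(1,)))
    pairs = []
    for i in range(spec.n_subjects):
        sid = f"S{i + 1:02d}"
        params, baseline = _draw_subject(rng, spec, fixed)
        after_params, after_baseline = _after_visit(params, baseline, spec, fixed)
        traj_b = simulate_subject(params, protocol, fixed, baseline)
        traj_a = simulate_subject(after_params, protocol, fixed, after_baseline)
        rec_b = observe(traj_b, schedule, noise, subject_id=sid, visit="before",
                        rng=noise_rng)
        rec_a = observe(traj_a, schedule, noise, subject_id=sid, visit="after",
                        rng=noise_rng)
        pairs.append(SubjectPair(before=rec_b, after=rec_a))
    return pairs
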