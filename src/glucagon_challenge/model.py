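"""Core model of the glucagon challenge test.

Three blood compartments (glucose G in g/L, insulin I in mU/L, glucagon E
in pmol/L) are coupled one-way to the kinetics of the glucagon receptor on
the hepatocyte membrane.  The receptor exists in three forms — free,
glucagon-bound and internalized — whose amounts are conserved and therefore
tracked as dimensionless fractions ``r``, ``r_e`` and ``r_i = 1 - r - r_e``
of the total receptor number.  Hepatic glucose production responds to the
bound fraction through a Hill function with coefficient 2; the apparent
dissociation constant ``K'1 = K1 / R_tot`` is the identifiable surrogate
for the (unidentifiable) total receptor number.

The challenge protocol has two phases.  During the first 3 h the subject is
at steady state with no infusion; during the second 3 h endogenous hormone
secretion is clamped off (somatostatin) and glucose, insulin and glucagon
are infused at constant rates, which makes the hormone equations exactly
solvable (exponential relaxation to an infusion plateau).

All internal rates are per hour and internal time lives on [0, 6] h with
the infusion switch at t = 3 h; observation files carry minutes and are
converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FixedKinetics",
    "SubjectParameters",
    "Protocol",
    "BaselineState",
    "SystemState",
    "DegenerateModelError",
    "hgp_rate",
    "receptor_steady_state",
    "receptor_rhs",
    "hormone_trajectory",
    "glucose_rhs",
    "system_rhs",
    "eliminate_baseline_params",
    "make_baseline",
    "apply_baseline_constraints",
]


class DegenerateModelError(ValueError):
    """All kinetic rates vanish; the receptor subsystem has no dynamics."""


def _check_nonnegative(obj, names):
    for name in names:
        if getattr(obj, name) < 0:
            raise ValueError(f"{name} must be >= 0, got {getattr(obj, name)}")


@dataclass(frozen=True)
class FixedKinetics:
    """Receptor rate constants held fixed across subjects (literature values).

    ``k_on`` is the association rate of glucagon and free receptor
    (1/pmol/h), ``k_off`` the dissociation rate (1/h), ``k_rec`` the
    recycling rate of internalized receptor (1/h), ``k_in_free`` the
    internalization rate of *free* receptor (1/h; collapses to 0 during
    estimation) and ``K_ii`` the Michaelis constant of insulin-independent
    glucose clearance (g/L; also collapses to 0).
    """

    k_on: float = 3.6e-3
    k_off: float = 14.4
    k_rec: float = 0.18
    k_in_free: float = 0.0
    K_ii: float = 0.0

    def __post_init__(self):
        _check_nonnegative(self, ("k_on", "k_off", "k_rec", "k_in_free", "K_ii"))


@dataclass
class SubjectParameters:
    """Per-subject kinetic constants (the fitted quantities).

    Units: ``b_G``, ``V_1``, ``V_ii`` in g/L/h (maximal rates of the HGP and
    insulin-independent clearance terms); ``V_id`` in (g/L/h) per (mU/L) of
    insulin; ``K1_prime`` dimensionless; ``K_id`` g/L; ``k_degI``,
    ``k_degE``, ``k_in`` per hour; ``V_h`` litres.  ``hill_n`` is the Hill
    coefficient of the HGP response, fixed to 2 (estimating it would make
    the model strongly nonlinear in the parameter).
    """

    b_G: float = 0.0804
    V_1: float = 5.63
    K1_prime: float = 0.00501
    V_ii: float = 0.896
    V_id: float = 1.52
    K_id: float = 11.0
    k_degI: float = 30.5
    k_degE: float = 5.73
    k_in: float = 21.5
    V_h: float = 4.65
    hill_n: float = 2.0

    def __post_init__(self):
        _check_nonnegative(
            self,
            ("b_G", "V_1", "V_ii", "V_id", "K_id", "k_degI", "k_degE", "k_in", "V_h"),
        )
        if self.K1_prime <= 0:
            raise ValueError(f"K1_prime must be > 0, got {self.K1_prime}")


@dataclass(frozen=True)
class Protocol:
    """Infusion rates, distribution volumes and phase timing of the test.

    Infusions are zero for ``t < t_switch`` and the stated constants after.
    Two printed values exist for the glucagon distribution volume (9.6 and
    19.6 L); the default is 19.6 L, the only one consistent with the design
    goal of a 2–3-fold glucagon rise given k_degE ~ 5.7/h.
    """

    Q_G: float = 0.24       # g/h
    Q_I: float = 480.0      # mU/h
    Q_E: float = 4134.7     # pmol/h
    V_G: float = 4.44       # L
    V_I: float = 1.52       # L
    V_E: float = 19.6       # L
    t_switch: float = 3.0   # h
    t_end: float = 6.0      # h

    def __post_init__(self):
        for name in ("V_G", "V_I", "V_E"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.t_switch < self.t_end:
            raise ValueError("require 0 <= t_switch < t_end")

    def infusion_rates(self, t):
        """(Q_G, Q_I, Q_E) active at time(s) t (h)."""
        on = np.asarray(t) >= self.t_switch
        return (self.Q_G * on, self.Q_I * on, self.Q_E * on)


@dataclass
class BaselineState:
    """Steady state of the first 3 h (no infusion, basal secretion).

    Holds the basal concentrations, the basal receptor fractions and the
    basal hepatic glucose production rate.  The unfitted basal secretion
    rates F_I = k_degI*I_bar and F_E = k_degE*E_bar exist only in phase 1
    and are derived, never free.
    """

    G_bar: float
    I_bar: float
    E_bar: float
    r_bar: float
    re_bar: float
    Fhgp_bar: float

    def __post_init__(self):
        if not (0.0 <= self.r_bar <= 1.0 and 0.0 <= self.re_bar <= 1.0):
            raise ValueError("receptor fractions must lie in [0, 1]")
        if self.r_bar + self.re_bar > 1.0 + 1e-12:
            raise ValueError("r_bar + re_bar must not exceed 1")
        if self.Fhgp_bar <= 0:
            raise ValueError("Fhgp_bar must be > 0")

    def basal_secretion_rates(self, params: SubjectParameters):
        """Basal (F_I, F_E) balancing first-order hormone clearance."""
        return params.k_degI * self.I_bar, params.k_degE * self.E_bar


@dataclass
class SystemState:
    """Instantaneous state of the full system at time t (h)."""

    t: float
    G: float
    I: float
    E: float
    r: float
    r_e: float

    @property
    def r_i(self) -> float:
        """Internalized receptor fraction, by conservation."""
        return 1.0 - self.r - self.r_e


def _hill(r_e, V_1, K1_prime, n):
    """Glucagon-bound-receptor drive of HGP; no domain checks (internal)."""
    ren = r_e ** n
    return V_1 * ren / (K1_prime ** n + ren)


def _hill_deriv(r_e, V_1, K1_prime, n):
    ren = r_e ** n
    denom = (K1_prime ** n + ren) ** 2
    return V_1 * n * K1_prime ** n * r_e ** (n - 1.0) / denom


def hgp_rate(r_e, params: SubjectParameters):
    """Hepatic glucose production rate b_G + V_1 r_e^n / (K'1^n + r_e^n).

    Monotone non-decreasing in ``r_e`` and bounded by ``b_G + V_1``.
    Accepts scalars or arrays.
    """
    r_e = np.asarray(r_e, dtype=float)
    if np.any(r_e < 0):
        raise ValueError("r_e must be >= 0")
    if params.K1_prime <= 0:
        raise ValueError("K1_prime must be > 0")
    out = params.b_G + _hill(r_e, params.V_1, params.K1_prime, params.hill_n)
    return out if out.ndim else float(out)


def receptor_steady_state(E_bar, params: SubjectParameters, fixed: FixedKinetics):
    """Closed-form attracting steady state (r_bar, re_bar) at constant glucagon.

    For fixed glucagon concentration ``E_bar`` the linear receptor subsystem
    has a unique steady state; with no ligand and no free-receptor
    internalization all receptor sits free, (1, 0).
    """
    if E_bar < 0:
        raise ValueError("E_bar must be >= 0")
    a = fixed.k_on * params.V_h * E_bar  # binding rate k_on * E_h (1/h)
    denom = (fixed.k_in_free + fixed.k_rec) * (fixed.k_off + params.k_in) + (
        params.k_in + fixed.k_rec
    ) * a
    if denom == 0.0:
        raise DegenerateModelError("all receptor kinetic rates are zero")
    r_bar = (fixed.k_off + params.k_in) * fixed.k_rec / denom
    re_bar = fixed.k_rec * a / denom
    return r_bar, re_bar


def receptor_rhs(r, r_e, E, params: SubjectParameters, fixed: FixedKinetics):
    """Time derivatives (dr/dt, dr_e/dt) of the receptor fractions.

    The hepatic glucagon amount is E_h = V_h * E; conservation of total
    receptor is built in through the recycling term k_rec * (1 - r - r_e).
    """
    if np.any(np.asarray(E) < 0):
        raise ValueError("E must be >= 0")
    a = fixed.k_on * params.V_h * E
    dr = -a * r + fixed.k_off * r_e - fixed.k_in_free * r + fixed.k_rec * (1.0 - r - r_e)
    dre = a * r - fixed.k_off * r_e - params.k_in * r_e
    return dr, dre


def hormone_trajectory(t, baseline, Q, V, k_deg, t_switch=3.0):
    """Exact hormone concentration under the clamped challenge protocol.

    Before ``t_switch`` the concentration is the baseline; after it the
    turnover equation dC/dt = Q/V - k_deg*C relaxes exponentially to the
    infusion plateau C_inf = Q / (V * k_deg).  Continuous at the switch.
    """
    if k_deg <= 0 or V <= 0:
        raise ValueError("k_deg and V must be > 0")
    t = np.asarray(t, dtype=float)
    c_inf = Q / (V * k_deg)
    out = np.where(
        t < t_switch,
        baseline,
        c_inf + (baseline - c_inf) * np.exp(-k_deg * np.maximum(t - t_switch, 0.0)),
    )
    return out if out.ndim else float(out)


def _clearance(G, I, params: SubjectParameters, fixed: FixedKinetics):
    """Total glucose disposal rate Rd = ii-term + id-term (g/L/h)."""
    ii = params.V_ii * G / (fixed.K_ii + G)
    id_ = params.V_id * I * G / (params.K_id + G)
    return ii + id_


def glucose_rhs(G, I, r_e, params: SubjectParameters, protocol: Protocol,
                t, fixed: FixedKinetics = FixedKinetics()):
    """dG/dt: infusion + hepatic production − MM clearance (two routes).

    With the default K_ii = 0 the insulin-independent term degenerates to a
    constant V_ii for any G > 0 but is singular at G = 0, so non-positive
    glucose is rejected rather than floored.
    """
    if fixed.K_ii == 0.0 and np.any(np.asarray(G) <= 0):
        raise ValueError("G must be > 0 when K_ii = 0")
    q_g = protocol.infusion_rates(t)[0]
    return q_g / protocol.V_G + hgp_rate(r_e, params) - _clearance(G, I, params, fixed)


def system_rhs(y, t, params: SubjectParameters, protocol: Protocol,
               fixed: FixedKinetics = FixedKinetics(),
               baseline: "BaselineState | None" = None):
    """Stacked right-hand side of the full system, y = (G, I, E, r, r_e).

    During the challenge phase hormone states follow first-order turnover
    driven only by infusion (one-way coupling: hormones drive glucose and
    the receptor, never the reverse).  For ``t < t_switch`` the basal
    endogenous secretion rates, taken from ``baseline`` when supplied,
    exactly balance hormone clearance so the baseline state is a fixed
    point; the simulator never integrates this phase (it is a steady state
    by design).
    """
    G, I, E, r, r_e = y
    q_g, q_i, q_e = protocol.infusion_rates(t)
    dG = q_g / protocol.V_G + hgp_rate(max(r_e, 0.0), params) - _clearance(G, I, params, fixed)
    if fixed.K_ii == 0.0 and G <= 0:
        raise ValueError("G must be > 0 when K_ii = 0")
    f_i = f_e = 0.0
    if baseline is not None and t < protocol.t_switch:
        f_i, f_e = baseline.basal_secretion_rates(params)
    dI = q_i / protocol.V_I + f_i - params.k_degI * I
    dE = q_e / protocol.V_E + f_e - params.k_degE * E
    dr, dre = receptor_rhs(r, r_e, E, params, fixed)
    return np.array([dG, dI, dE, dr, dre])


def eliminate_baseline_params(baseline: BaselineState, params: SubjectParameters,
                              fixed: FixedKinetics = FixedKinetics()):
    """Solve the baseline balance for (b_G, V_ii) given the free parameters.

    The basal HGP rate must both equal production (b_G plus the Hill term at
    the basal bound fraction) and balance total clearance at the basal
    glucose and insulin levels; eliminating b_G and V_ii through these two
    relations keeps every candidate parameter vector consistent with the
    observed steady state.  A negative eliminated value is reported as a
    warning, not an error: it flags a parameter vector whose Hill term (or
    insulin-dependent clearance) already exceeds the basal rate.
    """
    if params.K_id + baseline.G_bar == 0:
        raise ValueError("K_id + G_bar must be nonzero")
    b_G = baseline.Fhgp_bar - _hill(
        baseline.re_bar, params.V_1, params.K1_prime, params.hill_n
    )
    id_term = params.V_id * baseline.I_bar * baseline.G_bar / (params.K_id + baseline.G_bar)
    V_ii = (baseline.Fhgp_bar - id_term) * (fixed.K_ii + baseline.G_bar) / baseline.G_bar
    if b_G < 0 or V_ii < 0:
        warnings.warn(
            f"eliminated baseline parameter negative (b_G={b_G:.4g}, V_ii={V_ii:.4g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return b_G, V_ii


def make_baseline(G_bar, I_bar, E_bar, params: SubjectParameters,
                  fixed: FixedKinetics = FixedKinetics(), Fhgp_bar=None) -> BaselineState:
    """Assemble a consistent BaselineState from basal concentrations.

    Receptor fractions come from the closed-form steady state at ``E_bar``;
    if ``Fhgp_bar`` is not supplied it is taken self-consistently from the
    model's own HGP rate at the basal bound fraction.
    """
    r_bar, re_bar = receptor_steady_state(E_bar, params, fixed)
    if Fhgp_bar is None:
        Fhgp_bar = float(hgp_rate(re_bar, params))
    return BaselineState(G_bar=G_bar, I_bar=I_bar, E_bar=E_bar,
                         r_bar=r_bar, re_bar=re_bar, Fhgp_bar=Fhgp_bar)


def apply_baseline_constraints(params: SubjectParameters, baseline: BaselineState,
                               fixed: FixedKinetics = FixedKinetics()) -> SubjectParameters:
    """Return a copy of ``params`` with (b_G, V_ii) replaced by the
    constraint-eliminated values for this baseline.

    Negative eliminated values are allowed through (with the warning from
    :func:`eliminate_baseline_params`): optimizers must be able to traverse
    such parameter vectors even though they are not physically admissible
    as a final answer.
    """
    import copy

    b_G, V_ii = eliminate_baseline_params(baseline, params, fixed)
    out = copy.copy(params)
    out.b_G = b_G
    out.V_ii = V_ii
    return out
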