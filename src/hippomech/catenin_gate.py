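"""Three-state force-dependent alpha-catenin gate at an adherens junction.

The cadherin-catenin complex (CCC) is modeled with three conformational
states of alpha-catenin:

* C1 — fully folded: only the N domain is exposed,
* C2 — the M1 subdomain is unfolded (M1 exposure inhibits Jub recruitment),
* C3 — the whole central modulatory domain (M1 together with M2/M3, which
  fold and unfold as one unit) is open.

Transitions follow a linear chain C1 <-> C2 <-> C3 with Bell-form rates:
unfolding is promoted by the per-molecule force f,

    ku_i(f) = ku_i0 * exp(+f * xu_i / kBT),

and refolding is suppressed,

    kf_i(f) = kf_i0 * exp(-f * xf_i / kBT),

where xu_i/xf_i are transition distances (nm) and kBT is the thermal energy
(pN nm).  Vinculin inhibits only the C2 -> C1 refolding step, which it does
through a saturating multiplier 1/(1 + V/KV) on kf_1; the C2 <-> C3
transition and Jub binding itself are Vinculin-independent.

Ajuba (Jub) docks on the N domain with a state-dependent affinity ordered
a3 > a1 > a2: the open C3 state binds best, the M1-exposed C2 state worst.
Competitive occupancy of a finite pool of Jub over N_cat catenin sites
produces the characteristic biphasic bound-Jub curve with a minimum at
intermediate forces, where C2 dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "BellParams",
    "CateninEnsemble",
    "bell_lifetime",
    "transition_rates",
    "equilibrium_occupancy",
    "relax",
    "bound_jub",
    "crossover_force",
]

#: Thermal energy at 25 degC, pN*nm.
KBT_DEFAULT = 4.1


@dataclass(frozen=True)
class BellParams:
    """Bell-model rate parameters for the two-step unfolding chain.

    The shipped defaults are calibrated so that, at zero Vinculin, the
    equilibrium C1-C2 crossover sits at 4.5 pN, the C2-C3 crossover at
    10 pN, and relaxation from the fully folded state near the first
    crossover settles in a few seconds.  With both transition distances
    set to 1 nm the crossover of transition i is at
    kBT*ln(kf_i0/ku_i0)/(xu_i + xf_i).
    """

    # transition 1: C1 <-> C2
    kf10: float = 0.3 * float(np.exp(9.0 / 4.1))   # 1/s, zero-force folding
    ku10: float = 0.3                               # 1/s, zero-force unfolding
    xf1: float = 1.0                                # nm
    xu1: float = 1.0                                # nm
    # transition 2: C2 <-> C3 (sharper: 2 nm transition distances)
    kf20: float = 0.03 * float(np.exp(40.0 / 4.1))  # 1/s
    ku20: float = 0.03                              # 1/s
    xf2: float = 2.0                                # nm
    xu2: float = 2.0                                # nm
    kBT: float = KBT_DEFAULT                        # pN*nm
    #: Vinculin half-inhibition scale for the C2->C1 refolding step.
    KV: float = 2.0
    # Legacy single-bond Bell lifetime parameters, exposed as a utility only.
    tau0: float = 1e-3                              # s
    E0: float = 20.0                                # pN*nm
    gamma: float = 1.0                              # nm

    def __post_init__(self) -> None:
        for name in ("kf10", "ku10", "xf1", "xu1", "kf20", "ku20", "xf2",
                     "xu2", "kBT", "KV", "tau0", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BellParams.{name} must be positive")


@dataclass
class CateninEnsemble:
    """Occupancy state of the catenin pool at one junctional node."""

    C1: float = 1.0
    C2: float = 0.0
    C3: float = 0.0
    n_cat: float = 30.0          # alpha-catenin molecules per node
    V: float = 0.0               # relative Vinculin level
    jub_pool: float = 80.0       # total Jub available to the node
    #: per-state Jub association constants (1/Jub-unit), ordered a3 > a1 > a2
    jub_affinity: tuple[float, float, float] = (0.012, 0.008, 0.09)

    def occupancies(self) -> np.ndarray:
        return np.array([self.C1, self.C2, self.C3])


def bell_lifetime(F: float, params: BellParams) -> float:
    """Bell bond lifetime tau0*exp((E0 - gamma*F)/kBT); strictly decreasing in F."""
    if F < 0:
        raise ValueError("force must be non-negative")
    return params.tau0 * np.exp((params.E0 - params.gamma * F) / params.kBT)


def transition_rates(f, params: BellParams, V: float = 0.0):
    """Force- and Vinculin-dependent rates (u1, f1, u2, f2) in 1/s.

    Vinculin multiplies only the C2->C1 refolding rate f1 by
    1/(1 + V/KV); u1, u2 and f2 are Vinculin-independent.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    if V < 0:
        raise ValueError("Vinculin level must be non-negative")
    u1 = params.ku10 * np.exp(f * params.xu1 / params.kBT)
    f1 = params.kf10 * np.exp(-f * params.xf1 / params.kBT) / (1.0 + V / params.KV)
    u2 = params.ku20 * np.exp(f * params.xu2 / params.kBT)
    f2 = params.kf20 * np.exp(-f * params.xf2 / params.kBT)
    return u1, f1, u2, f2


def equilibrium_occupancy(f, params: BellParams, V: float = 0.0) -> np.ndarray:
    """Equilibrium occupancies (C1, C2, C3) of the linear chain.

    Detailed balance on the chain gives C1:C2:C3 = 1 : u1/f1 : u1*u2/(f1*f2),
    normalized to sum to one.
    """
    u1, f1, u2, f2 = transition_rates(f, params, V)
    w1 = np.ones_like(np.asarray(f, dtype=float))
    w2 = u1 / f1
    w3 = w2 * u2 / f2
    total = w1 + w2 + w3
    return np.array([w1 / total, w2 / total, w3 / total])


def _kinetic_rhs(t, p, u1, f1, u2, f2):
    p1, p2, p3 = p
    return [-u1 * p1 + f1 * p2,
            u1 * p1 - (f1 + u2) * p2 + f2 * p3,
            u2 * p2 - f2 * p3]


def relax(f: float, params: BellParams, V: float = 0.0,
          initial=(1.0, 0.0, 0.0), horizon: float = 30.0, tol: float = 0.01):
    """Integrate the three-state kinetics and report the settling time.

    Settling is the first time after which every occupancy stays within
    ``tol`` (default 0.01, i.e. one percent of the total pool) of its
    analytic equilibrium value.  Returns ``(t, occupancies, settling_time,
    settled)``; if the horizon is too short the horizon itself is returned
    with ``settled=False``.
    """
    initial = np.asarray(initial, dtype=float)
    if abs(initial.sum() - 1.0) > 1e-9:
        raise ValueError("initial occupancies must sum to 1")
    u1, f1, u2, f2 = transition_rates(f, params, V)
    eq = equilibrium_occupancy(f, params, V)
    sol = solve_ivp(_kinetic_rhs, (0.0, horizon), initial,
                    args=(u1, f1, u2, f2), dense_output=True,
                    rtol=1e-10, atol=1e-12)
    t = np.linspace(0.0, horizon, max(2001, int(horizon * 400) + 1))
    traj = sol.sol(t)
    dev = np.abs(traj - eq[:, None]).max(axis=0)
    inside = dev <= tol
    # last excursion outside the tolerance band
    outside = np.nonzero(~inside)[0]
    if inside[-1] and (outside.size == 0 or outside[-1] < len(t) - 1):
        start = 0 if outside.size == 0 else outside[-1] + 1
        return t, traj, float(t[start]), True
    return t, traj, float(horizon), False


def bound_jub(f, params: BellParams, V: float = 0.0,
              jub_pool: float = 80.0, n_cat: float = 30.0,
              affinity=(0.012, 0.008, 0.09)):
    """Steady-state (bound, free) Jub at one node under per-molecule force f.

    Each of the ``n_cat`` catenin molecules offers one Jub site whose
    association constant depends on its conformational state
    (a1, a2, a3 with a3 > a1 > a2; C2 is the M1-exposed, inhibited state).
    The free level J solves the conservation law

        jub_pool = J + n_cat * sum_s C_s * a_s J / (1 + a_s J).

    Vinculin enters only through the occupancies.
    """
    if jub_pool < 0:
        raise ValueError("jub_pool must be non-negative")
    if jub_pool == 0:
        return 0.0, 0.0
    a = np.asarray(affinity, dtype=float)
    C = equilibrium_occupancy(f, params, V)

    def excess(J):
        theta = a * J / (1.0 + a * J)
        return J + n_cat * float(C @ theta) - jub_pool

    J = brentq(excess, 0.0, jub_pool, xtol=1e-12 * max(1.0, jub_pool))
    theta = a * J / (1.0 + a * J)
    bound = n_cat * float(C @ theta)
    return bound, J


def crossover_force(which: str, params: BellParams, V: float = 0.0,
                    bracket=(0.0, 50.0), xtol: float = 0.01) -> float:
    """Force at which two equilibrium occupancies are equal, by bisection.

    ``which`` selects the pair: ``"C1C2"`` (onset of M1 exposure) or
    ``"C2C3"`` (full unfolding).  Raises if the occupancy difference does
    not change sign inside the bracket.
    """
    pair = {"C1C2": (0, 1), "C2C3": (1, 2)}
    if which not in pair:
        raise ValueError(f"unknown crossover {which!r}; expected C1C2 or C2C3")
    i, j = pair[which]

    def diff(f):
        C = equilibrium_occupancy(f, params, V)
        return float(C[i] - C[j])

    lo, hi = bracket
    if diff(lo) * diff(hi) > 0:
        raise ValueError(f"no {which} crossover in bracket {bracket}")
    return float(brentq(diff, lo, hi, xtol=xtol * 0.1))
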