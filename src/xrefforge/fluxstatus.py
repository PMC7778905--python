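"""Flux-carrying status (A/a/b/B) of every reaction in a GSMN.

A reaction's status summarizes whether it can carry non-zero steady-state
flux under three progressively relaxed bound regimes:

* **A** — under the model's own bounds;
* **a** — after every boundary (exchange) reaction is made bi-directional;
* **b** — after *every* reaction is made bi-directional;
* **B** — never: the network topology (e.g. a dead-end metabolite) forces
  zero flux regardless of directionality.

Each regime is decided by a flux-variability variant: minimize and maximize
v_r over {v : S v = 0, bounds}; the reaction "carries flux" when the range
escapes a small tolerance band around zero.  Relaxation only enlarges the
feasible set, so status can only improve along A → a → b, and regimes are
evaluated lazily.

Status profiles computed before and after mapping a model to the unified
namespace are compared to verify that reconciliation preserves the model's
intrinsic properties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.optimize import linprog

from .exact import rational_rank

logger = logging.getLogger(__name__)

__all__ = [
    "Status",
    "Regime",
    "FluxProblem",
    "StatusProfile",
    "flux_range",
    "can_carry_flux",
    "classify_status",
    "status_profile",
    "conservation_check",
    "ConservationReport",
    "nullspace_flux_test",
    "problem_from_model",
]

DEFAULT_TOL = 1e-6
DEFAULT_BIG_M = 1000.0


class Status(Enum):
    A = "A"   # carries flux under original bounds
    a = "a"   # ... after boundary reactions are relaxed
    b = "b"   # ... after all reactions are relaxed
    B = "B"   # blocked by topology

    @property
    def capability(self) -> int:
        return {"A": 3, "a": 2, "b": 1, "B": 0}[self.value]


class Regime(Enum):
    ORIGINAL = "ORIGINAL"
    BOUNDARY_RELAXED = "BOUNDARY_RELAXED"
    ALL_RELAXED = "ALL_RELAXED"


_REGIME_OF_STATUS = {
    Status.A: Regime.ORIGINAL,
    Status.a: Regime.BOUNDARY_RELAXED,
    Status.b: Regime.ALL_RELAXED,
}


@dataclass
class FluxProblem:
    """Steady-state flux polytope S v = 0, lb <= v <= ub."""

    S: np.ndarray                 # metabolites x reactions
    lb: np.ndarray
    ub: np.ndarray
    reaction_ids: list[str]
    boundary: frozenset[int]      # indices of boundary (exchange) reactions
    tol: float = DEFAULT_TOL
    big_m: float = DEFAULT_BIG_M

    def __post_init__(self) -> None:
        n = self.S.shape[1]
        if not (len(self.lb) == len(self.ub) == len(self.reaction_ids) == n):
            raise ValueError("inconsistent problem dimensions")
        if not self.boundary <= set(range(n)):
            raise ValueError("boundary set contains unknown reaction indices")
        # the status definition presumes v = 0 feasible; clamp bounds that
        # exclude it (e.g. forced maintenance fluxes) and warn
        lb, ub = np.asarray(self.lb, float).copy(), np.asarray(self.ub, float).copy()
        forced = (lb > 0) | (ub < 0)
        if forced.any():
            for i in np.flatnonzero(forced):
                logger.warning(
                    "bounds of reaction %s exclude zero flux; clamped for status computation",
                    self.reaction_ids[i],
                )
            lb = np.minimum(lb, 0.0)
            ub = np.maximum(ub, 0.0)
        self.lb = np.clip(lb, -self.big_m, self.big_m)
        self.ub = np.clip(ub, -self.big_m, self.big_m)

    def bounds_for(self, regime: Regime) -> tuple[np.ndarray, np.ndarray]:
        lb, ub = self.lb.copy(), self.ub.copy()
        if regime is Regime.BOUNDARY_RELAXED:
            idx = sorted(self.boundary)
            lb[idx], ub[idx] = -self.big_m, self.big_m
        elif regime is Regime.ALL_RELAXED:
            lb[:], ub[:] = -self.big_m, self.big_m
        return lb, ub


def _lp_extreme(problem: FluxProblem, r: int, lb, ub, sense: int) -> float:
    """Optimize sense * v_r over the polytope (sense=+1 min, -1 max)."""
    n = problem.S.shape[1]
    c = np.zeros(n)
    c[r] = sense
    res = linprog(
        c, A_eq=problem.S if problem.S.size else None,
        b_eq=np.zeros(problem.S.shape[0]) if problem.S.size else None,
        bounds=list(zip(lb, ub)), method="highs",
    )
    if not res.success:
        raise RuntimeError(
            f"LP failed for reaction {problem.reaction_ids[r]} (status {res.status}): {res.message}"
        )
    return sense * res.fun


def flux_range(problem: FluxProblem, r: int, regime: Regime = Regime.ORIGINAL) -> tuple[float, float]:
    """(min, max) steady-state flux of reaction r under a bound regime."""
    lb, ub = problem.bounds_for(regime)
    vmax = _lp_extreme(problem, r, lb, ub, -1)
    vmin = _lp_extreme(problem, r, lb, ub, +1)
    return vmin, vmax


def can_carry_flux(problem: FluxProblem, r: int, regime: Regime) -> bool:
    """Whether reaction r escapes the +-tol band around zero in a regime."""
    lb, ub = problem.bounds_for(regime)
    if _lp_extreme(problem, r, lb, ub, -1) > problem.tol:
        return True
    return _lp_extreme(problem, r, lb, ub, +1) < -problem.tol


def classify_status(problem: FluxProblem, r: int) -> Status:
    """A/a/b/B status of reaction r (regimes evaluated lazily)."""
    for status in (Status.A, Status.a, Status.b):
        if can_carry_flux(problem, r, _REGIME_OF_STATUS[status]):
            return status
    return Status.B


@dataclass
class StatusProfile:
    statuses: dict[str, Status]
    counts: dict[Status, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = {s: 0 for s in Status}
            for st in self.statuses.values():
                self.counts[st] += 1


def status_profile(problem: FluxProblem) -> StatusProfile:
    """Classify every reaction of the problem."""
    statuses = {
        rid: classify_status(problem, i) for i, rid in enumerate(problem.reaction_ids)
    }
    return StatusProfile(statuses)


@dataclass
class ConservationReport:
    pairs: dict[str, tuple[Status, Status]]
    changed: list[str]
    conserved: bool


def conservation_check(
    before: StatusProfile,
    after: StatusProfile,
    reaction_map: dict[str, str],
) -> ConservationReport:
    """Compare statuses across a mapping of one-to-one mapped reactions.

    ``reaction_map`` sends a reaction id of the *before* profile to its id
    in the *after* profile; the verdict is "conserved" iff no mapped
    reaction changed status.
    """
    pairs: dict[str, tuple[Status, Status]] = {}
    changed: list[str] = []
    for rid, mapped in sorted(reaction_map.items()):
        if rid not in before.statuses:
            raise KeyError(f"reaction {rid} not in the pre-mapping profile")
        if mapped not in after.statuses:
            raise KeyError(f"mapped reaction {mapped} not in the post-mapping profile")
        pair = (before.statuses[rid], after.statuses[mapped])
        pairs[rid] = pair
        if pair[0] != pair[1]:
            changed.append(rid)
    return ConservationReport(pairs=pairs, changed=changed, conserved=not changed)


def nullspace_flux_test(S, r: int) -> bool:
    """Exact oracle for the everything-reversible limit.

    True iff some v with S v = 0 has v_r != 0, decided in rational
    arithmetic: rank of S with the unit row e_r appended exceeds rank(S).
    Equivalent to "can carry flux under ALL_RELAXED" for any big-M > 0.
    """
    rows = [list(row) for row in S]
    n = len(rows[0]) if rows else r + 1
    base = rational_rank(rows)
    e = [0] * n
    e[r] = 1
    return rational_rank(rows + [e]) > base


def problem_from_model(model, tol: float = DEFAULT_TOL, big_m: float = DEFAULT_BIG_M) -> FluxProblem:
    """Build a FluxProblem from a gsmnmap Model.

    Boundary-flagged species are environment pools and contribute no mass-
    balance row.  A reaction is a boundary (exchange) reaction when one of
    its sides is empty or consists only of boundary species.
    """
    internal = [s.id for s in model.species if not s.boundary]
    row = {sid: i for i, sid in enumerate(internal)}
    boundary_species = {s.id for s in model.species if s.boundary}

    n = len(model.reactions)
    S = np.zeros((len(internal), n))
    lb = np.empty(n)
    ub = np.empty(n)
    boundary: set[int] = set()
    ids = []
    for j, rxn in enumerate(model.reactions):
        ids.append(rxn.id)
        lb[j], ub[j] = rxn.lower, rxn.upper
        for sign, side in ((-1, rxn.equation.left), (+1, rxn.equation.right)):
            for t in side:
                if t.met in row:
                    S[row[t.met], j] += sign * float(t.coeff)
        for side in (rxn.equation.left, rxn.equation.right):
            if not side or all(t.met in boundary_species for t in side):
                boundary.add(j)
                break
    return FluxProblem(
        S=S, lb=lb, ub=ub, reaction_ids=ids,
        boundary=frozenset(boundary), tol=tol, big_m=big_m,
    )
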