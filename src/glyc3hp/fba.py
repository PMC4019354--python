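"""Flux balance analysis: standard and lexicographic (two-stage) LP.

The model compiles to

    maximize    c' v
    subject to  S v = 0
                v_min <= v <= v_max

Growth simulations maximise the biomass flux.  Because the optimal flux
vector is generally degenerate, a production flux read from a single
growth optimum is not well defined; the two-stage solve removes the
degeneracy by re-optimising the production flux with the biomass flux
pinned at its optimum (relaxed by a factor 1e-6 for numerical safety).

The solver backend is abstracted behind one contract — matrix, bounds
and objective in; status, objective value and a point out — with
scipy's HiGHS simplex as the default for reproducible basic solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import Model, StoichiometricMatrix, build_stoichiometric_matrix

__all__ = [
    "FluxSolution",
    "InfeasibleError",
    "solve_fba",
    "solve_lexicographic",
    "LP_FEASIBILITY_TOL",
    "REPORTING_TOL",
    "ZERO_FLUX_TOL",
]

# LP hygiene: feasibility tolerance for the solver, a looser reporting
# tolerance for steady-state/bound checks, and a threshold below which a
# flux is reported as zero in tables (suppresses spurious "byproducts").
LP_FEASIBILITY_TOL = 1e-9
REPORTING_TOL = 1e-6
ZERO_FLUX_TOL = 1e-7

# relative relaxation of the primary optimum when it is fixed in stage 2
LEXICOGRAPHIC_RELAXATION = 1e-6


class InfeasibleError(RuntimeError):
    """Raised when an LP required to be solvable is infeasible/unbounded."""


@dataclass
class FluxSolution:
    """One optimal solution of an FBA linear program.

    ``objective_value`` is unique even when the flux vector is not.  For
    lexicographic solves, ``primary_value`` holds the stage-1 optimum and
    ``objective_value`` the stage-2 (secondary) optimum.
    """

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float
    fluxes: Dict[str, float]
    objective_id: str
    primary_id: Optional[str] = None
    primary_value: Optional[float] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def max_steady_state_violation(self, matrix: StoichiometricMatrix) -> float:
        v = np.array([self.fluxes[rid] for rid in matrix.col_index])
        return float(np.abs(matrix.S @ v).max()) if len(v) else 0.0


def _solve_highs(
    c: np.ndarray,
    S: sparse.csc_matrix,
    bounds: Sequence[Tuple[float, float]],
) -> Tuple[str, float, Optional[np.ndarray]]:
    """Default backend: maximise c'v s.t. Sv=0 via scipy HiGHS (dual simplex)."""
    res = linprog(
        -c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(bounds),
        method="highs-ds",
        options={"primal_feasibility_tolerance": LP_FEASIBILITY_TOL},
    )
    if res.status == 0:
        return "optimal", -float(res.fun), np.asarray(res.x)
    if res.status == 2:
        return "infeasible", float("nan"), None
    if res.status == 3:
        return "unbounded", float("nan"), None
    raise RuntimeError(f"LP solver failed: {res.message}")


Backend = Callable[
    [np.ndarray, sparse.csc_matrix, Sequence[Tuple[float, float]]],
    Tuple[str, float, Optional[np.ndarray]],
]


def _model_lp(model: Model):
    matrix = build_stoichiometric_matrix(model)
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    return matrix, bounds


def _objective_vector(matrix: StoichiometricMatrix, objective: str, sense: str):
    if objective not in matrix.col_index:
        raise KeyError(f"objective reaction {objective!r} not in model")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    c = np.zeros(len(matrix.col_index))
    c[matrix.col_index[objective]] = 1.0 if sense == "max" else -1.0
    return c


def _finish(
    matrix: StoichiometricMatrix,
    status: str,
    value: float,
    x: Optional[np.ndarray],
    objective: str,
    sense: str,
) -> FluxSolution:
    if status != "optimal":
        return FluxSolution(
            status=status, objective_value=float("nan"), fluxes={}, objective_id=objective
        )
    signed = value if sense == "max" else -value
    fluxes = {rid: float(x[j]) for rid, j in matrix.col_index.items()}
    return FluxSolution(
        status=status,
        objective_value=signed,
        fluxes=fluxes,
        objective_id=objective,
    )


def solve_fba(
    model: Model,
    objective: Optional[str] = None,
    sense: str = "max",
    backend: Backend = _solve_highs,
) -> FluxSolution:
    """Solve one FBA LP for ``model``.

    ``objective`` defaults to the model's biomass reaction.  Infeasible
    and unbounded problems are reported through ``status`` — never as a
    silently zero solution.
    """
    if objective is None:
        objective = model.biomass_reaction.id
    matrix, bounds = _model_lp(model)
    c = _objective_vector(matrix, objective, sense)
    status, value, x = backend(c, matrix.S, bounds)
    return _finish(matrix, status, value, x, objective, sense)


def solve_lexicographic(
    model: Model,
    primary: Optional[str] = None,
    secondary: Optional[str] = None,
    backend: Backend = _solve_highs,
) -> FluxSolution:
    """Two-stage solve: maximise ``primary``, pin it, maximise ``secondary``.

    Stage 1 maximises the primary objective (biomass by default) to z*.
    Stage 2 maximises the secondary objective subject to
    v_primary >= z* (1 - 1e-6), which removes the degeneracy of the
    secondary flux at the growth optimum.  Stage-1 infeasibility
    propagates in ``status``.
    """
    if primary is None:
        primary = model.biomass_reaction.id
    if secondary is None:
        raise ValueError("lexicographic solve requires a secondary objective")
    matrix, bounds = _model_lp(model)
    c1 = _objective_vector(matrix, primary, "max")
    status, z_star, x = backend(c1, matrix.S, bounds)
    if status != "optimal":
        return FluxSolution(
            status=status,
            objective_value=float("nan"),
            fluxes={},
            objective_id=secondary,
            primary_id=primary,
        )
    j = matrix.col_index[primary]
    floor = z_star - abs(z_star) * LEXICOGRAPHIC_RELAXATION
    bounds2 = list(bounds)
    bounds2[j] = (max(bounds2[j][0], floor), bounds2[j][1])
    c2 = _objective_vector(matrix, secondary, "max")
    status2, value2, x2 = backend(c2, matrix.S, bounds2)
    if status2 != "optimal":  # should not happen: stage-1 point is feasible
        raise InfeasibleError(
            f"stage 2 ({secondary}) reported {status2} although stage 1 was optimal"
        )
    solution = _finish(matrix, status2, value2, x2, secondary, "max")
    solution.primary_id = primary
    solution.primary_value = float(z_star)
    return solution
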