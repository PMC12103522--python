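"""Growth-rate-parameterized stoichiometric models and their LP machinery.

A metabolism-and-expression (ME) model couples metabolic fluxes to the cost
of expressing the catalytic machinery.  Each stoichiometric coefficient is
affine in the growth rate ``mu``: an entry ``(metabolite, a, b)`` contributes
``a + b * mu`` to the column of its reaction.  Dilution of a species appears
as ``b = -1`` terms, enzyme usage as ``b = -1/k_eff`` (one unit of flux ties
up ``mu / k_eff`` units of enzyme against dilution).  At fixed ``mu`` the
model is an ordinary linear feasibility problem

    S(mu) . v = 0,   lb <= v <= ub,   v_growth = mu,

and the maximum growth rate is found by bisection on feasibility, which is
monotone non-increasing in ``mu`` for well-posed models.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

__all__ = [
    "Reaction",
    "MEModel",
    "GrowthSolution",
    "FVAResult",
    "ScanResult",
    "ModelValidationError",
    "SolverError",
    "BracketError",
    "NonMonotoneWarning",
    "DEFAULT_FEASIBILITY_TOL",
    "DEFAULT_BISECT_TOL",
    "DEFAULT_MU_TEST",
    "EXPRESSION_SUBSYSTEMS",
    "evaluate_stoichiometry",
    "is_feasible",
    "maximize_growth",
    "grid_max_growth",
    "flux_variability",
    "gene_essentiality",
    "substrate_scan",
    "strip_expression",
    "catalyzed_reaction_of",
]

#: LP feasibility tolerance (double precision; quad-precision solvers go to
#: 1e-16 but are not portably available and the toy models here are
#: well-conditioned).
DEFAULT_FEASIBILITY_TOL = 1e-9

#: Bisection convergence tolerance on mu, in 1/h.
DEFAULT_BISECT_TOL = 1e-6

#: Growth rate at which knockout feasibility is probed, in 1/h.
DEFAULT_MU_TEST = 1e-3

#: Subsystem labels treated as expression machinery (everything else is
#: metabolic).  Translation targets of genes are expression regardless.
EXPRESSION_SUBSYSTEMS = frozenset(
    {"translation", "transcription", "trna_charging", "complex_formation", "expression"}
)


class ModelValidationError(ValueError):
    """A model violates a structural invariant."""


class SolverError(RuntimeError):
    """The LP backend failed; carries the backend status message."""


class BracketError(ValueError):
    """The bisection bracket does not enclose the optimum."""


class NonMonotoneWarning(UserWarning):
    """Feasibility was observed to be non-monotone in mu."""


@dataclass
class Reaction:
    """A reaction with bounds and mu-affine stoichiometry.

    ``entries`` is a list of ``(metabolite_id, a, b)``: the coefficient of
    the metabolite at growth rate ``mu`` is ``a + b * mu``.
    """

    id: str
    lower_bound: float
    upper_bound: float
    entries: list[tuple[str, float, float]] = field(default_factory=list)
    subsystem: str = ""

    def coefficient(self, metabolite_id: str, mu: float) -> float:
        return sum(a + b * mu for m, a, b in self.entries if m == metabolite_id)


@dataclass
class MEModel:
    metabolite_ids: list[str]
    reactions: list[Reaction]
    genes: list[str] = field(default_factory=list)
    translation_of: dict[str, str] = field(default_factory=dict)
    growth_reaction_id: str = "BIOMASS"
    mu_max_hint: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------

    def reaction(self, reaction_id: str) -> Reaction:
        for rxn in self.reactions:
            if rxn.id == reaction_id:
                return rxn
        raise KeyError(f"unknown reaction: {reaction_id!r}")

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def subsystem_of(self) -> dict[str, str]:
        return {r.id: r.subsystem for r in self.reactions}

    def exchange_reaction_ids(self) -> list[str]:
        """Boundary reactions: subsystem "exchange", touching exactly one
        metabolite with constant stoichiometry.  The convention is
        coefficient -1, so positive flux exports (secretes) the metabolite."""
        out = []
        for r in self.reactions:
            mets = {m for m, _, _ in r.entries}
            if (
                r.subsystem == "exchange"
                and len(mets) == 1
                and all(b == 0 for _, _, b in r.entries)
            ):
                out.append(r.id)
        return out

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.mu_max_hint <= 0:
            raise ModelValidationError("mu_max_hint must be > 0")
        ids = set(self.metabolite_ids)
        if len(ids) != len(self.metabolite_ids):
            raise ModelValidationError("duplicate metabolite ids")
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lower_bound > upper_bound"
                )
            for m, a, b in rxn.entries:
                if m not in ids:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {m!r}"
                    )
                if not (math.isfinite(a) and math.isfinite(b)):
                    raise ModelValidationError(
                        f"reaction {rxn.id!r}: non-finite coefficient for {m!r}"
                    )
        if self.growth_reaction_id not in seen:
            raise ModelValidationError(
                f"growth_reaction_id {self.growth_reaction_id!r} is not a reaction"
            )
        for gene, rid in self.translation_of.items():
            if rid not in seen:
                raise ModelValidationError(
                    f"gene {gene!r} maps to unknown translation reaction {rid!r}"
                )

    def copy(self) -> "MEModel":
        return copy.deepcopy(self)


@dataclass
class GrowthSolution:
    mu_star: float
    fluxes: dict[str, float]
    status: str  # "optimal" | "infeasible_at_floor"
    monotone_warning: bool = False


@dataclass
class FVAResult:
    """Per-reaction flux range at a fixed growth rate."""

    table: pd.DataFrame  # index reaction id; columns v_min, v_max, range
    mu: float

    def range_of(self, reaction_id: str) -> float:
        return float(self.table.loc[reaction_id, "range"])


@dataclass
class ScanResult:
    """Growth and secretion along an uptake-bound scan."""

    table: pd.DataFrame  # columns: uptake_bound, mu_star, one col per secretion
    exchange_id: str


# ---------------------------------------------------------------------------
# LP assembly


def evaluate_stoichiometry(model: MEModel, mu: float) -> sparse.csr_matrix:
    """Stoichiometric matrix S(mu), metabolites x reactions, at growth rate mu."""
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    met_index = {m: i for i, m in enumerate(model.metabolite_ids)}
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions):
        acc: dict[int, float] = {}
        for m, a, b in rxn.entries:
            try:
                i = met_index[m]
            except KeyError:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolite {m!r}"
                ) from None
            acc[i] = acc.get(i, 0.0) + a + b * mu
        for i, v in acc.items():
            rows.append(i)
            cols.append(j)
            vals.append(v)
    return sparse.csr_matrix(
        (vals, (rows, cols)),
        shape=(len(model.metabolite_ids), len(model.reactions)),
    )


def _bounds_at(model: MEModel, mu: float) -> list[tuple[float, float]]:
    bounds = []
    for rxn in model.reactions:
        if rxn.id == model.growth_reaction_id:
            bounds.append((mu, mu))
        else:
            bounds.append((rxn.lower_bound, rxn.upper_bound))
    return bounds


def _solve_at(
    model: MEModel,
    mu: float,
    tol: float,
    objective: np.ndarray | None = None,
    sense: int = 1,
):
    """Solve the fixed-mu LP.  Returns the scipy result; status 2 means
    infeasible, 0 optimal."""
    n = len(model.reactions)
    c = np.zeros(n) if objective is None else sense * objective
    S = evaluate_stoichiometry(model, mu)
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=_bounds_at(model, mu),
        method="highs",
        options={
            "primal_feasibility_tolerance": tol,
            "dual_feasibility_tolerance": tol,
        },
    )
    if res.status not in (0, 2):  # 2 = infeasible is an expected answer
        raise SolverError(f"LP backend failure (status {res.status}): {res.message}")
    return res


def is_feasible(model: MEModel, mu: float, tol: float = DEFAULT_FEASIBILITY_TOL) -> bool:
    """True iff {S(mu) v = 0, lb <= v <= ub, v_growth = mu} admits a point."""
    if mu < 0:
        raise ValueError(f"mu must be >= 0, got {mu}")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    growth = model.reaction(model.growth_reaction_id)
    if not (growth.lower_bound <= mu <= growth.upper_bound):
        return False
    return _solve_at(model, mu, tol).status == 0


def maximize_growth(
    model: MEModel,
    mu_lo: float = 0.0,
    mu_hi: float | None = None,
    bisect_tol: float = DEFAULT_BISECT_TOL,
    tol: float = DEFAULT_FEASIBILITY_TOL,
    check_monotone: bool = False,
) -> GrowthSolution:
    """Maximum feasible growth rate by bisection on LP feasibility.

    Assumes feasibility is monotone non-increasing in mu (true for the
    generated models); with ``check_monotone`` a coarse grid over the bracket
    is probed afterwards and a violation sets ``monotone_warning`` and emits
    :class:`NonMonotoneWarning`.
    """
    if mu_hi is None:
        mu_hi = model.mu_max_hint
    if not (0 <= mu_lo < mu_hi):
        raise ValueError(f"need 0 <= mu_lo < mu_hi, got {mu_lo}, {mu_hi}")
    if not is_feasible(model, mu_lo, tol):
        return GrowthSolution(mu_star=math.nan, fluxes={}, status="infeasible_at_floor")
    if is_feasible(model, mu_hi, tol):
        raise BracketError(
            f"model is feasible at mu_hi = {mu_hi}; raise mu_hi (mu_max_hint)"
        )
    lo, hi = mu_lo, mu_hi
    while hi - lo > bisect_tol:
        mid = 0.5 * (lo + hi)
        if is_feasible(model, mid, tol):
            lo = mid
        else:
            hi = mid
    res = _solve_at(model, lo, tol)
    if res.status != 0:  # pragma: no cover - lo was feasible moments ago
        raise SolverError("LP infeasible at certified mu_star")
    fluxes = dict(zip(model.reaction_ids, (float(v) for v in res.x)))
    flagged = False
    if check_monotone:
        feas = [is_feasible(model, m, tol) for m in np.linspace(mu_lo, mu_hi, 9)]
        # once infeasible, must stay infeasible
        if any(not a and b for a, b in zip(feas, feas[1:])):
            warnings.warn(
                "feasibility is non-monotone in mu over the bracket",
                NonMonotoneWarning,
            )
            flagged = True
    return GrowthSolution(
        mu_star=float(lo), fluxes=fluxes, status="optimal", monotone_warning=flagged
    )


def grid_max_growth(
    model: MEModel,
    step: float = 1e-4,
    mu_lo: float = 0.0,
    mu_hi: float | None = None,
    tol: float = DEFAULT_FEASIBILITY_TOL,
    coarse_step: float = 0.05,
) -> float:
    """Maximum feasible mu by exhaustive grid scan (bisection-free oracle).

    A coarse pass brackets the feasibility boundary, then every point of the
    fine ``step`` grid inside the bracketing interval is tested exhaustively.
    Returns the largest feasible grid point (``nan`` if mu_lo is infeasible).
    """
    if mu_hi is None:
        mu_hi = model.mu_max_hint
    if not is_feasible(model, mu_lo, tol):
        return math.nan
    coarse = np.arange(mu_lo, mu_hi + coarse_step, coarse_step)
    lo = mu_lo
    hi = mu_hi
    for m in coarse:
        if m > mu_hi:
            break
        if is_feasible(model, float(m), tol):
            lo = float(m)
        else:
            hi = float(m)
            break
    best = lo
    for m in np.arange(lo, min(hi, mu_hi) + step, step):
        if m > mu_hi:
            break
        if is_feasible(model, float(m), tol):
            best = float(m)
    return best


def flux_variability(
    model: MEModel,
    mu_star: float,
    tol: float = DEFAULT_FEASIBILITY_TOL,
) -> FVAResult:
    """Per-reaction flux min/max at fixed growth rate mu_star."""
    if not is_feasible(model, mu_star, tol):
        raise ValueError(f"model is infeasible at mu = {mu_star}")
    n = len(model.reactions)
    rows = []
    for j, rxn in enumerate(model.reactions):
        obj = np.zeros(n)
        obj[j] = 1.0
        lo = _solve_at(model, mu_star, tol, objective=obj, sense=+1)
        hi = _solve_at(model, mu_star, tol, objective=obj, sense=-1)
        if lo.status != 0 or hi.status != 0:
            raise SolverError(f"FVA subproblem infeasible for {rxn.id!r}")
        v_min, v_max = float(lo.x[j]), float(hi.x[j])
        rows.append((rxn.id, v_min, v_max, max(v_max - v_min, 0.0)))
    table = pd.DataFrame(rows, columns=["reaction", "v_min", "v_max", "range"])
    table = table.set_index("reaction")
    return FVAResult(table=table, mu=mu_star)


def gene_essentiality(
    model: MEModel,
    gene: str,
    mu_test: float = DEFAULT_MU_TEST,
    tol: float = DEFAULT_FEASIBILITY_TOL,
) -> bool:
    """Is ``gene`` essential?  Its translation reaction is closed (bounds set
    to zero) and feasibility is probed at ``mu_test``; the model is restored
    afterwards."""
    if gene not in model.translation_of:
        raise KeyError(f"gene {gene!r} has no translation reaction")
    rxn = model.reaction(model.translation_of[gene])
    saved = (rxn.lower_bound, rxn.upper_bound)
    try:
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
        return not is_feasible(model, mu_test, tol)
    finally:
        rxn.lower_bound, rxn.upper_bound = saved


def substrate_scan(
    model: MEModel,
    exchange_id: str,
    uptake_values: list[float],
    bisect_tol: float = DEFAULT_BISECT_TOL,
    tol: float = DEFAULT_FEASIBILITY_TOL,
) -> ScanResult:
    """Growth and by-product secretion as a function of the uptake bound.

    For each value ``u`` the exchange lower bound is set to ``-u`` (uptake
    magnitude) and growth is maximized; positive fluxes through the other
    exchange reactions are recorded as secretions.
    """
    if len(uptake_values) == 0:
        raise ValueError("uptake_values must be non-empty")
    ups = [float(u) for u in uptake_values]
    if any(u < 0 for u in ups) or any(b <= a for a, b in zip(ups, ups[1:])):
        raise ValueError("uptake_values must be nonnegative and strictly increasing")
    work = model.copy()
    ex = work.reaction(exchange_id)  # raises KeyError if absent
    secretion_ids = [r for r in work.exchange_reaction_ids() if r != exchange_id]
    rows = []
    for u in ups:
        ex.lower_bound = -u
        sol = maximize_growth(work, 0.0, None, bisect_tol=bisect_tol, tol=tol)
        mu = sol.mu_star if sol.status == "optimal" else math.nan
        row = {"uptake_bound": u, "mu_star": mu}
        for rid in secretion_ids:
            row[rid] = max(sol.fluxes.get(rid, 0.0), 0.0)
        rows.append(row)
    return ScanResult(table=pd.DataFrame(rows), exchange_id=exchange_id)


def catalyzed_reaction_of(model: MEModel, gene: str) -> str | None:
    """The reaction that consumes the protein translated from ``gene`` —
    its annotated functional home.  For machinery genes (e.g. the ribosomal
    protein, consumed by translation itself) this is an expression reaction."""
    tl = model.translation_of.get(gene)
    if tl is None:
        return None
    products = {m for m, a, _ in model.reaction(tl).entries if a > 0}
    for rxn in model.reactions:
        if rxn.id == tl:
            continue
        for m, a, b in rxn.entries:
            if m in products and (a < 0 or b < 0):
                return rxn.id
    return None


def strip_expression(
    model: MEModel,
    expression_subsystems: frozenset[str] = EXPRESSION_SUBSYSTEMS,
) -> MEModel:
    """Metabolism-only analog: drop expression reactions and all mu-dependent
    coupling terms, then drop orphaned (expression) metabolites.

    Reactions whose subsystem is in ``expression_subsystems``, and reactions
    that are translation targets, are removed; surviving reactions keep only
    their constant (``a``) stoichiometry.
    """
    translation_targets = set(model.translation_of.values())

    def is_expression(rxn: Reaction) -> bool:
        return rxn.subsystem in expression_subsystems or rxn.id in translation_targets

    growth = model.reaction(model.growth_reaction_id)
    if is_expression(growth):
        raise ModelValidationError("growth reaction is labeled as expression")
    kept = []
    for rxn in model.reactions:
        if is_expression(rxn):
            continue
        entries = [(m, a, 0.0) for m, a, b in rxn.entries if a != 0.0]
        kept.append(replace(copy.deepcopy(rxn), entries=entries))
    referenced = {m for rxn in kept for m, _, _ in rxn.entries}
    metabolites = [m for m in model.metabolite_ids if m in referenced]
    return MEModel(
        metabolite_ids=metabolites,
        reactions=kept,
        genes=[],
        translation_of={},
        growth_reaction_id=model.growth_reaction_id,
        mu_max_hint=model.mu_max_hint,
    )
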