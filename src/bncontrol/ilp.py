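"""Linear 0/1 encoding of Boolean-network fixed points, and a MILP backend.

The encoding linearises each node's truth table with one indicator variable
per input assignment.  Writing ``tau_1(x) = x`` and ``tau_0(x) = 1 - x`` for
the two literals over a binary variable, a node ``i`` with inputs
``(x_{i1}, ..., x_{ik})`` and table ``f_i`` gets, for every assignment
``b = (b_1, ..., b_k)`` with ``f_i(b) = 1``::

    x_{i,b} >= sum_j tau_{b_j}(x_{ij}) - (k - 1)
    x_{i,b} <= (1/k) sum_j tau_{b_j}(x_{ij})

and ``x_{i,b} = 0`` whenever ``f_i(b) = 0``; the node's value variable is
then pinched between ``sum_b x_{i,b}`` and ``(1/2^k) sum_b x_{i,b}``.  In any
feasible 0/1 solution the indicator ``x_{i,b}`` is 1 exactly when all input
literals match ``b`` and ``f_i(b) = 1``, so the feasible set of the whole
model projects onto precisely the fixed points of the network.

:class:`LinearModel` is a small solver-agnostic container (binary variables,
linear constraints, linear objective); :func:`solve` runs it through
``scipy.optimize.milp`` (the HiGHS solver), single-threaded and
deterministic.  Models export to LP text for debugging; note that the
bracketed variable names (``x[0]``, ``xind[0][01]``) are chosen for stable
diffs rather than strict LP-format identifier rules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .core import BooleanNetwork, State

__all__ = [
    "LinearModel",
    "SolveResult",
    "LinExpr",
    "tau",
    "encode_function_constraints",
    "build_detection_model",
    "solve",
    "state_from_assignment",
    "add_state_exclusion_cut",
    "enumerate_singleton_attractors_ilp",
]

_INF = math.inf


@dataclass(frozen=True)
class LinExpr:
    """A linear expression ``sum coeffs[v] * v + const`` over named binaries."""

    coeffs: Mapping[str, float]
    const: float = 0.0

    def __add__(self, other: "LinExpr") -> "LinExpr":
        c = dict(self.coeffs)
        for v, a in other.coeffs.items():
            c[v] = c.get(v, 0.0) + a
        return LinExpr(c, self.const + other.const)

    def evaluate(self, assignment: Mapping[str, int]) -> float:
        return self.const + sum(a * assignment[v] for v, a in self.coeffs.items())


def tau(b: int, var: str) -> LinExpr:
    """The literal transform: ``tau_1(x) = x``, ``tau_0(x) = 1 - x``."""
    if b not in (0, 1):
        raise ValueError("b must be 0 or 1")
    return LinExpr({var: 1.0}) if b == 1 else LinExpr({var: -1.0}, 1.0)


@dataclass
class SolveResult:
    """Outcome of a MILP solve.

    ``status`` is ``"optimal"``, ``"infeasible"`` or ``"limit"``; the variable
    assignment is present only for ``"optimal"``.
    """

    status: str
    objective: float | None = None
    assignment: dict[str, int] | None = None


class LinearModel:
    """Named binary variables, linear constraints, and a linear objective.

    The objective defaults to a constant (pure feasibility); use
    :meth:`set_objective` to optimise.  Constraints are two-sided
    ``lb <= expr <= ub`` rows with ``inf`` bounds where one side is absent.
    """

    def __init__(self, name: str = "model"):
        self.name = name
        self._vars: dict[str, int] = {}
        self._constraints: list[tuple[str, dict[str, float], float, float]] = []
        self.objective: dict[str, float] = {}
        self.objective_const: float = 0.0
        self.sense: str = "max"

    # -- building -----------------------------------------------------------
    @property
    def variables(self) -> list[str]:
        return list(self._vars)

    @property
    def num_variables(self) -> int:
        return len(self._vars)

    @property
    def num_constraints(self) -> int:
        return len(self._constraints)

    def add_binary(self, name: str) -> str:
        if name in self._vars:
            raise ValueError(f"variable {name!r} already declared")
        self._vars[name] = len(self._vars)
        return name

    def has_variable(self, name: str) -> bool:
        return name in self._vars

    def add_constraint(
        self,
        coeffs: Mapping[str, float],
        lb: float = -_INF,
        ub: float = _INF,
        name: str | None = None,
    ) -> None:
        for v in coeffs:
            if v not in self._vars:
                raise KeyError(f"constraint references undeclared variable {v!r}")
        if name is None:
            name = f"c{len(self._constraints)}"
        self._constraints.append((name, dict(coeffs), float(lb), float(ub)))

    def add_expr_constraint(
        self, expr: LinExpr, lb: float = -_INF, ub: float = _INF, name: str | None = None
    ) -> None:
        """Constrain ``lb <= expr <= ub`` (the constant is folded into the bounds)."""
        lo = lb - expr.const if lb != -_INF else -_INF
        hi = ub - expr.const if ub != _INF else _INF
        self.add_constraint(expr.coeffs, lo, hi, name=name)

    def fix(self, var: str, value: int) -> None:
        self.add_constraint({var: 1.0}, value, value, name=f"fix_{var}")

    def set_objective(
        self, coeffs: Mapping[str, float], sense: str = "max", const: float = 0.0
    ) -> None:
        if sense not in ("max", "min"):
            raise ValueError("sense must be 'max' or 'min'")
        for v in coeffs:
            if v not in self._vars:
                raise KeyError(f"objective references undeclared variable {v!r}")
        self.objective = dict(coeffs)
        self.objective_const = float(const)
        self.sense = sense

    # -- solving ------------------------------------------------------------
    def solve(self, time_limit: float | None = None) -> SolveResult:
        return solve(self, time_limit=time_limit)

    # -- export -------------------------------------------------------------
    def to_lp(self) -> str:
        """Render the model as LP-style text (for diffing and debugging)."""
        lines = [f"\\ {self.name}"]
        lines.append("Maximize" if self.sense == "max" else "Minimize")
        lines.append(" obj: " + _format_terms(self.objective, self.objective_const))
        lines.append("Subject To")
        for name, coeffs, lb, ub in self._constraints:
            body = _format_terms(coeffs, 0.0)
            if lb == ub:
                lines.append(f" {name}: {body} = {_fmt_num(lb)}")
            else:
                if lb != -_INF:
                    lines.append(f" {name}_lo: {body} >= {_fmt_num(lb)}")
                if ub != _INF:
                    lines.append(f" {name}_hi: {body} <= {_fmt_num(ub)}")
        lines.append("Binaries")
        for v in self._vars:
            lines.append(f" {v}")
        lines.append("End")
        return "\n".join(lines) + "\n"


def _fmt_num(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:.12g}"


def _format_terms(coeffs: Mapping[str, float], const: float) -> str:
    parts = []
    for v, a in coeffs.items():
        if a == 0:
            continue
        sign = "-" if a < 0 else ("+" if parts else "")
        mag = abs(a)
        coef = "" if mag == 1 else f"{_fmt_num(mag)} "
        parts.append(f"{sign} {coef}{v}".strip())
    if const or not parts:
        sign = "-" if const < 0 else ("+" if parts else "")
        parts.append(f"{sign} {_fmt_num(abs(const))}".strip())
    return " ".join(parts)


_STATUS_MAP = {0: "optimal", 1: "limit", 2: "infeasible", 3: "infeasible", 4: "limit"}
# HiGHS status 3 is "unbounded"; over pure binaries a model is never unbounded,
# so it can only be reported for an infeasible-or-unbounded presolve outcome.


def solve(model: LinearModel, time_limit: float | None = None) -> SolveResult:
    """Solve a :class:`LinearModel` with HiGHS via ``scipy.optimize.milp``."""
    nv = model.num_variables
    order = model._vars
    c = np.zeros(nv)
    for v, a in model.objective.items():
        c[order[v]] = a
    sign = -1.0 if model.sense == "max" else 1.0

    constraints = []
    if model._constraints:
        rows, cols, vals, lbs, ubs = [], [], [], [], []
        for r, (_, coeffs, lb, ub) in enumerate(model._constraints):
            for v, a in coeffs.items():
                rows.append(r)
                cols.append(order[v])
                vals.append(a)
            lbs.append(lb)
            ubs.append(ub)
        A = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(model._constraints), nv)
        )
        constraints = [LinearConstraint(A, np.array(lbs), np.array(ubs))]

    options = {"presolve": True}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        sign * c,
        constraints=constraints,
        integrality=np.ones(nv),
        bounds=Bounds(0, 1),
        options=options,
    )
    status = _STATUS_MAP.get(res.status, "limit")
    if status != "optimal":
        return SolveResult(status=status)
    assignment = {v: int(round(res.x[i])) for v, i in order.items()}
    objective = model.objective_const + sum(
        a * assignment[v] for v, a in model.objective.items()
    )
    return SolveResult(status="optimal", objective=objective, assignment=assignment)


# ---------------------------------------------------------------------------
# encoding
# ---------------------------------------------------------------------------

def _bstr(assignment: Sequence[int]) -> str:
    return "".join(str(b) for b in assignment)


def _assignments(k: int):
    """Big-endian input assignments 00..0 through 11..1, matching table order."""
    for idx in range(2**k):
        yield tuple((idx >> (k - 1 - j)) & 1 for j in range(k))


def encode_function_constraints(
    model: LinearModel,
    value_var: str,
    input_vars: Sequence[str],
    table: Sequence[int],
    indicator_base: str,
    integer_coefficients: bool = False,
) -> list[str]:
    """Add the truth-table encoding for one node.

    ``value_var`` is the node's (already declared) value variable;
    ``input_vars`` name the effective-state variables of its inputs.
    Indicator variables are declared as ``{indicator_base}[{bits}]``.  With
    ``integer_coefficients`` the fractional rows are multiplied through by
    ``k`` and ``2^k`` (identical feasible set over binaries).

    Returns the list of indicator variable names (empty for constant nodes,
    whose value variable is simply fixed to the table entry).
    """
    k = len(input_vars)
    if len(table) != 2**k:
        raise ValueError(f"table length {len(table)} != 2^{k}")
    if k == 0:
        model.fix(value_var, table[0])
        return []

    indicators = []
    for idx, b in enumerate(_assignments(k)):
        ind = model.add_binary(f"{indicator_base}[{_bstr(b)}]")
        indicators.append(ind)
        if table[idx] == 0:
            model.fix(ind, 0)
            continue
        tau_sum = tau(b[0], input_vars[0])
        for bj, xj in zip(b[1:], input_vars[1:]):
            tau_sum = tau_sum + tau(bj, xj)
        # ind >= sum tau - (k-1)
        lower = LinExpr({ind: 1.0}) + LinExpr(
            {v: -a for v, a in tau_sum.coeffs.items()}, -tau_sum.const
        )
        model.add_expr_constraint(lower, lb=-(k - 1))
        # ind <= (1/k) sum tau
        scale = float(k) if integer_coefficients else 1.0
        upper = LinExpr({ind: scale}) + LinExpr(
            {v: -(scale / k) * a for v, a in tau_sum.coeffs.items()},
            -(scale / k) * tau_sum.const,
        )
        model.add_expr_constraint(upper, ub=0.0)

    # value <= sum indicators ; value >= 2^-k sum indicators
    model.add_constraint(
        {value_var: 1.0, **{ind: -1.0 for ind in indicators}}, ub=0.0
    )
    scale = float(2**k) if integer_coefficients else 1.0
    model.add_constraint(
        {value_var: scale, **{ind: -scale / (2**k) for ind in indicators}}, lb=0.0
    )
    return indicators


def add_network_encoding(
    model: LinearModel,
    net: BooleanNetwork,
    value_prefix: str,
    input_prefix: str | None = None,
    indicator_prefix: str | None = None,
    integer_coefficients: bool = False,
) -> None:
    """Encode every node of ``net``.

    Value variables ``{value_prefix}[i]`` are declared if absent.  The
    encoding's input literals reference ``{input_prefix}[j]`` (defaults to the
    value variables themselves, which yields the plain fixed-point model);
    the control models pass a distinct effective-state prefix here.
    """
    if input_prefix is None:
        input_prefix = value_prefix
    if indicator_prefix is None:
        indicator_prefix = value_prefix + "ind"
    for i in range(net.n):
        v = f"{value_prefix}[{i}]"
        if not model.has_variable(v):
            model.add_binary(v)
    for j in range(net.n):
        iv = f"{input_prefix}[{j}]"
        if not model.has_variable(iv):
            model.add_binary(iv)
    for i in range(net.n):
        encode_function_constraints(
            model,
            value_var=f"{value_prefix}[{i}]",
            input_vars=[f"{input_prefix}[{j}]" for j in net.inputs[i]],
            table=net.tables[i],
            indicator_base=f"{indicator_prefix}[{i}]",
            integer_coefficients=integer_coefficients,
        )


def build_detection_model(
    net: BooleanNetwork,
    objective: Mapping[str, float] | None = None,
    sense: str = "max",
    integer_coefficients: bool = False,
) -> LinearModel:
    """The singleton-attractor detection model.

    Feasible assignments of the state variables ``x[i]`` are exactly the
    fixed points of ``net``.  Detection is a decision problem, so the default
    objective is constant (pure feasibility); any linear objective over the
    declared variables may be supplied instead.
    """
    model = LinearModel(name="attractor-detection")
    add_network_encoding(
        model, net, value_prefix="x", indicator_prefix="xind",
        integer_coefficients=integer_coefficients,
    )
    if objective is not None:
        model.set_objective(objective, sense=sense)
    return model


def state_from_assignment(
    assignment: Mapping[str, int], n: int, prefix: str = "x"
) -> State:
    return State(assignment[f"{prefix}[{i}]"] for i in range(n))


def add_state_exclusion_cut(
    model: LinearModel, s: State, prefix: str = "x"
) -> None:
    """Forbid one state: ``sum_{s_i=1} (1-x_i) + sum_{s_i=0} x_i >= 1``."""
    coeffs = {}
    ones = 0
    for i, b in enumerate(s):
        coeffs[f"{prefix}[{i}]"] = -1.0 if b else 1.0
        ones += b
    model.add_constraint(coeffs, lb=1 - ones)


def enumerate_singleton_attractors_ilp(
    net: BooleanNetwork, time_limit: float | None = None
) -> list[State]:
    """All fixed points, by repeated solving with state-exclusion cuts.

    Each solve either proves infeasibility (enumeration complete) or yields a
    new fixed point, which a no-good cut then removes.  Results sorted by
    bitstring.
    """
    model = build_detection_model(net)
    found: list[State] = []
    for _ in range(2**net.n + 1):
        res = solve(model, time_limit=time_limit)
        if res.status == "infeasible":
            return sorted(found, key=str)
        if res.status != "optimal":
            raise RuntimeError(f"solver returned status {res.status!r}")
        s = state_from_assignment(res.assignment, net.n)
        found.append(s)
        add_state_exclusion_cut(model, s)
    raise RuntimeError("exclusion-cut enumeration failed to terminate")
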