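"""Attractor-control problems over a cancer/normal network pair.

Three problems are solved with one machinery.  A control picks ``m`` nodes
and clamps each to 0 or 1, identically in both networks (an anti-cancer drug
acts on both cell types).  Writing ``w_i = 1`` for a controlled node and
``z_i`` for its clamped value:

* **SAC** (simultaneous attractor control): find a control whose *worst*
  joint singleton attractor still scores at least ``theta`` under the
  combined score ``h + g`` (cancer ON-reward plus normal OFF-reward).
* **ACDC**: guarantee substantial damage to the cancer network (some cancer
  attractor's damage score reaches ``xi1``) while maximising the minimum
  protection score of the normal network against ``theta1``.
* **ACKN**: guarantee the normal network stays protected (some normal
  attractor's protection score reaches ``xi2``) while maximising the minimum
  cancer score against ``theta2``.

The max-min structure is attacked in two phases per candidate control:

* **ILP-A** searches over controls and attractors simultaneously for the
  *maximum*-score solution (internal node values ``p_i``/``q_i`` are tied to
  the effective states ``x_i``/``s_i`` through ``w_i``, ``z_i`` by big-M-free
  pinching constraints).
* **ILP-A'** fixes the control found and computes the *minimum*-score
  attractor under it, by re-running the detection encoding on the clamped
  networks.
* **ILP-B** is ILP-A plus one *no-good cut* per already-examined control,
  each removing exactly that (node-set, value) combination.

The loop alternates the two phases, accepting when the minimum meets the
threshold, and declaring no solution when even the maximum falls below it
(the maximum is non-increasing as cuts accumulate, and every attractor's
minimum is bounded by it).

:func:`bruteforce_control_oracle` solves the same problems by exhaustive
enumeration of all ``C(n, m) * 2^m`` controls and all fixed points; it is
the ground truth the ILP path is validated against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core import (
    BooleanNetwork,
    ControlAssignment,
    State,
    apply_control,
    enumerate_singleton_attractors_bruteforce,
)
from .ilp import (
    LinearModel,
    SolveResult,
    add_network_encoding,
    solve,
    state_from_assignment,
)
from .scoring import ScoreConfig, score_cancer, score_normal

__all__ = [
    "ControlProblemSpec",
    "ControlSolution",
    "build_ilp_a",
    "build_ilp_a_prime",
    "add_exclusion_cut",
    "solve_sac",
    "solve_acdc",
    "solve_ackn",
    "solve_control",
    "bruteforce_control_oracle",
    "control_table",
]

Mode = Literal["SAC", "ACDC", "ACKN"]


@dataclass
class ControlProblemSpec:
    """An instance of one of the three control problems.

    Thresholds left as ``None`` take the calibrated defaults
    ``theta = 1.2 n`` and ``theta1 = xi1 = theta2 = xi2 = 0.6 n`` (tuned for
    unit score coefficients).  ``damage_coefficients`` selects the
    coefficient vector used in ACDC's damage constraint: ``"alpha"`` (the
    cancer-score coefficients; the default) or ``"gamma"``.
    """

    net1: BooleanNetwork
    net2: BooleanNetwork
    cfg: ScoreConfig
    m: int
    mode: Mode = "SAC"
    theta: float | None = None
    theta1: float | None = None
    xi1: float | None = None
    theta2: float | None = None
    xi2: float | None = None
    max_repeats: int = 20
    damage_coefficients: str = "alpha"
    time_limit: float | None = None
    integer_coefficients: bool = False

    def __post_init__(self):
        if self.net1.node_names != self.net2.node_names:
            raise ValueError("the two networks must share the same ordered node set")
        n = self.net1.n
        if self.cfg.n != n:
            raise ValueError("score coefficient length must equal the node count")
        if not 0 <= self.m <= n:
            raise ValueError(f"control budget m={self.m} out of range [0, {n}]")
        if self.mode not in ("SAC", "ACDC", "ACKN"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.max_repeats < 1:
            raise ValueError("max_repeats must be >= 1")
        if self.damage_coefficients not in ("alpha", "gamma"):
            raise ValueError("damage_coefficients must be 'alpha' or 'gamma'")
        if self.theta is None:
            self.theta = 1.2 * n
        if self.theta1 is None:
            self.theta1 = 0.6 * n
        if self.xi1 is None:
            self.xi1 = 0.6 * n
        if self.theta2 is None:
            self.theta2 = 0.6 * n
        if self.xi2 is None:
            self.xi2 = 0.6 * n

    @property
    def n(self) -> int:
        return self.net1.n

    @property
    def damage_vector(self) -> np.ndarray:
        return self.cfg.alpha if self.damage_coefficients == "alpha" else self.cfg.gamma


@dataclass
class ControlSolution:
    """Result of a control search.

    ``status`` is ``"found"`` (control meets the mode's min-score threshold),
    ``"none_exists"`` (proven that no control of size ``m`` works), or
    ``"repeat_limit"`` (undecided within ``max_repeats`` iterations).
    ``attractors`` holds the witness fixed points keyed by
    ``max_cancer`` / ``max_normal`` / ``min_cancer`` / ``min_normal``
    (the subset relevant to the mode).
    """

    status: str
    control: ControlAssignment | None = None
    attractors: dict[str, State] = field(default_factory=dict)
    max_score: float | None = None
    min_score: float | None = None
    iterations: int = 0

    def to_dict(self, node_names: tuple[str, ...] | None = None) -> dict:
        def name(i):
            return node_names[i] if node_names is not None else i

        return {
            "status": self.status,
            "control": (
                [[name(i), b] for i, b in self.control.pairs()]
                if self.control is not None
                else None
            ),
            "attractors": {k: str(v) for k, v in self.attractors.items()},
            "max_score": self.max_score,
            "min_score": self.min_score,
            "iterations": self.iterations,
        }


# ---------------------------------------------------------------------------
# model builders
# ---------------------------------------------------------------------------

def build_ilp_a(spec: ControlProblemSpec) -> LinearModel:
    """The max-phase model (ILP-A) for the given mode.

    Variables per node: effective states ``x[i]`` (cancer) and ``s[i]``
    (normal), internal function values ``p[i]``/``q[i]``, control indicators
    ``w[i]`` with clamped values ``z[i]``, and the linearisation helpers
    ``u[i]`` (ON, free, cancer) and ``r[i]`` (OFF, free, normal).  The
    control is shared between the two networks through the common ``w``/``z``.

    Mode differences: SAC maximises ``sum alpha_i u_i + gamma_i r_i``; ACDC
    adds the damage constraint ``sum d_i u_i >= xi1`` and maximises
    ``sum gamma_i r_i``; ACKN adds the protection constraint
    ``sum gamma_i r_i >= xi2`` and maximises ``sum alpha_i u_i``.
    """
    n = spec.n
    model = LinearModel(name=f"ILP-A[{spec.mode}]")
    for prefix in ("x", "s", "w", "z", "u", "r"):
        for i in range(n):
            model.add_binary(f"{prefix}[{i}]")
    # p/q are declared by the encodings
    add_network_encoding(
        model, spec.net1, value_prefix="p", input_prefix="x",
        indicator_prefix="xind", integer_coefficients=spec.integer_coefficients,
    )
    add_network_encoding(
        model, spec.net2, value_prefix="q", input_prefix="s",
        indicator_prefix="sind", integer_coefficients=spec.integer_coefficients,
    )
    for i in range(n):
        x, s, p, q = f"x[{i}]", f"s[{i}]", f"p[{i}]", f"q[{i}]"
        w, z, u, r = f"w[{i}]", f"z[{i}]", f"u[{i}]", f"r[{i}]"
        # x_i = p_i if w_i = 0, else z_i  (and the same for s_i with q_i)
        model.add_constraint({x: 1, p: -1, w: 1}, lb=0)    # x >= p - w
        model.add_constraint({x: 1, p: -1, w: -1}, ub=0)   # x <= p + w
        model.add_constraint({x: 1, z: -1, w: -1}, lb=-1)  # x >= z + w - 1
        model.add_constraint({x: 1, z: -1, w: 1}, ub=1)    # x <= z - w + 1
        model.add_constraint({s: 1, q: -1, w: 1}, lb=0)
        model.add_constraint({s: 1, q: -1, w: -1}, ub=0)
        model.add_constraint({s: 1, z: -1, w: -1}, lb=-1)
        model.add_constraint({s: 1, z: -1, w: 1}, ub=1)
        # u_i = AND(x_i, not w_i), r_i = AND(not s_i, not w_i) (upper halves;
        # maximisation pushes them up, the mode constraints never push down)
        model.add_constraint({u: 1, x: -1}, ub=0)
        model.add_constraint({u: 1, w: 1}, ub=1)
        model.add_constraint({r: 1, s: 1}, ub=1)
        model.add_constraint({r: 1, w: 1}, ub=1)
    model.add_constraint({f"w[{i}]": 1.0 for i in range(n)}, lb=spec.m, ub=spec.m)

    alpha, gamma = spec.cfg.alpha, spec.cfg.gamma
    if spec.mode == "SAC":
        obj = {f"u[{i}]": float(alpha[i]) for i in range(n)}
        for i in range(n):
            obj[f"r[{i}]"] = obj.get(f"r[{i}]", 0.0) + float(gamma[i])
        model.set_objective(obj, sense="max")
    elif spec.mode == "ACDC":
        d = spec.damage_vector
        model.add_constraint(
            {f"u[{i}]": float(d[i]) for i in range(n)}, lb=spec.xi1,
            name="damage",
        )
        model.set_objective(
            {f"r[{i}]": float(gamma[i]) for i in range(n)}, sense="max"
        )
    else:  # ACKN
        model.add_constraint(
            {f"r[{i}]": float(gamma[i]) for i in range(n)}, lb=spec.xi2,
            name="protection",
        )
        model.set_objective(
            {f"u[{i}]": float(alpha[i]) for i in range(n)}, sense="max"
        )
    return model


def build_ilp_a_prime(
    spec: ControlProblemSpec, control: ControlAssignment
) -> LinearModel:
    """The min-phase model (ILP-A') under a fixed control.

    The control is substituted in (each clamped node's function is replaced
    by its constant), and the minimum attractor score over the free nodes is
    sought.  SAC keeps both networks and minimises
    ``sum_{i not in I} alpha_i x_i + gamma_i (1 - s_i)``; ACDC keeps only the
    normal network, minimising ``sum gamma_i (1 - s_i)``; ACKN keeps only the
    cancer network, minimising ``sum alpha_i x_i``.
    """
    n = spec.n
    free = [i for i in range(n) if i not in control.values]
    model = LinearModel(name=f"ILP-Aprime[{spec.mode}]")
    obj: dict[str, float] = {}
    const = 0.0
    if spec.mode in ("SAC", "ACKN"):
        add_network_encoding(
            model, apply_control(spec.net1, control), value_prefix="x",
            indicator_prefix="xind",
            integer_coefficients=spec.integer_coefficients,
        )
        for i in free:
            obj[f"x[{i}]"] = float(spec.cfg.alpha[i])
    if spec.mode in ("SAC", "ACDC"):
        add_network_encoding(
            model, apply_control(spec.net2, control), value_prefix="s",
            indicator_prefix="sind",
            integer_coefficients=spec.integer_coefficients,
        )
        for i in free:
            obj[f"s[{i}]"] = -float(spec.cfg.gamma[i])
            const += float(spec.cfg.gamma[i])
    model.set_objective(obj, sense="min", const=const)
    return model


def add_exclusion_cut(model: LinearModel, previous: ControlAssignment) -> None:
    """No-good cut removing one already-examined control ``(V', B')``.

    Adds ``sum_{i in I} [ b_i=1 : -z_i - w_i | b_i=0 : z_i - w_i ]
    >= 1 - sum_{i in I} (1 + b_i)``.  The only 0/1 assignment it forbids is
    ``w_i = 1 and z_i = b_i`` for all ``i in I``: the previous control,
    re-selected with the same values.
    """
    coeffs: dict[str, float] = {}
    rhs = 1.0
    for i, b in previous.values.items():
        coeffs[f"z[{i}]"] = -1.0 if b == 1 else 1.0
        coeffs[f"w[{i}]"] = -1.0
        rhs -= 1 + b
    model.add_constraint(coeffs, lb=rhs)


# ---------------------------------------------------------------------------
# the repeat loop
# ---------------------------------------------------------------------------

def _accepts(spec: ControlProblemSpec, min_score: float) -> bool:
    # Acceptance follows each algorithm's wording: "no less than" for SAC
    # and ACKN, strictly "greater than" for ACDC.
    if spec.mode == "SAC":
        return min_score >= spec.theta
    if spec.mode == "ACDC":
        return min_score > spec.theta1
    return min_score >= spec.theta2


def _max_phase_viable(spec: ControlProblemSpec, max_score: float) -> bool:
    # Every attractor's min score is bounded by the current max-phase optimum,
    # which is non-increasing under cuts; once it cannot meet the acceptance
    # threshold, no remaining control can either.
    if spec.mode == "SAC":
        return max_score >= spec.theta
    if spec.mode == "ACDC":
        return max_score > spec.theta1
    return max_score >= spec.theta2


def _extract_control(assignment: dict[str, int], n: int) -> ControlAssignment:
    pairs = [(i, assignment[f"z[{i}]"]) for i in range(n) if assignment[f"w[{i}]"] == 1]
    return ControlAssignment.from_pairs(pairs)


def solve_control(spec: ControlProblemSpec) -> ControlSolution:
    """The two-phase repeat algorithm, shared by all three modes.

    Each iteration solves ILP-B (ILP-A plus the accumulated exclusion cuts)
    for the best remaining control, then ILP-A' for that control's worst
    attractor.  Accept when the worst meets the threshold; stop with
    ``none_exists`` when even the best cannot; otherwise cut the control out
    and repeat, up to ``max_repeats`` iterations.
    """
    n = spec.n
    base = build_ilp_a(spec)
    for it in range(1, spec.max_repeats + 1):
        res = solve(base, time_limit=spec.time_limit)
        if res.status == "infeasible":
            return ControlSolution(status="none_exists", iterations=it)
        if res.status != "optimal":
            raise RuntimeError(f"max-phase solver status {res.status!r}")
        max_score = res.objective
        if not _max_phase_viable(spec, max_score):
            return ControlSolution(
                status="none_exists", max_score=max_score, iterations=it
            )
        control = _extract_control(res.assignment, n)
        attractors = {
            "max_cancer": state_from_assignment(res.assignment, n, "x"),
            "max_normal": state_from_assignment(res.assignment, n, "s"),
        }
        mres = solve(build_ilp_a_prime(spec, control), time_limit=spec.time_limit)
        if mres.status != "optimal":
            raise RuntimeError(f"min-phase solver status {mres.status!r}")
        min_score = mres.objective
        if _accepts(spec, min_score):
            if spec.mode in ("SAC", "ACKN"):
                attractors["min_cancer"] = state_from_assignment(
                    mres.assignment, n, "x"
                )
            if spec.mode in ("SAC", "ACDC"):
                attractors["min_normal"] = state_from_assignment(
                    mres.assignment, n, "s"
                )
            return ControlSolution(
                status="found",
                control=control,
                attractors=attractors,
                max_score=max_score,
                min_score=min_score,
                iterations=it,
            )
        add_exclusion_cut(base, control)
    return ControlSolution(status="repeat_limit", iterations=spec.max_repeats)


def solve_sac(spec: ControlProblemSpec) -> ControlSolution:
    if spec.mode != "SAC":
        raise ValueError("spec.mode must be 'SAC'")
    return solve_control(spec)


def solve_acdc(spec: ControlProblemSpec) -> ControlSolution:
    if spec.mode != "ACDC":
        raise ValueError("spec.mode must be 'ACDC'")
    return solve_control(spec)


def solve_ackn(spec: ControlProblemSpec) -> ControlSolution:
    if spec.mode != "ACKN":
        raise ValueError("spec.mode must be 'ACKN'")
    return solve_control(spec)


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

def _iter_controls(n: int, m: int):
    for idxs in itertools.combinations(range(n), m):
        for bits in itertools.product((0, 1), repeat=m):
            yield ControlAssignment.from_pairs(zip(idxs, bits))


def _coeff_score(coeffs: np.ndarray, s: State, c: ControlAssignment, on: bool) -> float:
    total = 0.0
    for i, b in enumerate(s):
        if i in c.values:
            continue
        total += coeffs[i] * (b if on else 1 - b)
    return float(total)


def control_table(spec: ControlProblemSpec, limit_n: int = 12) -> list[dict]:
    """Per-control exhaustive statistics (the oracle's raw material).

    One record per control: whether the mode's max phase is feasible for it,
    its max and min attractor scores, and whether it qualifies (min phase
    meets the threshold).  Guarded to small ``n``.
    """
    if spec.n > limit_n:
        raise ValueError(f"n={spec.n} exceeds the exhaustive-oracle guard {limit_n}")
    records = []
    for c in _iter_controls(spec.n, spec.m):
        fps1 = enumerate_singleton_attractors_bruteforce(apply_control(spec.net1, c))
        fps2 = enumerate_singleton_attractors_bruteforce(apply_control(spec.net2, c))
        rec = {"control": c, "feasible": False, "max_score": None, "min_score": None,
               "qualifies": False}
        if spec.mode == "SAC":
            if fps1 and fps2:
                h = [score_cancer(spec.cfg, a, c) for a in fps1]
                g = [score_normal(spec.cfg, a, c) for a in fps2]
                rec.update(
                    feasible=True,
                    max_score=max(h) + max(g),
                    min_score=min(h) + min(g),
                )
        elif spec.mode == "ACDC":
            d = spec.damage_vector
            damaged = any(
                _coeff_score(d, a, c, on=True) >= spec.xi1 for a in fps1
            )
            if damaged and fps2:
                g = [score_normal(spec.cfg, a, c) for a in fps2]
                rec.update(feasible=True, max_score=max(g), min_score=min(g))
        else:  # ACKN
            protected = any(
                score_normal(spec.cfg, a, c) >= spec.xi2 for a in fps2
            )
            if protected and fps1:
                h = [score_cancer(spec.cfg, a, c) for a in fps1]
                rec.update(feasible=True, max_score=max(h), min_score=min(h))
        if rec["feasible"]:
            rec["qualifies"] = _accepts(spec, rec["min_score"])
        records.append(rec)
    return records


def bruteforce_control_oracle(
    spec: ControlProblemSpec, limit_n: int = 12
) -> ControlSolution:
    """Exhaustive-search solution of the control problem (ground truth).

    Mirrors the iterative algorithm's semantics: controls are examined in
    decreasing max-phase score, the first qualifying one is returned.  When
    several controls tie on the max-phase score the iterative solver's choice
    among them is solver-dependent; the oracle breaks such ties by control
    identity, so comparisons against it should be on status and scores.
    """
    records = control_table(spec, limit_n=limit_n)
    feasible = [r for r in records if r["feasible"]]
    qualifying = [r for r in feasible if r["qualifies"]]
    if qualifying:
        best = max(
            qualifying, key=lambda r: (r["max_score"], tuple(r["control"].pairs()))
        )
        n_better = sum(
            1
            for r in feasible
            if not r["qualifies"] and r["max_score"] > best["max_score"]
        )
        if n_better + 1 <= spec.max_repeats:
            return ControlSolution(
                status="found",
                control=best["control"],
                max_score=best["max_score"],
                min_score=best["min_score"],
                iterations=n_better + 1,
            )
        return ControlSolution(status="repeat_limit", iterations=spec.max_repeats)
    n_above = sum(1 for r in feasible if _max_phase_viable(spec, r["max_score"]))
    if n_above < spec.max_repeats:
        return ControlSolution(status="none_exists", iterations=n_above + 1)
    return ControlSolution(status="repeat_limit", iterations=spec.max_repeats)
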