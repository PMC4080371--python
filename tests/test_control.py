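import itertools

import numpy as np
import pytest

from bncontrol import (
    BooleanNetwork,
    ControlAssignment,
    ControlProblemSpec,
    ScoreConfig,
    State,
    add_exclusion_cut,
    apply_control,
    bruteforce_control_oracle,
    build_ilp_a,
    build_ilp_a_prime,
    is_singleton_attractor,
    score_cancer,
    score_normal,
    solve,
    solve_acdc,
    solve_ackn,
    solve_control,
    solve_sac,
)
from bncontrol.generate import GeneratorConfig, random_bn_pair

from conftest import assert_control_matches_oracle


def identity_net(n):
    return BooleanNetwork(
        tuple(f"v{i}" for i in range(n)),
        tuple((i,) for i in range(n)),
        tuple((0, 1) for _ in range(n)),
    )


def constant_net(n, bit):
    return BooleanNetwork(
        tuple(f"v{i}" for i in range(n)), tuple(() for _ in range(n)),
        tuple((bit,) for _ in range(n)),
    )


def single_net_spec(net, alpha, m, **kw):
    """The single-network reduction: SAC with gamma = 0 and N2 = N1."""
    cfg = ScoreConfig(np.asarray(alpha, float), np.zeros(net.n))
    return ControlProblemSpec(net1=net, net2=net, cfg=cfg, m=m, mode="SAC", **kw)


# ---------------------------------------------------------------------------
# ILP-A (max phase)
# ---------------------------------------------------------------------------

def test_ilp_a_maximum_on_worked_example(toy_net):
    spec = single_net_spec(toy_net, [1, 2, 3], m=1, theta=0)
    res = solve(build_ilp_a(spec))
    assert res.status == "optimal"
    # best single-node control is (v2, 0) whose attractor 101 scores 4
    assert res.objective == 4
    assert res.assignment["w[1]"] == 1 and res.assignment["z[1]"] == 0


def test_ilp_a_infeasible_without_any_attractor():
    negation = BooleanNetwork(("v1", "v2"), ((0,), (1,)), ((1, 0), (1, 0)))
    spec = ControlProblemSpec(
        net1=negation, net2=negation, cfg=ScoreConfig.uniform(2), m=0, mode="SAC"
    )
    assert solve(build_ilp_a(spec)).status == "infeasible"


@pytest.mark.parametrize("seed", range(8))
def test_ilp_a_optimum_matches_exhaustive_max(seed):
    """ILP-A equals the brute-force max over all controls and joint attractors."""
    from bncontrol.control import control_table

    net1, net2 = random_bn_pair(GeneratorConfig(n=6, K=2, seed=seed))
    spec = ControlProblemSpec(
        net1=net1, net2=net2, cfg=ScoreConfig.uniform(6), m=2, mode="SAC"
    )
    feasible = [r["max_score"] for r in control_table(spec) if r["feasible"]]
    res = solve(build_ilp_a(spec))
    if not feasible:
        assert res.status == "infeasible"
    else:
        assert res.status == "optimal" and res.objective == pytest.approx(max(feasible))


# ---------------------------------------------------------------------------
# ILP-A' (min phase)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pairs,expected_min", [([(1, 0)], 0.0), ([(0, 1)], 3.0)]
)
def test_ilp_a_prime_minimum_on_worked_example(toy_net, pairs, expected_min):
    spec = single_net_spec(toy_net, [1, 2, 3], m=1, theta=0)
    res = solve(build_ilp_a_prime(spec, ControlAssignment.from_pairs(pairs)))
    assert res.status == "optimal" and res.objective == expected_min


def test_ilp_a_prime_full_clamp_min_equals_max(toy_net):
    spec = single_net_spec(toy_net, [1, 2, 3], m=3, theta=0)
    control = ControlAssignment.from_pairs([(0, 1), (1, 1), (2, 0)])
    mres = solve(build_ilp_a_prime(spec, control))
    # the only attractor is the clamped state itself; min = max = its score
    assert mres.objective == 0.0  # controlled nodes score nothing


def test_max_min_sandwich(toy_net):
    spec = single_net_spec(toy_net, [1, 2, 3], m=1, theta=0)
    res = solve(build_ilp_a(spec))
    for pairs in ([(0, 1)], [(1, 0)], [(2, 0)]):
        mres = solve(build_ilp_a_prime(spec, ControlAssignment.from_pairs(pairs)))
        assert mres.objective <= res.objective + 1e-9


# ---------------------------------------------------------------------------
# exclusion cuts
# ---------------------------------------------------------------------------

def all_single_controls(n):
    return [
        ControlAssignment.from_pairs([(i, b)])
        for i in range(n)
        for b in (0, 1)
    ]


def probe_control_feasible(spec, model, control):
    probe = solve_with_fixed_control(spec, model, control)
    return probe.status == "optimal"


def solve_with_fixed_control(spec, base_model, control):
    import copy

    model = copy.deepcopy(base_model)
    for i in range(spec.n):
        model.fix(f"w[{i}]", 1 if i in control.values else 0)
        if i in control.values:
            model.fix(f"z[{i}]", control.values[i])
    return solve(model)


def test_exclusion_cut_removes_exactly_one_control():
    net = identity_net(3)  # every control admits attractors
    spec = ControlProblemSpec(
        net1=net, net2=net, cfg=ScoreConfig.uniform(3), m=1, mode="SAC", theta=0
    )
    base = build_ilp_a(spec)
    excluded = ControlAssignment.from_pairs([(0, 1)])
    add_exclusion_cut(base, excluded)
    for control in all_single_controls(3):
        feasible = probe_control_feasible(spec, base, control)
        assert feasible == (control != excluded)


def test_exhausting_all_cuts_yields_infeasibility():
    net = identity_net(3)
    spec = ControlProblemSpec(
        net1=net, net2=net, cfg=ScoreConfig.uniform(3), m=1, mode="SAC", theta=0
    )
    base = build_ilp_a(spec)
    for control in all_single_controls(3):  # C(3,1) * 2 = 6 controls
        add_exclusion_cut(base, control)
    assert solve(base).status == "infeasible"


def test_iterations_never_revisit_a_control(toy_net):
    """The loop visits each (V', B') at most once before running out."""
    net = identity_net(3)
    spec = ControlProblemSpec(
        net1=net, net2=net, cfg=ScoreConfig.uniform(3), m=1, mode="SAC",
        theta=1000.0, max_repeats=50,
    )
    base = build_ilp_a(spec)
    seen = set()
    while True:
        res = solve(base)
        if res.status == "infeasible":
            break
        control = ControlAssignment.from_pairs(
            (i, res.assignment[f"z[{i}]"])
            for i in range(3)
            if res.assignment[f"w[{i}]"] == 1
        )
        assert control not in seen
        seen.add(control)
        add_exclusion_cut(base, control)
    assert len(seen) == 6


# ---------------------------------------------------------------------------
# the three solvers
# ---------------------------------------------------------------------------

def test_sac_worked_example_theta3(toy_net):
    spec = single_net_spec(toy_net, [1, 2, 3], m=1, theta=3)
    sol = solve_sac(spec)
    assert sol.status == "found"
    assert sol.control.pairs() == [(0, 1)]
    assert sol.min_score == 3
    assert str(sol.attractors["max_cancer"]) == "101"


def test_sac_unreachable_threshold(toy_net):
    # brute force over all six single-node controls: the best max score is 4
    sol = solve_sac(single_net_spec(toy_net, [1, 2, 3], m=1, theta=5))
    assert sol.status == "none_exists"


def test_sac_zero_threshold_accepts_first_control(toy_net):
    sol = solve_sac(single_net_spec(toy_net, [1, 2, 3], m=1, theta=0))
    assert sol.status == "found" and sol.iterations == 1


def test_sac_m0_without_fixed_points():
    negation = BooleanNetwork(("v1", "v2"), ((0,), (1,)), ((1, 0), (1, 0)))
    spec = ControlProblemSpec(
        net1=negation, net2=negation, cfg=ScoreConfig.uniform(2), m=0,
        mode="SAC", theta=0,
    )
    assert solve_sac(spec).status == "none_exists"


def test_repeat_limit_status(toy_net):
    # theta between the two feasible max scores forces repeated rejections
    spec = single_net_spec(toy_net, [1, 2, 3], m=1, theta=3.5, max_repeats=1)
    sol = solve_sac(spec)
    assert sol.status == "repeat_limit" and sol.iterations == 1


def test_acdc_unsatisfiable_damage(toy_net):
    spec = ControlProblemSpec(
        net1=toy_net, net2=toy_net, cfg=ScoreConfig.uniform(3), m=1,
        mode="ACDC", xi1=100.0, theta1=0.0,
    )
    assert solve_acdc(spec).status == "none_exists"


def test_acdc_vacuous_thresholds_found():
    net1 = identity_net(4)
    net2 = constant_net(4, 0)  # normal cell rests at all-OFF
    spec = ControlProblemSpec(
        net1=net1, net2=net2, cfg=ScoreConfig.uniform(4), m=1,
        mode="ACDC", xi1=0.0, theta1=0.0,
    )
    sol = solve_acdc(spec)
    assert sol.status == "found"
    assert sol.min_score > 0  # acceptance is strict for ACDC


def test_ackn_unsatisfiable_protection(toy_net):
    spec = ControlProblemSpec(
        net1=toy_net, net2=toy_net, cfg=ScoreConfig.uniform(3), m=1,
        mode="ACKN", xi2=100.0, theta2=0.0,
    )
    assert solve_ackn(spec).status == "none_exists"


def test_ackn_constant_off_normal_reduces_to_single_net():
    """With N2 resting at all-OFF, protection is free and ACKN becomes the
    max-min control of N1 alone."""
    net1 = identity_net(4)
    net2 = constant_net(4, 0)
    cfg = ScoreConfig.uniform(4)
    spec = ControlProblemSpec(
        net1=net1, net2=net2, cfg=cfg, m=1, mode="ACKN", xi2=3.0, theta2=3.0,
        max_repeats=100,
    )
    sol = solve_ackn(spec)
    # identity dynamics: worst attractor zeroes every free node unless clamped
    assert sol.status == "none_exists"
    spec2 = ControlProblemSpec(
        net1=constant_net(4, 1), net2=net2, cfg=cfg, m=1, mode="ACKN",
        xi2=3.0, theta2=3.0,
    )
    sol2 = solve_ackn(spec2)
    assert sol2.status == "found" and sol2.min_score == 3.0


def test_mode_guards(toy_net):
    spec = single_net_spec(toy_net, [1, 2, 3], m=1)
    with pytest.raises(ValueError):
        solve_acdc(spec)
    with pytest.raises(ValueError):
        solve_ackn(spec)


def test_mismatched_node_sets_rejected(toy_net):
    other = identity_net(3)  # different node names
    with pytest.raises(ValueError, match="same ordered node set"):
        ControlProblemSpec(
            net1=toy_net, net2=other, cfg=ScoreConfig.uniform(3), m=1
        )


# ---------------------------------------------------------------------------
# soundness and oracle agreement
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "mode,seed",
    [("SAC", 6), ("SAC", 8), ("SAC", 9),
     ("ACDC", 37), ("ACDC", 45), ("ACDC", 61),
     ("ACKN", 37), ("ACKN", 45), ("ACKN", 61)],
)
def test_found_solutions_are_sound(mode, seed):
    """Witness states are verified fixed points and scores recompute exactly
    (random instances known to admit solutions at the default thresholds)."""
    net1, net2 = random_bn_pair(GeneratorConfig(n=7, K=2, seed=seed))
    cfg = ScoreConfig.uniform(7)
    spec = ControlProblemSpec(
        net1=net1, net2=net2, cfg=cfg, m=2, mode=mode, max_repeats=300
    )
    sol = solve_control(spec)
    assert sol.status == "found"
    c = sol.control
    c1, c2 = apply_control(net1, c), apply_control(net2, c)
    assert is_singleton_attractor(c1, sol.attractors["max_cancer"])
    assert is_singleton_attractor(c2, sol.attractors["max_normal"])
    if mode == "SAC":
        recomputed = score_cancer(
            cfg, sol.attractors["min_cancer"], c
        ) + score_normal(cfg, sol.attractors["min_normal"], c)
    elif mode == "ACDC":
        recomputed = score_normal(cfg, sol.attractors["min_normal"], c)
    else:
        recomputed = score_cancer(cfg, sol.attractors["min_cancer"], c)
    assert sol.min_score == pytest.approx(recomputed)
    assert sol.min_score <= sol.max_score + 1e-9


@pytest.mark.parametrize("mode", ["SAC", "ACDC", "ACKN"])
@pytest.mark.parametrize("seed", range(6))
def test_solver_agrees_with_bruteforce_oracle(mode, seed):
    net1, net2 = random_bn_pair(GeneratorConfig(n=7, K=2, seed=500 + seed))
    spec = ControlProblemSpec(
        net1=net1, net2=net2, cfg=ScoreConfig.uniform(7), m=2, mode=mode,
        max_repeats=1000,
    )
    assert_control_matches_oracle(spec, solve_control(spec))


def test_oracle_full_clamp(toy_net):
    """m = n: the oracle picks the best fully clamped state by direct scoring."""
    cfg = ScoreConfig(np.array([1.0, 2.0, 3.0]), np.zeros(3))
    spec = ControlProblemSpec(
        net1=toy_net, net2=toy_net, cfg=cfg, m=3, mode="SAC", theta=0
    )
    oracle = bruteforce_control_oracle(spec)
    # every node controlled: all scores are 0, any clamp qualifies at theta=0
    assert oracle.status == "found" and oracle.max_score == 0.0


def test_oracle_worked_example(toy_net):
    spec = single_net_spec(toy_net, [1, 2, 3], m=1, theta=3)
    oracle = bruteforce_control_oracle(spec)
    assert oracle.status == "found"
    assert oracle.control.pairs() == [(0, 1)]
    assert oracle.min_score == 3.0


def test_oracle_size_guard():
    net = identity_net(13)
    spec = ControlProblemSpec(
        net1=net, net2=net, cfg=ScoreConfig.uniform(13), m=1, mode="SAC"
    )
    with pytest.raises(ValueError, match="guard"):
        bruteforce_control_oracle(spec)
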