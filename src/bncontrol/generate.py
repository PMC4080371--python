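"""Seeded random Boolean-network instance generation.

The experimental protocol the package targets runs on randomly generated
network pairs with exact indegree ``K = 2``: both members share the node
set, but wiring and truth tables are drawn independently.  The sampling
model is the conventional random-BN ensemble: each node receives ``K``
distinct inputs uniformly at random (self-inputs excluded by default) and a
truth table drawn uniformly from the ``2^(2^K)`` Boolean functions.

:func:`biased_pair` is an explicitly synthetic stand-in for a cancer/normal
pair in which the cancer network is dominated by OR-type regulation (most
genes activate when any regulator does, favouring mostly-ON attractors) and
the normal network by AND-type regulation (favouring mostly-OFF attractors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BooleanNetwork, example_network  # re-exported fixture

__all__ = [
    "GeneratorConfig",
    "random_bn",
    "random_bn_pair",
    "biased_pair",
    "example_network",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling parameters for random networks.

    ``K`` is the exact indegree of every node unless ``exact_k`` is false,
    in which case indegrees are drawn uniformly from ``1..K``.
    """

    n: int
    K: int = 2
    seed: int = 0
    allow_self_inputs: bool = False
    exact_k: bool = True

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        limit = self.n if self.allow_self_inputs else self.n - 1
        if self.n > 1 and not 1 <= self.K <= limit:
            raise ValueError(f"K={self.K} out of range [1, {limit}] for n={self.n}")
        if self.n == 1 and not self.allow_self_inputs:
            raise ValueError("n=1 requires allow_self_inputs=True")


def _draw_network(
    cfg: GeneratorConfig, rng: np.random.Generator, node_names: tuple[str, ...]
) -> BooleanNetwork:
    inputs, tables = [], []
    for i in range(cfg.n):
        candidates = [j for j in range(cfg.n) if cfg.allow_self_inputs or j != i]
        k = cfg.K if cfg.exact_k else int(rng.integers(1, cfg.K + 1))
        chosen = rng.choice(len(candidates), size=k, replace=False)
        inputs.append(tuple(candidates[j] for j in chosen))
        tables.append(tuple(int(b) for b in rng.integers(0, 2, size=2**k)))
    return BooleanNetwork(node_names, tuple(inputs), tuple(tables))


def _node_names(n: int) -> tuple[str, ...]:
    return tuple(f"v{i + 1}" for i in range(n))


def random_bn(cfg: GeneratorConfig) -> BooleanNetwork:
    """One random network; a pure function of the config (seed included)."""
    rng = np.random.default_rng(cfg.seed)
    return _draw_network(cfg, rng, _node_names(cfg.n))


def random_bn_pair(cfg: GeneratorConfig) -> tuple[BooleanNetwork, BooleanNetwork]:
    """Two networks over the same nodes, independently wired, one seed stream."""
    rng = np.random.default_rng(cfg.seed)
    names = _node_names(cfg.n)
    return _draw_network(cfg, rng, names), _draw_network(cfg, rng, names)


def _literal_table(
    k: int, signs: np.ndarray, use_or: bool
) -> tuple[int, ...]:
    """Truth table of an OR (or AND) of k literals with the given signs."""
    table = []
    for idx in range(2**k):
        bits = [(idx >> (k - 1 - j)) & 1 for j in range(k)]
        lits = [b if sg == 1 else 1 - b for b, sg in zip(bits, signs)]
        table.append(max(lits) if use_or else min(lits))
    return tuple(table)


def biased_pair(
    n: int,
    or_fraction_cancer: float = 0.8,
    and_fraction_normal: float = 0.8,
    seed: int = 0,
    K: int = 2,
    negation_prob: float = 0.25,
) -> tuple[BooleanNetwork, BooleanNetwork]:
    """A synthetic cancer/normal pair with shared wiring and biased logic.

    Each node's function is an OR of literals in the cancer network with
    probability ``or_fraction_cancer`` (else an AND), and an AND of literals
    in the normal network with probability ``and_fraction_normal`` (else an
    OR).  Literal signs are negated with probability ``negation_prob``
    (``0`` gives purely positive regulation, under which the all-ON state is
    a fixed point of a pure-OR network and the all-OFF state of a pure-AND
    network).
    """
    if not (0 <= or_fraction_cancer <= 1 and 0 <= and_fraction_normal <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    names = _node_names(n)
    base_cfg = GeneratorConfig(n=n, K=K, seed=seed)
    inputs = []
    for i in range(n):
        candidates = [j for j in range(n) if j != i]
        chosen = rng.choice(len(candidates), size=base_cfg.K, replace=False)
        inputs.append(tuple(candidates[j] for j in chosen))

    def draw_tables(or_fraction: float) -> tuple[tuple[int, ...], ...]:
        tables = []
        for i in range(n):
            k = len(inputs[i])
            signs = np.where(rng.random(k) < negation_prob, -1, 1)
            use_or = bool(rng.random() < or_fraction)
            tables.append(_literal_table(k, signs, use_or))
        return tuple(tables)

    cancer = BooleanNetwork(names, tuple(inputs), draw_tables(or_fraction_cancer))
    normal = BooleanNetwork(
        names, tuple(inputs), draw_tables(1.0 - and_fraction_normal)
    )
    return cancer, normal
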