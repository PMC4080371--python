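"""Boolean-network data model and synchronous dynamics.

A Boolean network holds, for each node, an ordered list of input nodes and a
truth table over those inputs.  States update synchronously: every node reads
its inputs at time ``t`` and takes the tabulated value at ``t + 1``.  A
*singleton attractor* is a fixed point of that update map, ``v = f(v)``; in
the gene-regulation reading it models a stable cell state.

Node order is authoritative throughout the package: a state renders as a
left-to-right bitstring with node 1 leftmost, so ``"001"`` means
``v1 = 0, v2 = 0, v3 = 1``.  Truth tables are indexed by reading the input
assignment ``(b1, ..., bk)`` as a big-endian binary number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "BooleanNetwork",
    "State",
    "ControlAssignment",
    "update_state",
    "apply_control",
    "is_singleton_attractor",
    "enumerate_singleton_attractors_bruteforce",
    "example_network",
]


class State:
    """An immutable 0/1 vector over the network's node order."""

    __slots__ = ("bits",)

    def __init__(self, bits: Iterable[int]):
        bits = tuple(int(b) for b in bits)
        if any(b not in (0, 1) for b in bits):
            raise ValueError(f"state bits must be 0/1, got {bits!r}")
        object.__setattr__(self, "bits", bits)

    @classmethod
    def from_string(cls, bitstring: str) -> "State":
        if not set(bitstring) <= {"0", "1"}:
            raise ValueError(f"invalid bitstring {bitstring!r}")
        return cls(int(ch) for ch in bitstring)

    def __str__(self) -> str:
        return "".join(str(b) for b in self.bits)

    def __repr__(self) -> str:
        return f"State({str(self)!r})"

    def __len__(self) -> int:
        return len(self.bits)

    def __getitem__(self, i: int) -> int:
        return self.bits[i]

    def __iter__(self) -> Iterator[int]:
        return iter(self.bits)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, State):
            return self.bits == other.bits
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.bits)

    def __setattr__(self, *a):  # immutability guard
        raise AttributeError("State is immutable")


@dataclass(frozen=True)
class BooleanNetwork:
    """A synchronous Boolean network ``v(t+1) = f(v(t))``.

    Parameters
    ----------
    node_names
        Ordered node identifiers; their order fixes the bitstring rendering.
    inputs
        Per node, the ordered tuple of input node indices (may be empty for a
        constant node).
    tables
        Per node, a truth table of length ``2**k`` giving the node's next
        value for each big-endian input assignment.
    """

    node_names: tuple[str, ...]
    inputs: tuple[tuple[int, ...], ...]
    tables: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        object.__setattr__(self, "node_names", tuple(self.node_names))
        object.__setattr__(
            self, "inputs", tuple(tuple(int(j) for j in row) for row in self.inputs)
        )
        object.__setattr__(
            self, "tables", tuple(tuple(int(b) for b in row) for row in self.tables)
        )
        n = len(self.node_names)
        if len(set(self.node_names)) != n:
            raise ValueError("duplicate node names")
        if len(self.inputs) != n or len(self.tables) != n:
            raise ValueError("inputs/tables length must equal the node count")
        for i, (inp, tab) in enumerate(zip(self.inputs, self.tables)):
            if len(set(inp)) != len(inp):
                raise ValueError(f"node {self.node_names[i]}: duplicate inputs")
            for j in inp:
                if not 0 <= j < n:
                    raise ValueError(f"node {self.node_names[i]}: input index {j} out of range")
            if len(tab) != 2 ** len(inp):
                raise ValueError(
                    f"node {self.node_names[i]}: table length {len(tab)} != 2^{len(inp)}"
                )
            if any(b not in (0, 1) for b in tab):
                raise ValueError(f"node {self.node_names[i]}: table entries must be 0/1")

    @property
    def n(self) -> int:
        return len(self.node_names)

    @property
    def max_indegree(self) -> int:
        """The maximum indegree K of the network."""
        return max((len(inp) for inp in self.inputs), default=0)

    def indegree(self, i: int) -> int:
        return len(self.inputs[i])

    def node_index(self, name: str) -> int:
        try:
            return self.node_names.index(name)
        except ValueError:
            raise KeyError(f"unknown node {name!r}") from None

    def step(self, state: State) -> State:
        return update_state(self, state)


@dataclass(frozen=True)
class ControlAssignment:
    """A control ``(V', B')``: clamped node indices and their fixed values.

    ``controlled`` is stored sorted; ``values`` maps exactly those indices to
    the bit each clamped node is held at.
    """

    controlled: tuple[int, ...]
    values: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self):
        ctl = tuple(sorted(int(i) for i in self.controlled))
        vals = {int(i): int(b) for i, b in self.values.items()}
        if len(set(ctl)) != len(ctl):
            raise ValueError("duplicate controlled indices")
        if set(vals) != set(ctl):
            raise ValueError("values must be defined exactly on the controlled set")
        if any(b not in (0, 1) for b in vals.values()):
            raise ValueError("control values must be 0/1")
        object.__setattr__(self, "controlled", ctl)
        object.__setattr__(self, "values", vals)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "ControlAssignment":
        d = dict(pairs)
        return cls(tuple(d), d)

    @property
    def m(self) -> int:
        return len(self.controlled)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.values.items())))

    def __eq__(self, other) -> bool:
        if isinstance(other, ControlAssignment):
            return dict(self.values) == dict(other.values)
        return NotImplemented

    def pairs(self) -> list[tuple[int, int]]:
        return sorted(self.values.items())


def update_state(net: BooleanNetwork, s: State) -> State:
    """One synchronous step: look every node's truth table up on ``s``."""
    if len(s) != net.n:
        raise ValueError(f"state length {len(s)} != network size {net.n}")
    out = []
    for inp, tab in zip(net.inputs, net.tables):
        idx = 0
        for j in inp:
            idx = (idx << 1) | s[j]
        out.append(tab[idx])
    return State(out)


def is_singleton_attractor(net: BooleanNetwork, s: State) -> bool:
    """True iff ``s`` is a fixed point of the synchronous update."""
    return update_state(net, s) == s


def apply_control(net: BooleanNetwork, c: ControlAssignment) -> BooleanNetwork:
    """Clamp the controlled nodes to constants.

    Each controlled node becomes an indegree-0 node whose table is its fixed
    bit; every other node keeps its function.  The fixed points of the result
    are exactly the controlled singleton attractors: clamped nodes hold their
    assigned values while free nodes satisfy ``v_i = f_i(v)``.
    """
    for i in c.controlled:
        if not 0 <= i < net.n:
            raise ValueError(f"control index {i} out of range for n={net.n}")
    inputs = list(net.inputs)
    tables = list(net.tables)
    for i, b in c.values.items():
        inputs[i] = ()
        tables[i] = (b,)
    return BooleanNetwork(net.node_names, tuple(inputs), tuple(tables))


def _all_states_matrix(n: int) -> np.ndarray:
    """All 2^n states as a (2^n, n) uint8 array, row r = big-endian bits of r."""
    r = np.arange(2**n, dtype=np.int64)
    shifts = n - 1 - np.arange(n)
    return ((r[:, None] >> shifts) & 1).astype(np.uint8)


def _next_states_matrix(net: BooleanNetwork, states: np.ndarray) -> np.ndarray:
    """Vectorised synchronous update of every row of ``states``."""
    out = np.empty_like(states)
    for i, (inp, tab) in enumerate(zip(net.inputs, net.tables)):
        k = len(inp)
        if k == 0:
            out[:, i] = tab[0]
            continue
        idx = np.zeros(states.shape[0], dtype=np.int64)
        for j in inp:
            idx = (idx << 1) | states[:, j]
        out[:, i] = np.asarray(tab, dtype=np.uint8)[idx]
    return out


def enumerate_singleton_attractors_bruteforce(
    net: BooleanNetwork, limit_n: int = 20
) -> list[State]:
    """All fixed points of ``net``, by exhausting the 2^n state space.

    The ground-truth oracle used to validate the ILP encodings.  Refuses
    networks with more than ``limit_n`` nodes.  Results are sorted by
    bitstring (equivalently, by state index).
    """
    if net.n > limit_n:
        raise ValueError(
            f"brute-force enumeration over 2^{net.n} states exceeds the "
            f"limit_n={limit_n} guard"
        )
    states = _all_states_matrix(net.n)
    nxt = _next_states_matrix(net, states)
    fixed = np.flatnonzero((states == nxt).all(axis=1))
    return [State(states[r]) for r in fixed]


def example_network() -> BooleanNetwork:
    """The worked three-node example network.

    ``v1(t+1) = v3(t)``, ``v2(t+1) = NOT v1(t)``, ``v3(t+1) = v1(t) AND NOT
    v2(t)``.  Its two singleton attractors are ``010`` and ``101``.
    """
    return BooleanNetwork(
        node_names=("v1", "v2", "v3"),
        inputs=((2,), (0,), (0, 1)),
        tables=((0, 1), (1, 0), (0, 0, 1, 0)),
    )
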