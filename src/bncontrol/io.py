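"""Network file formats.

Two dialects:

* ``bnet`` — BoolNet-style text: an optional ``targets, factors`` header,
  then one ``name, expression`` line per node, with ``!`` (not), ``&``
  (and), ``|`` (or), parentheses and the constants ``0``/``1``.  Chosen for
  interoperability with existing Boolean-network tooling.
* ``json`` — the lossless native format: explicit node list, input lists
  and truth tables.

Writing the ``bnet`` dialect emits each node's function as a full
disjunctive normal form over its inputs (all-false tables as a conjunction
of contradictory literal pairs), so ``read(write(net))`` reproduces the
network exactly — including input order and truth tables.  Expressions
referencing more than 16 inputs are refused to bound table size.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

from .core import BooleanNetwork

__all__ = ["NetworkParseError", "read_network", "write_network", "loads_bnet", "dumps_bnet"]

MAX_EXPRESSION_INPUTS = 16


class NetworkParseError(ValueError):
    """A malformed network file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# expression parsing (precedence: ! > & > |)
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_.]*)|(?P<op>[01!&|()]))")


def _tokenize(expr: str, line: int) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            if expr[pos:].strip():
                raise NetworkParseError(
                    f"unexpected character {expr[pos:].strip()[0]!r} in expression",
                    line,
                )
            break
        tokens.append(m.group("ident") or m.group("op"))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], line: int):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise NetworkParseError("unexpected end of expression", self.line)
        self.pos += 1
        return tok

    def parse(self):
        ast = self.parse_or()
        if self.peek() is not None:
            raise NetworkParseError(
                f"trailing token {self.peek()!r} in expression", self.line
            )
        return ast

    def parse_or(self):
        node = self.parse_and()
        while self.peek() == "|":
            self.take()
            node = ("or", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_unary()
        while self.peek() == "&":
            self.take()
            node = ("and", node, self.parse_unary())
        return node

    def parse_unary(self):
        tok = self.take()
        if tok == "!":
            return ("not", self.parse_unary())
        if tok == "(":
            node = self.parse_or()
            if self.take() != ")":
                raise NetworkParseError("unbalanced parentheses", self.line)
            return node
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok in ("&", "|", ")"):
            raise NetworkParseError(f"misplaced operator {tok!r}", self.line)
        return ("var", tok)


def _referenced(ast, order: list[str]):
    kind = ast[0]
    if kind == "var":
        if ast[1] not in order:
            order.append(ast[1])
    elif kind == "not":
        _referenced(ast[1], order)
    elif kind in ("and", "or"):
        _referenced(ast[1], order)
        _referenced(ast[2], order)


def _eval(ast, env: dict[str, int]) -> int:
    kind = ast[0]
    if kind == "var":
        return env[ast[1]]
    if kind == "const":
        return ast[1]
    if kind == "not":
        return 1 - _eval(ast[1], env)
    if kind == "and":
        return _eval(ast[1], env) & _eval(ast[2], env)
    return _eval(ast[1], env) | _eval(ast[2], env)


def loads_bnet(text: str) -> BooleanNetwork:
    """Parse the ``bnet`` dialect from a string."""
    entries: list[tuple[str, object, int]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if re.fullmatch(r"targets\s*,\s*factors", stripped, flags=re.IGNORECASE):
            continue
        if "," not in stripped:
            raise NetworkParseError("expected 'name, expression'", lineno)
        name, expr = stripped.split(",", 1)
        name = name.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.]*", name):
            raise NetworkParseError(f"invalid node name {name!r}", lineno)
        tokens = _tokenize(expr, lineno)
        if not tokens:
            raise NetworkParseError("empty expression", lineno)
        entries.append((name, _Parser(tokens, lineno).parse(), lineno))

    names = [name for name, _, _ in entries]
    if len(set(names)) != len(names):
        dup = next(nm for nm in names if names.count(nm) > 1)
        raise NetworkParseError(f"node {dup!r} defined more than once")
    index = {nm: i for i, nm in enumerate(names)}

    inputs, tables = [], []
    for name, ast, lineno in entries:
        refs: list[str] = []
        _referenced(ast, refs)
        for ref in refs:
            if ref not in index:
                raise NetworkParseError(
                    f"expression for {name!r} references undefined node {ref!r}",
                    lineno,
                )
        if len(refs) > MAX_EXPRESSION_INPUTS:
            raise NetworkParseError(
                f"expression for {name!r} has {len(refs)} inputs "
                f"(limit {MAX_EXPRESSION_INPUTS})",
                lineno,
            )
        k = len(refs)
        table = []
        for row in range(2**k):
            env = {ref: (row >> (k - 1 - j)) & 1 for j, ref in enumerate(refs)}
            table.append(_eval(ast, env))
        inputs.append(tuple(index[r] for r in refs))
        tables.append(tuple(table))
    return BooleanNetwork(tuple(names), tuple(inputs), tuple(tables))


def dumps_bnet(net: BooleanNetwork) -> str:
    """Render a network in the ``bnet`` dialect (full-DNF expressions)."""
    lines = ["targets, factors"]
    for i in range(net.n):
        inp, tab = net.inputs[i], net.tables[i]
        k = len(inp)
        if k == 0:
            expr = str(tab[0])
        elif not any(tab):
            # keep the inputs referenced so the round trip preserves them
            expr = " & ".join(
                f"{net.node_names[j]} & !{net.node_names[j]}" for j in inp
            )
        else:
            minterms = []
            for row, out in enumerate(tab):
                if not out:
                    continue
                lits = []
                for j, node in enumerate(inp):
                    bit = (row >> (k - 1 - j)) & 1
                    lits.append(
                        net.node_names[node] if bit else f"!{net.node_names[node]}"
                    )
                minterms.append("(" + " & ".join(lits) + ")")
            expr = " | ".join(minterms)
        lines.append(f"{net.node_names[i]}, {expr}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _net_to_json_obj(net: BooleanNetwork) -> dict:
    return {
        "nodes": list(net.node_names),
        "inputs": [list(row) for row in net.inputs],
        "tables": [list(row) for row in net.tables],
    }


def _net_from_json_obj(obj: dict) -> BooleanNetwork:
    try:
        return BooleanNetwork(
            tuple(obj["nodes"]),
            tuple(tuple(row) for row in obj["inputs"]),
            tuple(tuple(row) for row in obj["tables"]),
        )
    except (KeyError, TypeError) as exc:
        raise NetworkParseError(f"malformed JSON network: {exc}") from exc


# ---------------------------------------------------------------------------
# file-level API
# ---------------------------------------------------------------------------

def _resolve_dialect(path: Path, dialect: str) -> str:
    if dialect != "auto":
        if dialect not in ("bnet", "json"):
            raise ValueError(f"unknown dialect {dialect!r}")
        return dialect
    return "json" if path.suffix.lower() == ".json" else "bnet"


def read_network(path: str | Path, dialect: str = "auto") -> BooleanNetwork:
    """Read a network file; dialect inferred from the extension by default."""
    path = Path(path)
    text = path.read_text()
    if _resolve_dialect(path, dialect) == "json":
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise NetworkParseError(f"invalid JSON: {exc}", exc.lineno) from exc
        return _net_from_json_obj(obj)
    return loads_bnet(text)


def write_network(net: BooleanNetwork, path: str | Path, dialect: str = "auto") -> None:
    path = Path(path)
    if _resolve_dialect(path, dialect) == "json":
        path.write_text(json.dumps(_net_to_json_obj(net), indent=1) + "\n")
    else:
        path.write_text(dumps_bnet(net))
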