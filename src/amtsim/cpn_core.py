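"""Minimal colored-Petri-net engine.

A colored Petri net is a bipartite graph of places (token containers) and
transitions (events), connected by arcs whose expressions describe which
tokens a firing consumes and produces.  Tokens are typed ("colored"): each
place declares a color set and every token it holds must satisfy it.  A
transition is *enabled* under a binding of its arc variables when every
normal input arc's demanded multiset is covered by the source place, every
inhibitor input place is empty, and its guard evaluates to true; *firing*
removes the input multisets and adds the output multisets.

The engine is deliberately small: no time, no hierarchy, no stochastic
extensions.  Sequencing and concurrency constraints are layered on top by
:mod:`amtsim.tgtc` rather than baked into the net semantics.

Arc expressions and guards are written in a safe arithmetic mini-language
(constants, variables, ``+ - * /``, ``abs``/``min``/``max``, comparisons and
boolean connectives), parsed once via the :mod:`ast` module and evaluated
against variable bindings.  Markings are value objects: :func:`fire` returns
a new marking and never mutates its input, so traces can be stored and
replayed exactly.
"""

from __future__ import annotations

import ast
import json
import random
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence


class CPNError(Exception):
    """Base class for engine errors."""


class StructuralError(CPNError):
    """The net references unknown elements or violates bipartiteness."""


class ColorError(CPNError):
    """A token does not satisfy its place's color set."""


class ContractViolation(CPNError):
    """An operation was called outside its precondition (e.g. firing a
    transition that is not enabled under the given binding)."""


class ExpressionError(CPNError):
    """An arc/guard expression is malformed or uses a disallowed construct."""


class ResourceError(CPNError):
    """An exhaustive exploration exceeded its caller-enforced budget."""


class _Unit:
    """The single value of the UNIT color set (the 'black token')."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "unit"

    def __reduce__(self):
        return (_Unit, ())


#: The unit token value.
UNIT = _Unit()


def _token_sort_key(value):
    """Total order over token values of mixed kinds, for reproducible
    tie-breaking when several tokens could bind the same variable."""
    if value is UNIT:
        return (0, 0)
    if isinstance(value, bool):
        return (1, value)
    if isinstance(value, (int, float)):
        return (2, value)
    if isinstance(value, str):
        return (3, value)
    if isinstance(value, tuple):
        return (4, tuple(_token_sort_key(v) for v in value))
    return (5, repr(value))


_KINDS = ("REAL", "INT", "STRING", "UNIT", "PRODUCT")


@dataclass(frozen=True)
class ColorSet:
    name: str
    kind: str = "REAL"

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise StructuralError(f"unknown color-set kind {self.kind!r}")

    def admits(self, value) -> bool:
        if self.kind == "REAL":
            return isinstance(value, (int, float)) and not isinstance(value, bool)
        if self.kind == "INT":
            return isinstance(value, int) and not isinstance(value, bool)
        if self.kind == "STRING":
            return isinstance(value, str)
        if self.kind == "UNIT":
            return value is UNIT
        if self.kind == "PRODUCT":
            return isinstance(value, tuple)
        return False


@dataclass(frozen=True)
class Place:
    id: str
    colorset: ColorSet
    label: str = ""


# --------------------------------------------------------------------------
# expression mini-language
# --------------------------------------------------------------------------

_ALLOWED_CALLS = {"abs": abs, "min": min, "max": max}

_BINOPS = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: lambda a, b: a / b,
}

_CMPOPS = {
    ast.Lt: lambda a, b: a < b,
    ast.LtE: lambda a, b: a <= b,
    ast.Gt: lambda a, b: a > b,
    ast.GtE: lambda a, b: a >= b,
    ast.Eq: lambda a, b: a == b,
    ast.NotEq: lambda a, b: a != b,
}

_CONST_NAMES = {"unit": UNIT, "true": True, "false": False}


class Expr:
    """A parsed mini-language expression.

    Supported syntax: numeric constants, variable names, the literals
    ``unit``/``true``/``false``, ``+ - * /``, unary minus, calls to
    ``abs``/``min``/``max``, comparisons, and ``and``/``or``/``not``.
    """

    __slots__ = ("src", "_tree", "free_vars")

    def __init__(self, src: str):
        self.src = src
        try:
            tree = ast.parse(src, mode="eval")
        except SyntaxError as exc:
            raise ExpressionError(f"cannot parse {src!r}: {exc}") from exc
        self._tree = tree.body
        self.free_vars = frozenset(self._validate(self._tree))

    def _validate(self, node) -> set:
        if isinstance(node, ast.Constant):
            if isinstance(node.value, bool) or isinstance(node.value, (int, float)):
                return set()
            raise ExpressionError(f"disallowed constant {node.value!r} in {self.src!r}")
        if isinstance(node, ast.Name):
            return set() if node.id in _CONST_NAMES else {node.id}
        if isinstance(node, ast.BinOp) and type(node.op) in _BINOPS:
            return self._validate(node.left) | self._validate(node.right)
        if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd, ast.Not)):
            return self._validate(node.operand)
        if isinstance(node, ast.Call):
            if not (isinstance(node.func, ast.Name) and node.func.id in _ALLOWED_CALLS):
                raise ExpressionError(f"disallowed call in {self.src!r}")
            if node.keywords:
                raise ExpressionError(f"keyword arguments not allowed in {self.src!r}")
            out: set = set()
            for arg in node.args:
                out |= self._validate(arg)
            return out
        if isinstance(node, ast.Compare):
            if not all(type(op) in _CMPOPS for op in node.ops):
                raise ExpressionError(f"disallowed comparison in {self.src!r}")
            out = self._validate(node.left)
            for cmp in node.comparators:
                out |= self._validate(cmp)
            return out
        if isinstance(node, ast.BoolOp):
            out = set()
            for v in node.values:
                out |= self._validate(v)
            return out
        raise ExpressionError(f"disallowed syntax {type(node).__name__} in {self.src!r}")

    def eval(self, binding: Mapping[str, object]):
        return self._eval(self._tree, binding)

    def _eval(self, node, b):
        if isinstance(node, ast.Constant):
            return node.value
        if isinstance(node, ast.Name):
            if node.id in _CONST_NAMES:
                return _CONST_NAMES[node.id]
            try:
                return b[node.id]
            except KeyError:
                raise ExpressionError(f"unbound variable {node.id!r} in {self.src!r}") from None
        if isinstance(node, ast.BinOp):
            return _BINOPS[type(node.op)](self._eval(node.left, b), self._eval(node.right, b))
        if isinstance(node, ast.UnaryOp):
            v = self._eval(node.operand, b)
            if isinstance(node.op, ast.USub):
                return -v
            if isinstance(node.op, ast.UAdd):
                return +v
            return not v
        if isinstance(node, ast.Call):
            args = [self._eval(a, b) for a in node.args]
            return _ALLOWED_CALLS[node.func.id](*args)
        if isinstance(node, ast.Compare):
            left = self._eval(node.left, b)
            for op, cmp in zip(node.ops, node.comparators):
                right = self._eval(cmp, b)
                if not _CMPOPS[type(op)](left, right):
                    return False
                left = right
            return True
        if isinstance(node, ast.BoolOp):
            if isinstance(node.op, ast.And):
                res = True
                for v in node.values:
                    res = self._eval(v, b)
                    if not res:
                        return res
                return res
            res = False
            for v in node.values:
                res = self._eval(v, b)
                if res:
                    return res
            return res
        raise ExpressionError(f"unreachable node in {self.src!r}")

    def is_bare_variable(self) -> bool:
        return isinstance(self._tree, ast.Name) and self._tree.id not in _CONST_NAMES

    @property
    def variable(self) -> str:
        return self._tree.id  # type: ignore[attr-defined]

    def __repr__(self) -> str:
        return f"Expr({self.src!r})"


def _as_exprs(expression) -> tuple[Expr, ...]:
    out = []
    for e in expression:
        out.append(e if isinstance(e, Expr) else Expr(str(e)))
    return tuple(out)


@dataclass(frozen=True)
class Transition:
    id: str
    guard: Expr | None = None

    @staticmethod
    def with_guard(id: str, guard: str) -> "Transition":
        return Transition(id, Expr(guard))


@dataclass(frozen=True)
class Arc:
    """A normal or inhibitor arc.

    ``expression`` is a tuple of mini-language expressions, one per token
    demanded/produced (an arc of weight *n* lists *n* expressions).  For
    inhibitor arcs the expression is ignored: the arc tests emptiness of its
    source place and may only run place -> transition.
    """

    source: str
    target: str
    expression: tuple[Expr, ...] = ()
    kind: str = "normal"

    def __post_init__(self):
        if self.kind not in ("normal", "inhibitor"):
            raise StructuralError(f"unknown arc kind {self.kind!r}")
        object.__setattr__(self, "expression", _as_exprs(self.expression))


class Marking:
    """A token distribution: place id -> multiset of token values.

    Treated as immutable by contract; all mutating-style operations return a
    new marking.
    """

    __slots__ = ("_tokens",)

    def __init__(self, tokens: Mapping[str, Iterable] | None = None):
        data: dict[str, Counter] = {}
        if tokens:
            for pid, toks in tokens.items():
                cnt = Counter(toks) if not isinstance(toks, Counter) else Counter(toks)
                if any(n < 0 for n in cnt.values()):
                    raise ContractViolation("negative multiplicity in marking")
                cnt = +cnt
                if cnt:
                    data[pid] = cnt
        self._tokens = data

    def tokens(self, place_id: str) -> Counter:
        return Counter(self._tokens.get(place_id, Counter()))

    def count(self, place_id: str) -> int:
        return sum(self._tokens.get(place_id, Counter()).values())

    def value(self, place_id: str):
        """The single token in ``place_id`` (convenience for 1-safe places)."""
        cnt = self._tokens.get(place_id)
        if not cnt or sum(cnt.values()) != 1:
            raise ContractViolation(f"place {place_id!r} does not hold exactly one token")
        return next(iter(cnt))

    def places(self) -> list[str]:
        return sorted(self._tokens)

    def updated(self, remove: Mapping[str, Counter] | None = None,
                add: Mapping[str, Counter] | None = None) -> "Marking":
        data = {pid: Counter(cnt) for pid, cnt in self._tokens.items()}
        for pid, cnt in (remove or {}).items():
            cur = data.setdefault(pid, Counter())
            cur.subtract(cnt)
            if any(n < 0 for n in cur.values()):
                raise ContractViolation(f"removing absent tokens from {pid!r}")
        for pid, cnt in (add or {}).items():
            data.setdefault(pid, Counter()).update(cnt)
        m = Marking()
        m._tokens = {pid: +cnt for pid, cnt in data.items() if +cnt}
        return m

    def without(self, place_ids: Iterable[str]) -> "Marking":
        drop = set(place_ids)
        m = Marking()
        m._tokens = {pid: Counter(cnt) for pid, cnt in self._tokens.items() if pid not in drop}
        return m

    def __eq__(self, other) -> bool:
        return isinstance(other, Marking) and self._tokens == other._tokens

    def __repr__(self) -> str:
        items = ", ".join(
            f"{pid}: {sorted(cnt.elements(), key=_token_sort_key)}"
            for pid, cnt in sorted(self._tokens.items())
        )
        return f"Marking({{{items}}})"


@dataclass
class Net:
    """A colored Petri net: places, transitions and arcs.

    ``metadata`` carries free-form module-grouping labels used only for
    reporting; it has no semantics.
    """

    places: list[Place] = field(default_factory=list)
    transitions: list[Transition] = field(default_factory=list)
    arcs: list[Arc] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self._index()

    def _index(self):
        self._place_by_id = {p.id: p for p in self.places}
        self._trans_by_id = {t.id: t for t in self.transitions}
        if len(self._place_by_id) != len(self.places):
            raise StructuralError("duplicate place ids")
        if len(self._trans_by_id) != len(self.transitions):
            raise StructuralError("duplicate transition ids")
        if self._place_by_id.keys() & self._trans_by_id.keys():
            raise StructuralError("place and transition ids overlap")
        self._inputs: dict[str, list[Arc]] = {t.id: [] for t in self.transitions}
        self._outputs: dict[str, list[Arc]] = {t.id: [] for t in self.transitions}
        for arc in self.arcs:
            if arc.source in self._place_by_id and arc.target in self._trans_by_id:
                self._inputs[arc.target].append(arc)
            elif arc.source in self._trans_by_id and arc.target in self._place_by_id:
                if arc.kind == "inhibitor":
                    raise StructuralError("inhibitor arcs must run place -> transition")
                self._outputs[arc.source].append(arc)
            else:
                raise StructuralError(
                    f"arc {arc.source!r} -> {arc.target!r} is not place<->transition")
        for tid in self._inputs:
            self._inputs[tid].sort(key=lambda a: a.source)
            self._outputs[tid].sort(key=lambda a: a.target)

    def place(self, pid: str) -> Place:
        try:
            return self._place_by_id[pid]
        except KeyError:
            raise StructuralError(f"unknown place {pid!r}") from None

    def transition(self, tid: str) -> Transition:
        try:
            return self._trans_by_id[tid]
        except KeyError:
            raise StructuralError(f"unknown transition {tid!r}") from None

    def input_arcs(self, tid: str) -> list[Arc]:
        self.transition(tid)
        return self._inputs[tid]

    def output_arcs(self, tid: str) -> list[Arc]:
        self.transition(tid)
        return self._outputs[tid]

    def validate_marking(self, marking: Marking) -> None:
        for pid in marking.places():
            place = self.place(pid)
            for value in marking.tokens(pid):
                if not place.colorset.admits(value):
                    raise ColorError(
                        f"token {value!r} violates color set {place.colorset.name!r}"
                        f" of place {pid!r}")

    def extended(self, places=(), transitions=(), arcs=()) -> "Net":
        return Net(self.places + list(places), self.transitions + list(transitions),
                   self.arcs + list(arcs), dict(self.metadata))


# --------------------------------------------------------------------------
# enabling and firing
# --------------------------------------------------------------------------

def _binding_key(binding: Mapping[str, object]):
    return tuple(sorted((k, _token_sort_key(v)) for k, v in binding.items()))


def enabled(net: Net, marking: Marking, t: Transition | str) -> list[dict]:
    """All variable bindings under which ``t`` may fire, in canonical order.

    Input-arc expressions must be either ground (no free variables, e.g. a
    weight-``n`` arc listing ``n`` constants) or a bare variable that binds to
    a token of the source place.  This covers every net this package builds
    and keeps binding enumeration exact.
    """
    tid = t.id if isinstance(t, Transition) else t
    trans = net.transition(tid)

    # inhibitor arcs: source place must be empty
    demands = []  # (place_id, expr) for normal arcs, elementwise
    for arc in net.input_arcs(tid):
        if arc.kind == "inhibitor":
            if marking.count(arc.source) > 0:
                return []
        else:
            for e in arc.expression:
                demands.append((arc.source, e))

    results: list[dict] = []

    def backtrack(i: int, binding: dict, avail: dict[str, Counter]):
        if i == len(demands):
            if trans.guard is None or trans.guard.eval(binding):
                results.append(dict(binding))
            return
        pid, e = demands[i]
        pool = avail.setdefault(pid, Counter(marking.tokens(pid)))
        free = e.free_vars - binding.keys()
        if not free:
            val = e.eval(binding)
            if pool.get(val, 0) > 0:
                pool[val] -= 1
                backtrack(i + 1, binding, avail)
                pool[val] += 1
            return
        if not e.is_bare_variable():
            raise StructuralError(
                f"input arc expression {e.src!r} must be ground or a bare variable")
        var = e.variable
        for val in sorted((v for v, n in pool.items() if n > 0), key=_token_sort_key):
            pool[val] -= 1
            binding[var] = val
            backtrack(i + 1, binding, avail)
            del binding[var]
            pool[val] += 1

    backtrack(0, {}, {})
    # dedupe (identical bindings can arise from symmetric token choices)
    seen = {}
    for b in results:
        seen.setdefault(_binding_key(b), b)
    return [seen[k] for k in sorted(seen)]


def fire(net: Net, marking: Marking, t: Transition | str, binding: Mapping[str, object]) -> Marking:
    """Fire ``t`` under ``binding`` and return the successor marking.

    The input marking is left untouched.  Firing a transition whose binding is
    not currently enabled raises :class:`ContractViolation`.
    """
    tid = t.id if isinstance(t, Transition) else t
    key = _binding_key(binding)
    if key not in {_binding_key(b) for b in enabled(net, marking, tid)}:
        raise ContractViolation(f"transition {tid!r} is not enabled under {dict(binding)!r}")
    remove: dict[str, Counter] = {}
    for arc in net.input_arcs(tid):
        if arc.kind == "inhibitor":
            continue
        cnt = remove.setdefault(arc.source, Counter())
        for e in arc.expression:
            cnt[e.eval(binding)] += 1
    add: dict[str, Counter] = {}
    for arc in net.output_arcs(tid):
        place = net.place(arc.target)
        cnt = add.setdefault(arc.target, Counter())
        for e in arc.expression:
            val = e.eval(binding)
            if not place.colorset.admits(val):
                raise ColorError(
                    f"transition {tid!r} would place token {val!r} violating color set"
                    f" of {arc.target!r}")
            cnt[val] += 1
    return marking.updated(remove=remove, add=add)


@dataclass(frozen=True)
class FiringEvent:
    step: int
    transition: str
    binding: dict
    marking_after: Marking


@dataclass
class FiringTrace:
    events: list[FiringEvent] = field(default_factory=list)
    initial_marking: Marking | None = None

    @property
    def transition_ids(self) -> list[str]:
        return [e.transition for e in self.events]

    @property
    def final_marking(self) -> Marking:
        if self.events:
            return self.events[-1].marking_after
        if self.initial_marking is None:
            raise ContractViolation("empty trace with no initial marking")
        return self.initial_marking

    def to_log(self) -> str:
        lines = []
        for e in self.events:
            b = ", ".join(f"{k}={v!r}" for k, v in sorted(e.binding.items()))
            lines.append(f"step {e.step}: fire {e.transition} [{b}]")
        return "\n".join(lines)

    def __len__(self) -> int:
        return len(self.events)


def run(net: Net, m0: Marking, max_steps: int, seed: int = 0,
        policy: str = "random", priority: Sequence[str] | None = None) -> FiringTrace:
    """Execute the net until no transition is enabled or ``max_steps`` firings.

    ``policy='random'`` draws uniformly (seeded) among all enabled
    (transition, binding) pairs; ``policy='priority-list'`` always fires the
    first enabled transition in ``priority`` order (remaining transitions,
    sorted by id, are appended).  Identical seed and policy give an identical
    trace.
    """
    if max_steps < 0:
        raise ContractViolation("max_steps must be >= 0")
    if policy not in ("random", "priority-list"):
        raise ContractViolation(f"unknown policy {policy!r}")
    order = [t.id for t in sorted(net.transitions, key=lambda t: t.id)]
    if priority:
        head = [tid for tid in priority if tid in set(order)]
        order = head + [tid for tid in order if tid not in set(head)]
    rng = random.Random(seed)
    trace = FiringTrace(initial_marking=m0)
    marking = m0
    for step in range(max_steps):
        choices = []
        for tid in order:
            for b in enabled(net, marking, tid):
                choices.append((tid, b))
            if choices and policy == "priority-list":
                break
        if not choices:
            break
        tid, binding = choices[0] if policy == "priority-list" else choices[rng.randrange(len(choices))]
        marking = fire(net, marking, tid, binding)
        trace.events.append(FiringEvent(step, tid, dict(binding), marking))
    return trace


def reachable_sequences(net: Net, m0: Marking, depth: int,
                        max_nodes: int = 200_000) -> set[tuple[str, ...]]:
    """Exhaustively enumerate all maximal firing sequences up to ``depth``.

    Brute-force oracle for small nets: explores every enabled
    (transition, binding) choice.  Sequences are recorded as tuples of
    transition ids, at the point where the net is dead or the depth cap is
    hit.  Exceeding ``max_nodes`` explored states raises
    :class:`ResourceError`.
    """
    sequences: set[tuple[str, ...]] = set()
    explored = 0
    order = sorted(net.transitions, key=lambda t: t.id)

    def dfs(marking: Marking, seq: tuple[str, ...]):
        nonlocal explored
        explored += 1
        if explored > max_nodes:
            raise ResourceError(f"exploration budget of {max_nodes} states exceeded")
        if len(seq) >= depth:
            sequences.add(seq)
            return
        any_fired = False
        for t in order:
            for b in enabled(net, marking, t):
                any_fired = True
                dfs(fire(net, marking, t, b), seq + (t.id,))
        if not any_fired:
            sequences.add(seq)

    dfs(m0, ())
    return sequences


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def _token_to_json(value):
    if value is UNIT:
        return {"unit": True}
    if isinstance(value, tuple):
        return {"product": [_token_to_json(v) for v in value]}
    return value


def _token_from_json(obj):
    if isinstance(obj, dict):
        if obj.get("unit"):
            return UNIT
        if "product" in obj:
            return tuple(_token_from_json(v) for v in obj["product"])
    return obj


def net_to_dict(net: Net) -> dict:
    colorsets = sorted({p.colorset for p in net.places}, key=lambda c: c.name)
    return {
        "colorsets": [{"name": c.name, "kind": c.kind} for c in colorsets],
        "places": [{"id": p.id, "colorset": p.colorset.name, "label": p.label}
                   for p in net.places],
        "transitions": [{"id": t.id, "guard": t.guard.src if t.guard else None}
                        for t in net.transitions],
        "arcs": [{"src": a.source, "dst": a.target, "kind": a.kind,
                  "expr": [e.src for e in a.expression]} for a in net.arcs],
        "metadata": net.metadata,
    }


def net_from_dict(data: dict) -> Net:
    css = {c["name"]: ColorSet(c["name"], c["kind"]) for c in data.get("colorsets", [])}
    places = [Place(p["id"], css[p["colorset"]], p.get("label", "")) for p in data["places"]]
    transitions = [Transition(t["id"], Expr(t["guard"]) if t.get("guard") else None)
                   for t in data["transitions"]]
    arcs = [Arc(a["src"], a["dst"], tuple(Expr(s) for s in a.get("expr", [])),
                a.get("kind", "normal")) for a in data["arcs"]]
    return Net(places, transitions, arcs, dict(data.get("metadata", {})))


def marking_to_dict(marking: Marking) -> dict:
    return {pid: [[_token_to_json(v), n] for v, n in
                  sorted(marking.tokens(pid).items(), key=lambda kv: _token_sort_key(kv[0]))]
            for pid in marking.places()}


def marking_from_dict(data: dict) -> Marking:
    tokens = {}
    for pid, pairs in data.items():
        cnt: Counter = Counter()
        for value, n in pairs:
            cnt[_token_from_json(value)] += n
        tokens[pid] = cnt
    return Marking(tokens)


def save_net(net: Net, path) -> None:
    with open(path, "w") as fh:
        json.dump(net_to_dict(net), fh, indent=1)


def load_net(path) -> Net:
    with open(path) as fh:
        return net_from_dict(json.load(fh))
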