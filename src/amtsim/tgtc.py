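"""Token-guided transition control (TGTC).

A colored Petri net by itself fires any enabled transition in any order.  To
make a net respect a prescribed series-parallel execution schedule, TGTC adds
an auxiliary *control layer*: one UNIT-colored control place per scheduled
transition, an initial control token, and control arcs that hand the token
from each transition to its successors.  Sequential composition is a chain of
hand-offs; parallel composition splits the token into one copy per branch and
joins the branches at a shared control place whose outgoing arc weight equals
the branch count, so the successor can only fire once every branch has
completed.  Control places and tokens are disjoint from the data layer:
stripping the control layer restores the original net exactly, and control
tokens never alter data-token behavior.

Schedules are series-parallel trees of :class:`Step` (a single transition),
:class:`Seq` (run children in order) and :class:`Par` (run children
concurrently, in any interleaving).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

from .cpn_core import (
    UNIT,
    Arc,
    ColorSet,
    Expr,
    FiringTrace,
    Marking,
    Net,
    Place,
    StructuralError,
    Transition,
)

CONTROL_COLORSET = ColorSet("__ctrl", "UNIT")


class ScheduleError(StructuralError):
    """The schedule is malformed (empty, duplicated or unknown transitions)."""


@dataclass(frozen=True)
class Step:
    transition: str


@dataclass(frozen=True)
class Seq:
    children: tuple
    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(_as_node(c) for c in children))


@dataclass(frozen=True)
class Par:
    children: tuple
    def __init__(self, *children):
        object.__setattr__(self, "children", tuple(_as_node(c) for c in children))


ScheduleNode = Union[Step, Seq, Par]


def _as_node(obj) -> ScheduleNode:
    if isinstance(obj, (Step, Seq, Par)):
        return obj
    if isinstance(obj, str):
        return Step(obj)
    raise ScheduleError(f"cannot interpret {obj!r} as a schedule node")


def schedule_from_dict(obj) -> ScheduleNode:
    """Parse the structured-text schedule form, e.g.
    ``{"seq": [{"par": [{"seq": ["t1","t2"]}, "t3"]}, "t4"]}``."""
    if isinstance(obj, str):
        return Step(obj)
    if isinstance(obj, dict) and len(obj) == 1:
        key, children = next(iter(obj.items()))
        if key == "seq":
            return Seq(*(schedule_from_dict(c) for c in children))
        if key == "par":
            return Par(*(schedule_from_dict(c) for c in children))
    raise ScheduleError(f"malformed schedule fragment {obj!r}")


def schedule_to_dict(node: ScheduleNode):
    if isinstance(node, Step):
        return node.transition
    key = "seq" if isinstance(node, Seq) else "par"
    return {key: [schedule_to_dict(c) for c in node.children]}


def schedule_transitions(node: ScheduleNode) -> list[str]:
    """Transition ids in the schedule, in tree (pre-)order."""
    if isinstance(node, Step):
        return [node.transition]
    out: list[str] = []
    for c in node.children:
        out.extend(schedule_transitions(c))
    return out


def validate_schedule(node: ScheduleNode) -> None:
    tids = schedule_transitions(node)
    if not tids:
        raise ScheduleError("schedule is empty")
    if len(tids) != len(set(tids)):
        dupes = sorted({t for t in tids if tids.count(t) > 1})
        raise ScheduleError(f"transitions appear more than once in schedule: {dupes}")


def predecessor_map(node: ScheduleNode) -> dict[str, set[str]]:
    """For each scheduled transition, the set of transitions that must fire
    before it (the schedule's partial order, transitively closed)."""
    validate_schedule(node)
    preds: dict[str, set[str]] = {t: set() for t in schedule_transitions(node)}

    def walk(n: ScheduleNode) -> list[str]:
        if isinstance(n, Step):
            return [n.transition]
        if isinstance(n, Par):
            out = []
            for c in n.children:
                out.extend(walk(c))
            return out
        done: list[str] = []
        for c in n.children:
            tids = walk(c)
            for t in tids:
                preds[t].update(done)
            done.extend(tids)
        return done

    walk(node)
    return preds


def linear_extensions(node: ScheduleNode) -> set[tuple[str, ...]]:
    """All total orders compatible with the schedule's partial order.

    Brute-force (topological-sort enumeration); intended as a test oracle on
    small schedules.
    """
    preds = predecessor_map(node)
    out: set[tuple[str, ...]] = set()

    def extend(prefix: tuple[str, ...], remaining: set[str]):
        if not remaining:
            out.add(prefix)
            return
        done = set(prefix)
        for t in sorted(remaining):
            if preds[t] <= done:
                extend(prefix + (t,), remaining - {t})

    extend((), set(preds))
    return out


@dataclass
class ControlAugmentation:
    """Bookkeeping for the control layer added by :func:`augment`."""

    control_places: dict[str, str]        # scheduled transition id -> control place id
    start_place: str
    start_transition: str
    join_places: list[str] = field(default_factory=list)
    relay_transitions: list[str] = field(default_factory=list)
    control_arcs: list[Arc] = field(default_factory=list)
    colorset: ColorSet = CONTROL_COLORSET

    @property
    def all_control_places(self) -> set[str]:
        return set(self.control_places.values()) | set(self.join_places) | {self.start_place}

    @property
    def all_control_transitions(self) -> set[str]:
        return set(self.relay_transitions) | {self.start_transition}

    def seed(self, marking: Marking) -> Marking:
        """Return ``marking`` with control places cleared and one control
        token in the start place (arms one pass through the schedule)."""
        cleared = marking.without(self.all_control_places)
        return cleared.updated(add={self.start_place: _unit_counter(1)})

    def strip(self, net: Net) -> Net:
        """Remove the control layer, restoring the original net."""
        cp = self.all_control_places
        ct = self.all_control_transitions
        places = [p for p in net.places if p.id not in cp]
        transitions = [t for t in net.transitions if t.id not in ct]
        arcs = [a for a in net.arcs
                if a.source not in cp | ct and a.target not in cp | ct]
        return Net(places, transitions, arcs, dict(net.metadata))


def _unit_counter(n: int):
    from collections import Counter
    return Counter({UNIT: n})


def _unit_arc(src: str, dst: str, weight: int = 1) -> Arc:
    return Arc(src, dst, tuple(Expr("unit") for _ in range(weight)))


def augment(net: Net, schedule: ScheduleNode,
            start_transition_id: str = "t_start") -> tuple[Net, ControlAugmentation]:
    """Add a TGTC control layer enforcing ``schedule`` on ``net``.

    Every scheduled transition gains exactly one control place and one input
    control arc.  A new start transition (``start_transition_id``) consumes
    the initial control token and deposits one token per entry branch.  After
    a parallel block, the branch-terminal transitions all feed one shared
    join place; the successor's control arc carries weight = branch count, so
    it fires only when every branch has completed.  Transitions not in the
    schedule are left ungated.  Data places and arcs are untouched.
    """
    validate_schedule(schedule)
    known = {t.id for t in net.transitions}
    missing = [t for t in schedule_transitions(schedule) if t not in known]
    if missing:
        raise ScheduleError(f"scheduled transitions missing from net: {missing}")
    if start_transition_id in known:
        raise ScheduleError(f"start transition id {start_transition_id!r} already in net")

    new_places: list[Place] = []
    new_transitions: list[Transition] = []
    new_arcs: list[Arc] = []
    aug = ControlAugmentation(control_places={}, start_place="__ctrl_start",
                              start_transition=start_transition_id)
    counter = {"relay": 0}

    def fresh_relay() -> tuple[str, str]:
        counter["relay"] += 1
        return f"__ctrl_join_{counter['relay']}", f"__tgtc_relay_{counter['relay']}"

    def compile_node(node: ScheduleNode, producers: list[str]) -> list[str]:
        """Wire ``node`` so that each transition in ``producers`` deposits one
        control token toward it; return the node's terminal transitions."""
        if isinstance(node, Step):
            tid = node.transition
            cid = f"__ctrl_{tid}"
            new_places.append(Place(cid, CONTROL_COLORSET, f"control place of {tid}"))
            aug.control_places[tid] = cid
            for prod in producers:
                new_arcs.append(_unit_arc(prod, cid))
            new_arcs.append(_unit_arc(cid, tid, weight=len(producers)))
            if len(producers) > 1:
                aug.join_places.append(cid)
            return [tid]
        if isinstance(node, Seq):
            exits = producers
            for child in node.children:
                exits = compile_node(child, exits)
            return exits
        # Par: each branch needs its own token from a single producer.
        if len(producers) > 1:
            # collapse multiple producers through a relay so the token can be split
            jid, rid = fresh_relay()
            new_places.append(Place(jid, CONTROL_COLORSET, "join place"))
            aug.join_places.append(jid)
            new_transitions.append(Transition(rid))
            aug.relay_transitions.append(rid)
            for prod in producers:
                new_arcs.append(_unit_arc(prod, jid))
            new_arcs.append(_unit_arc(jid, rid, weight=len(producers)))
            producers = [rid]
        exits: list[str] = []
        for child in node.children:
            exits.extend(compile_node(child, list(producers)))
        return exits

    new_places.append(Place(aug.start_place, CONTROL_COLORSET, "schedule start"))
    new_transitions.append(Transition(start_transition_id))
    new_arcs.append(_unit_arc(aug.start_place, start_transition_id))
    compile_node(schedule, [start_transition_id])

    aug.control_arcs = list(new_arcs)
    augmented = net.extended(new_places, new_transitions, new_arcs)
    return augmented, aug


def verify_order(trace: FiringTrace | Iterable[str], schedule: ScheduleNode) -> bool:
    """True iff the trace, restricted to scheduled transitions, is an
    admissible prefix of a linear extension of the schedule's partial order
    (each scheduled transition fires at most once, and never before all of
    its predecessors)."""
    ids = trace.transition_ids if isinstance(trace, FiringTrace) else list(trace)
    preds = predecessor_map(schedule)
    fired: set[str] = set()
    for tid in ids:
        if tid not in preds:
            continue
        if tid in fired or not preds[tid] <= fired:
            return False
        fired.add(tid)
    return True
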