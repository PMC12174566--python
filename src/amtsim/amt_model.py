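"""Discrete-time organ-network dynamics of acupuncture/moxibustion treatment.

Each organ carries a scalar state in (0.5, 5.5), with [2.5, 3.5] the healthy
band around the target h = 3.  One simulation cycle (tau-1 -> tau) runs a
fixed stage pipeline:

1. Five-Elements stage (viscera): each element-bearing viscus X is updated
   synchronously from the previous cycle's states,
       f_X(tau') = g*f_gen(X)(tau-1) - r*f_res(X)(tau-1) + s*f_X(tau-1),
   where gen(X)/res(X) are X's generation and restriction partners.
2. Viscera -> bowels: f_B(tau') = c*f_V(tau') + s*f_B(tau-1) for each
   exterior-interior pair (all six, incl. pericardium <-> triple energizer).
3. Bowels -> viscera: f_V(tau'') = c*f_B(tau') + s*f_V(tau').
4. Acupoint stimulation: each treated acupoint contributes w * fp(mu, f) to
   its affiliated organ (summed over points; conception/governor-vessel and
   extra points are routed per ``vessel_routing``).  The stimulus kernel fp
   is pluggable, see below.
5. Substance generation/transport/absorption: systemic pools of qi, blood
   and body fluid are produced (scaled down by whole-body and
   generator-organ imbalance), transported (uniformly, scaled by
   transporter-organ imbalance) and absorbed,
       f_V(tau) = m*f_V + q*fq_V + b*fb_V + l*fl_V,
   after which states are clamped to the admissible bounds.

At the printed defaults g - r + s = c + s = 1 and
m + (q + b + l) * fi_normal/(v*h) * h = 1, so the all-3 state is an exact
fixed point of the full pipeline.

Stimulus kernels
----------------
``gated`` (default): fp(mu, f) = mu * e * v * min(1, |h - f| / delta1).
The stimulation direction is the treatment's (tonification raises, purgation
lowers) and its magnitude scales with the organ's *responsiveness* — its
distance from the healthy target — saturating at the full gain e*v once the
state is ``stimulus_scale`` away from target (default: half the distance
from the target to the upper admissible bound, (5.5 - 3)/2 = 1.25).  A
correctly signed protocol therefore corrects a pathological organ quickly
and its effect dies away as balance is restored, while a wrongly signed one
(purging a deficiency, tonifying an excess) actively harms — which is what
separates good from bad protocols in a screen.

``linear``: fp(mu) = mu * e * v / (v + e * v), a state-independent kernel
(0.2 * mu at the defaults).  A constant kernel either corrects too slowly
or pushes states past the healthy band under a sustained course, which is
why it is not the default; it is retained for sensitivity analyses.

The same pipeline can run as a direct sequential update (``mode='direct'``)
or compiled into a colored Petri net whose transitions embed the stage
equations as arc expressions, gated by a TGTC schedule (``mode='cpn'``).
Both modes agree to floating-point roundoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import pandas as pd

from . import organ_registry as reg
from .cpn_core import (
    Arc,
    ColorSet,
    ContractViolation,
    Marking,
    Net,
    Place,
    StructuralError,
    Transition,
    run as run_net,
)
from .tgtc import Par, ScheduleNode, Seq, augment

SUBSTANCES = ("qi", "blood", "fluid")


class ProtocolError(ValueError):
    """A stimulation protocol is invalid."""


def _default_fi_normal() -> dict:
    return {s: 3.0 for s in SUBSTANCES}


def _default_generators() -> dict:
    # the spleen is the source of the acquired essence in standard physiology
    return {"qi": "spleen", "blood": "spleen", "fluid": "spleen"}


def _default_transporters() -> dict:
    # lung governs qi, heart governs blood, kidney governs water
    return {"qi": "lung", "blood": "heart", "fluid": "kidney"}


@dataclass
class ModelParams:
    """Model parameters.

    The twelve scalar couplings are the published calibration: g/r/s the
    generation, restriction and self-retention weights of the Five-Elements
    stage; c the exterior-interior coupling; e and v the stimulus gain
    constants; w the per-acupoint stimulation weight; h the healthy target
    state; m the absorption retention and q/b/l the qi/blood/fluid absorption
    weights.
    """

    g: float = 0.15
    r: float = 0.05
    s: float = 0.9
    c: float = 0.1
    e: float = 0.25
    w: float = 0.01
    h: float = 3.0
    v: float = 10.0
    m: float = 0.999
    q: float = 0.004
    b: float = 0.004
    l: float = 0.002

    fi_normal: dict = field(default_factory=_default_fi_normal)
    organ_set: tuple = reg.ALL_ORGANS      # organs summed in the whole-body factor
    substance_generator: dict = field(default_factory=_default_generators)
    substance_transporter: dict = field(default_factory=_default_transporters)
    state_bounds: tuple = (0.5, 5.5)
    healthy_range: tuple = (2.5, 3.5)

    stimulus: str | Callable = "gated"     # "gated", "linear", or fp(mu, f, params)
    stimulus_scale: Optional[float] = None # responsiveness saturation distance;
                                           # default (state_bounds[1] - h) / 2
    vessel_routing: str | dict = "viscera" # CV/GV/EX routing: "viscera", "none", or map

    @property
    def gate_scale(self) -> float:
        if self.stimulus_scale is not None:
            return self.stimulus_scale
        return (self.state_bounds[1] - self.h) / 2.0

    @property
    def n(self) -> int:
        return len(self.organ_set)

    def stimulus_fn(self) -> Callable:
        if callable(self.stimulus):
            return self.stimulus
        if self.stimulus == "gated":
            return stimulus_gated
        if self.stimulus == "linear":
            return lambda mu, f, p: stimulus_linear(mu, p)
        raise ProtocolError(f"unknown stimulus kernel {self.stimulus!r}")

    def vessel_weights(self) -> dict[str, float]:
        """Routing weights for acupoints without an affiliated organ."""
        if isinstance(self.vessel_routing, Mapping):
            bad = set(self.vessel_routing) - set(reg.ALL_ORGANS)
            if bad:
                raise ProtocolError(f"unknown organs in vessel routing: {sorted(bad)}")
            return dict(self.vessel_routing)
        if self.vessel_routing == "none":
            return {}
        if self.vessel_routing == "viscera":
            return {v: 1.0 / len(reg.ELEMENT_VISCERA) for v in reg.ELEMENT_VISCERA}
        raise ProtocolError(f"unknown vessel routing {self.vessel_routing!r}")


def stimulus_linear(mu: float, params: ModelParams) -> float:
    """State-independent stimulus kernel: mu * e * v / (v + e * v)."""
    return mu * params.e * params.v / (params.v + params.e * params.v)


def stimulus_gated(mu: float, f: float, params: ModelParams) -> float:
    """Responsiveness-gated stimulus kernel (default; see module docstring)."""
    gate = min(1.0, abs(params.h - f) / params.gate_scale)
    return mu * params.e * params.v * gate


# --------------------------------------------------------------------------
# states and protocols
# --------------------------------------------------------------------------

def initial_states(**overrides: float) -> dict[str, float]:
    """All twelve organs at the healthy target 3.0, with overrides by name."""
    states = {o: 3.0 for o in reg.ALL_ORGANS}
    for name, value in overrides.items():
        if name not in states:
            raise ProtocolError(f"unknown organ {name!r}")
        states[name] = float(value)
    return states


def validate_states(states: Mapping[str, float], params: ModelParams | None = None) -> dict:
    params = params or ModelParams()
    lo, hi = params.state_bounds
    out = {}
    for organ in reg.ALL_ORGANS:
        if organ not in states:
            raise ProtocolError(f"missing state for organ {organ!r}")
        value = float(states[organ])
        if not lo <= value <= hi:
            raise ProtocolError(f"state {value} for {organ!r} outside [{lo}, {hi}]")
        out[organ] = value
    return out


def validate_protocol(protocol: Mapping[str, int]) -> dict[str, int]:
    """Canonicalize a map acupoint-code -> stimulation level in [-5, 5]."""
    out: dict[str, int] = {}
    for code, level in protocol.items():
        point = reg.parse_acupoint(code)
        level = int(level)
        if not -5 <= level <= 5:
            raise ProtocolError(f"stimulation level {level} for {code} outside [-5, 5]")
        key = str(point)
        if key in out:
            raise ProtocolError(f"acupoint {key} appears twice in protocol")
        if level != 0:
            out[key] = level
    return dict(sorted(out.items()))


def stimulation_terms(protocol: Mapping[str, int],
                      params: ModelParams) -> dict[str, list[tuple[int, float]]]:
    """Per organ, the (level, routing weight) stimulation terms of a protocol."""
    terms: dict[str, list[tuple[int, float]]] = {}
    vessel = params.vessel_weights()
    for code, level in validate_protocol(protocol).items():
        organ = reg.organ_of_acupoint(code)
        if organ is not None:
            terms.setdefault(organ, []).append((level, 1.0))
        else:
            for target, weight in vessel.items():
                terms.setdefault(target, []).append((level, weight))
    return terms


# --------------------------------------------------------------------------
# stage operations (direct mode)
# --------------------------------------------------------------------------

def step_viscera(states: Mapping[str, float], params: ModelParams) -> dict[str, float]:
    """Five-Elements stage: synchronous update of the five element-bearing
    viscera from the previous cycle's states; all other organs unchanged."""
    out = dict(states)
    for viscus in reg.ELEMENT_VISCERA:
        gen = states[reg.generation_partner(viscus)]
        res = states[reg.restriction_partner(viscus)]
        out[viscus] = params.g * gen - params.r * res + params.s * states[viscus]
    return out


def step_viscera_to_bowels(states: Mapping[str, float], prev: Mapping[str, float],
                           params: ModelParams) -> dict[str, float]:
    """Exterior-to-interior stage: each bowel follows its paired viscus."""
    out = dict(states)
    for viscus, bowel in reg.VISCUS_BOWEL_PAIRS:
        out[bowel] = params.c * states[viscus] + params.s * prev[bowel]
    return out


def step_bowels_to_viscera(states: Mapping[str, float],
                           params: ModelParams) -> dict[str, float]:
    """Interior-to-exterior feedback: each viscus follows its paired bowel."""
    out = dict(states)
    for viscus, bowel in reg.VISCUS_BOWEL_PAIRS:
        out[viscus] = params.c * states[bowel] + params.s * states[viscus]
    return out


def apply_stimulation(states: Mapping[str, float], protocol: Mapping[str, int],
                      params: ModelParams) -> dict[str, float]:
    """Acupoint stimulation stage: f_V += w * sum of fp over treated points.

    All stimulus terms are evaluated on the pre-stimulation states, so the
    contributions of several points on one organ sum (simultaneous
    application)."""
    fp = params.stimulus_fn()
    out = dict(states)
    for organ, terms in stimulation_terms(protocol, params).items():
        total = sum(weight * fp(mu, states[organ], params) for mu, weight in terms)
        out[organ] = states[organ] + params.w * total
    return out


def _whole_body_factor(states: Mapping[str, float], params: ModelParams) -> float:
    nh = params.n * params.h
    total = sum(states[o] for o in params.organ_set)
    return max(0.0, nh - abs(total - nh)) / nh


def _organ_factor(value: float, params: ModelParams) -> float:
    return max(0.0, params.h - abs(value - params.h)) / params.h


def substance_generation(states: Mapping[str, float],
                         params: ModelParams) -> dict[str, float]:
    """Generation of qi/blood/fluid pools, maximal (= fi_normal) when the
    whole body and the generator organ sit exactly at the target h."""
    body = _whole_body_factor(states, params)
    return {
        i: params.fi_normal[i] * body
           * _organ_factor(states[params.substance_generator[i]], params)
        for i in SUBSTANCES
    }


def substance_transport(fi: Mapping[str, float], states: Mapping[str, float],
                        params: ModelParams) -> dict[str, float]:
    """Uniform transported amount per organ for each substance."""
    body = _whole_body_factor(states, params)
    return {
        i: fi[i] / params.v * body
           * _organ_factor(states[params.substance_transporter[i]], params)
        for i in SUBSTANCES
    }


def substance_absorption(states: Mapping[str, float], deliveries: Mapping[str, float],
                         params: ModelParams) -> dict[str, float]:
    """Absorption stage with final clamping to the admissible state bounds."""
    lo, hi = params.state_bounds
    gain = (deliveries["qi"] * params.q + deliveries["blood"] * params.b
            + deliveries["fluid"] * params.l)
    return {organ: min(hi, max(lo, value * params.m + gain))
            for organ, value in states.items()}


def run_cycle(states: Mapping[str, float], protocol: Mapping[str, int],
              params: ModelParams, collect_stages: bool = False):
    """One full cycle tau-1 -> tau of the stage pipeline (direct update)."""
    prev = dict(states)
    tau_p = step_viscera(prev, params)                     # stage tau'
    tau_p = step_viscera_to_bowels(tau_p, prev, params)
    tau_pp = step_bowels_to_viscera(tau_p, params)         # stage tau''
    tau_hat = apply_stimulation(tau_pp, protocol, params)  # tau~ -> tau^
    fi = substance_generation(tau_hat, params)
    deliveries = substance_transport(fi, tau_hat, params)
    new = substance_absorption(tau_hat, deliveries, params)
    if collect_stages:
        stages = {"tau_prime": tau_p, "tau_second": tau_pp, "tau_hat": tau_hat}
        return new, fi, stages
    return new, fi, None


# --------------------------------------------------------------------------
# trajectories
# --------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Per-cycle record of organ and substance states, tau = 0..T.

    ``df`` has the cycle index ``tau`` as index and one column per organ
    plus ``qi``, ``blood``, ``fluid`` (the generated pool levels; the tau=0
    row reports the pools implied by the initial states)."""

    df: pd.DataFrame
    stages: Optional[pd.DataFrame] = None

    @property
    def n_cycles(self) -> int:
        return len(self.df) - 1

    def organs(self) -> pd.DataFrame:
        return self.df[list(reg.ALL_ORGANS)]

    def states_at(self, tau: int) -> dict[str, float]:
        return self.df.loc[tau, list(reg.ALL_ORGANS)].to_dict()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index_label="tau", float_format="%.6g",
                       lineterminator="\n")

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path, index_col="tau")
        missing = set(reg.ALL_ORGANS) - set(df.columns)
        if missing:
            raise ProtocolError(f"trajectory file lacks organ columns: {sorted(missing)}")
        return cls(df)

    @classmethod
    def from_records(cls, rows: list[dict], stage_rows: list[dict] | None = None) -> "Trajectory":
        df = pd.DataFrame(rows)
        df.index.name = "tau"
        stages = None
        if stage_rows:
            stages = pd.DataFrame(stage_rows).set_index(["tau", "stage"])
        return cls(df, stages)


def first_cycle_in_range(traj: Trajectory, organs, healthy_range=(2.5, 3.5)) -> Optional[int]:
    """First cycle tau >= 1 at which all given organs lie in the healthy
    range, or None if that never happens."""
    lo, hi = healthy_range
    sub = traj.df.loc[1:, list(organs)]
    ok = ((sub >= lo) & (sub <= hi)).all(axis=1)
    hits = ok[ok].index
    return int(hits[0]) if len(hits) else None


def simulate(initial: Mapping[str, float], protocol: Mapping[str, int], steps: int,
             params: ModelParams | None = None, mode: str = "direct", seed: int = 0,
             record_stages: bool = False) -> Trajectory:
    """Simulate ``steps`` cycles of the treatment pipeline.

    ``mode='direct'`` evaluates the stage equations in sequence;
    ``mode='cpn'`` compiles the pipeline into a TGTC-scheduled colored Petri
    net and executes it (``seed`` picks among admissible interleavings; the
    result is interleaving-invariant).
    """
    if steps < 0:
        raise ContractViolation("steps must be >= 0")
    params = params or ModelParams()
    states = validate_states(initial, params)
    protocol = validate_protocol(protocol)
    if mode == "direct":
        return _simulate_direct(states, protocol, steps, params, record_stages)
    if mode == "cpn":
        return _simulate_cpn(states, protocol, steps, params, seed)
    raise ProtocolError(f"unknown mode {mode!r}")


def _row(states: Mapping[str, float], fi: Mapping[str, float]) -> dict:
    row = {o: states[o] for o in reg.ALL_ORGANS}
    row.update({i: fi[i] for i in SUBSTANCES})
    return row


def _simulate_direct(states, protocol, steps, params, record_stages) -> Trajectory:
    rows = [_row(states, substance_generation(states, params))]
    stage_rows: list[dict] = []
    for tau in range(1, steps + 1):
        states, fi, stages = run_cycle(states, protocol, params,
                                       collect_stages=record_stages)
        rows.append(_row(states, fi))
        if stages:
            for name, snap in stages.items():
                stage_rows.append({"tau": tau, "stage": name, **snap})
    return Trajectory.from_records(rows, stage_rows or None)


# --------------------------------------------------------------------------
# CPN compilation
# --------------------------------------------------------------------------

REAL = ColorSet("REAL", "REAL")
INT = ColorSet("INT", "INT")


def _fmt(x: float) -> str:
    return repr(float(x))


def _stim_term_expr(var: str, mu: int, weight: float, params: ModelParams) -> str:
    """Mini-language source of one stimulus term w*weight*fp(mu, f)."""
    if callable(params.stimulus):
        raise StructuralError(
            "cpn mode requires a named stimulus kernel ('gated' or 'linear')")
    if params.stimulus == "linear":
        return _fmt(params.w * weight * stimulus_linear(mu, params))
    gain = params.w * weight * mu * params.e * params.v
    h, d1 = _fmt(params.h), _fmt(params.gate_scale)
    return f"{_fmt(gain)}*min(1.0, abs({h} - {var})/{d1})"


def build_net(protocol: Mapping[str, int], params: ModelParams | None = None
              ) -> tuple[Net, ScheduleNode, Marking]:
    """Compile the stage pipeline for ``protocol`` into a colored Petri net.

    Data layer: one REAL place per organ state, staging places for the
    synchronous Five-Elements update, one INT place per treated acupoint
    (holding its stimulation level), and REAL places for the substance pools
    and transported amounts.  The returned schedule runs the snapshot and
    Five-Elements transitions in parallel per viscus, the six
    exterior-interior pair chains as parallel branches, then the stimulation
    and substance transitions in sequence; :func:`amtsim.tgtc.augment` turns
    it into control places/arcs.  The returned marking holds the acupoint
    levels (organ states are seeded by the caller).
    """
    params = params or ModelParams()
    protocol = validate_protocol(protocol)
    places: list[Place] = []
    transitions: list[Transition] = []
    arcs: list[Arc] = []

    def organ_place(o: str) -> str:
        return f"p_{o}"

    for organ in reg.ALL_ORGANS:
        places.append(Place(organ_place(organ), REAL, f"state of {organ}"))

    # --- Five-Elements stage: snapshot then synchronous update -------------
    snap_ids, eq1_ids = [], []
    for viscus in reg.ELEMENT_VISCERA:
        for role in ("self", "asgen", "asres"):
            places.append(Place(f"stage_{viscus}_{role}", REAL,
                                f"{viscus} snapshot ({role})"))
        tid = f"t_snap_{viscus}"
        snap_ids.append(tid)
        transitions.append(Transition(tid))
        arcs.append(Arc(organ_place(viscus), tid, ("x",)))
        for role in ("self", "asgen", "asres"):
            arcs.append(Arc(tid, f"stage_{viscus}_{role}", ("x",)))
    for viscus in reg.ELEMENT_VISCERA:
        tid = f"t_five_{viscus}"
        eq1_ids.append(tid)
        transitions.append(Transition(tid))
        arcs.append(Arc(f"stage_{viscus}_self", tid, ("x",)))
        arcs.append(Arc(f"stage_{reg.generation_partner(viscus)}_asgen", tid, ("y",)))
        arcs.append(Arc(f"stage_{reg.restriction_partner(viscus)}_asres", tid, ("z",)))
        arcs.append(Arc(tid, organ_place(viscus),
                        (f"{_fmt(params.g)}*y - {_fmt(params.r)}*z + {_fmt(params.s)}*x",)))

    # --- exterior-interior pair chains -------------------------------------
    pair_chains = []
    for viscus, bowel in reg.VISCUS_BOWEL_PAIRS:
        t_vb = f"t_out_{bowel}"
        transitions.append(Transition(t_vb))
        arcs.append(Arc(organ_place(viscus), t_vb, ("x",)))
        arcs.append(Arc(organ_place(bowel), t_vb, ("y",)))
        arcs.append(Arc(t_vb, organ_place(viscus), ("x",)))
        arcs.append(Arc(t_vb, organ_place(bowel),
                        (f"{_fmt(params.c)}*x + {_fmt(params.s)}*y",)))
        t_bv = f"t_back_{viscus}"
        transitions.append(Transition(t_bv))
        arcs.append(Arc(organ_place(viscus), t_bv, ("x",)))
        arcs.append(Arc(organ_place(bowel), t_bv, ("y",)))
        arcs.append(Arc(t_bv, organ_place(bowel), ("y",)))
        arcs.append(Arc(t_bv, organ_place(viscus),
                        (f"{_fmt(params.c)}*y + {_fmt(params.s)}*x",)))
        pair_chains.append(Seq(t_vb, t_bv))

    # --- stimulation stage (single simultaneous transition) ----------------
    marking_tokens: dict[str, list] = {}
    terms = stimulation_terms(protocol, params)
    organ_vars = {organ: f"o_{organ}" for organ in reg.ALL_ORGANS}
    stim_ids = []
    if protocol:
        tid = "t_stimulate"
        stim_ids.append(tid)
        transitions.append(Transition(tid))
        for i, (code, level) in enumerate(protocol.items()):
            pid = f"ap_{code.replace('-', '_')}"
            places.append(Place(pid, INT, f"acupoint {code}"))
            marking_tokens[pid] = [level]
            var = f"a{i}"
            arcs.append(Arc(pid, tid, (var,)))
            arcs.append(Arc(tid, pid, (var,)))
        for organ in reg.ALL_ORGANS:
            var = organ_vars[organ]
            arcs.append(Arc(organ_place(organ), tid, (var,)))
            if organ in terms:
                summed = " + ".join(_stim_term_expr(var, mu, weight, params)
                                    for mu, weight in terms[organ])
                arcs.append(Arc(tid, organ_place(organ), (f"{var} + ({summed})",)))
            else:
                arcs.append(Arc(tid, organ_place(organ), (var,)))

    # --- substance stage ----------------------------------------------------
    for sub in SUBSTANCES:
        places.append(Place(f"pool_{sub}", REAL, f"{sub} pool"))
        places.append(Place(f"delivered_{sub}", REAL, f"{sub} transported amount"))

    nh = params.n * params.h
    sum_src = " + ".join(organ_vars[o] for o in params.organ_set)
    body = f"max(0.0, {_fmt(nh)} - abs(({sum_src}) - {_fmt(nh)}))/{_fmt(nh)}"

    def organ_factor(var: str) -> str:
        return f"max(0.0, {_fmt(params.h)} - abs({var} - {_fmt(params.h)}))/{_fmt(params.h)}"

    t_gen = Transition("t_generate")
    transitions.append(t_gen)
    for organ in reg.ALL_ORGANS:
        arcs.append(Arc(organ_place(organ), "t_generate", (organ_vars[organ],)))
        arcs.append(Arc("t_generate", organ_place(organ), (organ_vars[organ],)))
    for sub in SUBSTANCES:
        gen_var = organ_vars[params.substance_generator[sub]]
        arcs.append(Arc("t_generate", f"pool_{sub}",
                        (f"{_fmt(params.fi_normal[sub])}*({body})*({organ_factor(gen_var)})",)))

    t_tr = Transition("t_transport")
    transitions.append(t_tr)
    for organ in reg.ALL_ORGANS:
        arcs.append(Arc(organ_place(organ), "t_transport", (organ_vars[organ],)))
        arcs.append(Arc("t_transport", organ_place(organ), (organ_vars[organ],)))
    for sub in SUBSTANCES:
        pool_var = f"pool{sub}"
        arcs.append(Arc(f"pool_{sub}", "t_transport", (pool_var,)))
        arcs.append(Arc("t_transport", f"pool_{sub}", (pool_var,)))
        tr_var = organ_vars[params.substance_transporter[sub]]
        arcs.append(Arc("t_transport", f"delivered_{sub}",
                        (f"{pool_var}/{_fmt(params.v)}*({body})*({organ_factor(tr_var)})",)))

    t_ab = Transition("t_absorb")
    transitions.append(t_ab)
    lo, hi = params.state_bounds
    for sub in SUBSTANCES:
        arcs.append(Arc(f"delivered_{sub}", "t_absorb", (f"d{sub}",)))
    gain = (f"dqi*{_fmt(params.q)} + dblood*{_fmt(params.b)} + dfluid*{_fmt(params.l)}")
    for organ in reg.ALL_ORGANS:
        var = organ_vars[organ]
        arcs.append(Arc(organ_place(organ), "t_absorb", (var,)))
        arcs.append(Arc("t_absorb", organ_place(organ),
                        (f"min({_fmt(hi)}, max({_fmt(lo)}, {var}*{_fmt(params.m)} + {gain}))",)))

    schedule = Seq(
        Par(*snap_ids),
        Par(*eq1_ids),
        Par(*pair_chains),
        *stim_ids,
        "t_generate", "t_transport", "t_absorb",
    )
    net = Net(places, transitions, arcs,
              metadata={"module": "treatment pipeline", "protocol_size": len(protocol)})
    return net, schedule, Marking(marking_tokens)


def _simulate_cpn(states, protocol, steps, params, seed) -> Trajectory:
    from .tgtc import schedule_transitions

    net, schedule, protocol_marking = build_net(protocol, params)
    augmented, aug = augment(net, schedule, start_transition_id="t_start")
    # one pass fires every scheduled transition, the start transition and any
    # control relays the augmentation inserted between parallel blocks
    n_firings = len(schedule_transitions(schedule)) + 1 + len(aug.relay_transitions)

    base = {f"p_{o}": [states[o]] for o in reg.ALL_ORGANS}
    marking = Marking(base)
    for pid in protocol_marking.places():
        marking = marking.updated(add={pid: protocol_marking.tokens(pid)})

    rows = [_row(states, substance_generation(states, params))]
    for _tau in range(1, steps + 1):
        marking = aug.seed(marking)
        trace = run_net(augmented, marking, max_steps=n_firings + 5,
                        seed=seed, policy="random")
        marking = trace.final_marking
        if len(trace) != n_firings:
            raise StructuralError(
                f"cycle deadlocked after {len(trace)} of {n_firings} firings")
        cur = {o: marking.value(f"p_{o}") for o in reg.ALL_ORGANS}
        fi = {sub: marking.value(f"pool_{sub}") for sub in SUBSTANCES}
        rows.append(_row(cur, fi))
        # pools and leftover deliveries are per-cycle quantities
        marking = marking.without([f"pool_{s}" for s in SUBSTANCES]
                                  + [f"delivered_{s}" for s in SUBSTANCES])
    return Trajectory.from_records(rows)
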