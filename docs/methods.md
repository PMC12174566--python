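# Methods

## Model overview

The package simulates a course of acupuncture/moxibustion treatment as a
discrete-time dynamical system over twelve organ-state variables, with an
explicit stage pipeline per cycle: Five-Elements generation/restriction
among the five element-bearing viscera, exterior-to-interior regulation
from viscera to bowels, the reciprocal feedback, acupoint stimulation, and
qi–blood–fluid generation/transport/absorption.  Stage ordering is part of
the model's semantics: the Five-Elements stage reads only the previous
cycle's values (synchronous update), each later stage reads the output of
the one before it, and a regression test guards against accidental
reordering (swapping the two exterior–interior stages measurably changes a
deficiency trajectory).

States live in (0.5, 5.5) and are clamped once per cycle, after
absorption.  The interval [2.5, 3.5] is the healthy band; (0.5, 1.5) and
[1.5, 2.5) are weakness and mild weakness, (3.5, 4.5] and (4.5, 5.5) mild
strength and strength.

## Parameters

| symbol | default | meaning |
|---|---|---|
| g | 0.15 | generation-cycle coupling between viscera |
| r | 0.05 | restriction-cycle coupling |
| s | 0.9  | self-retention of the organ state |
| c | 0.1  | exterior–interior (viscus↔bowel) coupling |
| e, v | 0.25, 10 | stimulus gain constants (effect scale e·v = 2.5) |
| w | 0.01 | per-acupoint stimulation weight |
| h | 3 | healthy target state |
| m | 0.999 | absorption retention |
| q, b, l | 0.004, 0.004, 0.002 | qi/blood/fluid absorption weights |

These are the published calibration and are not re-fit here.  Two
identities make the uniform healthy state an exact fixed point:
g − r + s = c + s = 1, and at equilibrium each substance pool is
fi_normal = 3, each organ receives fi/v = 0.3, and
m·3 + 0.3·(q + b + l) = 3 exactly.  fi_normal = 3 is the unique pool level
with this property and is the default for all three substances
(configurable).

Substance physiology defaults (configurable, as the main text leaves them
open): the spleen generates all three pools (source of the acquired
essence); transport is governed by the lung (qi), heart (blood) and kidney
(fluid).  The whole-body factor in generation/transport sums all twelve
organs (n = 12).

## The stimulus kernel

The stimulation stage is `f_V ← f_V + w·Σ_a fp(μ_a, f_V)`, summing over
treated acupoints affiliated with organ V; all terms are evaluated on the
pre-stimulation state, so multiple points on one meridian add
simultaneously.  The kernel fp is deliberately pluggable, because the
printed form of the stimulus equation is ambiguous and its appendix-level
definition is not available.  Two kernels ship:

* `linear` — `fp(μ) = μ·e·v/(v + e·v) = 0.2·μ`: the literal ratio
  reading.  Its per-cycle effect (≤ 0.01·|μ| after the weight w) is an
  order of magnitude too small to reproduce the reported recovery speed of
  the reference case, and *any* state-independent kernel fails on one side
  or the other: too weak misses the recovery window, strong enough
  overshoots and drifts out of the healthy band under a sustained
  50-cycle course.  Kept for sensitivity analyses.
* `gated` (default) — `fp(μ, f) = μ·e·v·min(1, |h − f|/δ₁)`: the
  treatment acts in its own direction (tonification raises, purgation
  lowers) with a magnitude proportional to the organ's *responsiveness*,
  its distance from the healthy target, saturating at the full gain e·v
  once the state is δ₁ away from target.  δ₁ defaults to half the distance
  from target to the admissible bound, (5.5 − 3)/2 = 1.25.  Consequences:
  a correctly signed protocol corrects a pathological organ quickly and
  its effect dies out as balance is restored; a wrongly signed protocol
  (purging a deficiency, tonifying an excess) actively harms — which is
  what gives the screening step its discriminative power.

With the default kernel the reference Meniere's case (liver 5, spleen 1,
kidney 1, six-point protocol at ±3) brings all three treated organs into
the healthy band by cycle 7 of 50 and holds them there through the end of
the course, with final states within 0.22 of the target.

Acupoints on the conception and governor vessels (and the extra points)
have no affiliated organ.  The default routing distributes their
contribution equally across the five element-bearing viscera (weight 1/5
each), reflecting their systemic character; `none` and custom per-organ
weight maps are available.  The reference protocol's GV20/GV16 tonification
requires *some* systemic route for its intent to register at all.

## CPN execution and TGTC

`build_net` compiles the pipeline into a colored Petri net: REAL-colored
places for organ states, substance pools and transported amounts,
INT-colored places holding each treated acupoint's level, and transitions
whose arc expressions (a safe arithmetic mini-language: constants,
variables, + − × ÷, abs/min/max, comparisons) embed the stage equations.
The synchronous Five-Elements stage is realized with snapshot places: a
per-viscus snapshot transition first copies the state into three staging
places (own update, generation input, restriction input), so the five
update transitions can fire in any order and still read only
previous-cycle values.

The schedule runs the snapshots and Five-Elements updates as parallel
blocks, the six viscera–bowel pair chains as parallel branches, then
stimulation and the three substance transitions in sequence.  The TGTC
layer enforces it: one UNIT-colored control place and input control arc
per scheduled transition, sequential hand-off of the control token along
Seq chains, token splitting into one copy per Par branch, and a shared
join place whose outgoing arc weight equals the branch count so the
successor fires only when every branch has completed.  Consecutive
parallel blocks are bridged by a relay transition that collapses the join
tokens and re-splits them.  The control layer is disjoint from the data
layer; stripping it restores the original net exactly, and the augmented
net's reachable firing orders are exactly the linear extensions of the
schedule's partial order (verified exhaustively on a ten-transition
fork–join schedule: 20 interleavings).

Each simulated cycle re-arms the control layer with one token in the start
place and runs the net to completion; pools and deliveries are cleared
between cycles.  Because every admissible interleaving computes the same
states, direct and CPN trajectories agree to floating-point roundoff
(observed ≈1e−14 over 50 cycles); the equivalence suite checks the
reference protocol over the full course and 100 random protocols over
5-cycle runs, a length chosen to keep the whole suite fast while still
exercising every stage each cycle.

## Evaluation defaults

Eval = 0.4·PTR + 0.4·fRMSD + 0.2·PET.  The composite rule and its weights
are fixed; the component internals are documented defaults exposed in
configuration, since their published appendix-level definitions are not
available:

* PTR averages the in-band time fraction over all twelve organs, cycles
  1..T (the initial condition is excluded so a protocol is not penalized
  for the presenting pathology).
* fRMSD uses sliding windows of length W = 10 over cycles 1..T, per-organ
  minimum, threshold θ = 0.5 (the healthy band half-width), target h.
* PET uses a pointwise min/max envelope over the reference trajectories
  with margin δ = 0.25, counted over (organ, cycle) points, cycles 1..T.

Display rounding is half-to-even at 3 decimals (2 for components); all
arithmetic is done at full precision.

## Protocol generation

The three screening strategies draw from the WHO acupoint registry (361
standard points on 14 meridians + 48 extra points, validated against the
published per-meridian counts at load): R samples uniformly from all 409
points excluding the reference protocol's points (exclusion is at acupoint
level — published random rounds do reuse meridians that appear in the
reference); M restricts to the affected organs' own meridians; C to the
meridians of their paired bowels.  Protocol sizes are uniform on 5–7
(the range observed across the published screening rounds) and levels
uniform on the nonzero integers in [−5, 5]; the published rounds favor ±3
but no generation law is stated, so the uniform law is the default and the
level set is configurable.

## Known limitations

* The gated kernel lets sustained tonification push past the target once
  an organ recovers: far beyond the 50-cycle treatment course (≈cycle 70+
  for the reference case) states drift out of the healthy band.  The model
  represents a finite course, not indefinite maintenance treatment.
* Component scores for the screening groups do not reproduce the published
  per-group PTR/PET values — those depend on unavailable appendix-level
  definitions; the composite rule and the qualitative separation of good
  from harmful protocols are what the package reproduces.
* The whole-body imbalance factor uses the absolute deviation of the organ
  sum, so equal-and-opposite organ deviations cancel in it; only the
  per-organ generator/transporter factors see them.
* The eight extraordinary meridians beyond the conception and governor
  vessels are not modeled; extra points are supported in the registry but
  route like vessel points.
* One simulation cycle is an abstract treatment iteration, not a calibrated
  physical duration; cross-case comparisons are in cycles, not days.
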