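# amtsim

Simulation and screening of acupuncture/moxibustion treatment (AMT)
protocols on a discrete-time organ network, executed either directly or as
a colored Petri net (CPN) under token-guided transition control (TGTC).

## Who this is for

Researchers in computational traditional Chinese medicine and systems
biology who want a quantitative, reproducible way to (a) simulate how a
course of acupoint stimulation moves internal-organ states toward or away
from balance, and (b) screen candidate acupoint/level combinations against
a clinically validated reference protocol.

## The model

Each of the twelve internal organs (five element-bearing viscera — liver,
heart, spleen, lung, kidney — plus pericardium and the six paired bowels)
carries a scalar state f in (0.5, 5.5); [2.5, 3.5] is the healthy band
around the target h = 3.  One simulation cycle τ−1 → τ runs a fixed stage
pipeline:

1. **Five-Elements stage** (synchronous over the five viscera):
   `f_X(τ') = g·f_gen(X)(τ−1) − r·f_res(X)(τ−1) + s·f_X(τ−1)`,
   with gen/res the generation (wood→fire→earth→metal→water→wood) and
   restriction (wood⊣earth, earth⊣water, water⊣fire, fire⊣metal,
   metal⊣wood) partners.
2. **Viscera → bowels**: `f_B(τ') = c·f_V(τ') + s·f_B(τ−1)` per
   exterior–interior pair (liver↔gallbladder, …, pericardium↔triple
   energizer).
3. **Bowels → viscera**: `f_V(τ'') = c·f_B(τ') + s·f_V(τ')`.
4. **Acupoint stimulation**: each treated point contributes `w·fp(μ, f)` to
   its meridian's organ (μ ∈ [−5, 5]; μ > 0 tonification, μ < 0 purgation;
   conception/governor-vessel points route across the five viscera).  The
   default kernel is responsiveness-gated:
   `fp(μ, f) = μ·e·v·min(1, |h − f|/δ₁)`.
5. **Qi–blood–fluid regulation**: systemic pools are generated (scaled by
   whole-body and generator-organ balance), transported uniformly, and
   absorbed: `f_V(τ) = m·f_V + q·fq + b·fb + l·fl`, then clamped.

Default parameters: g = 0.15, r = 0.05, s = 0.9, c = 0.1, e = 0.25,
w = 0.01, h = 3, v = 10, m = 0.999, q = b = 0.004, l = 0.002.  Because
g − r + s = c + s = 1 and absorption exactly reconstitutes the target, the
all-3 state is an exact fixed point.

The same pipeline compiles into a colored Petri net — one place per organ
state, acupoint and substance pool, transitions embedding the stage
equations as arc expressions — and a TGTC control layer (control places,
tokens and arcs) forces the net to fire in the physiological stage order
while leaving the six viscera–bowel pair chains genuinely concurrent.
Direct and CPN execution agree to ≈1e−14 per state per cycle.

Protocols are scored by `Eval = 0.4·PTR + 0.4·fRMSD + 0.2·PET`, where PTR
is the time fraction organs spend in the healthy band, fRMSD a binary
minimum-windowed-RMSD indicator, and PET the fraction of points inside a
reference-trajectory envelope (±0.25 margin).

## Worked example

The Meniere's-disease pattern is liver excess with spleen and kidney
deficiency (initial states 5, 1, 1; all other organs 3).  The clinical
reference protocol purges GB20 at normal intensity (−3) and tonifies GV20,
GV16, BL23, KI3 and GB39 (+3), for 50 cycles:

```
$ amtsim fixtures -o fx
$ amtsim simulate -c fx/protocols/Ref.json -o ref_run
wrote ref_run/trajectory.csv (50 cycles)
final states: liver=2.923, heart=2.977, spleen=3.207, lung=3.259,
kidney=3.109, pericardium=2.967, gallbladder=2.893, small_intestine=3.057,
stomach=3.247, large_intestine=3.166, bladder=3.019, triple_energizer=2.967
```

All three pathological organs are back inside the healthy band by cycle 7
and settle near 3.0.  Screening the sixteen case-study protocols against
the reference run:

```python
from amtsim import simulate, batch_screen, load_fixture_protocols, first_cycle_in_range
from amtsim.fixtures import meniere_initial_states

init = meniere_initial_states()
ref = simulate(init, load_fixture_protocols()["Ref"], 50)
print(first_cycle_in_range(ref, ["liver", "spleen", "kidney"]))   # 7
for entry in batch_screen(load_fixture_protocols(), init, 50, reference=ref)[:3]:
    print(entry.group, entry.result.as_row())
```

prints a ranking headed by the reference protocol
(`Ref PTR=0.94 fRMSD=1 PET=1.00 Eval=0.974`), with wrongly-signed random
protocols falling below 0.4 (e.g. `R1 Eval=0.315`) because purging an
already-deficient organ actively harms it.  `amtsim explore --strategy M`
generates and ranks fresh meridian-constrained candidates the same way.

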