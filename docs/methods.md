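# Methods

## Model

All nodes follow the additive shunting membrane equation
τ·dx/dt = −A·x + (B − x)·E − (x − D)·I with decay A = 1, excitatory
ceiling B = 1 and floor D = 0 (D = −1 for the matching layer, see below).
E and I are non-negative drives assembled from the thresholded output
signals of other layers; layers never read raw potentials.  Integration is
synchronous explicit Euler with dt = 0.01 time units: each step computes
every layer's drives from the previous step's outputs, so results are
independent of the order in which layers are declared.  The step size
satisfies dt·(A + E + I)/τ < 1 for every layer at its maximal drive, which
makes the Euler map contractive toward [D, B]; the integrator nevertheless
aborts with the offending time point if a potential ever leaves its bounds
by more than 1e−6.

Signal functions: threshold-linear rectification for the input, matching
and gain layers; squared rectification (faster than linear) for the
category layer's recurrent collaterals, which is what turns the
competitive field into a choice circuit; a rectified steep sigmoid for the
reset node so it acts as a gate.

### One ART module

- **F0 (registration).** E = 2·s + 0.5·f0 (input plus self-excitation),
  I = 0.05·(Σf0 − f0) (off-surround).  With a unit-amplitude bump the
  equilibrium potential is ≈ 0.68; the output threshold 0.2 leaves uniform
  noise at 10 % of peak sub-threshold while preserving multiple
  simultaneous bumps (F0 enhances, it does not choose).
- **F1 (matching).** E = 4·f0 + 0.7·(Tᵀ·f2) (bottom-up plus top-down
  template read-out), I = 1.22·g1, with floor D = −1 so the non-specific
  inhibition acts subtractively near rest.  The output threshold 0.22 is
  elevated: with G1 fully driven, nodes receiving only bottom-up input
  equilibrate at ≈ 0.17 (silent) and nodes receiving both inputs at
  ≈ 0.31 (active) — the AND rule.  Without any active category G1 is
  silent and F1 mirrors F0.  Because top-down excitation (≤ 0.7·f2) is
  always smaller than the G1 inhibition it recruits, expectation alone
  drives F1 *negative*: the circuit cannot hallucinate.  This holds for
  priming drives up to ≈ 1.5; far stronger artificial drives would push
  the category layer past the gain control, which is outside the operating
  envelope (the default associative gain is 0.85).
- **G1.** E = 14·Σf2 (τ = 1.5).  The gain is a compromise: large enough
  that a weakly primed category pair (total output ≈ 0.12) produces a
  clearly measurable G1 signal (the F1-region activation in the metabolic
  battery), small enough that priming-level G1 still lets F1 answer
  bottom-up input — otherwise match trials would open a spurious mismatch
  window at target onset.
- **G2.** E = gate·(1 + 0.5·Σf2) with the multiplicative gate
  max(1 − Σf0, 0): sensory registration shuts G2 off entirely (potential
  decays to ≈ 0, which matters for the absolute-potential metabolic
  metric).  G2's inhibition of F2 (gain 15) makes the no-input field
  monostable at a weak equilibrium: a primed category sits at potential
  ≈ 0.09, output ≈ 0.06 — supra-threshold but an order of magnitude below
  resonance.
- **F2 (choice).** E = 0.3·(W·f1) + priming + rec + bias,
  I = 0.4·(Σrec − rec) + 15·g2 + latch, where rec = 40·max(x − 0.10, 0)²
  is the recurrent collateral.  With input present (G2 released) any
  seeded category ignites and self-amplifies to ≈ 0.94 potential; lateral
  inhibition from the leader's collaterals crushes the rest, so the
  settled choice has exactly one full-amplitude node.  An infinitesimal
  index-decreasing bias (1e−3) makes exact ties resolve deterministically
  to the lowest index.  Bottom-up weights are row-normalized templates
  (the filtered signal is the mean matched F1 activity), top-down weights
  are the binary templates.
- **R (reset).** E = 2·m + 1.5·Σf2, I = 3 (tonic), where
  m = max(ρ·Σf0 − Σf1, 0)/Σf0 is the vigilance-gated mismatch.  The
  normalization by Σf0 implements a ratio comparison, making the reset
  calibration independent of input-layer size (hue arrays and word grids
  differ by a factor of four in total activity).  The tonic inhibition is
  sized so neither the mismatch alone (first feedforward wave, asymptote
  0.28) nor category activity alone (asymptote 0.25) can reach the
  threshold 0.35, while their conjunction (asymptote 0.42) does, after a
  first-passage time proportional to τ_R.
- **F3 (latch).** Idealized as coincidence-gated flip-flops: at the moment
  R crosses its threshold (rising edge), every category whose membrane
  potential exceeds a low floor (0.02) enters the latch set; a latched
  category's excitatory drive is gated off and strong inhibition drains
  it, so its output is exactly zero for the remainder of the trial.  The
  edge trigger matters: during R's decay the *next* category sought by
  the field is already rising and a continuously active gate would clip
  it.  The low potential floor matters because the erroneous expectation
  spans several hue categories, of which only one wins the competition —
  the siblings, held just below output threshold by the winner's lateral
  inhibition, must be removed in the same reset or they would trigger a
  second one.

Vigilance defaults to ρ = 0.8 in both modules.  Learning (fast template
contraction at resonance, with re-normalized bottom-up weights) is
implemented and tested but switched off in all replication experiments;
the modules run on pre-committed weights generated from the stimuli.

### Two modules and the associative map

The color module's input is a 1-D array of 50 hue-tuned nodes; each color
word owns two overlapping boxcar bumps (width 4, overlap 0.5), different
colors are disjoint.  The word module's input is a flattened 5×7 binary
glyph; glyphs are derived deterministically from the word label (MD5
bits), pairwise distinct by construction — recognizability is irrelevant
to the model, distinctness is what matters.  The lexicon is six color
words and six neutral words.

The associative map contains one concept node per color word, linked
one-to-one to the word category and one-to-many (fan-out 2 by default) to
the hue categories.  Map nodes are pass-through gates without intrinsic
dynamics; the expectation drive they deliver to color F2 is a single
configurable gain (0.85) shared by all links.  Neutral words have no
concept node and deliver a zero drive, so a neutral-word trial is
node-for-node identical to a no-word trial.  The word module always runs
with the slow reset preset (the task's speed manipulation applies to the
color module) and with a doubled bottom-up gain: its category race starts
with every committed word partially supported, and ignition must outrun
the gain-control throttle.

### Trial protocol and response network

1. *Reference phase* (40 units): the reference hue drives the color
   module to resonance; the winner is latched into the binary working
   memory F5.  Simulated once per reference color and cached — the
   reference presentation precedes every trial identically.
2. *Word phase* (40 units): the glyph drives the word module to
   resonance; the resonant word node's map projection is held constant as
   the color-module priming for the main phase.
3. *Main phase*: priming from t = 0, target hue at t = 40, run until a
   response or t = 250.

Comparison layers are algebraic read-outs of the current outputs: C1 =
max(f2 + f5 − 1.2, 0) (AND via elevated threshold; neither input alone
reaches 1.2) and C2 = a saturating unit per node active when f2 + f5
exceeds 0.2 (OR).  The Same accumulator integrates 2·ΣC1, the Different
accumulator 3·max(ΣC2 − 1.5, 0) — the elevated input gate that makes one
active C2 node insufficient and two sufficient.  Both are leaky (leak 1,
τ = 5) with mutual inhibition 0.5 and rectification at zero, and the
first to cross the motor threshold (default 0.5; the effect ordering is
unchanged anywhere in [0.2, 1]) issues the response.

The F2 input to both comparison layers is multiplied by a *mismatch veto*
max(1 − m/0.2, 0): while a vigilance mismatch is pending, the comparison
network reads nothing from the category layer.  This is a design addition
of this implementation, beyond the classical circuit: without it, the transient full
activation of an erroneous expectation (one C2 node) together with the
working-memory node (a second C2 node) drives the Different unit during
the pre-reset window, and at slow reset speeds the wrong response can win.
We interpret it as the comparison operating on classified percepts only.

### Reaction-time calibration

Simulated crossing times are mapped to milliseconds by one affine map per
batch: the slope is fixed so the medium-speed interference equals 60 ms,
and the intercept places the neutral reaction time at 500 ms (cosmetic:
contrasts are intercept-free).  Facilitation at all three speeds and the
interference at the fast and slow speeds are then parameter-free
predictions.  The reset-node time constants (4 / 8 / 16, ratio 1:2:4) and
the associative gain (0.85) are the two constants calibrated against the
behavioral anchors the simulator targets (facilitation ≈ 3 ms, 60 ms
medium interference); with them fixed, the
simulator predicts ≈ 47 ms (fast) and ≈ 97 ms (slow) interference.

### Metabolic proxy

Each condition runs the color module for 40 units with its drive present
throughout.  Two metrics are computed per cortical region (F0; F1
including G1; F2 including G2): the space–time mean of supra-threshold
outputs, and of absolute membrane potentials.  No hemodynamic convolution
is applied — the proxy is exactly the stated average.  A region counts as
active above a floor of 5 % of the maximum region value across the four
conditions (per metric).  Passive engagement is modeled as modulation of
the gain-node drives: passive perception adds a strong extra drive to G1
(8.0), which blocks the F1 output pathway (no classification) while G1
itself stays active; passive cognition scales the G1 drive to zero,
silencing the F1 region while G2 keeps the primed F2 band weak.  F2
spread is the count of categories with supra-threshold output averaged
over the final quarter of the window: the associative fan-out (2) during
cognition, 1 during perception.

## What the synthetic stimuli do and do not capture

The generator realizes the *structure* the model needs — graded hue
similarity via overlapping supports, discrete word identities via
distinct binary masks, disjointness between color categories — with no
attempt at colorimetric realism, font rendering, or lexical statistics.
All dynamics are noise-free (single smooth trajectories); an accumulator noise term with seed control exists
but is off for replication.  Passing tests therefore show that the
circuit mechanisms produce the reported effect structure under idealized
inputs; they say nothing about robustness to realistic sensory noise,
trial-to-trial variability, or reaction-time distributions.

## Numerical choices and degenerate inputs

- dt = 0.01 everywhere; the dynamics tests verify first-order convergence
  under step-size refinement.
- Ties in the category race resolve to the lowest index via the 1e−3
  excitatory bias; the tie-break is test-pinned.
- Boundary convention: Σf1 = ρ·Σf0 counts as a match (no reset).
- Zero input: the mismatch is defined as 0 when Σf0 = 0 (no drive without
  registration).
- A trial with no accumulator crossing by t = 250 returns choice "none".
- If every committed category is latched, the search raises an explicit
  "no category available" error (with learning enabled this is where a
  fresh category would be recruited).

## Known limitations

- The AND behavior of F1 and the weak-but-supra priming band are
  equilibrium properties of one calibrated operating point; several
  margins (e.g., the primed potential vs. the recurrent threshold, the
  blocked-F1 potential vs. its output threshold) are a few hundredths
  wide.  The configuration file exposes every gain so the envelope can be
  explored, but distant parameter combinations can stall the category
  race (the gain-control feedback loop pins candidates below ignition).
- Vigilance resolution is coarse: because the reset requires a
  substantial normalized mismatch (≈ 0.38) on top of the ρ-threshold,
  nearby template overlaps are not discriminated as sharply as the ρ
  semantics of idealized ART would suggest.
- Distributed (non-winner-take-all) category codes, slow learning,
  map-field learning, and within-map reset (modality switching) are out
  of scope.
- The millisecond scale is anchored, not derived: absolute reaction
  times are arbitrary; only contrasts are meaningful.
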