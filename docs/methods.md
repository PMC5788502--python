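# Methods

This note documents the models, parameter choices and numerical decisions
behind riboconnect, and what the synthetic fixtures do and do not emulate.

## Secondary-structure model

The fold engine is a weighted Nussinov-style dynamic program: it maximizes
the summed pair weights GC = 3, AU = 2, GU = 1 over non-crossing structures
with a minimum hairpin loop of 3 unpaired nucleotides.  Scores are abstract
stability units, *not* free energies; the weights only need to order pair
stabilities the way stacking energies do, because every downstream use is a
fold-and-inspect decision (is the antisense single-stranded? is the aptamer
stem intact?) or a two-state comparison, never a ΔG prediction.  The design
pays for this simplicity deliberately: an exact brute-force enumerator
(`enumerate_structures`, ≤ 25 nt) can certify the DP's optimality, which no
full nearest-neighbor implementation would allow.  A pluggable backend
could substitute a thermodynamic folder without touching callers; GU wobble
pairs are included (weight 1) because natural aptamer stems contain them.
Pseudoknots are outside the model.

**Tie-break.** Maximum-score structures are massively degenerate for the
repetitive chimeras this package builds (an antisense domain complementary
to an aptamer stem can substitute for the stem's own partner strand at
exactly equal score).  The traceback therefore resolves ties *toward
accessibility*: at every subproblem the 5ʹ-most index is left unpaired
whenever some optimal structure allows it; when it must pair, the nearest
optimal partner is chosen.  This is deterministic, preserves the optimal
score, and selects the member of the tie set in which modules fold locally
(antisense exposed, aptamer stems closed) — the conformation the selection
step is asking about.  A "pair-first" tie-break was rejected because it
systematically reports chimeric chain conformations that misrepresent
equally-optimal accessible folds.

**Constraints.** `fold(seq, constraints=…)` forces indices to stay
unpaired.  Constrained optima can only lose score, which the tests check.

## Device architecture and structural selection

A device is assembled from modules joined by an `AAA` linker (an unpaired
spacer; the linker deliberately contains no G/C/U so it cannot seed stable
helices with either antisense or aptamer domains):

* repressor: `antisense + (linker + sensor)×c`
* activator: `antisense + (linker + eIF4G-effector)×c`
* sequestration switch: `sensor + linker + antisense + (linker + effector)×c`

with copy number c ∈ {1, 2, 3} (the explored valency range; 2 is the
default and the calibration reference).  Selection criteria on the folded
chimera:

* **exposedness** — fraction of the 20 antisense nt unpaired; threshold
  τe = 0.8;
* **preservation** — fraction of each aptamer's reference pairs present
  (shifted by the module offset), averaged over copies; threshold τp = 0.8.

The thresholds are package-defined (the selection principle itself is
qualitative); both are exposed as options.  The composite score multiplies
in a 5ʹ-distance prior `exp(−d/λ)` with λ = 300 nt: repression and
activation efficacy both decline with distance from the 5ʹ end, and the
exponential is the simplest strictly-decreasing positive form; λ is
configurable and its exact value only affects ranking, not pass/fail.

**Sequestration switch as two states.**  The OFF (sequestered) conformation
is folded with the stem's 3ʹ partner strand held unpaired, so the 5ʹ stem
strand pairs the antisense; the ON (aptamer-formed) conformation is folded
with the antisense held unpaired.  Ligand binding adds the sensor's
`binding_bonus` (5 score units for small molecules, 7 for proteins —
chosen so that bonuses exceed typical OFF−ON score gaps and switches
actually flip) to the ON side; the device is ON iff the effective ON score
strictly exceeds the OFF score, ties resolving OFF.  This two-state
treatment ignores intermediate conformations and kinetics.

## Packaged aptamer library

The published device sequences are not available in machine-readable form,
so the shipped library (`data/aptamers.json`) contains *synthetic*
reconstructions of the architecture: 7-bp stem + 4-nt loop hairpins with an
annotated 5ʹ stem strand, one entry per ligand used by the applications
(theophylline, tetracycline, eIF4G, β-catenin, NF-kB, VEGF, OPN).  Two
structural choices matter under the pair-weight model and are intentional:

* the loop is all-A: a loop G would let a C-containing antisense "unzip"
  the hairpin at a strictly higher score (pairing both stem strands plus
  the loop), destroying the reference structure;
* the loop-adjacent stem pair is G·C: with an A·U innermost pair a loop
  adenosine can substitute for the stem partner at equal score, costing one
  reference pair under the accessibility tie-break.

With these choices each packaged reference structure is a maximum-score
fold of its own sequence, reproduced exactly by the engine (tested).

## Regulation model

The quantitative layer is a declared Hill/Emax form — the minimal
saturating dose–effect model consistent with the qualitative behavior it
represents (dose-dependent, saturable, with a maximum effect):

* occupancy θ(L) = L^h / (K^h + L^h);
* valency v(c) = [c/(c+κ)] / [2/(2+κ)], normalized so the 2-copy reference
  device has v = 1; κ = 0.5 copies by default.  v is strictly increasing
  with shrinking gaps, matching the observed ordering (1 copy ≪ 2 copies ≲
  3 copies).  Note v(3) ≈ 1.07, so a 3-copy device slightly exceeds the
  2-copy-calibrated ceiling; the exact bounds are E ∈ (1 − Emax_r·v(3), 1]
  and F ∈ [1, 1 + (Fmax−1)·v(3)];
* repression E = 1 − Emax_r·v·efficacy·θ; activation
  F = 1 + (Fmax−1)·v·efficacy·θ.

Packaged calibrations (`data/device_params.json`): theophylline K = 300 µM,
h = 1.3 (sub-saturating through 1000 µM, consistent with the 0–1000 µM
assay range); tetracycline K = 20 µM with logic-high 100 µM; the 2×-eIF4G
activator Fmax = 15 (its saturating fold-change at full efficacy and
reference valency); protein sensors K = 1 in arbitrary cellular
concentration units, h = 1.5.  These are package calibrations, not
published constants.

**Calibration.** `calibrate()` fits the free subset of (K, h, Emax_r|Fmax)
by trust-region least squares started from a fixed 3×3×3 grid (log-spaced K
over the dosed range; h ∈ {0.7, 1.3, 2.5}; ceiling grid per mode), taking
the best finishing point — deterministic, and robust to the local minima a
single start hits.  Noise-free synthetic curves are recovered to machine
precision; 5% multiplicative noise on 20 doses recovers parameters within
~10% (seeded test).  Fewer than 4 points or constant responses are
rejected as unidentifiable.

## Circuit composition

* Each ligand-gated device (repressor or switch-activator) is *engaged* in
  a given input condition when its occupancy θ ≥ 0.5.
* Repressors multiply relative-expression factors; activators multiply
  fold terms.
* **Synergy**: when ≥ 2 repressors (or ≥ 2 activators) are concurrently
  engaged, their combined product is raised to s = 2.  The exponent is the
  free parameter that lets individually weak devices jointly cross the
  digital threshold (AND/NAND recipes); its exact value is not identified
  by qualitative gate data, and it is applied symmetrically to both device
  classes because the weak-repressor NAND behaves synergistically in the
  same way the weak-activator AND does.
* **Annihilation**: two devices whose antisense domains are Watson–Crick
  complementary at ≥ 16 of 20 antiparallel positions inactivate each other
  (all-or-none), *only while both are engaged*.  The engagement condition
  matters: XNOR is two strong repressors with complementary antisense, and
  its (1,0)/(0,1) rows repress — so the duplex must form only when both
  devices are active.  The threshold is exposed in config.
* **Digitization**: output ≥ midpoint of the gate's calibrated ON/OFF
  levels → 1 (ties ON).  ON/OFF levels are computed at build time from the
  recipe's intended extreme conditions (e.g. for AND, the synergistic
  both-on output vs baseline); build_gate additionally verifies that
  AND/NAND singles are individually sub-threshold.
* Strong/weak device classes are split at the pool's median composite
  score.

## Networks and scenarios

`simulate_network` integrates d[X]/dt = production·(edge modifiers) −
decay·[X] with fixed-step RK4 (defaults dt = 0.01, t_end = 100; halving dt
moves packaged-scenario endpoints by < 1e-6).  A connector edge modulates
its target's *production* term (translation) as E or F of the sensor
species' concentration; timed perturbations either set a concentration or
rescale a production rate (knockdown ≈ ×0.05).

The packaged OPN–VEGF loops use production 1, decay 0.1 per species (time
units are abstract; steady scale 10) and edge parameters K = 10, h = 2,
Emax_r = 0.9, Fmax = 5: K sits at the loop's own concentration scale so
both species operate on the sensitive part of the Hill curve, and the
smaller Fmax keeps the positive loop's fixed point off saturation so
perturbation responses are visible.  The negative loop (OPN→VEGF activate,
VEGF→OPN repress) is monostable: it restores steady state within 1% after
transient perturbations and shows the expected directionality (VEGF up ⇒
OPN down; VEGF knockdown ⇒ OPN recovers).  The positive loop settles well
above the uncoupled baseline and amplifies overexpression.

`rewire_scenario` separates the two arms acting on one gene: the
transcriptional arm `mRNA = 1 + g·tf/(tf+1)` with gain g = 2, and the
translational arm multiplying by the connector's repression.  g = 2 keeps
the transcriptional gain below the reciprocal of the repression ceiling
(Emax_r = 0.9), so the protein readout *falls* below baseline while mRNA
rises — the observed signature of translational rewiring dominating
transcription.  `and_classifier` gates a ribozyme-flanked repressor's
expression on the promoter state and its activity on the ligand, so
knockdown is nonzero only in the (active, present) state.
`redirect_scenario` evaluates two sequestration-switch activators and two
repressors sensing the same protein, giving simultaneous up- and
down-regulation of their four targets.

## Synthetic fixtures

`FixtureSpec` drives all test/demo inputs from one seed: pseudo-random
transcripts with annotated UTR/CDS boundaries, perfect-hairpin toy
aptamers, and `sensor_for_antisense` (a hairpin whose 5ʹ stem strand is the
reverse complement of an antisense prefix, as a sequestration switch
requires).  Fixture transcripts embed deterministic *device-accessible
windows*: an all-C/all-G inverted-repeat pair (one copy in the UTR, its
reverse complement at the CDS start) providing the mutually complementary
antisense pair behind XOR/XNOR, plus three pyrimidine-only windows (one
near the 5ʹ end, two deep in the CDS) whose purine-only antisense domains
cannot out-score the aptamer stems.  Strong and weak device classes then
arise purely from the position prior.

What the fixtures do **not** emulate: real target mRNAs are structured, so
genuine antisense domains face accessibility competition the embedded
windows remove by construction; there is no off-target transcriptome, no
expression noise, no RNA turnover and no delivery variation.  Passing
tests therefore demonstrate the internal consistency of the design rules
and regulation models, not wet-lab effect sizes.

## Problem sizes

Defaults keep everything desk-scale: 600-nt fixture transcripts, ~110-nt
chimeras (cubic-time folding, milliseconds each), 200 random sequences of
≤ 18 nt for the oracle comparison, 20-dose calibration tables, and 10⁴–10⁵
RK4 steps per network simulation.  The full test suite and the acceptance
script each run in well under a minute on one CPU.

## Known limitations

* The fold model is score-based, not thermodynamic; structural criteria
  are defined relative to this engine, and agreement with free-energy
  folders is not claimed.
* The Hill/Emax layer is phenomenological; binding kinetics, ribosome flux
  and mRNA-level effects are out of scope (the devices are modeled as
  purely translational, consistent with unchanged mRNA readouts).
* The synergy exponent and annihilation threshold are qualitative-behavior
  parameters, not measured constants.
* Packaged aptamers are synthetic architecture stand-ins; redesigning
  against real aptamer sequences requires supplying their structures in
  the library JSON.
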