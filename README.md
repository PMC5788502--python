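# riboconnect

Design and simulation toolkit for **RNA signal-connectors**: small
trans-acting RNA devices that couple a cellular or exogenous signal to the
*translation* of a chosen mRNA.  A connector pairs a 20-nt **antisense
domain** (which recognizes a window on the target transcript) with one or
more **aptamer domains** that either sense a ligand/protein signal or
recruit the translation initiation factor eIF4G.  Depending on its
topology a device:

* **represses** translation — the ligand–aptamer complex acts as a roadblock
  to ribosome scanning (5ʹ-UTR targets) or elongation (CDS targets);
* **activates** translation — tethered eIF4G aptamers recruit initiation
  machinery to the target;
* **switches on** in response to a signal — the antisense is sequestered by
  the stem of a sensor aptamer until ligand binding stabilizes the aptamer
  and frees the antisense.

The package is aimed at synthetic-biology modelers who want to design such
devices against annotated transcripts, screen them structurally, fit and
predict dose–response behavior, and compose them into Boolean logic gates,
rewired signaling pathways, feedback loops and cell-state classifiers —
entirely in silico, from seeded synthetic fixtures.

## The model in brief

**Structural screening.** Each assembled chimera is folded with a weighted
base-pair-maximization dynamic program (GC=3, AU=2, GU=1, minimum loop 3).
A design passes when its antisense domain stays exposed
(`exposedness ≥ τe = 0.8`) and each aptamer keeps its reference stem
(`preservation ≥ τp = 0.8`).  Candidates are ranked by the composite

```
composite = exposedness · preservation · exp(−d₅ʹ / λ),   λ = 300 nt
```

where `d₅ʹ` is the distance of the target window from the 5ʹ end (devices
targeting near the cap are empirically more effective).

**Quantitative regulation.** A device's effect factorizes into Hill
occupancy θ(L) = L^h/(K^h+L^h), a saturating valency scale
v(c) = [c/(c+κ)]/[2/(2+κ)] (2-copy reference, v(2)=1), its structural
efficacy, and a ceiling:

```
repression:  E = 1 − Emax_r · v(c) · efficacy · θ(L)     (relative expression)
activation:  F = 1 + (Fmax − 1) · v(c) · efficacy · θ    (fold-change)
```

`calibrate()` fits (K, h, Emax_r | Fmax) to dose–response tables with a
deterministic multi-start least-squares scheme.

**Circuits.** Repressors multiply relative expression, activators multiply
fold terms; concurrently engaged device pairs combine with a synergy
exponent (s = 2), and devices with mutually complementary antisense domains
annihilate each other when both are engaged.  These rules suffice to build
all seven two-input Boolean gates (NOT, AND, NAND, OR, NOR, XOR, XNOR), and
the same primitives drive ODE models (fixed-step RK4) of rewired pathways
and OPN–VEGF feedback loops.

## Worked example

Build the XOR gate from seeded synthetic fixtures — two strong
ligand-gated activators whose antisense domains are mutually complementary,
acting on an uncapped reporter:

```bash
$ riboconnect simulate-gate --gate xor --seed 0
theophylline	tetracycline	analog	output
0	0	1	0
0	1	10.23	1
1	0	11.48	1
1	1	1	0
```

Each row is one input combination (1 = logic-high ligand: 1000 µM
theophylline, 100 µM tetracycline).  `analog` is the modeled reporter
output relative to baseline: either ligand alone activates ~10–11-fold
(digital 1); with both ligands present the two devices' antisense domains
base-pair and inactivate each other, returning the reporter to baseline
(digital 0).

The same devices are available from Python:

```python
from riboconnect.demo import demo_gate_pool
from riboconnect import build_gate, simulate_gate

pool = demo_gate_pool(seed=0)
spec = build_gate("xor", pool["devices"])
print(simulate_gate(spec).digital())
# {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 0}
```

Designing repressors against your own transcript:

```bash
riboconnect fixtures --seed 1 --out fx/            # or bring your own FASTA+TSV
riboconnect design --target fx/transcripts.fasta --annotations fx/annotations.tsv \
    --topology repressor --sensor theo --region utr5 --step 5 --out designs/
```

`designs/designs.tsv` lists one scored candidate per row (window,
antisense, exposedness, preservation, position prior, composite, pass) with
the full device sequences in `designs/designs.fasta`.

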