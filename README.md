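# cytokinetics

Quantitative time-lapse analysis of protein accumulation kinetics at the
budding-yeast division site.

During cytokinesis, dozens of proteins — septins, the actomyosin ring (AMR),
the vesicle-transport machinery, the primary/secondary septum synthases, and
the MEN/RAM signaling pathways — arrive at and leave the bud neck in a strict
temporal order. This package implements the analysis used to chart that
order from multi-channel fluorescence movies:

* **Clock alignment.** Every cell carries an internal clock: the frame of
  mitotic spindle breakage (tubulin channel), defined as time 0. Per-cell
  intensity traces are re-timed to this clock, interpolated onto a common
  1-min grid, and aggregated to mean ± SD curves.
* **Kinetic signatures.** A protein's signature is the peak time (or times)
  of its mean curve, with arrival/departure defined by threshold crossings.
  Proteins of the same functional module share a signature; the Pearson
  correlation of mean curves over a common window ranks candidate partners
  and predicts module membership for uncharacterized proteins.
* **Biphasic ring constriction.** The AMR diameter d(t) declines in two
  linear phases, slow then fast. The model fitted per cell is the continuous
  two-segment line
  d(t) = d₀ − r_slow·(t − t_on) for t_on ≤ t ≤ t_b, then
  d(t_b) − r_fast·(t − t_b), with r_slow, r_fast ≥ 0; the breakpoint t_b is
  found by exhaustive search over grid candidates, minimizing the constrained
  least-squares SSE. Phase contributions are the diameter lost in each phase.
* **Condition comparisons.** Drug or deletion effects are summarized as
  ratios to control: peak value, peak shift, maximal 5-min rising slope
  ("rate"), and area under the curve.

Because the underlying imaging data are not publicly deposited, the package
ships a first-class synthetic-data generator: a panel of 25 template curves
(six modules) whose peak/arrival/departure times encode the published
kinetics, a biphasic constriction simulator with per-cell parameter sampling
around the published ensemble statistics (slow 0.02 ± 0.02 μm/min over
0.10 ± 0.07 μm; fast 0.18 ± 0.05 μm/min over 0.92 ± 0.11 μm), condition
effects (latrunculin-A, cyk3Δ) expressed in measurement space, and a movie
renderer (ring puncta + breaking spindle, Poisson/read noise) with a ground
truth table per cell. All analysis stages are validated by parameter
recovery against this truth.

## Worked example

```python
from cytokinetics import load_signature_table, simulate_panel, aggregate, extract_signature
from cytokinetics.signature import correlation_matrix, rank_similarity

panel = load_signature_table()                       # 25 proteins, 6 modules
traces, truth = simulate_panel(panel, n_cells=30, seed=1)
mks = {}
for tpl in panel:
    cells = [t for t in traces if t.protein_id == tpl.protein_id]
    mks[tpl.protein_id] = aggregate(cells, protein_id=tpl.protein_id)

hof1 = extract_signature(mks["Hof1"])
print("Hof1 peaks (min):", hof1.peak_times)

matrix = correlation_matrix(list(mks.values()))      # window −20…+30 min
for name, r in rank_similarity(matrix, "Kre6")[:3]:
    print(f"Kre6 neighbor: {name:6s} r = {r:.3f}")
```

prints

```
Hof1 peaks (min): [-5.0, -1.0, 6.0]
Kre6 neighbor: Crh1   r = 0.929
Kre6 neighbor: Fks1   r = 0.718
Kre6 neighbor: Cyk3   r = 0.482
```

The F-BAR protein Hof1 shows its characteristic three-peak kinetics (septin
hourglass remodeling at −5 min, the AMR peak at −1 min, and the
secondary-septum-stage peak at +6 min), and the β-1,6-glucan synthase
candidate Kre6 correlates most strongly with the transglycosylase Crh1 —
the septum-maturation signature.

## Command line

```bash
cytokinetics simulate --out run/ --seed 1 --n-cells 30   # traces + truth (+ --render for movies)
cytokinetics quantify --movies run/movies --out run/q    # movies -> measurements + traces
cytokinetics align    --traces run/traces.csv --out run/ # mean ± SD kinetics
cytokinetics fit      --traces run/traces.csv --out run/ # biphasic constriction fits
cytokinetics signature --mean-kinetics run/mean_kinetics.csv --out run/
cytokinetics report   --traces run/traces.csv --out run/ # full bundle + landscape figure
cytokinetics run-all  --out run/ --seed 1                # simulate + report
```

Every stage writes its resolved configuration next to its outputs;
re-running with the same seed reproduces all outputs bit-identically.

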