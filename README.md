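# nds-synergy

Screening for synergy among many antibiotics is limited by combinatorics:
testing `d` drugs at `m` concentrations exhaustively needs `m^d` wells
(10⁸ for eight drugs at ten concentrations). `nds-synergy` implements a
*normalized diagonal sampling* (NDS) screen that tests each drug subset only
along its equal-normalized-concentration diagonal — `m · 2^d` wells, 2,560
for the same eight-drug screen — together with the scoring framework that
makes this reduction sound, and a brute-force oracle that checks the
soundness empirically.

It is written for microbiologists and computational biologists running
combination screens on plate readers, and for methodologists who want a
simulator and an exhaustive-enumeration oracle to probe when diagonal
designs can fail.

## The index and scores

Each drug *i* carries a normalization constant *N*ᵢ (its MIC, its EUCAST
breakpoint, or a custom dose — the choice changes what "synergy" means and
is recorded in every output). For a concentration vector **x**, the minimax
concentration is `MEC(x) = max_i x_i / N_i` over the drugs present. For a
drug set Ω,

```
MECI(Ω) = min { MEC(x) : x tested, support(x) ⊆ Ω, x effective }
TSS(Ω)  = MECI(Ω) / min_{i∈Ω} MECI({i})          (total synergy score)
ESS(Ω)  = MECI(Ω) / min_{Ω'⊂Ω, Ω'≠∅} MECI(Ω')   (emergent synergy score)
```

with `TSS ≤ ESS ≤ 1` wherever defined. `ESS ≤ 0.25` is interpreted as
synergy, `0.25 < ESS < 1` as weak synergy, `ESS ≥ 1` as none — calibrated
so that a drug pair effective at ¼ MIC each (classical checkerboard FICI
0.5) sits exactly on the synergy boundary. "Effective" defaults to the area
under the background-subtracted OD600 growth curve (AUGC, trapezoidal over
24 h) falling at or below 10% of the drug-free control mean.

The diagonal design provably recovers the exact MECI of every subset
*provided growth is non-paradoxical*: along any ray in concentration space,
once the response starts to fall it may not rise again (rise-then-fall
hyperantagonism is fine; Eagle-effect-like recovery is not). The
`oracle` module verifies this claim empirically by solving the MECI
optimization by exhaustive enumeration and comparing, and constructs
paradoxical counterexamples where the diagonal design demonstrably fails.

## Worked example

A simulated two-drug MIC-normalized screen whose pair diagonal is effective
down to ¼ MIC while each single drug needs its full MIC:

```python
import pandas as pd
import nds_synergy as ns

panel = ns.DrugPanel(tuple(
    ns.DrugSpec(n, mic=1.0, normalization_label="MIC") for n in ("A", "B")))
surface = ns.injected_pair_synergy_surface(panel, ("A", "B"), threshold_frac=0.1)
ladder = ns.build_ladder(1.0, 2.0, 6)                 # 1, 1/2, ..., 1/32
design = ns.randomize_layout(ns.enumerate_nds(panel, ladder, replicates=2), seed=1)
dataset = ns.synthesize_readings(surface, design, noise_sd=0.01, seed=2)

rows, controls = [], []
for point, curve in zip(design.points, dataset.readings):
    value = ns.augc(curve, 24.0)
    rows.append({"subset": ns.subset_key(point.subset, panel),
                 "step_index": point.step_index or 0,
                 "ratio": ladder.ratio(point.step_index) if point.step_index else 0.0,
                 "measure_value": value})
    if point.is_control:
        controls.append(value)
threshold = ns.control_threshold(controls, fraction=0.1)
table = ns.call_effectiveness(pd.DataFrame(rows), threshold, "mean")
frame = ns.scores_to_frame(ns.score_all_subsets(table, panel), panel)
print(frame[["subset", "meci", "tss", "ess", "fici_diagonal_bound",
             "classification"]].to_string(index=False))
```

prints

```
subset  meci  tss  ess  fici_diagonal_bound classification
     A  1.00 1.00  NaN                  1.0           none
     B  1.00 1.00  NaN                  1.0           none
   A;B  0.25 0.25 0.25                  0.5        synergy
```

Each single drug is effective only at its MIC (MECI 1); the pair is
effective with both drugs at ¼ MIC (MECI 0.25), a four-fold emergent
improvement (ESS 0.25 — on the synergy boundary), and the best sampled
Loewe FIC sum is ¼ + ¼ = 0.5. Singletons have no proper subset, so their
ESS is undefined (NaN).

The same pipeline is available from a shell:

```
nds-synergy design   --panel panel.yaml --steps 10 --factor 2 --replicates 2 --seed 7 --out design.csv
nds-synergy simulate --panel panel.yaml --surface surface.yaml --design design.csv --seed 11 \
                     --out-readings readings.csv --out-truth truth.csv
nds-synergy quantify --readings readings.csv --design design.csv --panel panel.yaml \
                     --threshold-frac 0.1 --out effectiveness.csv
nds-synergy score    --effectiveness effectiveness.csv --panel panel.yaml --out scores.csv
nds-synergy verify   --panel panel.yaml --surface surface.yaml --steps 6 --out report.json
```

An example eight-antibiotic *E. coli* MG-1655 panel with EUCAST breakpoints
and measured MICs ships as `ns.ecoli_mg1655_panel()`.

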