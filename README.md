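# sccompreg

Comparative gene-regulatory-network analysis between two conditions from
paired single-cell data.

Given scRNA-seq and scATAC-seq from each of two cell populations (say, a
patient and a healthy control), `sccompreg` identifies, per matched cell
subpopulation, the TF → target-gene (TG) regulatory relations that differ
between the conditions. It provides:

- **Coupled clustering** of expression and accessibility (CoupledNMF): joint
  nonnegative factorization of the peak×cell matrix *O* and gene×cell matrix
  *E*, coupled through a gene×peak prior *A* via a trace reward
  −λ₂·tr(W₂ᵀAW₁), so the K factors agree across modalities. *A* combines
  context correlation and distance decay, A = R⁺·exp(−d/d₀), d₀ = 40 kb.
- **Subpopulation linking** across conditions by the mapping score
  (observed Pearson correlation of cluster profiles minus its marginal
  expectation; a link requires a positive score in both modalities).
- **TF regulatory potential (TFRP)**, a cell-level index
  TFRP = TF_expression × Σₖ Bₖ·REₖ·Iₖ combining motif binding strength B,
  subpopulation-level RE accessibility, and RE–TG interaction strength I.
- **A likelihood-ratio test for differential regulation**: per (TF, TG)
  pair, TFRP is regressed on TG expression pooled vs per condition,
  LR = n·ln σ̂₀² − n₁·ln σ̂₁² − n₂·ln σ̂₂². Because the chi-square(3)
  reference fits the empirical null poorly, p-values come from a
  two-parameter Gamma fitted to the lower quantiles (0.05…0.50) of the
  observed LR distribution, followed by Benjamini–Hochberg FDR control.
- **A generative simulator** of two-condition regulatory systems (with
  expression dropout) used to validate the detector end to end.

## Worked example

Simulate a two-condition system in which 10% of TFs and 10% of REs are
perturbed and 1% of regulatory edges are rewired, then measure how well the
LR statistic separates truly differential TF→TG pairs from unchanged ones:

```python
from sccompreg import SimulationParams, Scenario, simulate_dataset
from sccompreg.diffreg import benchmark_auc, benchmark_fdr

ds = simulate_dataset(SimulationParams(scenario=Scenario.combined, seed=1))
print("TFRP AUC     ", round(benchmark_auc(ds, "tfrp"), 4))
print("baseline AUC ", round(benchmark_auc(ds, "baseline"), 4))
r = benchmark_fdr(ds, null="gamma", fdr_threshold=0.1)
print("calls", r["n_calls"], "false", r["n_false"])
```

prints

```
TFRP AUC      0.918
baseline AUC  0.7716
calls 37 false 0
```

The TFRP-based detector ranks differential pairs far better than the
expression-only baseline (which cannot see accessibility changes), and the
Gamma-null calls at an estimated FDR of 0.1 contain no false positives on
this draw.

The same machinery is exposed on the command line:

```bash
sc-compreg simulate --scenario combined --seed 1 --out sim/
sc-compreg run --config pipeline.json       # end-to-end two-condition analysis
```

`sc-compreg cluster`, `link`, `diffreg` and `evaluate` run the individual
stages; `sc-compreg run` chains them (preprocess → CoupledNMF per condition →
link subpopulations → screen differential TGs → TFRP → LR/Gamma/BH →
differential networks) and writes a JSON manifest.

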