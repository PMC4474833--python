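# turnover15n

Analysis pipeline for proteome-wide protein turnover measured by **¹⁵N
pulse labeling** in bacteria, together with the companion assays used to
study translational shutdown under oxidative stress: dual-isotope MS1
peptide quantification, modification-aware tRNA-seq with spike-in
normalization and 3′-truncation profiling, and the growth-curve / ΔΔCT
statistics that tie the assays together. Every input the pipeline consumes
can be generated synthetically with known ground truth, so the whole
workflow is testable end to end without raw instrument data.

## Who this is for

Microbial proteomics and RNA labs that (a) switch exponentially growing
cells from ¹⁴N to ¹⁵N minimal medium and read out the light/heavy peptide
ratio by LC-MS1, (b) sequence small-RNA libraries against a tRNA reference
set carrying modified nucleotides, or (c) want a seeded simulator of either
experiment for method development.

## The model

After the medium switch at `t0`, pre-existing (¹⁴N) protein decays while
new (¹⁵N) protein is made. For a steady-state proteome (`k_deg = k_syn`)
the measured ratio `R(t) = N14(t) / N15(t)` obeys

```
1 + 1/R = exp(k_syn · (t − t0))        ⇒        Y ≡ ln(1 + 1/R) = k_syn · (t − t0)
```

so an ordinary least-squares fit of `Y` against `t` yields the synthesis
rate constant `k_syn` (slope) per protein, and the half-life of the
pre-existing pool is `T = ln 2 / k_syn`. Fits whose Pearson correlation is
insignificant (`P > 0.05`) cannot resolve half-lives beyond 500 min and are
reported censored at that cap.

Around the kinetic core:

* **`isotopes`** — in-silico tryptic digestion, elemental composition and
  monoisotopic mass under either nitrogen label (the ¹⁵N−¹⁴N shift is
  exactly `n_N × 0.9970349` Da), isotope-envelope prediction by per-element
  isotopologue convolution, a mass-sorted dual-label peptide index with
  ±10 ppm candidate lookup, and `R = area(¹⁴N)/area(¹⁵N)` MS1 integration.
* **`trnaseq`** — semi-global unit-cost alignment in which annotated
  modified positions match any base (reverse transcriptase misreads them),
  acceptance at ≤3 errors and ≥25 nt, spike-in-normalized per-species fold
  changes, and per-species 3′-truncation profiles (offset 3 on a tandem
  CCACCA species marks loss of one CCA unit).
* **`assays`** — Beer–Lambert OD from transmitted intensity, windowed
  exponential growth-rate constants with two-sample t-tests, moving
  averages, and ΔΔCT with the spike-in-minus-target sign convention.
* **`simulate`** — seeded generators for all of the above, each emitting a
  ground-truth table beside the observations.

## Worked example

Simulate a 200-protein pulse-labeling cohort with 10% multiplicative ratio
noise, then fit it:

```
$ turnover15n simulate-turnover --n-proteins 200 --noise-cv 0.1 --seed 7 \
      --out ratios.tsv --truth-out truth.tsv
$ turnover15n fit-turnover --ratios ratios.tsv --out estimates.tsv
fitted 200 proteins; mean uncensored half-life 106.29 min; 0.0% censored >500 min
$ head -2 estimates.tsv
protein_id  k_syn_per_min  pearson_r  p_value   half_life_min  censored  n_points  reason
P000        0.006407       0.999152   0.000848  108.186        False     4
```

Protein `P000` was simulated with `k_syn ≈ 0.0064 /min`; the fit recovers
it and converts it to a 108-min half-life with a highly significant linear
fit (`r = 0.9992`). The cohort mean sits near 100 min, the scale typical of
exponentially growing *E. coli*. A growth-curve fit from the same toolbox:

```
$ turnover15n simulate-growth --noise-sd 0.001 --seed 2 --out curve.tsv
$ turnover15n growth-fit --curve curve.tsv
k = 0.02312 per min (stderr 3.8e-05); doubling time 30.0 min
```

The library API mirrors the CLI (`simulate_turnover`, `fit_ksyn`,
`assign_reads`, `normalize_and_fold_change`, `quantify_ratio`, …); see the
module docstrings and `docs/methods.md`.

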