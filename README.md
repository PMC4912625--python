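# recon — overall repertoire diversity from a sample

Estimating the diversity of a B- or T-cell repertoire from a blood or
tissue sample is confounded by the *missing-species problem*: clones too
small to contribute even one cell to the sample go undetected, so sample
diversity systematically undercounts overall diversity — by roughly half
at one sampled cell per overall clone, and by at least 10-fold at a
tenth of that. `recon` reconstructs the **overall** clone-size
distribution from the **sample** clone-size distribution and reports
diversity with calibrated error bars, for immunologists and anyone else
facing unseen-species corrections in large, complex populations (tumour
clones, microbial taxa, sequence variants).

## Model

The input is a sample spectrum: for each clone size `x` (cells), the
number of clones observed at that size. Each overall clone of frequency
`f` is assumed to contribute `Poisson(f·S)` cells to a sample of `S`
cells (valid for well-mixed repertoires much larger than the sample).
The overall distribution is modelled as a finite mixture: a fraction
`w_j` of clones each contributes a mean of `m_j` cells. Because clones
are only seen if they contribute ≥1 cell, fitting maximizes the
*zero-truncated* mixture likelihood

    L = Σ_i n_i · ln[ P(i) / (1 − P(0)) ],   P(i) = Σ_j w_j e^(−m_j) m_j^i / i!

by EM, alternating with a Horvitz–Thompson update of the unseen-clone
count `D·P(0)/(1−P(0))` until self-consistent. Components are added one
at a time from 56 deterministic starting points per round (plus a start
averaging the two best fits), and growth stops when the corrected Akaike
information criterion no longer improves or the new component's expected
contribution of corroborated (≥2-cell) clones fails to exceed sampling
noise by 3 standard deviations. Clones above 30 sampled cells have
negligible relative sampling error and are counted directly.

From the fitted mixture the package reports any Hill diversity
`^qD = (Σ p_i^q)^(1/(1−q))` (`q=0` species richness, `q→1` exponential
Shannon entropy, `q=2` inverse Simpson, `q=∞` inverse Berger–Parker),
the number of missing species, the minimum detected clone size
`m_min·N/S`, the upper richness bound `U = R_max·w_m·m_min·N/S`, error
bars from coverage-indexed worst-case error profiles (cross-validated to
95% bracketing), and power tables for experimental design.

## Worked example

Simulate a gold-standard repertoire of 10,000 clones (10⁹ cells,
exponential clone-size distribution), sample it at 3x coverage, and
reconstruct:

```sh
recon simulate --family exponential --s 0.1 --clones 10000 --cells 1e9 \
      --coverage 3 --seed 1 --out sample.tsv --truth truth.json
recon fit --input sample.tsv --sample-cells 30000 --total-cells 1e9 \
      --seed 1 --output report.json
```

From `report.json` of this run (true overall diversities, known from
`truth.json`: `^0D` 10000, `^1D` 6871.8, `^2D` 5283.2):

```
"diversity_sample":  {"0": 7827.0, "1": 5775.3, "2": 4502.2, "inf": 1082.9}
"diversity_overall": {"0": 9533.3, "1": 6870.0, "2": 5292.5, "inf": 2071.5}
"missing": 1706.3
"min_detected_clone_size": 34663
```

The sample contained 7,827 distinct clones — 22% below the true richness
of 10,000 — while the reconstruction estimates 9,533 overall clones
(4.7% error), of which 1,706 were never sampled; the entropy and Simpson
effective numbers are recovered to within 0.2%. The minimum detected
clone size says the fit resolves overall clones down to ~35,000 cells
(of 10⁹); smaller clones would contribute essentially no cells at this
sample size. `recon resample --fit report.json --out predicted.tsv`
writes the predicted sample spectrum (including a size-0 row for
predicted missing clones) for overlay against `sample.tsv`.

The same pipeline runs from Python via `recon.make_parent`,
`recon.poisson_sample`, `recon.reconstruct`, `recon.calibrate_profile`
and `recon.power_table`; every function takes an explicit seed.

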