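# clonetrack

Clonal barcode tracking and HSC-activity quantification for ex vivo
expansion experiments.

Murine hematopoietic stem cells (HSCs) can be expanded in culture, but
individual input cells differ enormously in how much they self-renew. One
way to measure that heterogeneity is lentiviral DNA barcoding: each
transduced founder cell is tagged with a short random sequence, cultures
are split across transplant recipients, and amplicon sequencing of the
recipients months later reveals each clone's contribution. `clonetrack`
packages the full analysis for such experiments, for experimentalists and
computational biologists working with barcode clonal-tracking data:

* a **generative simulator** of heterogeneous clonal expansion,
  well-to-recipient splitting (the parental/daughter design), engraftment
  subsampling, PCR overdispersion and FASTQ emission — so every downstream
  stage is testable against ground truth;
* **barcode extraction** from FASTQ into count matrices (anchored exact or
  1-mismatch matching against a barcode library);
* the documented **filtering pipeline**: per-recipient background removal
  of barcodes below 0.1% frequency, exclusion of barcodes found in more
  than one parental recipient, and normalization to 10⁶ reads per
  recipient;
* **clone statistics**: size summaries, parental→daughter sharing and its
  regression, Mann–Whitney comparison of clone-size distributions,
  frequency-bin dominance profiles, and a calibrated estimator of the
  lognormal heterogeneity parameter σ with a parametric-bootstrap CI
  (statsmodels-style `CloneHeterogeneity` model / `HeterogeneityResults`);
* **repopulating units** (RU) from competitive-repopulation chimerism —
  RU = p/(100−p) · C/10⁵ for test chimerism p% against C competitor
  whole-bone-marrow cells, with 1 RU ≡ the activity of 10⁵ WBM cells —
  plus functional and phenotypic expansion-fold arithmetic;
* **division counting** from dye-dilution (CellTrace-style) intensities:
  d = round(anchor − log2 I), clipped at a detection limit.

## Worked example

Simulate the pre-culture design (5 wells × 1000 HSCs, 35% transduction,
heterogeneity σ = 1), run the filtering pipeline, and analyse it:

```python
import clonetrack as ct

model = ct.ExpansionModel.pre_culture(seed=42, log_expansion_sd=1.0)
counts, truth = ct.simulate_counts(model)
table = ct.run_pipeline(counts)

print(f"barcodes observed: {len(counts.barcodes)}, kept: {len(table.kept_barcodes)}")
mp = (table.exclusions["reason"] == "multi_parental").sum()
print(f"multi-parental exclusions: {mp}")

summary = ct.clone_size_summary(table, role="parental")
print(f"parental clone sizes: median {summary['median_pct']:.2f}%, "
      f"range {summary['min_pct']:.2f}-{summary['max_pct']:.2f}%")

sharing = ct.sharing_analysis(table)
reg = ct.sharing_regression(sharing)
print(f"daughter vs parental regression: slope {reg['slope']:.2f}, r {reg['pearson_r']:.2f}")

fit = ct.estimate_heterogeneity(table, model=model, seed=0)
print(fit.summary())
```

Output:

```
barcodes observed: 1479, kept: 1017
multi-parental exclusions: 99
parental clone sizes: median 0.32%, range 0.12-4.36%
daughter vs parental regression: slope 1.89, r 0.90
Clone-size heterogeneity fit (lognormal sigma)
==============================================
sigma_hat                       1.0165
95% CI (parametric boot)    [0.9570, 1.0955]
raw pooled log-SD               0.7295
clones used                       1017
bootstrap replicates               100
seed                                 0
```

Reading it: 1,479 distinct barcodes produced reads; 1,017 survive the
background filter and multi-parental exclusion (99 barcodes appeared in two
or more parental recipients — library collisions — and were removed
everywhere). Parental clone sizes span well over an order of magnitude, and
clones that are large in their parental recipient contribute more across
the daughter recipients (r = 0.90), the signature of heterogeneous
expansion capacity. The heterogeneity fit recovers the generating σ = 1.0
(σ̂ = 1.02, CI [0.96, 1.10]); note the raw pooled log-SD (0.73) is far from
σ — engraftment subsampling, PCR noise and the 0.1% threshold bias it —
which is why the estimator inverts a simulation-calibrated curve instead of
reporting the raw statistic (see `docs/methods.md`).

The same steps are available from a shell:

```sh
clonetrack simulate --design pre_culture --seed 42 --out sim/
clonetrack extract sim/*.fastq --library sim/library.tsv --out counts.tsv
clonetrack filter counts.tsv --out table.tsv --exclusions excluded.tsv
clonetrack stats table.tsv --mode heterogeneity
```

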