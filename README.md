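# ipscvar

Statistical pipeline for dissecting transcriptional heterogeneity in human
iPSC panels: variance-component decomposition of expression, negative-
binomial classification of reprogramming outcomes, allele-specific
expression and imprinting analysis, and replication of externally
ascertained eQTLs — exercised end to end on a synthetic-data generator
with known ground truth.

## The problem

Human iPSC lines are heterogeneous, and the competing explanations —
epigenetic memory of the somatic tissue of origin, aberrations of
reprogramming, intrinsic iPSC/ESC differences, donor genetic background —
are confounded in most study designs because tissue and donor usually
vary together. With a panel in which several tissues are collected from
the *same* donors (here: 4 donors × {fibroblast, keratinocyte, EPC} →
25 iPSC lines, plus 18 adult samples, 4 ESC samples, 2 batches; 47
samples), the sources can be separated by a linear mixed model on
log2 FPKM per gene j:

    y_j = b1 + Z2 b2 + Z3 b3 + Z4 b4 + Z5 b5 + ε

with Gaussian random effects for cell class (b2), iPSC tissue of origin
(b3), donor within cell class (b4) and sequencing batch (b5), and the
contribution of component k reported as the intraclass correlation
%VE = δ²ₖ/(δ²ₖ + σ²). Around this sit the companion analyses: a five-
hypothesis NB classification of each gene's reprogramming outcome
(invariant / correctly reprogrammed / memory / aberrant / complex, the
last split into partial memory and partial aberrant), permutation-based
FDR control, an empirical-Bayes mixture for transcriptome-wide category
proportions, a beta-binomial analogue for isoform ratios, phased
allele-specific expression with imprinting classification, and pooled
eQTL-replication statistics for a four-donor panel. Everything runs on
synthetic studies whose ground truth is recorded, so every estimator is
tested as a recovery or calibration property.

## Worked example

```python
import numpy as np
from ipscvar import synthetic_data as sd, normalization as nz, variance_components as vc

# a 47-sample panel study: donor effects dominate iPSC heterogeneity
cfg = sd.SimulationConfig(n_genes=2000, seed=3)
study = sd.simulate_study(cfg)
log2fpkm = nz.log_transform(nz.compute_fpkm(study["counts"]))
fit = vc.fit_mixed_model(log2fpkm.values, study["design"])
for comp, ve in sorted(fit.ve.items(), key=lambda kv: -kv[1]):
    print(f"{comp:14s} {100 * ve:5.1f}%")
```

prints (true values 50 / 42 / 38 / 4 / 2 / 1%):

```
adult_tissue    49.0%
donor_adult     39.7%
donor_ipsc      38.2%
origin           4.1%
batch            2.2%
pluripotent      0.9%
```

Transcriptional variation between iPSC lines is dominated by the donor
(38.2%), while tissue of origin ("epigenetic memory") explains ~4% and
the iPSC-vs-ESC distinction ~1%. Dropping the donor component on a
confounded design inflates the apparent origin effect severalfold
(`vc.refit_excluding`), the quantitative form of mistaking genetic
background for memory.

The numbered scripts under `analysis/` run each stage as a narrative
analysis (simulate → variance components → differential expression →
splicing → imprinting → eQTL replication) and write tables under
`results/`:

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_variance_components.py --seed 1
...
```

## Layout

```
src/ipscvar/        io_formats, synthetic_data, normalization,
                    variance_components, diff_expression, ase_imprinting,
                    eqtl_replication
analysis/           numbered narrative drivers over the library
scripts/acceptance.py   end-to-end reproduction script
tests/              pytest suite (unit, property and end-to-end checks)
docs/methods.md     models, assumptions, parameter choices, limitations
```
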