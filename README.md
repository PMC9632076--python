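# mitoabc

Serial-coalescent simulation and rejection-ABC model choice for structured,
heterochronously sampled mitogenome data.

`mitoabc` is built for ancient-DNA population genetics: a set of complete
mitochondrial genomes sampled at different points in time (radiocarbon-dated
ancient specimens plus moderns), structured into populations ("demes") that
represent temporal slices of distinct mitochondrial clades. The question it
answers is a demographic one — did the population pass through bottlenecks
during particular climatic windows, such as the Last Glacial Maximum
(LGM, 28.6–22.5 ka BP) and the Eemian interglacial (130–115 ka BP)?

## The method

Four competing demographic scenarios are compared: constant size, an LGM
bottleneck, an Eemian bottleneck, and both. Each scenario is a structured
serial coalescent: within a deme of current female effective size
*N*<sub>ef</sub>, *k* active lineages coalesce at rate *k*(*k*−1)/2 · 1/*N*
per generation (haploid scaling — mtDNA is maternally inherited, so the
relevant size is the number of females); lineages enter the genealogy at
their sampling ages; backward-in-time join events encode the clade
most-recent-common-ancestor structure; a bottleneck multiplies deme sizes
by a severity factor *b* ∈ (0, 1] over its window. Bottleneck onsets carry
log-uniform priors (LGM on [20, 30] ka BP, Eemian on [115, 130] ka BP) and
severities uniform priors on [0.2, 0.6] (*b* = 1 for the constant model).

Mutations are dropped on each simulated genealogy under the infinite-sites
model at rate μ per site per generation, and each replicate is reduced to
the summary-statistic vector used for inference — for *d* demes:
segregating sites *S* per deme plus their mean, SD and total; nucleotide
diversity π per deme plus mean and SD; and Hudson's
*F*<sub>ST</sub> = 1 − *H*<sub>w</sub>/*H*<sub>b</sub> for every deme pair
(2*d* + 5 + *d*(*d*−1)/2 entries; 109 for the default 13-deme layout).

Model choice is rejection ABC: simulate a reference table of
(scenario, drawn parameters, summary vector) rows, standardize each
statistic by the table's mean and SD, rank rows by Euclidean distance to
the observed vector, and accept the nearest fraction ε (default tolerance
0.05). Posterior model probabilities are acceptance frequencies; accepted
draws give rejection posteriors for bottleneck timing and severity.
Leave-one-out cross-validation produces the confusion matrix over
scenarios.

## Worked example

Generate a synthetic observed dataset (113 mitogenomes in 13 demes across
5 clades, ages 0–50 ka BP, ~16.3 kb) under the dual-bottleneck scenario,
then infer the scenario back:

```python
import numpy as np
from mitoabc import DemographicABC, default_layout, generate_observed

rng = np.random.default_rng(7)
dataset = generate_observed("lgm_eemian", None, default_layout(), rng)
paths = dataset.write("demo")

mod = DemographicABC.from_files(paths["fasta"], paths["metadata"])
res = mod.fit(n_sims=500, tolerance=0.05, seed=7)
print(res.summary())
```

```
Rejection-ABC model choice
==========================================================
Reference rows:     2000  (500 per model)
Tolerance:          0.05
Accepted rows:      100
Statistics used:    109
----------------------------------------------------------
model              posterior    accepted
constant              0.2700          27
lgm                   0.1400          14
eemian                0.2500          25
lgm_eemian            0.3400          34
----------------------------------------------------------
Best model:         lgm_eemian
Posterior quantiles of the best model's parameters:
       lgm_onset_years_bp  lgm_severity  eemian_onset_years_bp  eemian_severity
0.025           2.095e+04        0.2173              1.161e+05           0.2263
0.500            2.47e+04        0.4837              1.226e+05           0.3937
0.975           2.962e+04        0.5955              1.292e+05            0.553
```

The dual-bottleneck scenario that generated the data receives the highest
posterior probability (0.34 of the accepted rows against a 0.25 prior),
and the severity posteriors concentrate below 0.6. `res.plot_posterior()`
draws the posterior bar chart; `res.cross_validate(n_pseudo=25)` returns
the scenario confusion matrix.

The same pipeline is available from the shell:

```sh
mitoabc models print-defaults > config.yaml
mitoabc full-run --config config.yaml --seed 7 --n-sims 5000 \
    --tolerance 0.05 --out results/
```

which writes the reference table CSV, the observed summary vector CSV and
a JSON report of posteriors. `simulate-reference`, `summarize-observed`,
`abc-fit` and `cross-validate` expose the individual stages.

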