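# Methods

## The demographic model

The unit of structure is the *deme*: a population sampled at one point in
time, labelled with the mitochondrial clade it belongs to. The default
layout has 13 demes over 5 clades — three temporal slices of clade 1, two
of clade 2, three of clade 3, two of clade 4, and for the extant clade 5
one ancient deme (14 ka BP) plus two modern demes — totalling 113 samples
(59 ancient spanning 14–50 ka BP, 54 modern). Structure is purely
temporal: there is no migration between contemporaneous demes. Backward
in time, join events move all lineages of one deme into another; within a
clade the final join sits at the clade's most-recent-common-ancestor age
(clade 5 at 27 ka BP, clades 1 and 3 at 56.5 ka BP — the midpoints of
their published interval estimates), and the inter-clade joins form a
ladder rooting at 100 ka BP. The clade-2 and clade-4 mrca ages (50 and
45 ka BP) and the inter-clade join ages (65, 70, 80 ka BP) are not
published quantities; they are placeholders chosen to respect the sampled
ages and the root age, and every one of them is overridable through the
YAML configuration (`mitoabc models print-defaults`).

Four scenarios share this layout and differ only in their bottlenecks:
`constant` (none; severity implicitly 1.0), `lgm`, `eemian`, and
`lgm_eemian`. A bottleneck multiplies deme sizes by a severity
*b* ∈ (0, 1] over a window whose most recent edge (the "onset", in years
BP) is drawn from a log-uniform prior — LGM on [20,000, 30,000], Eemian
on [115,000, 130,000] — and whose severity is drawn uniformly on
[0.2, 0.6]. Two decisions here were genuinely open:

- **Window extent.** Only the timing prior is specified by the analysis
  design, not what the drawn time anchors. We treat the draw as the
  window's recent edge and extend the reduction further back over the
  climatic window length: 8.6 ka for the LGM, 15 ka for the Eemian
  (configurable `duration`). A sustained reduced-size epoch was chosen
  over an instantaneous size change because "extent of the bottleneck"
  reads most naturally as a size reduction maintained over the climatic
  window.
- **Scope.** The reduction applies to every deme extant in the window by
  default; `bottleneck_scope: root` restricts it to the final ancestral
  deme, making the alternative reading explicit and testable.
- **Independence.** Each bottleneck's severity is drawn independently;
  `shared_severity: true` collapses the draws to one shared value.

## Parameters, units, defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| generations per year *g* | 2 | 1/year | the species' published generation time |
| mutation rate μ | 1.035 × 10⁻⁷ | /site/generation | 2.07 × 10⁻⁷ subs/site/year ÷ 2 generations/year |
| sequence length *L* | 16,300 | bp | mitogenome length |
| *N*<sub>ef</sub> per deme | 90,000 | females | the mitochondrial skyline plateau estimate |
| tolerance ε | 0.05 | retained fraction | the rejection-ABC design value |
| reference table | 5,000 rows/scenario | — | desk-scale default; the full design (500,000) is reachable via `--n-sims` |

Times are **years BP** at every interface and **generations BP**
internally, converted exactly by *g* (the conversion is invertible by
construction). All per-deme sizes, sample counts and ages live in the
configuration document and can be replaced wholesale when a real
sample manifest is available; the packaged per-deme values are structural
defaults, not published quantities.

## Simulation

The serial structured coalescent is simulated exactly in continuous time.
Within a deme holding *k* lineages and of current size *N*, the
coalescence rate is *k*(*k*−1)/2 · 1/*N* per generation (haploid scaling:
mtDNA tracks females only). Sampling ages, join times and bottleneck
window boundaries form an event queue of rate discontinuities; between
boundaries rates are constant, so exponential waiting times are exact,
and the memorylessness of the exponential makes "advance to the boundary
and redraw" exact as well. After the last join a single ancestral deme
persists indefinitely, so coalescence to a single root is guaranteed.

Mutations follow the infinite-sites model: Poisson(μ·*L*·branch length)
per branch, each mutation at its own uniformly drawn position; a drawn
mutation count exceeding *L* raises rather than silently reusing
positions (at the defaults this is astronomically unlikely). Finite-site
effects (recurrent and back mutation) are deliberately ignored: at the
divergence scales involved, S, π and F<sub>ST</sub> are insensitive to
them, and this is the one structural difference from a finite-sites
simulator a user should keep in mind.

Reproducibility: row (*i*, *r*) of a reference table uses the RNG
substream `SeedSequence([master_seed, i, r])`, so tables are bit-identical
under rerun and safe to parallelise.

## Summary statistics

All statistics are computed from per-deme allele-count tables and are
alphabet-agnostic, so simulated 0/1 haplotypes and nucleotide FASTA take
the same code path. π is the mean per-site pairwise difference within a
deme; F<sub>ST</sub> is Hudson's 1 − *H*<sub>w</sub>/*H*<sub>b</sub> with
*H*<sub>w</sub> the unweighted mean of the two within-deme diversities
and *H*<sub>b</sub> the mean difference over between-deme pairs. The
estimator is deliberately assumption-light for haploid data; the original
analysis toolchain's exact F<sub>ST</sub> variant is not documented, so
the estimator sits behind a named function and negative estimates are
reported as computed (a clamp-to-zero flag exists). Conventions chosen
for determinism and fixed vector length: demes with one sample report
S = 0 and π = 0; SDs over demes use denominator *d*;
*H*<sub>b</sub> = 0 yields F<sub>ST</sub> = 0. The canonical vector for
13 demes has 109 entries (2*d* + 5 + *d*(*d*−1)/2); the analysis design
this emulates reports 107, a discrepancy we document rather than force —
no straightforward composition of the named blocks yields 107 for
*d* = 13.

## Rejection ABC

Statistics are standardized by the reference table's mean and SD (zero-SD
columns are dropped and reported; MAD scaling is available as an option),
distance is Euclidean, and the accepted set is the ⌈ε·*n*⌉ nearest rows
with ties broken by (distance, row index) for determinism. Posterior
model probabilities are acceptance frequencies. Cross-validation is
leave-one-out: held-out reference rows are classified by highest
posterior against the remaining table. Regression adjustment and
sequential schemes are out of scope.

## The synthetic-data generator

`generate_observed` stands in for the real alignment: it simulates one
genealogy under a chosen scenario, drops mutations, and embeds the 0/1
variants into a random monomorphic A/C/G/T background (ancestral = the
reference base, derived = its transition partner; the mapping is
bijective per site, so every pairwise difference — hence S, π,
F<sub>ST</sub> — is preserved exactly, which the round-trip tests check).
What it does **not** emulate: sequencing error, post-mortem deamination
damage, missing data, alignment gaps, and real clade topology beyond the
configured joins. Passing tests therefore demonstrate correctness of the
inference machinery under the model's own assumptions, not robustness to
the artefacts of real ancient-DNA data.

## Problem sizes and numerical checks

The packaged analysis sizes are desk-scale choices: reference tables of
5,000 rows per scenario for power checks and 2,000 per scenario in the
acceptance script, with 25–100 pseudo-observed replicates; the full
500,000-row design is a `--n-sims` flag away and changes nothing
structurally. The simulator is validated against closed forms
(E[T₂] = *N*; serial pair 500 generations apart: 500 + *N*; isolation at
*T* with ancestral size *N*: *T* + *N*; Watterson's E[S] = θ·Σ1/*i*;
E[π] = θ per site), against msprime configured identically on a 3-deme
join scenario (two-sample KS on the TMRCA distribution), and the
statistics and rejection step against brute-force enumeration oracles.

## Known limitations

- No migration between contemporaneous demes and no recombination
  (appropriate for mtDNA, not portable to nuclear data).
- Infinite sites, no finite-sites substitution model.
- The per-deme sizes, clade-2/4 mrca ages and inter-clade topology in the
  default configuration are structural placeholders (see above), not
  published estimates.
- Rejection ABC only; posterior parameter summaries are provided but no
  claims are attached to them beyond what the accepted draws contain.
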