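# metaboflux

Network inference, expression-constrained flux balance analysis and
survival signatures for joint metabolomics/transcriptomics analysis of
tumor cohorts.

Quantified metabolite and gene-expression matrices carry correlated,
pathway-structured signal, but single-feature analyses ignore it.  This
package implements a functional, pathway-level workflow for such data —
the kind produced by untargeted metabolomics of tumor tissue alongside
expression arrays — aimed at computational biologists who want to go from
feature × sample matrices to interpretable networks, per-pathway metabolic
flux summaries, and prognostic signatures, with every stage testable on
synthetic data at desk scale.

## What it computes

**Decomposable Gaussian graphical models** (`ggm`).  Features are joined
by correlation alone, with no prior annotation.  The learner first finds
the maximum-likelihood spanning tree — for Gaussian data the Chow–Liu tree
with edge weights equal to the pairwise mutual information,
w(u,v) = −(n/2)·ln(1 − r²ᵤᵥ) — then greedily adds edges that preserve
decomposability (chordality) while the Bayesian Information Criterion,
BIC = −2·logL + (2p + |E|)·ln n, strictly decreases.  For a decomposable
model the gain of adding (u,v) is local: −(n/2)·ln(1 − ρ²ᵤᵥ|S) with ρ the
partial correlation given the new clique's separator S.  Networks export
to GraphML.

**Functional node activities** (`activity`).  The network is split into
branches (iterated removal of the highest-betweenness edge), each branch
takes the majority pathway label of its members, and its per-sample
activity is the mean value of the members matching that label.  Branch
activities are compared between sample groups (Mann–Whitney,
Benjamini–Hochberg).

**Expression-constrained FBA and flux activities** (`fluxmodel`).  A
constraint-based metabolic model (SBML L3/FBC or a documented JSON
dialect) is constrained per sample by a modified E-flux scheme: each
reaction's GPR boolean rule is resolved numerically (OR = sum of isozyme
values, AND = min over complex subunits), scores are max–min normalized
to [0,1] within the sample, and reaction bounds are scaled by the scores
(exchanges exempt).  Parsimonious FBA maximizes the biomass objective and
then minimizes total |flux|, and the per-pathway **flux activity** is
Σ |v| over the pathway's reactions — a pathway × sample matrix comparable
across samples.

**Survival signatures** (`survival`).  Features are ranked by the p-value
of a median-split log-rank test; the top k form a compound covariate
risk score Σ wᵢ·zᵢ with wᵢ the univariate Cox coefficient (Efron ties)
and zᵢ the standardized feature, dichotomized at the a-priori 50:50
median cutoff.  Negative weights mark protective features.  Validity is
assessed by leave-one-out cross-validation with feature selection inside
the loop, and significance by permutation: the log-rank statistic of the
cross-validated risk groups is compared against full re-runs under
permuted survival records.  A multivariate Cox model checks independence
from clinical covariates.

**Synthetic cohorts** (`simulate`).  Every input is generated at desk
scale: block-correlated omics matrices aligned to pathway labels,
detection-limit (left-censored) missingness, two sample groups with
planted pathway shifts, exponential proportional-hazards survival with
planted prognostic features, and a feasible toy metabolic model with
GPRs and redundant pathways.

## Worked example

`examples/03_survival_signature.py` plants a protective metabolite
(log-hazard −1.5) in a 100-sample cohort and rebuilds the signature:

```
cohort: 100 samples, 75 events

8 features at log-rank p < 0.05; top 3:
feature  statistic   p
m_p0_f0    52.2528 0.0
m_p0_f3    29.3857 0.0
m_p0_f7    23.0459 0.0
  weight[m_p0_f0] = -1.365 (protective)
  weight[m_p0_f3] = -0.494 (protective)
  weight[m_p0_f7] = -0.588 (protective)

LOOCV risk groups: 51 high / 49 low
log-rank p of cross-validated groups: 7.349e-11
permutation p (200 permutations, selection re-run per permutation): 0.00995
```

The planted feature is recovered at rank 1 with a negative (protective)
weight; its correlated block-mates inherit part of the signal, as
co-regulated metabolites do.  The cross-validated risk split stays
significant under the permutation null — the signature is not a
selection artifact.  The other
examples cover the metabolite network with node activities
(`01_metabolite_network.py`), per-sample E-flux FBA
(`02_eflux_fba.py`) and the combined multi-layer network
(`04_combined_network.py`).

A thin CLI wraps the same stages:

```bash
metaboflux simulate --seed 1 --out data/
metaboflux preprocess --in data/metabolites.tsv --out pre.tsv --seed 7
metaboflux ggm --in pre.tsv --out net.graphml --trace trace.tsv
metaboflux survival --matrix pre.tsv --surv data/samples.tsv --k 5 \
    --nperm 1000 --seed 7 --out sig
metaboflux all --out run/ --seed 1    # full pipeline with manifest
```

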