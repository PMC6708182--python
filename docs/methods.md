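# Methods

## The inference chain

The package reconstructs a ceRNA (competing endogenous RNA) interaction
network from three normalized expression matrices (lncRNA and mRNA in FPKM,
miRNA in RPM) over a shared two-group cohort, then screens the network
topologically and clinically. The chain is deliberately modular; every stage
is exposed as a library function and as a CLI verb, and every intermediate
is a TSV.

**Differential expression.** The screen is a two-sided Welch *t* test on
log2(x + c) with pseudocount c = 0.25, Benjamini–Hochberg adjustment within
each RNA class (the three classes come from separate library preparations
and are treated as separate screens), and the filter
|log2 FC| ≥ 1 ∧ P ≤ 0.05 ∧ q ≤ 0.05 with inclusive boundaries. The fold
change is computed from pseudocounted group means on the abundance scale,
written as a difference of logs so that swapping the groups negates it
exactly. This Welch-on-log stand-in replaces count-model engines (Cuffdiff
and the like): downstream stages only consume a calibrated DE gene list, and
the test's null behavior is verified (type-I rate ≈ 5%, pooled null
p-values uniform by Kolmogorov–Smirnov). Genes with zero within-group
variance are flagged and their variance floored at machine epsilon, so two
identical groups give t = 0, p = 1 rather than NaN.

**Correlation scale.** Pearson correlations — both gene–gene and
gene–clinical — are computed on log2(x + c). This matters: abundances are
approximately lognormal, and the exponential map attenuates negative
correlations far more than positive ones (corr(e^X, e^−Y) cannot reach −1),
which would make lncRNA–miRNA and miRNA–mRNA sponge correlations
systematically weaker than lncRNA–mRNA ones on the raw scale. Log-scale
Pearson is the field standard for co-expression and keeps the two signs
symmetric. Significance uses the exact *t*-transform
t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom; this choice reproduces
all six published clinical (r, P) pairs at a common n = 9 (and at no other
n in 5..15), which is also the basis for inferring that one case sample
lacked clinical data. No multiple-testing correction is applied to the
correlation screens, matching the source procedure. Gene–gene edges use
|r| ≥ 0.8 (inclusive, configurable) and the clinical screen |r| > 0.8
(strict, as printed); both use P ≤ 0.05 and pairwise-complete deletion with
the effective n recorded.

**Network stage.** Correlation edges survive only if their unordered pair
and pair class appear in the candidate interaction table (starBase-style
TSV). The graph is undirected and simple; an optional sign filter drops
edges violating sponge consistency. Centralities are computed on the full
graph including all components with in-package breadth-first machinery:
betweenness by Brandes accumulation, reported as unnormalized unordered-pair
counts (ranks are invariant to normalization), and closeness in the
Wasserman–Faust convention, (c−1)/Σd scaled by (c−1)/(n−1) for a component
of size c, isolated nodes scoring 0. Both are verified against an
exhaustive all-simple-paths enumeration oracle and against networkx.
The pivotal set is the intersection of the top-k sets of degree,
betweenness and closeness with inclusive ties; k defaults to 10 and is a
first-class parameter because the source procedure's cutoff is unknown.

**Enrichment.** A generic one-sided hypergeometric (Fisher) upper-tail test
of a query list against user-supplied GMT gene sets, BH-adjusted across
sets; the universe defaults to all detected genes. Database-version-bound
enrichment scores are out of scope by design.

**qPCR.** 2^−ΔΔCT with 100% efficiency assumed; for cohort comparisons the
calibrator is the control-group mean ΔCT (the standard choice when no
explicit calibrator sample is named), giving a geometric-mean fold change,
with a Welch *t* on ΔCT values.

## The synthetic cohort

The generator emulates the study conditions, not read-level data: log2
abundances are Gaussian with gene baselines uniform on [3, 8] and
within-group noise sd 0.5 (all on the log2 scale); planted DE genes are
mean-shifted by ±1.5 in the 10-sample case group versus the 5-sample
control group. Defaults plant 50/75/100 DE genes among 200/300/400 genes
per class — a deliberately generous desk-scale fraction chosen so that the
BH cutoff does not starve the screen at these tiny group sizes (see
"Calibration" below). Sponge structure is induced by a single per-sample
latent disease factor shared by all planted modules: a module gene loads
±√ρ on the factor (miRNA with opposite sign to lncRNA/mRNA), so any two
module genes have within-group correlation ρ (default target 0.9) with the
canonical sign pattern, and the aligned DE shifts raise the pooled
correlation further. One miRNA hub with four partners and two full trios
are planted by default (10 true interactions), plus 5× as many decoy
database pairs drawn among non-DE genes — decoys deliberately avoid planted
genes so that the cross-reference filter, not luck, determines the outcome.
Clinical parameters (EF %, TC mmol/L, Hcy µmol/L, plus an uncoupled LDL)
are linear functions of a named miRNA's standardized log2 abundance plus
noise, with the noise orthogonalized in-sample so the realized sample
correlation equals the target (−0.85) exactly. Identical config and seed
give bit-identical files (%.17g float serialization).

What the generator does not emulate: count noise and library-size effects,
batch structure, gene-length bias, miRNA isoforms, and realistic DE
prevalence (real studies find DE fractions far below 25%). Passing tests
therefore demonstrate that the chain recovers structure it is designed to
see at this scale, not field performance on real cohorts.

## Calibration and measured operating characteristics

Under the fixed conditions (10 vs 5, shift 1.5, noise 0.5), the log2
fold-change estimator has sd ≈ 0.5·√(1/10+1/5) ≈ 0.28, so a planted gene
fails the |log2 FC| ≥ 1 boundary with probability ≈ 3.5%; the Welch
variance estimate at ~8 degrees of freedom is heavy-tailed, and with the
within-class BH cutoff this caps the per-planted-gene pass rate at about
0.92 (0.915 measured over 200 seeds). Consequences measured at the
defaults: null pass rate ≈ 2·10⁻⁴; exact recovery of the full 10-edge
planted set in ≈ 80% of seeds (it requires all 11 module genes to pass
jointly); the hub reaches the pivotal set in ≈ 92% of seeds (bounded by its
own filter pass rate); hierarchical clustering and PCA on the surviving DE
signature separate the groups perfectly (ARI = 1) in essentially every
seed, while null cohorts show |ARI| < 0.3. These rates are properties of
the stated study conditions, not tunables; the n_de default is the one
generator parameter chosen by this power analysis, fixed before the
evaluation suite was run.

## Numerical conventions and degenerate inputs

Inclusive boundaries throughout the DE filter; strict inequality only where
the clinical screen's |r| > 0.8 rule is printed as strict. BH is
statsmodels' `fdr_bh`. p-values are clipped to [0, 1]; |r| is clipped to
[−1, 1]; |r| = 1 maps to p = 0 exactly. Constant genes are skipped from
correlation with a warning rather than erroring the whole screen; clinical
parameters with fewer than 3 complete pairs are skipped likewise. The
single-gene separation report falls back to absolute-difference distances
(a one-gene profile has no between-gene correlation structure). An empty DE
set propagates as empty downstream outputs and a manifest warning, not a
failure. Ties in the pivotal screen are kept (everything at the k-th value),
and per-metric ranks use the minimum-rank convention.

## Known limitations

The Welch stand-in is not a count model and the package does not estimate
dispersions; identifiers are opaque strings with no alias resolution; the
permutation distribution of Pearson's r at very small n is conditional on
the observed vectors and can deviate from the t approximation by more than
a few percent for individual draws (the t-transform is used for reported
p-values regardless, as it is the only choice consistent with the published
values); and the pivotal screen's k is a sensitivity parameter, not an
inferred quantity.
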