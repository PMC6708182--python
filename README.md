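# cernet

Competing-endogenous-RNA (ceRNA) network inference from differential
lncRNA/miRNA/mRNA expression, with centrality-based pivotal-gene screening
and clinical-parameter correlation.

Long non-coding RNAs can sponge miRNAs through shared miRNA response
elements, de-repressing the miRNAs' mRNA targets. In small case–control
transcriptome studies (e.g. coronary heart disease patients vs healthy
controls profiled by RNA-Seq and small-RNA-Seq), this motivates a standard
inference chain over normalized abundances (FPKM for lncRNA/mRNA, RPM for
miRNA):

1. **Differential expression screen.** Per RNA class, a two-sided Welch *t*
   on log2(x + c) (pseudocount c = 0.25) with Benjamini–Hochberg adjustment;
   a gene is kept when |log2 FC| ≥ 1, *P* ≤ 0.05 and FDR ≤ 0.05 (inclusive),
   where log2 FC = log2((x̄_case + c)/(x̄_control + c)).
2. **Co-expression.** Pearson *r* between all cross-class pairs of DE genes
   on the log2 scale, with significance from
   *t* = r·√((n−2)/(1−r²)) ~ t(n−2); pairs with |r| ≥ 0.8 and *P* ≤ 0.05
   are candidate interactions.
3. **Database cross-reference.** Candidate pairs survive only if the same
   unordered pair (with matching pair class) appears in a starBase-style
   predicted-interaction table; optionally a sponge-consistency sign filter
   (lncRNA–miRNA and miRNA–mRNA negative, lncRNA–mRNA positive).
4. **Pivotal-gene screen.** On the resulting undirected tripartite graph:
   degree, unnormalized betweenness, and Wasserman–Faust closeness; the
   pivotal set is the three-way intersection of the per-metric top-*k* sets
   (ties at the *k*-th value included).
5. **Clinical screen.** Pearson correlation of network genes against
   clinical parameters (ejection fraction, total cholesterol,
   homocysteine, …), keeping pairs with |r| > 0.8 (strict) and *P* < 0.05,
   pairwise-complete over missing values.

Because cohorts of this kind are typically not publicly deposited, the
package ships a seeded synthetic-data generator that emulates the study
design (10 cases vs 5 controls; planted DE genes with |log2 FC| = 1.5;
latent-factor sponge modules with target |r| = 0.9 and the canonical
down-lncRNA / up-miRNA / down-mRNA sign pattern; a planted hub; decoy
database pairs; clinical covariates coupled to named miRNAs), so every
stage can be validated against known ground truth. A 2^−ΔΔCT qPCR
quantification module covers the validation-cohort stage, and a generic
hypergeometric over-representation test (GMT input) stands in for
database-bound GO/KEGG enrichment.

## Worked example

```sh
cernet demo --seed 1 --out-dir demo_run
```

prints

```
network: 11 nodes, 10 edges
pivotal nodes (k=10): lnc_0001, lnc_0002, lnc_0003, lnc_0004, mir_0001, mir_0002, mir_0003, mrna_0001, mrna_0002, mrna_0003, mrna_0004
planted hub mir_0001: recovered (recovery is expected for most but not all seeds)
```

Here the generator planted 225 DE genes (50 lncRNA, 75 miRNA, 100 mRNA
among 200/300/400), a hub miRNA (`mir_0001`) with four sponge partners, two
lncRNA–miRNA–mRNA sponge trios, and 50 decoy database pairs. The pipeline
recovered exactly the 10 planted interactions (no decoy survived the
correlation + cross-reference intersection) and the hub is in the pivotal
set. `demo_run/` holds every intermediate as TSV (DE tables, correlation
edges, centralities with ranks, clinical correlations), the network as
SIF and GraphML for external viewers, the ground truth, and a JSON
manifest with per-stage record counts. The same analysis runs on real
data from TSV inputs via `cernet run --config config.yaml` (see
`cernet --help` for the stage-by-stage commands).

In the clinical screen, a planted coupling such as (mir_0001, EF,
r = −0.85) is reported with *P* = 6.0e−05 at n = 15; at the study's
cohort size of n = 9 a correlation of r = −0.878 gives *P* = 0.0019 by the
same *t*-transform.

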