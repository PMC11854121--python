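# assemblyscope

Null-model inference of microbial community assembly processes from
amplicon (ASV) data:

- **Neutral community model fit** — occurrence frequency vs. metacommunity
  relative abundance, with migration rate `m`, `R²`, 95% prediction bands
  and above/within/below partitioning of taxa.
- **βMNTD / βNTI** — abundance-weighted between-community mean nearest
  taxon distance against a tip-shuffling null over the regional pool
  (z-scores), plus a phylogenetic-signal correlogram that justifies the
  metric.
- **RCbray** — abundance-weighted Raup–Crick null model on Bray–Curtis
  dissimilarity (richness- and size-matched null communities, scaled to
  [−1, 1]).
- **Process partitioning** — the five-way classification per sample pair
  (variable selection, homogeneous selection, dispersal limitation,
  homogenizing dispersal, drift) and per-group fraction summaries.
- **Keystone screen** — leave-one-genus-out recomputation of βNTI with a
  flip flag for genera whose removal erases the selection signal.
- **Driver screen** — CV prefilter plus Mantel correlation of metabolite
  difference matrices against βNTI with an `r > 0.2` selection rule.
- **Synthetic data** — ground-truth generators (Yule tree, lognormal
  metacommunity, Brownian niche optima, neutral / selected / homogenizing
  regimes, planted keystone clades and planted metabolite drivers) so every
  stage is testable against known truth.

Shared infrastructure includes TSV/BIOM table I/O, Newick phylogenies,
QIIME-style taxonomy parsing, rarefaction to minimum depth, alpha
diversity, Bray–Curtis, a seeded vectorised Mantel test, and a Spearman
co-occurrence network builder.

## CLI

Every stage is exposed through one executable:

```bash
# generate a ground-truth scenario (table.tsv, tree.nwk, taxonomy.tsv,
# metadata.tsv, metabolites.tsv, truth.json)
assemblyscope simulate --scenario drivers --seed 1 --out demo/

# neutral model fit
assemblyscope neutral-fit --table demo/table.tsv --out fit.tsv

# betaNTI and RCbray (long-format pairwise TSVs)
assemblyscope bnti   --table demo/table.tsv --tree demo/tree.nwk \
    --nulls 999 --seed 1 --out bnti.tsv
assemblyscope rcbray --table demo/table.tsv --nulls 999 --seed 1 \
    --convention standard --out rc.tsv

# five-process partition per pair and per group
assemblyscope partition --bnti bnti.tsv --rc rc.tsv \
    --metadata demo/metadata.tsv --scope between_group \
    --out-pairs pairs.tsv --out-summary summary.tsv

# leave-one-genus-out keystone screen
assemblyscope keystone --table demo/table.tsv --tree demo/tree.nwk \
    --taxonomy demo/taxonomy.tsv --nulls 999 --seed 1 --out keystone.tsv

# metabolite driver screen against betaNTI
assemblyscope drivers --bnti bnti.tsv --metabolites demo/metabolites.tsv \
    --cv 0.5 --r 0.2 --out drivers.tsv

# alpha diversity (rarefied to minimum depth) and co-occurrence network
assemblyscope alpha-div --table demo/table.tsv --out alpha.tsv
assemblyscope network --table demo/table.tsv --top-n 150 --rho 0.8 \
    --out edges.tsv
```

`rcbray --convention paper_literal` inverts the numerator direction of the
Raup–Crick tail count for auditability; the default `standard` convention
maps "more similar than the null" to −1 (homogenizing dispersal) and "less
similar" to +1 (dispersal limitation), which is the orientation the ±0.95
interpretation thresholds assume.

## Library use

```python
import assemblyscope as asc

sc = asc.make_scenario("variable", seed=1)          # ground-truth scenario
fit = asc.fit_neutral_model(sc.communities)          # neutral model
res = asc.beta_nti(sc.communities, sc.tree, n_null=999, seed=1)
rc = asc.rc_bray(sc.communities, n_null=999, seed=1)
summary = asc.partition_fractions(res, rc, groups=sc.groups,
                                  scope="between_group")
```
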