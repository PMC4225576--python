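# vitisnet

Differential **metabolite correlation-network analysis** for two-condition
profiling studies, built around the design of a progressive water-deficit
trial on two grapevine cultivars (Cabernet Sauvignon *Cs* and Shiraz *Sh*,
irrigated *IR* vs water deficit *D*, sampled on days 4/18/26/34 with six
replicates).

It is aimed at plant physiologists and systems biologists who profile
relative metabolite intensities (GC/MS, LC/MS) across conditions and want to
go beyond per-metabolite fold changes: the question is whether a stress
*coordinates* metabolism — visible as a denser correlation network — and
which metabolites change their structural role.

## What it computes

**Profiling statistics.** Platform normalization (internal standard for
GC/MS, total-intensity 10,000 for LC/MS), log10 transformation, per-day
fold changes FC = mean(D)/mean(IR), equal-variance Student's *t* with
Benjamini–Hochberg FDR per stratum, and the two-part validity rule (same
trend on all days, significant on ≥ 1 day). Trait–metabolite Pearson
correlations and SVD-based PCA round out the preprocessing.

**Correlation networks.** For each cultivar × treatment data matrix, all
pairwise Pearson coefficients are tested (t transform, two-sided), BH
q-values computed per matrix, and an edge kept iff

    r >= r_min (0.9)   and   q <= q_max (0.01).

Nodes exist only as edge endpoints. Four properties summarize a network:
average node degree k̄ = 2E/N, density 2E/(N(N−1)), clustering coefficient,
and diameter (longest shortest path, largest component).

**Network algebra.** Union / intersection / difference / symmetric
difference on edge sets (edge identity = unordered node pair), the "1 to R"
specificity ratio between condition-specific edge counts, per-node
condition-specific contributions deg(v, difference) / deg(v, condition), and
nodal-degree ratios between conditions (with explicit "lost all relations"
flags).

**Permutation test.** Each metabolite column is shuffled independently
within each arm, both networks rebuilt (q-values recomputed each time), and
the difference of a chosen network parameter recorded, for n = 1000
iterations. With c = number of permuted differences that equal or exceed the
observed one,

    p = (c + 1) / (n + 1).

Permuted matrices usually yield *non-viable* (zero-node) networks at the
stringent thresholds; those iterations are non-comparable and count as
non-exceedances, and a per-arm node-count histogram documents them.

**Also included:** compound-class communities (greedy modularity or
annotation-imposed) with hypergeometric class enrichment; a synthetic-data
generator emulating the full trial design with known ground truth; suberin
fluorescence quantification for stained cross-sections (blue channel, mean
intensity of pixels ≥ 30).

## Worked example

```bash
vitisnet simulate --preset paper-like --seed 1 --out run
vitisnet network  --profiles run/profiles.tsv --metadata run/metadata.tsv \
                  --annotations run/annotations.tsv --out run/net
vitisnet permtest --profiles run/profiles.tsv --metadata run/metadata.tsv \
                  --cultivar Sh --n-iter 1000 --seed 1 --out run/perm
```

prints (numbers from this exact invocation):

```
Cs_D: nodes=66 edges=146 avg_degree=4.42 density=0.07 clustering=0.56 diameter=3
Cs_IR: nodes=65 edges=93 avg_degree=2.86 density=0.04 clustering=0.39 diameter=4
Sh_D: nodes=89 edges=523 avg_degree=11.75 density=0.13 clustering=0.98 diameter=1
Sh_IR: nodes=94 edges=446 avg_degree=9.49 density=0.10 clustering=0.78 diameter=3
Sh density: observed diff=0.0315 c=0 p=0.000999
```

Reading: the stressed Shiraz network is the densest (the generator plants a
within-class correlation contrast rho(Sh,D) > rho(Sh,IR) > rho(Cs,·)), and
the D−IR density difference for Shiraz is never reached by any of 1000
column permutations, so the empirical p-value hits its floor 1/1001 < 0.001.
The same library calls are available in Python:

```python
import vitisnet as vn
data = vn.generate(vn.preset_paper_like(), seed=1)
arms = vn.split_conditions(vn.log_transform(data.profile))
net = vn.network_from_matrix(arms[("Sh", "D")])
print(vn.network_stats(net))
```

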