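# ethnophylo

Phylogenetic signal and "hot node" detection for ethnomedicinal use data.

Traditional medicinal uses are not scattered at random across a plant
phylogeny: closely related species tend to share chemistry, and therefore
uses. `ethnophylo` quantifies that pattern for ethnobotanists and
bioprospectors. Given a rooted phylogeny with branch lengths and a record of
which taxa are used for which medicinal purpose, it answers two questions:

1. **Is a category of use phylogenetically clumped?** The taxa sharing a
   use form a "community" on the tree. Two community-phylogenetics metrics
   are computed per community of size *n*:

   - **MPD**, the mean patristic distance over all n(n−1)/2 pairs of
     community members (sensitive to clumping at deep nodes), and
   - **MNTD**, the mean distance from each member to its nearest co-member
     (sensitive to clumping near the tips).

   Each observed value is compared with the same metric on R random samples
   of *n* tips drawn uniformly from the full tip pool. The one-tailed
   clumping p-value is `p = (k + 1) / (R + 1)` with *k* the number of null
   samples at least as clumped (metric ≤ observed). Standardized effect
   sizes follow the NRI/NTI convention
   `SES = (mean_null − observed) / sd_null`, so positive values mean
   clumping. An exact enumeration oracle over all C(N, n) subsets is
   provided for small problems.

2. **Where on the tree is the clumping?** Every internal node *v* (root
   excluded) with D_v descendant tips is tested for overabundance of
   community members among those tips. Under the uniform-draw null the
   member count X_v is exactly Hypergeometric(N, D_v, n); the test runs
   either as that closed-form upper tail or as a Phylocom-style
   randomization (a node is flagged `MORE` when the observed count beats
   the null in ≥ 97.5% of runs). Flagged "hot nodes" are named
   `MRCA(first_tip,last_tip)` and can be exported as an annotated Newick
   tree; their unscreened descendants are bioprospecting candidates.

A synthetic-data module generates ultrametric Yule (pure-birth) trees and
communities with a tunable clumping fraction *f* (f=0 random, f=1 fully
clade-restricted), so the whole pipeline is testable and calibratable
without any external data.

## Worked example

```python
import pandas as pd
import ethnophylo as ep
from ethnophylo.signal import NullModelConfig

tree = ep.simulate_yule_tree(30, seed=4)              # 30-tip Yule tree
sample, focal = ep.simulate_community(tree, 6, 1.0, seed=1)
# 6 tips drawn entirely from the 7-tip clade MRCA(t6,t12)

mat = pd.DataFrame([[int(t in sample) for t in tree.tip_labels]],
                   index=["Skin"], columns=tree.tip_labels)
print(ep.signal_test(mat, tree, NullModelConfig(runs=999, seed=0)).round(4))
```

```
        n  mpd_obs  mpd_null_mean  mpd_null_sd  ses_mpd  p_mpd  mntd_obs  mntd_null_mean  mntd_null_sd  ses_mntd  p_mntd
sample
Skin    6   0.4587         5.1011       0.8512   5.4542  0.001    0.3153          2.7794        0.9202    2.6777   0.002
```

The observed MPD (0.459) sits far below the null mean (5.10), more than 5
null standard deviations (SES 5.45): with 999 randomizations no null sample
was as clumped, so p = 1/1000. The node test then locates the signal:

```python
nodes = ep.nodesig_test(mat, tree, NullModelConfig(runs=999, seed=0))
print(nodes.table[nodes.table.flag == "MORE"].round(4).to_string(index=False))
```

```
sample   node_label  D_v  X_v  null_mean  p_more flag
  Skin MRCA(t2,t14)   13    6     2.6096   0.002 MORE
  Skin MRCA(t6,t14)    9    6     1.8408   0.001 MORE
  Skin MRCA(t6,t12)    7    6     1.4404   0.001 MORE
  Skin MRCA(t7,t12)    6    5     1.2422   0.001 MORE
  Skin MRCA(t7,t11)    5    4     1.0511   0.001 MORE
  Skin MRCA(t8,t11)    4    4     0.8579   0.001 MORE
  Skin MRCA(t8,t10)    3    3     0.6456   0.008 MORE
```

All six "Skin" taxa fall under `MRCA(t6,t12)` (7 descendants, null
expectation 1.44) — the planted focal clade is recovered, together with its
nested and enclosing nodes. `ep.annotate_tree(tree, nodes)` writes the tree
with `MORE:Skin` labels at the flagged nodes.

The same analyses run from the shell on real data:

```sh
ethnophylo signal  --tree tree.nwk --samples uses.tsv --runs 999 --seed 1 --out signal.tsv
ethnophylo nodesig --tree tree.nwk --samples uses.tsv --runs 999 --seed 1 \
                   --out nodes.tsv --annotated-tree hot_nodes.nwk
ethnophylo summary --records records.tsv --out-prefix tallies
ethnophylo simulate --n-tips 100 --n-sample 10 -f 0 --replicates 500 --out calib.tsv
```

`--samples` accepts either a wide 0/1 TSV (taxa × samples) or the 3-column
Phylocom sample format; `--records` accepts long-form (taxon, category,
region, condition) tables, which are canonicalized against the 13 standard
use categories. `--prune` drops outgroup tips, `--mapping` expands species
names to accession tips. Outputs carry `#` provenance headers and are
byte-identical for a fixed seed.

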