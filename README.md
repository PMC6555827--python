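# nconserve

Tools for asking whether the responses of microbial taxa to an environmental
perturbation — e.g. the shift in relative abundance of soil bacterial OTUs
under nitrogen addition — are **phylogenetically conserved**: do closely
related taxa respond more similarly than distantly related ones, and at what
genetic depth?

The package takes a phylogeny (newick, branch lengths in substitutions/site)
and replicated treatment/control OTU count tables from one or more study
locations, and provides:

* **Response quantification** — per-location log2-fold response ratios from
  median-of-ratios-normalised counts, with a rare-OTU occupancy filter
  (OTUs in fewer than half of a location's plots are dropped), and
  cross-location averaging of *widespread* OTUs (present at ≥ 5 locations).
* **consenTRAIT** — consensus clades (nodes closest to the root under which
  > 90% of descendant tips share a response direction) and their mean
  genetic depth τ_D, with a tip-shuffling permutation test. A clade's
  depth is the average node-to-tip distance; a lone responding tip outside
  any consensus clade counts as a singleton clade at half its
  nearest-neighbour patristic distance.
* **Fritz–Purvis D** — the sum of sister-clade differences of the binary
  response, scaled so D ≈ 1 for a phylogenetically random trait and D ≈ 0
  for a trait evolved by threshold Brownian motion.
* **Mantel correlogram** — per-distance-class autocorrelation of the
  *continuous* response magnitude, with permutation significance and
  progressive Holm correction.
* **Taxonomic enrichment** — two-tailed exact binomial tests for taxa
  (phylum → genus) whose members respond more consistently positively or
  negatively than chance.
* **Synthetic data with known truth** — random trees, clades "planted" at a
  target depth, Brownian traits, taxonomies cut from the tree, and
  overdispersed multi-location count tables, so the whole pipeline is
  testable end-to-end without sequence data.

## Worked example

```python
import pandas as pd
import nconserve as nc

# a synthetic study: 256-tip tree, clades planted at depth 0.05,
# 6 locations x (8 treatment + 8 control) plots, 5e4 reads per plot
tree = nc.simulate_tree(256, seed=11)
truth = nc.plant_clades(tree, target_depth=0.05, prevalence=0.5, flip_noise=0.02, seed=11)
tables = nc.simulate_counts(truth, n_treatment=8, n_control=8, depth=5e4, n_locations=6, seed=11)

responses = pd.concat([nc.respond(t) for t in tables], ignore_index=True)
merged = nc.merge_responses(responses, min_locations=5)

nz = merged.ratios()[merged.ratios() != 0]
sub = tree.prune_to(nz.index)
ct = nc.consentrait_test(sub, (nz > 0).to_dict(), n_perm=1000, seed=1)
d = nc.d_test(sub, (nz > 0).astype(int).to_dict(), n_sim=1000, seed=1)
cg = nc.mantel_correlogram(nc.patristic_distance_matrix(sub), nz, n_perm=999, seed=1)
```

which prints (via the obvious f-strings):

```
widespread OTUs: 154
positive consensus clades: 21  tau_D = 0.0337  P = 0.000
scaled D = -0.214  P = 0.000
first distance class [0.000, 0.020): coef = 0.036  P = 0.000
```

Reading: 154 of the 256 OTUs survive the rare filter in ≥ 5 locations; the
positively responding OTUs cluster into 21 consensus clades of mean depth
τ_D = 0.034 substitutions/site, far deeper than any of the 1000 shuffled
τ_D values (P < 0.001); D below 0 confirms the response is even more
clumped than Brownian evolution would produce; and the closest OTU pairs
(< 2% divergent) respond significantly more similarly than average.

The same analyses are scriptable from the shell:

```sh
nconserve simulate --n-tips 256 --seed 11 --out study/
nconserve respond --counts study/counts_loc01.tsv --design study/design.tsv --out r1.tsv
nconserve consentrait --tree study/tree.nwk --responses merged.tsv --nperm 1000 --seed 42 --out ct.tsv
nconserve run --config analysis.yaml --out results/
```

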