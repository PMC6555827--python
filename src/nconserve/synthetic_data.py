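"""Synthetic trees, traits, taxonomies and count tables with known truth.

Every pipeline stage can be exercised end-to-end without any sequence
data: a random tree stands in for the 16S phylogeny, clades "planted" at a
target genetic depth define which taxa respond positively, and multi-site
negative-binomial count tables emulate replicated treatment/control plot
designs. The planted node ids, per-OTU effect sizes and all generator
parameters are carried in :class:`SyntheticTruth` so recovery can be
scored exactly.

Default scales mirror a 16S amplicon study: mean root-to-tip distance
0.15 substitutions/site, 10^4–10^5 reads per plot, negative-binomial
dispersion 0.3. The default planted depth is 0.05: on trees of a few
hundred tips, pendant branches are long enough that shallower planting
(e.g. genus-level 0.018) is indistinguishable from the shuffle null —
that regime needs the tip densities of full amplicon surveys.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .phylo_core import PhyloTree, read_newick, write_newick
from .response_quant import CountTable
from .taxonomy_enrichment import RANKS

__all__ = [
    "SyntheticTruth",
    "simulate_tree",
    "plant_clades",
    "simulate_bm_response",
    "brownian_tip_values",
    "simulate_counts",
    "simulate_taxonomy",
    "DEFAULT_RANK_DEPTHS",
]

# node-to-tip depths at which taxonomy labels are cut, per rank, on a
# 0.15-deep tree; strictly decreasing phylum -> genus
DEFAULT_RANK_DEPTHS = {
    "phylum": 0.12,
    "class": 0.09,
    "order": 0.06,
    "family": 0.035,
    "genus": 0.018,
}


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic study."""

    tree: PhyloTree
    planted_nodes: list[int]  # preorder node ids of planted clades
    planted_depths: list[float]
    labels: pd.Series  # tip -> +1 (positive responder) / -1
    beta: pd.Series  # tip -> true log2 effect
    liability: pd.Series  # continuous response underlying the labels
    taxonomy: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def planted_tip_sets(self) -> list[frozenset[str]]:
        ix = self.tree.index
        out = []
        for node in self.planted_nodes:
            stack, tips = [node], []
            while stack:
                i = stack.pop()
                if ix.is_tip[i]:
                    tips.append(ix.tip_labels[int(np.searchsorted(ix.tip_ids, i))])
                else:
                    stack.extend(ix.children[i])
            out.append(frozenset(tips))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "newick": write_newick(self.tree),
                "planted_nodes": [int(i) for i in self.planted_nodes],
                "planted_depths": [float(d) for d in self.planted_depths],
                "labels": {k: int(v) for k, v in self.labels.items()},
                "beta": {k: float(v) for k, v in self.beta.items()},
                "liability": {k: float(v) for k, v in self.liability.items()},
                "params": self.params,
                "seed": self.seed,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            tree=read_newick(d["newick"]),
            planted_nodes=d["planted_nodes"],
            planted_depths=d["planted_depths"],
            labels=pd.Series(d["labels"]),
            beta=pd.Series(d["beta"]),
            liability=pd.Series(d["liability"]),
            params=d.get("params", {}),
            seed=d.get("seed"),
        )


def simulate_tree(
    n_tips: int,
    model: str = "yule",
    total_depth: float = 0.15,
    seed: int | None = None,
) -> PhyloTree:
    """Random rooted bifurcating tree, rescaled so the mean root-to-tip
    distance equals ``total_depth`` (substitutions/site)."""
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if total_depth <= 0:
        raise ValueError("total_depth must be positive")
    rng = random.Random(seed)
    if model == "yule":
        t = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng
        )
    elif model == "coalescent":
        tns = dendropy.TaxonNamespace([f"T{i}" for i in range(n_tips)])
        t = treesim.pure_kingman_tree(taxon_namespace=tns, pop_size=1.0, rng=rng)
    else:
        raise ValueError(f"unknown model {model!r}")
    t.seed_node.edge.length = 0.0
    width = len(str(n_tips))
    for i, leaf in enumerate(sorted(t.leaf_node_iter(), key=lambda n: n.taxon.label)):
        leaf.taxon.label = f"OTU{i + 1:0{width}d}"
    tree = PhyloTree(t)
    mean_rt = float(tree.index.depth_from_root[tree.index.tip_ids].mean())
    if mean_rt == 0.0:  # degenerate simultaneous-split draw (e.g. n_tips=2)
        for nd in t.preorder_node_iter():
            if nd.parent_node is not None:
                nd.edge.length = 1.0
        tree = PhyloTree(t)
        mean_rt = float(tree.index.depth_from_root[tree.index.tip_ids].mean())
    scale = total_depth / mean_rt
    for nd in t.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= scale
    return PhyloTree(t)


def plant_clades(
    tree: PhyloTree,
    target_depth: float = 0.05,
    prevalence: float = 0.5,
    flip_noise: float = 0.0,
    seed: int | None = None,
    depth_tolerance: float = 0.25,
    effect_size: float = 2.0,
    effect_sd: float = 0.5,
) -> SyntheticTruth:
    """Assign a positive response to disjoint clades near ``target_depth``.

    Internal nodes whose mean node-to-tip depth lies within
    ``±depth_tolerance`` (fractional) of ``target_depth`` are selected
    greedily, in random order, skipping overlaps, until about
    ``prevalence`` of the tips are covered. Covered tips respond
    positively, the rest negatively; each tip's direction is then flipped
    independently with probability ``flip_noise``. β magnitudes are drawn
    lognormal around ``effect_size`` and signed by the (post-flip) label;
    the continuous liability equals β.
    """
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    if not 0 <= flip_noise < 0.5:
        raise ValueError("flip_noise must be in [0, 0.5)")
    ix = tree.index
    if not 0 < target_depth < np.nanmax(ix.mean_depth):
        raise ValueError("target_depth must lie inside the tree's depth range")
    rng = np.random.default_rng(seed)
    lo, hi = target_depth * (1 - depth_tolerance), target_depth * (1 + depth_tolerance)
    candidates = [
        i
        for i in range(ix.n_nodes)
        if (not ix.is_tip[i]) and lo <= ix.mean_depth[i] <= hi
    ]
    if not candidates:
        raise ValueError(
            f"no internal node with mean depth in [{lo:.4g}, {hi:.4g}]; "
            "tree too small or shallow for this target"
        )
    rng.shuffle(candidates)

    n_target = prevalence * ix.n_tips
    # ancestor sets let us reject overlapping picks quickly
    chosen: list[int] = []
    covered = np.zeros(ix.n_nodes, dtype=bool)
    n_covered = 0
    for node in candidates:
        if n_covered >= n_target:
            break
        # overlap if node is under a chosen clade or a chosen clade is under node
        j, under = node, False
        while j != -1:
            if covered[j]:
                under = True
                break
            j = ix.parent[j]
        if under:
            continue
        sub = _subtree_nodes(ix, node)
        if covered[sub].any():
            continue
        chosen.append(node)
        covered[sub] = True
        n_covered += int(ix.n_desc_tips[node])

    if not chosen:
        raise ValueError("could not plant any clade; relax target_depth or prevalence")

    tip_cov = covered[ix.tip_ids]
    labels = np.where(tip_cov, 1, -1)
    flips = rng.random(ix.n_tips) < flip_noise
    labels = np.where(flips, -labels, labels)
    mag = np.exp(rng.normal(np.log(effect_size), effect_sd, ix.n_tips))
    beta = labels * mag
    tips = ix.tip_labels
    return SyntheticTruth(
        tree=tree,
        planted_nodes=chosen,
        planted_depths=[float(ix.mean_depth[i]) for i in chosen],
        labels=pd.Series(labels, index=tips),
        beta=pd.Series(beta, index=tips),
        liability=pd.Series(beta, index=tips),
        params={
            "target_depth": target_depth,
            "prevalence": prevalence,
            "flip_noise": flip_noise,
            "depth_tolerance": depth_tolerance,
            "effect_size": effect_size,
            "effect_sd": effect_sd,
        },
        seed=seed,
    )


def _subtree_nodes(ix, node: int) -> np.ndarray:
    stack, out = [node], []
    while stack:
        i = stack.pop()
        out.append(i)
        if not ix.is_tip[i]:
            stack.extend(ix.children[i])
    return np.array(out)


def brownian_tip_values(
    tree: PhyloTree,
    sigma: float = 1.0,
    n_replicates: int = 1,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Brownian motion down the tree: root value 0, each branch adds a
    N(0, sigma² · branch length) increment. Returns (n_replicates, n_tips)
    in ``tip_labels`` order."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = rng if rng is not None else np.random.default_rng()
    ix = tree.index
    eps = rng.standard_normal((ix.n_nodes, n_replicates)) * (
        sigma * np.sqrt(ix.edge_len)[:, None]
    )
    vals = np.zeros((ix.n_nodes, n_replicates))
    for i in range(1, ix.n_nodes):
        vals[i] = vals[ix.parent[i]] + eps[i]
    return vals[ix.tip_ids].T


def simulate_bm_response(
    tree: PhyloTree, sigma: float = 1.0, seed: int | None = None
) -> pd.Series:
    """One Brownian trait realisation as a tip-indexed Series."""
    vals = brownian_tip_values(tree, sigma, 1, np.random.default_rng(seed))[0]
    return pd.Series(vals, index=tree.index.tip_labels)


def simulate_counts(
    truth: SyntheticTruth,
    n_treatment: int = 8,
    n_control: int = 8,
    depth: float = 5e4,
    dispersion: float = 0.3,
    n_locations: int = 6,
    presence_prob: float = 0.8,
    baseline_sd: float = 1.5,
    seed: int | None = None,
) -> list[CountTable]:
    """Replicated treatment/control count tables for several locations.

    Per location, each OTU is present with probability ``presence_prob``
    (so cross-location merging has something to filter), gets a lognormal
    baseline abundance, and treatment plots multiply its expectation by
    2^β. Plot counts are negative-binomial with variance
    λ + dispersion·λ², scaled to ``depth`` expected reads per plot.
    """
    if n_treatment < 3 or n_control < 3:
        raise ValueError("need at least 3 treatment and 3 control plots")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    tips = list(truth.beta.index)
    beta = truth.beta.to_numpy(dtype=float)
    n_otu = len(tips)
    size = 1.0 / dispersion  # NB shape parameter

    tables = []
    for loc_i in range(n_locations):
        loc = f"loc{loc_i + 1:02d}"
        present = rng.random(n_otu) < presence_prob
        if not present.any():
            present[rng.integers(n_otu)] = True
        base = np.where(present, np.exp(rng.normal(0.0, baseline_sd, n_otu)), 0.0)
        rel_c = base / base.sum()
        treat = base * np.exp2(beta)
        rel_t = treat / treat.sum()

        plots, groups, cols = [], [], []
        for j in range(n_treatment):
            lam = depth * rel_t
            cols.append(_nb_draw(rng, lam, size))
            plots.append(f"{loc}_T{j + 1}")
            groups.append("treatment")
        for j in range(n_control):
            lam = depth * rel_c
            cols.append(_nb_draw(rng, lam, size))
            plots.append(f"{loc}_C{j + 1}")
            groups.append("control")
        counts = pd.DataFrame(np.column_stack(cols), index=tips, columns=plots)
        design = pd.DataFrame({"location": loc, "group": groups}, index=pd.Index(plots, name="plot_id"))
        tables.append(CountTable(counts, design))
    return tables


def _nb_draw(rng: np.random.Generator, lam: np.ndarray, size: float) -> np.ndarray:
    out = np.zeros(len(lam), dtype=np.int64)
    pos = lam > 0
    p = size / (size + lam[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_taxonomy(
    tree: PhyloTree,
    ranks_depths: dict[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Nested taxonomy labels obtained by cutting the tree at per-rank depths.

    A rank's taxa are the shallowest nodes whose mean node-to-tip depth is
    at or below the rank's cut depth (the node closest to the root on each
    root-to-tip path); all tips under one such node share the rank label.
    Nesting across ranks holds because cut depths strictly decrease from
    phylum to genus.
    """
    depths = dict(ranks_depths) if ranks_depths is not None else dict(DEFAULT_RANK_DEPTHS)
    vals = [depths[r] for r in RANKS if r in depths]
    if list(depths) != [r for r in RANKS if r in depths] or any(
        later >= earlier for earlier, later in zip(vals, vals[1:])
    ):
        raise ValueError("rank depths must be strictly decreasing phylum -> genus")
    ix = tree.index
    out = pd.DataFrame(index=pd.Index(ix.tip_labels, name="otu_id"))
    for rank, cut in depths.items():
        label = np.full(ix.n_nodes, -1, dtype=np.int64)
        counter = 0
        stack = [0]
        assignments = np.full(ix.n_tips, -1, dtype=np.int64)
        while stack:
            i = stack.pop()
            d = ix.mean_depth[i] if not ix.is_tip[i] else 0.0
            if d <= cut:
                counter += 1
                for j in _subtree_nodes(ix, i):
                    if ix.is_tip[j]:
                        assignments[int(np.searchsorted(ix.tip_ids, j))] = counter
            else:
                stack.extend(ix.children[i])
        out[rank] = [f"{rank[0]}{a:03d}" for a in assignments]
    return out
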