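"""Phylogenetic-signal statistics for per-taxon responses.

Three complementary analyses of whether a response is conserved on a tree:

* **consenTRAIT** — finds *consensus clades*, the nodes closest to the root
  under which more than a threshold fraction (default >90%) of tips share a
  binary trait, and summarises their mean genetic depth τ_D. Significance
  comes from shuffling the trait across tips.
* **Fritz–Purvis D** — sum of sister-clade differences of the binary trait,
  scaled between the expectation under random tip shuffles (D = 1) and under
  threshold-Brownian evolution (D = 0).
* **Mantel correlogram** — per-distance-class autocorrelation of a
  *continuous* response, with a permutation null and progressive Holm
  correction across classes.

All permutation tests report the plain empirical fraction (so P = 0 is
possible) to match the convention of the permutation counts; pass
``plus_one=True`` for the (b+1)/(m+1) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
from scipy.spatial.distance import pdist, squareform

from .phylo_core import PhyloTree, TreeIndex, resolve_polytomies

__all__ = [
    "ConsensusClade",
    "ConsenTraitResult",
    "DTestResult",
    "CorrelogramResult",
    "consensus_clades",
    "tau_D",
    "consentrait_test",
    "d_statistic",
    "d_test",
    "mantel_correlogram",
    "depth_to_dissimilarity",
]


def depth_to_dissimilarity(depth: float) -> float:
    """Expected tip-to-tip dissimilarity implied by a node-to-tip clade depth.

    Two tips descending from a node at mean depth ``d`` are separated by
    roughly ``2 d`` substitutions/site (each contributes one node-to-tip
    path), so a mean clade depth of 0.018 corresponds to ~3.6% pairwise
    sequence dissimilarity within consensus clades.
    """
    return 2.0 * depth


# ---------------------------------------------------------------------------
# consenTRAIT


@dataclass(frozen=True)
class ConsensusClade:
    node_id: int  # preorder index in the tree's TreeIndex
    direction: str
    depth: float
    size: int
    is_singleton: bool
    tips: tuple[str, ...]


@dataclass
class ConsenTraitResult:
    direction: str
    clades: list[ConsensusClade]
    tau_d: float
    p_value: float | None
    n_permutations: int
    seed: int | None
    threshold: float
    include_singletons: bool

    def clades_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "node_id": c.node_id,
                    "direction": c.direction,
                    "depth": c.depth,
                    "size": c.size,
                    "singleton": c.is_singleton,
                }
                for c in self.clades
            ]
        )


class ConsenTraitEngine:
    """Vectorised consenTRAIT evaluator.

    Tree geometry (descendant counts, mean depths, half nearest-neighbour
    distances) is precomputed once; each trait assignment — observed or
    permuted — then costs one postorder and one preorder sweep of numpy
    row operations, evaluated for all permutations simultaneously.
    """

    def __init__(self, tree: PhyloTree, threshold: float = 0.9):
        if not 0.5 < threshold <= 1.0:
            raise ValueError("threshold must be in (0.5, 1]")
        self.tree = tree
        self.threshold = threshold
        ix = tree.index
        self.ix = ix
        self.internal = np.flatnonzero(~ix.is_tip)
        pat = ix.patristic().copy()
        np.fill_diagonal(pat, np.inf)
        # singleton depth = half the patristic distance to the nearest tip
        self.nn_half = pat.min(axis=1) / 2.0 if ix.n_tips > 1 else np.zeros(1)

    def _sweep(self, traits: np.ndarray):
        """traits: bool (n_assign, n_tips) in tip_labels order.

        Returns (clade_mask over nodes × assignments, singleton mask over
        tips × assignments)."""
        ix = self.ix
        m = traits.shape[0]
        counts = np.zeros((ix.n_nodes, m))
        counts[ix.tip_ids] = traits.T
        for i in ix.postorder:
            if not ix.is_tip[i]:
                c = ix.children[i]
                counts[i] = counts[c[0]]
                for j in c[1:]:
                    counts[i] = counts[i] + counts[j]
        # strict ">threshold" fraction rule, internal nodes only
        qual = np.zeros((ix.n_nodes, m), dtype=bool)
        for i in self.internal:
            qual[i] = counts[i] > self.threshold * ix.n_desc_tips[i]
        covered = np.zeros((ix.n_nodes, m), dtype=bool)
        for i in range(1, ix.n_nodes):
            p = ix.parent[i]
            covered[i] = covered[p] | qual[p]
        clade = qual & ~covered
        singleton = traits.T.astype(bool) & ~covered[ix.tip_ids]
        return clade, singleton

    def tau_d_many(self, traits: np.ndarray, include_singletons: bool = True) -> np.ndarray:
        clade, singleton = self._sweep(traits)
        depths = np.nan_to_num(self.ix.mean_depth)
        num = depths @ clade
        den = clade.sum(axis=0).astype(float)
        if include_singletons:
            num = num + self.nn_half @ singleton
            den = den + singleton.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, num / np.maximum(den, 1), np.nan)

    def clades(self, trait_vec: np.ndarray, direction: str = "positive") -> list[ConsensusClade]:
        clade, singleton = self._sweep(trait_vec[None, :].astype(bool))
        ix = self.ix
        out: list[ConsensusClade] = []
        for i in np.flatnonzero(clade[:, 0]):
            out.append(
                ConsensusClade(
                    node_id=int(i),
                    direction=direction,
                    depth=float(ix.mean_depth[i]),
                    size=int(ix.n_desc_tips[i]),
                    is_singleton=False,
                    tips=tuple(self._tips_under(int(i))),
                )
            )
        for k in np.flatnonzero(singleton[:, 0]):
            out.append(
                ConsensusClade(
                    node_id=int(ix.tip_ids[k]),
                    direction=direction,
                    depth=float(self.nn_half[k]),
                    size=1,
                    is_singleton=True,
                    tips=(ix.tip_labels[k],),
                )
            )
        return out

    def _tips_under(self, node: int) -> list[str]:
        ix = self.ix
        stack, tips = [node], []
        while stack:
            i = stack.pop()
            if ix.is_tip[i]:
                tips.append(ix.tip_labels[int(np.searchsorted(ix.tip_ids, i))])
            else:
                stack.extend(ix.children[i])
        return sorted(tips)


def _trait_vector(tree: PhyloTree, trait: Mapping[str, object]) -> np.ndarray:
    labels = tree.index.tip_labels
    missing = [lab for lab in labels if lab not in trait]
    if missing:
        raise KeyError(f"trait missing for tips: {missing[:5]}")
    return np.array([bool(trait[lab]) for lab in labels])


def consensus_clades(
    tree: PhyloTree,
    trait: Mapping[str, object],
    threshold: float = 0.9,
    direction: str = "positive",
) -> list[ConsensusClade]:
    """Deepest nodes (closest to the root) whose descendant tips share the
    trait in a fraction strictly above ``threshold``; trait-bearing tips not
    inside any such clade become singleton clades with depth = half the
    nearest-neighbour patristic distance."""
    eng = ConsenTraitEngine(tree, threshold)
    return eng.clades(_trait_vector(tree, trait), direction=direction)


def tau_D(clades: Sequence[ConsensusClade]) -> float:
    """Unweighted mean genetic depth of consensus clades (singletons included)."""
    if len(clades) == 0:
        raise ValueError("tau_D of an empty clade list is undefined")
    return float(np.mean([c.depth for c in clades]))


def consentrait_test(
    tree: PhyloTree,
    trait: Mapping[str, object],
    threshold: float = 0.9,
    n_perm: int = 1000,
    seed: int | None = None,
    direction: str = "positive",
    include_singletons: bool = True,
    plus_one: bool = False,
) -> ConsenTraitResult:
    """Observed τ_D plus a tip-shuffling permutation test.

    P is the fraction of permuted τ_D values greater than or equal to the
    observed one; permutations preserve trait prevalence exactly.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    eng = ConsenTraitEngine(tree, threshold)
    vec = _trait_vector(tree, trait)
    n_has = int(vec.sum())
    if n_has < 2 or (len(vec) - n_has) < 2:
        warnings.warn(
            "fewer than 2 tips in one trait state; the permutation test is degenerate"
        )
    clades = eng.clades(vec, direction=direction)
    obs = eng.tau_d_many(vec[None, :], include_singletons)[0] if clades else np.nan
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, len(vec)))
    perms = vec[np.argsort(keys, axis=1)]
    sim = eng.tau_d_many(perms, include_singletons)
    if np.isnan(obs):
        p = 1.0
    else:
        b = int(np.sum(sim[~np.isnan(sim)] >= obs))
        p = (b + 1) / (n_perm + 1) if plus_one else b / n_perm
    return ConsenTraitResult(
        direction=direction,
        clades=clades,
        tau_d=float(obs),
        p_value=float(p),
        n_permutations=n_perm,
        seed=seed,
        threshold=threshold,
        include_singletons=include_singletons,
    )


# ---------------------------------------------------------------------------
# Fritz–Purvis D


@dataclass
class DTestResult:
    d_obs: float
    mean_random: float
    mean_brownian: float
    scaled_d: float
    p_value: float
    n_sim: int
    seed: int | None


def _binary_vector(tree: PhyloTree, trait: Mapping[str, object]) -> np.ndarray:
    labels = tree.index.tip_labels
    missing = [lab for lab in labels if lab not in trait]
    if missing:
        raise KeyError(f"trait missing for tips: {missing[:5]}")
    vals = np.array([trait[lab] for lab in labels], dtype=float)
    if not set(np.unique(vals)) <= {0.0, 1.0}:
        raise ValueError("D-test trait must be binary 0/1")
    return vals


def _ensure_bifurcating(tree: PhyloTree) -> PhyloTree:
    if any(len(c) > 2 for c in tree.index.children):
        return resolve_polytomies(tree)
    return tree


def _d_sum_many(ix: TreeIndex, values: np.ndarray) -> np.ndarray:
    """Sum over internal nodes of |left − right| nodal values; nodal value =
    mean of the two children's values (tip-to-root recursion).

    values: (n_rep, n_tips) → (n_rep,)"""
    m = values.shape[0]
    vals = np.zeros((ix.n_nodes, m))
    vals[ix.tip_ids] = values.T
    d = np.zeros(m)
    for i in ix.postorder:
        if ix.is_tip[i]:
            continue
        c1, c2 = ix.children[i]
        d += np.abs(vals[c1] - vals[c2])
        vals[i] = 0.5 * (vals[c1] + vals[c2])
    return d


def d_statistic(tree: PhyloTree, trait: Mapping[str, object]) -> float:
    """Unscaled sum of sister-clade differences of a binary trait."""
    tree = _ensure_bifurcating(tree)
    vals = _binary_vector(tree, trait)
    return float(_d_sum_many(tree.index, vals[None, :])[0])


def d_test(
    tree: PhyloTree,
    trait: Mapping[str, object],
    n_sim: int = 1000,
    seed: int | None = None,
    plus_one: bool = False,
) -> DTestResult:
    """Scaled D with permutation significance.

    Random null: shuffle tip values. Brownian null: simulate Brownian
    motion on the tree and binarise each replicate at its own quantile so
    simulated prevalence equals the observed prevalence exactly. scaled
    D = (d_obs − mean_brownian)/(mean_random − mean_brownian); P is the
    fraction of random-null d values ≤ d_obs.
    """
    from .synthetic_data import brownian_tip_values  # local import: no cycle at import time

    tree = _ensure_bifurcating(tree)
    ix = tree.index
    vals = _binary_vector(tree, trait)
    k = int(vals.sum())
    n = len(vals)
    if k == 0 or k == n:
        raise ValueError("trait prevalence must be strictly between 0 and 1")
    d_obs = float(_d_sum_many(ix, vals[None, :])[0])

    rng = np.random.default_rng(seed)
    keys = rng.random((n_sim, n))
    d_rand = _d_sum_many(ix, vals[np.argsort(keys, axis=1)])

    bm = brownian_tip_values(tree, sigma=1.0, n_replicates=n_sim, rng=rng)
    # binarise at the per-replicate quantile: top-k tips get the trait
    order = np.argpartition(bm, n - k, axis=1)[:, n - k :]
    binar = np.zeros_like(bm)
    np.put_along_axis(binar, order, 1.0, axis=1)
    d_brown = _d_sum_many(ix, binar)

    mean_r, mean_b = float(d_rand.mean()), float(d_brown.mean())
    if np.isclose(mean_r, mean_b):
        raise ValueError("random and Brownian null means coincide; D is undefined")
    scaled = (d_obs - mean_b) / (mean_r - mean_b)
    b = int(np.sum(d_rand <= d_obs))
    p = (b + 1) / (n_sim + 1) if plus_one else b / n_sim
    return DTestResult(
        d_obs=d_obs,
        mean_random=mean_r,
        mean_brownian=mean_b,
        scaled_d=float(scaled),
        p_value=float(p),
        n_sim=n_sim,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mantel correlogram


@dataclass
class CorrelogramResult:
    table: pd.DataFrame  # class_lo, class_hi, n_pairs, coef, p, p_corrected, significant
    n_permutations: int
    seed: int | None
    correction: str
    distance_source: str = "patristic"


def _progressive_holm(p: np.ndarray) -> np.ndarray:
    """Progressive multiple-testing correction across ordered distance
    classes: class k is Holm-corrected among the first k classes only."""
    out = np.empty_like(p)
    for i in range(len(p)):
        sub = p[: i + 1]
        order = np.argsort(sub)
        m = i + 1
        adj = (m - np.arange(m)) * sub[order]
        adj = np.maximum.accumulate(adj)
        adj = np.minimum(adj, 1.0)
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(m)
        out[i] = adj[ranks[i]]
    return out


def sturges_classes(n_pairs: int) -> int:
    return int(np.ceil(np.log2(n_pairs))) + 1


def mantel_correlogram(
    dist: skbio.DistanceMatrix,
    responses: Mapping[str, float] | pd.Series,
    n_classes: int | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    alpha: float = 0.05,
    correction: str = "holm",
    distance_source: str = "patristic",
) -> CorrelogramResult:
    """Autocorrelogram of response similarity over phylogenetic distance.

    For each equal-width distance class the coefficient is −1 × the Mantel
    correlation between |r_i − r_j| and the class-membership indicator, so
    a positive coefficient means pairs in that class respond more similarly
    than average. Two-sided permutation P per class (shuffling responses
    across taxa), progressively Holm-corrected by default.
    """
    responses = pd.Series(responses)
    ids = list(dist.ids)
    missing = [i for i in ids if i not in responses.index]
    if missing:
        raise KeyError(f"responses missing for: {missing[:5]}")
    r = responses.loc[ids].to_numpy(dtype=float)
    if np.isclose(r.var(), 0.0):
        raise ValueError("responses have zero variance; correlogram undefined")
    d = squareform(dist.data, checks=False)
    n_pairs = len(d)
    k = n_classes if n_classes is not None else sturges_classes(n_pairs)
    dmax = d.max()
    width = dmax / k
    cls = np.minimum((d / width).astype(int), k - 1)

    t_obs = pdist(r[:, None], metric="cityblock")
    kept, indic = [], []
    for c in range(k):
        mask = cls == c
        np_c = int(mask.sum())
        if np_c == 0:
            warnings.warn(f"distance class {c} is empty; dropped")
            continue
        kept.append((c * width, (c + 1) * width if c < k - 1 else dmax, np_c))
        indic.append(mask.astype(float))
    I = np.array(indic)
    I_c = I - I.mean(axis=1, keepdims=True)
    I_norm = np.linalg.norm(I_c, axis=1)

    def coefs(t: np.ndarray) -> np.ndarray:
        t_c = t - t.mean()
        denom = I_norm * np.linalg.norm(t_c)
        return -(I_c @ t_c) / denom

    obs = coefs(t_obs)
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(kept))
    for _ in range(n_perm):
        rp = r[rng.permutation(len(r))]
        tp = pdist(rp[:, None], metric="cityblock")
        hits += np.abs(coefs(tp)) >= np.abs(obs)
    p = hits / n_perm
    if correction == "holm":
        p_corr = _progressive_holm(p)
    elif correction == "none":
        p_corr = p.copy()
    else:
        raise ValueError(f"unknown correction {correction!r}")
    table = pd.DataFrame(
        {
            "class_lo": [lo for lo, _, _ in kept],
            "class_hi": [hi for _, hi, _ in kept],
            "n_pairs": [np_c for _, _, np_c in kept],
            "coef": obs,
            "p": p,
            "p_corrected": p_corr,
            "significant": p_corr <= alpha,
        }
    )
    return CorrelogramResult(
        table=table,
        n_permutations=n_perm,
        seed=seed,
        correction=correction,
        distance_source=distance_source,
    )
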