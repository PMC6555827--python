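"""Taxonomic groups whose merged responses skew positive or negative.

At each rank (phylum → genus), every taxon with enough classified OTUs is
tested against an equal split of positive and negative responses with a
two-tailed exact binomial test at p = 0.5.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .response_quant import MergedResponse

__all__ = ["RANKS", "two_tailed_exact", "group_tests", "read_taxonomy"]

RANKS = ("phylum", "class", "order", "family", "genus")
UNASSIGNED = {"NA", "na", "unassigned", ""}


def read_taxonomy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("otu_id")
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ValueError(f"taxonomy table missing ranks: {missing}")
    return df


def two_tailed_exact(k: int, n: int, method: str = "double") -> float:
    """Exact binomial P of ``k`` positives out of ``n`` against p = 0.5.

    ``double``: twice the smaller tail, capped at 1 (default).
    ``minlike``: sum of all outcomes no more likely than the observed one.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    if method == "double":
        lo = stats.binom.cdf(k, n, 0.5)
        hi = stats.binom.sf(k - 1, n, 0.5)
        return float(min(1.0, 2.0 * min(lo, hi)))
    if method == "minlike":
        return float(stats.binomtest(k, n, 0.5, alternative="two-sided").pvalue)
    raise ValueError(f"unknown method {method!r}")


def group_tests(
    merged: MergedResponse | pd.Series,
    taxonomy: pd.DataFrame,
    min_group: int = 5,
    alpha: float = 0.05,
    method: str = "double",
    bh_correction: bool = False,
    ranks: Iterable[str] = RANKS,
) -> pd.DataFrame:
    """Per-taxon two-tailed exact tests of response-direction balance.

    OTUs with ratio exactly 0 carry no direction and are excluded; taxa
    unassigned at a rank are skipped at that rank only. Groups smaller
    than ``min_group`` are untestable (below n = 5 the two-tailed exact
    test cannot reach P <= 0.05) and omitted. Direction is called when
    P <= alpha. Raw P values by default; ``bh_correction`` applies
    Benjamini–Hochberg within each rank.
    """
    ratios = merged.ratios() if isinstance(merged, MergedResponse) else pd.Series(merged)
    shared = ratios.index.intersection(taxonomy.index)
    if len(shared) == 0:
        raise ValueError("no overlapping OTU ids between responses and taxonomy")
    ratios = ratios.loc[shared]
    ratios = ratios[ratios != 0]
    tax = taxonomy.loc[ratios.index]
    sign = ratios > 0

    rows = []
    for rank in ranks:
        labels = tax[rank].fillna("NA")
        for taxon, idx in labels.groupby(labels).groups.items():
            if str(taxon) in UNASSIGNED:
                continue
            s = sign.loc[idx]
            n = len(s)
            if n < min_group:
                continue
            k = int(s.sum())
            p = two_tailed_exact(k, n, method=method)
            rows.append(
                {"rank": rank, "taxon": taxon, "n_pos": k, "n_neg": n - k, "p": p}
            )
    out = pd.DataFrame(rows, columns=["rank", "taxon", "n_pos", "n_neg", "p"])
    if out.empty:
        out["p_adj"] = out.get("p", pd.Series(dtype=float))
        out["call"] = pd.Series(dtype=str)
        return out
    if bh_correction:
        out["p_adj"] = np.nan
        for rank in out["rank"].unique():
            mask = out["rank"] == rank
            p = out.loc[mask, "p"].to_numpy()
            order = np.argsort(p)
            m = len(p)
            adj = p[order] * m / (np.arange(m) + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            vals = np.empty(m)
            vals[order] = np.minimum(adj, 1.0)
            out.loc[mask, "p_adj"] = vals
    else:
        out["p_adj"] = out["p"]
    calls = np.where(
        out["p_adj"] <= alpha,
        np.where(out["n_pos"] > out["n_neg"], "positive", "negative"),
        "ns",
    )
    out["call"] = calls
    return out
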