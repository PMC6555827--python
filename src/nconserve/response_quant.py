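"""Per-location response ratios from OTU count tables, and cross-location merging.

The response of an OTU at a location is the log2 ratio of its mean
normalised abundance in treatment plots over control plots. Counts are
normalised with median-of-ratios size factors (the standard library-size
estimator for overdispersed count tables); a pseudocount added to the two
group means keeps ratios finite when one group is structurally zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "MergedResponse",
    "EmptyFilterResult",
    "filter_rare",
    "size_factors",
    "log2_response",
    "respond",
    "merge_responses",
    "read_counts",
    "read_design",
]

GROUPS = ("treatment", "control")


class EmptyFilterResult(ValueError):
    """The occupancy filter removed every OTU at a location."""


@dataclass
class CountTable:
    """OTU × plot integer counts plus the plot design.

    ``counts``: DataFrame indexed by OTU id, columns are plot ids.
    ``design``: DataFrame indexed by plot id with columns ``location``
    and ``group`` (``treatment`` or ``control``).
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"plots missing from design: {sorted(missing)[:5]}")
        bad = set(self.design["group"].unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"design groups must be in {GROUPS}, got {bad}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        for loc, sub in self.design.loc[list(self.counts.columns)].groupby("location"):
            for g in GROUPS:
                if not (sub["group"] == g).any():
                    raise ValueError(f"location {loc!r} has no {g} plots")

    @property
    def locations(self) -> list[str]:
        return sorted(self.design.loc[list(self.counts.columns), "location"].unique())

    def location_plots(self, location: str) -> pd.Index:
        sub = self.design.loc[list(self.counts.columns)]
        plots = sub.index[sub["location"] == location]
        if len(plots) == 0:
            raise KeyError(f"unknown location {location!r}")
        return plots

    def subset(self, location: str) -> "CountTable":
        plots = self.location_plots(location)
        return CountTable(self.counts[list(plots)], self.design.loc[list(plots)])


@dataclass
class MergedResponse:
    """Cross-location average response of widespread OTUs.

    ``table``: DataFrame indexed by OTU id with ``mean_log2fc`` and
    ``n_locations``; ``per_location``: wide DataFrame (OTU × location)
    of the individual ratios (NaN where the OTU was filtered out).
    """

    table: pd.DataFrame
    per_location: pd.DataFrame
    min_locations: int = 5

    def ratios(self) -> pd.Series:
        return self.table["mean_log2fc"]


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "otu_id"
    return df


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("plot_id")
    return df.rename(columns={"location_id": "location"})


def filter_rare(table: CountTable, location: str) -> CountTable:
    """Drop OTUs present in fewer than half of a location's plots.

    Retention threshold is ``ceil(n_plots / 2)`` nonzero plots: an OTU in
    exactly half of an even number of plots is kept, one in strictly less
    than half is removed.
    """
    sub = table.subset(location)
    n_plots = sub.counts.shape[1]
    if n_plots < 2:
        raise ValueError(f"location {location!r} has fewer than 2 plots")
    occupancy = (sub.counts > 0).sum(axis=1)
    keep = occupancy >= math.ceil(n_plots / 2)
    if not keep.any():
        raise EmptyFilterResult(f"no OTU passes the occupancy filter at {location!r}")
    return CountTable(sub.counts.loc[keep], sub.design)


def size_factors(table: CountTable, pseudocount: float = 0.0) -> pd.Series:
    """Median-of-ratios size factor per plot, normalised to geometric mean 1.

    The reference set is the OTUs with nonzero counts in every plot; each
    plot's factor is the median over that set of count / geometric-mean
    across plots. With no all-nonzero OTU an error points at the
    ``pseudocount`` escape hatch (which is added to every count before
    the computation).
    """
    counts = table.counts.to_numpy(dtype=float) + pseudocount
    all_nonzero = (counts > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no OTU has nonzero counts in every plot; pass pseudocount > 0 "
            "to size_factors to enable pseudocount mode"
        )
    ref = counts[all_nonzero]
    log_geomean = np.log(ref).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(ref) - log_geomean, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=table.counts.columns, name="size_factor")


def log2_response(
    table: CountTable, pseudocount: float = 0.5, location: str | None = None
) -> pd.DataFrame:
    """Per-OTU log2 treatment/control ratio for one location.

    ratio = log2((mean normalised treatment count + pc) /
                 (mean normalised control count + pc)).
    The pseudocount is applied to the group means, not the raw counts.
    Returns a DataFrame with columns ``otu_id``, ``location_id``, ``log2fc``.
    """
    if location is not None:
        table = table.subset(location)
    locs = table.locations
    if len(locs) != 1:
        raise ValueError("log2_response operates on a single location; pass `location`")
    loc = locs[0]
    if (table.counts.sum(axis=1) == 0).any():
        bad = table.counts.index[table.counts.sum(axis=1) == 0]
        raise ValueError(f"OTUs with all-zero counts (filter first): {list(bad[:5])}")
    sf = size_factors(table)
    norm = table.counts / sf
    groups = table.design.loc[list(table.counts.columns), "group"]
    mt = norm.loc[:, (groups == "treatment").to_numpy()].mean(axis=1)
    mc = norm.loc[:, (groups == "control").to_numpy()].mean(axis=1)
    lfc = np.log2((mt + pseudocount) / (mc + pseudocount))
    if not np.isfinite(lfc).all():
        raise ValueError("non-finite response ratio; use a positive pseudocount")
    return pd.DataFrame(
        {"otu_id": table.counts.index, "location_id": loc, "log2fc": lfc.to_numpy()}
    ).reset_index(drop=True)


def respond(table: CountTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Rare-filter then compute ratios for every location in the table."""
    out = []
    for loc in table.locations:
        filtered = filter_rare(table, loc)
        out.append(log2_response(filtered, pseudocount=pseudocount))
    return pd.concat(out, ignore_index=True)


def merge_responses(responses: pd.DataFrame, min_locations: int = 5) -> MergedResponse:
    """Average ratios of OTUs present in ``min_locations``+ locations.

    The mean is unweighted across locations (each location counts equally,
    regardless of its sequencing effort or replication).
    """
    n_locs = responses["location_id"].nunique()
    if n_locs < min_locations:
        raise ValueError(
            f"only {n_locs} locations supplied, need >= {min_locations} to merge"
        )
    wide = responses.pivot_table(
        index="otu_id", columns="location_id", values="log2fc", aggfunc="mean"
    )
    n_present = wide.notna().sum(axis=1)
    keep = n_present >= min_locations
    table = pd.DataFrame(
        {
            "mean_log2fc": wide.loc[keep].mean(axis=1, skipna=True),
            "n_locations": n_present[keep].astype(int),
        }
    )
    n_zero = int((table["mean_log2fc"] == 0).sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} OTU(s) with mean ratio exactly 0; they carry no response "
            "direction and are excluded from binary classifications downstream"
        )
    return MergedResponse(table=table, per_location=wide.loc[keep], min_locations=min_locations)
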