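"""One-command orchestration of the full conservation analysis.

The flow mirrors the study design it supports: per-location response
ratios → cross-location merge of widespread OTUs → consenTRAIT (both
response directions, per location and merged, one code path for both
levels) → D-test → Mantel correlogram → taxonomic-group exact tests.
Every parameter and derived seed lands in a run manifest so a run can be
reproduced bit-identically from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conservation import (
    ConsenTraitResult,
    CorrelogramResult,
    DTestResult,
    consentrait_test,
    d_test,
    mantel_correlogram,
)
from .phylo_core import (
    PhyloTree,
    patristic_distance_matrix,
    read_distance_matrix,
    read_newick,
    write_newick,
)
from .response_quant import (
    CountTable,
    MergedResponse,
    merge_responses,
    read_counts,
    read_design,
    respond,
)
from .synthetic_data import (
    SyntheticTruth,
    plant_clades,
    simulate_counts,
    simulate_taxonomy,
    simulate_tree,
)
from .taxonomy_enrichment import group_tests, read_taxonomy

log = logging.getLogger("nconserve")

DEFAULT_PARAMS = {
    "threshold": 0.9,
    "n_perm": 1000,
    "n_perm_correlogram": 999,
    "min_locations": 5,
    "min_group": 5,
    "pseudocount": 0.5,
    "alpha": 0.05,
    "seed": 0,
    "include_singletons": True,
    "distance_source": "patristic",
}


@dataclass
class AnalysisResult:
    responses: pd.DataFrame
    merged: MergedResponse
    consentrait_per_location: dict[tuple[str, str], ConsenTraitResult]
    consentrait_merged: dict[str, ConsenTraitResult]
    dtest: DTestResult
    correlogram: CorrelogramResult
    enrichment: pd.DataFrame
    manifest: dict

    def consentrait_summary(self) -> pd.DataFrame:
        rows = []
        for (loc, direction), res in self.consentrait_per_location.items():
            rows.append(_ct_row(loc, direction, res))
        for direction, res in self.consentrait_merged.items():
            rows.append(_ct_row("merged", direction, res))
        return pd.DataFrame(rows)


def _ct_row(scope, direction, res: ConsenTraitResult) -> dict:
    return {
        "scope": scope,
        "direction": direction,
        "tau_D": res.tau_d,
        "p": res.p_value,
        "n_clades": len(res.clades),
        "n_singletons": sum(c.is_singleton for c in res.clades),
        "n_perm": res.n_permutations,
        "seed": res.seed,
    }


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _stage_seeds(seed: int) -> dict[str, int]:
    names = [
        "simulate",
        "consentrait_merged_positive",
        "consentrait_merged_negative",
        "dtest",
        "correlogram",
        "consentrait_locations",
    ]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_full_analysis(config: dict, out_dir: str | Path | None = None) -> AnalysisResult:
    """Execute the whole pipeline from a config mapping.

    The config either names input files (``inputs:`` with tree, counts,
    design, taxonomy) or asks for a synthetic study (``synthetic:`` with
    generator parameters). ``params:`` overrides the analysis defaults.
    """
    params = dict(DEFAULT_PARAMS)
    params.update(config.get("params") or {})
    seeds = _stage_seeds(int(params["seed"]))
    manifest: dict = {
        "version": __version__,
        "params": params,
        "stage_seeds": seeds,
        "inputs": {},
        "stages": {},
    }

    truth: SyntheticTruth | None = None
    if "synthetic" in config:
        s = dict(config["synthetic"] or {})
        tree = simulate_tree(
            n_tips=int(s.get("n_tips", 300)),
            model=s.get("model", "yule"),
            total_depth=float(s.get("total_depth", 0.15)),
            seed=seeds["simulate"],
        )
        truth = plant_clades(
            tree,
            target_depth=float(s.get("target_depth", 0.05)),
            prevalence=float(s.get("prevalence", 0.5)),
            flip_noise=float(s.get("flip_noise", 0.0)),
            seed=seeds["simulate"],
        )
        taxonomy = simulate_taxonomy(tree, seed=seeds["simulate"])
        tables = simulate_counts(
            truth,
            n_treatment=int(s.get("n_treatment", 8)),
            n_control=int(s.get("n_control", 8)),
            depth=float(s.get("depth", 5e4)),
            dispersion=float(s.get("dispersion", 0.3)),
            n_locations=int(s.get("n_locations", 6)),
            seed=seeds["simulate"],
        )
        manifest["inputs"]["synthetic"] = {**truth.params, "seed": seeds["simulate"]}
    elif "inputs" in config:
        inputs = config["inputs"]
        for key in ("tree", "counts", "design"):
            if key not in inputs:
                raise KeyError(f"config inputs missing required key {key!r}")
        tree = read_newick(Path(inputs["tree"]).read_text())
        design = read_design(inputs["design"])
        count_paths = inputs["counts"]
        if isinstance(count_paths, (str, Path)):
            count_paths = [count_paths]
        tables = []
        for p in count_paths:
            counts = read_counts(p)
            plots = [c for c in counts.columns if c in design.index]
            tables.append(CountTable(counts[plots], design.loc[plots]))
        taxonomy = read_taxonomy(inputs["taxonomy"]) if "taxonomy" in inputs else None
        manifest["inputs"]["files"] = {
            "tree": _digest(inputs["tree"]),
            "design": _digest(inputs["design"]),
            "counts": [_digest(p) for p in count_paths],
        }
        if taxonomy is not None:
            manifest["inputs"]["files"]["taxonomy"] = _digest(inputs["taxonomy"])
    else:
        raise KeyError("config must contain either 'synthetic' or 'inputs'")

    # 1. responses per location
    log.info("computing per-location response ratios")
    responses = pd.concat(
        [respond(t, pseudocount=float(params["pseudocount"])) for t in tables],
        ignore_index=True,
    )
    manifest["stages"]["responses"] = {
        "n_rows": int(len(responses)),
        "n_locations": int(responses["location_id"].nunique()),
    }

    # 2. merge widespread OTUs
    merged = merge_responses(responses, min_locations=int(params["min_locations"]))
    manifest["stages"]["merged"] = {"n_otus": int(len(merged.table))}
    log.info("merged %d widespread OTUs", len(merged.table))

    # 3. consenTRAIT per location and merged (same implementation both levels)
    ct_loc: dict[tuple[str, str], ConsenTraitResult] = {}
    rng_loc = np.random.default_rng(seeds["consentrait_locations"])
    tree_tips = set(tree.tip_labels)
    for loc, sub in responses.groupby("location_id"):
        sub = sub[sub["otu_id"].isin(tree_tips) & (sub["log2fc"] != 0)]
        if sub["otu_id"].nunique() < 4:
            log.warning("location %s: too few OTUs on the tree; skipped", loc)
            continue
        sub_tree = tree.prune_to(sub["otu_id"])
        ratios = sub.set_index("otu_id")["log2fc"]
        for direction, mask in (("positive", ratios > 0), ("negative", ratios < 0)):
            ct_loc[(loc, direction)] = consentrait_test(
                sub_tree,
                mask.to_dict(),
                threshold=float(params["threshold"]),
                n_perm=int(params["n_perm"]),
                seed=int(rng_loc.integers(2**31)),
                direction=direction,
                include_singletons=bool(params["include_singletons"]),
            )

    merged_ratios = merged.ratios()
    merged_ratios = merged_ratios[merged_ratios.index.isin(tree_tips)]
    nz = merged_ratios[merged_ratios != 0]
    merged_tree = tree.prune_to(nz.index)
    ct_merged = {}
    for direction, mask in (("positive", nz > 0), ("negative", nz < 0)):
        ct_merged[direction] = consentrait_test(
            merged_tree,
            mask.to_dict(),
            threshold=float(params["threshold"]),
            n_perm=int(params["n_perm"]),
            seed=seeds[f"consentrait_merged_{direction}"],
            direction=direction,
            include_singletons=bool(params["include_singletons"]),
        )

    # 4. D-test on the merged binary response
    dres = d_test(
        merged_tree,
        (nz > 0).astype(int).to_dict(),
        n_sim=int(params["n_perm"]),
        seed=seeds["dtest"],
    )

    # 5. correlogram on the merged continuous response
    src = params["distance_source"]
    if src == "patristic":
        dm = patristic_distance_matrix(merged_tree)
    else:
        dm = read_distance_matrix(src)
        dm = dm.filter([i for i in dm.ids if i in set(nz.index)])
    correlogram = mantel_correlogram(
        dm,
        nz,
        n_perm=int(params["n_perm_correlogram"]),
        seed=seeds["correlogram"],
        alpha=float(params["alpha"]),
        distance_source=str(src),
    )

    # 6. taxonomic-group exact tests
    if taxonomy is not None:
        enrichment = group_tests(
            merged,
            taxonomy,
            min_group=int(params["min_group"]),
            alpha=float(params["alpha"]),
        )
    else:
        enrichment = pd.DataFrame(columns=["rank", "taxon", "n_pos", "n_neg", "p", "p_adj", "call"])
    manifest["stages"]["enrichment"] = {"n_taxa_tested": int(len(enrichment))}

    result = AnalysisResult(
        responses=responses,
        merged=merged,
        consentrait_per_location=ct_loc,
        consentrait_merged=ct_merged,
        dtest=dres,
        correlogram=correlogram,
        enrichment=enrichment,
        manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, out_dir, merged_tree=merged_tree, truth=truth)
    return result


def write_outputs(
    result: AnalysisResult,
    out_dir: str | Path,
    merged_tree: PhyloTree | None = None,
    truth: SyntheticTruth | None = None,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ff = dict(sep="\t", index=False, float_format="%.6g")
    result.responses.to_csv(out / "responses.tsv", **ff)
    merged_tbl = result.merged.table.reset_index().rename(columns={"index": "otu_id"})
    merged_tbl.to_csv(out / "merged_responses.tsv", **ff)
    result.consentrait_summary().to_csv(out / "consentrait_summary.tsv", **ff)
    clades = []
    for direction, res in result.consentrait_merged.items():
        df = res.clades_frame()
        df.insert(0, "scope", "merged")
        clades.append(df)
    if clades:
        pd.concat(clades, ignore_index=True).to_csv(out / "consensus_clades.tsv", **ff)
    pd.DataFrame([vars(result.dtest)]).to_csv(out / "dtest.tsv", **ff)
    result.correlogram.table.to_csv(out / "correlogram.tsv", **ff)
    result.enrichment.to_csv(out / "enrichment.tsv", **ff)
    if merged_tree is not None:
        (out / "merged_tree.nwk").write_text(write_newick(merged_tree) + "\n")
    if truth is not None:
        (out / "truth.json").write_text(truth.to_json())
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))


def plot_correlogram(result: CorrelogramResult, path: str | Path) -> None:
    """Minimal correlogram plot: coefficient vs class midpoint, filled
    markers where the corrected P is significant."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = result.table
    mid = (t["class_lo"] + t["class_hi"]) / 2
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.axhline(0, color="0.7", lw=0.8)
    ax.plot(mid, t["coef"], "-", color="0.4", lw=1)
    sig = t["significant"].to_numpy(dtype=bool)
    ax.plot(mid[sig], t["coef"][sig], "o", color="k", label="significant")
    ax.plot(mid[~sig], t["coef"][~sig], "o", mfc="w", mec="k", label="ns")
    ax.set_xlabel("phylogenetic distance (class midpoint)")
    ax.set_ylabel("autocorrelation")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
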