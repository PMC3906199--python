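"""End-to-end orchestration of the stress-transcriptome analysis stages.

Stages run in order: differential expression -> co-expression network ->
plasticity -> promoter elements -> set/term enrichment.  Inputs come
either from files or from the synthetic generator; identical config and
seed give identical outputs.
"""

from __future__ import annotations

import json
import logging
from itertools import combinations
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as snio
from . import motifs as snmotifs
from . import network as snnetwork
from . import plasticity as snplast
from . import sam as snsam
from . import setenrich as snenrich
from . import simulate as snsim

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "outdir": "stressnet_out",
    "input": {},
    "simulate": {},
    "stages": {
        "diffexpr": True,
        "network": True,
        "plasticity": True,
        "elements": True,
        "enrich": True,
    },
    "params": {
        "sam": {},
        "network": {},
        "plasticity": {},
        "elements": {},
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(config: str | Path | dict[str, Any]) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULT_CONFIG, config)
    for key in ("expression", "design", "promoters_fasta", "tf_genes", "term_map"):
        path = cfg["input"].get(key)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"configured input {key} not found: {path}")
    return cfg


def run_pipeline(config: str | Path | dict[str, Any]) -> dict[str, Any]:
    """Execute the configured stages and write report tables to ``outdir``.

    Returns a dict of in-memory results keyed by stage.
    """
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    results: dict[str, Any] = {"config": cfg}

    # ------------------------------------------------------------------ input
    inp = cfg["input"]
    truth = None
    annotations: dict[str, Any] = {}
    if inp.get("expression"):
        matrix, design = snio.read_expression(inp["expression"], inp["design"])
        promoters = (
            snio.read_fasta(inp["promoters_fasta"]) if inp.get("promoters_fasta") else None
        )
        tf_genes = snio.read_gene_list(inp["tf_genes"]) if inp.get("tf_genes") else []
        term_map = {}
        if inp.get("term_map"):
            with open(inp["term_map"]) as fh:
                term_map = json.load(fh)
        annotations = {"tf_genes": tf_genes, "term_map": term_map, "nonmodular_class": []}
    else:
        sim_cfg = snsim.SyntheticConfig(rng_seed=seed, **cfg["simulate"])
        matrix, design, truth = snsim.generate_dataset(sim_cfg)
        promoters = snsim.generate_promoters(sim_cfg, truth)
        annotations = snsim.generate_annotations(sim_cfg, truth)
        snsim.write_bundle(outdir / "fixture", matrix, design, truth, promoters, annotations)
    results["matrix"], results["design"], results["truth"] = matrix, design, truth

    stages = cfg["stages"]

    # --------------------------------------------------------------- diffexpr
    de = None
    if stages.get("diffexpr"):
        logger.info("stage diffexpr: %d genes, %d arrays", *matrix.shape)
        sam_params = snsam.SAMParams(rng_seed=seed, **cfg["params"]["sam"])
        de = snsam.call_all(matrix, design, sam_params)
        for stress in de.up:
            snio.write_gene_list(de.up[stress], outdir / f"{stress}.up.txt")
            snio.write_gene_list(de.down[stress], outdir / f"{stress}.down.txt")
        de.diagnostics.to_csv(outdir / "sam_diagnostics.tsv", sep="\t", index=False)
        if len(de.up) == 4:
            for direction, sets in (("up", de.up), ("down", de.down)):
                regions = snsam.venn_partition(sets)
                pd.DataFrame(
                    [(",".join(sorted(k)), v) for k, v in sorted(regions.items(), key=lambda kv: sorted(kv[0]))],
                    columns=["region", "count"],
                ).to_csv(outdir / f"venn_{direction}.tsv", sep="\t", index=False)
        results["de"] = de

    # ---------------------------------------------------------------- network
    assignment = None
    if stages.get("network"):
        if de is None:
            raise RuntimeError("network stage requires diffexpr")
        de_genes = sorted(de.all_de_genes())
        sub = matrix.loc[de_genes]
        sub = sub[sub.std(axis=1) > 0]
        logger.info("stage network: %d DE genes", len(sub))
        net_params = snnetwork.NetworkParams(**cfg["params"]["network"])
        results["network"] = None
        if len(sub) >= 3:
            adj = snnetwork.adjacency(sub, net_params)
            dissim = snnetwork.tom_dissimilarity(adj)
            assignment = snnetwork.detect_modules(dissim, net_params)
            assignment = snnetwork.merge_modules(assignment, sub, net_params)
            profiles = snnetwork.module_profiles(assignment, sub, design)
            edges = snnetwork.export_edge_list(adj, assignment, net_params)
            assignment.labels.rename("module").to_csv(
                outdir / "module_membership.tsv", sep="\t", index_label="gene"
            )
            profiles.to_csv(outdir / "module_profiles.tsv", sep="\t", index=False)
            edges.to_csv(outdir / "edge_list.tsv", sep="\t", index=False)
            results["network"] = {
                "assignment": assignment,
                "profiles": profiles,
                "edges": edges,
            }

    # ------------------------------------------------------------- plasticity
    if stages.get("plasticity"):
        if de is None:
            raise RuntimeError("plasticity stage requires diffexpr")
        plast_params = snplast.PlasticityParams(
            rng_seed=seed, **cfg["params"]["plasticity"]
        )
        stresses = sorted(design.loc[~design["is_control"], "condition"].unique())
        comparisons = []
        for pair in combinations(stresses, 2):
            comparisons.append(
                snplast.compare_conditions(
                    matrix, design, de, annotations.get("tf_genes", []), pair, plast_params
                )
            )
        table = snplast.summary_table(comparisons)
        table.to_csv(outdir / "plasticity_summary.tsv", sep="\t", index=False)
        snio.write_gene_list(
            snplast.nonplastic_genes(comparisons), outdir / "nonplastic_genes.txt"
        )
        results["plasticity"] = {"comparisons": comparisons, "summary": table}

    # --------------------------------------------------------------- elements
    if stages.get("elements") and promoters is not None:
        if assignment is None:
            raise RuntimeError("elements stage requires network modules")
        el_params = snmotifs.ElementParams(**cfg["params"]["elements"])
        module_proms = {
            m: {g: promoters[g] for g in assignment.members(m) if g in promoters}
            for m in sorted(assignment.labels.unique())
            if m != 0
        }
        tables = snmotifs.enrich_module_promoters(module_proms, promoters, el_params)
        for m, t in tables.items():
            t[t["significant"]].to_csv(
                outdir / f"elements_module{m:02d}.tsv", sep="\t", index=False
            )
        summary = snmotifs.unique_total_summary(tables)
        summary.to_csv(outdir / "elements_summary.tsv", sep="\t", index=False)
        results["elements"] = {"tables": tables, "summary": summary}

    # ----------------------------------------------------------------- enrich
    if stages.get("enrich") and assignment is not None:
        term_map = annotations.get("term_map", {})
        universe = set(matrix.index)
        members = set(assignment.labels.index[assignment.labels > 0])
        enrich_out: dict[str, Any] = {"terms": {}}
        for m in sorted(assignment.labels.unique()):
            if m == 0 or not term_map:
                continue
            table = snenrich.term_enrichment(
                set(assignment.members(m)), universe, term_map
            )
            enrich_out["terms"][m] = table
        if enrich_out["terms"]:
            pd.concat(
                [t.assign(module=m) for m, t in enrich_out["terms"].items()],
                ignore_index=True,
            ).to_csv(outdir / "term_enrichment.tsv", sep="\t", index=False)
        cls = set(annotations.get("nonmodular_class", [])) & universe
        if cls:
            ov = snenrich.overlap_test(
                universe, members, cls, method="permutation", seed=seed
            )
            pd.DataFrame([ov.__dict__]).to_csv(
                outdir / "class_overlap.tsv", sep="\t", index=False
            )
            enrich_out["class_overlap"] = ov
        results["enrich"] = enrich_out

    logger.info("pipeline complete; outputs in %s", outdir)
    return results
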