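"""Pipeline orchestration: run stages from a config, write a manifest.

The config is a flat YAML document with one section per stage; every
stage's outputs are files under the run directory, and the manifest
records the config snapshot, input digests, seeds, parameters and the
path of every file produced, so each number in the report is traceable
to a stage output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anchors import assign_gene_models, classify_peaks
from .coexpression import coexpression_enrichment, sample_distance_matched_null
from .domains import DomainSet, call_cids, partition_modules
from .eqtl import (classify_cis_trans, contact_frequency_test,
                   find_loop_supported_pairs, simulate_matched_pairs)
from .network import build_gene_network
from .simulate import SimulationConfig, simulate_dataset
from . import io as cio

log = logging.getLogger("chialoop")

DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": {"enabled": True},
    "anchors": {"promoter_window": 2000},
    "domains": {
        "coverage_threshold": 2,
        "min_span": 10_000,
        "max_span": {"H3K4me3": 200_000, "H3K9me2": 1_000_000,
                     "RNAPII": 1_000_000},
    },
    "network": {"promoter_window": 2000, "min_intra_pets": 4,
                "min_inter_pets": 6, "top_k": 100},
    "coexpr": {"enabled": True, "n_permutations": 200, "tolerance": 0.1,
               "null_type": "A"},
    "eqtl": {"enabled": True, "n_sims": 5, "tolerance": 0.1,
             "cis_max_distance": 1_000_000, "promoter_window": 2000,
             "slop": 0},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_simulated_dataset(outdir: Path, cfg: SimulationConfig) -> dict:
    """Run the generator and write the full fixture plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    layout, peaks, loops, genes, expr, eqtl_pairs, truth = simulate_dataset(cfg)
    paths: dict = {}
    cio.write_chrom_sizes(layout, outdir / "genome.chrom.sizes")
    paths["genome"] = "genome.chrom.sizes"
    for mark, ps in peaks.items():
        cio.write_peaks(ps, outdir / f"peaks.{mark}.bed")
        paths[f"peaks.{mark}"] = f"peaks.{mark}.bed"
    for mark, ls in loops.items():
        cio.write_loops(ls, outdir / f"loops.{mark}.bedpe")
        paths[f"loops.{mark}"] = f"loops.{mark}.bedpe"
    cio.write_genes(genes, outdir / "genes.gff3")
    paths["genes"] = "genes.gff3"
    cio.write_expression(expr, outdir / "expression.tsv")
    paths["expression"] = "expression.tsv"
    cio.write_table(eqtl_pairs, outdir / "eqtl_pairs.tsv")
    paths["eqtl_pairs"] = "eqtl_pairs.tsv"
    for mark, doms in truth.planted_domains.items():
        cio.write_bed(doms, outdir / "truth" / f"domains.{mark}.bed")
    cio.write_table(pd.DataFrame(truth.looped_pair_ids,
                                 columns=["gene_i", "gene_j"]),
                    outdir / "truth" / "looped_pairs.tsv")
    cio.write_table(pd.DataFrame({"pair_id": truth.supported_eqtl_ids}),
                    outdir / "truth" / "supported_eqtl.tsv")
    return paths


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Execute the stages in dependency order; return the manifest."""
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = _merge(DEFAULT_CONFIG, config)
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    manifest: dict = {"version": __version__, "seed": seed, "config": cfg,
                      "stages": {}, "outputs": {}, "inputs": {}}
    report: dict = {}
    t0 = time.time()

    # ---- inputs -----------------------------------------------------------
    if cfg["simulate"].get("enabled", False):
        sim_kwargs = {k: v for k, v in cfg["simulate"].items()
                      if k not in ("enabled",)}
        sim_cfg = SimulationConfig(seed=seed, **sim_kwargs)
        data_dir = outdir / "data"
        write_simulated_dataset(data_dir, sim_cfg)
        inputs = {k: data_dir / v for k, v in {
            "genome": "genome.chrom.sizes", "genes": "genes.gff3",
            "expression": "expression.tsv", "eqtl_pairs": "eqtl_pairs.tsv",
            **{f"peaks.{m}": f"peaks.{m}.bed" for m in sim_cfg.domains_per_mark},
            **{f"loops.{m}": f"loops.{m}.bedpe" for m in sim_cfg.domains_per_mark},
        }.items()}
    else:
        inputs = {k: Path(v) for k, v in cfg.get("inputs", {}).items()}
    for key, path in inputs.items():
        if not path.exists():
            raise FileNotFoundError(f"stage inputs: missing {key} ({path})")
        manifest["inputs"][key] = {"path": str(path), "sha256": _digest(path)}

    layout = cio.read_chrom_sizes(inputs["genome"])
    genes = cio.read_genes(inputs["genes"], layout)
    marks = sorted({k.split(".", 1)[1] for k in inputs if k.startswith("loops.")})
    peaks = {m: cio.read_peaks(inputs[f"peaks.{m}"], m, layout) for m in marks
             if f"peaks.{m}" in inputs}
    loops = {m: cio.read_loops(inputs[f"loops.{m}"], m, layout) for m in marks}

    # ---- anchors ----------------------------------------------------------
    t = time.time()
    window = cfg["anchors"]["promoter_window"]
    anchor_fractions = {}
    for m in marks:
        if m not in peaks:
            continue
        assignment = classify_peaks(peaks[m], loops[m])
        anchor_fractions[m] = assignment.anchor_fraction
        out = outdir / f"peaks.{m}.labelled.bed"
        labelled = assignment.df.copy()
        labelled["name"] = labelled["name"] + ":" + labelled["label"]
        cio.write_bed(labelled, out, name_col="name")
        manifest["outputs"][f"peaks_labelled.{m}"] = str(out)
        models = assign_gene_models(genes, peaks[m], assignment, window)
        mpath = outdir / f"genes.models.{m}.tsv"
        cio.write_table(models, mpath)
        manifest["outputs"][f"gene_models.{m}"] = str(mpath)
    report["anchor_fraction"] = anchor_fractions
    manifest["stages"]["anchors"] = {"seconds": round(time.time() - t, 2),
                                     "promoter_window": window}

    # ---- domains + partition ---------------------------------------------
    t = time.time()
    dcfg = cfg["domains"]
    domain_sets = {}
    for m in marks:
        max_span = dcfg["max_span"].get(m, 1_000_000) \
            if isinstance(dcfg["max_span"], dict) else dcfg["max_span"]
        ds = call_cids(loops[m], layout, dcfg["coverage_threshold"],
                       dcfg["min_span"], max_span)
        domain_sets[m] = ds
        path = outdir / f"domains.{m}.bed"
        cio.write_bed(ds.df, path)
        manifest["outputs"][f"domains.{m}"] = str(path)
    k9 = domain_sets.get("H3K9me2", DomainSet("H3K9me2", pd.DataFrame(
        columns=["chrom", "start", "end"])))
    k4 = domain_sets.get("H3K4me3", DomainSet("H3K4me3", pd.DataFrame(
        columns=["chrom", "start", "end"])))
    pii = domain_sets.get("RNAPII", DomainSet("RNAPII", pd.DataFrame(
        columns=["chrom", "start", "end"])))
    partition = partition_modules(k9, k4, pii, layout)
    ppath = outdir / "modules.bed"
    cio.write_bed(partition.df, ppath, name_col="label")
    cio.write_table(partition.summary, outdir / "modules.summary.tsv")
    manifest["outputs"]["modules"] = str(ppath)
    manifest["outputs"]["modules_summary"] = str(outdir / "modules.summary.tsv")
    report["module_fractions"] = dict(
        zip(partition.summary["label"], partition.summary["fraction"].round(4)))
    manifest["stages"]["domains"] = {"seconds": round(time.time() - t, 2),
                                     **{k: v for k, v in dcfg.items()}}

    # ---- network ----------------------------------------------------------
    t = time.time()
    ncfg = cfg["network"]
    net_mark = "H3K4me3" if "H3K4me3" in marks else marks[0]
    net = build_gene_network(loops[net_mark], genes, ncfg["promoter_window"])
    epath = outdir / "network.edges.tsv"
    cio.write_table(net.edge_table(), epath)
    manifest["outputs"]["network_edges"] = str(epath)
    deg = net.degrees
    report["network"] = {
        "n_nodes": int(net.report["n_nodes"]),
        "n_edges": int(net.report["n_edges"]),
        "degree_ge3_fraction": float((deg >= 3).mean()) if len(deg) else 0.0,
    }
    manifest["stages"]["network"] = {"seconds": round(time.time() - t, 2),
                                     **ncfg}

    # ---- co-expression ----------------------------------------------------
    ccfg = cfg["coexpr"]
    if ccfg.get("enabled", True) and "expression" in inputs:
        t = time.time()
        expr = cio.read_expression(inputs["expression"])
        pairs = [(u, v) for u, v in net.graph.edges]
        intra_pairs = []
        chrom_of = genes.df.set_index("gene_id")["chrom"]
        for u, v in pairs:
            if chrom_of.get(u) == chrom_of.get(v):
                intra_pairs.append((u, v))
        if intra_pairs:
            nulls = sample_distance_matched_null(
                intra_pairs, genes, ccfg["n_permutations"], ccfg["tolerance"],
                ccfg["null_type"], seed=seed)
            res = coexpression_enrichment(expr, intra_pairs, nulls,
                                          ccfg["null_type"], seed)
            cpath = outdir / "coexpression.tsv"
            cio.write_table(pd.DataFrame([{
                "observed_mean_pcc": res.observed_mean_pcc,
                "null_mean_pcc": float(pd.Series(res.null_means).mean()),
                "empirical_p": res.empirical_p,
                "n_pairs": res.n_pairs,
                "n_permutations": res.n_permutations,
            }]), cpath)
            manifest["outputs"]["coexpression"] = str(cpath)
            report["coexpression"] = {
                "observed_mean_pcc": round(res.observed_mean_pcc, 4),
                "empirical_p": res.empirical_p,
            }
        manifest["stages"]["coexpr"] = {"seconds": round(time.time() - t, 2),
                                        **ccfg}
    else:
        manifest["stages"]["coexpr"] = {"skipped":
                                        "disabled or no expression input"}
        log.info("coexpr stage skipped (disabled or no expression table)")

    # ---- eQTL support -----------------------------------------------------
    ecfg = cfg["eqtl"]
    if ecfg.get("enabled", True) and "eqtl_pairs" in inputs:
        t = time.time()
        pairs = cio.read_eqtl_pairs(inputs["eqtl_pairs"])
        pairs = classify_cis_trans(pairs, genes, ecfg["cis_max_distance"])
        loop_list = list(loops.values())
        pairs = find_loop_supported_pairs(pairs, loop_list, genes,
                                          ecfg["promoter_window"],
                                          ecfg["slop"])
        sims = simulate_matched_pairs(pairs, genes, layout, ecfg["n_sims"],
                                      ecfg["tolerance"], seed)
        real_supported = pairs[pairs["supported"]]
        test = (contact_frequency_test(real_supported, sims, loop_list, genes,
                                       ecfg["promoter_window"], ecfg["slop"])
                if len(real_supported) >= 10 else {"p_value": None})
        epath = outdir / "eqtl_support.tsv"
        cio.write_table(pairs, epath)
        manifest["outputs"]["eqtl_support"] = str(epath)
        labelled = pairs[pairs["cis_trans"] != "unclassified"]
        report["eqtl"] = {
            "support_rate": round(float(pairs["supported"].mean()), 4),
            "cis_fraction": round(float((labelled["cis_trans"] == "cis").mean()), 4)
            if len(labelled) else None,
            "contact_frequency_p": test.get("p_value"),
        }
        manifest["stages"]["eqtl"] = {"seconds": round(time.time() - t, 2),
                                      **ecfg}
    else:
        manifest["stages"]["eqtl"] = {"skipped": "disabled or no eqtl input"}
        log.info("eqtl stage skipped (disabled or no pair table)")

    manifest["elapsed_seconds"] = round(time.time() - t0, 2)
    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest["outputs"]["report"] = str(report_path)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return manifest
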