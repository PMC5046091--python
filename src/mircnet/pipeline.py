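"""Staged orchestration of the full analysis from a single YAML config.

Stages run in order: preprocess → per-dataset DE → consensus → permutation
tests → interaction integration → motif scan → network assembly → loop
analysis → enrichment → subnetworks.  All randomness derives from one
global seed fanned out per stage by fixed offsets, so stages can be rerun
in isolation; every output file is recorded in ``manifest.json`` with its
SHA-256 hash, and identical (config, seed, inputs) produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from mircnet import enrichment as enr
from mircnet import io_formats as iof
from mircnet import motif_scan as ms
from mircnet import network_loops as nl
from mircnet import target_integration as ti
from mircnet.consensus_de import (
    ConsensusConfig,
    calls_to_frame,
    consensus_features,
    consensus_select,
    de_sets_from_tables,
    differential_expression,
    mean_fold_change,
    permutation_consensus_test,
)

logger = logging.getLogger(__name__)

# deterministic per-stage seed offsets (fanned out from the global seed)
_STAGE_SEED_OFFSET = {"permutation_overlap": 101, "permutation_direction": 102}

_DEFAULTS: dict[str, dict[str, Any]] = {
    "consensus": {
        "alpha": 0.05,
        "k_min": 3,
        "require_direction": True,
        "permutations": 5000,
        "test": "welch",
    },
    "motif_scan": {
        "upstream": 1500,
        "downstream": 500,
        "p_threshold": 0.05,
        "top_fraction": 0.01,
        "both_strands": True,
    },
    "enrichment": {"fdr": 0.05},
}


class ConfigError(ValueError):
    """The pipeline configuration is incomplete or contradictory."""


@dataclass
class PipelineConfig:
    datasets: list[dict]
    output_dir: Path
    seed: int = 0
    consensus: dict = field(default_factory=dict)
    databases: dict = field(default_factory=dict)
    motif_scan: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)
    base_dir: Path = Path(".")

    def resolve(self, path: str | Path) -> Path:
        p = Path(path)
        return p if p.is_absolute() else self.base_dir / p

    def arm(self, molecule_type: str) -> list[dict]:
        return [d for d in self.datasets if d.get("type", "mirna") == molecule_type]


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.setdefault("base_dir", path.parent)
    return validate_config(raw)


def validate_config(raw: Mapping[str, Any]) -> PipelineConfig:
    """Fill defaults and reject incomplete or contradictory configs."""
    missing = [k for k in ("datasets", "output_dir") if k not in raw]
    if missing:
        raise ConfigError(f"config missing required fields: {missing}")
    if not raw["datasets"]:
        raise ConfigError("config lists no datasets")
    cfg = PipelineConfig(
        datasets=list(raw["datasets"]),
        output_dir=Path(raw["output_dir"]),
        seed=int(raw.get("seed", 0)),
        consensus={**_DEFAULTS["consensus"], **(raw.get("consensus") or {})},
        databases=dict(raw.get("databases") or {}),
        motif_scan={**_DEFAULTS["motif_scan"], **(raw.get("motif_scan") or {})},
        enrichment={**_DEFAULTS["enrichment"], **(raw.get("enrichment") or {})},
        base_dir=Path(raw.get("base_dir", ".")),
    )
    for i, d in enumerate(cfg.datasets):
        for key in ("id", "matrix", "groups"):
            if key not in d:
                raise ConfigError(f"dataset #{i}: missing field {key!r}")
        for key in ("matrix", "groups"):
            p = cfg.resolve(d[key])
            if not p.exists():
                raise ConfigError(f"dataset {d['id']}: path does not exist: {p}")
        d.setdefault("type", "mirna")
        if d["type"] not in ("mirna", "gene"):
            raise ConfigError(f"dataset {d['id']}: type must be mirna|gene")
    for arm in ("mirna", "gene"):
        n = len(cfg.arm(arm))
        if n and cfg.consensus["k_min"] > n:
            raise ConfigError(
                f"k_min={cfg.consensus['k_min']} exceeds the {n} {arm} datasets"
            )
    if not 0 < cfg.consensus["alpha"] < 1:
        raise ConfigError(f"alpha out of range: {cfg.consensus['alpha']}")
    if cfg.consensus["permutations"] <= 0:
        raise ConfigError("permutations must be positive")
    for key, p in cfg.databases.items():
        if not cfg.resolve(p).exists():
            raise ConfigError(f"databases.{key}: path does not exist: {p}")
    for key in ("motifs", "promoters", "tss"):
        p = cfg.motif_scan.get(key)
        if p and not cfg.resolve(p).exists():
            raise ConfigError(f"motif_scan.{key}: path does not exist: {p}")
    gmt = cfg.enrichment.get("gene_sets")
    if gmt and not cfg.resolve(gmt).exists():
        raise ConfigError(f"enrichment.gene_sets: path does not exist: {gmt}")
    return cfg


# ---------------------------------------------------------------------------
# stages


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_consensus_stage(cfg: PipelineConfig, arm: str, outdir: Path) -> dict:
    """Per-dataset DE, consensus calls and both permutation tests for one arm."""
    datasets = []
    for d in cfg.arm(arm):
        ds = iof.read_expression_matrix(
            cfg.resolve(d["matrix"]),
            cfg.resolve(d["groups"]),
            dataset_id=d["id"],
            log2_input=bool(d.get("log2_input", False)),
            include_samples=d.get("include_samples"),
        )
        if d.get("replicate_groups"):
            ds = iof.collapse_replicates(ds, d["replicate_groups"])
        datasets.append(ds)

    ccfg = ConsensusConfig(
        alpha=cfg.consensus["alpha"],
        k_min=cfg.consensus["k_min"],
        require_direction=cfg.consensus["require_direction"],
    )
    de_tables = {}
    for ds in datasets:
        tbl = differential_expression(ds, test=cfg.consensus["test"])
        tbl.to_csv(outdir / f"de_{ds.dataset_id}.tsv", sep="\t")
        de_tables[ds.dataset_id] = tbl
        logger.info(
            "%s/%s: %d/%d features DE at alpha=%g", arm, ds.dataset_id,
            int((tbl["p_value"] <= ccfg.alpha).sum()), len(tbl), ccfg.alpha,
        )

    calls = consensus_select(de_tables, ccfg)
    frame = calls_to_frame(calls)
    frame.to_csv(outdir / "consensus.tsv", sep="\t")
    overlap_feats = consensus_features(calls, require_direction=False)
    directional_feats = consensus_features(calls, require_direction=True)
    logger.info(
        "%s arm: %d features pass overlap, %d also pass direction",
        arm, len(overlap_feats), len(directional_feats),
    )

    universes = {ds.dataset_id: list(de_tables[ds.dataset_id].index)
                 for ds in datasets}
    de_sets, directions = de_sets_from_tables(de_tables, ccfg.alpha)
    B = int(cfg.consensus["permutations"])
    perm = {}
    for name, require in (("overlap", False), ("direction", True)):
        res = permutation_consensus_test(
            universes,
            de_sets,
            ConsensusConfig(ccfg.alpha, ccfg.k_min, require),
            B=B,
            seed=cfg.seed + _STAGE_SEED_OFFSET[f"permutation_{name}"],
            directions=directions,
        )
        perm[name] = {
            "observed": res.observed,
            "exceedances": res.exceedances,
            "B": res.B,
            "p_report": res.p_report,
            "is_bound": res.is_bound,
        }
        logger.info(
            "%s arm, %s permutation test: T_obs=%d, p %s %g", arm, name,
            res.observed, "<" if res.is_bound else "=", res.p_report,
        )
    with open(outdir / "permutation.json", "w") as fh:
        json.dump(perm, fh, indent=1)
    fcs = {f: mean_fold_change(de_tables, f) for f in directional_feats}
    return {
        "datasets": datasets,
        "de_tables": de_tables,
        "calls": calls,
        "consensus_features": directional_feats
        if ccfg.require_direction
        else overlap_feats,
        "mean_fold_changes": fcs,
        "permutation": perm,
    }


def run_integration_stage(cfg: PipelineConfig, consensus_mirnas: list[str],
                          outdir: Path) -> dict:
    """Filter the interaction tables and materialize miRNA-target edges."""
    vrecs = ti.validated_records_from_table(
        iof.read_edge_table(cfg.resolve(cfg.databases["validated_targets"]))
    )
    precs = ti.predicted_records_from_table(
        iof.read_edge_table(cfg.resolve(cfg.databases["predicted_targets"]))
    )
    tfregs = ti.tf_records_from_table(
        iof.read_edge_table(cfg.resolve(cfg.databases["tf_mirna"]))
    )
    keep = set(consensus_mirnas)
    validated = {p for p in ti.filter_validated(vrecs) if p[0] in keep}
    predicted = {p for p in ti.filter_predicted(precs) if p[0] in keep}
    target_edges = ti.merge_target_edges(validated, predicted)
    logger.info(
        "integration: %d validated + %d predicted pairs -> %d unique edges",
        len(validated), len(predicted), len(target_edges),
    )
    tfregs = [r for r in tfregs if r.mirna in keep]
    augmented = ti.feedback_partner_edges(tfregs, target_edges)
    logger.info(
        "integration: feedback partners raise miRNA-target edges %d -> %d",
        len(target_edges), len(augmented),
    )
    with open(outdir / "target_edges.tsv", "w") as fh:
        fh.write("src\tdst\tsign\tcategory\tevidence\n")
        for e in augmented:
            fh.write(f"{e.src}\t{e.dst}\t{e.sign:+d}\t{e.category}\t{e.evidence}\n")
    return {"target_edges": augmented, "tfregs": tfregs}


def run_scan_stage(cfg: PipelineConfig, mirna_names: set[str],
                   outdir: Path) -> dict:
    """Scan promoters for TF motifs; split predictions by target type."""
    mcfg = cfg.motif_scan
    motifs = iof.read_motifs_meme(cfg.resolve(mcfg["motifs"]))
    seqs = iof.read_fasta(cfg.resolve(mcfg["promoters"]))
    windows = []
    if mcfg.get("tss"):
        tss = pd.read_csv(cfg.resolve(mcfg["tss"]), sep="\t")
        for row in tss.itertuples(index=False):
            windows.append(
                ms.extract_promoter(
                    seqs[row.seq_name], int(row.tss), row.strand,
                    upstream=mcfg["upstream"], downstream=mcfg["downstream"],
                    target=row.target,
                )
            )
    else:  # FASTA records are already promoter windows
        windows = [
            ms.PromoterWindow(target=name, sequence=s, tss=mcfg["upstream"],
                              strand="+")
            for name, s in seqs.items()
        ]
    hits = ms.scan_promoters(
        windows, motifs, p_threshold=mcfg["p_threshold"],
        both_strands=mcfg["both_strands"],
    )
    pd.DataFrame(ms.hits_to_rows(hits, upstream=mcfg["upstream"])).to_csv(
        outdir / "tf_hits.tsv", sep="\t", index=False
    )
    # top 1% separately for TF->miRNA and TF->gene predictions
    mirna_hits = [h for h in hits if h.target in mirna_names]
    gene_hits = [h for h in hits if h.target not in mirna_names]
    kept = {
        "tf_mirna": ms.rank_and_truncate(mirna_hits, mcfg["top_fraction"]),
        "tf_gene": ms.rank_and_truncate(gene_hits, mcfg["top_fraction"]),
    }
    logger.info(
        "motif scan: %d hits -> %d TF-miRNA and %d TF-gene predictions",
        len(hits), len(kept["tf_mirna"]), len(kept["tf_gene"]),
    )
    rows = []
    edges = []
    for category, klist in kept.items():
        for h in klist:
            rows.append({"tf": h.tf, "target": h.target, "category": category,
                         "p_value": h.p_value})
            edges.append(
                nl.SignedEdge(src=h.tf.upper(), dst=h.target, sign=nl.ACTIVATION,
                              category=category, evidence="predicted")
            )
    pd.DataFrame(rows, columns=["tf", "target", "category", "p_value"]).to_csv(
        outdir / "tf_predicted.tsv", sep="\t", index=False
    )
    return {"tf_edges": edges, "hits": hits}


def run_network_stage(cfg: PipelineConfig, target_edges, tfregs, tf_edges,
                      outdir: Path) -> dict:
    """Assemble the signed network and enumerate FBL/FFL motifs."""
    curated = ti.tf_edges_from_records(tfregs)
    net = nl.assemble_network([target_edges, curated, tf_edges], overrides=tfregs)
    netdir = outdir / "network"
    iof.write_network(net, netdir)
    summary = nl.network_summary(net)
    fbls = nl.find_feedback_loops(net)
    ffls = nl.find_feedforward_loops(net)
    summary["n_fbl"] = len(fbls)
    summary["fbl_signs"] = {
        "positive": sum(l.sign == "positive" for l in fbls),
        "negative": sum(l.sign == "negative" for l in fbls),
    }
    summary["n_ffl"] = len(ffls)
    summary["ffl_coherence"] = {
        "coherent": sum(f.coherent for f in ffls),
        "incoherent": sum(not f.coherent for f in ffls),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    with open(netdir / "loops_fbl.tsv", "w") as fh:
        fh.write("cycle\tsign\n")
        for l in fbls:
            fh.write("->".join(l.cycle) + f"\t{l.sign}\n")
    with open(netdir / "loops_ffl.tsv", "w") as fh:
        fh.write("X\tY\tZ\tcoherence\tcontains_mirna\n")
        for f in ffls:
            fh.write(
                f"{f.regulator}\t{f.intermediate}\t{f.target}\t"
                f"{'coherent' if f.coherent else 'incoherent'}\t"
                f"{f.contains_mirna}\n"
            )
    logger.info(
        "network: %d nodes, %d edges, %d FBLs, %d FFLs",
        summary["n_nodes"], summary["n_edges"], len(fbls), len(ffls),
    )
    return {"network": net, "summary": summary, "fbls": fbls, "ffls": ffls}


def run_enrichment_stage(cfg: PipelineConfig, net: nl.RegNetwork,
                         outdir: Path) -> dict:
    """Over-representation of network genes, plus term subnetworks."""
    sets = iof.read_gene_sets_gmt(cfg.resolve(cfg.enrichment["gene_sets"]))
    mirnas = net.nodes_with_role("mirna")
    genes = {n for n in net.nodes if n not in mirnas}
    background = set(sets.all_genes()) | {g.upper() for g in genes}
    table = enr.hypergeometric_enrichment(
        genes, sets, background, fdr=cfg.enrichment["fdr"]
    )
    table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    subdir = outdir / "subnetworks"
    subdir.mkdir(parents=True, exist_ok=True)
    subnets = {}
    for row in table[table["enriched"]].itertuples(index=False):
        term_genes = sets.sets[row.term_id][1]
        sn = enr.extract_subnetwork(net, term_genes)
        subnets[row.term_id] = sn
        safe = row.term_id.replace(":", "_").replace("/", "_")
        with open(subdir / f"{safe}.sif", "w") as fh:
            for e in sn.edges:
                fh.write(f"{e.src}\t{'+1' if e.sign > 0 else '-1'}\t{e.dst}\n")
    matrix = enr.mirna_term_matrix(subnets, sorted(mirnas))
    matrix.to_csv(outdir / "mirna_term_matrix.tsv", sep="\t")
    logger.info(
        "enrichment: %d terms tested, %d enriched (FDR<=%g)",
        len(table), int(table["enriched"].sum()), cfg.enrichment["fdr"],
    )
    return {"table": table, "subnetworks": subnets, "matrix": matrix}


def run_pipeline(cfg: PipelineConfig, skip_motif_scan: bool = False) -> dict:
    """Execute all stages; returns the output manifest (also written to disk).

    A stage failure aborts the run with the stage name; the partial
    manifest of files produced so far is still written.
    """
    outdir = cfg.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": cfg.seed, "stages": [], "files": {}}
    stage = "preprocess"
    try:
        results: dict[str, Any] = {}
        for arm in ("mirna", "gene"):
            if not cfg.arm(arm):
                continue
            stage = f"consensus[{arm}]"
            armdir = outdir / arm
            armdir.mkdir(parents=True, exist_ok=True)
            results[arm] = run_consensus_stage(cfg, arm, armdir)
            manifest["stages"].append(stage)
        if "mirna" not in results:
            raise ConfigError("pipeline requires at least one mirna dataset")
        mirna_dir = outdir / "mirna"
        consensus_mirnas = results["mirna"]["consensus_features"]

        stage = "integration"
        integ = run_integration_stage(cfg, consensus_mirnas, mirna_dir)
        manifest["stages"].append(stage)

        tf_edges = []
        if not skip_motif_scan and cfg.motif_scan.get("motifs"):
            stage = "motif_scan"
            scan = run_scan_stage(cfg, set(consensus_mirnas), mirna_dir)
            tf_edges = scan["tf_edges"]
            manifest["stages"].append(stage)

        stage = "network"
        # miRNAs without any surviving target drop out of the network
        linked = {e.src for e in integ["target_edges"]}
        target_edges = [e for e in integ["target_edges"] if e.src in linked]
        netres = run_network_stage(
            cfg, target_edges, integ["tfregs"], tf_edges, mirna_dir
        )
        manifest["stages"].append(stage)

        if cfg.enrichment.get("gene_sets"):
            stage = "enrichment"
            run_enrichment_stage(cfg, netres["network"], mirna_dir)
            manifest["stages"].append(stage)
    except Exception:
        manifest["failed_stage"] = stage
        _finalize_manifest(manifest, outdir)
        logger.error("pipeline aborted at stage %s", stage)
        raise
    _finalize_manifest(manifest, outdir)
    return manifest


def _finalize_manifest(manifest: dict, outdir: Path) -> None:
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
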