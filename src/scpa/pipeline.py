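"""End-to-end pipeline orchestrator.

Stage order: QC -> normalize -> expression clustering (resolution-optimized)
-> metaCells -> per-cluster ARACNe networks -> metaVIPER activity -> activity
re-clustering -> master regulators -> bulk DEG -> GSEA of top MRs with
leading edges -> GSVA.  Every artifact is written under the output directory
and listed, with a content hash, in ``manifest.json``; a fixed master seed
makes the whole run reproducible, and completed stages are reloaded instead
of recomputed when ``resume`` is on.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bulkdeg, clustering, enrichment, io, network, qc, viper

log = logging.getLogger(__name__)

STAGES = ["qc", "normalize", "cluster", "network", "viper", "mr", "deg", "gsea", "gsva"]


@dataclass
class PipelineConfig:
    counts_mtx: str
    genes_tsv: str
    barcodes_tsv: str
    outdir: str
    cell_meta_tsv: str | None = None
    bulk_counts_tsv: str | None = None
    bulk_groups_tsv: str | None = None
    regulator_list: str | None = None
    gene_sets_gmt: str | None = None
    master_seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        for key in ("counts_mtx", "genes_tsv", "barcodes_tsv", "cell_meta_tsv",
                    "bulk_counts_tsv", "bulk_groups_tsv", "regulator_list",
                    "gene_sets_gmt"):
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config path {key} = {val!r} does not exist")

    def param(self, key: str, default):
        return self.params.get(key, default)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.master_seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", float_format="%.6g", **kw)
    return path


def run_pipeline(config: PipelineConfig, until: str = "gsva", resume: bool = False) -> Path:
    """Run the pipeline through stage ``until``; returns the artifact directory."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; stages: {STAGES}")
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "master_seed": config.master_seed,
        "params": config.params,
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    for key in ("counts_mtx", "genes_tsv", "barcodes_tsv", "cell_meta_tsv",
                "bulk_counts_tsv", "bulk_groups_tsv", "regulator_list", "gene_sets_gmt"):
        val = getattr(config, key)
        if val is not None:
            manifest["inputs"][key] = {"path": val, "sha256": _sha256(Path(val))}

    def record(stage: str, status: str, t0: float, files: list[Path]) -> None:
        log.info("stage %-9s %s (%.1fs)", stage, status, time.time() - t0)
        manifest["stages"][stage] = {"status": status}
        for f in files:
            manifest["outputs"][f.name] = _sha256(f)

    stop = STAGES.index(until)

    # ---- qc ------------------------------------------------------------
    t0 = time.time()
    gem = io.read_counts(config.counts_mtx, config.genes_tsv, config.barcodes_tsv,
                         config.cell_meta_tsv)
    metrics = qc.compute_qc_metrics(gem)
    filtered, report = qc.filter_cells(gem, metrics, config.param("qc_thresholds", None))
    files = [
        _write_tsv(metrics, out / "qc_metrics.tsv"),
        _write_tsv(report, out / "qc_report.tsv", index=False),
        _write_tsv(pd.DataFrame({"barcode": filtered.cell_ids}), out / "retained_barcodes.tsv",
                   index=False),
    ]
    record("qc", "done", t0, files)
    if stop == STAGES.index("qc"):
        return _finish(out, manifest)

    # ---- normalize -----------------------------------------------------
    t0 = time.time()
    norm = qc.normalize_pearson_residuals(filtered)
    qc.select_hvg(norm, config.param("n_hvg", 3000))
    if config.param("per_sample_standardize", False) and "sample" in filtered.cell_meta:
        norm = qc.standardize_per_sample(norm, filtered.cell_meta["sample"].to_numpy())
    hvg = norm.hvg_view()
    files = [
        _write_tsv(pd.DataFrame({"gene": norm.gene_ids[norm.hvg_flags]}), out / "hvg.tsv",
                   index=False),
        _write_tsv(pd.DataFrame(hvg.values, index=hvg.gene_ids, columns=hvg.cell_ids),
                   out / "hvg_residuals.tsv"),
    ]
    record("normalize", "done", t0, files)
    if stop == STAGES.index("normalize"):
        return _finish(out, manifest)

    # ---- cluster -------------------------------------------------------
    t0 = time.time()
    labels_path = out / "expression_clusters.tsv"
    emb = clustering.run_pca(norm, config.param("n_pcs", 30))
    if resume and labels_path.exists():
        df = pd.read_csv(labels_path, sep="\t")
        assign_labels = df["cluster"].to_numpy()
        trace = pd.read_csv(out / "silhouette_trace.tsv", sep="\t")
        files = []
        status = "resumed"
    else:
        assign = clustering.optimize_resolution(
            emb,
            grid=np.asarray(config.param("resolution_grid", clustering.DEFAULT_RESOLUTION_GRID)),
            n_repeats=config.param("n_silhouette_repeats", 100),
            subsample=config.param("silhouette_subsample", 500),
            k_neighbors=config.param("k_neighbors", 20),
            seed=config.stage_seed("cluster"),
        )
        assign_labels = assign.labels
        trace = assign.silhouette_trace
        files = [
            _write_tsv(pd.DataFrame({"barcode": filtered.cell_ids, "cluster": assign_labels}),
                       labels_path, index=False),
            _write_tsv(trace, out / "silhouette_trace.tsv", index=False),
            _write_tsv(pd.DataFrame(emb.coords, index=filtered.cell_ids), out / "pca.tsv"),
        ]
        status = "done"
    record("cluster", status, t0, files)
    if stop == STAGES.index("cluster"):
        return _finish(out, manifest)

    # ---- network -------------------------------------------------------
    t0 = time.time()
    regulators = (io.read_regulator_list(config.regulator_list)
                  if config.regulator_list else None)
    if regulators is None:
        raise ValueError("network stage requires a regulator list")
    networks: list[network.InteractionNetwork] = []
    files = []
    for c in np.unique(assign_labels):
        reg_path = out / f"regulons_cluster{c}.tsv"
        if resume and reg_path.exists():
            regs = network.read_regulons(reg_path)
            networks.append(network.InteractionNetwork(f"cluster{c}", regs, float("nan"),
                                                       config.param("n_bootstraps", 100)))
            continue
        mask = assign_labels == c
        sub = filtered.subset_cells(mask)
        sub_emb = clustering.Embedding(emb.coords[mask], emb.explained_variance,
                                       emb.n_pcs, emb.cell_ids[mask])
        meta = network.pool_metacells(
            sub, np.ones(sub.n_cells, dtype=int), sub_emb,
            n_meta=config.param("n_metacells", 250),
            k=config.param("metacell_k", 10),
            seed=config.stage_seed(f"metacells{c}"),
        )
        if meta.n_metacells < 10:
            log.warning("cluster %s: only %d metacells; network skipped", c, meta.n_metacells)
            continue
        net = network.bootstrap_consensus_network(
            meta, regulators,
            n_boot=config.param("n_bootstraps", 100),
            p_threshold=config.param("mi_p_threshold", 1e-8),
            dpi_tolerance=config.param("dpi_tolerance", 0.0),
            seed=config.stage_seed(f"network{c}"),
            n_null_pairs=config.param("n_null_pairs", 1000),
            context_id=f"cluster{c}",
        )
        if net.edge_table.empty:
            log.warning("cluster %s: empty consensus network; skipped", c)
            continue
        network.build_regulons(
            net, meta,
            max_targets=config.param("max_targets", 50),
            min_targets=config.param("min_targets", 25),
            regulators=regulators,
        )
        network.write_regulons(net.regulons, reg_path)
        files.append(reg_path)
        with open(out / f"network_cluster{c}.json", "w") as fh:
            json.dump({"context": net.context_id, "mi_threshold": net.mi_threshold,
                       "n_bootstraps": net.n_bootstraps,
                       "n_regulons": len(net.regulons)}, fh)
        files.append(out / f"network_cluster{c}.json")
        networks.append(net)
    if not networks:
        raise RuntimeError("network stage produced no usable network")
    record("network", "done", t0, files)
    if stop == STAGES.index("network"):
        return _finish(out, manifest)

    # ---- viper ---------------------------------------------------------
    t0 = time.time()
    lib = np.asarray(filtered.counts.sum(axis=0)).ravel()
    log2cpm = np.log2(filtered.to_dense() / np.maximum(lib, 1) * 1e6 + 1.0)
    sig = viper.compute_signatures(log2cpm, filtered.gene_ids, filtered.cell_ids,
                                   method=config.param("signature_method", "zscore"))
    activity = viper.metaviper_activity(sig, networks,
                                        min_targets=config.param("area_min_targets", None))
    act_norm = viper.activity_to_norm(activity)
    act_emb = clustering.run_pca(act_norm, config.param("n_pcs_activity", 30))
    act_assign = clustering.optimize_resolution(
        act_emb,
        grid=np.asarray(config.param("resolution_grid", clustering.DEFAULT_RESOLUTION_GRID)),
        n_repeats=config.param("n_silhouette_repeats", 100),
        subsample=config.param("silhouette_subsample", 500),
        k_neighbors=config.param("k_neighbors", 20),
        seed=config.stage_seed("viper_cluster"),
    )
    files = [
        _write_tsv(pd.DataFrame(activity.values, index=activity.protein_ids,
                                columns=activity.cell_ids), out / "activity.tsv"),
        _write_tsv(pd.DataFrame({"barcode": filtered.cell_ids, "cluster": act_assign.labels}),
                   out / "activity_clusters.tsv", index=False),
    ]
    with open(out / "activity_provenance.json", "w") as fh:
        json.dump(activity.provenance, fh)
    files.append(out / "activity_provenance.json")
    record("viper", "done", t0, files)
    if stop == STAGES.index("viper"):
        return _finish(out, manifest)

    # ---- mr ------------------------------------------------------------
    t0 = time.time()
    mr_table = viper.master_regulators(
        activity, act_assign.labels,
        n_boot=config.param("mr_bootstraps", 100),
        seed=config.stage_seed("mr"),
    )
    files = [_write_tsv(mr_table, out / "master_regulators.tsv", index=False)]
    record("mr", "done", t0, files)
    if stop == STAGES.index("mr"):
        return _finish(out, manifest)

    # ---- deg -----------------------------------------------------------
    t0 = time.time()
    if config.bulk_counts_tsv is None:
        record("deg", "skipped (no bulk input)", t0, [])
        record("gsea", "skipped (no bulk input)", time.time(), [])
        ranked = None
    else:
        bulk = pd.read_csv(config.bulk_counts_tsv, sep="\t", index_col=0)
        groups = pd.read_csv(config.bulk_groups_tsv, sep="\t", index_col=0).iloc[:, 0]
        deg = bulkdeg.differential_expression(bulk, groups.loc[bulk.columns])
        ranked = bulkdeg.rank_genes(deg, deg_only=config.param("gsea_deg_only", False))
        files = [
            _write_tsv(deg, out / "deg.tsv", index=False),
            _write_tsv(ranked, out / "ranked_genes.tsv", index=False),
        ]
        record("deg", "done", t0, files)
    if stop == STAGES.index("deg"):
        return _finish(out, manifest)

    # ---- gsea ----------------------------------------------------------
    if ranked is not None:
        t0 = time.time()
        rows = []
        le_sets: dict[str, set[str]] = {}
        universe = set(ranked["gene"])
        for c in sorted(set(mr_table["cluster"])):
            top = viper.top_master_regulators(mr_table, c, config.param("gsea_top_mrs", 100))
            usable = [g for g in top if g in universe]
            if len(usable) < 5:
                log.warning("cluster %s: too few MRs in bulk universe; GSEA skipped", c)
                continue
            res = enrichment.gsea(
                ranked, usable, set_id=f"cluster{c}_top_mrs",
                weight_p=config.param("gsea_weight_p", 1.0),
                n_perm=config.param("gsea_permutations", 1000),
                seed=config.stage_seed(f"gsea{c}"),
            )
            le_sets[res.set_id] = set(res.leading_edge)
            rows.append((res.set_id, res.es, res.nes, res.p_perm, res.significant,
                         ",".join(res.leading_edge)))
        gsea_table = pd.DataFrame(
            rows, columns=["set", "ES", "NES", "p", "significant", "leading_edge"]
        )
        files = [_write_tsv(gsea_table, out / "gsea_top_mrs.tsv", index=False)]
        if len(le_sets) >= 2:
            inter = enrichment.intersect_leading_edges(le_sets)
            with open(out / "leading_edge_intersection.json", "w") as fh:
                json.dump({**inter, "shared": sorted(inter["shared"])}, fh)
            files.append(out / "leading_edge_intersection.json")
        record("gsea", "done", t0, files)
    if stop == STAGES.index("gsea"):
        return _finish(out, manifest)

    # ---- gsva ----------------------------------------------------------
    t0 = time.time()
    if config.gene_sets_gmt is None:
        record("gsva", "skipped (no gene sets)", t0, [])
    else:
        sets = io.read_gmt(config.gene_sets_gmt)
        act_df = pd.DataFrame(activity.values, index=activity.protein_ids,
                              columns=activity.cell_ids)
        source = act_df if config.param("gsva_on_activity", True) else pd.DataFrame(
            log2cpm, index=filtered.gene_ids, columns=filtered.cell_ids)
        scores = enrichment.gsva_scores(source, sets)
        files = [_write_tsv(scores, out / "gsva_scores.tsv")]
        record("gsva", "done", t0, files)
    return _finish(out, manifest)


def _finish(out: Path, manifest: dict) -> Path:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
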