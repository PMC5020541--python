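"""End-to-end pipeline: counts -> topics -> tree -> backbone -> enrichment.

A flat, serialisable RunConfig drives every stage; identical config + seed
reproduces bit-identical outputs (the manifest lists a SHA-256 checksum per
artefact, so determinism is checkable by diffing manifests).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import backbone as bb
from . import enrichment as enr
from . import io as tio
from . import lda
from . import simulate as sim
from . import tree as ttree

log = logging.getLogger("topictree")


@dataclass
class RunConfig:
    """Every user-settable knob of the pipeline, with defaults."""

    # input: either a file, or the built-in synthetic trajectory when unset
    input_path: str = ""
    input_format: str = "tsv"
    groups_path: str = ""
    group_order_path: str = ""
    # synthetic generation (used when input_path is empty)
    synth_cells: int = 80
    synth_genes: int = 500
    synth_topics: int = 4
    synth_branches: int = 1
    synth_tokens: int = 1000
    synth_noise: float = 0.1
    # pre-treatment (file inputs only)
    sd_threshold: float = 0.5
    log_base: float = 2.0
    discretise_scale: float = 1.0
    # model
    topics: str = "auto"  # "auto" or an integer as string
    k_min: int = 2
    k_max: int = 10
    sweeps: int = 800
    burn_in: int = 200
    thin: int = 10
    alpha: float = 0.0  # 0 -> default 50/K
    beta: float = 0.1
    # tree
    rooting: str = "diameter"  # diameter | centrality
    start_group: str = "auto"  # "auto" or a group label
    # backbone
    delta: str = "auto"  # "auto" or a float as string
    outlier_fraction: float = 0.05
    # enrichment
    gene_sets_path: str = ""
    dag_edges_path: str = ""
    enrich_method: str = "weight"
    sig_alpha: float = 0.05
    # run
    seed: int = 0
    out_dir: str = "topictree_run"
    log_level: str = "INFO"

    def save(self, path: str | Path) -> None:
        lines = [f"{f.name}={getattr(self, f.name)}"
                 for f in dataclasses.fields(self)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        kv = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        out = {}
        for k, v in kv.items():
            if k not in types:
                raise KeyError(f"unknown config key {k!r}")
            current = getattr(defaults, k)
            if isinstance(current, bool):
                out[k] = v.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                out[k] = int(v)
            elif isinstance(current, float):
                out[k] = float(v)
            else:
                out[k] = v
        return cls(**out)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict[str, str]:
    """Execute the full pipeline; returns the artefact manifest (file -> sha)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    t0 = time.time()

    def emit(name: str, text: str) -> Path:
        p = out / name
        p.write_text(text)
        manifest[name] = _sha256(p)
        return p

    cfg.save(out / "config.txt")
    manifest["config.txt"] = _sha256(out / "config.txt")

    # ---- input -------------------------------------------------------
    truth = None
    if cfg.input_path:
        m = tio.read_expression(cfg.input_path, cfg.input_format,
                                cfg.groups_path or None,
                                cfg.group_order_path or None)
        m = tio.pretreat(m, cfg.sd_threshold, cfg.log_base)
        counts = tio.discretise(m, cfg.discretise_scale)
    else:
        counts, truth = sim.generate_trajectory(
            M=cfg.synth_cells, V=cfg.synth_genes, K=cfg.synth_topics,
            branches=cfg.synth_branches, tokens_per_cell=cfg.synth_tokens,
            noise=cfg.synth_noise, seed=cfg.seed)
        emit("truth_pseudotime.tsv", "cell_id\tpseudotime\tbranch\tstage\n" +
             "".join(f"{c}\t{t:.6f}\t{b}\t{s}\n" for c, t, b, s in
                     zip(truth.cell_ids, truth.pseudotime_true,
                         truth.branch_true, truth.group_labels)))
        enr.write_gmt({f"topic{k}_anchor": g
                       for k, g in truth.planted_terms.items()},
                      out / "planted_terms.gmt")
        manifest["planted_terms.gmt"] = _sha256(out / "planted_terms.gmt")
    log.info("input: %d genes x %d cells (%.1fs)", counts.n_genes,
             counts.n_cells, time.time() - t0)

    # ---- model -------------------------------------------------------
    t1 = time.time()
    alpha = None if cfg.alpha == 0 else cfg.alpha
    if cfg.topics == "auto":
        best_k, scores = lda.select_topic_count(
            counts, cfg.k_min, cfg.k_max, seed=cfg.seed, alpha=alpha,
            beta=cfg.beta)
        emit("topic_scan.tsv", "K\tscore\n" +
             "".join(f"{k}\t{s:.4f}\n" for k, s in sorted(scores.items())))
        K = best_k
    else:
        K = int(cfg.topics)
    model = lda.fit_lda(counts, K, alpha=alpha, beta=cfg.beta,
                        sweeps=cfg.sweeps, burn_in=cfg.burn_in,
                        thin=cfg.thin, seed=cfg.seed)
    emit("model.json", json.dumps(model.to_json_dict()))
    log.info("LDA: K=%d fitted (%.1fs)", K, time.time() - t1)

    # ---- distances and tree -----------------------------------------
    dm = ttree.distance_matrix(model)
    emit("distances.tsv", "\t".join([""] + dm.cell_ids) + "\n" +
         "".join(c + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n"
                 for c, row in zip(dm.cell_ids, dm.d)))
    mst = ttree.minimum_spanning_tree(dm)

    groups = counts.groups
    if groups and cfg.start_group != "auto":
        start_label = cfg.start_group
    elif groups:
        start_label = ttree.detect_start_group(dm, groups)
    else:
        start_label = None
    if start_label is not None:
        start_cells = {c for c in dm.cell_ids if groups[c] == start_label}
    else:
        start_cells = {min(dm.cell_ids)}
    if cfg.rooting == "centrality":
        rooted = ttree.set_root(mst, ttree.root_by_centrality(dm, start_cells))
    else:
        rooted = ttree.root_by_diameter(mst, dm, start_cells)
    emit("mst.dot", ttree.tree_to_dot(rooted))
    emit("mst_edges.tsv", ttree.tree_to_edge_tsv(rooted))
    ordering = ttree.ordering_from_tree(rooted)
    emit("ordering.tsv", ttree.ordering_to_tsv(ordering))
    log.info("tree: rooted at %s (start group %s)", rooted.root, start_label)

    # ---- backbone ----------------------------------------------------
    delta = None if cfg.delta == "auto" else float(cfg.delta)
    bt = bb.build_backbone(dm, delta=delta,
                           outlier_fraction=cfg.outlier_fraction)
    bt = bb.root_backbone(bt, dm, start_cells)
    emit("backbone.tsv", bb.backbone_to_tsv(bt, dm))
    emit("backbone.dot", bb.backbone_to_dot(bt, dm))
    log.info("backbone: %d backbone vertices, %d vertebrae, %d outliers, "
             "delta=%.4f", len(bt.backbone_vertices),
             len(bt.vertebra_attachments), len(bt.outliers), bt.delta)

    # ---- enrichment --------------------------------------------------
    gmt_path = cfg.gene_sets_path or (str(out / "planted_terms.gmt")
                                      if truth is not None else "")
    if gmt_path:
        dag = enr.load_gene_set_dag(gmt_path, cfg.dag_edges_path or None)
        table = enr.enrich_all_topics(model, dag, cfg.enrich_method)
        table = enr.partition_unique_terms(table, cfg.sig_alpha)
        emit("enrichment.tsv", enr.enrichment_to_tsv(table))

    # ---- evaluation (when truth is known) ---------------------------
    if truth is not None:
        edm = ttree.euclidean_distance_matrix(
            np.log1p(counts.counts) / np.log(2), counts.cell_ids)
        report = evaluate_ordering(ordering, edm, start_cells, truth,
                                   seed=cfg.seed)
        emit("evaluation.tsv", "metric\tvalue\n" +
             "".join(f"{k}\t{v}\n" for k, v in report.items()))

    manifest_text = "".join(f"{k}\t{v}\n" for k, v in sorted(manifest.items()))
    (out / "manifest.tsv").write_text(manifest_text)
    log.info("pipeline complete in %.1fs; %d artefacts", time.time() - t0,
             len(manifest))
    return manifest


def evaluate_ordering(ordering: list[str], dm: ttree.CellDistanceMatrix,
                      start_cells: set[str], truth: sim.SyntheticTruth,
                      seed: int = 0) -> dict[str, float]:
    """Pairwise ordering accuracy of the tree ordering vs the TSP baseline."""
    ranks = truth.truth_ranks()
    truth_order = sorted(truth.cell_ids, key=lambda c: (ranks[c], c))
    acc_tree = ttree.pairwise_ordering_accuracy(ordering, truth_order, ranks)
    tsp = ttree.tsp_baseline_ordering(dm, start_cells, seed=seed)
    acc_tsp = ttree.pairwise_ordering_accuracy(tsp, truth_order, ranks)
    return {"tree_ordering_accuracy": round(acc_tree, 4),
            "tsp_baseline_accuracy": round(acc_tsp, 4)}
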