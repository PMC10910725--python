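"""End-to-end orchestration: simulate -> DE -> RIF -> PCIT -> MCODE -> summaries.

Each stage reads only its declared inputs from the output directory (so
stages are independently re-invokable on prior outputs) and appends the
files it wrote to a checksummed manifest.  A rerun with the same config and
seed is bit-identical for the deterministic stages, which here is all of
them: the only randomness enters through the master seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, mcode, pcit, prep, regulators, simulate, summary
from .config import RunConfig

log = logging.getLogger("coexnet")

__all__ = ["run_pipeline", "stage_simulate", "stage_de", "stage_rif",
           "stage_network", "stage_cluster", "stage_summarize"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(manifest: list, outdir: Path, stage: str, *paths: Path) -> None:
    for p in paths:
        manifest.append({"file": str(p.relative_to(outdir)), "stage": stage,
                         "sha256": _sha256(p)})


def _load_counts_design(cfg: RunConfig, outdir: Path):
    if cfg.simulate is not None:
        counts = io.read_counts(outdir / "counts.tsv")
        design = io.read_design(outdir / "design.tsv")
        tf_list = outdir / "tf_list.txt"
        secretome = outdir / "secretome_list.txt"
    else:
        counts = io.read_counts(cfg.inputs["counts"])
        design = io.read_design(cfg.inputs["design"])
        tf_list = Path(cfg.inputs["tf_list"])
        secretome = Path(cfg.inputs["secretome_list"])
    return counts, design, tf_list, secretome


def stage_simulate(cfg: RunConfig, outdir: Path, manifest: list) -> None:
    if cfg.simulate is None:
        return
    design, params = cfg.simulate
    counts, design_tbl, truth = simulate.simulate_counts(design, params)
    io.write_counts(counts, outdir / "counts.tsv")
    io.write_design(design_tbl, outdir / "design.tsv")
    truth.to_json(outdir / "truth.json")
    simulate.write_fixture_lists(truth, outdir / "tf_list.txt",
                                 outdir / "secretome_list.txt")
    log.info("simulate: %d genes x %d samples", *counts.shape)
    _record(manifest, outdir, "simulate",
            outdir / "counts.tsv", outdir / "design.tsv", outdir / "truth.json",
            outdir / "tf_list.txt", outdir / "secretome_list.txt")


def stage_de(cfg: RunConfig, outdir: Path, manifest: list) -> None:
    counts, design, _, _ = _load_counts_design(cfg, outdir)
    thr = cfg.thresholds
    for spec in prep.standard_contrasts(design):
        result = prep.de_test(counts, design, spec,
                              cpm_threshold=thr["cpm"],
                              min_fraction=thr["min_fraction"],
                              prior_df=thr["prior_df"])
        selected = set(prep.select_top_fraction(result, thr["fraction"]))
        tab = result.table.copy()
        tab["selected"] = tab.index.isin(selected)
        path = outdir / f"de_{result.label}.tsv"
        tab.to_csv(path, sep="\t", float_format="%.10g")
        log.info("de %s: %d tested, %d selected", result.label,
                 result.n_tested, len(selected))
        _record(manifest, outdir, "de", path)


def _read_de(outdir: Path) -> dict[str, pd.DataFrame]:
    tables = {}
    for path in sorted(outdir.glob("de_*.tsv")):
        label = path.stem.split("_", 1)[1]
        tables[label] = pd.read_csv(path, sep="\t", index_col="gene")
    if not tables:
        raise FileNotFoundError("no de_*.tsv outputs found; run the de stage")
    return tables


def _tissue_of_label(label: str, design: pd.DataFrame) -> str:
    for tissue in pd.unique(design["tissue"]):
        if simulate.contrast_label(tissue, "rfi")[1] == label[1]:
            return tissue
    raise ValueError(f"no tissue matches contrast label {label!r}")


def _condition_pair(label: str, design: pd.DataFrame):
    """(levels, per-sample series) for the contrast factor behind a label."""
    code = label[0]
    factor = {"R": "rfi", "D": "diet", "B": "breed"}[code]
    if factor == "diet":
        values = design["diet"].map(
            lambda d: "HC" if d in prep.HC_PHASES else d)
        levels = ("HC", "ZG")
    else:
        values = design[factor]
        uniq = sorted(values.unique())
        if factor == "rfi" and "High" in uniq:
            levels = ("High", next(x for x in uniq if x != "High"))
        else:
            levels = (uniq[0], uniq[1])
    return levels, values


def stage_rif(cfg: RunConfig, outdir: Path, manifest: list) -> None:
    counts, design, tf_list, _ = _load_counts_design(cfg, outdir)
    de_tables = _read_de(outdir)
    tfs = io.read_gene_list(tf_list)
    design = design.set_index("sample")
    for label, tab in de_tables.items():
        tissue = _tissue_of_label(label, design.reset_index())
        sub = design[design["tissue"] == tissue]
        cols = [s for s in sub.index if s in counts.columns]
        counts_t = counts[cols]
        factors = prep.tmm_factors(counts_t)
        cpm = prep.compute_cpm(counts_t, factors)
        expressed = prep.filter_expressed(cpm, cfg.thresholds["cpm"],
                                          cfg.thresholds["min_fraction"])
        log_cpm = np.log2(cpm.loc[expressed] + 1.0)
        levels, values = _condition_pair(label, sub.reset_index())
        cond = pd.Series(values.to_numpy(), index=sub.index).loc[cols]
        regs = [g for g in tfs if g in log_cpm.index]
        targets = [g for g in tab.index[tab["selected"]] if g in log_cpm.index]
        if not regs or not targets:
            log.info("rif %s: skipped (no regulators or targets expressed)",
                     label)
            continue
        rif = regulators.rif_for_contrast(log_cpm, cond, regs, targets, levels)
        out = rif.table.copy()
        out.insert(0, "contrast", label)
        path = outdir / f"rif_{label}.tsv"
        out.to_csv(path, sep="\t", float_format="%.10g")
        log.info("rif %s: %d regulators x %d targets, %d significant", label,
                 len(regs), len(targets), int(out["significant"].sum()))
        _record(manifest, outdir, "rif", path)


def stage_network(cfg: RunConfig, outdir: Path, manifest: list) -> None:
    counts, design, tf_list, secretome = _load_counts_design(cfg, outdir)
    de_tables = _read_de(outdir)
    thr = cfg.thresholds
    design = design.set_index("sample")
    deg_sets = {label: set(tab.index[tab["selected"]])
                for label, tab in de_tables.items()}
    nodes_all = regulators.annotate_nodes(counts.index, tf_list, secretome,
                                          deg_sets)
    per_contrast = {}
    for label, tab in de_tables.items():
        tissue = _tissue_of_label(label, design.reset_index())
        sub = design[design["tissue"] == tissue]
        cols = [s for s in sub.index if s in counts.columns]
        counts_t = counts[cols]
        factors = prep.tmm_factors(counts_t)
        cpm = prep.compute_cpm(counts_t, factors)
        expressed = prep.filter_expressed(cpm, thr["cpm"], thr["min_fraction"])
        node_set = (deg_sets[label]
                    | set(nodes_all.index[nodes_all["is_tf"]])
                    | set(nodes_all.index[nodes_all["is_secretome"]]))
        node_set = sorted(node_set & set(expressed.index[expressed]))
        log_cpm = np.log2(cpm.loc[node_set] + 1.0)
        R = pcit.correlation_matrix(log_cpm)
        retained = pcit.pcit_filter(R.to_numpy())
        edges = pcit.significant_edges(R, retained, label,
                                       abs_threshold=thr["abs_r"],
                                       sd_mult=thr["sd_mult"])
        per_contrast[label] = edges
        path = outdir / f"edges_{label}.tsv"
        edges.to_csv(path, sep="\t", index=False, float_format="%.10g")
        log.info("network %s: %d nodes in run, %d significant edges", label,
                 len(node_set), len(edges))
        _record(manifest, outdir, "network", path)
    net = pcit.build_network(per_contrast, nodes_all)
    edges_path = outdir / "edges_all.tsv"
    net.edges.to_csv(edges_path, sep="\t", index=False, float_format="%.10g")
    nodes_path = outdir / "nodes.tsv"
    net.nodes.to_csv(nodes_path, sep="\t")
    graphml = outdir / "network.graphml"
    net.write_graphml(graphml)
    log.info("network: %d labelled edges over %d distinct pairs, %d nodes",
             len(net.edges), net.n_distinct_pairs, len(net.nodes))
    _record(manifest, outdir, "network", edges_path, nodes_path, graphml)


def load_network(outdir: Path) -> pcit.LabeledNetwork:
    edges = pd.read_csv(outdir / "edges_all.tsv", sep="\t")
    if edges.empty:
        edges = pd.DataFrame(columns=["gene_a", "gene_b", "r", "label"])
    nodes = pd.read_csv(outdir / "nodes.tsv", sep="\t", index_col="gene")
    counts = {label: int(n) for label, n in
              edges.groupby("label").size().items()} if len(edges) else {}
    return pcit.LabeledNetwork(edges=edges, nodes=nodes, label_counts=counts)


def stage_cluster(cfg: RunConfig, outdir: Path, manifest: list) -> None:
    net = load_network(outdir)
    graph = net.to_simple_graph()
    clusters = mcode.find_complexes(
        graph, vwp=cfg.thresholds["vwp"],
        degree_cutoff=int(cfg.thresholds["degree_cutoff"]))
    rows = []
    for i, c in enumerate(clusters, start=1):
        members = set(c.members)
        sub = net.edges[net.edges["gene_a"].isin(members)
                        & net.edges["gene_b"].isin(members)]
        composition = ",".join(f"{lbl}:{n}" for lbl, n in
                               sub.groupby("label").size().items())
        rows.append({"cluster": i, "seed": c.seed, "score": c.score,
                     "size": c.size, "density": c.density,
                     "label_composition": composition,
                     "members": ";".join(c.members)})
    path = outdir / "clusters.tsv"
    pd.DataFrame(rows, columns=["cluster", "seed", "score", "size", "density",
                                "label_composition", "members"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g")
    log.info("cluster: %d complexes", len(clusters))
    _record(manifest, outdir, "cluster", path)


def stage_summarize(cfg: RunConfig, outdir: Path, manifest: list) -> None:
    net = load_network(outdir)
    de_tables = _read_de(outdir)
    hubs = summary.hub_per_contrast(net)
    hub_path = outdir / "hubs.tsv"
    out = hubs.copy()
    if len(out):
        out["tf_first_neighbors"] = out["tf_first_neighbors"].map(";".join)
    out.to_csv(hub_path, sep="\t", float_format="%.10g")
    written = [hub_path]
    if len(hubs):
        tf_net = summary.tf_first_neighbors(net, hubs["hub"].tolist())
        tf_path = outdir / "tf_neighbors.graphml"
        import networkx as nx
        nx.write_graphml(tf_net, tf_path)
        written.append(tf_path)
    overlaps: dict = {}
    for mode, sets_by_tissue in (
        ("deg", _deg_sets_by_tissue(de_tables)),
        ("network", _network_sets_by_tissue(net)),
    ):
        overlaps[mode] = {}
        for tissue_code, sets in sets_by_tissue.items():
            if len(sets) >= 2:
                overlaps[mode][tissue_code] = summary.contrast_overlap(sets)
    venn_path = outdir / "venn.json"
    venn_path.write_text(json.dumps(overlaps, indent=1, sort_keys=True) + "\n")
    written.append(venn_path)
    if cfg.inputs.get("gene_sets"):
        gene_sets = io.read_gmt(cfg.inputs["gene_sets"])
        universe = set()
        for tab in de_tables.values():
            universe |= set(tab.index)
        clusters = pd.read_csv(outdir / "clusters.tsv", sep="\t")
        frames = []
        for row in clusters.itertuples(index=False):
            members = set(str(row.members).split(";")) & universe
            enr = summary.enrichment_hypergeom(members, gene_sets, universe)
            enr.insert(0, "cluster", row.cluster)
            frames.append(enr.reset_index())
        if frames:
            enr_path = outdir / "enrichment.tsv"
            pd.concat(frames, ignore_index=True).to_csv(
                enr_path, sep="\t", index=False, float_format="%.10g")
            written.append(enr_path)
    log.info("summarize: %d hub contrasts", len(hubs))
    _record(manifest, outdir, "summarize", *written)


def _deg_sets_by_tissue(de_tables: dict[str, pd.DataFrame]):
    by_tissue: dict[str, dict[str, set]] = {}
    for label, tab in de_tables.items():
        by_tissue.setdefault(label[1], {})[label] = set(
            tab.index[tab["selected"]])
    return by_tissue


def _network_sets_by_tissue(net: pcit.LabeledNetwork):
    by_tissue: dict[str, dict[str, set]] = {}
    for label in sorted(net.label_counts):
        sub = net.edges[net.edges["label"] == label]
        by_tissue.setdefault(label[1], {})[label] = \
            set(sub["gene_a"]) | set(sub["gene_b"])
    return by_tissue


_STAGES = [
    ("simulate", stage_simulate),
    ("de", stage_de),
    ("rif", stage_rif),
    ("network", stage_network),
    ("cluster", stage_cluster),
    ("summarize", stage_summarize),
]


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> list[dict]:
    """Run the requested stages (default: all) and return the manifest.

    The validated config is echoed into the output directory; any stage
    failure aborts with the stage name attached to the exception.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(cfg.echo(), indent=1, sort_keys=True) + "\n")
    manifest: list[dict] = []
    wanted = stages or [name for name, _ in _STAGES]
    for name, fn in _STAGES:
        if name not in wanted:
            continue
        try:
            fn(cfg, outdir, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
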