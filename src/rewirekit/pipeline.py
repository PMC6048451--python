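"""End-to-end orchestration: clustering -> significance -> networks -> drugs.

A :class:`RunConfig` carries the analysis constants (S = 1000 bootstrap
simulations, N = 10000 label permutations, alpha = 0.05 edge retention,
0.7 strong-edge threshold) and a master seed.  The master seed spawns one
named substream per stage so stages are independently reproducible; every
report embeds the config hash and the seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import drugmap
from .cohortsig import omnibus_rewiring_test
from .exprio import ExpressionMatrix, extract_panel, read_annotation_tsv, read_expression_tsv
from .matequiv import permutation_equivalence_test
from .mixture import fit_mixture
from .netarch import (
    build_network,
    centralities,
    centrality_correlation,
    consensus_hub,
    count_known_edges,
    strong_edges,
)
from .netmodules import detect_modules, match_modules, module_rewiring_test, overlap_permutation_null

logger = logging.getLogger(__name__)


def _seed_int(ss: np.random.SeedSequence) -> int:
    """Derive a plain integer seed from a (possibly spawned) SeedSequence."""
    return int(ss.generate_state(1, dtype=np.uint64)[0])

__all__ = ["RunConfig", "run_unsupervised", "run_supervised"]

_STAGES = (
    "cluster", "significance", "network", "matequiv", "modules", "assoc",
)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; defaults follow the analysis
    constants used throughout (S=1000, N=10000, alpha=0.05, |r|>0.7)."""

    input_path: str
    output_dir: str
    panel_path: str | None = None
    annotation_path: str | None = None
    annotation_column: str | None = None
    k_values: list[int] = field(default_factory=lambda: [2])
    n_simulations: int = 1000
    n_permutations: int = 10000
    alpha: float = 0.05
    strong_edge_threshold: float = 0.7
    module_k: list[int] = field(default_factory=lambda: [10, 20])
    seed: int = 0
    n_restarts: int = 10

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.alpha >= 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_simulations < 99 or self.n_permutations < 99:
            raise ValueError("simulation and permutation counts must be >= 99")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("output_dir")  # hash the analysis, not the destination
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> np.random.SeedSequence:
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        root = np.random.SeedSequence(self.seed)
        return root.spawn(len(_STAGES))[_STAGES.index(stage)]


def _load_known_edges() -> list[tuple[str, str]]:
    from importlib import resources

    text = resources.files("rewirekit.data").joinpath("known_edges.tsv").read_text()
    rows = [line.split("\t") for line in text.splitlines()[1:] if line.strip()]
    return [(r[0], r[1]) for r in rows]


def _load_matrix(config: RunConfig) -> ExpressionMatrix:
    matrix = read_expression_tsv(config.input_path)
    if config.panel_path:
        panel = [
            line.strip() for line in Path(config.panel_path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        matrix, unmapped = extract_panel(matrix, panel)
        if unmapped:
            logger.warning("%d panel genes unmapped: %s", len(unmapped), unmapped[:8])
    return matrix


def _stamp(config: RunConfig, payload: dict) -> dict:
    payload["config_hash"] = config.config_hash()
    payload["seed"] = config.seed
    return payload


def _log_stage(stage: str, started: float, extra: dict | None = None) -> None:
    record = {"stage": stage, "wall_seconds": round(time.time() - started, 3)}
    if extra:
        record.update(extra)
    logger.info("stage complete: %s", record)


def _network_report(matrix, labels, config, out, prefix, drug_table) -> list[dict]:
    """Per-group networks, centralities, consensus hubs, and drug hits."""
    rows = []
    for group in np.unique(labels):
        sub = matrix.select_samples(np.asarray(labels) == group)
        if sub.n_samples < 4:
            logger.warning("group %s has %d samples; network skipped", group, sub.n_samples)
            continue
        net = build_network(sub, alpha=config.alpha)
        records = centralities(net)
        pd.DataFrame(
            [
                {"gene": r.gene, "degree": r.degree, "closeness": r.closeness,
                 "betweenness": r.betweenness, "eigenvector": r.eigenvector}
                for r in records
            ]
        ).to_csv(out / f"{prefix}_centrality_group{group}.tsv", sep="\t", index=False)
        edges = [
            {"gene_i": u, "gene_j": v, "r": d["r"], "r2": d["weight"], "p": d["p"]}
            for u, v, d in net.graph.edges(data=True)
        ]
        pd.DataFrame(edges, columns=["gene_i", "gene_j", "r", "r2", "p"]).to_csv(
            out / f"{prefix}_network_group{group}.tsv", sep="\t", index=False
        )
        hubs, per_metric = consensus_hub(records)
        drug_hits = drugmap.map_genes_to_drugs(hubs, drug_table)
        rows.append(
            {
                "group": int(group),
                "n_samples": sub.n_samples,
                "n_edges": net.n_edges,
                "degree_top": ", ".join(per_metric["degree"]),
                "closeness_top": ", ".join(per_metric["closeness"]),
                "betweenness_top": ", ".join(per_metric["betweenness"]),
                "eigenvector_top": ", ".join(per_metric["eigenvector"]),
                "consensus": ", ".join(hubs),
                "predicted_drugs": "; ".join(
                    f"{g}: {', '.join(ds) if ds else 'NA'}" for g, ds in drug_hits.items()
                ),
            }
        )
    return rows


def run_unsupervised(config: RunConfig) -> dict:
    """Cluster -> bootstrap significance -> per-cluster networks -> drugs."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = _load_matrix(config)
    drug_table = drugmap.load_default_table()
    bundle: dict = {"kind": "unsupervised", "outputs": []}

    started = time.time()
    fits = {}
    for k in config.k_values:
        fit = fit_mixture(
            matrix, k, n_restarts=config.n_restarts, seed=config.stage_seed("cluster")
        )
        fits[k] = fit
        pd.DataFrame(
            {"sample_id": matrix.sample_ids, "cluster": fit.labels + 1}
        ).to_csv(out / f"clusters_k{k}.tsv", sep="\t", index=False)
        post = pd.DataFrame(
            fit.posteriors, index=matrix.sample_ids,
            columns=[f"posterior_{c + 1}" for c in range(k)],
        )
        post.index.name = "sample_id"
        post.to_csv(out / f"posteriors_k{k}.tsv", sep="\t")
        bundle["outputs"] += [f"clusters_k{k}.tsv", f"posteriors_k{k}.tsv"]
    _log_stage("cluster", started)

    started = time.time()
    sig_rows = []
    for k in config.k_values:
        if k == 1:
            continue
        results = omnibus_rewiring_test(
            matrix, k=k, n_simulations=config.n_simulations,
            seed=config.stage_seed("significance"),
            n_restarts=config.n_restarts,
        )
        for r in results:
            sig_rows.append(
                {"k": k, "statistic_name": r.statistic_name, "statistic": r.statistic,
                 "df": r.df, "p_asymptotic": r.p_asymptotic,
                 "p_simulated": r.p_simulated, "n_null": r.n_null}
            )
    sig = pd.DataFrame(sig_rows)
    sig.to_csv(out / "significance_report.tsv", sep="\t", index=False)
    bundle["outputs"].append("significance_report.tsv")
    _log_stage("significance", started)

    started = time.time()
    k_main = [k for k in config.k_values if k > 1][0]
    hub_rows = _network_report(
        matrix, fits[k_main].labels, config, out, "unsupervised", drug_table
    )
    pd.DataFrame(hub_rows).to_csv(out / "consensus_hubs.tsv", sep="\t", index=False)
    bundle["outputs"].append("consensus_hubs.tsv")
    _log_stage("network", started)

    if config.annotation_path:
        started = time.time()
        annotation = read_annotation_tsv(config.annotation_path).reindex(
            matrix.sample_ids
        )
        predictors = {
            c: annotation[c].astype(float).to_numpy()
            for c in annotation.columns
            if set(annotation[c].dropna().unique()) <= {0, 1}
            and not annotation[c].isna().any()
        }
        if predictors:
            results = assoc_mod.cluster_association(fits[k_main].labels, predictors)
            pd.DataFrame(
                [{"predictor": r.predictor, "estimate": r.estimate,
                  "std_error": r.std_error, "z_value": r.z_value,
                  "p_value": r.p_value, "fdr_adjusted_p": r.fdr_adjusted_p,
                  "separation": r.separation} for r in results]
            ).to_csv(out / "association_report.tsv", sep="\t", index=False)
            bundle["outputs"].append("association_report.tsv")
        _log_stage("assoc", started)

    summary = _stamp(config, {
        "kind": "unsupervised",
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "fits": {
            int(k): {
                "log_likelihood": float(f.log_likelihood),
                "n_params": int(f.n_params),
                "component_sizes": [int(c) for c in f.component_sizes],
                "degenerate": bool(f.degenerate),
            }
            for k, f in fits.items()
        },
    })
    with open(out / "run_summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    bundle["outputs"].append("run_summary.yaml")
    bundle["summary"] = summary
    return bundle


def run_supervised(config: RunConfig) -> dict:
    """Mutation-stratified equivalence tests, networks, and module rewiring."""
    if not config.annotation_path or not config.annotation_column:
        raise ValueError("supervised run needs annotation_path and annotation_column")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix = _load_matrix(config)
    annotation = read_annotation_tsv(config.annotation_path)
    column = config.annotation_column
    if column not in annotation.columns:
        raise ValueError(f"annotation column {column!r} not found")
    aligned = annotation.reindex(matrix.sample_ids)
    if aligned[column].isna().any():
        missing = aligned.index[aligned[column].isna()].tolist()[:5]
        raise ValueError(f"samples missing {column!r} annotation: {missing}")
    labels = aligned[column].astype(int).to_numpy()
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError(f"annotation column {column!r} must be binary 0/1")
    drug_table = drugmap.load_default_table()
    bundle: dict = {"kind": "supervised", "outputs": []}

    started = time.time()
    equiv_rows = []
    seed = config.stage_seed("matequiv")
    for method, sub_seed in zip(("steiger", "jennrich"), seed.spawn(2)):
        kwargs = {}
        if method == "jennrich" and matrix.n_samples <= matrix.n_genes:
            kwargs["shrinkage"] = 0.1
        res = permutation_equivalence_test(
            matrix, labels, method=method,
            n_permutations=config.n_permutations,
            seed=_seed_int(sub_seed), **kwargs,
        )
        equiv_rows.append(
            {"network": "panel", "method": method, "chisq": res.statistic,
             "df": res.df, "p_permutation": res.p_simulated, "n_null": res.n_null,
             "significant": res.p_simulated is not None and res.p_simulated <= config.alpha}
        )
    equiv = pd.DataFrame(equiv_rows)
    equiv["sig_in_1_model"] = "*" if equiv["significant"].any() else ""
    equiv.to_csv(out / "equivalence_report.tsv", sep="\t", index=False)
    bundle["outputs"].append("equivalence_report.tsv")
    _log_stage("matequiv", started)

    started = time.time()
    hub_rows = _network_report(matrix, labels, config, out, "supervised", drug_table)
    pd.DataFrame(hub_rows).to_csv(out / "supervised_hubs.tsv", sep="\t", index=False)
    cent = {}
    strong_rows = []
    known = _load_known_edges()
    for group in (0, 1):
        sub = matrix.select_samples(labels == group)
        net = build_network(sub, alpha=config.alpha)
        cent[group] = centralities(net)
        pairs = strong_edges(net.corr, threshold=config.strong_edge_threshold)
        n_known, n_total = count_known_edges(pairs, known)
        for a, b, r in pairs:
            strong_rows.append(
                {"group": group, "gene_a": a, "gene_b": b, "r": r,
                 "previously_reported": frozenset((a, b)) in
                 {frozenset(p[:2]) for p in known}}
            )
        logger.info("group %d: %d/%d strong edges previously reported",
                    group, n_known, n_total)
    pd.DataFrame(
        strong_rows, columns=["group", "gene_a", "gene_b", "r", "previously_reported"]
    ).to_csv(out / "strong_edges.tsv", sep="\t", index=False)
    corr = centrality_correlation(cent[0], cent[1])
    pd.DataFrame([corr]).to_csv(out / "centrality_correlation.tsv", sep="\t", index=False)
    bundle["outputs"] += [
        "supervised_hubs.tsv", "strong_edges.tsv", "centrality_correlation.tsv",
    ]
    _log_stage("network", started)

    started = time.time()
    module_rows = []
    mod_seed = config.stage_seed("modules")
    for k in config.module_k:
        if matrix.n_genes < k:
            logger.warning("skipping module k=%d: only %d genes", k, matrix.n_genes)
            continue
        ref = detect_modules(matrix.select_samples(labels == 0), k)
        other = detect_modules(matrix.select_samples(labels == 1), k)
        matches = match_modules(ref, other)
        nulls = overlap_permutation_null(
            ref, other, n_permutations=min(config.n_permutations, 1000),
            seed=_seed_int(mod_seed),
        )
        null_p = {row["ref_module"]: row["p_value"] for row in nulls}
        for row, rew_seed in zip(matches, mod_seed.spawn(len(matches))):
            rew = module_rewiring_test(
                matrix, labels, row["intersection"],
                n_permutations=min(config.n_permutations, 1000),
                seed=_seed_int(rew_seed),
            )
            module_rows.append(
                {"k": k, "module": row["ref_module"], "size": row["ref_size"],
                 "matched_module": row["matched_module"],
                 "intersection_size": len(row["intersection"]),
                 "overlap_p": null_p[row["ref_module"]],
                 "chisq": rew.statistic if rew else "NA",
                 "p_value": rew.p_simulated if rew else "NA"}
            )
    pd.DataFrame(module_rows).to_csv(out / "module_rewiring.tsv", sep="\t", index=False)
    bundle["outputs"].append("module_rewiring.tsv")
    _log_stage("modules", started)

    summary = _stamp(config, {
        "kind": "supervised",
        "annotation_column": column,
        "n_genes": matrix.n_genes,
        "n_samples": matrix.n_samples,
        "group_sizes": [int((labels == 0).sum()), int((labels == 1).sum())],
    })
    with open(out / "run_summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    bundle["outputs"].append("run_summary.yaml")
    bundle["summary"] = summary
    return bundle
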