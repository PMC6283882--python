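"""End-to-end pipeline: simulate -> compare-groups -> network -> gini ->
cluster -> lda -> msfa, with a reproducibility manifest.

The configuration (a plain dict, typically loaded from YAML) declares either
an input cohort CSV or a simulation scenario, the stage list, and per-stage
parameter blocks.  Every artifact is a CSV/JSON written under the output
directory and checksummed into ``manifest.json``; CSVs are the contract,
figures are by-products.  A stage failure is recorded and downstream stages
are skipped with a reason.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortTable, read_cohort_table, write_cohort_table
from .clustering import build_signature_matrix, hcluster
from .gini import gini_profile
from .groups import compare_panel, panel_summary, results_frame
from .lda import discrimination_score, fit_lda, scores_frame
from .msfa import ecm_fit, loadings_frame, marginal_covariance
from .networks import build_network, compare_networks, correlation_matrix
from .simulate import default_scenario, generate_cohort, DEFAULT_GROUP_SIZES

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "compare", "network", "gini", "cluster", "lda", "msfa")


def default_config(seed: int = 0) -> dict:
    """The bundled HD vs disease scenario with default stage parameters."""
    return {
        "seed": seed,
        "stages": list(ALL_STAGES),
        "simulate": {"scenario": "default", "group_sizes": dict(DEFAULT_GROUP_SIZES)},
        "compare": {"reference": "HD", "comparators": ["SSc", "OC", "AD"], "alpha": 0.05},
        "network": {"method": "spearman", "threshold": 0.6, "rule": "signed", "min_n": 10},
        "gini": {"B": 1000, "level": 0.95},
        "cluster": {"method": "pearson", "linkage": "average"},
        "lda": {"folds": 5, "shrinkage": 0.1},
        "msfa": {"K": 6, "J": 1, "init": "pca", "tol": 1e-6, "max_iter": 500},
    }


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(frame: pd.DataFrame, path: Path, index: bool = False) -> Path:
    frame.to_csv(path, index=index, float_format="%.10g")
    return path


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Run the configured stages in order and write the run manifest.

    Returns the manifest dict (also written to ``<outdir>/manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", ALL_STAGES))
    unknown = [s for s in stages if s not in ALL_STAGES]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "stages": {},
        "artifacts": {},
    }
    artifacts: list[Path] = []
    table: CohortTable | None = None
    truth = None
    failed = False
    fail_reason = ""

    for stage in stages:
        entry: dict = {"status": "skipped"}
        if failed:
            entry["reason"] = f"upstream failure: {fail_reason}"
            manifest["stages"][stage] = entry
            continue
        t0 = time.time()
        try:
            if stage == "simulate":
                params = config.get("simulate", {})
                truth = default_scenario(seed=seed)
                sizes = params.get("group_sizes", DEFAULT_GROUP_SIZES)
                table = generate_cohort(truth, sizes, seed=seed)
                artifacts.append(write_cohort_table(table, outdir / "cohort.csv"))
                gt = {
                    "analytes": truth.analytes,
                    "groups": truth.groups,
                    "transform": truth.transform,
                    "seed": seed,
                    "population_correlations": {
                        g: truth.correlation(g).round(6).to_dict() for g in truth.groups
                    },
                }
                gt_path = outdir / "ground_truth.json"
                gt_path.write_text(json.dumps(gt, indent=1, sort_keys=True))
                artifacts.append(gt_path)
                entry["shape"] = [table.n_subjects, len(table.analytes)]
            else:
                if table is None:
                    input_path = config.get("input")
                    if not input_path:
                        raise ValueError("no cohort available: add 'simulate' stage or 'input' path")
                    table = read_cohort_table(input_path, config.get("schema"))
                if stage == "compare":
                    params = config.get("compare", {})
                    ref = params.get("reference", "HD")
                    frames = []
                    for comp in params.get("comparators", []):
                        res = compare_panel(table, ref, comp, alpha=params.get("alpha", 0.05))
                        frame = results_frame(res)
                        frame.insert(0, "comparison", f"{ref}_vs_{comp}")
                        frames.append(frame)
                        entry[f"{ref}_vs_{comp}"] = panel_summary(res)
                    artifacts.append(_write_csv(pd.concat(frames), outdir / "group_tests.csv"))
                elif stage == "network":
                    params = config.get("network", {})
                    nets = {}
                    for group in table.groups:
                        corr = correlation_matrix(
                            table.select_groups([group]),
                            method=params.get("method", "spearman"),
                            min_n=params.get("min_n", 10),
                        )
                        artifacts.append(
                            _write_csv(corr.values, outdir / f"correlation_{group}.csv", index=True)
                        )
                        net = build_network(
                            corr, threshold=params.get("threshold", 0.6),
                            rule=params.get("rule", "signed"),
                        )
                        nets[group] = net
                        artifacts.append(
                            _write_csv(net.edge_list(), outdir / f"edges_{group}.tsv")
                        )
                    ref = config.get("compare", {}).get("reference", "HD")
                    if ref in nets:
                        comp_rows = []
                        for group, net in nets.items():
                            if group == ref:
                                continue
                            cmp_res = compare_networks(nets[ref], net)
                            comp_rows.append({
                                "comparison": f"{ref}_vs_{group}",
                                "jaccard": cmp_res["jaccard"],
                                "n_lost": len(cmp_res["lost"]),
                                "n_gained": len(cmp_res["gained"]),
                                "lost": ";".join("-".join(e) for e in cmp_res["lost"]),
                                "gained": ";".join("-".join(e) for e in cmp_res["gained"]),
                            })
                        artifacts.append(
                            _write_csv(pd.DataFrame(comp_rows), outdir / "network_comparison.csv")
                        )
                elif stage == "gini":
                    params = config.get("gini", {})
                    frame = gini_profile(
                        table, table.groups, B=params.get("B", 1000),
                        level=params.get("level", 0.95), seed=seed,
                    )
                    artifacts.append(_write_csv(frame, outdir / "gini.csv"))
                elif stage == "cluster":
                    params = config.get("cluster", {})
                    strata = [(g, table.select_groups([g])) for g in table.groups]
                    sig = build_signature_matrix(strata, method=params.get("method", "pearson"))
                    dendro = hcluster(sig, linkage=params.get("linkage", "average"))
                    order = [sig.row_labels[i] for i in dendro.leaf_order]
                    leaf_frame = pd.DataFrame(order, columns=["stratum", "analyte"])
                    artifacts.append(_write_csv(leaf_frame, outdir / "cluster_leaf_order.csv"))
                    (outdir / "cluster_dendrogram.nwk").write_text(dendro.to_newick())
                    artifacts.append(outdir / "cluster_dendrogram.nwk")
                elif stage == "lda":
                    params = config.get("lda", {})
                    model = fit_lda(table, shrinkage=params.get("shrinkage", 0.1))
                    artifacts.append(
                        _write_csv(scores_frame(model, table), outdir / "lda_scores.csv", index=True)
                    )
                    ref = config.get("compare", {}).get("reference", "HD")
                    accs = {}
                    for group in table.groups:
                        if group == ref:
                            continue
                        pair = table.select_groups([ref, group])
                        accs[f"{ref}_vs_{group}"] = discrimination_score(
                            pair, folds=params.get("folds", 5), seed=seed,
                            shrinkage=params.get("shrinkage", 0.1),
                        )
                    entry["cv_accuracy"] = accs
                    acc_frame = pd.DataFrame(
                        [{"comparison": k, "cv_accuracy": v} for k, v in accs.items()]
                    )
                    artifacts.append(_write_csv(acc_frame, outdir / "lda_accuracy.csv"))
                elif stage == "msfa":
                    params = config.get("msfa", {})
                    ref = config.get("compare", {}).get("reference", "HD")
                    others = [g for g in table.groups if g != ref]
                    study_names = [ref] + others
                    data = [
                        np.log(np.clip(table.group_values(g).to_numpy(dtype=float), 1e-12, None))
                        if config.get("msfa", {}).get("log_transform", True)
                        else table.group_values(g).to_numpy(dtype=float)
                        for g in study_names
                    ]
                    fit = ecm_fit(
                        data, K=params.get("K", 6), J=params.get("J", 1),
                        init=params.get("init", "pca"), tol=params.get("tol", 1e-6),
                        max_iter=params.get("max_iter", 500), seed=seed,
                    )
                    fit.params.analytes = table.analytes
                    artifacts.append(
                        _write_csv(loadings_frame(fit, study_names),
                                   outdir / "msfa_loadings.csv", index=True)
                    )
                    trace = pd.DataFrame({"iteration": np.arange(len(fit.loglik_trace)),
                                          "loglik": fit.loglik_trace})
                    artifacts.append(_write_csv(trace, outdir / "msfa_loglik_trace.csv"))
                    for s, name in enumerate(study_names):
                        sigma = pd.DataFrame(marginal_covariance(fit.params, s),
                                             index=table.analytes, columns=table.analytes)
                        artifacts.append(
                            _write_csv(sigma, outdir / f"msfa_sigma_{name}.csv", index=True)
                        )
                    entry["converged"] = bool(fit.converged)
                    entry["n_iter"] = int(fit.n_iter)
            entry["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - manifest records any failure
            logger.exception("stage %s failed", stage)
            entry["status"] = "failed"
            entry["error"] = str(exc)
            failed = True
            fail_reason = f"{stage}: {exc}"
        entry["wall_time_s"] = round(time.time() - t0, 3)
        manifest["stages"][stage] = entry

    for path in artifacts:
        manifest["artifacts"][path.name] = _checksum(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return manifest
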