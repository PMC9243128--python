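"""Config-driven end-to-end orchestration.

``run_pipeline`` executes, in order: data acquisition (synthetic generation
or file ingestion), preprocessing (batch correction, median quotient
normalization, rank transform), derived-trait computation, univariate
screening with clustering, the supervised multi-block integration, and
relevance-network inference.  Every stage writes its artifacts into the run
directory; a machine-readable ``summary.json`` collects the key numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from glycoblock import io as gio
from glycoblock.cluster import correlation_matrix, corr_distance, ward_cluster
from glycoblock.datamodel import GlycanPeakMatrix, SampleMetadata
from glycoblock.discriminant import auc as rank_auc
from glycoblock.discriminant import cross_validate, fit_diablo, predict, split_train_test
from glycoblock.errors import GlycoblockError
from glycoblock.network import build_network, circos_edges, similarity_matrix
from glycoblock.preprocess import (combat_correct, median_quotient_normalize,
                                   pca_batch_check, rank_transform)
from glycoblock.simulate import SimulationConfig, planted_truth, simulate_glycome
from glycoblock.traits import compute_traits, default_trait_table
from glycoblock.univariate import results_frame, screen_features

logger = logging.getLogger("glycoblock")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {"enabled": True},       # SimulationConfig overrides
    "input": {"peaks": None, "metadata": None, "traits_file": None},
    "preprocess": {
        "enabled": True,
        "combat": True,
        "preserve_group": True,
        "quotient": True,
        "rank": True,
        "rank_mode": "standardized",
    },
    "univariate": {"alpha": 0.05},
    "cluster": {"k_peaks": 4, "k_traits": 6, "method": "spearman"},
    "integrate": {
        "n_dims": 2,
        "keepx": {"peaks": 10},
        "split_fraction": 0.8,
        "folds": 5,
        "repeats": 1,
        "distance": "centroid-dist",
    },
    "network": {"threshold": 0.5, "n_dims_use": 1},
}


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None,
                overrides: Mapping | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def _config_hash(cfg: Mapping) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_pipeline(config: Mapping | None = None, out_dir: str | Path = "glycoblock_run") -> dict:
    """Execute the full analysis; returns the summary dict (also written to
    ``summary.json`` in ``out_dir``)."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    seed = int(cfg["seed"])
    summary: dict[str, Any] = {"config_hash": _config_hash(cfg), "seed": seed,
                               "stages": {}, "settings": {
                                   "keepx": cfg["integrate"]["keepx"],
                                   "split_fraction": cfg["integrate"]["split_fraction"],
                                   "network_threshold": cfg["network"]["threshold"],
                                   "n_dims": cfg["integrate"]["n_dims"],
                               }}
    stage = "init"
    try:
        # ------------------------------------------------------------ data
        stage = "data"
        t0 = time.time()
        if cfg["simulate"]["enabled"]:
            sim_kwargs = {k: v for k, v in cfg["simulate"].items() if k != "enabled"}
            sim_kwargs.setdefault("seed", seed)
            sim_cfg = SimulationConfig(**sim_kwargs)
            peaks, meta = simulate_glycome(sim_cfg)
            truth = sorted(planted_truth(sim_cfg))
            (out / "truth.json").write_text(json.dumps({"effect_peaks": truth}))
            summary["stages"]["data"] = {"source": "synthetic", "truth": truth}
        else:
            peaks = gio.read_peak_table(cfg["input"]["peaks"])
            meta = gio.read_metadata(cfg["input"]["metadata"])
            summary["stages"]["data"] = {"source": str(cfg["input"]["peaks"])}
        gio.write_peak_table(peaks, out / "peaks_raw.csv")
        gio.write_metadata(meta, out / "metadata.csv")
        summary["stages"]["data"].update(
            n_samples=peaks.n_samples, n_peaks=peaks.n_peaks,
            seconds=round(time.time() - t0, 3))

        # ----------------------------------------------------- preprocess
        stage = "preprocess"
        t0 = time.time()
        pp = cfg["preprocess"]
        current = peaks
        quotient_matrix = peaks  # positive-scale matrix for trait derivation
        if pp["enabled"]:
            if pp["combat"]:
                current, _ = combat_correct(current, meta,
                                            preserve_group=pp["preserve_group"])
            if pp["quotient"]:
                positive = current.values
                if (positive <= 0).any():
                    # batch correction can produce non-positive cells; shift
                    # is not meaningful for quotients, so normalize the raw
                    # compositional scale instead and carry the factors over
                    q_src = peaks
                else:
                    q_src = current
                normalized, factors = median_quotient_normalize(q_src)
                current = current.with_values(
                    current.values / factors[:, None], compositional=False)
                quotient_matrix = normalized
            ranked = rank_transform(current, mode=pp["rank_mode"]) if pp["rank"] else current
        else:
            ranked = current
        pca_table = pca_batch_check(ranked, meta)
        pca_table.to_csv(out / "pca_batch_check.csv", index=False)
        gio.write_peak_table(ranked, out / "peaks_processed.csv")
        summary["stages"]["preprocess"] = {
            "enabled": bool(pp["enabled"]),
            "pc1_batch_p": float(pca_table.loc[0, "p"]),
            "seconds": round(time.time() - t0, 3),
        }

        # ---------------------------------------------------------- traits
        stage = "traits"
        t0 = time.time()
        if cfg["input"].get("traits_file"):
            defs = gio.read_trait_definitions(cfg["input"]["traits_file"],
                                              panel=peaks.peak_ids)
        else:
            defs = default_trait_table(peaks.peak_ids)
        trait_source = quotient_matrix if pp["enabled"] else peaks
        traits = compute_traits(trait_source, defs)
        traits.to_frame().to_csv(out / "derived_traits.csv", index_label="sample_id")
        summary["stages"]["traits"] = {"n_traits": len(defs.trait_ids),
                                       "seconds": round(time.time() - t0, 3)}

        # ------------------------------------------------------ univariate
        stage = "univariate"
        t0 = time.time()
        corr = correlation_matrix(ranked.values, method=cfg["cluster"]["method"],
                                  names=list(ranked.peak_ids))
        dend, labels = ward_cluster(corr_distance(corr), k=cfg["cluster"]["k_peaks"],
                                    labels=ranked.peak_ids, precomputed=True)
        cluster_map = {pid: f"cluster{l}" for pid, l in zip(ranked.peak_ids, labels)}
        results, cluster_summaries = screen_features(
            ranked, meta, alpha=cfg["univariate"]["alpha"], clusters=cluster_map)
        results_frame(results).assign(
            cluster=[cluster_map[r.feature_id] for r in results]
        ).to_csv(out / "univariate_peaks.csv", index=False)
        (out / "peak_dendrogram.txt").write_text(dend.to_newick() + "\n")
        from glycoblock.cluster import clustered_image_map
        from glycoblock.viz import plot_cim
        row_d, col_d, reordered = clustered_image_map(
            corr, row_labels=ranked.peak_ids, col_labels=ranked.peak_ids)
        plot_cim(reordered,
                 [row_d.labels[i] for i in row_d.leaf_order],
                 [col_d.labels[i] for i in col_d.leaf_order],
                 out / "peak_correlation_cim.png",
                 title="Peak correlation signatures")
        summary["stages"]["univariate"] = {
            "n_significant_q05": int(sum(r.q < 0.05 for r in results)),
            "clusters": {c.cluster_id: {"K": c.K, "k": c.k} for c in cluster_summaries},
            "seconds": round(time.time() - t0, 3),
        }

        # ------------------------------------------------------- integrate
        stage = "integrate"
        t0 = time.time()
        icfg = cfg["integrate"]
        frames = {"peaks": ranked.to_frame(), "traits": traits.to_frame()}
        group_labels = meta.groups_for(ranked.sample_ids).astype(str)
        tr_idx, te_idx = split_train_test(group_labels,
                                          fraction=icfg["split_fraction"], seed=seed)
        tr_frames = {b: df.iloc[tr_idx] for b, df in frames.items()}
        te_frames = {b: df.iloc[te_idx] for b, df in frames.items()}
        model = fit_diablo(tr_frames, group_labels[tr_idx], keepx=icfg["keepx"],
                           n_dims=icfg["n_dims"])
        pred_tr = predict(model, tr_frames, distance=icfg["distance"])
        pred_te = predict(model, te_frames, distance=icfg["distance"])
        auc_train = rank_auc(pred_tr.scores, group_labels[tr_idx])
        auc_test = rank_auc(pred_te.scores, group_labels[te_idx])
        cv = cross_validate(frames, group_labels, folds=icfg["folds"],
                            repeats=icfg["repeats"], seed=seed,
                            keepx=icfg["keepx"], n_dims=icfg["n_dims"],
                            distance=icfg["distance"])
        (out / "sgcca_model.json").write_text(json.dumps(model.sgcca.to_dict()))
        from glycoblock.sgcca import rank_loadings
        from glycoblock.viz import plot_loadings
        for d in range(icfg["n_dims"]):
            loadings_table = rank_loadings(model.sgcca, "peaks", d=d,
                                           top=max(model.sgcca.keepx["peaks"]),
                                           groups=group_labels[tr_idx])
            loadings_table.to_csv(out / f"loadings_peaks_comp{d + 1}.csv", index=False)
            plot_loadings(loadings_table, out / f"loadings_peaks_comp{d + 1}.png",
                          title=f"Peak loadings, component {d + 1}")
        summary["stages"]["integrate"] = {
            "auc_train": float(auc_train), "auc_test": float(auc_test),
            "cv_balanced_error": float(cv["mean_balanced_error"]),
            "selected_peaks_comp1": rank_loadings(
                model.sgcca, "peaks", d=0,
                top=model.sgcca.keepx["peaks"][0])["variable"].tolist(),
            "seconds": round(time.time() - t0, 3),
        }

        # --------------------------------------------------------- network
        stage = "network"
        t0 = time.time()
        ncfg = cfg["network"]
        sims = similarity_matrix(model.sgcca, "peaks", "traits",
                                 n_dims_use=ncfg["n_dims_use"])
        net = build_network(sims, threshold=ncfg["threshold"],
                            blocks=("peaks", "traits"))
        gio.write_network(net, out / "relevance_network_edges.csv", format="edge-list")
        gio.write_network(net, out / "relevance_network.graphml", format="graphml")
        circos = circos_edges(frames, threshold=ncfg["threshold"],
                              groups=group_labels)
        circos.to_csv(out / "circos_edges.csv", index=False)
        summary["stages"]["network"] = {
            "n_edges": net.n_edges,
            "hubs": net.hubs(3) if net.n_edges else [],
            "n_circos_edges": int(len(circos)),
            "seconds": round(time.time() - t0, 3),
        }
    except GlycoblockError as exc:
        logger.error("stage %s failed: %s", stage, exc)
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        logger.removeHandler(handler)
        raise
    logger.removeHandler(handler)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
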