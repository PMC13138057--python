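"""End-to-end orchestration with a single validated config and one seed.

Stages (each skippable): simulate -> select -> fit -> map -> shift ->
associate -> tf_link.  Every stage writes its outputs plus a provenance
JSON (config hash, stage seed, package version) into the run directory;
outputs are deterministic functions of the config, so reruns are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import identity_drug_correlation
from .containers import ExpressionMatrix
from .io import (
    read_expression_tsv, read_gmt, read_mtx_bundle, read_model,
    write_expression_tsv, write_model, write_mtx_bundle,
)
from .mapping import map_cells, normalize_cells, profiles_to_frame
from .nmf import fit_identity_model
from .select import GeneSelectionConfig, select_salient_genes
from .shifts import chisq_residuals, cluster_contributions, identity_contingency
from .simulate import (
    generate_bulk, generate_drug_table, generate_single_cells, generate_tf_multiome,
)
from .tf import linkage_to_frame, tf_relevance_table

logger = logging.getLogger(__name__)

__all__ = ["validate_config", "run_pipeline", "stage_seed", "simulate_bundle"]

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "outdir", "stages", "simulate", "select", "fit", "map",
         "shift", "associate", "tf_link"},
    "simulate": {"n_genes", "n_samples", "k_true", "program_overlap",
                 "noise_sd", "shift_delta", "shift_identity",
                 "n_cells_per_condition", "mixture_alpha", "depth",
                 "n_drugs", "tf_cells_per_condition"},
    "select": {"expr", "anchor_gene", "mode", "min_samples", "min_max_expr",
               "min_range", "min_cluster_size", "min_centroid_dist",
               "min_separation", "basal_samples"},
    "fit": {"expr", "genes", "k", "k_grid", "n_restarts", "mixture_margin"},
    "map": {"model", "expr", "mtx", "features", "barcodes", "conditions",
            "clusters", "normalize"},
    "shift": {"control", "treated", "residual_type", "cluster_level"},
    "associate": {"drugs", "factor"},
    "tf_link": {"accessibility", "expr", "targets", "pathway", "control",
                "treatments", "focus_treatment"},
}

_STAGE_ORDER = ["simulate", "select", "fit", "map", "shift", "associate", "tf_link"]


def validate_config(config: Mapping[str, Any]) -> dict[str, Any]:
    """Schema-check a run config before any computation; unknown keys fail."""
    unknown = set(config) - _SCHEMA[""]
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _SCHEMA.items():
        if not section or section not in config:
            continue
        body = config[section]
        if body is None:
            continue
        if not isinstance(body, Mapping):
            raise ValueError(f"config section {section!r} must be a mapping")
        bad = set(body) - allowed
        if bad:
            raise ValueError(f"unknown keys in section {section!r}: {sorted(bad)}")
    if "outdir" not in config:
        raise ValueError("config requires an 'outdir'")
    return dict(config)


def stage_seed(seed: int, stage: str) -> int:
    """Fan one global seed out to a per-stage seed by stable hashing."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _provenance(outdir: Path, stage: str, config: Mapping, seed: int) -> None:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    doc = {
        "stage": stage,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "scidentity_version": __version__,
    }
    (outdir / f"{stage}.provenance.json").write_text(json.dumps(doc, indent=1))


def simulate_bundle(outdir: Path, params: Mapping[str, Any], seed: int) -> dict:
    """Generate the full fixture bundle and write it under ``outdir``."""
    bulk_kwargs = {
        k: params[k]
        for k in ("n_genes", "n_samples", "k_true", "program_overlap",
                  "noise_sd", "shift_delta", "shift_identity")
        if k in params
    }
    bulk, truth = generate_bulk(seed=seed, **bulk_kwargs)
    write_expression_tsv(bulk, outdir / "bulk.tsv")
    counts, labels = generate_single_cells(
        truth,
        n_cells_per_condition=params.get("n_cells_per_condition"),
        mixture_alpha=params.get("mixture_alpha", 50.0),
        depth=params.get("depth", 2000),
        seed=seed,
        normalize=False,
    )
    write_mtx_bundle(
        counts, outdir / "matrix.mtx", outdir / "features.tsv",
        outdir / "barcodes.tsv",
    )
    meta = pd.DataFrame(
        [
            {"cell_id": c, "condition": counts.condition_of(c),
             "cluster": counts.cluster_of(c)}
            for c in counts.column_ids
        ]
    )
    meta.to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)
    drugs = generate_drug_table(truth, n_drugs=params.get("n_drugs", 25), seed=seed)
    drugs.to_csv(outdir / "drugs.tsv", sep="\t", index_label="drug")
    truth_doc = {
        "k_true": truth.k_true,
        "anchor_gene": truth.anchor_gene,
        "marker_blocks": truth.marker_blocks,
        "condition_compositions": {
            c: list(map(float, v)) for c, v in truth.condition_compositions.items()
        },
        "drug_effect": truth.drug_effect,
        "tf_effect": truth.tf_effect,
        "seed": truth.seed,
        "cell_identity_labels": truth.cell_identity_labels,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_doc))
    return {"bulk": bulk, "truth": truth, "counts": counts, "labels": labels,
            "drugs": drugs}


def run_pipeline(config: Mapping[str, Any] | str | Path) -> Path:
    """Execute the configured stages; returns the run directory.

    Any stage error aborts the run with the stage name attached.  Stages
    not named in ``stages`` (default: every configured section) are
    skipped, and a stage can consume either the simulate outputs or the
    file inputs named in its own section.
    """
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    config = validate_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages") or [s for s in _STAGE_ORDER if s in config]
    ctx: dict[str, Any] = {}
    for stage in stages:
        try:
            _run_stage(stage, config, outdir, seed, ctx)
            _provenance(outdir, stage, config, stage_seed(seed, stage))
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return outdir


def _run_stage(stage: str, config: Mapping, outdir: Path, seed: int, ctx: dict) -> None:
    params = config.get(stage) or {}
    sseed = stage_seed(seed, stage)
    if stage == "simulate":
        ctx.update(simulate_bundle(outdir, params, sseed))
    elif stage == "select":
        expr = ctx.get("bulk")
        if expr is None:
            expr = read_expression_tsv(params["expr"])
        cfg_kwargs = {
            k: params[k]
            for k in ("anchor_gene", "mode", "min_samples", "min_max_expr",
                      "min_range", "min_cluster_size", "min_centroid_dist",
                      "min_separation")
            if k in params
        }
        cfg = GeneSelectionConfig(**cfg_kwargs)
        salient = select_salient_genes(
            expr, cfg, basal_samples=params.get("basal_samples")
        )
        rows = [{"gene": salient.anchor, "best_eps": "", "centroid_dist": "",
                 "min_sizes": "", "separation": ""}]
        for g in salient.genes[1:]:
            ev = salient.per_gene_evidence[g]
            rows.append({
                "gene": g, "best_eps": ev["best_eps"],
                "centroid_dist": ev["best_pair_centroid_dist"],
                "min_sizes": "x".join(map(str, ev["best_pair_min_sizes"])),
                "separation": ev["separation"],
            })
        pd.DataFrame(rows).to_csv(outdir / "salient_genes.tsv", sep="\t", index=False)
        ctx["salient"] = salient
        ctx["bulk"] = expr
    elif stage == "fit":
        expr = ctx.get("bulk")
        if expr is None:
            expr = read_expression_tsv(params["expr"])
        if "salient" in ctx:
            genes = ctx["salient"].genes
        elif "genes" in params:
            genes = pd.read_csv(params["genes"], sep="\t")["gene"].tolist()
        else:
            genes = expr.gene_ids
        sub = expr.subset_genes(genes)
        k_grid = params.get("k_grid", [4, 9])
        if isinstance(k_grid, str):
            lo, hi = map(int, k_grid.split(":"))
        else:
            lo, hi = int(k_grid[0]), int(k_grid[-1])
        model = fit_identity_model(
            sub, k_grid=range(lo, hi + 1),
            n_restarts=params.get("n_restarts", 10),
            seed=sseed,
            mixture_margin=params.get("mixture_margin", 0.10),
            k=params.get("k"),
        )
        write_model(model, outdir / "model.json")
        pd.Series(model.sample_labels, name="identity").rename_axis("sample") \
            .to_csv(outdir / "sample_labels.tsv", sep="\t")
        pd.Series(model.gene_groups, name="identity").rename_axis("gene") \
            .to_csv(outdir / "gene_groups.tsv", sep="\t")
        pd.Series(model.recon_err_by_k, name="recon_err").rename_axis("k") \
            .to_csv(outdir / "recon_err.tsv", sep="\t")
        ctx["model"] = model
    elif stage == "map":
        model = ctx.get("model")
        if model is None:
            model = read_model(params["model"])
        if "counts" in ctx:
            sc = ctx["counts"]
        elif "mtx" in params:
            sc = read_mtx_bundle(params["mtx"], params["features"], params["barcodes"])
        else:
            sc = read_expression_tsv(params["expr"])
        if params.get("conditions"):
            meta_df = pd.read_csv(params["conditions"], sep="\t").set_index("cell_id")
            meta = {
                c: {"condition": str(meta_df.loc[c, "condition"]),
                    "cluster": str(meta_df.loc[c].get("cluster", ""))}
                for c in sc.column_ids if c in meta_df.index
            }
            sc = ExpressionMatrix(sc.values, sc.gene_ids, sc.column_ids, meta)
        if params.get("normalize", True):
            sc = normalize_cells(sc)
        profiles = map_cells(sc, model)
        profiles_to_frame(profiles).to_csv(outdir / "cells.tsv", sep="\t", index=False)
        ctx["profiles"] = profiles
    elif stage == "shift":
        profiles = ctx["profiles"]
        pair = (params.get("control", "control"), params.get("treated", "treated"))
        table = identity_contingency(profiles, pair)
        result = chisq_residuals(
            table, residual_type=params.get("residual_type", "pearson")
        )
        shift_df = table.copy()
        shift_df["residual"] = [result.residual_scores[i] for i in table.index]
        shift_df.to_csv(outdir / "shift.tsv", sep="\t", index_label="identity")
        (outdir / "shift_stats.json").write_text(json.dumps({
            "chi2": result.chi2, "dof": result.dof, "p_value": result.p_value,
            "most_expanded": result.most_expanded,
        }))
        ctx["shift"] = result
        if params.get("cluster_level", True):
            try:
                contrib = cluster_contributions(profiles, result.most_expanded, pair)
                contrib.table.assign(
                    residual=[contrib.residual_scores[c] for c in contrib.table.index]
                ).to_csv(outdir / "cluster_shift.tsv", sep="\t", index_label="cluster")
            except ValueError as exc:
                logger.warning("cluster contributions skipped: %s", exc)
    elif stage == "associate":
        model = ctx["model"]
        if "drugs" in ctx:
            drugs = ctx["drugs"]
        else:
            drugs = pd.read_csv(params["drugs"], sep="\t", index_col=0)
        zrows = {
            name: dict(zip(model.sample_ids, model.H_zscores[i]))
            for i, name in enumerate(model.factor_names)
        }
        rows = []
        for drug in drugs.index:
            auc = drugs.loc[drug].to_dict()
            for name, z in zrows.items():
                try:
                    res = identity_drug_correlation(z, auc)
                except ValueError:
                    continue
                rows.append({
                    "kind": "auc_correlation", "drug": drug, "identity": name,
                    "pcc": res.pcc, "p_value": res.p_value,
                    "slope": res.slope, "intercept": res.intercept, "n": res.n,
                })
        pd.DataFrame(rows).to_csv(outdir / "associations.tsv", sep="\t", index=False)
        ctx["associations"] = rows
    elif stage == "tf_link":
        if "truth" in ctx:
            data = generate_tf_multiome(
                ctx["truth"],
                n_cells=(config.get("simulate") or {}).get("tf_cells_per_condition"),
                seed=sseed,
            )
            access, expr = data.accessibility, data.expr
            targets, pathway = data.targets, data.pathway_genes
        else:
            access = pd.read_csv(params["accessibility"], sep="\t", index_col=0)
            expr = read_expression_tsv(params["expr"]) if "expr" in params else None
            targets = {n: g for n, g in read_gmt(params["targets"]).sets.items()}
            pathway = next(iter(read_gmt(params["pathway"]).sets.values()))
        results = tf_relevance_table(
            access, expr, targets, pathway,
            control=params.get("control", "control"),
            treatments=params.get("treatments", ["treated"]),
            focus_treatment=params.get("focus_treatment"),
            seed=sseed,
        )
        linkage_to_frame(results).to_csv(outdir / "tf_table.tsv", sep="\t")
        ctx["tf_results"] = results
    else:
        raise ValueError(f"unknown stage {stage!r}")
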