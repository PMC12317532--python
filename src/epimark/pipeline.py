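"""Config-driven orchestration of the full analysis workflow.

A YAML (or dict) config names the input files, the contrasts with
their per-contrast |delta-beta| thresholds, and the region/enrichment
parameters; :func:`run_all` executes
filter -> (optional) quantile normalization -> per-contrast DMPs ->
DMRs -> promoter enrichment -> sample scores -> clock -> integration ->
overlaps, writing each stage's tables plus a summary JSON carrying the
config snapshot and SHA-256 hashes of every input. Reruns with the
same config and seed are bit-identical.
"""

from __future__ import annotations

import json
import logging
import os

import yaml

from . import clock as clock_mod
from . import dmp as dmp_mod
from . import integration as integ_mod
from . import io as io_mod
from . import preprocess
from . import regions as region_mod
from . import scores as score_mod

logger = logging.getLogger(__name__)


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _require_inputs(cfg: dict) -> None:
    for key in ("manifest", "beta_matrix", "sample_sheet"):
        path = cfg.get("inputs", {}).get(key)
        if not path:
            raise ValueError(f"config inputs.{key} is required")
        if not os.path.exists(path):
            raise FileNotFoundError(f"config input {key!r}: no such file {path}")
    for key, path in cfg.get("inputs", {}).items():
        if path and not os.path.exists(path):
            raise FileNotFoundError(f"config input {key!r}: no such file {path}")


def run_all(config: dict | str, out_dir: str) -> dict:
    """Execute every stage; returns the summary dict (also written to
    ``out_dir``/summary.json)."""
    cfg = load_config(config) if isinstance(config, str) else config
    _require_inputs(cfg)
    io_mod.ensure_dir(out_dir)
    inputs = cfg["inputs"]
    summary: dict = {
        "config": cfg,
        "input_hashes": {
            k: io_mod.sha256_of(v) for k, v in inputs.items() if v and os.path.exists(v)
        },
        "stages": {},
    }
    try:
        result = _run_stages(cfg, out_dir, summary)
    except Exception as exc:
        with open(os.path.join(out_dir, "FAILED"), "w") as fh:
            fh.write(f"{type(exc).__name__}: {exc}\n")
        raise
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(result, fh, indent=1, sort_keys=True, default=str)
    return result


def _run_stages(cfg: dict, out_dir: str, summary: dict) -> dict:
    inputs = cfg["inputs"]
    annot = io_mod.read_manifest(inputs["manifest"])
    betas = io_mod.read_beta_matrix(inputs["beta_matrix"], inputs.get("detection_p"))
    sheet = io_mod.read_sample_sheet(inputs["sample_sheet"])

    # -- filter -------------------------------------------------------
    kept, removed = preprocess.filter_probes(
        betas, annot, cfg.get("detection_p_max", 0.01)
    )
    betas = betas.subset_probes(kept)
    summary["stages"]["filter"] = {"kept": len(kept), "removed": removed}

    if cfg.get("quantile_normalize", False):
        betas = preprocess.quantile_normalize(betas)
        summary["stages"]["quantile_normalize"] = True

    m = preprocess.beta_to_m(betas)

    # -- DMPs ---------------------------------------------------------
    dmp_tables: dict[str, "object"] = {}
    for spec in cfg.get("contrasts", []):
        contrast = dmp_mod.ContrastSpec(
            tumor_group=spec["tumor"],
            normal_group=spec["normal"],
            covariates=tuple(spec.get("covariates", ("age", "location"))),
            adj_p_max=spec.get("adj_p_max", 0.01),
            delta_beta_min=spec.get("delta_beta_min", 0.10),
            use_raw_p=spec.get("use_raw_p", False),
        )
        label = f"{contrast.tumor_group}|{contrast.normal_group}"
        table = dmp_mod.run_contrast(betas, m, sheet, contrast)
        dmp_tables[label] = table
        dmp_mod.write_dmp_table(
            table, annot, os.path.join(out_dir, f"dmp_{label.replace('|', '_vs_')}.tsv")
        )
        summary["stages"].setdefault("dmp", {})[label] = {
            "n_tested": int(len(table)),
            "n_dmp": int(table["is_dmp"].sum()),
            "n_hyper": int((table["is_dmp"] & (table["direction"] == "hyper")).sum()),
            "n_hypo": int((table["is_dmp"] & (table["direction"] == "hypo")).sum()),
        }

    # -- DMRs + promoter enrichment -----------------------------------
    dmr_cfg = cfg.get("dmr", {})
    gsea_cfg = cfg.get("gsea", {})
    promoter_sets = (
        io_mod.read_promoter_sets(inputs["promoter_sets"])
        if inputs.get("promoter_sets")
        else annot.promoter_sets()
    )
    for label, table in dmp_tables.items():
        tag = label.replace("|", "_vs_")
        dmrs = region_mod.call_dmrs(
            table,
            annot,
            lambda_bp=dmr_cfg.get("lambda_bp", 1000),
            min_cpgs=dmr_cfg.get("min_cpgs", 2),
            meandiff_min=dmr_cfg.get("meandiff_min", 0.10),
        )
        region_mod.write_dmr_tables(
            dmrs,
            os.path.join(out_dir, f"dmr_{tag}.tsv"),
            os.path.join(out_dir, f"dmr_{tag}.bed"),
        )
        summary["stages"].setdefault("dmr", {})[label] = int(dmrs["is_dmr"].sum())
        if cfg.get("run_gsea", True) and promoter_sets:
            ranked = region_mod.rank_probes(table)
            gsea = region_mod.promoter_gsea(
                ranked,
                promoter_sets,
                min_cpgs=gsea_cfg.get("min_cpgs", 5),
                n_perm=gsea_cfg.get("n_perm", 1000),
                seed=cfg.get("seed", 0),
            )
            out = gsea.copy()
            out["leading_edge"] = out["leading_edge"].map(",".join)
            out.to_csv(os.path.join(out_dir, f"gsea_{tag}.tsv"), sep="\t")
            summary["stages"].setdefault("gsea", {})[label] = int(
                (gsea["p_adj"] < 0.05).sum()
            )

    # -- scores -------------------------------------------------------
    tumor_groups = tuple(s["tumor"] for s in cfg.get("contrasts", []))
    hm_probes: list[str] | None = None
    score_contrasts = cfg.get("hypermeth_contrasts") or [
        label for label in dmp_tables if label.split("|")[0].startswith("LS")
    ]
    if score_contrasts:
        try:
            hm_probes = score_mod.hypermeth_index_probes(
                {k: dmp_tables[k] for k in score_contrasts if k in dmp_tables}, annot
            )
        except ValueError as exc:
            logger.warning("hypermethylation index unavailable: %s", exc)
    panel = score_mod.build_score_panel(
        betas, annot, sheet, hm_probes, tumor_groups, cfg.get("panel_mb", 6.4)
    )
    panel.to_csv(os.path.join(out_dir, "score_panel.csv"))
    assoc = score_mod.score_associations(panel, sheet)
    with open(os.path.join(out_dir, "score_associations.json"), "w") as fh:
        json.dump(assoc, fh, indent=1, sort_keys=True)
    summary["stages"]["scores"] = {"n_samples": int(len(panel))}

    # -- clock --------------------------------------------------------
    if inputs.get("clock"):
        model = clock_mod.read_clock(inputs["clock"])
        ages = clock_mod.predict_dnam_age(
            betas, model, sheet, cfg.get("clock_missing_policy", "warn")
        )
        ages.to_csv(os.path.join(out_dir, "dnam_age.tsv"), sep="\t")
        report = clock_mod.age_delta_analysis(ages, sheet, cfg.get("split_age", 50))
        with open(os.path.join(out_dir, "dnam_age_report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        summary["stages"]["clock"] = {"n_samples": int(len(ages))}

    # -- integration --------------------------------------------------
    if inputs.get("expression"):
        expression = io_mod.read_matrix(inputs["expression"])
        groups = {
            g: ps for g, ps in promoter_sets.items() if g in set(expression.index)
        }
        if groups:
            mean_beta = integ_mod.probe_group_mean_beta(betas, groups)
            corr = integ_mod.meth_expr_correlation(mean_beta, expression)
            corr.to_csv(os.path.join(out_dir, "meth_expr_correlation.tsv"), sep="\t")
            summary["stages"]["integration"] = {
                "n_features": int(len(corr)),
                "n_significant_negative": int(corr["significant_negative"].sum()),
            }

    # -- overlaps -----------------------------------------------------
    if len(dmp_tables) >= 2:
        overlaps = integ_mod.pairwise_overlaps(dmp_tables)
        venn = integ_mod.multi_set_intersection(
            {
                label: set(t.index[t["is_dmp"]])
                for label, t in dmp_tables.items()
            }
        )
        with open(os.path.join(out_dir, "overlaps.json"), "w") as fh:
            json.dump(
                {
                    "pairwise": [
                        {
                            "a": o.label_a,
                            "b": o.label_b,
                            "n_a": o.n_a,
                            "n_b": o.n_b,
                            "intersection": o.intersection,
                            "concordant": o.concordant,
                        }
                        for o in overlaps
                    ],
                    "venn": integ_mod.venn_counts_json(venn),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        summary["stages"]["overlap"] = {"n_pairs": len(overlaps)}
    return summary
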