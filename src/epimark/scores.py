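"""Per-sample epigenetic and genomic biomarker scores.

* LINE-1 index — mean beta over probes mapping to evolutionarily young
  LINE-1 elements (surrogate for global hypomethylation; lower in
  tumors).
* Hypermethylation index — mean beta over probes hypermethylated in
  every tumor-vs-normal contrast of a family, restricted to CpG-island
  probes in promoter regions (5'UTR/TSS200/TSS1500/1stExon).
* CIMP — positive when at least 3 of 5 panel genes are hypermethylated.
* MSI — MSI when at least one of BAT25/BAT26 is unstable, MSS when both
  stable.
* TMB — significant somatic mutations per megabase of panel (default
  6.4 Mb); hypermutated strictly above 10/Mb.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    PROMOTER_REGIONS,
    BetaMatrix,
    ProbeAnnotationTable,
    SampleSheet,
)
from .stats import bh_adjust, kruskal_wallis, spearman, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

DEFAULT_PANEL_MB = 6.4
HYPERMUTATION_TMB = 10.0


def line1_index(betas: BetaMatrix, annot: ProbeAnnotationTable) -> pd.Series:
    """Mean beta over young-LINE-1 probes, per sample."""
    flagged = [p for p in betas.probe_ids if annot.table.loc[p, "line1_young"]]
    if not flagged:
        raise ValueError("no line1_young probes among kept probes")
    return betas.values.loc[flagged].mean(axis=0)


def hypermeth_index_probes(
    dmp_tables: dict[str, pd.DataFrame], annot: ProbeAnnotationTable
) -> list[str]:
    """Probes hypermethylated in *every* supplied contrast, on a CpG
    island, and in at least one promoter gene region."""
    if not dmp_tables:
        raise ValueError("need at least one contrast table")
    common: set[str] | None = None
    for table in dmp_tables.values():
        hyper = set(table.index[table["is_dmp"] & (table["direction"] == "hyper")])
        common = hyper if common is None else common & hyper
    ann = annot.table
    selected = [
        pid
        for pid in ann.index
        if pid in common
        and ann.loc[pid, "cgi_relation"] == "Island"
        and (ann.loc[pid, "gene_regions"] & PROMOTER_REGIONS)
    ]
    if not selected:
        raise ValueError(
            "no commonly hypermethylated promoter-island probes; review thresholds"
        )
    return selected


def hypermeth_index(betas: BetaMatrix, probe_set: list[str]) -> pd.Series:
    """Mean beta over the hypermethylation probe set, per sample."""
    if not probe_set:
        raise ValueError("empty probe set")
    return betas.values.loc[list(probe_set)].mean(axis=0)


def cimp_call(gene_statuses) -> bool | None:
    """CIMP positive when >= 3 of the 5 panel genes are hypermethylated.

    Returns None (logged) when statuses are missing.
    """
    if gene_statuses is None:
        logger.warning("CIMP statuses missing; call absent")
        return None
    statuses = list(gene_statuses)
    if len(statuses) != 5 or any(s is None for s in statuses):
        logger.warning("incomplete CIMP panel (%d statuses); call absent", len(statuses))
        return None
    return sum(bool(s) for s in statuses) >= 3


def msi_call(bat25: str | None, bat26: str | None) -> str | None:
    """MSI when >= 1 of the two markers is unstable; MSS when both stable."""
    if bat25 is None or bat26 is None:
        logger.warning("MSI marker missing; call absent")
        return None
    for name, v in (("BAT25", bat25), ("BAT26", bat26)):
        if v not in ("stable", "unstable"):
            raise ValueError(f"{name} status must be 'stable' or 'unstable', got {v!r}")
    return "MSI" if "unstable" in (bat25, bat26) else "MSS"


def tmb(mutation_count: int, panel_mb: float = DEFAULT_PANEL_MB) -> tuple[float, bool]:
    """Tumor mutation burden per Mb and the strict >10/Mb
    hypermutation call."""
    if mutation_count < 0:
        raise ValueError("mutation count must be nonnegative")
    if panel_mb <= 0:
        raise ValueError("panel size must be positive")
    value = mutation_count / panel_mb
    return value, value > HYPERMUTATION_TMB


def build_score_panel(
    betas: BetaMatrix,
    annot: ProbeAnnotationTable,
    sheet: SampleSheet,
    hypermeth_probes: list[str] | None = None,
    tumor_groups: tuple[str, ...] = (),
    panel_mb: float = DEFAULT_PANEL_MB,
) -> pd.DataFrame:
    """Assemble the per-sample biomarker panel.

    The hypermethylation index is reported for tumor-group samples only
    (when ``hypermeth_probes`` is given); CIMP/MSI/TMB fields are
    absent (NaN/None) where their inputs are missing.
    """
    t = sheet.table
    samples = [s for s in t.index if s in set(betas.sample_ids)]
    l1 = line1_index(betas.subset_samples(samples), annot)
    panel = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    panel["group"] = t.loc[samples, "group"]
    panel["line1_index"] = l1
    if hypermeth_probes:
        hm = hypermeth_index(betas.subset_samples(samples), hypermeth_probes)
        in_tumor = t.loc[samples, "group"].isin(tumor_groups) if tumor_groups else True
        panel["hypermeth_index"] = hm.where(in_tumor)
    cimp, msi, tmbs, hyper = [], [], [], []
    for s in samples:
        row = t.loc[s]
        cimp.append(cimp_call(row.get("cimp_gene_status")))
        msi.append(msi_call(row.get("msi_bat25"), row.get("msi_bat26")))
        count = row.get("somatic_mutation_count")
        if count is None or (isinstance(count, float) and np.isnan(count)):
            tmbs.append(np.nan)
            hyper.append(None)
        else:
            v, h = tmb(int(count), panel_mb)
            tmbs.append(v)
            hyper.append(h)
    panel["cimp_positive"] = cimp
    panel["msi_status"] = msi
    panel["tmb"] = tmbs
    panel["hypermutated"] = hyper
    return panel


def score_associations(
    panel: pd.DataFrame,
    sheet: SampleSheet,
    scores: tuple[str, ...] = ("line1_index", "hypermeth_index", "tmb"),
) -> dict:
    """Group comparisons and inter-score correlations.

    Per score: Kruskal-Wallis across groups (groups with < 2 usable
    samples excluded with a warning) and all pairwise Wilcoxon tests
    BH-adjusted within the pair family. Plus Spearman R/p for
    (line1 vs hypermeth), (tmb vs line1), (tmb vs hypermeth).
    """
    t = sheet.table
    report: dict = {"per_score": {}, "correlations": {}}
    for score in scores:
        if score not in panel.columns:
            continue
        values = panel[score]
        groups: dict[str, np.ndarray] = {}
        for g in sheet.groups():
            ids = [s for s in t.index[t["group"] == g] if s in values.index]
            vals = values.loc[ids].dropna().to_numpy(dtype=float)
            if vals.size < 2:
                if vals.size:
                    logger.warning("group %r has < 2 samples for %s; excluded", g, score)
                continue
            groups[g] = vals
        if len(groups) < 2:
            continue
        h, df, p_kw = kruskal_wallis(list(groups.values()))
        names = list(groups)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
        raw = [wilcoxon_rank_sum(groups[a], groups[b]) for a, b in pairs]
        adj = bh_adjust(raw)
        report["per_score"][score] = {
            "kruskal_wallis": {"H": h, "df": df, "p": p_kw},
            "pairwise_wilcoxon": {
                f"{a}|{b}": {"p_raw": pr, "p_adj": pa}
                for (a, b), pr, pa in zip(pairs, raw, list(adj))
            },
        }
    pairs = [
        ("line1_index", "hypermeth_index"),
        ("tmb", "line1_index"),
        ("tmb", "hypermeth_index"),
    ]
    for a, b in pairs:
        if a not in panel.columns or b not in panel.columns:
            continue
        sub = panel[[a, b]].dropna()
        if len(sub) < 3:
            continue
        r, p = spearman(sub[a].to_numpy(), sub[b].to_numpy())
        report["correlations"][f"{a}|{b}"] = {"r": r, "p": p, "n": int(len(sub))}
    return report
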