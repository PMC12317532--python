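"""Region-level differential methylation and promoter-set enrichment.

Differentially methylated regions are called by a transparent
seed-and-merge scheme: probes with a raw p below a seed threshold are
clustered along each chromosome while consecutive seeds lie within a
proximity bandwidth (default 1000 bp), the member p-values are combined
by a signed Stouffer sum, and candidate regions are kept when the
BH-adjusted combined p is below 0.05 and the mean member delta-beta
clears the threshold (0.10 / 0.15, or 0.08 for sensitive runs).

Promoter enrichment follows the rank-list GSEA recipe: a weighted
Kolmogorov-Smirnov running sum over probes ranked by M-value log2 fold
change, a permutation null over random same-size probe sets, NES
normalization by matching-sign null means, and leading-edge extraction.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .datatypes import ProbeAnnotationTable
from .stats import bh_adjust

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300


def stouffer_combine(p_values, signs) -> tuple[float, float]:
    """Signed Stouffer combination of two-sided p-values.

    z_i = sign_i * Phi^-1(1 - p_i / 2); z = sum(z_i) / sqrt(n);
    returns (z, two-sided p of |z|). Zero p-values are clipped to
    1e-300 with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    s = np.asarray(signs, dtype=float)
    if p.size != s.size or p.size == 0:
        raise ValueError("p_values and signs must be equal-length and nonempty")
    if not np.all(np.isin(s, (-1.0, 1.0))):
        raise ValueError("signs must be +1 or -1")
    if (p <= 0).any():
        warnings.warn("p-value of 0 clipped to 1e-300")
        p = np.clip(p, _P_FLOOR, None)
    if (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    z_i = s * _sps.norm.isf(p / 2.0)
    z = float(z_i.sum() / np.sqrt(p.size))
    p_comb = float(2.0 * _sps.norm.sf(abs(z)))
    return z, min(1.0, max(p_comb, _P_FLOOR))


def call_dmrs(
    dmps: pd.DataFrame,
    annot: ProbeAnnotationTable,
    lambda_bp: int = 1000,
    p_seed_max: float = 0.01,
    min_cpgs: int = 2,
    meandiff_min: float = 0.10,
    p_adj_max: float = 0.05,
) -> pd.DataFrame:
    """Cluster seed probes into candidate regions and score them.

    Returns one row per candidate cluster with chrom, start, end
    (1-based inclusive probe positions), n_cpgs, stouffer_z,
    p_stouffer, p_adj (BH over candidates), meandiff, genes, probe ids
    and the final ``is_dmr`` flag (p_adj < ``p_adj_max`` and
    |meandiff| > ``meandiff_min``).
    """
    ann = annot.table
    seeds = dmps[dmps["p_raw"] < p_seed_max]
    records = []
    for chrom, ids in _seed_clusters(seeds, ann, lambda_bp):
        if len(ids) < min_cpgs:
            continue
        sub = dmps.loc[ids]
        signs = np.where(sub["delta_beta"].to_numpy() > 0, 1.0, -1.0)
        z, p = stouffer_combine(sub["p_raw"].to_numpy(), signs)
        genes: set[str] = set()
        for pid in ids:
            genes |= set(ann.loc[pid, "gene_symbols"])
        records.append(
            {
                "chrom": chrom,
                "start": int(ann.loc[ids, "pos"].min()),
                "end": int(ann.loc[ids, "pos"].max()),
                "n_cpgs": len(ids),
                "stouffer_z": z,
                "p_stouffer": p,
                "meandiff": float(sub["delta_beta"].mean()),
                "genes": ",".join(sorted(genes)),
                "probes": ids,
            }
        )
    out = pd.DataFrame.from_records(records)
    if out.empty:
        return pd.DataFrame(
            columns=[
                "chrom", "start", "end", "n_cpgs", "stouffer_z", "p_stouffer",
                "p_adj", "meandiff", "genes", "probes", "is_dmr",
            ]
        )
    out["p_adj"] = bh_adjust(out["p_stouffer"].to_numpy())
    out["is_dmr"] = (out["p_adj"] < p_adj_max) & (out["meandiff"].abs() > meandiff_min)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _seed_clusters(seeds: pd.DataFrame, ann: pd.DataFrame, lambda_bp: int):
    """Yield (chrom, [probe ids]) clusters of seed probes whose
    consecutive genomic gaps are <= lambda_bp."""
    ids = [p for p in seeds.index if p in ann.index]
    if not ids:
        return
    sub = ann.loc[ids, ["chrom", "pos"]]
    for chrom, grp in sub.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        if not np.all(np.diff(pos) >= 0):
            warnings.warn(f"probes on {chrom} were not position-sorted; sorting")
        order = np.argsort(pos, kind="stable")
        sorted_ids = [grp.index[i] for i in order]
        sorted_pos = pos[order]
        cluster = [sorted_ids[0]]
        for i in range(1, len(sorted_ids)):
            if sorted_pos[i] - sorted_pos[i - 1] <= lambda_bp:
                cluster.append(sorted_ids[i])
            else:
                yield chrom, cluster
                cluster = [sorted_ids[i]]
        yield chrom, cluster


def rank_probes(dmps: pd.DataFrame) -> pd.Series:
    """Probes ordered by descending M-value log2 fold change; ties
    broken by probe id (lexicographic)."""
    scores = dmps["log2fc_m"]
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("non-finite log2fc_m")
    order = sorted(scores.index, key=lambda pid: (-scores[pid], pid))
    return scores.loc[order]


def _running_es(ranked_scores: np.ndarray, member_mask: np.ndarray) -> tuple[float, int]:
    """Weighted KS running sum (weight = |score|, exponent 1).

    Returns (enrichment score, 0-based index of the extremum).
    """
    n = ranked_scores.size
    n_hit = int(member_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must be a proper nonempty subset of the ranked list")
    w = np.abs(ranked_scores) * member_mask
    w_sum = w.sum()
    if w_sum == 0:
        w = member_mask.astype(float)
        w_sum = w.sum()
    hit = np.cumsum(w / w_sum)
    miss = np.cumsum((~member_mask) / float(n - n_hit))
    running = hit - miss
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        return float(running[i_max]), i_max
    return float(running[i_min]), i_min


@dataclass
class PromoterSetResult:
    gene: str
    n_cpgs: int
    es: float
    nes: float
    p_perm: float
    p_adj: float
    leading_edge: list[str]


def promoter_gsea(
    ranked: pd.Series,
    promoter_sets: dict[str, list[str]],
    min_cpgs: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """GSEA-style promoter enrichment over a ranked probe list.

    Sets with fewer than ``min_cpgs`` members present in the list are
    excluded before testing. The permutation null draws random
    same-size probe sets; each gene gets an independent substream
    derived from ``seed`` and the gene name, so results do not depend
    on evaluation order. NES divides the observed score by the mean
    |null| score of matching sign; p_perm = (1 + #null as-or-more
    extreme, same sign) / (1 + #same-sign nulls); BH across genes.
    """
    probe_ids = np.asarray(ranked.index)
    scores = ranked.to_numpy(dtype=float)
    index_of = {pid: i for i, pid in enumerate(probe_ids)}
    n = probe_ids.size
    results = []
    for gene in sorted(promoter_sets):
        members = [p for p in promoter_sets[gene] if p in index_of]
        if not members:
            logger.warning("promoter set %r has no probes in the ranked list; skipped", gene)
            continue
        if len(members) < min_cpgs:
            continue
        mask = np.zeros(n, dtype=bool)
        mask[[index_of[p] for p in members]] = True
        es, i_ext = _running_es(scores, mask)
        if es >= 0:
            le = [probe_ids[i] for i in range(i_ext + 1) if mask[i]]
        else:
            le = [probe_ids[i] for i in range(i_ext, n) if mask[i]]
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, zlib.crc32(gene.encode())])
        )
        k = len(members)
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            null_mask = np.zeros(n, dtype=bool)
            null_mask[rng.choice(n, size=k, replace=False)] = True
            null_es[b], _ = _running_es(scores, null_mask)
        same_sign = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            nes = np.nan
            p_perm = 1.0 / (1.0 + n_perm)
        else:
            nes = es / float(np.abs(null_es[same_sign]).mean())
            extreme = int((np.abs(null_es[same_sign]) >= abs(es)).sum())
            p_perm = (1.0 + extreme) / (1.0 + n_same)
        results.append(
            PromoterSetResult(gene, k, es, nes, p_perm, np.nan, list(le))
        )
    if not results:
        return pd.DataFrame(
            columns=["n_cpgs", "es", "nes", "p_perm", "p_adj", "leading_edge"]
        )
    out = pd.DataFrame(
        {
            "n_cpgs": [r.n_cpgs for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "p_perm": [r.p_perm for r in results],
            "leading_edge": [r.leading_edge for r in results],
        },
        index=pd.Index([r.gene for r in results], name="gene"),
    )
    out["p_adj"] = bh_adjust(out["p_perm"].to_numpy())
    return out[["n_cpgs", "es", "nes", "p_perm", "p_adj", "leading_edge"]]


def write_dmr_tables(dmrs: pd.DataFrame, tsv_path: str, bed_path: str | None = None) -> None:
    cols = ["chrom", "start", "end", "n_cpgs", "stouffer_z", "p_stouffer", "p_adj", "meandiff", "genes", "is_dmr"]
    dmrs[cols].to_csv(tsv_path, sep="\t", index=False, float_format="%.6g")
    if bed_path:
        from .io import write_bed

        kept = dmrs[dmrs["is_dmr"]].copy()
        kept["name"] = kept["genes"].replace("", ".")
        write_bed(kept, bed_path)
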