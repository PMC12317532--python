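"""Methylation-expression integration and cross-comparison overlap.

Couples per-feature averaged beta (over DMR members or leading-edge
probes) with gene expression by Spearman correlation, flags features
whose methylation and expression are significantly negatively
correlated (BH-adjusted P < 0.05), and provides probe-set overlap,
Venn-partition counting and a database-agnostic hypergeometric
over-representation test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .datatypes import BetaMatrix
from .stats import bh_adjust, spearman

logger = logging.getLogger(__name__)


def probe_group_mean_beta(
    betas: BetaMatrix, groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-feature, per-sample mean beta over each feature's probe set.

    Features with no surviving probes are dropped with a warning.
    """
    if not groups:
        raise ValueError("no probe groups supplied")
    known = set(betas.probe_ids)
    rows = {}
    for feature, probes in groups.items():
        keep = [p for p in probes if p in known]
        if not keep:
            logger.warning("feature %r has no surviving probes; dropped", feature)
            continue
        rows[feature] = betas.values.loc[keep].mean(axis=0)
    if not rows:
        raise ValueError("every feature lost all probes")
    return pd.DataFrame(rows).T


def meth_expr_correlation(
    mean_beta: pd.DataFrame,
    expression: pd.DataFrame,
    feature_to_gene: dict[str, str] | None = None,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of feature methylation against gene
    expression over shared samples.

    ``feature_to_gene`` maps feature ids to expression rows (identity
    by default). Features whose gene is absent are skipped with a log
    line. BH across all tested features; ``significant_negative`` is
    r < 0 with adjusted P < 0.05.
    """
    records = []
    for feature in mean_beta.index:
        gene = feature_to_gene.get(feature, feature) if feature_to_gene else feature
        if gene not in expression.index:
            logger.warning("gene %r absent from expression matrix; skipped", gene)
            continue
        shared = [s for s in mean_beta.columns if s in expression.columns]
        mb = mean_beta.loc[feature, shared].to_numpy(dtype=float)
        ex = expression.loc[gene, shared].to_numpy(dtype=float)
        ok = ~(np.isnan(mb) | np.isnan(ex))
        if ok.sum() < min_samples:
            logger.warning("feature %r has < %d shared samples; skipped", feature, min_samples)
            continue
        r, p = spearman(mb[ok], ex[ok])
        records.append((feature, gene, int(ok.sum()), r, p))
    if not records:
        return pd.DataFrame(
            columns=["gene", "n_samples", "spearman_r", "p_raw", "p_adj", "significant_negative"]
        )
    out = pd.DataFrame(
        records, columns=["feature", "gene", "n_samples", "spearman_r", "p_raw"]
    ).set_index("feature")
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant_negative"] = (out["spearman_r"] < 0) & (out["p_adj"] < 0.05)
    return out


@dataclass
class OverlapResult:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    intersection: int
    concordant: int

    @property
    def concordance_fraction(self) -> float:
        return self.concordant / self.intersection if self.intersection else float("nan")


def overlap_dmps(
    a: pd.DataFrame, b: pd.DataFrame, label_a: str = "a", label_b: str = "b"
) -> OverlapResult:
    """Overlap of significant probes between two DMP tables, with a
    count of direction-concordant shared probes."""
    sig_a = a[a["is_dmp"]]
    sig_b = b[b["is_dmp"]]
    shared = sig_a.index.intersection(sig_b.index)
    concordant = int(
        (sig_a.loc[shared, "direction"].to_numpy() == sig_b.loc[shared, "direction"].to_numpy()).sum()
    )
    return OverlapResult(
        label_a, label_b, len(sig_a), len(sig_b), len(shared), concordant
    )


def multi_set_intersection(sets: dict[str, set]) -> dict[frozenset, int]:
    """Venn-partition counts over >= 2 named sets.

    Returns {frozenset of member labels: count}; partitions are
    disjoint and sum to the union size.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    union = set().union(*sets.values())
    counts: dict[frozenset, int] = {}
    for item in union:
        key = frozenset(label for label, s in sets.items() if item in s)
        counts[key] = counts.get(key, 0) + 1
    return counts


def venn_counts_json(counts: dict[frozenset, int]) -> dict[str, int]:
    return {"&".join(sorted(k)): v for k, v in sorted(counts.items(), key=lambda kv: "&".join(sorted(kv[0])))}


def gene_set_overrepresentation(
    hits: set[str], universe: set[str], sets: dict[str, set[str]]
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``hits`` in each
    gene set, BH-adjusted across sets.

    p = P(overlap >= observed) drawing |hits| genes from the universe.
    """
    if not hits <= universe:
        raise ValueError(f"hits outside universe: {sorted(hits - universe)[:3]}")
    n_univ = len(universe)
    n_hits = len(hits)
    records = []
    for name in sorted(sets):
        members = sets[name] & universe
        k = len(hits & members)
        # sf(k-1) = P(X >= k)
        p = float(_sps.hypergeom.sf(k - 1, n_univ, len(members), n_hits))
        records.append((name, len(members), k, min(max(p, 1e-300), 1.0)))
    out = pd.DataFrame(records, columns=["set", "set_size", "overlap", "p_raw"]).set_index("set")
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def pairwise_overlaps(tables: dict[str, pd.DataFrame]) -> list[OverlapResult]:
    """All pairwise DMP-table overlaps among named comparisons."""
    labels = list(tables)
    return [
        overlap_dmps(tables[a], tables[b], a, b)
        for a, b in itertools.combinations(labels, 2)
    ]
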