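"""Beta/M conversion, probe filtering, quantile normalization and
most-variable-probe selection."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import BetaMatrix, MValueMatrix, ProbeAnnotationTable

DEFAULT_EPSILON = 1e-6

#: probe-removal criteria, applied in order; a removed probe is
#: attributed to the first criterion it matches
FILTER_CRITERIA = (
    "detection_p",
    "cross_reactive",
    "sex_chromosome",
    "non_cpg",
    "snp_masked",
)


def beta_to_m(beta, epsilon: float = DEFAULT_EPSILON):
    """logit2 transform: M = log2(b / (1 - b)) with b clipped to
    [epsilon, 1 - epsilon] so M stays finite.

    Accepts scalars, arrays, DataFrames or a BetaMatrix (returning an
    MValueMatrix in that case).
    """
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must lie in (0, 0.5)")
    if isinstance(beta, BetaMatrix):
        return MValueMatrix(beta_to_m(beta.values, epsilon))
    arr = np.asarray(beta, dtype=float)
    if arr.size and (np.nanmin(arr) < 0 or np.nanmax(arr) > 1):
        raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, epsilon, 1 - epsilon)
    m = np.log2(clipped / (1 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse logit2: beta = 2^m / (1 + 2^m)."""
    arr = np.asarray(m, dtype=float)
    # 2^m/(1+2^m) computed stably via the logistic of m*log(2)
    b = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if np.isscalar(m):
        return float(b)
    return b


def filter_probes(
    betas: BetaMatrix,
    annot: ProbeAnnotationTable,
    detection_p_max: float = 0.01,
    sex_chromosomes: tuple[str, ...] = ("chrX", "chrY", "X", "Y"),
) -> tuple[list[str], dict[str, int]]:
    """Apply the standard EPIC-array probe filters.

    Removes, in order, probes (1) with detection P >= ``detection_p_max``
    in at least one sample, (2) flagged cross-reactive, (3) on the sex
    chromosomes, (4) not interrogating a CpG, (5) SNP-masked. Each
    removed probe is counted under the first criterion it fails.

    Returns the surviving probe ids in manifest order plus the
    per-criterion removal counts.
    """
    ann = annot.table.loc[[p for p in annot.probe_ids if p in set(betas.probe_ids)]]
    counts = {c: 0 for c in FILTER_CRITERIA}
    kept: list[str] = []
    failed_detection: set[str] = set()
    if betas.detection_p is not None:
        dp = betas.detection_p
        bad = (dp.to_numpy(dtype=float) >= detection_p_max).any(axis=1)
        failed_detection = set(dp.index[bad])
    for pid, row in ann.iterrows():
        if pid in failed_detection:
            counts["detection_p"] += 1
        elif row["cross_reactive"]:
            counts["cross_reactive"] += 1
        elif row["chrom"] in sex_chromosomes:
            counts["sex_chromosome"] += 1
        elif not row["is_cpg"]:
            counts["non_cpg"] += 1
        elif row["snp_masked"]:
            counts["snp_masked"] += 1
        else:
            kept.append(pid)
    if not kept:
        raise ValueError("all probes filtered")
    return kept, counts


def quantile_normalize(betas: BetaMatrix) -> BetaMatrix:
    """Across-sample quantile normalization.

    Every sample column is mapped onto the mean of the per-column order
    statistics; ties within a column receive the mean of their target
    quantiles (mid-rank interpolation).
    """
    v = betas.values
    if v.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    arr = v.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("missing values present; impute before normalizing")
    n = arr.shape[0]
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    positions = np.arange(n, dtype=float)
    for j in range(arr.shape[1]):
        ranks = rankdata(arr[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, positions, reference)
    return BetaMatrix(
        pd.DataFrame(out, index=v.index, columns=v.columns),
        betas.detection_p,
    )


def most_variable_probes(betas: BetaMatrix, n: int = 1000) -> list[str]:
    """The ``n`` probes with the largest across-sample variance of beta,
    ties broken by row (manifest) order."""
    if n > len(betas.probe_ids):
        raise ValueError(f"n={n} exceeds probe count {len(betas.probe_ids)}")
    var = betas.values.to_numpy(dtype=float).var(axis=1, ddof=1)
    order = np.argsort(-var, kind="stable")[:n]
    return [betas.probe_ids[i] for i in order]
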