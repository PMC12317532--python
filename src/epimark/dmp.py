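"""Per-probe differential methylation with empirical-Bayes variance
moderation.

The model is the standard array workflow: an ordinary least squares fit
of M values on a design matrix (intercept, group indicator, optional
age and colon-location covariates) per probe, followed by shrinkage of
the residual variances toward a common prior estimated by moment
matching of log s^2 (digamma/trigamma inversion), a moderated t with
d0 + d degrees of freedom, Benjamini-Hochberg adjustment across probes,
and the dual significance rule: adjusted P below the cut-off AND an
absolute group difference of mean beta above the |delta-beta|
threshold (0.10 for low-grade / normal-normal comparisons, 0.15 for
high-grade and carcinoma comparisons).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps
from scipy.special import digamma, polygamma

from .datatypes import BetaMatrix, MValueMatrix, ProbeAnnotationTable, SampleSheet
from .stats import bh_adjust

logger = logging.getLogger(__name__)

#: prior df above this cap is reported as infinite
D0_CAP = 1e6


@dataclass
class ContrastSpec:
    """A tumor-vs-normal (or normal-vs-normal) group contrast."""

    tumor_group: str
    normal_group: str
    covariates: tuple[str, ...] = ("age", "location")
    adj_p_max: float = 0.01
    delta_beta_min: float = 0.10
    use_raw_p: bool = False

    def __post_init__(self) -> None:
        if self.tumor_group == self.normal_group:
            raise ValueError("contrast groups must be distinct")
        if self.adj_p_max <= 0 or self.delta_beta_min <= 0:
            raise ValueError("thresholds must be positive")
        unknown = set(self.covariates) - {"age", "location"}
        if unknown:
            raise ValueError(f"unknown covariates: {sorted(unknown)}")


@dataclass
class ProbeFitResult:
    """Per-probe OLS output prior to moderation."""

    probe_ids: list[str]
    coef: np.ndarray
    residual_sd: np.ndarray
    residual_df: int
    unscaled_var: float  # c^T (X^T X)^{-1} c


@dataclass
class ModeratedStats:
    d0: float
    s0_sq: float
    posterior_sd: np.ndarray
    t_moderated: np.ndarray
    p_raw: np.ndarray
    df_total: float
    zero_variance_flag: np.ndarray = field(default_factory=lambda: np.array([], bool))


def build_design(
    sheet: SampleSheet, contrast: ContrastSpec
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Design matrix for one contrast: intercept, group indicator
    (tumor = 1), centered age, location indicator (distal = 1).

    Constant covariate columns are dropped with a logged warning.
    Returns (design, contrast vector, sample ids in design row order).
    """
    t = sheet.table
    samples = [
        s
        for s in t.index
        if t.loc[s, "group"] in (contrast.normal_group, contrast.tumor_group)
    ]
    if not samples:
        raise ValueError("no samples in either contrast group")
    sub = t.loc[samples]
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(samples)),
        "group": (sub["group"] == contrast.tumor_group).to_numpy(dtype=float),
    }
    if "age" in contrast.covariates:
        age = sub["age_at_sampling"].to_numpy(dtype=float)
        if np.isnan(age).any():
            bad = sub.index[np.isnan(age)][0]
            raise ValueError(f"sample {bad!r} is missing age_at_sampling")
        cols["age"] = age - age.mean()
    if "location" in contrast.covariates:
        if "location" not in sub.columns or sub["location"].isna().any():
            missing = (
                sub.index[sub["location"].isna()][0]
                if "location" in sub.columns
                else samples[0]
            )
            raise ValueError(f"sample {missing!r} is missing location")
        cols["location"] = (sub["location"] == "distal").to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=samples)
    for col in list(design.columns):
        if col in ("intercept", "group"):
            continue
        if np.ptp(design[col].to_numpy()) == 0:
            logger.warning("covariate %r is constant; dropped from design", col)
            design = design.drop(columns=[col])
    if np.ptp(design["group"].to_numpy()) == 0:
        raise ValueError("both contrast groups must be present")
    contrast_vec = np.zeros(design.shape[1])
    contrast_vec[list(design.columns).index("group")] = 1.0
    return design, contrast_vec, samples


def fit_probe_models(
    m: MValueMatrix, design: pd.DataFrame, contrast_vec: np.ndarray
) -> ProbeFitResult:
    """Ordinary least squares per probe, vectorized across probes."""
    x = design.to_numpy(dtype=float)
    n, k = x.shape
    if n < k + 1:
        raise ValueError("need more samples than design columns")
    y = m.values[list(design.index)].to_numpy(dtype=float)  # probes x samples
    xtx_inv = np.linalg.inv(x.T @ x)
    rank = np.linalg.matrix_rank(x)
    if rank < k:
        raise ValueError("design matrix is rank deficient")
    beta = y @ x @ xtx_inv.T  # probes x k
    resid = y - beta @ x.T
    df = n - rank
    if df <= 0:
        raise ValueError("residual degrees of freedom <= 0")
    rss = (resid**2).sum(axis=1)
    sigma = np.sqrt(rss / df)
    coef = beta @ contrast_vec
    unscaled_var = float(contrast_vec @ xtx_inv @ contrast_vec)
    return ProbeFitResult(
        probe_ids=list(m.probe_ids),
        coef=coef,
        residual_sd=sigma,
        residual_df=df,
        unscaled_var=unscaled_var,
    )


def _trigamma(x):
    return polygamma(1, x)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(_trigamma(x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return x


def estimate_prior(residual_sd: np.ndarray, residual_df: int) -> tuple[float, float]:
    """Moment-matching estimate of the prior df d0 and prior variance
    s0^2 of the scaled inverse-chi-square variance model.

    Probes with zero residual variance are excluded from estimation.
    Returns (d0, s0_sq); d0 = inf (capped at 1e6) when log s^2 shows no
    excess dispersion.
    """
    s_sq = np.asarray(residual_sd, dtype=float) ** 2
    s_sq = s_sq[s_sq > 0]
    if s_sq.size == 0:
        raise ValueError("degenerate variance distribution: all residual sds zero")
    d = residual_df
    z = np.log(s_sq)
    e = z - float(digamma(d / 2.0)) + math.log(d / 2.0)
    e_mean = float(e.mean())
    n = e.size
    if n < 2:
        return math.inf, float(np.mean(s_sq))
    e_var = float(((e - e_mean) ** 2).sum() / (n - 1))
    excess = e_var - float(_trigamma(d / 2.0))
    if excess <= 0:
        # no excess dispersion of log s^2: fully pooled variance
        d0 = math.inf
        s0_sq = float(np.mean(s_sq))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        if d0 > D0_CAP:
            d0 = math.inf
            s0_sq = float(np.mean(s_sq))
        else:
            s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - math.log(d0 / 2.0)))
    return d0, s0_sq


def moderate_variances(
    fit: ProbeFitResult, d0: float | None = None, s0_sq: float | None = None
) -> ModeratedStats:
    """Shrink per-probe variances toward the prior and compute the
    moderated t and its two-sided p.

    ``d0``/``s0_sq`` may be forced (d0 = 0 reproduces the ordinary t;
    d0 = inf gives the fully pooled normal reference); by default they
    are estimated from the data.
    """
    s_sq = fit.residual_sd.astype(float) ** 2
    d = fit.residual_df
    if d0 is None:
        d0, s0_est = estimate_prior(fit.residual_sd, d)
        if s0_sq is None:
            s0_sq = s0_est
    elif s0_sq is None:
        if d0 == 0:
            s0_sq = float(np.mean(s_sq[s_sq > 0])) if (s_sq > 0).any() else 1.0
        else:
            _, s0_sq = estimate_prior(fit.residual_sd, d)
    zero_flag = s_sq == 0
    if d0 == 0:
        post_sq = s_sq.copy()
        post_sq[zero_flag] = s0_sq  # flagged: no within-probe variance signal
        df_total: float = float(d)
    elif math.isinf(d0):
        post_sq = np.full_like(s_sq, s0_sq)
        df_total = math.inf
    else:
        post_sq = (d0 * s0_sq + d * s_sq) / (d0 + d)
        df_total = float(d0 + d)
    post_sd = np.sqrt(post_sq)
    se = post_sd * math.sqrt(fit.unscaled_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fit.coef / se, 0.0)
    if math.isinf(df_total):
        p = 2.0 * _sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * _sps.t.sf(np.abs(t), df_total)
    return ModeratedStats(
        d0=d0,
        s0_sq=float(s0_sq),
        posterior_sd=post_sd,
        t_moderated=t,
        p_raw=np.clip(p, 1e-300, 1.0),
        df_total=df_total,
        zero_variance_flag=zero_flag,
    )


def group_mean_delta_beta(
    betas: BetaMatrix, sheet: SampleSheet, contrast: ContrastSpec
) -> pd.Series:
    """Covariate-unadjusted delta beta: mean beta(tumor) - mean beta(normal)."""
    tumor = sheet.samples_in_group(contrast.tumor_group)
    normal = sheet.samples_in_group(contrast.normal_group)
    v = betas.values
    return v[tumor].mean(axis=1) - v[normal].mean(axis=1)


def call_dmps(
    fit: ProbeFitResult,
    stats: ModeratedStats,
    delta_beta: pd.Series,
    contrast: ContrastSpec,
) -> pd.DataFrame:
    """Assemble the per-probe result table and apply the dual rule.

    Columns: log2fc_m, delta_beta, t, df_total, p_raw, p_adj,
    direction, is_dmp. BH is computed over all tested probes.
    """
    if set(fit.probe_ids) != set(delta_beta.index):
        raise ValueError("probe sets of fit and delta_beta disagree")
    db = delta_beta.reindex(fit.probe_ids).to_numpy(dtype=float)
    p_adj = bh_adjust(stats.p_raw)
    p_crit = stats.p_raw if contrast.use_raw_p else p_adj
    is_dmp = (p_crit < contrast.adj_p_max) & (np.abs(db) > contrast.delta_beta_min)
    out = pd.DataFrame(
        {
            "log2fc_m": fit.coef,
            "delta_beta": db,
            "t": stats.t_moderated,
            "df_total": stats.df_total,
            "p_raw": stats.p_raw,
            "p_adj": p_adj,
            "direction": np.where(db > 0, "hyper", "hypo"),
            "is_dmp": is_dmp,
        },
        index=pd.Index(fit.probe_ids, name="probe_id"),
    )
    return out


def run_contrast(
    betas: BetaMatrix,
    m: MValueMatrix,
    sheet: SampleSheet,
    contrast: ContrastSpec,
) -> pd.DataFrame:
    """End-to-end DMP analysis for one contrast (design, OLS,
    moderation, dual-rule calling)."""
    design, cvec, _ = build_design(sheet, contrast)
    fit = fit_probe_models(m, design, cvec)
    stats = moderate_variances(fit)
    db = group_mean_delta_beta(betas, sheet, contrast)
    return call_dmps(fit, stats, db, contrast)


def stratify_dmps(
    dmps: pd.DataFrame, annot: ProbeAnnotationTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count DMPs by direction x CGI relation and direction x gene
    region.

    A probe annotated to several gene regions is counted once per
    region (multi-counting); an unannotated probe counts under
    'intergenic'. The CGI table partitions the DMP set.
    """
    hits = dmps[dmps["is_dmp"]]
    missing = set(hits.index) - set(annot.probe_ids)
    if missing:
        raise ValueError(f"DMP probe(s) missing from annotation: {sorted(missing)[:3]}")
    from .datatypes import CGI_RELATIONS, GENE_REGIONS

    cgi = pd.DataFrame(0, index=list(CGI_RELATIONS), columns=["hyper", "hypo"])
    region = pd.DataFrame(0, index=[*GENE_REGIONS, "intergenic"], columns=["hyper", "hypo"])
    ann = annot.table
    for pid, row in hits.iterrows():
        direction = row["direction"]
        cgi.loc[ann.loc[pid, "cgi_relation"], direction] += 1
        regions = ann.loc[pid, "gene_regions"]
        if regions:
            for r in regions:
                region.loc[r, direction] += 1
        else:
            region.loc["intergenic", direction] += 1
    return cgi, region


def write_dmp_table(
    dmps: pd.DataFrame, annot: ProbeAnnotationTable, path: str
) -> None:
    out = dmps.copy()
    out.insert(0, "chrom", annot.table.loc[out.index, "chrom"])
    out.insert(1, "pos", annot.table.loc[out.index, "pos"])
    cols = ["chrom", "pos", "log2fc_m", "delta_beta", "t", "p_raw", "p_adj", "direction", "is_dmp"]
    out[cols].to_csv(path, sep="\t", index_label="probe_id", float_format="%.6g")
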