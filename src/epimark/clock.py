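"""Epigenetic-clock age prediction.

A clock is a penalized-regression model: DNAm age is the inverse of
the adult-calibrated age transform applied to
``intercept + sum_k w_k * beta_k`` over the clock CpGs. The transform
is logarithmic below the adult age (default 20 years) and linear above
it, so that prediction error is roughly proportional on the juvenile
scale and additive on the adult scale:

    F(age)  = log((age + 1) / (adult + 1))        for age <= adult
            = (age - adult) / (adult + 1)         for age >  adult

The module reads/writes clock coefficient CSVs (an ``(Intercept)`` row
plus probe_id/coefficient rows), predicts DNAm age with configurable
handling of probes lost to filtering, and reproduces the delta
(DNAm age minus chronological age) analyses: per-group Spearman
correlation, young-vs-old delta comparison, and stratification by
colon location.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, SampleSheet
from .stats import spearman, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

DEFAULT_ADULT_AGE = 20.0


def age_transform(age, adult_age: float = DEFAULT_ADULT_AGE):
    """Adult-calibrated age transform; F(adult_age) = 0, strictly
    increasing and continuous. Domain: age > -1."""
    arr = np.asarray(age, dtype=float)
    if np.any(arr <= -1):
        raise ValueError("age must be greater than -1")
    out = np.where(
        arr <= adult_age,
        np.log((arr + 1.0) / (adult_age + 1.0)),
        (arr - adult_age) / (adult_age + 1.0),
    )
    return float(out) if np.isscalar(age) else out


def age_anti_transform(x, adult_age: float = DEFAULT_ADULT_AGE):
    """Inverse of :func:`age_transform`."""
    arr = np.asarray(x, dtype=float)
    out = np.where(
        arr < 0,
        (1.0 + adult_age) * np.exp(arr) - 1.0,
        (1.0 + adult_age) * arr + adult_age,
    )
    return float(out) if np.isscalar(x) else out


@dataclass
class ClockModel:
    """Linear clock: intercept + per-probe beta weights."""

    intercept: float
    coefficients: dict[str, float]
    adult_age: float = DEFAULT_ADULT_AGE

    def __post_init__(self) -> None:
        if not self.coefficients:
            raise ValueError("clock needs at least one coefficient")
        if self.adult_age <= 0:
            raise ValueError("adult_age must be positive")


def read_clock(path: str) -> ClockModel:
    """Read a clock CSV with columns (probe_id, coefficient) and an
    '(Intercept)' row."""
    df = pd.read_csv(path)
    if not {"probe_id", "coefficient"} <= set(df.columns):
        raise ValueError("clock CSV needs probe_id and coefficient columns")
    inter = df[df["probe_id"] == "(Intercept)"]
    if len(inter) != 1:
        raise ValueError("clock CSV must contain exactly one (Intercept) row")
    coefs = {
        r["probe_id"]: float(r["coefficient"])
        for _, r in df.iterrows()
        if r["probe_id"] != "(Intercept)"
    }
    return ClockModel(float(inter["coefficient"].iloc[0]), coefs)


def write_clock(clock: ClockModel, path: str) -> None:
    rows = [("(Intercept)", clock.intercept)]
    rows += sorted(clock.coefficients.items())
    pd.DataFrame(rows, columns=["probe_id", "coefficient"]).to_csv(path, index=False)


def predict_dnam_age(
    betas: BetaMatrix,
    clock: ClockModel,
    sheet: SampleSheet | None = None,
    missing_policy: str = "warn",
) -> pd.DataFrame:
    """Predict DNAm age per sample.

    ``missing_policy``: 'strict' errors when any clock probe is absent;
    'warn' drops missing terms (requires >= 50% present); 'impute'
    substitutes beta = 0.5 for absent probes. Returns a table with
    dnam_age, n_missing_probes, and — when a sample sheet is given —
    age_at_sampling and delta = dnam_age - age_at_sampling.
    """
    present = [p for p in clock.coefficients if p in set(betas.probe_ids)]
    missing = sorted(set(clock.coefficients) - set(present))
    if missing_policy == "strict" and missing:
        raise ValueError(f"clock probes missing from matrix: {missing}")
    if missing_policy == "warn":
        if len(present) < 0.5 * len(clock.coefficients):
            raise ValueError(
                f"only {len(present)}/{len(clock.coefficients)} clock probes present"
            )
        if missing:
            logger.warning("%d clock probes missing; terms dropped", len(missing))
    weights = pd.Series(clock.coefficients)
    predictor = pd.Series(clock.intercept, index=betas.sample_ids, dtype=float)
    predictor += betas.values.loc[present].mul(weights.loc[present], axis=0).sum(axis=0)
    if missing_policy == "impute" and missing:
        predictor += 0.5 * weights.loc[missing].sum()
    out = pd.DataFrame(index=betas.sample_ids.rename("sample_id"))
    out["dnam_age"] = age_anti_transform(predictor.to_numpy(), clock.adult_age)
    out["n_missing_probes"] = len(missing)
    if sheet is not None:
        ages = sheet.table["age_at_sampling"].reindex(out.index)
        out["age_at_sampling"] = ages
        out["delta"] = out["dnam_age"] - ages
    return out


def age_delta_analysis(
    ages: pd.DataFrame,
    sheet: SampleSheet,
    split_age: float = 50.0,
) -> dict:
    """Per-group DNAm-age concordance and age-acceleration summary.

    For every sample group: Spearman R/p of DNAm age vs chronological
    age (omitted with a warning below 3 samples), mean +/- sd of delta
    for samples younger vs at-or-above ``split_age`` with a two-sided
    Wilcoxon test, and the same statistics stratified by colon
    location.
    """
    if "age_at_sampling" not in ages.columns or ages["age_at_sampling"].isna().any():
        raise ValueError("every sample needs both DNAm and chronological age")
    t = sheet.table
    report: dict = {}
    for group in sheet.groups():
        ids = [s for s in t.index[t["group"] == group] if s in ages.index]
        if not ids:
            continue
        entry = _delta_stats(ages.loc[ids], split_age, label=group)
        if "location" in t.columns:
            for loc in ("proximal", "distal"):
                loc_ids = [s for s in ids if t.loc[s, "location"] == loc]
                if loc_ids:
                    entry[f"location:{loc}"] = _delta_stats(
                        ages.loc[loc_ids], split_age, label=f"{group}/{loc}"
                    )
        report[group] = entry
    return report


def _delta_stats(sub: pd.DataFrame, split_age: float, label: str) -> dict:
    chron = sub["age_at_sampling"].to_numpy(dtype=float)
    dnam = sub["dnam_age"].to_numpy(dtype=float)
    delta = sub["delta"].to_numpy(dtype=float)
    entry: dict = {"n": int(len(sub))}
    if len(sub) >= 3 and len(np.unique(chron)) > 1 and len(np.unique(dnam)) > 1:
        r, p = spearman(dnam, chron)
        entry["spearman"] = {"r": r, "p": p}
    else:
        logger.warning("group %s: correlation omitted (n < 3 or constant)", label)
    young = delta[chron < split_age]
    old = delta[chron >= split_age]
    entry["delta_young"] = _mean_sd(young)
    entry["delta_old"] = _mean_sd(old)
    if young.size >= 1 and old.size >= 1:
        entry["wilcoxon_p"] = wilcoxon_rank_sum(young, old)
    return entry


def _mean_sd(x: np.ndarray) -> dict:
    if x.size == 0:
        return {"n": 0, "mean": math.nan, "sd": math.nan}
    sd = float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    return {"n": int(x.size), "mean": float(np.mean(x)), "sd": sd}
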