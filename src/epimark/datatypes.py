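"""Core containers for methylation-array analysis.

Thin, validated wrappers around pandas DataFrames: a probe annotation
manifest, beta/M value matrices (probes x samples) and a sample sheet.
All downstream modules consume these types; file parsing lives in
:mod:`epimark.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CGI_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
GENE_REGIONS = ("TSS200", "TSS1500", "5UTR", "1stExon", "Body", "3UTR")
#: promoter-associated gene regions used for the hypermethylation index
PROMOTER_REGIONS = frozenset({"5UTR", "TSS200", "TSS1500", "1stExon"})

_BOOL_FLAGS = ("is_cpg", "cross_reactive", "snp_masked", "line1_young", "clock_probe")


@dataclass
class ProbeAnnotationTable:
    """Per-probe genomic and functional metadata.

    ``table`` is indexed by unique probe id with columns ``chrom``,
    ``pos`` (1-based), ``cgi_relation`` (one of :data:`CGI_RELATIONS`),
    ``gene_regions`` / ``gene_symbols`` (frozensets, possibly empty),
    and the boolean flags ``is_cpg``, ``cross_reactive``,
    ``snp_masked``, ``line1_young``, ``clock_probe``. Unknown input
    columns are carried through untouched.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate probe_id: {dup!r}")
        for col in ("chrom", "pos", "cgi_relation"):
            if col not in t.columns:
                raise ValueError(f"manifest missing required column {col!r}")
        if (t["pos"] < 1).any():
            bad = t.index[t["pos"] < 1][0]
            raise ValueError(f"probe {bad!r} has position < 1")
        bad_rel = set(t["cgi_relation"]) - set(CGI_RELATIONS)
        if bad_rel:
            raise ValueError(f"unknown cgi_relation value(s): {sorted(bad_rel)}")
        for col in _BOOL_FLAGS:
            if col not in t.columns:
                t[col] = False
            t[col] = t[col].astype(bool)
        for col in ("gene_regions", "gene_symbols"):
            if col not in t.columns:
                t[col] = [frozenset()] * len(t)

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, probe_ids) -> "ProbeAnnotationTable":
        return ProbeAnnotationTable(self.table.loc[list(probe_ids)].copy())

    def promoter_sets(self, min_probes: int = 1) -> dict[str, list[str]]:
        """Map gene -> promoter probe ids (probes in a promoter region
        annotated to that gene), for promoter-set enrichment."""
        sets: dict[str, list[str]] = {}
        for pid, regions, genes in zip(
            self.table.index, self.table["gene_regions"], self.table["gene_symbols"]
        ):
            if regions & PROMOTER_REGIONS:
                for g in genes:
                    sets.setdefault(g, []).append(pid)
        return {g: ps for g, ps in sets.items() if len(ps) >= min_probes}


@dataclass
class BetaMatrix:
    """Probes x samples matrix of beta values in [0, 1], with an
    optional detection-P matrix of identical shape."""

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise ValueError("probe and sample labels must be unique")
        arr = v.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValueError("beta matrix contains missing values")
        if arr.min() < 0 or arr.max() > 1:
            raise ValueError("beta values must lie in [0, 1]")
        if self.detection_p is not None:
            d = self.detection_p
            if d.shape != v.shape or not d.index.equals(v.index) or not d.columns.equals(v.columns):
                raise ValueError("detection_p must match the beta matrix layout")
            darr = d.to_numpy(dtype=float)
            if np.nanmin(darr) < 0 or np.nanmax(darr) > 1:
                raise ValueError("detection P values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_probes(self, probe_ids) -> "BetaMatrix":
        ids = list(probe_ids)
        det = self.detection_p.loc[ids] if self.detection_p is not None else None
        return BetaMatrix(self.values.loc[ids], det)

    def subset_samples(self, sample_ids) -> "BetaMatrix":
        ids = list(sample_ids)
        det = self.detection_p[ids] if self.detection_p is not None else None
        return BetaMatrix(self.values[ids], det)


@dataclass
class MValueMatrix:
    """Probes x samples matrix of M values (logit2 of clipped beta)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("probe and sample labels must be unique")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("M values must be finite")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class SampleSheet:
    """Per-sample phenotype table indexed by unique sample id.

    Expected columns: ``patient_id``, ``group``, ``age_at_sampling``
    (years), ``location`` ('proximal'/'distal'), and optionally
    ``sublocation``, ``pair_id`` (tumor -> paired normal sample id),
    ``cimp_gene_status`` (tuple of 5 booleans or None), ``msi_bat25`` /
    ``msi_bat26`` ('stable'/'unstable' or None) and
    ``somatic_mutation_count`` (nonnegative int or None).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        for col in ("patient_id", "group", "age_at_sampling"):
            if col not in t.columns:
                raise ValueError(f"sample sheet missing required column {col!r}")
        ages = t["age_at_sampling"].dropna()
        if (ages < 0).any():
            raise ValueError("age_at_sampling must be nonnegative")
        if "pair_id" in t.columns:
            known = set(t.index)
            for sid, pid in t["pair_id"].dropna().items():
                if pid not in known:
                    raise ValueError(f"pair_id {pid!r} of sample {sid!r} is not a sample")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def groups(self) -> list[str]:
        seen: list[str] = []
        for g in self.table["group"]:
            if g not in seen:
                seen.append(g)
        return seen
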