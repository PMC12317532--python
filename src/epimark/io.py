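"""Readers and writers for the plain-text formats the pipeline consumes.

Manifest and sample sheet are CSV; methylation / expression matrices are
CSV or TSV with probes (genes) in rows and a header row of sample ids;
genomic exports are BED (0-based half-open). Manifest positions follow
the Illumina convention (1-based). All writers emit a deterministic
column order.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, ProbeAnnotationTable, SampleSheet

_SET_SEP = ";"

_MANIFEST_BOOL = ("is_cpg", "cross_reactive", "snp_masked", "line1_young", "clock_probe")


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _parse_set(val) -> frozenset:
    if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
        return frozenset()
    return frozenset(s for s in str(val).split(_SET_SEP) if s)


def _parse_bool(val) -> bool:
    if isinstance(val, (bool, np.bool_)):
        return bool(val)
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return False
    return str(val).strip().lower() in {"true", "1", "yes", "t"}


def read_manifest(path: str) -> ProbeAnnotationTable:
    """Read a probe-annotation manifest CSV.

    Requires columns probe_id, chrom, pos, cgi_relation; boolean flag
    columns default to False when absent; gene_regions / gene_symbols
    are ';'-separated lists. Duplicate probe ids and unparseable
    positions are hard errors.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    for col in ("probe_id", "chrom", "pos", "cgi_relation"):
        if col not in raw.columns:
            raise ValueError(f"manifest is missing required column {col!r}")
    if raw["probe_id"].duplicated().any():
        dup = raw["probe_id"][raw["probe_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate probe_id: {dup!r}")
    pos = pd.to_numeric(raw["pos"], errors="coerce")
    if pos.isna().any():
        # +2: header line plus 1-based numbering
        line = int(np.flatnonzero(pos.isna())[0]) + 2
        raise ValueError(f"unparseable pos at line {line} of {path}")
    table = pd.DataFrame(index=pd.Index(raw["probe_id"], name="probe_id"))
    table["chrom"] = raw["chrom"].to_numpy()
    table["pos"] = pos.astype(int).to_numpy()
    table["cgi_relation"] = raw["cgi_relation"].to_numpy()
    for col in ("gene_regions", "gene_symbols"):
        if col in raw.columns:
            table[col] = [_parse_set(v) for v in raw[col]]
        else:
            table[col] = [frozenset()] * len(raw)
    for col in _MANIFEST_BOOL:
        if col in raw.columns:
            table[col] = [_parse_bool(v) for v in raw[col]]
        else:
            table[col] = False if col != "is_cpg" else True
    known = {"probe_id", "chrom", "pos", "cgi_relation", "gene_regions", "gene_symbols", *_MANIFEST_BOOL}
    for col in raw.columns:
        if col not in known:
            table[col] = raw[col].to_numpy()
    return ProbeAnnotationTable(table)


def write_manifest(annot: ProbeAnnotationTable, path: str) -> None:
    t = annot.table
    out = pd.DataFrame(index=t.index)
    out["chrom"] = t["chrom"]
    out["pos"] = t["pos"]
    out["cgi_relation"] = t["cgi_relation"]
    out["gene_regions"] = [_SET_SEP.join(sorted(v)) for v in t["gene_regions"]]
    out["gene_symbols"] = [_SET_SEP.join(sorted(v)) for v in t["gene_symbols"]]
    for col in _MANIFEST_BOOL:
        out[col] = t[col]
    extra = [c for c in t.columns if c not in out.columns and c not in ("gene_regions", "gene_symbols")]
    for col in extra:
        out[col] = t[col]
    out.to_csv(path, sep=_sep_for(path), index_label="probe_id")


def read_matrix(path: str) -> pd.DataFrame:
    """Read a probes(genes)-by-samples numeric matrix (TSV/CSV)."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path: str, index_label: str = "probe_id") -> None:
    df.to_csv(path, sep=_sep_for(path), index_label=index_label, float_format="%.10g")


def read_beta_matrix(path: str, detection_p_path: str | None = None) -> BetaMatrix:
    values = read_matrix(path)
    det = read_matrix(detection_p_path) if detection_p_path else None
    return BetaMatrix(values, det)


_SHEET_OPTIONAL = ("sublocation", "pair_id", "msi_bat25", "msi_bat26")


def read_sample_sheet(path: str) -> SampleSheet:
    """Read the per-sample phenotype CSV.

    Columns: sample_id, patient_id, group, age_at_sampling, location,
    and optionally sublocation, pair_id, cimp_1..cimp_5 (booleans),
    msi_bat25/msi_bat26 ('stable'/'unstable'), somatic_mutation_count.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    if "sample_id" not in raw.columns:
        raise ValueError("sample sheet must have a sample_id column")
    t = pd.DataFrame(index=pd.Index(raw["sample_id"], name="sample_id"))
    for col in ("patient_id", "group", "location"):
        if col in raw.columns:
            t[col] = raw[col].to_numpy()
    t["age_at_sampling"] = pd.to_numeric(raw["age_at_sampling"]).to_numpy()
    for col in _SHEET_OPTIONAL:
        if col in raw.columns:
            t[col] = [v if v != "" else None for v in raw[col]]
    cimp_cols = [f"cimp_{i}" for i in range(1, 6)]
    if all(c in raw.columns for c in cimp_cols):
        statuses = []
        for _, row in raw.iterrows():
            vals = [row[c] for c in cimp_cols]
            if any(v == "" for v in vals):
                statuses.append(None)
            else:
                statuses.append(tuple(_parse_bool(v) for v in vals))
        t["cimp_gene_status"] = statuses
    if "somatic_mutation_count" in raw.columns:
        t["somatic_mutation_count"] = [
            int(v) if v != "" else None for v in raw["somatic_mutation_count"]
        ]
    return SampleSheet(t)


def write_sample_sheet(sheet: SampleSheet, path: str) -> None:
    t = sheet.table
    out = pd.DataFrame(index=t.index)
    for col in ("patient_id", "group", "age_at_sampling", "location"):
        if col in t.columns:
            out[col] = t[col]
    for col in _SHEET_OPTIONAL:
        if col in t.columns:
            out[col] = ["" if v is None else v for v in t[col]]
    if "cimp_gene_status" in t.columns:
        for i in range(5):
            out[f"cimp_{i + 1}"] = [
                "" if v is None else str(bool(v[i])) for v in t["cimp_gene_status"]
            ]
    if "somatic_mutation_count" in t.columns:
        out["somatic_mutation_count"] = [
            "" if v is None or (isinstance(v, float) and np.isnan(v)) else int(v)
            for v in t["somatic_mutation_count"]
        ]
    out.to_csv(path, index_label="sample_id")


def write_bed(intervals: pd.DataFrame, path: str) -> None:
    """Write genomic intervals as BED (0-based, half-open).

    ``intervals`` must have chrom/start/end columns with 1-based
    inclusive coordinates; an optional ``name`` column becomes column 4.
    """
    with open(path, "w") as fh:
        for _, row in intervals.iterrows():
            name = row["name"] if "name" in intervals.columns else "."
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t{name}\n")


def read_promoter_sets(path: str) -> dict[str, list[str]]:
    """Read a two-column (gene, probe_id) TSV into gene -> probe list."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, probe = line.split("\t")[:2]
            sets.setdefault(gene, []).append(probe)
    return sets


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read GMT-style gene sets: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def sha256_of(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
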