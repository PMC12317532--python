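"""Synthetic methylation-array cohort generator with recorded ground
truth.

Emulates the structure of a hereditary-CRC methylation study: two
syndrome arms with paired tumor/normal samples, CpG-island promoter
hypermethylation and open-sea hypomethylation planted in tumors,
LINE-1 probe loss in tumors, clock probes carrying an age signal,
genes whose expression is negatively coupled to promoter methylation,
and a mutation count positively coupled to the hypermethylation index.

Every planted effect is recorded in a :class:`SyntheticTruth` registry
for parameter-recovery tests. Group differences are applied on the
logit2 (M) scale and back-transformed, so the planted delta-beta is
exact at the per-probe baseline and beta never leaves [0, 1];
within-group variation comes from a Beta distribution parameterized by
mean and a concentration (default 50, roughly sd 0.05 near beta 0.5).

One global seed feeds a fixed, ordered sequence of substream seeds
(manifest, baseline, sample sheet, clock, detection, beta noise,
expression, mutation counts, tumor severity), so identical seeds give
byte-identical outputs and adding a later feature never perturbs
earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .clock import ClockModel, age_transform
from .datatypes import BetaMatrix, ProbeAnnotationTable, SampleSheet
from .preprocess import beta_to_m, m_to_beta

TUMOR_TO_NORMAL = {
    "LS_AdL": "LS_normal",
    "LS_AdH": "LS_normal",
    "LS_CRC": "LS_normal",
    "FAP_adenoma": "FAP_normal",
}

DEFAULT_GROUP_SIZES = {
    "LS_normal": 33,
    "LS_UA_normal": 14,
    "LS_AdL": 21,
    "LS_AdH": 7,
    "LS_CRC": 5,
    "FAP_normal": 24,
    "FAP_adenoma": 12,
}

DEFAULT_EXPRESSION_GROUPS = {
    "LS_UA_normal": 14,
    "LS_normal": 10,
    "LS_AdL": 4,
    "LS_AdH": 4,
    "LS_CRC": 4,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort. Defaults mirror the study design
    (group sizes, tumor-depressed LINE-1 around 0.73 -> 0.68,
    hypo-dominant differential methylation, 6.4 Mb mutation panel)."""

    n_probes: int = 20_000
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    # planted differential methylation in tumors vs matched normals
    hyper_fraction: float = 0.01
    hyper_delta_beta: float = 0.2
    hypo_fraction: float = 0.025
    hypo_delta_beta: float = 0.2
    promoter_block_size: int = 5  # hyper probes per planted promoter gene
    # baseline beta: bimodal (low for islands, high elsewhere)
    island_baseline: tuple[float, float] = (2.0, 11.0)  # Beta(a, b), mean ~0.15
    opensea_baseline: tuple[float, float] = (9.0, 3.0)  # mean 0.75
    concentration: float = 50.0
    # LINE-1 surrogate probes
    n_line1_probes: int = 100
    line1_mean: float = 0.73
    line1_shift_m: float = -0.35  # logit2 shift in tumors (~0.73 -> 0.68)
    # clock probes
    n_clock_probes: int = 50
    clock_noise_sd: float = 0.3  # sd on the transformed-age predictor
    adult_age: float = 20.0
    # CIMP latent structure
    cimp_gene_p_positive: float = 0.75
    cimp_gene_p_negative: float = 0.15
    # expression coupling
    n_coupled_genes: int = 40
    n_null_genes: int = 160
    coupling_slope: float = -3.0
    expression_noise_sd: float = 0.5
    expression_groups: dict = field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_GROUPS)
    )
    # per-tumor severity: one multiplier per tumor sample jointly
    # scaling its hyper-, hypo- and LINE-1 shifts, so biomarker scores
    # co-vary across tumors (severe tumors gain more promoter
    # methylation AND lose more LINE-1 methylation)
    severity_range: tuple[float, float] = (0.8, 1.2)
    cimp_severity_boost: float = 0.35  # extra severity for CIMP-positive tumors
    # mutation counts: count = round(a + b * hypermeth_index + noise);
    # calibrated so tumor TMB spans roughly 0-40 per Mb with a mix of
    # hypermutated and non-hypermutated tumors
    tmb_intercept: float = -280.0
    tmb_slope: float = 1000.0
    tmb_noise_sd: float = 20.0
    msi_rate_ls_tumor: float = 0.6
    # probe masks / detection failures
    sex_probe_fraction: float = 0.02
    cross_reactive_fraction: float = 0.005
    snp_masked_fraction: float = 0.01
    non_cpg_fraction: float = 0.005
    detection_failure_rate: float = 0.002
    age_range: tuple[float, float] = (25.0, 80.0)
    seed: int = 0

    def n_hyper_genes(self) -> int:
        n_hyper = int(round(self.hyper_fraction * self.n_probes))
        return n_hyper // self.promoter_block_size

    def validate(self) -> None:
        n_hyper = self.n_hyper_genes() * self.promoter_block_size
        n_hypo = int(round(self.hypo_fraction * self.n_probes))
        special = n_hyper + n_hypo + self.n_line1_probes + self.n_clock_probes
        if special > self.n_probes // 2:
            raise ValueError(
                f"planted probes ({special}) exceed half of n_probes ({self.n_probes})"
            )
        if self.n_coupled_genes > max(self.n_hyper_genes(), 0) and self.n_coupled_genes > 0:
            if self.n_hyper_genes() == 0:
                raise ValueError("coupled genes require planted hyper promoter genes")
            raise ValueError(
                f"n_coupled_genes ({self.n_coupled_genes}) exceeds planted promoter genes ({self.n_hyper_genes()})"
            )
        for frac in (self.hyper_fraction, self.hypo_fraction, self.detection_failure_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        for eff in (self.hyper_delta_beta, self.hypo_delta_beta):
            if not 0 < eff < 1:
                raise ValueError("effect sizes must lie in (0, 1)")
        tumors = [g for g in self.group_sizes if g in TUMOR_TO_NORMAL]
        for t in tumors:
            n_norm = self.group_sizes.get(TUMOR_TO_NORMAL[t], 0)
            if n_norm == 0 and self.group_sizes.get(t, 0) > 0:
                raise ValueError(f"tumor group {t} has no normal group to pair with")


@dataclass
class SyntheticTruth:
    """Registry of every planted effect."""

    differential: dict  # contrast -> {probe_id: 'hyper'|'hypo'}
    dmr_intervals: list  # dicts: chrom, start, end, probes, gene
    line1_probes: list
    clock_probes: list
    coupled_genes: list
    gene_probe_groups: dict  # gene -> probe ids (coupled + null features)
    true_ages: dict  # sample_id -> years
    clock_intercept: float
    clock_coefficients: dict

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class SyntheticDataset:
    annot: ProbeAnnotationTable
    betas: BetaMatrix
    sheet: SampleSheet
    expression: pd.DataFrame
    truth: SyntheticTruth
    clock: ClockModel


def _substreams(seed: int, n: int = 8):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def build_clock_block(
    probe_ids: list[str],
    ages: np.ndarray,
    rng: np.random.Generator,
    noise_sd: float = 0.0,
    adult_age: float = 20.0,
) -> tuple[ClockModel, np.ndarray]:
    """Construct clock weights and a clock-probe beta block such that
    intercept + sum(w_k * beta_k) equals the transformed true age plus
    N(0, noise_sd) noise.

    Per-probe betas are base_k + t_s / (K * w_k); the weight magnitude
    adapts to the age span so betas stay inside [0, 1] without
    clipping.
    """
    k = len(probe_ids)
    if k < 10:
        raise ValueError("need at least 10 clock probes")
    t = age_transform(ages, adult_age)
    # small mixed-sign weights (real clocks spread the signal over many
    # CpGs); magnitude chosen so the per-probe beta swing stays inside
    # [0, 1] without clipping for the ages supplied
    t_span = max(np.abs(t).max(), 1.0)
    gamma = max(0.15, t_span / (0.35 * k))
    sign = rng.choice([-1.0, 1.0], size=k)
    w = sign * gamma
    base = rng.uniform(0.4, 0.6, size=k)
    if noise_sd > 0:
        t = t + rng.normal(0.0, noise_sd, size=len(ages))
    # sum_k w_k / (k w_k) = 1, so the predictor recovers t exactly
    betas = base[:, None] + t[None, :] / (k * w[:, None])
    betas = np.clip(betas, 0.0, 1.0)
    intercept = -float((w * base).sum())
    model = ClockModel(intercept, dict(zip(probe_ids, w)), adult_age)
    return model, betas


def generate_clock_model(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ClockModel, pd.DataFrame, dict]:
    """Standalone clock construction: returns the model, the clock-probe
    beta block (probes x samples) and the true ages used."""
    cfg = config
    rng_ages, rng_clock = _substreams(cfg.seed if seed is None else seed, 2)
    n_samples = sum(cfg.group_sizes.values())
    ages = rng_ages.uniform(*cfg.age_range, size=n_samples)
    probe_ids = [f"cgclock{i:05d}" for i in range(cfg.n_clock_probes)]
    sample_ids = [f"s{i:03d}" for i in range(n_samples)]
    model, block = build_clock_block(
        probe_ids, ages, rng_clock, cfg.clock_noise_sd, cfg.adult_age
    )
    df = pd.DataFrame(block, index=probe_ids, columns=sample_ids)
    return model, df, dict(zip(sample_ids, ages.tolist()))


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full synthetic cohort with recorded truth."""
    cfg = config
    cfg.validate()
    (
        rng_manifest,
        rng_baseline,
        rng_sheet,
        rng_clock,
        rng_detect,
        rng_noise,
        rng_expr,
        rng_tmb,
        rng_severity,
    ) = _substreams(cfg.seed, 9)

    n = cfg.n_probes
    probe_ids = [f"cg{i:08d}" for i in range(n)]

    # ---- probe roles ------------------------------------------------
    n_genes = cfg.n_hyper_genes()
    block = cfg.promoter_block_size
    hyper_blocks: list[list[int]] = []
    used = np.zeros(n, dtype=bool)
    if n_genes:
        stride = n // (n_genes + 1)
        for g in range(n_genes):
            start = stride * (g + 1)
            hyper_blocks.append(list(range(start, start + block)))
            used[start : start + block] = True
    hyper_idx = [i for b in hyper_blocks for i in b]
    free = np.flatnonzero(~used)
    n_hypo = int(round(cfg.hypo_fraction * n))
    picks = rng_manifest.choice(
        free, size=n_hypo + cfg.n_line1_probes + cfg.n_clock_probes, replace=False
    )
    hypo_idx = sorted(picks[:n_hypo].tolist())
    line1_idx = sorted(picks[n_hypo : n_hypo + cfg.n_line1_probes].tolist())
    clock_idx = sorted(picks[n_hypo + cfg.n_line1_probes :].tolist())
    used[picks] = True
    special = set(np.flatnonzero(used).tolist())

    # ---- manifest ---------------------------------------------------
    chrom = np.empty(n, dtype=object)
    pos = np.zeros(n, dtype=int)
    autosomes = [f"chr{i}" for i in range(1, 23)]
    chunk = int(np.ceil(n / len(autosomes)))
    gaps = rng_manifest.integers(5_000, 20_000, size=n)
    in_block = np.zeros(n, dtype=bool)
    for b in hyper_blocks:
        in_block[b[1:]] = True  # small gap *to* every non-first block member
    gaps[in_block] = rng_manifest.integers(50, 150, size=int(in_block.sum()))
    cursor = 0
    for ci, c in enumerate(autosomes):
        hi = min(cursor + chunk, n)
        if cursor >= hi:
            break
        chrom[cursor:hi] = c
        pos[cursor:hi] = 1 + np.cumsum(gaps[cursor:hi])
        cursor = hi

    rel_choices = np.array(["Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"])
    rel_p = np.array([0.18, 0.08, 0.08, 0.04, 0.04, 0.58])
    cgi = rng_manifest.choice(rel_choices, size=n, p=rel_p)
    gene_regions = [frozenset() for _ in range(n)]
    gene_symbols = [frozenset() for _ in range(n)]
    body_mask = rng_manifest.random(n) < 0.55
    for i in np.flatnonzero(body_mask):
        gene_regions[i] = frozenset({"Body"})
        gene_symbols[i] = frozenset({f"G{i:05d}"})
    for g, b in enumerate(hyper_blocks):
        for i in b:
            cgi[i] = "Island"
            gene_regions[i] = frozenset({"TSS200", "1stExon"})
            gene_symbols[i] = frozenset({f"HYPG{g:03d}"})
    for i in hypo_idx:
        cgi[i] = "OpenSea"
        gene_regions[i] = frozenset({"Body"})
        gene_symbols[i] = frozenset({f"G{i:05d}"})
    for i in line1_idx:
        cgi[i] = "OpenSea"
        gene_regions[i] = frozenset()
        gene_symbols[i] = frozenset()

    def _mask(fraction: float) -> np.ndarray:
        m = rng_manifest.random(n) < fraction
        m[list(special)] = False
        return m

    cross_reactive = _mask(cfg.cross_reactive_fraction)
    snp_masked = _mask(cfg.snp_masked_fraction)
    non_cpg = _mask(cfg.non_cpg_fraction)
    sex = _mask(cfg.sex_probe_fraction)
    chrom[sex] = "chrX"
    line1_young = np.zeros(n, dtype=bool)
    line1_young[line1_idx] = True
    clock_flag = np.zeros(n, dtype=bool)
    clock_flag[clock_idx] = True

    annot = ProbeAnnotationTable(
        pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos,
                "cgi_relation": cgi,
                "gene_regions": gene_regions,
                "gene_symbols": gene_symbols,
                "is_cpg": ~non_cpg,
                "cross_reactive": cross_reactive,
                "snp_masked": snp_masked,
                "line1_young": line1_young,
                "clock_probe": clock_flag,
            },
            index=pd.Index(probe_ids, name="probe_id"),
        )
    )

    # ---- baseline beta ---------------------------------------------
    base = np.empty(n)
    is_island = cgi == "Island"
    base[is_island] = rng_baseline.beta(*cfg.island_baseline, size=int(is_island.sum()))
    base[~is_island] = rng_baseline.beta(*cfg.opensea_baseline, size=int((~is_island).sum()))
    base[line1_idx] = np.clip(
        rng_baseline.normal(cfg.line1_mean, 0.01, size=len(line1_idx)), 0.05, 0.95
    )
    base = np.clip(base, 0.02, 0.98)

    # ---- sample sheet ----------------------------------------------
    sheet, ages = _build_sheet(cfg, rng_sheet)
    sample_ids = list(sheet.sample_ids)
    n_s = len(sample_ids)
    group = sheet.table["group"]
    tumor_samples = [s for s in sample_ids if group[s] in TUMOR_TO_NORMAL]
    cimp_positive = {
        s: (sheet.table.loc[s, "cimp_gene_status"] is not None
            and sum(sheet.table.loc[s, "cimp_gene_status"]) >= 3)
        for s in sample_ids
    }

    # ---- group mean matrix on the logit scale -----------------------
    base_m = beta_to_m(base)
    mu_m = np.tile(base_m[:, None], (1, n_s))
    hyper_target = np.clip(base[hyper_idx] + cfg.hyper_delta_beta, 0.02, 0.98)
    hypo_target = np.clip(base[hypo_idx] - cfg.hypo_delta_beta, 0.02, 0.98)
    hyper_shift = beta_to_m(hyper_target) - base_m[hyper_idx]
    hypo_shift = beta_to_m(hypo_target) - base_m[hypo_idx]
    severity = {
        s: float(rng_severity.uniform(*cfg.severity_range))
        * (1.0 + cfg.cimp_severity_boost * cimp_positive[s])
        for s in tumor_samples
    }
    for j, s in enumerate(sample_ids):
        if s not in tumor_samples:
            continue
        u = severity[s]
        mu_m[hyper_idx, j] += u * hyper_shift
        mu_m[hypo_idx, j] += u * hypo_shift
        mu_m[line1_idx, j] += u * cfg.line1_shift_m
    mu = m_to_beta(mu_m)
    mu = np.clip(mu, 0.01, 0.99)

    c = cfg.concentration
    beta_vals = rng_noise.beta(mu * c, (1.0 - mu) * c)
    beta_vals = np.clip(beta_vals, 0.0, 1.0)

    # ---- clock block (overwrites clock-probe rows) ------------------
    clock_probe_ids = [probe_ids[i] for i in clock_idx]
    age_arr = np.array([ages[s] for s in sample_ids])
    clock_model, clock_block = build_clock_block(
        clock_probe_ids, age_arr, rng_clock, cfg.clock_noise_sd, cfg.adult_age
    )
    beta_vals[clock_idx, :] = clock_block

    # ---- detection P ------------------------------------------------
    det = rng_detect.uniform(1e-6, 1e-3, size=(n, n_s))
    fail = rng_detect.random((n, n_s)) < cfg.detection_failure_rate
    fail[list(special), :] = False
    det[fail] = rng_detect.uniform(0.01, 0.6, size=int(fail.sum()))

    values = pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids)
    betas = BetaMatrix(
        values, pd.DataFrame(det, index=probe_ids, columns=sample_ids)
    )

    # ---- expression -------------------------------------------------
    expr_samples: list[str] = []
    for g, k in cfg.expression_groups.items():
        expr_samples += sheet.samples_in_group(g)[:k]
    coupled_genes = [f"HYPG{g:03d}" for g in range(cfg.n_coupled_genes)]
    gene_groups: dict[str, list[str]] = {
        f"HYPG{g:03d}": [probe_ids[i] for i in hyper_blocks[g]]
        for g in range(n_genes)
    }
    null_pool = [i for i in range(n) if i not in special and not sex[i]]
    null_genes = []
    for q in range(cfg.n_null_genes):
        gname = f"NULLG{q:03d}"
        members = rng_expr.choice(null_pool, size=4, replace=False)
        gene_groups[gname] = [probe_ids[i] for i in members]
        null_genes.append(gname)
    expression = pd.DataFrame(
        index=coupled_genes + null_genes, columns=expr_samples, dtype=float
    )
    if expr_samples:
        col_idx = {s: j for j, s in enumerate(sample_ids)}
        pid_index = {p: i for i, p in enumerate(probe_ids)}
        for gname in coupled_genes:
            rows = [pid_index[p] for p in gene_groups[gname]]
            mean_b = beta_vals[rows][:, [col_idx[s] for s in expr_samples]].mean(axis=0)
            expression.loc[gname] = (
                cfg.coupling_slope * beta_to_m(mean_b)
                + rng_expr.normal(0.0, cfg.expression_noise_sd, size=len(expr_samples))
            )
        for gname in null_genes:
            expression.loc[gname] = rng_expr.normal(0.0, 1.0, size=len(expr_samples))

    # ---- mutation counts (LS tumors) --------------------------------
    if hyper_idx:
        col_idx = {s: j for j, s in enumerate(sample_ids)}
        counts = {}
        for s in tumor_samples:
            if not str(group[s]).startswith("LS"):
                continue
            hm = float(beta_vals[hyper_idx, col_idx[s]].mean())
            raw = cfg.tmb_intercept + cfg.tmb_slope * hm + rng_tmb.normal(0.0, cfg.tmb_noise_sd)
            counts[s] = max(0, int(round(raw)))
        sheet.table["somatic_mutation_count"] = [
            counts.get(s) for s in sheet.table.index
        ]

    # ---- truth ------------------------------------------------------
    differential = {}
    for tg, ng in TUMOR_TO_NORMAL.items():
        if cfg.group_sizes.get(tg, 0) and cfg.group_sizes.get(ng, 0):
            d = {probe_ids[i]: "hyper" for i in hyper_idx}
            d.update({probe_ids[i]: "hypo" for i in hypo_idx})
            differential[f"{tg}|{ng}"] = d
    dmr_intervals = [
        {
            "chrom": str(chrom[b[0]]),
            "start": int(pos[b[0]]),
            "end": int(pos[b[-1]]),
            "probes": [probe_ids[i] for i in b],
            "gene": f"HYPG{g:03d}",
        }
        for g, b in enumerate(hyper_blocks)
    ]
    truth = SyntheticTruth(
        differential=differential,
        dmr_intervals=dmr_intervals,
        line1_probes=[probe_ids[i] for i in line1_idx],
        clock_probes=clock_probe_ids,
        coupled_genes=coupled_genes,
        gene_probe_groups=gene_groups,
        true_ages={s: float(ages[s]) for s in sample_ids},
        clock_intercept=clock_model.intercept,
        clock_coefficients=dict(clock_model.coefficients),
    )
    return SyntheticDataset(annot, betas, sheet, expression, truth, clock_model)


def _build_sheet(cfg: SimulationConfig, rng: np.random.Generator):
    """Sample sheet with tumor-normal pairing, locations, ages, CIMP
    statuses and MSI markers."""
    rows = []
    ages: dict[str, float] = {}
    pair_counter: dict[str, int] = {}
    normals_by_group: dict[str, list[str]] = {}
    # normals first so tumors can reference them
    for g, k in cfg.group_sizes.items():
        if g in TUMOR_TO_NORMAL:
            continue
        ids = [f"{g}_{i:03d}" for i in range(k)]
        normals_by_group[g] = ids
        for i, sid in enumerate(ids):
            age = float(rng.uniform(*cfg.age_range))
            ages[sid] = age
            loc = "proximal" if (g.startswith("LS") and rng.random() < 0.78) else "distal"
            rows.append(
                {
                    "sample_id": sid,
                    "patient_id": f"P_{g}_{i:03d}",
                    "group": g,
                    "age_at_sampling": age,
                    "location": loc,
                    "pair_id": None,
                    "cimp_gene_status": None,
                    "msi_bat25": None,
                    "msi_bat26": None,
                }
            )
    normal_row = {r["sample_id"]: r for r in rows}
    for g, k in cfg.group_sizes.items():
        if g not in TUMOR_TO_NORMAL:
            continue
        ng = TUMOR_TO_NORMAL[g]
        pool = normals_by_group.get(ng, [])
        for i in range(k):
            c = pair_counter.get(ng, 0)
            pair_counter[ng] = c + 1
            paired = pool[c % len(pool)] if pool else None
            sid = f"{g}_{i:03d}"
            age = ages[paired] if paired else float(rng.uniform(*cfg.age_range))
            ages[sid] = age
            latent_cimp = rng.random() < 0.4
            p_gene = cfg.cimp_gene_p_positive if latent_cimp else cfg.cimp_gene_p_negative
            statuses = tuple(bool(rng.random() < p_gene) for _ in range(5))
            is_ls = g.startswith("LS")
            msi = is_ls and (rng.random() < cfg.msi_rate_ls_tumor)
            if msi:
                b25 = "unstable" if rng.random() < 0.8 else "stable"
                b26 = "unstable" if (b25 == "stable" or rng.random() < 0.8) else "stable"
            else:
                b25 = b26 = "stable"
            rows.append(
                {
                    "sample_id": sid,
                    "patient_id": normal_row[paired]["patient_id"] if paired else f"P_{g}_{i:03d}",
                    "group": g,
                    "age_at_sampling": age,
                    "location": normal_row[paired]["location"] if paired else "distal",
                    "pair_id": paired,
                    "cimp_gene_status": statuses,
                    "msi_bat25": b25 if is_ls else None,
                    "msi_bat26": b26 if is_ls else None,
                }
            )
    table = pd.DataFrame(rows).set_index("sample_id")
    return SampleSheet(table), ages
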