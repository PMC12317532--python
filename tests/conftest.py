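import numpy as np
import pandas as pd
import pytest

from epimark.datatypes import BetaMatrix, ProbeAnnotationTable, SampleSheet
from epimark.simulate import SimulationConfig, generate_dataset


@pytest.fixture
def toy_annot() -> ProbeAnnotationTable:
    """Six probes on two chromosomes with varied annotation."""
    table = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chrX"],
            "pos": [100, 300, 5000, 100, 200, 50],
            "cgi_relation": ["Island", "Island", "OpenSea", "N_Shore", "OpenSea", "Island"],
            "gene_regions": [
                frozenset({"TSS200"}),
                frozenset({"TSS200", "Body"}),
                frozenset({"Body"}),
                frozenset(),
                frozenset({"Body"}),
                frozenset({"TSS1500"}),
            ],
            "gene_symbols": [
                frozenset({"GA"}),
                frozenset({"GA"}),
                frozenset({"GB"}),
                frozenset(),
                frozenset({"GC"}),
                frozenset({"GX"}),
            ],
            "is_cpg": [True, True, True, True, False, True],
            "cross_reactive": [False, False, False, True, False, False],
            "snp_masked": [False, False, False, False, False, False],
            "line1_young": [False, False, True, False, True, False],
            "clock_probe": [False] * 6,
        },
        index=pd.Index([f"cg{i}" for i in range(6)], name="probe_id"),
    )
    return ProbeAnnotationTable(table)


@pytest.fixture
def toy_betas(toy_annot) -> BetaMatrix:
    rng = np.random.default_rng(0)
    vals = rng.uniform(0.05, 0.95, size=(6, 4))
    det = np.full((6, 4), 1e-5)
    idx = toy_annot.probe_ids
    cols = [f"s{i}" for i in range(4)]
    return BetaMatrix(
        pd.DataFrame(vals, index=idx, columns=cols),
        pd.DataFrame(det, index=idx, columns=cols),
    )


@pytest.fixture
def two_group_sheet() -> SampleSheet:
    rows = []
    for g, n in (("LS_normal", 3), ("LS_AdL", 3)):
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{g}_{i}",
                    "patient_id": f"P{i}",
                    "group": g,
                    "age_at_sampling": 40.0 + i,
                    "location": "proximal" if i % 2 else "distal",
                }
            )
    return SampleSheet(pd.DataFrame(rows).set_index("sample_id"))


def small_cohort_config(seed: int = 0, **overrides) -> SimulationConfig:
    base = dict(
        n_probes=2000,
        group_sizes={"LS_normal": 15, "LS_AdL": 15},
        n_coupled_genes=4,
        n_null_genes=10,
        n_line1_probes=40,
        n_clock_probes=20,
        detection_failure_rate=0.0,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """One planted-effect cohort shared across read-only tests."""
    return generate_dataset(small_cohort_config(seed=42))
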