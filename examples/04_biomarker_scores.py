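"""Per-sample biomarker panel: LINE-1 index, hypermethylation index,
CIMP, MSI, TMB.

LINE-1 methylation (mean beta over young-LINE-1 probes) is a surrogate
for global hypomethylation and drops in tumors; the hypermethylation
index averages beta over promoter-island probes hypermethylated in
every tumor contrast; TMB is mutations per 6.4 Mb panel with the
strict >10/Mb hypermutation rule.
"""

from epimark.dmp import ContrastSpec, run_contrast
from epimark.preprocess import beta_to_m
from epimark.scores import build_score_panel, hypermeth_index_probes, score_associations
from epimark.simulate import SimulationConfig, generate_dataset

ds = generate_dataset(
    SimulationConfig(
        n_probes=4000,
        group_sizes={"LS_normal": 15, "LS_AdL": 15},
        n_coupled_genes=8,
        n_null_genes=0,
        seed=4,
    )
)
table = run_contrast(
    ds.betas, beta_to_m(ds.betas), ds.sheet, ContrastSpec("LS_AdL", "LS_normal")
)
hm_probes = hypermeth_index_probes({"LS_AdL|LS_normal": table}, ds.annot)
print(f"hypermethylation index probes (island + promoter, hyper in all contrasts): {len(hm_probes)}")

panel = build_score_panel(ds.betas, ds.annot, ds.sheet, hm_probes, ("LS_AdL",))
by_group = panel.groupby("group")["line1_index"].agg(["mean", "std"])
print("\nLINE-1 index by group (tumors lose LINE-1 methylation):")
print(by_group.round(3))

tumors = panel[panel["group"] == "LS_AdL"]
print(f"\ntumors: {int((tumors['msi_status'] == 'MSI').sum())} MSI, "
      f"{int(tumors['hypermutated'].fillna(False).sum())} hypermutated (TMB > 10/Mb), "
      f"{int(tumors['cimp_positive'].fillna(False).sum())} CIMP positive")

rep = score_associations(panel, ds.sheet)
for pair, stats in rep["correlations"].items():
    print(f"Spearman {pair}: r = {stats['r']:+.2f} (p = {stats['p']:.2g}, n = {stats['n']})")
# Expected signs: LINE-1 vs hypermethylation negative, TMB vs LINE-1
# negative, TMB vs hypermethylation positive.
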