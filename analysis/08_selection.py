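"""Classify the TASs by selection history.

Each TAS is tested for a domestication signal (wild-vs-landrace Fst outlier
plus an allele-frequency shift) and a diversification signal (pairwise
subpopulation Fst outlier), then placed into one of four categories.
Outputs: selection_report.csv.
"""

from pathlib import Path

import pandas as pd

from soyadapt import io, selection
from soyadapt.pipeline import RunConfig

cfg = RunConfig.from_yaml(Path(__file__).parent / "config.yaml")
out = Path(cfg.outdir)
geno, _ = io.read_vcf(out / "called.vcf")
samples = pd.read_csv(out / "samples.csv").set_index("sample_id").reindex(geno.samples)
tas_all = pd.read_csv(out / "tas_list.csv")
tas_list = sorted(set(zip(tas_all["chrom"], tas_all["pos"].astype(int))))
if not tas_list:
    raise SystemExit("no TASs to classify; run the association scan first")
print(f"classifying {len(tas_list)} TASs (all traits pooled)")

groups = samples["group"].to_numpy()
wild = groups == "WILD"

dom = selection.domestication_scan(
    geno, wild, ~wild, tas_list, fst_quantile=cfg.fst_quantile
)
div = selection.diversification_scan(
    geno, groups, tas_list, fst_quantile=cfg.fst_quantile,
    maf_threshold=cfg.maf_threshold,
)
report = selection.classify(dom, div)
report.table.to_csv(out / "selection_report.csv", index=False)
print("category counts:")
for k, v in sorted(report.category_counts.items()):
    print(f"  {k}: {v}")
n_sel = len(tas_list) - report.category_counts["none"]
print(f"{n_sel}/{len(tas_list)} TASs show a selection signal at the "
      f"{cfg.fst_quantile:.0%} genome-wide Fst quantile")
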