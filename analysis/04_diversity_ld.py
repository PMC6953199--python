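"""Differentiation, diversity and LD of the called panel.

Computes pairwise Weir-Cockerham Fst among subpopulations (per SNP, 30-kb
windows, genome-wide), Watterson's theta per group, the LD decay profile and
half-maximum distance for the wild and landrace panels separately, and a
Pst-vs-Fst contrast for flowering time. Outputs: fst_pairs.csv, theta.csv,
ld_profile_{wild,landrace}.csv, pst.csv.
"""

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from soyadapt import io, popgen
from soyadapt.pipeline import RunConfig

cfg = RunConfig.from_yaml(Path(__file__).parent / "config.yaml")
out = Path(cfg.outdir)
geno, _ = io.read_vcf(out / "called.vcf")
samples = pd.read_csv(out / "samples.csv").set_index("sample_id").reindex(geno.samples)
traits = pd.read_csv(out / "traits.csv").set_index("sample_id").reindex(geno.samples)
groups = samples["group"].to_numpy()

rows = []
for a, b in combinations(("NR", "HR", "SR", "WILD"), 2):
    res = popgen.wc_fst(geno, groups, labels=(a, b))
    rows.append({"pair": f"{a}-{b}", "fst": res.genome_wide})
fst_pairs = pd.DataFrame(rows)
fst_pairs.to_csv(out / "fst_pairs.csv", index=False)
print("genome-wide pairwise Fst:")
print(fst_pairs.to_string(index=False))

theta_rows = []
for g in ("WILD", "NR", "HR", "SR"):
    _, mean, (lo, hi) = popgen.watterson_theta(geno, sample_mask=groups == g)
    theta_rows.append({"group": g, "theta_w_per_bp": mean, "q2.5": lo, "q97.5": hi})
theta = pd.DataFrame(theta_rows)
theta.to_csv(out / "theta.csv", index=False)
print("\nWatterson's theta (per bp, 1-Mb windows):")
print(theta.to_string(index=False))

print()
for label, mask in (("wild", groups == "WILD"), ("landrace", groups != "WILD")):
    sub = geno.take_samples(mask)
    prof = popgen.ld_decay_profile(popgen.ld_r2(sub), bin_width_bp=10_000)
    pd.DataFrame(
        {"bin_start_bp": prof.bin_edges_bp[:-1], "mean_r2": prof.mean_r2,
         "n_pairs": prof.counts}
    ).to_csv(out / f"ld_profile_{label}.csv", index=False)
    half = prof.half_max_distance_bp
    print(f"LD half-decay distance ({label}): "
          + (f"{half/1000:.0f} kb" if half is not None else "not reached"))

land = groups != "WILD"
ft = traits.loc[land, "FT_loc1"].to_numpy()
mean_fst = fst_pairs.loc[fst_pairs["pair"].isin(["NR-HR", "NR-SR", "HR-SR"]), "fst"].mean()
res = popgen.pst(ft, groups[land], n_boot=1000, seed=cfg.seed, fst_comparison=mean_fst)
pd.DataFrame([res.__dict__]).to_csv(out / "pst.csv", index=False)
print(
    f"\nPst(flowering time, landrace subpopulations) = {res.estimate:.3f} "
    f"[{res.ci_low:.3f}, {res.ci_high:.3f}] vs mean Fst {mean_fst:.3f} "
    f"-> {'Pst > Fst (directional selection pattern)' if res.estimate > mean_fst else 'no excess'}"
)
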