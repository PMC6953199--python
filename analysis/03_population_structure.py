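"""Population structure of the called panel.

Builds the variance-standardized relationship matrix, runs PCA, assigns
subpopulations (k-means on top PCs with an admixed class), scores assignment
accuracy against the generator's labels, and writes a neighbour-joining tree
from allele-sharing distances for a subsample. Outputs: structure.csv,
nj_tree.nwk.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from soyadapt import io, popstruct
from soyadapt.pipeline import RunConfig, stage_structure, stage_tree

cfg = RunConfig.from_yaml(Path(__file__).parent / "config.yaml")
out = Path(cfg.outdir)
geno, _ = io.read_vcf(out / "called.vcf")
samples = pd.read_csv(out / "samples.csv")

struct = stage_structure(cfg, geno, samples)
explained = struct["explained"]
print(f"PC1-PC3 explained variance fractions: {np.round(explained[:3], 3)}")

assigned = struct["assignment"].labels
truth = samples.set_index("sample_id").reindex(geno.samples)["group"].to_numpy()
non_mixed = assigned != "MIXED"
acc = (assigned[non_mixed] == truth[non_mixed]).mean()
print(
    f"assignment: {non_mixed.sum()}/{len(assigned)} non-admixed, "
    f"accuracy vs truth {acc:.3f}; {int((~non_mixed).sum())} samples MIXED"
)

# NJ tree on a 60-sample subsample (trees on hundreds of tips stay readable)
rng = np.random.default_rng(cfg.seed)
pick = np.sort(rng.choice(geno.n_samples, size=min(60, geno.n_samples), replace=False))
sub = geno.take_samples(pick)
d = popstruct.allele_sharing_distance(sub)
newick = popstruct.nj_tree(d, labels=list(sub.samples))
(out / "nj_tree.nwk").write_text(newick + "\n")
print(f"wrote structure.csv and nj_tree.nwk to {cfg.outdir}/")
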