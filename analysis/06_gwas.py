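"""Association scans for flowering time and the bioclimatic variables.

Runs the iterative fixed/random (FarmCPU-style) scan for each trait with the
top 3 PCs as covariates, applies the Bonferroni threshold convention, and
reports significant trait-associated SNPs (TASs) with genomic inflation
factors. Outputs: gwas_<trait>.tsv per trait and tas_list.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from soyadapt import gwas, io, popstruct
from soyadapt.pipeline import RunConfig

cfg = RunConfig.from_yaml(Path(__file__).parent / "config.yaml")
out = Path(cfg.outdir)
geno, _ = io.read_vcf(out / "called.vcf")
traits = pd.read_csv(out / "traits.csv").set_index("sample_id").reindex(geno.samples)

relmat = popstruct.relationship_matrix(geno)
coords, _ = popstruct.pca(relmat, k=3)
exact, threshold = gwas.bonferroni_threshold(0.01, geno.n_sites)
print(f"threshold: 0.01/{geno.n_sites} = {exact:.3g}, rounded {threshold:.1g}")

tas_rows = []
for trait_name in ("FT_loc1", "FT_loc2", "TAR", "AP", "MDL"):
    y = traits[trait_name].to_numpy(float)
    res = gwas.scan_farmcpu(geno, y, covariates=coords, trait_name=trait_name)
    res.threshold = threshold
    _, lam, _ = gwas.qq_and_inflation(res)
    sig = res.significant()
    io.write_association(out / f"gwas_{trait_name}.tsv", res.table)
    print(
        f"{trait_name}: {len(sig)} TAS at p<={threshold:.0e}, "
        f"lambda_GC={lam:.3f}, pseudo-QTNs={len(res.pseudo_qtns)}"
    )
    for r in sig.itertuples():
        tas_rows.append(
            {"trait": trait_name, "chrom": r.chrom, "pos": int(r.pos),
             "p": r.p, "beta": r.beta, "maf": r.maf}
        )

tas = pd.DataFrame(tas_rows, columns=["trait", "chrom", "pos", "p", "beta", "maf"])
tas.to_csv(out / "tas_list.csv", index=False)
n_unique = len(set(zip(tas["chrom"], tas["pos"]))) if len(tas) else 0
print(f"\n{len(tas)} associations over all traits -> {n_unique} unique TASs")
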