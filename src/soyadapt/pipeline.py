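"""End-to-end stage orchestration shared by the CLI and the analysis drivers.

Each stage function takes the artifacts of the previous stages plus a
RunConfig and writes its outputs under the configured directory, logging
record counts in and out so a run's accounting (sites per filter, samples
removed) can be audited from the logs alone.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioclim, calling, gwas, io, popgen, popstruct, postgwas, selection
from .core import GenotypeMatrix
from .simulate import SimConfig, simulate_panel

logger = logging.getLogger(__name__)

KNOWN_KEYS = {
    "seed",
    "outdir",
    "vcf",
    "passport_csv",
    "trait_csv",
    "intervals",
    "simulate",
    "threshold_alpha",
    "core_panel",
    "n_pcs",
    "impute_method",
    "sample_missing_threshold",
    "min_homozygous_minor",
    "admixture_threshold",
    "fst_quantile",
    "maf_threshold",
}


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "results"
    vcf: str | None = None
    passport_csv: str | None = None
    trait_csv: str | None = None
    intervals: str | None = None
    simulate: dict | None = None
    threshold_alpha: float = 0.01
    core_panel: bool = False
    n_pcs: int = 3
    impute_method: str = "mode"
    sample_missing_threshold: float = 0.80
    min_homozygous_minor: int = 20
    admixture_threshold: float = 0.55
    fst_quantile: float = 0.95
    maf_threshold: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("vcf", "passport_csv", "trait_csv", "intervals"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured {key} path does not exist: {p}")
        return cfg

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_simulate(cfg: RunConfig) -> dict:
    sim_kwargs = dict(cfg.simulate or {})
    sim_kwargs.setdefault("seed", cfg.seed)
    if "fst_targets" in sim_kwargs:
        sim_kwargs["fst_targets"] = {
            tuple(k.split("-")): v for k, v in sim_kwargs["fst_targets"].items()
        }
    sim = SimConfig(**sim_kwargs)
    panel = simulate_panel(sim)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel["samples"].to_csv(out / "samples.csv", index=False)
    panel["traits"].to_csv(out / "traits.csv", index=False)
    truth = panel["truth"]
    pd.DataFrame(
        {
            "causal_index": truth.causal_indices,
            "chrom": truth.true_genotypes.sites["chrom"].to_numpy()[truth.causal_indices],
            "pos": truth.true_genotypes.sites["pos"].to_numpy()[truth.causal_indices],
            "effect_days": truth.causal_effects,
        }
    ).to_csv(out / "truth_causal.csv", index=False)
    io.write_vcf(out / "panel.vcf", panel["genotypes"], depths=panel["depths"])
    logger.info(
        "simulate: %d samples, %d SNPs", panel["genotypes"].n_samples, panel["genotypes"].n_sites
    )
    return panel


def stage_call(cfg: RunConfig, depths) -> GenotypeMatrix:
    geno = calling.run_calling_pipeline(
        depths,
        sample_missing_threshold=cfg.sample_missing_threshold,
        impute_method=cfg.impute_method,
        min_homozygous_minor=cfg.min_homozygous_minor,
    )
    logger.info("call: %d sites x %d samples retained", geno.n_sites, geno.n_samples)
    return geno


def stage_structure(cfg: RunConfig, geno: GenotypeMatrix, samples: pd.DataFrame) -> dict:
    relmat = popstruct.relationship_matrix(geno)
    coords, explained = popstruct.pca(relmat, k=max(cfg.n_pcs, 4))
    ids = list(geno.samples)
    sub = samples.set_index("sample_id").reindex(ids)
    assign = popstruct.assign_groups(
        coords,
        k=4,
        admixture_threshold=cfg.admixture_threshold,
        seed=cfg.seed,
        latitudes=sub["latitude"].to_numpy(),
        wild_flags=(sub["group"] == "WILD").to_numpy() if "group" in sub else None,
    )
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "sample_id": ids,
            "assigned_group": assign.labels,
            **{f"PC{i+1}": coords[:, i] for i in range(coords.shape[1])},
        }
    ).to_csv(out / "structure.csv", index=False)
    return {"relmat": relmat, "coords": coords, "explained": explained, "assignment": assign}


def stage_tree(cfg: RunConfig, geno: GenotypeMatrix) -> str:
    d = popstruct.allele_sharing_distance(geno)
    newick = popstruct.nj_tree(d, labels=list(geno.samples))
    out = Path(cfg.outdir)
    (out / "nj_tree.nwk").write_text(newick + "\n")
    return newick


def stage_ldscan(cfg: RunConfig, geno: GenotypeMatrix) -> popgen.LDProfile:
    pairs = popgen.ld_r2(geno)
    profile = popgen.ld_decay_profile(pairs)
    out = Path(cfg.outdir)
    pd.DataFrame(
        {
            "bin_start_bp": profile.bin_edges_bp[:-1],
            "mean_r2": profile.mean_r2,
            "n_pairs": profile.counts,
        }
    ).to_csv(out / "ld_profile.csv", index=False)
    return profile


def stage_gwas(
    cfg: RunConfig,
    geno: GenotypeMatrix,
    trait: np.ndarray,
    covariates: np.ndarray | None,
    trait_name: str,
) -> gwas.AssociationResult:
    result = gwas.scan_farmcpu(geno, trait, covariates, trait_name=trait_name)
    n_tests = geno.n_sites
    alpha = 0.01
    exact, rounded = gwas.bonferroni_threshold(alpha, n_tests)
    result.threshold = 1e-6 if cfg.core_panel else rounded
    _, lam, _ = gwas.qq_and_inflation(result)
    result.lambda_gc = lam
    out = Path(cfg.outdir)
    io.write_association(out / f"gwas_{trait_name}.tsv", result.table)
    logger.info(
        "gwas[%s]: %d significant at %.1e (lambda_GC %.3f)",
        trait_name,
        len(result.significant()),
        result.threshold,
        lam,
    )
    return result


#: canonical stage order; ``upto`` stops the pipeline after the named stage
STAGE_ORDER = (
    "simulate",
    "call",
    "filter",
    "structure",
    "ldscan",
    "bioclim",
    "gwas",
    "postgwas",
    "selection",
    "report",
    "all",
)


def run_all(cfg: RunConfig, upto: str = "all") -> dict:
    """Pipeline through the ``upto`` stage on a (simulated or provided) panel."""
    if upto not in STAGE_ORDER:
        raise ValueError(f"unknown stage {upto!r}")
    stop_at = STAGE_ORDER.index(upto)

    def done(stage: str) -> bool:
        return STAGE_ORDER.index(stage) >= stop_at and upto != "all"

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    if cfg.simulate is not None or cfg.vcf is None:
        panel = stage_simulate(cfg)
        depths = panel["depths"]
        samples = panel["samples"]
        traits = panel["traits"]
        stages.append("simulate")
    else:
        geno_in, depths = io.read_vcf(cfg.vcf)
        samples = pd.read_csv(cfg.passport_csv)
        traits = pd.read_csv(cfg.trait_csv)
        panel = {"genotypes": geno_in, "depths": depths}

    if done("simulate"):
        io.write_manifest(out / "manifest.json", cfg.as_dict(), cfg.seed, stages)
        return panel

    if depths is not None:
        geno = stage_call(cfg, depths)
        stages.append("call")
    else:
        geno = panel["genotypes"]

    if done("filter"):
        io.write_manifest(out / "manifest.json", cfg.as_dict(), cfg.seed, stages)
        return {"genotypes": geno}

    # align passport/trait tables with retained samples
    ids = list(geno.samples)
    samples_idx = samples.set_index("sample_id").reindex(ids).reset_index()
    traits_idx = traits.set_index("sample_id").reindex(ids).reset_index()

    struct = stage_structure(cfg, geno, samples_idx)
    stages.append("structure")
    if done("structure"):
        io.write_manifest(out / "manifest.json", cfg.as_dict(), cfg.seed, stages)
        return {"genotypes": geno, "structure": struct}
    profile = stage_ldscan(cfg, geno)
    stages.append("ldscan")
    if done("ldscan"):
        io.write_manifest(out / "manifest.json", cfg.as_dict(), cfg.seed, stages)
        return {"genotypes": geno, "structure": struct, "ld_profile": profile}

    # bioclim traits (recomputed deterministically from passports)
    mdl_col = [
        bioclim.mdl(
            samples_idx["latitude"].iat[i],
            int(samples_idx["sowing_doy"].iat[i]),
            int(samples_idx["harvest_doy"].iat[i]),
        )
        for i in range(len(samples_idx))
    ]
    traits_idx["MDL"] = mdl_col
    corr, _ = bioclim.trait_correlations(
        traits_idx, [c for c in ("TAR", "AP", "MDL", "FT_loc1", "FT_loc2") if c in traits_idx]
    )
    corr.to_csv(out / "trait_correlations.csv")
    stages.append("bioclim")

    covars = struct["coords"][:, : cfg.n_pcs]
    results = {}
    for trait_name in ("FT_loc1", "FT_loc2", "TAR", "AP", "MDL"):
        if trait_name not in traits_idx:
            continue
        y = traits_idx[trait_name].to_numpy(float)
        results[trait_name] = stage_gwas(cfg, geno, y, covars, trait_name)
    stages.append("gwas")

    # post-GWAS on flowering-time TASs
    ft_res = results.get("FT_loc1")
    report = {}
    if ft_res is not None:
        sig = ft_res.significant()
        tas_list = [(r.chrom, int(r.pos)) for r in sig.itertuples()]
        if tas_list:
            dose = np.stack(
                [geno.codes[geno.site_index(*t)].astype(float) for t in tas_list]
            )
            y = traits_idx["FT_loc1"].to_numpy(float)
            r2_full, pve_j, _ = postgwas.pve(dose, y)
            report["r2_full"] = r2_full
            blocks = [popgen.ld_block(geno, *t) for t in tas_list]
            io.write_blocks_bed(out / "tas_blocks.bed", blocks)
            wild_mask = (samples_idx["group"] == "WILD").to_numpy()
            land_mask = ~wild_mask
            if wild_mask.any():
                dom = selection.domestication_scan(
                    geno, wild_mask, land_mask, tas_list, fst_quantile=cfg.fst_quantile
                )
                div = selection.diversification_scan(
                    geno,
                    samples_idx["group"].to_numpy(),
                    tas_list,
                    fst_quantile=cfg.fst_quantile,
                    maf_threshold=cfg.maf_threshold,
                )
                sel = selection.classify(dom, div)
                sel.table.to_csv(out / "selection_report.csv", index=False)
                report["selection_counts"] = sel.category_counts
        stages.append("postgwas")
        stages.append("selection")

    vc = postgwas.heritability(struct["relmat"], traits_idx["FT_loc1"].to_numpy(float))
    report["h2_FT_loc1"] = vc.h2
    pd.DataFrame([report]).to_csv(out / "report.csv", index=False)
    stages.append("report")

    io.write_manifest(out / "manifest.json", cfg.as_dict(), cfg.seed, stages)
    return {
        "genotypes": geno,
        "structure": struct,
        "ld_profile": profile,
        "gwas": results,
        "report": report,
    }
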