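"""End-to-end pipeline: simulate -> markers -> structure -> BLUPs -> GWAS.

Each stage reads its inputs from and writes its outputs to one artifact
directory, so stages can be run individually (from the CLI) or chained
with :func:`run_pipeline`, which also writes a manifest recording the
seed, a hash of the configuration, per-stage record counts and a sha256
per output file.  Rerunning with the same configuration reproduces every
artifact byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from namhap import assoc, io, markers, phenostats, popstruct, simcore

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

_FLOAT_FMT = "%.10g"


@dataclass
class QTLSpec:
    """One simulated QTL: locus by snp_id, additive effect of allele 1."""

    snp_id: str
    effect: float
    gene: str = "-"


@dataclass
class TraitSpec:
    name: str
    intercept: float = 0.0
    residual_sd: float = 1.0
    qtl: list[QTLSpec] = field(default_factory=list)
    culling_window: tuple[float, float] | None = None


@dataclass
class PipelineConfig:
    """All knobs of the synthetic end-to-end run.

    Marker/GWAS thresholds default to the published pipeline values
    (LD r^2 0.7, MAF 0.01, tag missingness 0.06, 10,000 kb window,
    codominant/dominant missingness cuts 40%/20%, marker call rate 70%,
    marker heterozygosity 6%, line call rate 50%, alpha 0.0005, top 10
    eigenvectors).
    """

    seed: int = 1
    # genome
    n_chrom: int = 3
    length_cM: float = 150.0
    n_loci_per_chrom: int = 200
    bp_per_cM: float = 1_000_000.0
    dominant_every: int = 0
    # design
    n_exotic: int = 10
    n_families: int = 10
    n_lines_per_family: int = 25
    max_culling_retries: int = 200
    # genotyping
    missing_rate: float = 0.02
    # traits
    traits: list[TraitSpec] = field(default_factory=list)
    # trial
    n_blocks: int = 2
    sigma_block: float = 0.5
    trial_id: str = "TRIAL1"
    # marker thresholds
    r2_min: float = 0.7
    maf_min: float = 0.01
    tag_max_missing: float = 0.06
    window_kb: float = 10_000.0
    max_missing_codominant: float = 0.40
    max_missing_dominant: float = 0.20
    min_marker_call_rate: float = 0.70
    max_marker_het: float = 0.06
    min_line_call_rate: float = 0.50
    impute_k: int = 5
    impute_l: int = 30
    # GWAS
    alpha: float = 0.0005
    n_eigenvectors: int = 10
    bonferroni: bool = False
    anchor_window_bp: int = 0

    def validate(self) -> None:
        checks = [
            0 <= self.missing_rate < 1,
            0 < self.r2_min <= 1,
            0 <= self.maf_min < 0.5,
            0 <= self.tag_max_missing <= 1,
            self.window_kb > 0,
            0 < self.alpha < 1,
            self.n_eigenvectors >= 0,
        ]
        if not all(checks):
            raise ValueError("configuration thresholds out of range")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        traits = [
            TraitSpec(
                name=t["name"],
                intercept=t.get("intercept", 0.0),
                residual_sd=t.get("residual_sd", 1.0),
                qtl=[
                    QTLSpec(q["snp_id"], q["effect"], q.get("gene", "-"))
                    for q in t.get("qtl", [])
                ],
                culling_window=tuple(t["culling_window"]) if t.get("culling_window") else None,
            )
            for t in raw.pop("traits", [])
        ]
        cfg = cls(**raw, traits=traits)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def demo_config(seed: int = 1) -> PipelineConfig:
    """A small two-trait demonstration run with one major maturity locus
    and one major height locus (placed mid-chromosome)."""
    cfg = PipelineConfig(
        seed=seed,
        traits=[
            TraitSpec(
                name="maturity",
                intercept=55.0,
                residual_sd=1.5,
                qtl=[QTLSpec("Schr1_100", 6.0, gene="Ppd-like")],
            ),
            TraitSpec(
                name="height",
                intercept=95.0,
                residual_sd=3.0,
                qtl=[QTLSpec("Schr2_100", -12.0, gene="Rht-like")],
            ),
        ],
    )
    return cfg


# ---------------------------------------------------------------------------
# stage implementations


def _build_world(cfg: PipelineConfig):
    gmap = simcore.default_genetic_map(
        cfg.n_chrom,
        cfg.length_cM,
        cfg.n_loci_per_chrom,
        cfg.bp_per_cM,
        cfg.dominant_every,
    )
    rng = np.random.default_rng(cfg.seed)
    panel = simcore.simulate_founders(gmap, cfg.n_exotic, rng)
    trait_models = {}
    culling = {}
    for t in cfg.traits:
        trait_models[t.name] = simcore.TraitArchitecture(
            name=t.name,
            qtl=[(q.snp_id, {0: 0.0, 1: q.effect}) for q in t.qtl],
            intercept=t.intercept,
            residual_sd=t.residual_sd,
        )
        if t.culling_window is not None:
            culling[t.name] = t.culling_window
    if cfg.n_families < 1:
        raise ValueError("design has zero families")
    fams = []
    for i in range(cfg.n_families):
        ref = panel.reference[i % 2]
        exo = panel.exotic[i % len(panel.exotic)]
        prefix = "GL" if i % 2 == 0 else "SC"
        fams.append(
            simcore.FamilySpec(f"{prefix}{exo}", ref, exo, cfg.n_lines_per_family)
        )
    design = simcore.NAMDesign(fams, culling, cfg.max_culling_retries)
    return gmap, panel, trait_models, design, rng


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    gmap, panel, trait_models, design, rng = _build_world(cfg)
    pop = simcore.simulate_nam(design, panel, gmap, trait_models, rng)
    gm = simcore.genotype_population(
        pop, gmap, cfg.missing_rate, rng, include_parents=True
    )
    io.write_vcf(gm, outdir / "genotypes.vcf")
    io.write_map_tsv(gmap, outdir / "map.tsv")
    gm.line_table.to_csv(outdir / "lines.tsv", sep="\t", index=False)
    pop.families.to_csv(outdir / "families.tsv", sep="\t", index=False)
    designs = [
        simcore.rcbd_design(
            cfg.trial_id, pop.line_ids, cfg.n_blocks, cfg.sigma_block, rng
        )
    ]
    pheno = simcore.simulate_trials(pop, gmap, trait_models, designs, rng)
    pheno.to_csv(outdir / "phenotypes.csv", index=False, float_format=_FLOAT_FMT)
    # truth files for downstream oracles
    truth_frac = simcore.true_exotic_fractions(pop)
    truth_frac.to_frame().reset_index(names="line_id").to_csv(
        outdir / "truth_exotic_fraction.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    qtl_rows = []
    for t in cfg.traits:
        for q in t.qtl:
            loc = gmap.locus_index(q.snp_id)
            qtl_rows.append(
                (
                    t.name,
                    q.snp_id,
                    gmap.table["chrom"].iat[loc],
                    int(gmap.table["pos_bp"].iat[loc]),
                    q.effect,
                    q.gene,
                )
            )
    pd.DataFrame(
        qtl_rows, columns=["trait", "snp_id", "chrom", "pos_bp", "effect", "gene"]
    ).to_csv(outdir / "truth_qtl.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return {"lines": pop.n_lines, "snps": gmap.n_loci, "plots": len(pheno)}


def stage_markers(cfg: PipelineConfig, outdir: Path) -> dict:
    lines = pd.read_csv(outdir / "lines.tsv", sep="\t").fillna("")
    gm = io.read_vcf(outdir / "genotypes.vcf", outdir / "map.tsv", lines)
    gm, miss_report = markers.filter_snps_by_missing(
        gm, cfg.max_missing_codominant, cfg.max_missing_dominant
    )
    gm = markers.ld_knn_impute(gm, cfg.impute_k, cfg.impute_l)
    fams = pd.read_csv(outdir / "families.tsv", sep="\t")
    backgrounds = list(pd.unique(fams["reference"]))
    group_lists = []
    for bg in backgrounds:
        group_lists.append(
            markers.tag_snps(
                gm,
                r2_min=cfg.r2_min,
                maf_min=cfg.maf_min,
                max_missing=cfg.tag_max_missing,
                window_kb=cfg.window_kb,
                background=bg,
            )
        )
    groups = markers.merge_tag_groups(group_lists, gm.snps)
    hms = markers.build_haplotype_markers(gm, groups)
    hms, filt_report = markers.filter_haplotype_markers_and_lines(
        hms,
        cfg.min_marker_call_rate,
        cfg.max_marker_het,
        cfg.min_line_call_rate,
    )
    io.write_haplotype_markers(
        hms, outdir / "marker_definitions.tsv", outdir / "marker_calls.tsv"
    )
    return {
        **miss_report,
        **filt_report,
        "tag_groups": len(groups),
        "haplotype_markers": hms.n_markers,
        "mean_alleles_per_marker": float(
            np.mean([m.n_alleles for m in hms.markers])
        ),
    }


def _read_markers(outdir: Path):
    return io.read_haplotype_markers(
        outdir / "marker_definitions.tsv", outdir / "marker_calls.tsv"
    )


def stage_structure(cfg: PipelineConfig, outdir: Path) -> dict:
    hms = _read_markers(outdir)
    gsc = popstruct.gsc_matrix(hms)
    gsc.to_frame().to_csv(outdir / "gsc.tsv", sep="\t", float_format=_FLOAT_FMT)
    es = popstruct.eigen_structure(gsc, cfg.n_eigenvectors)
    ev = es.to_frame()
    ev.index.name = "line_id"
    ev.to_csv(outdir / "eigenvectors.tsv", sep="\t", float_format=_FLOAT_FMT)
    pd.DataFrame(
        {
            "eigenvector": [f"EV{i + 1}" for i in range(len(es.percent_variance))],
            "percent_variance": es.percent_variance,
        }
    ).to_csv(outdir / "eigen_variance.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return {
        "gsc_lines": len(gsc.ids),
        "ev1_percent": float(es.percent_variance[0]),
    }


def stage_introgression(cfg: PipelineConfig, outdir: Path) -> dict:
    hms = _read_markers(outdir)
    fams = pd.read_csv(outdir / "families.tsv", sep="\t")
    profile = popstruct.exotic_allele_frequency(hms, fams)
    profile.locus_freq.to_csv(
        outdir / "introgression_freq.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    tracks = popstruct.introgression_tracks(profile)
    tracks.to_csv(
        outdir / "introgression_tracks.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    return {
        "informative_markers": int(profile.locus_freq["marker_id"].nunique()),
        "genome_wide_exotic_freq": profile.genome_wide_mean(),
    }


def stage_blup(cfg: PipelineConfig, outdir: Path) -> dict:
    pheno = pd.read_csv(outdir / "phenotypes.csv")
    blup_rows = []
    herit_rows = []
    for (trial, trait), _ in pheno.groupby(["trial", "trait"]):
        fit = phenostats.fit_trial(pheno, trait, trial)
        h2 = phenostats.generalized_heritability(fit)
        for lid in fit.blups.index:
            blup_rows.append(
                (lid, trait, trial, fit.mu + fit.blups[lid], fit.pev[lid])
            )
        vals = fit.mu + fit.blups
        herit_rows.append(
            (
                trait,
                trial,
                float(vals.min()),
                float(vals.max()),
                float(vals.mean()),
                len(vals),
                float(vals.std(ddof=1)),
                h2,
            )
        )
    pd.DataFrame(
        blup_rows, columns=["line_id", "trait", "trial", "blup", "pev"]
    ).to_csv(outdir / "blups.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(
        herit_rows, columns=["trait", "trial", "min", "max", "mean", "N", "SD", "H2"]
    ).to_csv(outdir / "heritability.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return {"fits": len(herit_rows)}


def stage_gwas(cfg: PipelineConfig, outdir: Path) -> dict:
    hms = _read_markers(outdir)
    blups = pd.read_csv(outdir / "blups.tsv", sep="\t")
    ev = pd.read_csv(outdir / "eigenvectors.tsv", sep="\t").set_index("line_id")
    truth = pd.read_csv(outdir / "truth_qtl.tsv", sep="\t")
    anchors = truth.rename(columns={"snp_id": "marker_id"})[
        ["marker_id", "gene", "chrom", "pos_bp"]
    ]
    all_results = []
    all_effects = []
    for (trial, trait), grp in blups.groupby(["trial", "trait"]):
        y = grp.set_index("line_id")["blup"]
        pre = assoc.stage1_scan(hms, y, ev, cfg.alpha, cfg.n_eigenvectors)
        res = assoc.stage2_stepwise(
            hms, pre, y, ev, cfg.alpha, cfg.n_eigenvectors, cfg.bonferroni
        )
        window = cfg.anchor_window_bp or int(cfg.window_kb * 1000)
        res = assoc.annotate_known_genes(res, anchors, window_bp=window)
        tab = assoc.results_table(res, trait=trait, environment=trial)
        all_results.append(tab)
        for r in res:
            for a, e in r.allele_effects.items():
                all_effects.append((trait, trial, r.marker_id, a, e))
    results = (
        pd.concat(all_results, ignore_index=True)
        if all_results
        else assoc.results_table([])
    )
    results.to_csv(
        outdir / "qtl_results.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    pd.DataFrame(
        all_effects, columns=["trait", "trial", "marker_id", "allele", "effect"]
    ).to_csv(outdir / "allele_effects.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    return {"qtl": len(results)}


STAGES = {
    "simulate": stage_simulate,
    "markers": stage_markers,
    "structure": stage_structure,
    "introgression": stage_introgression,
    "blup": stage_blup,
    "gwas": stage_gwas,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | os.PathLike,
    stages: list[str] | None = None,
) -> dict:
    """Run the pipeline stages in order, writing artifacts and a manifest.

    Any stage error aborts the run; the manifest written so far (with the
    failing stage named) is persisted before the exception propagates.
    Returns the manifest dictionary.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = stages or list(STAGES)
    manifest: dict = {
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": {},
        "files": {},
    }
    mpath = outdir / "manifest.json"
    for name in stages:
        if name not in STAGES:
            raise KeyError(f"unknown stage {name!r}")
        try:
            counts = STAGES[name](cfg, outdir)
        except Exception:
            manifest["failed_stage"] = name
            mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise
        manifest["stages"][name] = counts
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["files"][f.name] = _sha256(f)
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
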