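"""Configuration and stage orchestration.

``run_pipeline`` wires the stages (simulate, discover, design, qc, map,
blocks, deltak) through files in an output directory, so each stage can
also be run alone on externally supplied inputs of the same formats.
Every output carries a provenance header; reruns with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import design as design_mod
from . import diversity as div_mod
from . import io as io_mod
from . import qc as qc_mod
from .discovery import DiscoveryParams, annotate_genes, call_snps, \
    categorize_snps, filter_adjacent
from .design import DesignParams
from .mapping import F2Matrix, build_map, double_crossover_scan, rf_heatmap
from .pileup import build_genotype_table
from .simulate import SimConfig, make_f2_truth, panel_group_labels, \
    plant_snps, simulate_diversity_panel, simulate_f2, \
    simulate_panel_pileups, simulate_reference

log = logging.getLogger("peppermap")

STAGES = ("simulate", "discover", "design", "qc", "map", "blocks", "deltak")


@dataclass
class PipelineConfig:
    """All stage parameters plus the scale of the simulated inputs."""

    seed: int = 1
    discovery: DiscoveryParams = field(default_factory=DiscoveryParams)
    design: DesignParams = field(default_factory=DesignParams)
    sim: SimConfig = field(default_factory=SimConfig)
    # mapping thresholds
    lod_min: float = 3.0
    r_max: float = 0.4
    dco_sd_mult: float = 3.0
    dco_flank_reach: int = 5
    bin_min_shared: int = 1
    # simulated-input scale (kept desk-sized by default)
    sim_n_chrom: int = 2
    sim_chrom_len: int = 200_000
    sim_n_genes: int = 150
    sim_n_snps: int = 250
    sim_site_window: int | None = 60
    sim_f2_markers_per_chrom: int = 40
    sim_f2_chrom_cM: float = 100.0
    sim_diversity_groups: int = 3
    sim_diversity_markers: int = 400
    planted_block: tuple[str, tuple[int, int]] | None = ("G1", (150, 172))
    focal_marker_index: int = 161

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("discovery", DiscoveryParams),
                         ("design", DesignParams), ("sim", SimConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if d.get("planted_block") is not None:
            g, rng_ = d["planted_block"]
            d["planted_block"] = (g, tuple(rng_))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs missing input: {path}")
    return path


def run_pipeline(config: PipelineConfig, stages: Sequence[str],
                 out_dir: str | Path) -> dict:
    """Run the requested stages in dependency order; returns stage stats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]
    header = io_mod.provenance_header(config.seed, config.to_dict())
    stats: dict = {}

    if "simulate" in stages:
        cfg = config.sim
        ref = simulate_reference(config.sim_n_chrom, config.sim_chrom_len,
                                 config.sim_n_genes, config.seed)
        import numpy as np
        rng = np.random.default_rng(config.seed + 1)
        truth = plant_snps(ref, config.sim_n_snps, rng)
        io_mod.write_fasta(ref.sequence, out / "reference.fasta")
        io_mod.write_gff3(ref.genes, out / "genes.gff3")
        pileup_dir = out / "pileups"
        paths, truth_table = simulate_panel_pileups(
            ref, truth, cfg, pileup_dir, site_window=config.sim_site_window)
        truth.snps.to_csv(out / "truth_snps.tsv", sep="\t", index=False)
        io_mod.write_labels(panel_group_labels(truth, cfg), out / "groups.tsv")
        f2_truth = make_f2_truth(config.sim_n_chrom,
                                 config.sim_f2_markers_per_chrom,
                                 chrom_cM=config.sim_f2_chrom_cM,
                                 seed=config.seed + 2)
        f2 = simulate_f2(f2_truth, cfg.n_f2, cfg)
        f2.write_tsv(out / "f2_abh.tsv", header=header)
        f2_truth.f2_map.to_csv(out / "truth_f2_map.tsv", sep="\t", index=False)
        geno, info, labels = simulate_diversity_panel(
            config.sim_diversity_groups, config.sim_diversity_markers, cfg,
            planted_block=config.planted_block)
        io_mod.write_matrix_tsv(geno, out / "diversity_genotypes.tsv", header)
        io_mod.write_matrix_tsv(info, out / "diversity_markers.tsv", header)
        io_mod.write_labels(labels, out / "diversity_groups.tsv")
        stats["simulate"] = {"samples": len(paths),
                             "planted_snps": len(truth.snps),
                             "f2_markers": len(f2.markers)}
        log.info("simulate: %s", stats["simulate"])

    if "discover" in stages:
        pileup_dir = _require(out / "pileups", "discover")
        pileups = {p.stem: p for p in sorted(pileup_dir.glob("*.pileup"))}
        if not pileups:
            raise FileNotFoundError(
                f"stage 'discover' found no .pileup files in {pileup_dir}")
        groups = io_mod.read_labels(_require(out / "groups.tsv", "discover"))
        genes = io_mod.read_gff3(_require(out / "genes.gff3", "discover"))
        table = build_genotype_table(pileups, config.discovery)
        snps = call_snps(table, config.discovery)
        snps = filter_adjacent(snps, config.discovery)
        snps = categorize_snps(snps, table, groups, config.discovery)
        snps = annotate_genes(snps, genes)
        io_mod.write_vcf(snps, out / "snps.vcf", samples=table.samples,
                         seed=config.seed)
        io_mod.write_matrix_tsv(table.to_frame(), out / "genotype_table.tsv",
                                header)
        stats["discover"] = {"master_sites": len(table.sites),
                             "snps": len(snps)}
        log.info("discover: %s", stats["discover"])

    if "design" in stages:
        from .simulate import SimReference
        seqs = io_mod.read_fasta(_require(out / "reference.fasta", "design"))
        genes = io_mod.read_gff3(_require(out / "genes.gff3", "design"))
        _require(out / "snps.vcf", "design")
        snps = _read_vcf_snps(out / "snps.vcf")
        ref = SimReference({c: len(s) for c, s in seqs.items()}, genes, seqs)
        cands = design_mod.build_candidates(snps, ref)
        manifest = design_mod.select_markers(cands, config.design)
        manifest.to_csv(out / "manifest.csv", index=False)
        stats["design"] = {
            "candidates": len(cands), "manifest": len(manifest),
            "by_category": design_mod.manifest_category_counts(manifest)}
        log.info("design: %s", stats["design"])

    if "qc" in stages:
        geno = io_mod.read_matrix_tsv(
            _require(out / "diversity_genotypes.tsv", "qc"), dtype=str)
        qcs = qc_mod.qc_all(qc_mod.ArrayGenotypes(geno))
        io_mod.write_matrix_tsv(qc_mod.qc_frame(qcs), out / "marker_qc.tsv",
                                header)
        summary = qc_mod.summarize_qc(qcs)
        with open(out / "qc_summary.csv", "w") as fh:
            for name, table_ in summary.items():
                fh.write(f"# {name}\n")
                table_.to_csv(fh)
        stats["qc"] = qc_mod.status_counts(qcs)
        log.info("qc: %s", stats["qc"])

    if "map" in stages:
        f2 = F2Matrix.read_tsv(_require(out / "f2_abh.tsv", "map"))
        build = build_map(f2, lod_min=config.lod_min, r_max=config.r_max,
                          bin_min_shared=config.bin_min_shared)
        io_mod.write_matrix_tsv(build.gmap.to_frame(), out / "map.tsv", header)
        dco, flags = double_crossover_scan(
            f2.codes, flank_reach=config.dco_flank_reach,
            sd_mult=config.dco_sd_mult)
        pd.DataFrame({"marker": f2.markers, "dco": dco, "flagged": flags}
                     ).to_csv(out / "dco_report.tsv", sep="\t", index=False)
        for gi, g in enumerate(build.gmap.groups[:3]):
            if len(g) >= 3:
                mat, stat = rf_heatmap(g, build.R, build.marker_index)
                mat.round(4).to_csv(out / f"rf_group{gi + 1}.tsv", sep="\t")
        stats["map"] = {"groups": len(build.gmap.groups),
                        "total_cM": round(build.gmap.total_cM, 1),
                        "bins": build.gmap.n_bins}
        log.info("map: %s", stats["map"])

    if "blocks" in stages:
        geno = io_mod.read_matrix_tsv(
            _require(out / "diversity_genotypes.tsv", "blocks"), dtype=str)
        info = io_mod.read_matrix_tsv(
            _require(out / "diversity_markers.tsv", "blocks"))
        labels = io_mod.read_labels(
            _require(out / "diversity_groups.tsv", "blocks"))
        group = (config.planted_block[0] if config.planted_block
                 else sorted(set(labels.values()))[0])
        focal = str(info.index[config.focal_marker_index])
        block = div_mod.monomorphic_block(geno, info, labels, focal, group)
        div_mod.block_report(block).to_csv(out / "block_report.tsv",
                                           sep="\t", index=False)
        stats["blocks"] = {"n_markers": block.n_markers,
                           "bp_span": block.bp_span}
        log.info("blocks: %s", stats["blocks"])

    if "deltak" in stages:
        lnp_path = out / "lnp.csv"
        if not lnp_path.exists():
            from .simulate import simulate_replicate_loglik
            lnp = simulate_replicate_loglik(range(1, 11), true_k=5,
                                            seed=config.seed)
            lnp.to_csv(lnp_path, index=False)
        lnp = pd.read_csv(lnp_path)
        table = div_mod.evanno_delta_k(lnp)
        table.to_csv(out / "delta_k.csv", index=False)
        stats["deltak"] = {"best_K": div_mod.best_k(table)}
        log.info("deltak: %s", stats["deltak"])

    return stats


def _read_vcf_snps(path: Path) -> list:
    """Read back a discovered-SNP VCF (the package's own dialect)."""
    from .discovery import Snp
    snps = []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            f = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = f[9:]
                continue
            info = dict(kv.split("=", 1) for kv in f[7].split(";") if "=" in kv)
            genotypes = {}
            for s, gt in zip(samples, f[9:]):
                if gt.startswith("."):
                    genotypes[s] = "--"
                else:
                    allele = {"0": f[3], "1": f[4]}
                    genotypes[s] = "".join(sorted(
                        allele.get(a, ".") for a in gt.split("/")))
            snps.append(Snp(f[0], int(f[1]), f[3], f[4],
                            category=info.get("CATEGORY"),
                            gene=info.get("GENE"), genotypes=genotypes))
    return snps
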