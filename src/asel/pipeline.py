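"""End-to-end orchestration: simulate -> pseudogenome -> call -> classify ->
patterns -> annotate -> diversity -> enrich, with a reproducibility manifest.

Stages communicate only through files in the run directory, so any stage
can be re-run or inspected in isolation.  A manifest written last records
the configuration hash, seed, per-stage record counts and a checksum of
every output; identical configuration and seed reproduce identical
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import calling, classify, diversity, enrichment, io, patterns, pseudogenome, simulate
from .types import Genotype

logger = logging.getLogger("asel")


class PreflightError(ValueError):
    """Configuration problem detected before any stage runs."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: dict[str, dict] = dataclasses.field(default_factory=dict)
    checksums: dict[str, str] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PreflightError(f"{path}: config must be a YAML mapping")
    return cfg


def run_pipeline(config: dict, out_dir: str | Path, seed: int) -> RunManifest:
    """Execute all stages in dependency order; returns the manifest.

    The config needs either a ``simulation`` block or a ``counts`` path;
    missing input files abort before any stage runs.  A stage failure
    raises :class:`StageError` naming the stage, with earlier outputs
    retained on disk.
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- pre-flight
    sim_block = config.get("simulation")
    counts_path = config.get("counts")
    if sim_block is None and counts_path is None:
        raise PreflightError("config must provide a 'simulation' block or a 'counts' path")
    for key in ("counts", "tpm", "vcf", "gff3", "reference"):
        p = config.get(key)
        if p is not None and not Path(p).exists():
            raise PreflightError(f"input file for {key!r} not found: {p}")

    config_hash = hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()
    manifest = RunManifest(config_hash=config_hash, seed=seed, version=__version__)
    t0 = time.time()

    def record(stage: str, files: dict[str, Path], counts: dict[str, int]) -> None:
        for name, path in files.items():
            manifest.checksums[path.name] = _sha256(path)
        manifest.stages[stage] = {**counts, "elapsed_s": round(time.time() - t0, 2)}
        logger.info("stage %s done: %s", stage, counts)

    conditions = None
    truth = None

    # ---- simulate
    if sim_block is not None:
        stage = "simulate"
        try:
            sim_cfg = simulate.SimulationConfig(**{**sim_block, "seed": seed})
            conditions = list(sim_cfg.conditions)
            records, truth = simulate.simulate_allele_counts(sim_cfg)
            tpm, expr_truth = simulate.simulate_expression(sim_cfg)
            variants, genes, reference, var_truth = simulate.simulate_parental_variants(
                n_genes=min(sim_cfg.n_genes, 50), seed=seed + 2
            )
            hm1, hm2, hap_truth = simulate.simulate_two_population_haplotypes(seed=seed + 3)
            qtl = simulate.simulate_qtl_gene_set(truth, seed=seed + 4)
            truth.pattern_type = expr_truth.pattern_type
            truth.promoter_variants = var_truth.promoter_variants
            truth.cds_variants = var_truth.cds_variants
            truth.sweep_interval = hap_truth.sweep_interval
            truth.sweep_population = hap_truth.sweep_population

            files = {
                "counts": out / "counts.tsv", "tpm": out / "tpm.tsv",
                "vcf": out / "parental_variants.vcf", "gff3": out / "genes.gff3",
                "reference": out / "reference.fa",
                "pop1": out / "haplotypes_pop1.tsv", "pop2": out / "haplotypes_pop2.tsv",
                "truth": out / "truth.json",
            }
            io.write_allele_counts(records, files["counts"])
            io.write_tpm(tpm, files["tpm"])
            io.write_vcf(variants, files["vcf"])
            io.write_gff3(genes, files["gff3"])
            io.write_fasta(reference, files["reference"])
            io.write_haplotypes(hm1, files["pop1"])
            io.write_haplotypes(hm2, files["pop2"])
            files["truth"].write_text(json.dumps(truth.to_dict(), indent=1))
            record(stage, files, {"n_count_records": len(records), "n_variants": len(variants)})
            config = {**config, **{k: str(v) for k, v in files.items() if k != "truth"}}
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # ---- pseudogenome
    stage = "pseudogenome"
    try:
        if config.get("vcf") and config.get("reference"):
            variants = io.read_vcf(config["vcf"])
            reference = io.read_fasta(config["reference"])
            thresholds = pseudogenome.FilterThresholds(
                **config.get("pseudogenome", {})
            )
            kept = pseudogenome.snps_only(pseudogenome.filter_variants(variants, thresholds))
            pseudo = pseudogenome.build_pseudogenome(reference, kept)
            path = out / "pseudogenome.fa"
            io.write_fasta(pseudo, path)
            record(stage, {"pseudo": path}, {"n_substituted": len(kept)})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- call
    stage = "call"
    try:
        records = io.read_allele_counts(config["counts"])
        if conditions is None:
            conditions = sorted({r.sample.condition for r in records})
        call_cfg = config.get("calling", {})
        calls = calling.call_asegs_from_counts(records, **call_cfg)
        path = out / "asegs.tsv"
        io.write_aseg_calls(calls, path)
        record(stage, {"asegs": path},
               {"n_calls": len(calls), "n_aseg": sum(c.is_aseg for c in calls)})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- classify
    stage = "classify"
    try:
        categories = classify.classify_all(calls, conditions)
        summary = classify.summarize_categories(categories, calls)
        table = classify.bias_ratio_table(records)
        try:
            summary["reciprocal_r2"] = classify.bias_ratio_correlation(table)
        except ValueError:
            summary["reciprocal_r2"] = None
        cat_path = out / "categories.tsv"
        pd.DataFrame(
            [
                {"gene_id": c.gene_id, "category": c.category.value,
                 "direction": c.direction.value, "flagged": int(c.flagged)}
                for c in categories
            ]
        ).to_csv(cat_path, sep="\t", index=False)
        sum_path = out / "bias_summary.json"
        sum_path.write_text(json.dumps(summary, indent=1))
        record(stage, {"categories": cat_path, "summary": sum_path},
               {"n_genes": len(categories)})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- patterns
    stage = "patterns"
    try:
        if config.get("tpm"):
            tpm = io.read_tpm(config["tpm"])
            pat_cfg = config.get("patterns", {})
            all_calls = []
            for hybrid in (Genotype.H12, Genotype.H21):
                for condition in conditions:
                    all_calls.extend(
                        patterns.classify_patterns(tpm, hybrid, condition, **pat_cfg)
                    )
            spectrum = patterns.pattern_spectrum(all_calls)
            pat_path = out / "patterns.tsv"
            pd.DataFrame(
                [
                    {"gene_id": c.gene_id, "hybrid": c.hybrid.value,
                     "pattern": c.pattern.value if c.pattern else "unclassified",
                     "super_group": c.super_group or "unclassified",
                     "eld": c.eld_label or ""}
                    for c in all_calls
                ]
            ).to_csv(pat_path, sep="\t", index=False)
            spec_path = out / "pattern_spectrum.json"
            spec_path.write_text(json.dumps(spectrum, indent=1))
            record(stage, {"patterns": pat_path, "spectrum": spec_path},
                   {"n_typed": spectrum["n_typed"]})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- annotate
    stage = "annotate"
    try:
        if config.get("vcf") and config.get("gff3") and config.get("reference"):
            variants = io.read_vcf(config["vcf"])
            genes = io.read_gff3(config["gff3"])
            reference = io.read_fasta(config["reference"])
            effects, profiles = annotate_genes(variants, genes, reference)
            eff_path = out / "effects.tsv"
            pd.DataFrame(
                [
                    {"chrom": c.variant.chrom, "pos": c.variant.pos,
                     "gene_id": c.gene_id, "effect": c.effect.value,
                     "impact": c.impact.value}
                    for c in effects
                ]
            ).to_csv(eff_path, sep="\t", index=False)
            prom_path = out / "promoter_profile.tsv"
            pd.DataFrame(
                [
                    {"gene_id": p.gene_id, "n_variants": len(p.variants),
                     **{k.lower(): v for k, v in p.class_counts.items()}}
                    for p in profiles
                ]
            ).to_csv(prom_path, sep="\t", index=False)
            record(stage, {"effects": eff_path, "promoters": prom_path},
                   {"n_effects": len(effects)})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- diversity
    stage = "diversity"
    try:
        hap1, hap2 = config.get("haplotypes_pop1") or config.get("pop1"), \
            config.get("haplotypes_pop2") or config.get("pop2")
        if hap1 and hap2:
            hm1 = io.read_haplotypes(hap1)
            hm2 = io.read_haplotypes(hap2)
            div_cfg = config.get("diversity", {})
            width = div_cfg.get("width", diversity.DEFAULT_WIDTH)
            jump = div_cfg.get("jump", diversity.DEFAULT_JUMP)
            p1 = diversity.window_pi(hm1, width=width, jump=jump)
            p2 = diversity.window_pi(hm2, width=width, jump=jump)
            gene_interval = tuple(
                div_cfg.get("gene_interval")
                or (truth.sweep_interval if truth else None)
                or (hm1.region_start + hm1.region_length // 2 - 5000,
                    hm1.region_start + hm1.region_length // 2 + 4999)
            )
            summary = diversity.flank_contrast(
                p1, p2, gene_interval, flank=div_cfg.get("flank", diversity.DEFAULT_FLANK)
            )
            div_path = out / "diversity.json"
            div_path.write_text(json.dumps(
                {
                    b.block: {
                        "pi_pop1": b.pi_pop1, "pi_pop2": b.pi_pop2,
                        "ratio": None if not np.isfinite(b.ratio) else b.ratio,
                        "rank_sum_p": b.rank_sum_p, "n_windows": b.n_windows,
                    }
                    for b in summary.blocks.values()
                }, indent=1))
            record(stage, {"diversity": div_path},
                   {"n_windows": p1.n_windows})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- enrich
    stage = "enrich"
    try:
        qtl_genes = truth.qtl_genes if truth else None
        if config.get("qtl_bed"):
            qtl_genes = [name for _, _, _, name in io.read_bed(config["qtl_bed"])]
        if qtl_genes:
            universe = sorted({c.gene_id for c in categories})
            aseg_genes = [
                c.gene_id for c in categories
                if c.category.value in ("BC", "BS", "BR")
            ]
            test = enrichment.hypergeom_overlap(
                N=len(universe),
                K=len(set(qtl_genes) & set(universe)),
                n=len(aseg_genes),
                k=len(set(aseg_genes) & set(qtl_genes)),
                term="heterosis_qtl",
            )
            enr_path = out / "enrichment.json"
            enr_path.write_text(json.dumps(dataclasses.asdict(test), indent=1))
            record(stage, {"enrichment": enr_path}, {"overlap": test.overlap})
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest.to_dict(), indent=1, sort_keys=True))
    return manifest


def annotate_genes(variants, genes, reference):
    """Annotate every variant against its overlapping/nearest gene's regions
    and build each gene's promoter profile."""
    positions = np.array([v.pos for v in variants])
    order = np.argsort(positions)
    effects = []
    profiles = []
    for gene in genes:
        lo = gene.start - ann.DEFAULT_PROMOTER_WINDOW
        hi = gene.end + ann.DEFAULT_PROMOTER_WINDOW
        idx = order[np.searchsorted(positions[order], lo, side="left"):
                    np.searchsorted(positions[order], hi, side="right")]
        nearby = [variants[i] for i in idx if variants[i].chrom == gene.chrom]
        cds = _spliced_cds(gene, reference[gene.chrom])
        for v in nearby:
            call = ann.annotate_effect(v, gene, cds)
            if call.effect is not ann.Effect.INTERGENIC:
                effects.append(call)
        profiles.append(ann.promoter_profile(nearby, gene))
    return effects, profiles


def _spliced_cds(gene, chrom_seq: str) -> str:
    parts = [chrom_seq[s - 1 : e] for s, e in gene.cds_segments]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = cds[::-1].translate(str.maketrans("ACGTacgt", "TGCAtgca"))
    return cds
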