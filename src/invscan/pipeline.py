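"""End-to-end orchestration: simulate -> genotype inversions -> divergence
scan -> centromere profile -> association, with a run manifest.

Each stage writes its outputs under the run directory; the manifest records
the parameter hash, seeds, per-stage record counts and a SHA-256 digest of
every emitted file, so two runs of the same config can be compared
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import centromere as cen
from . import divergence as div
from . import genotyping as gt
from . import io, simulate
from .config import PipelineConfig
from .seq import random_sequence

log = logging.getLogger("invscan")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a synthetic scenario; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": hashlib.sha256(
            json.dumps(config.model_dump(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "files": {},
    }

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        gspec = simulate.GenomePairSpec(
            chromosomes=config.genome.chromosomes,
            inversions=[tuple(iv) for iv in config.genome.inversions],
            snp_rate=config.genome.snp_rate,
            seed=config.seed,
        )
        genome_a, genome_b, truth = simulate.generate_genome_pair(gspec)
        sat = config.satellite
        monomer = random_sequence(
            np.random.default_rng(config.seed + 10), sat.monomer_length
        )
        region = (sat.chrom, sat.start, sat.start + sat.monomer_length * sat.copies)
        genome_a = simulate.plant_satellite_array(
            genome_a, region, monomer, sat.copies, sat.mutation_rate,
            seed=config.seed + 11,
        )
        io.write_fasta(genome_a, outdir / "genome_A.fasta")
        io.write_fasta(genome_b, outdir / "genome_B.fasta")

        pspec = simulate.PopulationSpec(
            n_inland=config.population.n_inland,
            n_coastal=config.population.n_coastal,
            n_sites=config.population.n_sites,
            chrom=config.population.chrom,
            chrom_length=config.population.chrom_length,
            freq_range=(config.population.freq_lo, config.population.freq_hi),
            f_background=config.population.f_background,
            f_block=config.population.f_block,
            block=tuple(config.population.block),
            marker_positions=tuple(config.population.marker_positions),
            causal_positions=tuple(config.population.causal_positions),
            tolerant_freq_coastal=config.population.tolerant_freq_coastal,
            missing_rate=config.population.missing_rate,
            seed=config.seed + 20,
        )
        gm, labels, pop_truth = simulate.simulate_population(pspec)
        truth.arrangement = pop_truth.arrangement
        truth.haplotype_group = pop_truth.haplotype_group
        truth.block = pop_truth.block
        io.write_vcf(
            gm, outdir / "population.vcf",
            contig_lengths={config.population.chrom: config.population.chrom_length},
        )
        io.write_groups(dict(zip(gm.samples, labels)), outdir / "groups.tsv")

        pheno = simulate.simulate_phenotypes(
            pop_truth.haplotype_group,
            group_means={
                "tolerant": config.phenotype.tolerant_mean,
                "sensitive": config.phenotype.sensitive_mean,
            },
            noise_sd={
                "tolerant": config.phenotype.tolerant_sd,
                "sensitive": config.phenotype.sensitive_sd,
            },
            seed=config.seed + 30,
        )
        io.write_phenotypes(pheno, outdir / "phenotypes.tsv")

        # reads for the breakpoint genotyper: a small cohort per arrangement
        inv = gt.Inversion(*config.genome.inversions[0][:3])
        rconf = config.reads
        read_samples: dict[str, tuple[str, simulate.PairedReads]] = {}
        idx = 0
        for cls, n in (
            (gt.SAME_AS_A, rconf.n_same_a),
            (gt.SAME_AS_B, rconf.n_same_b),
            (gt.HETEROZYGOUS, rconf.n_het),
        ):
            for _ in range(n):
                idx += 1
                name = f"RS{idx:02d}"
                seed = config.seed + 100 + idx
                kwargs = dict(
                    read_len=rconf.read_len,
                    insert_mean=rconf.insert_mean,
                    insert_sd=rconf.insert_sd,
                    error_rate=rconf.error_rate,
                )
                if cls == gt.SAME_AS_A:
                    reads = simulate.simulate_paired_reads(
                        genome_a, rconf.depth, seed=seed, **kwargs
                    )
                elif cls == gt.SAME_AS_B:
                    reads = simulate.simulate_paired_reads(
                        genome_b, rconf.depth, seed=seed, **kwargs
                    )
                else:
                    half_a = simulate.simulate_paired_reads(
                        genome_a, rconf.depth / 2, seed=seed, **kwargs
                    )
                    half_b = simulate.simulate_paired_reads(
                        genome_b, rconf.depth / 2, seed=seed + 5000, **kwargs
                    )
                    reads = simulate.PairedReads(
                        r1=half_a.r1 + half_b.r1,
                        r2=half_a.r2 + half_b.r2,
                        names=[f"a_{n_}" for n_ in half_a.names]
                        + [f"b_{n_}" for n_ in half_b.names],
                    )
                read_samples[name] = (cls, reads)
                truth.arrangement[name] = cls
                io.write_fastq_pair(reads, outdir / f"reads_{name}")

        ip, inp = simulate.simulate_chip_tracks(
            genome_length=config.genome.chromosomes[sat.chrom],
            centromere=tuple(config.chip.centromere),
            fold=config.chip.fold,
            depth=config.chip.depth,
            window=config.chip.window,
            seed=config.seed + 40,
        )
        length = config.genome.chromosomes[sat.chrom]
        io.write_bedgraph(sat.chrom, config.chip.window, ip.counts, outdir / "chip_ip.bedGraph", length)
        io.write_bedgraph(sat.chrom, config.chip.window, inp.counts, outdir / "chip_input.bedGraph", length)
        io.write_truth(truth, outdir / "truth")
        manifest["stages"][stage] = {
            "n_samples": gm.n_samples,
            "n_sites": gm.n_sites,
            "n_read_samples": len(read_samples),
        }
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(stage, str(exc)) from exc

    # --- inversion genotyping ----------------------------------------------
    stage = "genotype-inversion"
    try:
        rows = []
        for name, (cls, reads) in read_samples.items():
            call = gt.genotype_inversion(
                genome_a, genome_b, inv, reads,
                flank=config.genotyping.flank,
                min_overlap=config.genotyping.min_overlap,
            )
            rows.append(
                {
                    "sample": name,
                    "n_a_left": call.counts[("A", "left")],
                    "n_a_right": call.counts[("A", "right")],
                    "n_b_left": call.counts[("B", "left")],
                    "n_b_right": call.counts[("B", "right")],
                    "ratio_left": call.ratio_left,
                    "ratio_right": call.ratio_right,
                    "ratio_pooled": call.ratio_pooled,
                    "arrangement": call.arrangement,
                }
            )
        calls = pd.DataFrame(rows)
        calls.to_csv(outdir / "inversion_calls.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_samples": len(calls)}
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- divergence scan ----------------------------------------------------
    stage = "scan"
    try:
        gm2, labels2 = io.read_genotypes(outdir / "population.vcf", outdir / "groups.tsv")
        filtered = div.filter_variants(
            gm2, config.scan.maf_min, config.scan.missing_max
        )
        log.info("scan: %d of %d sites pass filters", filtered.n_sites, gm2.n_sites)
        stats = div.site_stats(filtered, labels2)
        sconf = div.ScanConfig(
            window=config.scan.window,
            step=config.scan.step,
            gdr_quantile=config.scan.gdr_quantile,
        )
        windows = div.windowed_scan(
            stats, {config.population.chrom: config.population.chrom_length}, sconf
        )
        windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
        gdrs = div.call_gdrs(windows, sconf)
        io.write_bed(
            [
                (r.chrom, r.start, r.end, f"{r.mean_fst:.4f}")
                for r in gdrs.itertuples()
            ],
            outdir / "gdrs.bed",
        )
        gw = div.genome_wide_fst(stats.a.to_numpy(), stats.d.to_numpy())
        manifest["stages"][stage] = {
            "n_sites_filtered": filtered.n_sites,
            "n_windows": len(windows),
            "n_gdrs": len(gdrs),
            "genome_wide_fst": round(gw, 4),
        }
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- centromere ---------------------------------------------------------
    stage = "centromere"
    try:
        fold = cen.fold_enrichment(ip, inp)
        io.write_bedgraph(
            sat.chrom, config.chip.window,
            [f"{v:.4f}" for v in fold], outdir / "enrichment.bedGraph", length,
        )
        domains = cen.call_centromere_domain(
            fold, config.chip.window,
            fold_threshold=config.chip.fold_threshold,
            min_length=config.chip.min_length,
            max_gap=config.chip.max_gap,
        )
        io.write_bed([(sat.chrom, s, e) for s, e in domains], outdir / "domains.bed")
        array_seq = genome_a[sat.chrom][region[1]:region[2]]
        model = cen.profile_satellite(array_seq)
        pd.DataFrame(
            {
                "position": np.arange(model.period),
                "consensus": list(model.consensus),
                "variant_freq": model.variant_freq,
            }
        ).to_csv(outdir / "monomer_profile.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_domains": len(domains),
            "satellite_period": model.period,
            "n_monomers": model.n_monomers,
        }
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- association --------------------------------------------------------
    stage = "gwas"
    try:
        pheno_df = io.read_phenotypes(outdir / "phenotypes.tsv").set_index("sample")
        y = pheno_df.loc[gm2.samples, "survival"].to_numpy()
        filtered_assoc = div.filter_variants(
            gm2, config.scan.maf_min, config.scan.missing_max
        )
        pca = assoc.genotype_pca(filtered_assoc, config.gwas.n_components)
        result = assoc.glm_scan(
            y, filtered_assoc, pca,
            n_components=config.gwas.n_components,
            alpha=config.gwas.alpha,
            n_eff=config.gwas.n_eff,
        )
        tab = result.table.copy()
        tab["neg_log10_p"] = -np.log10(tab.p)
        tab.to_csv(outdir / "gwas.tsv", sep="\t", index=False)

        causal = [
            (config.population.chrom, p) for p in config.population.causal_positions
        ]
        present = [
            c for c in causal
            if ((filtered_assoc.chroms == c[0]) & (filtered_assoc.positions == c[1])).any()
        ]
        hap_rows = []
        comparison = {}
        if len(present) >= 2:
            haps = assoc.assign_haplotypes(
                filtered_assoc, present,
                phenotype=dict(zip(gm2.samples, y)),
            )
            for s in filtered_assoc.samples:
                hap_rows.append(
                    {"sample": s, "pattern": haps.patterns[s], "haplotype": haps.groups[s]}
                )
            va = [y[i] for i, s in enumerate(gm2.samples) if haps.groups[s] == "A"]
            vb = [y[i] for i, s in enumerate(gm2.samples) if haps.groups[s] == "B"]
            if len(va) >= 2 and len(vb) >= 2:
                t, p = assoc.compare_groups(va, vb)
                comparison = {"t": t, "p": p, "n_a": len(va), "n_b": len(vb)}
        pd.DataFrame(hap_rows).to_csv(outdir / "haplotypes.tsv", sep="\t", index=False)
        (outdir / "group_comparison.json").write_text(
            json.dumps(comparison, indent=1)
        )
        manifest["stages"][stage] = {
            "n_tested": result.n_tested,
            "p_threshold": result.p_threshold,
            "neg_log10_threshold": result.neg_log10_threshold,
            "top_hit_pos": int(tab.loc[tab.p.idxmin(), "pos"]),
            "comparison": comparison,
        }
    except Exception as exc:
        raise StageError(stage, str(exc)) from exc

    # --- manifest -----------------------------------------------------------
    for path in sorted(outdir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(outdir))] = _sha256(path)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
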