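"""Stage orchestration: each stage reads upstream artifacts from the output
directory, writes its own subdirectory atomically, and records a manifest
(config snapshot + input hashes) so a rerun with identical inputs is
reproducible bit for bit."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as sio
from . import kinetics as kin
from . import matrices as mat
from . import nascent as nc
from . import sgrna as sg
from . import simulate as sim
from . import stats as st
from .config import PipelineConfig

log = logging.getLogger("slamscreen")


class MissingInputError(FileNotFoundError):
    """An upstream artifact is absent (CLI exit code 3)."""


def _require(path: Optional[str | Path], what: str, stage_hint: str) -> Path:
    if path is None or not Path(path).exists():
        raise MissingInputError(
            f"missing {what} ({path}); run the '{stage_hint}' stage or point "
            "the config at an existing file"
        )
    return Path(path)


def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    d = Path(cfg.outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


def _derived_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def stage_simulate(cfg: PipelineConfig) -> Path:
    """Generate the synthetic screen: genome, annotation, guide whitelist,
    counts, guide capture records and (optionally) read-level SAM files."""
    out = _stage_dir(cfg, "simulate")
    genome = sim.build_genome(
        cfg.sim_n_genes, n_mito_genes=cfg.sim_n_mito_genes, seed=cfg.seed
    )
    nuclear = [g.gene_id for g in genome.genes if not g.is_mito]
    pick = np.linspace(0, len(nuclear) - 1, cfg.sim_n_targets).round().astype(int)
    targets = [nuclear[i] for i in dict.fromkeys(pick)]
    library = sim.make_library(
        targets,
        sgrnas_per_gene=cfg.sim_sgrnas_per_gene,
        n_ntc=cfg.sim_n_ntc,
        seed=cfg.seed,
    )
    truth = sim.make_truth(
        genome,
        library,
        n_cells=cfg.sim_n_cells,
        seed=cfg.seed,
        labeling_time_t=cfg.labeling_time,
        knockdown_effect=cfg.sim_knockdown_effect,
        doublet_rate=cfg.sim_doublet_rate,
        p_conversion=cfg.sim_p_conversion,
        p_error=cfg.sim_p_error,
        n_snps=cfg.sim_n_snps,
        ambient_sgrna_rate=cfg.sim_ambient_sgrna_rate,
        mean_sgrna_umis=cfg.sim_mean_sgrna_umis,
        dispersion=cfg.sim_dispersion,
    )
    counts = sim.simulate_counts(truth)

    genome.to_fasta(out / "genome.fa")
    genome.to_gtf(out / "annotation.gtf")
    library.to_tsv(out / "whitelist.tsv")
    sio.save_matrices(counts, out / "counts")
    truth.gene_params.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    counts.obs.to_csv(out / "truth_cells.tsv", sep="\t")
    records = sim.simulate_sgrna_records(truth)
    records.to_csv(out / "sgrna_records.tsv", sep="\t", index=False)
    if cfg.sim_read_level:
        truth_reads = sim.simulate_reads(
            truth, counts, genome, out / "reads.sam"
        )
        truth_reads.to_csv(out / "truth_reads.tsv", sep="\t", index=False)
        sim.simulate_control_reads(truth, genome, out / "control.sam")
    sio.write_manifest("simulate", out, dataclasses.asdict(cfg), {})
    log.info(
        "simulate: %d cells x %d genes, %d guides",
        cfg.sim_n_cells, len(genome.genes), len(library.sgrna_ids),
    )
    return out


def _whitelist_path(cfg: PipelineConfig) -> Path:
    default = Path(cfg.outdir) / "simulate" / "whitelist.tsv"
    return _require(cfg.whitelist or default, "guide whitelist", "simulate")


def stage_assign_sgrna(cfg: PipelineConfig) -> Path:
    """Correct, deduplicate and call per-cell guide identities."""
    out = _stage_dir(cfg, "assign-sgrna")
    whitelist = _whitelist_path(cfg)
    library = sg.SgRNALibrary.from_tsv(whitelist)
    inputs: dict[str, Path] = {"whitelist": whitelist}
    if cfg.sgrna_fastq:
        fq = _require(cfg.sgrna_fastq, "guide FASTQ", "simulate")
        records = sg.parse_sgrna_fastq(fq, library)
        inputs["sgrna_fastq"] = fq
    else:
        default = Path(cfg.outdir) / "simulate" / "sgrna_records.tsv"
        table = _require(
            cfg.sgrna_table or default, "guide record table", "simulate"
        )
        records = pd.read_csv(table, sep="\t")
        inputs["sgrna_table"] = table
    counts = sg.dedup_sgrna_umis(records)
    calls = sg.call_singlets(
        counts,
        min_total_umis=cfg.sgrna_min_total_umis,
        top_fraction=cfg.singlet_top_fraction,
        fold_over_second=cfg.singlet_fold,
    )
    counts.to_csv(out / "sgrna_counts.tsv", sep="\t", index=False)
    calls.to_csv(out / "sgrna_calls.tsv", sep="\t", index=False)
    sio.write_manifest("assign-sgrna", out, dataclasses.asdict(cfg), inputs)
    log.info(
        "assign-sgrna: %d cells, %d singlets",
        len(calls), int((calls["status"] == "singlet").sum()),
    )
    return out


def stage_snp_mask(cfg: PipelineConfig) -> Path:
    """Mask background SNPs from an unlabeled control alignment file."""
    out = _stage_dir(cfg, "snp-mask")
    default = Path(cfg.outdir) / "simulate" / "control.sam"
    control = _require(
        cfg.control_bam or default, "control alignments", "simulate"
    )
    background = nc.build_snp_background(
        nc.read_alignments(control, mapq_min=cfg.mapq_min),
        min_coverage=cfg.snp_min_coverage,
        min_alt_fraction=cfg.snp_min_alt_fraction,
    )
    background.to_bed(out / "snp_mask.bed")
    sio.write_manifest(
        "snp-mask", out, dataclasses.asdict(cfg), {"control_bam": control}
    )
    log.info("snp-mask: %d sites masked", len(background))
    return out


def stage_call_nascent(cfg: PipelineConfig) -> Path:
    """Deduplicate reads and label each one nascent or pre-existing."""
    out = _stage_dir(cfg, "call-nascent")
    bam = _require(
        cfg.bam or Path(cfg.outdir) / "simulate" / "reads.sam",
        "transcriptome alignments", "simulate",
    )
    gtf = _require(
        cfg.gtf or Path(cfg.outdir) / "simulate" / "annotation.gtf",
        "gene annotation", "simulate",
    )
    mask_default = Path(cfg.outdir) / "snp-mask" / "snp_mask.bed"
    mask_path = cfg.snp_mask or (
        mask_default if mask_default.exists() else None
    )
    background = (
        nc.SnpBackground.from_bed(mask_path)
        if mask_path
        else nc.SnpBackground()
    )
    index = mat.GeneIndex.from_gtf(gtf, mito_contig=cfg.mito_contig)
    deduped = mat.dedup_reads(nc.read_alignments(bam, mapq_min=cfg.mapq_min))
    labels = nc.call_nascent(
        deduped,
        background,
        gene_index=index,
        min_base_quality=cfg.min_base_quality,
        min_tc_fraction=cfg.min_tc_fraction,
    )
    labels.to_csv(out / "read_labels.tsv", sep="\t", index=False)
    inputs = {"bam": bam, "gtf": gtf}
    if mask_path:
        inputs["snp_mask"] = Path(mask_path)
    sio.write_manifest("call-nascent", out, dataclasses.asdict(cfg), inputs)
    log.info(
        "call-nascent: %d deduplicated reads, %.1f%% nascent",
        len(labels), 100 * (labels["label"] == "nascent").mean(),
    )
    return out


def stage_matrices(cfg: PipelineConfig) -> Path:
    """Build (or load) the whole/nascent matrices and attach guide calls."""
    out = _stage_dir(cfg, "matrices")
    library = sg.SgRNALibrary.from_tsv(_whitelist_path(cfg))
    calls_path = _require(
        Path(cfg.outdir) / "assign-sgrna" / "sgrna_calls.tsv",
        "guide calls", "assign-sgrna",
    )
    calls = pd.read_csv(calls_path, sep="\t")

    labels_path = Path(cfg.outdir) / "call-nascent" / "read_labels.tsv"
    inputs: dict[str, Path] = {"sgrna_calls": calls_path}
    if labels_path.exists():
        gtf = _require(
            cfg.gtf or Path(cfg.outdir) / "simulate" / "annotation.gtf",
            "gene annotation", "simulate",
        )
        index = mat.GeneIndex.from_gtf(gtf, mito_contig=cfg.mito_contig)
        labels = pd.read_csv(labels_path, sep="\t")
        adata = mat.build_matrices(
            labels, list(index.genes), mito_genes=index.mito_genes
        )
        inputs.update({"read_labels": labels_path, "gtf": gtf})
    else:
        counts_dir = Path(cfg.outdir) / "simulate" / "counts"
        _require(counts_dir / "whole.mtx", "count matrices", "simulate")
        adata = sio.load_matrices(counts_dir)
        X = adata.X
        adata.obs["total_umis"] = np.asarray(X.sum(axis=1)).ravel().astype(int)
        adata.obs["genes_detected"] = np.asarray((X > 0).sum(axis=1)).ravel()
        adata.obs["unannotated_fraction"] = 0.0
        inputs["counts"] = counts_dir / "whole.mtx"
    adata = mat.attach_sgrna_calls(adata, calls, library)
    sio.save_matrices(adata, out / "matrices")
    adata.obs.to_csv(out / "cell_qc.tsv", sep="\t")
    sio.write_manifest("matrices", out, dataclasses.asdict(cfg), inputs)
    log.info("matrices: %d cells x %d genes", *adata.shape)
    return out


def stage_qc(cfg: PipelineConfig) -> Path:
    """Cell QC, guide-efficacy filtering and on-target cell selection."""
    out = _stage_dir(cfg, "qc")
    library = sg.SgRNALibrary.from_tsv(_whitelist_path(cfg))
    mdir = _require(
        Path(cfg.outdir) / "matrices" / "matrices" / "whole.mtx",
        "count matrices", "matrices",
    ).parent
    adata = sio.load_matrices(mdir)
    adata = mat.filter_cells(
        adata,
        min_umis=cfg.min_umis,
        min_genes=cfg.min_genes,
        min_sgrna_umis=cfg.min_sgrna_umis,
        max_unannotated_fraction=cfg.max_unannotated_fraction,
    )
    filtered, efficiency = mat.knockdown_filter(
        adata,
        library,
        min_reduction=cfg.knockdown_min_reduction,
        min_cells_per_target=cfg.min_cells_per_target,
    )
    sio.save_matrices(filtered, out / "matrices")
    efficiency.to_csv(out / "efficiency.tsv", sep="\t", index=False)
    sio.write_manifest(
        "qc", out, dataclasses.asdict(cfg), {"matrices": mdir / "whole.mtx"}
    )
    log.info(
        "qc: %d cells kept in %d groups",
        filtered.n_obs, filtered.obs["group"].nunique(),
    )
    return out


def _load_qc(cfg: PipelineConfig):
    mdir = _require(
        Path(cfg.outdir) / "qc" / "matrices" / "whole.mtx",
        "QC-filtered matrices", "qc",
    ).parent
    return sio.load_matrices(mdir), mdir


def stage_kinetics(cfg: PipelineConfig) -> Path:
    """Pseudobulk aggregation and closed-form rate estimation per group."""
    out = _stage_dir(cfg, "kinetics")
    adata, mdir = _load_qc(cfg)
    whole = np.asarray(adata.X.todense())
    nasc = np.asarray(adata.layers["nascent"].todense())
    pbs = kin.aggregate_pseudobulk(
        whole, nasc, adata.obs["group"], genes=adata.var_names
    )
    tables = [kin.rates_table(pb, cfg.labeling_time) for pb in pbs.values()]
    rates = pd.concat(tables, ignore_index=True)
    rates.to_csv(out / "rates.tsv", sep="\t", index=False)
    if "NTC" in pbs:
        ntc_rates = rates[rates["group"] == "NTC"]
        fcs = [
            kin.rate_fold_changes(rates[rates["group"] == g], ntc_rates)
            for g in pbs
            if g != "NTC"
        ]
        if fcs:
            pd.concat(fcs, ignore_index=True).to_csv(
                out / "fold_changes.tsv", sep="\t", index=False
            )
    sio.write_manifest(
        "kinetics", out, dataclasses.asdict(cfg),
        {"matrices": mdir / "whole.mtx"},
    )
    log.info("kinetics: %d groups x %d genes", len(pbs), adata.n_vars)
    return out


def stage_stats(cfg: PipelineConfig) -> Path:
    """Randomization tests, global KS screens, DEG testing and feature
    selection against the NTC reference."""
    out = _stage_dir(cfg, "stats")
    adata, mdir = _load_qc(cfg)
    whole = np.asarray(adata.X.todense())
    nasc = np.asarray(adata.layers["nascent"].todense())
    groups = adata.obs["group"].to_numpy()
    gene_pos = {g: j for j, g in enumerate(adata.var_names)}
    ntc_mask = groups == "NTC"
    if not ntc_mask.any():
        raise MissingInputError("no NTC cells survive QC; cannot test")
    perts = [g for g in pd.unique(groups) if g != "NTC"]

    # per-target randomization tests of the targeted gene's rates
    results = []
    for i, pert in enumerate(sorted(perts)):
        j = gene_pos.get(pert)
        if j is None:
            continue
        mask = groups == pert
        if mask.sum() < cfg.min_cells_per_target:
            continue
        syn, deg = st.randomization_test(
            whole[mask, j], nasc[mask, j],
            whole[ntc_mask, j], nasc[ntc_mask, j],
            gene=pert, perturbation=pert,
            t=cfg.labeling_time, n_iter=cfg.n_iter,
            seed=_derived_seed(cfg.seed, 7, i),
            min_cells=cfg.min_cells_per_target,
        )
        results.extend([syn, deg])
    st.rate_tests_table(results).to_csv(
        out / "rate_tests.tsv", sep="\t", index=False
    )

    # global screens over the top NTC-expressed genes
    ntc_pb = pd.Series(whole[ntc_mask].sum(axis=0), index=adata.var_names)
    top = st.top_expressed_genes(ntc_pb, k=cfg.top_k_genes)
    cols = [gene_pos[g] for g in top]

    def group_rates(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # alpha scales with pseudobulk depth, so put it on a per-million
        # scale for cross-group comparison; beta is a ratio and scale-free
        R = whole[mask][:, cols].sum(axis=0)
        Rn = nasc[mask][:, cols].sum(axis=0)
        alpha, beta, valid, _ = kin.solve_rates_arrays(
            R, Rn, cfg.labeling_time
        )
        depth = whole[mask].sum()
        return alpha[valid] * 1e6 / depth, beta[valid]

    ntc_alpha, ntc_beta = group_rates(ntc_mask)
    screens = []
    syn_vals, deg_vals = {}, {}
    for pert in sorted(perts):
        mask = groups == pert
        if mask.sum() < cfg.min_cells_per_target:
            continue
        a, b = group_rates(mask)
        syn_vals[pert], deg_vals[pert] = a, b
    screens.append(
        st.global_ks_screen(
            syn_vals, ntc_alpha, "global_synthesis",
            fdr_threshold=cfg.fdr_threshold,
        )
    )
    screens.append(
        st.global_ks_screen(
            deg_vals, ntc_beta, "global_degradation",
            fdr_threshold=cfg.fdr_threshold,
        )
    )
    for metric, series in (
        ("nascent_exonic_fraction", mat.exonic_nascent_fraction(adata)
         if "exonic_nascent" in adata.layers else None),
        ("mito_turnover", mat.mito_turnover(adata)
         if adata.var.get("is_mito") is not None
         and adata.var["is_mito"].any() else None),
    ):
        if series is None:
            continue
        vals = {
            p: series.values[groups == p]
            for p in sorted(perts)
            if (groups == p).sum() >= cfg.min_cells_per_target
        }
        screens.append(
            st.global_ks_screen(
                vals, series.values[ntc_mask], metric,
                fdr_threshold=cfg.fdr_threshold,
            )
        )
    pd.concat(screens, ignore_index=True).to_csv(
        out / "global_screens.tsv", sep="\t", index=False
    )

    # DEG testing (rank-sum stand-in engine) + post-filters
    totals = whole.sum(axis=1).astype(float)
    deg_rows = []
    for pert in sorted(perts):
        mask = groups == pert
        if mask.sum() < 2:
            continue
        pvals, fcs, cpms_p, cpms_n = [], [], [], []
        for g in adata.var_names:
            j = gene_pos[g]
            p, fc, cpm_p, cpm_n = st.simple_deg_test(
                whole[mask, j], whole[ntc_mask, j],
                totals[mask], totals[ntc_mask],
            )
            pvals.append(p)
            fcs.append(fc)
            cpms_p.append(cpm_p)
            cpms_n.append(cpm_n)
        fdr = st.bh_adjust(pvals)
        deg_rows.append(
            pd.DataFrame(
                {
                    "perturbation": pert, "gene": adata.var_names,
                    "p": pvals, "fdr": fdr, "fc": fcs,
                    "cpm_perturbed": cpms_p, "cpm_ntc": cpms_n,
                }
            )
        )
    if deg_rows:
        deg_table = pd.concat(deg_rows, ignore_index=True)
        loose = st.deg_filter(deg_table, "loose", cfg.fdr_threshold)
        strict = st.deg_filter(deg_table, "strict", cfg.fdr_threshold)
        deg_table["kept_loose"] = deg_table.index.isin(loose.index)
        deg_table["kept_strict"] = deg_table.index.isin(strict.index)
        deg_table.to_csv(out / "deg_tests.tsv", sep="\t", index=False)

        # embedding feature selection from pseudobulk CPMs
        ntc_cpm = pd.Series(
            mat.cpm_normalize(ntc_pb.to_numpy()), index=adata.var_names
        )
        pert_cpms = pd.DataFrame(
            {
                p: mat.cpm_normalize(whole[groups == p].sum(axis=0))
                for p in sorted(perts)
                if (groups == p).sum() > 0
            },
            index=adata.var_names,
        )
        feats = st.select_embedding_features(
            pert_cpms, ntc_cpm,
            n_bins=cfg.n_bins, top_fraction=cfg.top_fraction,
        )
        (out / "features.txt").write_text("\n".join(feats) + "\n")

    sio.write_manifest(
        "stats", out, dataclasses.asdict(cfg), {"matrices": mdir / "whole.mtx"}
    )
    log.info("stats: %d perturbations screened", len(perts))
    return out


STAGES = {
    "simulate": stage_simulate,
    "assign-sgrna": stage_assign_sgrna,
    "snp-mask": stage_snp_mask,
    "call-nascent": stage_call_nascent,
    "matrices": stage_matrices,
    "qc": stage_qc,
    "kinetics": stage_kinetics,
    "stats": stage_stats,
}


def run_stage(stage_name: str, cfg: PipelineConfig) -> Path:
    if stage_name not in STAGES:
        raise KeyError(f"unknown stage {stage_name!r}")
    return STAGES[stage_name](cfg)


def run_all(cfg: PipelineConfig) -> Path:
    """Run every stage in order; read-level stages only when simulating
    reads or when an alignment file is supplied."""
    stage_simulate(cfg)
    stage_assign_sgrna(cfg)
    if cfg.sim_read_level or cfg.bam:
        stage_snp_mask(cfg)
        stage_call_nascent(cfg)
    stage_matrices(cfg)
    stage_qc(cfg)
    stage_kinetics(cfg)
    stage_stats(cfg)
    return Path(cfg.outdir)
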