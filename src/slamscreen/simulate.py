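"""Ground-truth-annotated synthetic screens for end-to-end testing.

The generator emulates a pooled CRISPRi screen read out with metabolic
labeling: per-gene birth-death kinetics at steady state, a 4sU labeling
window of length ``t``, chemical conversion making nascent reads carry T>C
mismatches, sequencing error, background SNPs, per-cell size factors, guide
singlets/doublets with ambient contamination, and knockdown acting on the
target gene's synthesis rate.

Count layer
-----------
Gene ``g`` in cell ``c`` has mean whole-count ``s_c * alpha'_g(c) / beta_g``
where the effective synthesis rate ``alpha'`` multiplies in ``1 - effect``
for each guide the cell carries against ``g``.  Whole counts are Poisson by
default (optional negative-binomial overdispersion); nascent counts are
Binomial(whole, f_g) with ``f_g = 1 - exp(-beta_g * t)``, the steady-state
fraction of molecules younger than the labeling window.

Read layer
----------
Each molecule becomes one aligned read (uniform start within its gene span)
on 1-2 synthetic contigs plus a fully exonic mitochondrial contig.  Nascent
reads convert each templated T with probability ``p_conversion`` (genomic
T>C on plus-strand genes, A>G on minus-strand genes); every read carries
per-base errors at ``p_error`` and the alternate allele at simulated SNP
positions.  Reads are emitted as SAM with MD/NM tags and the cell barcode
and UMI encoded in the read name; per-read truth (molecule origin and the
number of conversions actually planted) is recorded separately.

All randomness derives from a single master seed through fixed child
streams, so identical truth objects give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import anndata as ad
import numpy as np
import pandas as pd
import pysam
from scipy import sparse

from .matrices import GeneAnnotation
from .sgrna import SgRNALibrary

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_PHRED = 40  # simulated base quality for every emitted base


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(stream,))
    )


@dataclass
class SyntheticGenome:
    """Random contigs with uniformly structured gene models."""

    contigs: dict[str, np.ndarray]  # name -> array of S1 bytes
    genes: list[GeneAnnotation]
    mito_contig: str = "chrM"

    def sequence(self, contig: str, start: int, end: int) -> np.ndarray:
        return self.contigs[contig][start:end]

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                s = seq.tobytes().decode()
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")

    def to_gtf(self, path: str | Path) -> None:
        """GTF with gene and exon features (1-based inclusive coordinates)."""
        with open(path, "w") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_id}";'
                fh.write(
                    f"{g.contig}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t"
                    f".\t{g.strand}\t.\t{attrs}\n"
                )
                for s, e in g.exons:
                    fh.write(
                        f"{g.contig}\tsynthetic\texon\t{s + 1}\t{e}\t"
                        f".\t{g.strand}\t.\t{attrs}\n"
                    )


def build_genome(
    n_genes: int,
    n_mito_genes: int = 8,
    seed: int = 0,
    gene_length: int = 900,
    exon_offsets: tuple[tuple[int, int], ...] = ((0, 200), (500, 900)),
    intergenic_gap: int = 150,
    n_contigs: int = 2,
) -> SyntheticGenome:
    """Lay out ``n_genes`` nuclear genes over ``n_contigs`` contigs plus
    ``n_mito_genes`` single-exon genes on the mitochondrial contig.

    Nuclear genes share a uniform two-exon structure (intron between the exon
    offsets), alternate strand, and are separated by ``intergenic_gap``.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = _child_rng(seed, 0)
    genes: list[GeneAnnotation] = []
    contigs: dict[str, np.ndarray] = {}

    per_contig = int(np.ceil(n_genes / n_contigs))
    idx = 0
    for ci in range(n_contigs):
        name = f"chrS{ci + 1}"
        n_here = min(per_contig, n_genes - idx)
        if n_here <= 0:
            break
        length = n_here * (gene_length + intergenic_gap) + intergenic_gap
        contigs[name] = rng.choice(_BASES, size=length)
        pos = intergenic_gap
        for k in range(n_here):
            gid = f"gene{idx:04d}"
            strand = "+" if idx % 2 == 0 else "-"
            exons = [(pos + s, pos + e) for s, e in exon_offsets]
            genes.append(
                GeneAnnotation(
                    gene_id=gid,
                    contig=name,
                    strand=strand,
                    start=pos,
                    end=pos + gene_length,
                    exons=exons,
                    is_mito=False,
                )
            )
            pos += gene_length + intergenic_gap
            idx += 1

    if n_mito_genes > 0:
        mlen = 600
        length = n_mito_genes * (mlen + intergenic_gap) + intergenic_gap
        contigs["chrM"] = rng.choice(_BASES, size=length)
        pos = intergenic_gap
        for k in range(n_mito_genes):
            gid = f"mito{k:02d}"
            genes.append(
                GeneAnnotation(
                    gene_id=gid,
                    contig="chrM",
                    strand="+" if k % 2 == 0 else "-",
                    start=pos,
                    end=pos + mlen,
                    exons=[(pos, pos + mlen)],  # mito genes are intronless
                    is_mito=True,
                )
            )
            pos += mlen + intergenic_gap
    return SyntheticGenome(contigs=contigs, genes=genes)


def make_library(
    target_genes: Iterable[str],
    sgrnas_per_gene: int = 3,
    n_ntc: int = 5,
    seed: int = 0,
) -> SgRNALibrary:
    """Random whitelist: ``sgrnas_per_gene`` guides per target plus NTCs."""
    rng = _child_rng(seed, 1)
    targets = list(target_genes)
    spacers: set[str] = set()

    def new_spacer() -> str:
        while True:
            s = "".join(rng.choice(list("ACGT"), size=20))
            if s not in spacers:
                spacers.add(s)
                return s

    rows = []
    for gene in targets:
        for k in range(sgrnas_per_gene):
            rows.append(
                dict(
                    sgrna_id=f"{gene}_sg{k + 1}",
                    protospacer=new_spacer(),
                    target_gene=gene,
                    is_ntc=False,
                )
            )
    for k in range(n_ntc):
        rows.append(
            dict(
                sgrna_id=f"NTC_sg{k + 1}",
                protospacer=new_spacer(),
                target_gene="NTC",
                is_ntc=True,
            )
        )
    return SgRNALibrary(pd.DataFrame(rows))


@dataclass
class SimulationTruth:
    """Complete ground truth for one synthetic screen."""

    gene_params: pd.DataFrame  # gene_id, alpha, beta, is_mito
    labeling_time_t: float
    cell_size_factors: np.ndarray
    knockdown_effects: dict[str, float]
    sgrna_design: pd.DataFrame  # cell_barcode, sgrna_ids (tuple), doublet
    p_conversion: float
    p_error: float
    snp_positions: dict[tuple[str, int], str]  # site -> alternate base
    ambient_sgrna_rate: float
    mean_sgrna_umis: float
    seed: int
    library: Optional[SgRNALibrary] = None
    dispersion: Optional[float] = None  # NB size parameter; None = Poisson
    read_length: int = 50
    frac_intergenic: float = 0.02
    pcr_duplicate_rate: float = 0.0

    def __post_init__(self) -> None:
        gp = self.gene_params
        if (gp["alpha"] < 0).any():
            raise ValueError("synthesis rates must be non-negative")
        if (gp["beta"] <= 0).any():
            raise ValueError("degradation rates must be strictly positive")
        if self.labeling_time_t <= 0:
            raise ValueError("labeling time must be positive")
        for g, e in self.knockdown_effects.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"knockdown effect for {g} outside [0,1]")
        if not 0.0 <= self.p_conversion <= 1.0:
            raise ValueError("p_conversion outside [0,1]")
        if (self.cell_size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.sgrna_design)

    @property
    def n_genes(self) -> int:
        return len(self.gene_params)


def make_truth(
    genome: SyntheticGenome,
    library: SgRNALibrary,
    n_cells: int = 2000,
    seed: int = 0,
    labeling_time_t: float = 2.0,
    alpha_range: tuple[float, float] = (0.05, 5.0),
    halflife_range: tuple[float, float] = (0.5, 24.0),
    knockdown_effect: float | dict[str, float] = 0.7,
    doublet_rate: float = 0.05,
    p_conversion: float = 0.05,
    p_error: float = 0.001,
    n_snps: int = 50,
    ambient_sgrna_rate: float = 0.2,
    mean_sgrna_umis: float = 30.0,
    size_factor_sd: float = 0.3,
    dispersion: Optional[float] = None,
    read_length: int = 50,
) -> SimulationTruth:
    """Draw one screen's ground truth under the study conditions.

    Defaults reflect the screened system: a 2-h labeling window, half-lives
    log-uniform over 0.5-24 h, synthesis rates log-uniform over two decades
    chosen to give a few thousand UMIs per cell at ~300 genes (matching the
    shallow per-cell depth of combinatorial-indexing screens), ~70%
    knockdown of each target's synthesis rate, lognormal size factors, ~30
    guide UMIs per cell, and a few percent guide doublets.
    """
    rng = _child_rng(seed, 2)
    gene_ids = [g.gene_id for g in genome.genes]
    n_genes = len(gene_ids)
    alpha = np.exp(
        rng.uniform(np.log(alpha_range[0]), np.log(alpha_range[1]), n_genes)
    )
    halflife = np.exp(
        rng.uniform(
            np.log(halflife_range[0]), np.log(halflife_range[1]), n_genes
        )
    )
    gene_params = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "alpha": alpha,
            "beta": np.log(2) / halflife,
            "is_mito": [g.is_mito for g in genome.genes],
        }
    )

    targets = sorted(
        set(library.entries.loc[~library.entries["is_ntc"], "target_gene"])
    )
    if isinstance(knockdown_effect, dict):
        effects = dict(knockdown_effect)
    else:
        effects = {t: float(knockdown_effect) for t in targets}

    sgrna_ids = library.sgrna_ids
    cells = [f"C{i:05d}" for i in range(n_cells)]
    first = rng.choice(sgrna_ids, size=n_cells)
    doublet = rng.random(n_cells) < doublet_rate
    design_rows = []
    for i, cb in enumerate(cells):
        ids = [str(first[i])]
        if doublet[i]:
            other = str(rng.choice(sgrna_ids))
            while other == ids[0]:
                other = str(rng.choice(sgrna_ids))
            ids.append(other)
        design_rows.append(
            dict(cell_barcode=cb, sgrna_ids=tuple(ids), doublet=bool(doublet[i]))
        )
    sgrna_design = pd.DataFrame(design_rows)

    size_factors = np.exp(rng.normal(0.0, size_factor_sd, n_cells))
    size_factors /= size_factors.mean()

    snps: dict[tuple[str, int], str] = {}
    if n_snps > 0:
        names = list(genome.contigs)
        lengths = np.array([len(genome.contigs[n]) for n in names])
        probs = lengths / lengths.sum()
        while len(snps) < n_snps:
            name = str(rng.choice(names, p=probs))
            pos = int(rng.integers(0, len(genome.contigs[name])))
            ref = genome.contigs[name][pos].decode()
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            snps[(name, pos)] = alt

    return SimulationTruth(
        gene_params=gene_params,
        labeling_time_t=labeling_time_t,
        cell_size_factors=size_factors,
        knockdown_effects=effects,
        sgrna_design=sgrna_design,
        p_conversion=p_conversion,
        p_error=p_error,
        snp_positions=snps,
        ambient_sgrna_rate=ambient_sgrna_rate,
        mean_sgrna_umis=mean_sgrna_umis,
        seed=seed,
        library=library,
        dispersion=dispersion,
        read_length=read_length,
    )


def make_unperturbed_truth(
    gene_params: pd.DataFrame,
    n_cells: int,
    seed: int = 0,
    labeling_time_t: float = 2.0,
    size_factor_sd: float = 0.0,
    dispersion: Optional[float] = None,
    p_conversion: float = 0.05,
    p_error: float = 0.001,
) -> SimulationTruth:
    """Truth with explicit gene parameters and no perturbation.

    Convenience for calibration experiments (rate recovery, null screens)
    where the per-gene (alpha, beta) grid is prescribed rather than drawn.
    ``gene_params`` needs columns gene_id, alpha, beta (is_mito optional).
    """
    gp = gene_params.copy()
    if "is_mito" not in gp:
        gp["is_mito"] = False
    rng = _child_rng(seed, 9)
    sizes = (
        np.exp(rng.normal(0.0, size_factor_sd, n_cells))
        if size_factor_sd > 0
        else np.ones(n_cells)
    )
    sizes = sizes / sizes.mean()
    design = pd.DataFrame(
        {
            "cell_barcode": [f"C{i:05d}" for i in range(n_cells)],
            "sgrna_ids": [()] * n_cells,
            "doublet": [False] * n_cells,
        }
    )
    return SimulationTruth(
        gene_params=gp,
        labeling_time_t=labeling_time_t,
        cell_size_factors=sizes,
        knockdown_effects={},
        sgrna_design=design,
        p_conversion=p_conversion,
        p_error=p_error,
        snp_positions={},
        ambient_sgrna_rate=0.0,
        mean_sgrna_umis=0.0,
        seed=seed,
        library=None,
        dispersion=dispersion,
    )


def _effective_alpha(truth: SimulationTruth) -> np.ndarray:
    """Cells x genes matrix of knocked-down synthesis rates."""
    alpha = truth.gene_params["alpha"].to_numpy()
    gi = {g: j for j, g in enumerate(truth.gene_params["gene_id"])}
    tmap = truth.library.target_map if truth.library is not None else {}
    out = np.tile(alpha, (truth.n_cells, 1))
    for i, ids in enumerate(truth.sgrna_design["sgrna_ids"]):
        for sid in ids:
            target = tmap.get(sid)
            if target is None or target == "NTC":
                continue
            j = gi.get(target)
            if j is not None:
                out[i, j] *= 1.0 - truth.knockdown_effects.get(target, 0.0)
    return out


def simulate_counts(truth: SimulationTruth) -> ad.AnnData:
    """Sample whole/nascent counts for every cell under the truth.

    Returns an AnnData (cells x genes): ``X`` whole counts, layer
    ``nascent``; truth annotations in ``obs``/``var``.  Deterministic for a
    fixed truth (master seed, child stream).
    """
    rng = _child_rng(truth.seed, 3)
    beta = truth.gene_params["beta"].to_numpy()
    t = truth.labeling_time_t
    mu = _effective_alpha(truth) / beta * truth.cell_size_factors[:, None]
    if truth.dispersion is None:
        whole = rng.poisson(mu)
    else:
        size = truth.dispersion
        whole = rng.negative_binomial(size, size / (size + mu))
    f = 1.0 - np.exp(-beta * t)
    nascent = rng.binomial(whole, f[None, :])

    tmap = truth.library.target_map if truth.library is not None else {}
    primary = [
        ids[0] if ids else None for ids in truth.sgrna_design["sgrna_ids"]
    ]
    obs = pd.DataFrame(
        {
            "size_factor": truth.cell_size_factors,
            "true_sgrnas": [
                "+".join(ids) for ids in truth.sgrna_design["sgrna_ids"]
            ],
            "true_target": [tmap.get(s, "NTC") for s in primary],
            "true_doublet": truth.sgrna_design["doublet"].to_numpy(),
        },
        index=pd.Index(
            truth.sgrna_design["cell_barcode"], name="cell_barcode"
        ),
    )
    var = truth.gene_params.set_index("gene_id")[["alpha", "beta", "is_mito"]]
    var["nascent_fraction_true"] = f
    return ad.AnnData(
        X=sparse.csr_matrix(whole.astype(np.int32)),
        obs=obs,
        var=var,
        layers={"nascent": sparse.csr_matrix(nascent.astype(np.int32))},
    )


def _random_umis(rng: np.random.Generator, n: int, length: int = 10) -> list[str]:
    arr = rng.choice(_BASES, size=(n, length))
    return ["".join(row.astype(str)) for row in arr]


def simulate_sgrna_records(truth: SimulationTruth) -> pd.DataFrame:
    """UMI-level guide-capture records (cell_barcode, sgrna_id, umi).

    Each cell's true guide receives the dominant UMI mass (Poisson around
    ``mean_sgrna_umis``, split ~50/50 for doublets); ambient contamination
    adds stray single-UMI guides at ``ambient_sgrna_rate`` per cell.
    """
    if truth.library is None:
        raise ValueError("truth carries no guide library")
    rng = _child_rng(truth.seed, 4)
    sgrna_ids = truth.library.sgrna_ids
    cells, ids = [], []
    for i, row in truth.sgrna_design.iterrows():
        cb = row["cell_barcode"]
        own = list(row["sgrna_ids"])
        total = int(rng.poisson(truth.mean_sgrna_umis))
        if len(own) == 1:
            masses = [total]
        else:
            a = int(rng.binomial(total, 0.5))
            masses = [a, total - a]
        for sid, m in zip(own, masses):
            cells.extend([cb] * m)
            ids.extend([sid] * m)
        n_amb = int(rng.poisson(truth.ambient_sgrna_rate))
        for _ in range(n_amb):
            cells.append(cb)
            ids.append(str(rng.choice(sgrna_ids)))
    umis = _random_umis(rng, len(cells))
    return pd.DataFrame(
        {"cell_barcode": cells, "sgrna_id": ids, "umi": umis}
    )


def sgrna_records_to_fastq(
    records: pd.DataFrame,
    library: SgRNALibrary,
    path: str | Path,
    layout=None,
) -> None:
    """Render guide records as enrichment-library FASTQ reads."""
    from .sgrna import SgRNAReadLayout

    layout = layout or SgRNAReadLayout()
    spacer = dict(
        zip(library.entries["sgrna_id"], library.entries["protospacer"])
    )
    with open(path, "w") as fh:
        for k, row in enumerate(records.itertuples(index=False)):
            seq = (
                row.cell_barcode
                + row.umi
                + layout.anchor
                + spacer[row.sgrna_id]
            )
            fh.write(f"@sg{k}\n{seq}\n+\n{'I' * len(seq)}\n")


def _md_and_nm(ref: np.ndarray, read: np.ndarray) -> tuple[str, int]:
    """MD tag and NM count for an all-M alignment."""
    md = []
    run = 0
    nm = 0
    for rb, qb in zip(ref, read):
        if rb == qb:
            run += 1
        else:
            md.append(str(run))
            md.append(rb.decode())
            run = 0
            nm += 1
    md.append(str(run))
    return "".join(md), nm


def simulate_reads(
    truth: SimulationTruth,
    counts: ad.AnnData,
    genome: SyntheticGenome,
    sam_path: str | Path,
) -> pd.DataFrame:
    """Emit one aligned read per molecule of ``counts`` as SAM.

    Returns the per-read truth table (read_id, cell_barcode, umi, gene_id,
    origin in {nascent, preexisting, intergenic}, n_true_conversions).
    Conversions are planted only on nascent molecules; SNP alternate bases
    appear on every read covering the site; sequencing errors on all reads.
    """
    if not genome.contigs:
        raise ValueError("empty reference genome")
    rng = _child_rng(truth.seed, 5)
    L = truth.read_length
    genes = {g.gene_id: g for g in genome.genes}
    snp_by_contig: dict[str, dict[int, bytes]] = {}
    for (contig, pos), alt in truth.snp_positions.items():
        snp_by_contig.setdefault(contig, {})[pos] = alt.encode()

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": name, "LN": len(seq)}
            for name, seq in genome.contigs.items()
        ],
    }
    whole = np.asarray(counts.X.todense())
    nasc = np.asarray(counts.layers["nascent"].todense())
    gene_ids = list(counts.var_names)
    cell_ids = list(counts.obs_names)
    truth_rows = []
    serial = 0

    contig_names = list(genome.contigs)
    # valid intergenic read starts: the read must fit between gene spans
    inter_starts: list[tuple[str, int, int]] = []  # (contig, lo, hi)
    for contig in contig_names:
        spans = sorted(
            (g.start, g.end) for g in genome.genes if g.contig == contig
        )
        edges = [0] + [e for _, e in spans]
        nexts = [s for s, _ in spans] + [len(genome.contigs[contig])]
        for lo, hi in zip(edges, nexts):
            if hi - lo >= L:
                inter_starts.append((contig, lo, hi - L))
    inter_weights = np.array(
        [hi - lo + 1 for _, lo, hi in inter_starts], dtype=float
    )
    if inter_weights.size:
        inter_weights /= inter_weights.sum()

    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:

        def emit(
            cb: str,
            contig: str,
            start: int,
            strand: str,
            gene_id: Optional[str],
            is_nascent: bool,
        ) -> None:
            nonlocal serial
            ref = genome.sequence(contig, start, start + L).copy()
            read = ref.copy()
            # SNP alternate alleles, independent of labeling
            for pos, alt in snp_by_contig.get(contig, {}).items():
                if start <= pos < start + L:
                    read[pos - start] = alt
            # chemical conversions on templated T (transcript orientation)
            n_conv = 0
            if is_nascent and truth.p_conversion > 0:
                conv_from = b"T" if strand == "+" else b"A"
                conv_to = b"C" if strand == "+" else b"G"
                sites = np.flatnonzero(ref == conv_from)
                hit = sites[rng.random(sites.size) < truth.p_conversion]
                read[hit] = conv_to
                n_conv = int(hit.size)
            # sequencing error to a uniformly chosen different base
            if truth.p_error > 0:
                errs = np.flatnonzero(rng.random(L) < truth.p_error)
                for e in errs:
                    choices = _BASES[_BASES != read[e]]
                    read[e] = rng.choice(choices)
            umi = "".join(rng.choice(_BASES, size=10).astype(str))
            name = f"{cb}|{umi}|{serial}"
            serial += 1
            md, nm = _md_and_nm(ref, read)
            n_copies = 1 + int(rng.poisson(truth.pcr_duplicate_rate))
            for _ in range(n_copies):
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = read.tobytes().decode()
                a.flag = 16 if strand == "-" else 0
                a.reference_id = contig_names.index(contig)
                a.reference_start = start
                a.mapping_quality = 60
                a.cigarstring = f"{L}M"
                a.query_qualities = pysam.qualitystring_to_array("I" * L)
                a.set_tag("MD", md)
                a.set_tag("NM", nm)
                out.write(a)
            truth_rows.append(
                dict(
                    read_id=name,
                    cell_barcode=cb,
                    umi=umi,
                    gene_id=gene_id if gene_id else "",
                    origin=(
                        "nascent"
                        if is_nascent
                        else ("preexisting" if gene_id else "intergenic")
                    ),
                    n_true_conversions=n_conv,
                )
            )

        for i, cb in enumerate(cell_ids):
            genic = 0
            for j in np.flatnonzero(whole[i]):
                g = genes[gene_ids[j]]
                lo, hi = g.start, max(g.start + 1, g.end - L)
                w, n = int(whole[i, j]), int(nasc[i, j])
                genic += w
                starts = rng.integers(lo, hi, size=w)
                for k in range(w):
                    emit(cb, g.contig, int(starts[k]), g.strand, g.gene_id, k < n)
            # intergenic/unannotated reads
            n_inter = (
                int(rng.poisson(truth.frac_intergenic * genic))
                if inter_weights.size
                else 0
            )
            for _ in range(n_inter):
                k = int(rng.choice(len(inter_starts), p=inter_weights))
                contig, lo, hi = inter_starts[k]
                start = int(rng.integers(lo, hi + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                emit(cb, contig, start, strand, None, False)

    return pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "cell_barcode",
            "umi",
            "gene_id",
            "origin",
            "n_true_conversions",
        ],
    )


def simulate_control_reads(
    truth: SimulationTruth,
    genome: SyntheticGenome,
    sam_path: str | Path,
    n_cells: int = 20,
    seed_offset: int = 97,
) -> pd.DataFrame:
    """Unlabeled control sample for SNP-background estimation.

    Same genome and gene parameters, no 4sU (p_conversion = 0), a small
    number of cells with no perturbation.
    """
    import dataclasses

    design = pd.DataFrame(
        {
            "cell_barcode": [f"CTRL{i:04d}" for i in range(n_cells)],
            "sgrna_ids": [("NTC_sg1",)] * n_cells,
            "doublet": [False] * n_cells,
        }
    )
    ctrl = dataclasses.replace(
        truth,
        sgrna_design=design,
        cell_size_factors=np.ones(n_cells),
        knockdown_effects={},
        p_conversion=0.0,
        seed=truth.seed + seed_offset,
    )
    counts = simulate_counts(ctrl)
    return simulate_reads(ctrl, counts, genome, sam_path)
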