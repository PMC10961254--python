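"""Count-matrix construction and cell quality control.

Deduplicated, gene-assigned, nascent-labeled reads are accumulated into
gene x cell matrices carried as an :class:`anndata.AnnData` with cells as
observations: ``X`` holds whole-transcriptome UMI counts and layers
``nascent``, ``exonic_whole`` and ``exonic_nascent`` hold the sub-counts.
Cell QC keeps cells with >= 300 whole-transcriptome UMIs, >= 200 genes,
>= 10 sgRNA UMIs and an unannotated-read fraction below 40%.

Guide efficacy filtering merges the cells of each sgRNA into a pseudobulk,
CPM-normalizes it, and compares the target gene's CPM with the NTC
pseudobulk: guides achieving >= 40% target knockdown are "effective", their
singlets are "on-target" cells, and target genes keeping fewer than 50 such
cells are dropped from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import anndata as ad
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import sparse

from .nascent import ReadAlignment
from .sgrna import SgRNALibrary


@dataclass
class GeneAnnotation:
    """One gene: span, strand and merged exon intervals (0-based half-open)."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    is_mito: bool = False

    def __post_init__(self) -> None:
        self.exons = merge_intervals(self.exons)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene span"
                )


def merge_intervals(
    intervals: Iterable[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals into a sorted list."""
    ivs = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if e <= s:
            raise ValueError(f"empty interval ({s},{e})")
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


class GeneIndex:
    """Interval index over gene spans for read-to-gene assignment.

    A read is assigned to a gene iff its alignment span overlaps exactly one
    gene on the matching strand; overlap with zero genes or with more than
    one gene (ambiguous) yields no assignment.  The exonic flag records
    whether the read touches at least one exon of the assigned gene.
    """

    def __init__(self, genes: Iterable[GeneAnnotation]):
        self.genes: dict[str, GeneAnnotation] = {}
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
            key = (g.contig, g.strand)
            self._trees.setdefault(key, IntervalTree())
            self._trees[key][g.start : g.end] = g.gene_id

    def __len__(self) -> int:
        return len(self.genes)

    def strand_of(self, gene_id: str) -> str:
        return self.genes[gene_id].strand

    @property
    def mito_genes(self) -> list[str]:
        return [g.gene_id for g in self.genes.values() if g.is_mito]

    def assign(
        self, read: ReadAlignment
    ) -> tuple[Optional[str], bool]:
        """Assign one read; returns (gene_id or None, exonic)."""
        tree = self._trees.get((read.contig, read.strand))
        if tree is None:
            return None, False
        hits = tree[read.start : read.end]
        if len(hits) != 1:
            return None, False
        gene = self.genes[next(iter(hits)).data]
        exonic = any(
            read.start < e and s < read.end for s, e in gene.exons
        )
        return gene.gene_id, exonic

    @classmethod
    def from_gtf(
        cls, path: str | Path, mito_contig: str = "chrM"
    ) -> "GeneIndex":
        """Build the index from a GTF with gene and exon features.

        GTF coordinates are 1-based inclusive and converted to 0-based
        half-open on read.
        """
        import gffutils

        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        exons: dict[str, list[tuple[int, int]]] = {}
        for ex in db.features_of_type("exon"):
            gid = ex.attributes["gene_id"][0]
            exons.setdefault(gid, []).append((ex.start - 1, ex.end))
        genes = []
        for g in db.features_of_type("gene"):
            gid = g.attributes["gene_id"][0]
            genes.append(
                GeneAnnotation(
                    gene_id=gid,
                    contig=g.seqid,
                    strand=g.strand,
                    start=g.start - 1,
                    end=g.end,
                    exons=exons.get(gid, []),
                    is_mito=g.seqid == mito_contig,
                )
            )
        return cls(genes)


def dedup_reads(
    alignments: Iterable[ReadAlignment],
) -> list[ReadAlignment]:
    """Keep one read per (cell, UMI, contig, 5' position, strand).

    The first read seen for a key is its representative, so the operation is
    idempotent and deterministic for a fixed input order.
    """
    seen: set[tuple[str, str, str, int, str]] = set()
    kept: list[ReadAlignment] = []
    for aln in alignments:
        key = (aln.cell_barcode, aln.umi, aln.contig, aln.five_prime, aln.strand)
        if key not in seen:
            seen.add(key)
            kept.append(aln)
    return kept


def assign_read_to_gene(
    read: ReadAlignment, index: GeneIndex
) -> tuple[Optional[str], bool]:
    """Functional wrapper around :meth:`GeneIndex.assign`."""
    return index.assign(read)


def build_matrices(
    labeled_reads: pd.DataFrame,
    gene_ids: Iterable[str],
    mito_genes: Iterable[str] = (),
) -> ad.AnnData:
    """Accumulate labeled, assigned reads into a cells x genes AnnData.

    ``labeled_reads`` is the :func:`slamscreen.nascent.call_nascent` output
    for deduplicated reads (columns cell_barcode, gene_id, exonic, label).
    Whole counts include every assigned read; the ``nascent`` layer the
    nascent-labeled subset; ``exonic_*`` layers the exon-overlapping subsets.
    Per-cell totals and the unannotated fraction (reads assigned to no unique
    gene over all deduplicated reads) land in ``obs``.
    """
    gene_ids = list(gene_ids)
    cells = sorted(labeled_reads["cell_barcode"].unique())
    ci = {c: i for i, c in enumerate(cells)}
    gi = {g: j for j, g in enumerate(gene_ids)}

    shape = (len(cells), len(gene_ids))
    mats = {
        name: sparse.lil_matrix(shape, dtype=np.int32)
        for name in ("whole", "nascent", "exonic_whole", "exonic_nascent")
    }
    total = np.zeros(len(cells), dtype=np.int64)

    for row in labeled_reads.itertuples(index=False):
        i = ci[row.cell_barcode]
        total[i] += 1
        g = row.gene_id
        if g is None or (isinstance(g, float) and np.isnan(g)):
            continue
        j = gi[g]
        nascent = row.label == "nascent"
        mats["whole"][i, j] += 1
        if nascent:
            mats["nascent"][i, j] += 1
        if row.exonic:
            mats["exonic_whole"][i, j] += 1
            if nascent:
                mats["exonic_nascent"][i, j] += 1

    X = mats["whole"].tocsr()
    adata = ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_barcode")),
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
        layers={
            "nascent": mats["nascent"].tocsr(),
            "exonic_whole": mats["exonic_whole"].tocsr(),
            "exonic_nascent": mats["exonic_nascent"].tocsr(),
        },
    )
    adata.var["is_mito"] = adata.var_names.isin(set(mito_genes))
    assigned = np.asarray(X.sum(axis=1)).ravel()
    adata.obs["total_umis"] = assigned.astype(int)
    adata.obs["genes_detected"] = np.asarray((X > 0).sum(axis=1)).ravel()
    adata.obs["deduped_reads"] = total
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, (total - assigned) / total, 0.0)
    adata.obs["unannotated_fraction"] = frac
    return adata


def attach_sgrna_calls(
    adata: ad.AnnData, calls: pd.DataFrame, library: SgRNALibrary
) -> ad.AnnData:
    """Join per-cell guide calls onto ``obs`` and derive the target gene."""
    calls = calls.set_index("cell_barcode")
    adata.obs["sgrna_umis"] = (
        calls["total_umis"].reindex(adata.obs_names).fillna(0).astype(int)
    )
    adata.obs["sgrna_status"] = (
        calls["status"].reindex(adata.obs_names).fillna("no_sgrna")
    )
    adata.obs["assigned_sgrna"] = calls["assigned_sgrna"].reindex(
        adata.obs_names
    )
    tmap = library.target_map
    adata.obs["target_gene"] = adata.obs["assigned_sgrna"].map(tmap)
    return adata


def filter_cells(
    adata: ad.AnnData,
    min_umis: int = 300,
    min_genes: int = 200,
    min_sgrna_umis: int = 10,
    max_unannotated_fraction: float = 0.40,
) -> ad.AnnData:
    """Apply the cell QC quadruple; thresholds are inclusive except the
    unannotated-fraction bound, which is strict."""
    obs = adata.obs
    keep = (
        (obs["total_umis"] >= min_umis)
        & (obs["genes_detected"] >= min_genes)
        & (obs["sgrna_umis"] >= min_sgrna_umis)
        & (obs["unannotated_fraction"] < max_unannotated_fraction)
    )
    return adata[keep.values].copy()


def cpm_normalize(counts: np.ndarray) -> np.ndarray:
    """Counts-per-million of a pseudobulk vector; the output sums to 1e6."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot CPM-normalize a zero-total vector")
    return counts * 1e6 / total


def _pseudobulk_cpm(adata: ad.AnnData, mask: np.ndarray) -> np.ndarray:
    sub = adata.X[mask]
    vec = np.asarray(sub.sum(axis=0)).ravel()
    return cpm_normalize(vec)


def knockdown_filter(
    adata: ad.AnnData,
    library: SgRNALibrary,
    min_reduction: float = 0.40,
    min_cells_per_target: int = 50,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Keep on-target singlets of effective guides plus all NTC singlets.

    Expects ``obs`` columns ``assigned_sgrna``/``target_gene`` on singlet
    cells (others are dropped first).  Efficiency per guide is the whole-
    transcriptome pseudobulk CPM of its target divided by the NTC pseudobulk
    CPM of the same gene; a guide is effective iff that fold change is
    <= 1 - min_reduction.  Guides whose target is absent from the matrix or
    has zero NTC CPM are excluded with an undefined efficiency.  Target genes
    retaining fewer than ``min_cells_per_target`` on-target cells are dropped
    entirely; NTC cells are always kept as the reference.
    """
    import warnings

    singlet = adata.obs["assigned_sgrna"].notna().values
    adata = adata[singlet].copy()
    obs = adata.obs
    ntc_ids = set(library.ntc_ids)
    is_ntc = obs["assigned_sgrna"].isin(ntc_ids).values
    if not is_ntc.any():
        raise ValueError("no NTC cells present; cannot compute efficiencies")
    ntc_cpm = _pseudobulk_cpm(adata, is_ntc)
    var_index = {g: j for j, g in enumerate(adata.var_names)}

    rows = []
    effective: set[str] = set()
    for sgrna_id, grp in obs.groupby("assigned_sgrna", observed=True):
        if sgrna_id in ntc_ids:
            continue
        target = library.target_map[sgrna_id]
        n_cells = len(grp)
        j = var_index.get(target)
        if j is None or ntc_cpm[j] == 0:
            warnings.warn(
                f"{sgrna_id}: target {target} not quantifiable in NTC; "
                "guide excluded"
            )
            rows.append(
                dict(
                    sgrna_id=sgrna_id, target_gene=target, n_cells=n_cells,
                    target_cpm=np.nan, ntc_cpm=np.nan, fold_change=np.nan,
                    knockdown=np.nan, effective=False,
                )
            )
            continue
        mask = (obs["assigned_sgrna"] == sgrna_id).values
        cpm = _pseudobulk_cpm(adata, mask)
        fc = cpm[j] / ntc_cpm[j]
        rows.append(
            dict(
                sgrna_id=sgrna_id, target_gene=target, n_cells=n_cells,
                target_cpm=cpm[j], ntc_cpm=ntc_cpm[j], fold_change=fc,
                knockdown=1.0 - fc, effective=fc <= 1.0 - min_reduction,
            )
        )
        if fc <= 1.0 - min_reduction:
            effective.add(sgrna_id)
    efficiency = pd.DataFrame(
        rows,
        columns=[
            "sgrna_id", "target_gene", "n_cells", "target_cpm", "ntc_cpm",
            "fold_change", "knockdown", "effective",
        ],
    )

    on_target = obs["assigned_sgrna"].isin(effective).values
    keep_targets = {
        t
        for t, n in obs.loc[on_target, "target_gene"].value_counts().items()
        if n >= min_cells_per_target
    }
    keep = is_ntc | (
        on_target & obs["target_gene"].isin(keep_targets).values
    )
    filtered = adata[keep].copy()
    filtered.obs["group"] = np.where(
        filtered.obs["assigned_sgrna"].isin(ntc_ids),
        "NTC",
        filtered.obs["target_gene"],
    )
    return filtered, efficiency


def mito_turnover(adata: ad.AnnData) -> pd.Series:
    """Per-cell nascent/whole ratio over mitochondrial genes (NaN if no
    mitochondrial counts)."""
    mito = adata.var["is_mito"].values
    if not mito.any():
        return pd.Series(np.nan, index=adata.obs_names, name="mito_turnover")
    whole = np.asarray(adata.X[:, mito].sum(axis=1)).ravel()
    nasc = np.asarray(adata.layers["nascent"][:, mito].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(whole > 0, nasc / np.maximum(whole, 1), np.nan)
    return pd.Series(ratio, index=adata.obs_names, name="mito_turnover")


def exonic_nascent_fraction(adata: ad.AnnData) -> pd.Series:
    """Per-cell fraction of nascent reads overlapping exons (NaN when the
    cell has no nascent reads)."""
    nasc = np.asarray(adata.layers["nascent"].sum(axis=1)).ravel()
    exn = np.asarray(adata.layers["exonic_nascent"].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(nasc > 0, exn / np.maximum(nasc, 1), np.nan)
    return pd.Series(
        frac, index=adata.obs_names, name="exonic_nascent_fraction"
    )
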