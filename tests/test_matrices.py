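"""Dedup, gene assignment, matrix construction, QC and knockdown filtering."""

import itertools

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from slamscreen import simulate as sim
from slamscreen.matrices import (
    GeneAnnotation,
    GeneIndex,
    attach_sgrna_calls,
    build_matrices,
    cpm_normalize,
    dedup_reads,
    exonic_nascent_fraction,
    filter_cells,
    knockdown_filter,
    merge_intervals,
    mito_turnover,
)
from slamscreen.nascent import ReadAlignment
from slamscreen.sgrna import SgRNALibrary


def _read(contig="c1", start=100, end=150, strand="+", cell="c", umi="u",
          rid="r"):
    return ReadAlignment(
        read_id=rid, cell_barcode=cell, umi=umi, contig=contig,
        start=start, end=end, strand=strand, mapq=60,
    )


@pytest.fixture()
def index():
    return GeneIndex(
        [
            GeneAnnotation("gA", "c1", "+", 0, 1000,
                           [(0, 200), (500, 1000)]),
            GeneAnnotation("gB", "c1", "-", 1200, 2000, [(1200, 2000)]),
            # overlapping pair on the same strand: always ambiguous
            GeneAnnotation("gC", "c2", "+", 0, 500, [(0, 500)]),
            GeneAnnotation("gD", "c2", "+", 300, 900, [(300, 900)]),
            GeneAnnotation("mt1", "chrM", "+", 0, 600, [(0, 600)],
                           is_mito=True),
        ]
    )


class TestIntervalsAndIndex:
    def test_merge_intervals(self):
        assert merge_intervals([(5, 10), (0, 6), (20, 30)]) == \
            [(0, 10), (20, 30)]

    def test_exon_outside_span_rejected(self):
        with pytest.raises(ValueError):
            GeneAnnotation("g", "c", "+", 100, 200, [(50, 150)])

    def test_exonic_assignment(self, index):
        gene, exonic = index.assign(_read(start=100, end=150))
        assert gene == "gA" and exonic

    def test_intronic_assignment(self, index):
        gene, exonic = index.assign(_read(start=300, end=350))
        assert gene == "gA" and not exonic

    def test_strand_mismatch_unassigned(self, index):
        gene, _ = index.assign(_read(start=100, end=150, strand="-"))
        assert gene is None

    def test_ambiguous_overlap_unassigned(self, index):
        gene, _ = index.assign(_read(contig="c2", start=350, end=400))
        assert gene is None

    def test_no_overlap_unassigned(self, index):
        gene, _ = index.assign(_read(start=1050, end=1100))
        assert gene is None

    def test_gtf_round_trip(self, tmp_path):
        genome = sim.build_genome(10, n_mito_genes=2, seed=31)
        gtf = tmp_path / "ann.gtf"
        genome.to_gtf(gtf)
        idx = GeneIndex.from_gtf(gtf, mito_contig="chrM")
        assert len(idx) == 12
        assert set(idx.mito_genes) == {"mito00", "mito01"}
        for g in genome.genes:
            got = idx.genes[g.gene_id]
            assert (got.contig, got.strand, got.start, got.end) == \
                (g.contig, g.strand, g.start, g.end)
            assert got.exons == g.exons


class TestDedup:
    def test_same_key_collapses(self):
        reads = [_read(rid="a"), _read(rid="b")]
        assert [r.read_id for r in dedup_reads(reads)] == ["a"]

    def test_same_umi_different_position_kept(self):
        reads = [_read(rid="a", start=100, end=150),
                 _read(rid="b", start=200, end=250)]
        assert len(dedup_reads(reads)) == 2

    def test_five_prime_key_on_minus_strand(self):
        # same 5' end (end-1) on minus strand collapses despite start
        reads = [
            _read(rid="a", start=100, end=150, strand="-"),
            _read(rid="b", start=120, end=150, strand="-"),
        ]
        assert len(dedup_reads(reads)) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        reads = [
            _read(rid=f"r{i}", cell=f"c{rng.integers(3)}",
                  umi=f"u{rng.integers(4)}",
                  start=int(rng.integers(0, 5)) * 50)
            for i in range(100)
        ]
        for r in reads:
            r.end = r.start + 50
        once = dedup_reads(reads)
        assert dedup_reads(once) == once


class TestBuildMatrices:
    def _labels(self):
        rows = []
        for i in range(5):  # 5 reads on gA, 2 nascent
            rows.append(
                dict(read_id=f"r{i}", cell_barcode="cell1", gene_id="gA",
                     exonic=i % 2 == 0,
                     label="nascent" if i < 2 else "preexisting")
            )
        rows.append(
            dict(read_id="r5", cell_barcode="cell1", gene_id=None,
                 exonic=False, label="preexisting")
        )
        return pd.DataFrame(rows)

    def test_counts_and_unannotated_fraction(self):
        adata = build_matrices(self._labels(), ["gA", "gB"])
        assert adata["cell1", "gA"].X[0, 0] == 5
        assert adata["cell1", "gA"].layers["nascent"][0, 0] == 2
        assert adata.obs.loc["cell1", "total_umis"] == 5
        assert adata.obs.loc["cell1", "unannotated_fraction"] == \
            pytest.approx(1 / 6)

    def test_conservation(self, read_level_screen):
        """assigned + unassigned = deduplicated reads, per cell."""
        from slamscreen.nascent import SnpBackground, call_nascent, \
            read_alignments
        from slamscreen.matrices import dedup_reads

        genome, _, truth, _, sam, _ = read_level_screen
        idx = GeneIndex(genome.genes)
        deduped = dedup_reads(read_alignments(sam))
        labels = call_nascent(
            deduped, SnpBackground(), gene_index=idx, min_base_quality=30
        )
        adata = build_matrices(labels, [g.gene_id for g in genome.genes],
                               mito_genes=idx.mito_genes)
        per_cell = labels.groupby("cell_barcode").size()
        for cb, n in per_cell.items():
            assert adata.obs.loc[cb, "deduped_reads"] == n
        assigned = np.asarray(adata.X.sum(axis=1)).ravel()
        unassigned = (
            adata.obs["deduped_reads"].to_numpy()
            * adata.obs["unannotated_fraction"].to_numpy()
        )
        np.testing.assert_allclose(
            assigned + unassigned, adata.obs["deduped_reads"]
        )
        # entrywise layer invariant
        assert (
            (adata.X - adata.layers["nascent"]).toarray() >= 0
        ).all()


class TestFilterCells:
    def test_boundary_oracle(self):
        """All 2^4 pass/fail combinations around the four thresholds."""
        values = {
            "total_umis": (300, 299),
            "genes_detected": (200, 199),
            "sgrna_umis": (10, 9),
            "unannotated_fraction": (0.39, 0.40),
        }
        rows = []
        for bits in itertools.product([0, 1], repeat=4):
            rows.append(
                {k: values[k][b] for k, b in zip(values, bits)}
            )
        obs = pd.DataFrame(rows)
        adata = ad.AnnData(
            X=sparse.csr_matrix(np.zeros((len(obs), 1))), obs=obs
        )
        kept = filter_cells(adata)
        expected = obs[
            (obs.total_umis >= 300) & (obs.genes_detected >= 200)
            & (obs.sgrna_umis >= 10) & (obs.unannotated_fraction < 0.40)
        ]
        assert kept.n_obs == len(expected) == 1  # only the all-pass row


class TestCpm:
    def test_two_equal_counts(self):
        np.testing.assert_allclose(
            cpm_normalize([1, 1]), [5e5, 5e5]
        )

    def test_sums_to_million_and_scale_invariant(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 100, 50)
        counts[0] = 1
        out = cpm_normalize(counts)
        assert out.sum() == pytest.approx(1e6)
        np.testing.assert_allclose(out, cpm_normalize(counts * 7))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            cpm_normalize([0, 0])


def _screen_adata(n_per_group=60, kd=0.7, seed=0):
    """Tiny screen: NTC cells plus one effective and one weak guide."""
    rng = np.random.default_rng(seed)
    genes = ["t1", "t2", "other"]
    base = np.array([50.0, 50.0, 100.0])
    rows, obs_rows = [], []
    groups = [
        ("NTC_sg1", None, 1.0),
        ("t1_sg1", "t1", 1.0 - kd),   # strong knockdown of t1
        ("t2_sg1", "t2", 0.7),        # only 30% reduction: ineffective
    ]
    for sgrna, target, factor in groups:
        for i in range(n_per_group):
            mu = base.copy()
            if target:
                mu[genes.index(target)] *= factor
            rows.append(rng.poisson(mu))
            obs_rows.append(
                dict(cell_barcode=f"{sgrna}_{i}", assigned_sgrna=sgrna,
                     target_gene="NTC" if sgrna.startswith("NTC") else target)
            )
    obs = pd.DataFrame(obs_rows).set_index("cell_barcode")
    X = sparse.csr_matrix(np.array(rows))
    adata = ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=genes))
    adata.layers["nascent"] = sparse.csr_matrix(
        np.minimum(np.array(rows) // 2, np.array(rows))
    )
    lib = SgRNALibrary(
        pd.DataFrame(
            [
                ("NTC_sg1", "A" * 20, "NTC", True),
                ("t1_sg1", "C" * 20, "t1", False),
                ("t2_sg1", "G" * 20, "t2", False),
            ],
            columns=["sgrna_id", "protospacer", "target_gene", "is_ntc"],
        )
    )
    return adata, lib


class TestKnockdownFilter:
    def test_effective_and_ineffective_guides(self):
        adata, lib = _screen_adata()
        filtered, eff = knockdown_filter(adata, lib, min_cells_per_target=50)
        eff = eff.set_index("sgrna_id")
        assert bool(eff.loc["t1_sg1", "effective"])
        assert not bool(eff.loc["t2_sg1", "effective"])
        groups = set(filtered.obs["group"])
        assert groups == {"NTC", "t1"}  # weak guide's cells discarded

    def test_small_targets_dropped(self):
        adata, lib = _screen_adata()
        filtered, _ = knockdown_filter(adata, lib, min_cells_per_target=61)
        assert set(filtered.obs["group"]) == {"NTC"}

    def test_requires_ntc(self):
        adata, lib = _screen_adata()
        no_ntc = adata[adata.obs["assigned_sgrna"] != "NTC_sg1"].copy()
        with pytest.raises(ValueError):
            knockdown_filter(no_ntc, lib)

    def test_efficiency_recovery_on_simulation(self):
        """A 70% synthesis knockdown reads out as ~70% expression reduction."""
        genome = sim.build_genome(30, n_mito_genes=0, seed=41)
        nuclear = [g.gene_id for g in genome.genes]
        lib = sim.make_library(nuclear[:1], sgrnas_per_gene=1, n_ntc=1,
                               seed=41)
        truth = sim.make_truth(
            genome, lib, n_cells=3000, seed=41,
            alpha_range=(1.0, 5.0), knockdown_effect=0.7,
            doublet_rate=0.0, ambient_sgrna_rate=0.0, size_factor_sd=0.0,
        )
        counts = sim.simulate_counts(truth)
        counts.obs["assigned_sgrna"] = [
            ids[0] for ids in truth.sgrna_design["sgrna_ids"]
        ]
        counts.obs["target_gene"] = counts.obs["true_target"]
        _, eff = knockdown_filter(counts, lib, min_cells_per_target=50)
        assert eff["knockdown"].iloc[0] == pytest.approx(0.70, abs=0.02)


class TestPerCellMetrics:
    def test_mito_turnover_values(self):
        obs = pd.DataFrame(index=["c1", "c2", "c3"])
        var = pd.DataFrame({"is_mito": [True, False]}, index=["mt", "nuc"])
        X = sparse.csr_matrix(np.array([[10, 5], [0, 8], [4, 0]]))
        nasc = sparse.csr_matrix(np.array([[5, 1], [0, 2], [4, 0]]))
        adata = ad.AnnData(X=X, obs=obs, var=var,
                           layers={"nascent": nasc})
        mt = mito_turnover(adata)
        assert mt["c1"] == pytest.approx(0.5)
        assert np.isnan(mt["c2"])  # no mitochondrial coverage
        assert mt["c3"] == pytest.approx(1.0)

    def test_exonic_nascent_fraction(self):
        obs = pd.DataFrame(index=["c1", "c2"])
        var = pd.DataFrame(index=["g1", "g2"])
        X = sparse.csr_matrix(np.array([[10, 10], [5, 5]]))
        nasc = sparse.csr_matrix(np.array([[4, 4], [0, 0]]))
        exn = sparse.csr_matrix(np.array([[2, 4], [0, 0]]))
        adata = ad.AnnData(
            X=X, obs=obs, var=var,
            layers={"nascent": nasc, "exonic_nascent": exn},
        )
        frac = exonic_nascent_fraction(adata)
        assert frac["c1"] == pytest.approx(6 / 8)
        assert np.isnan(frac["c2"])
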