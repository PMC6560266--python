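"""Ingestion, site classification, allele counting and the neutral PCA."""
import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from pyfaidx import Fasta

from convergescan import variantio
from convergescan.model import GeneModel

from conftest import make_design, make_table


def _write_vcf(path, records, samples):
    lines = ["##fileformat=VCFv4.2",
             "##contig=<ID=sc1,length=100000>",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(samples)]
    lines += records
    path.write_text("\n".join(lines) + "\n")


def _design3():
    rows = [{"individual": f"s{i}", "population": "halleri_Mias" if i < 2
             else "halleri_Zapa",
             "site": "Mias" if i < 2 else "Zapa",
             "soil_class": "M" if i < 2 else "NM",
             "species": "halleri", "pair": "pair1"} for i in range(3)]
    # a contrast needs one M and one NM population
    return variantio.StudyDesign.from_table(pd.DataFrame(rows))


class TestReadVcf:
    def test_identity_ingestion(self, tmp_path):
        recs = [f"sc1\t{10 * (i + 1)}\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1"
                for i in range(5)]
        p = tmp_path / "a.vcf"
        _write_vcf(p, recs, ["s0", "s1", "s2"])
        t = variantio.read_vcf(p, _design3(), max_missing=1.0)
        assert t.n_sites == 5 and t.n_individuals == 3
        assert np.all(t.dosages == np.array([[0, 1, 2]] * 5).T)

    def test_triallelic_skipped(self, tmp_path):
        recs = [f"sc1\t{10 * (i + 1)}\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1"
                for i in range(9)]
        recs.insert(4, "sc1\t45\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t1/2")
        p = tmp_path / "b.vcf"
        _write_vcf(p, recs, ["s0", "s1", "s2"])
        t = variantio.read_vcf(p, _design3(), max_missing=1.0)
        assert t.n_sites == 9

    def test_population_missingness_filter(self, tmp_path):
        # site 2 missing in 1/2 = 50% of the M population; limit is 20%
        recs = ["sc1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
                "sc1\t20\t.\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t1/1",
                "sc1\t30\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/1\t1/1"]
        p = tmp_path / "c.vcf"
        _write_vcf(p, recs, ["s0", "s1", "s2"])
        t = variantio.read_vcf(p, _design3(), max_missing=0.2)
        assert t.sites["pos"].tolist() == [10, 30]

    def test_missing_sample_is_hard_error(self, tmp_path):
        recs = ["sc1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1"]
        p = tmp_path / "d.vcf"
        _write_vcf(p, recs, ["s0", "s1"])
        with pytest.raises(ValueError, match="s2"):
            variantio.read_vcf(p, _design3())

    def test_failing_filter_dropped(self, tmp_path):
        recs = ["sc1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1",
                "sc1\t20\t.\tA\tG\t.\tLowQual\t.\tGT\t0/0\t0/1\t1/1"]
        p = tmp_path / "e.vcf"
        _write_vcf(p, recs, ["s0", "s1", "s2"])
        t = variantio.read_vcf(p, _design3(), max_missing=1.0)
        assert t.sites["pos"].tolist() == [10]


def test_vcf_round_trip(tmp_path, small_dataset):
    """Writing a GenotypeTable back to VCF and re-reading reproduces dosages."""
    d, result = small_dataset
    design = variantio.read_design(d / "design.tsv")
    t1 = variantio.read_vcf(d / "variants.vcf", design, max_missing=1.0)
    out = tmp_path / "rt.vcf"
    variantio.write_vcf(t1, out)
    t2 = variantio.read_vcf(out, design, max_missing=1.0)
    assert np.array_equal(t1.dosages, t2.dosages)
    pd.testing.assert_frame_equal(t1.sites, t2.sites)


class TestAlleleCounts:
    def test_basic_arithmetic(self):
        table = make_table(np.array([[0, 2], [1, 2], [2, 2]]))
        design = make_design([3, 0, 0, 0])
        c = variantio.allele_counts(table, design)
        assert c.alt[0, 0] == 3 and c.called[0, 0] == 6

    def test_all_missing_gives_zero_counts(self):
        table = make_table(np.array([[-1], [-1]]))
        design = make_design([2, 0, 0, 0])
        c = variantio.allele_counts(table, design)
        assert c.alt[0, 0] == 0 and c.called[0, 0] == 0

    def test_mixed_missing_matches_direct_tally(self):
        rng = np.random.default_rng(5)
        dos = rng.integers(-1, 3, size=(8, 30)).astype(np.int8)
        table = make_table(dos)
        design = make_design([3, 2, 2, 1])
        c = variantio.allele_counts(table, design)
        pops = [("halleri_Mias", range(0, 3)), ("halleri_Zapa", range(3, 5)),
                ("halleri_Klet", range(5, 7)), ("halleri_Kowa", range(7, 8))]
        for pop, rows in pops:
            pi = c.populations.index(pop)
            for j in range(30):
                vals = [dos[i, j] for i in rows if dos[i, j] >= 0]
                assert c.alt[pi, j] == sum(vals)
                assert c.called[pi, j] == 2 * len(vals)

    def test_totals_conserved(self):
        rng = np.random.default_rng(6)
        dos = rng.integers(-1, 3, size=(8, 50)).astype(np.int8)
        c = variantio.allele_counts(make_table(dos), make_design([2, 2, 2, 2]))
        ref = c.called - c.alt
        assert np.all(c.alt + ref == c.called)


class TestPolarize:
    def test_reference_ancestral_identity(self):
        table = make_table(np.array([[0, 1], [1, 0], [2, 0]]))
        c = variantio.allele_counts(table, make_design([3, 0, 0, 0]))
        p = variantio.polarize(c, table)
        assert np.array_equal(p.derived, c.alt)
        assert p.polarized.all()

    def test_ancestral_tag_complement(self):
        table = make_table(np.array([[0, 0], [1, 1], [0, 0]]),
                           refs=["A", "A"], alts=["G", "G"])
        c = variantio.allele_counts(table, make_design([3, 0, 0, 0]))
        tag = pd.Series(["G", "C"])  # site 0: alt ancestral; site 1: neither
        p = variantio.polarize(c, table, "ancestral_tag", tag)
        assert p.derived[0, 0] == c.called[0, 0] - c.alt[0, 0]
        assert p.polarized[0] and not p.polarized[1]


def _toy_gene_fasta(tmp_path, cds, strand="+", intron_at=None):
    """One single- or two-exon gene embedded in flanking sequence."""
    flank = "T" * 50
    if intron_at is None:
        genomic_gene = cds if strand == "+" else str(Seq(cds).reverse_complement())
        exons = [(51, 50 + len(genomic_gene))]
        cds_segs = [(51, 50 + len(genomic_gene), 0)]
    else:
        intron = "GT" + "C" * 30 + "AG"
        left, right = cds[:intron_at], cds[intron_at:]
        gene_seq = left + intron + right
        if strand == "-":
            gene_seq = str(Seq(gene_seq).reverse_complement())
            e2 = (51, 50 + len(right))
            e1 = (51 + len(right) + len(intron),
                  50 + len(right) + len(intron) + len(left))
            exons = [e2, e1]
        else:
            e1 = (51, 50 + len(left))
            e2 = (51 + len(left) + len(intron),
                  50 + len(left) + len(intron) + len(right))
            exons = [e1, e2]
        phase2 = (3 - len(left) % 3) % 3
        if strand == "+":
            cds_segs = [(exons[0][0], exons[0][1], 0),
                        (exons[1][0], exons[1][1], phase2)]
        else:
            cds_segs = [(exons[0][0], exons[0][1], phase2),
                        (exons[1][0], exons[1][1], 0)]
        genomic_gene = gene_seq
    seq = flank + genomic_gene + flank
    fa = tmp_path / "ref.fa"
    fa.write_text(f">sc1\n{seq}\n")
    gene = GeneModel(gene_id="g1", scaffold="sc1", strand=strand,
                     start=51, end=50 + len(genomic_gene),
                     exons=exons, cds=cds_segs)
    return Fasta(str(fa)), gene, seq


class TestClassifySites:
    def test_fourfold_glycine_and_met(self, tmp_path):
        cds = "ATG" + "GGA" + "TAA"  # Met-Gly-stop
        fasta, gene, seq = _toy_gene_fasta(tmp_path, cds)
        # sites at third positions of ATG (pos 53) and GGA (pos 56)
        dos = np.zeros((2, 2), dtype=np.int8)
        table = make_table(dos, start_pos=53, spacing=3)
        table.sites.loc[:, "ref"] = [seq[52], seq[55]]
        cls = variantio.classify_sites(table, [gene], fasta)
        assert cls["site_class"].tolist() == ["cds", "cds"]
        assert cls["fourfold_degenerate"].tolist() == [False, True]

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_full_toy_gene_matches_codon_enumeration(self, tmp_path, strand):
        rng = np.random.default_rng(11)
        from convergescan.variantio import STANDARD_CODE
        nonstop = [c for c in STANDARD_CODE if STANDARD_CODE[c] != "*"]
        cds = "ATG" + "".join(rng.choice(nonstop, 8)) + "TAA"
        fasta, gene, seq = _toy_gene_fasta(tmp_path, cds, strand=strand)
        n = gene.end - gene.start + 1
        dos = np.zeros((2, n), dtype=np.int8)
        table = make_table(dos, start_pos=gene.start, spacing=1)
        cls = variantio.classify_sites(table, [gene], fasta)
        # independent oracle: translate each codon with Biopython
        expected = np.zeros(n, dtype=bool)
        for ci in range(len(cds) // 3):
            codon = cds[3 * ci:3 * ci + 3]
            aas = {str(Seq(codon[:2] + b).translate()) for b in "ACGT"}
            if len(aas) == 1:
                tx_index = 3 * ci + 2  # third position, transcription order
                g = tx_index if strand == "+" else n - 1 - tx_index
                expected[g] = True
        assert np.array_equal(cls["fourfold_degenerate"].to_numpy(), expected)

    def test_flagged_gene_gets_no_degeneracy_calls(self, tmp_path):
        cds = "ATGGGATA"  # length 8, not divisible by 3
        fasta, gene, seq = _toy_gene_fasta(tmp_path, cds)
        gene.flagged = True
        table = make_table(np.zeros((2, 3), dtype=np.int8), start_pos=52,
                           spacing=3)
        cls = variantio.classify_sites(table, [gene], fasta)
        assert (cls["site_class"] == "cds").all()
        assert not cls["fourfold_degenerate"].any()

    def test_splice_region_called_in_intron_edges(self, tmp_path):
        cds = "ATG" + "GGAGCTCCT" * 4 + "TAA"
        fasta, gene, seq = _toy_gene_fasta(tmp_path, cds, intron_at=18)
        istart, iend = gene.introns()[0]
        pos = [istart, istart + 1, istart + 5, iend - 1, iend]
        table = make_table(np.zeros((2, len(pos)), dtype=np.int8))
        table.sites["pos"] = pos
        cls = variantio.classify_sites(table, [gene], fasta)
        assert cls["site_class"].tolist() == [
            "splice_region", "splice_region", "intron",
            "splice_region", "splice_region"]

    def test_missing_scaffold_is_hard_error(self, tmp_path):
        fasta, gene, _ = _toy_gene_fasta(tmp_path, "ATGGGATAA")
        gene.scaffold = "sc_absent"
        table = make_table(np.zeros((2, 1), dtype=np.int8))
        table.sites["scaffold"] = "sc_absent"
        with pytest.raises(ValueError, match="absent"):
            variantio.classify_sites(table, [gene], fasta)


def test_fourfold_agrees_with_enumeration_on_random_cds():
    """1,000 random codons against an independent codon-table oracle."""
    rng = np.random.default_rng(3)
    bases = "ACGT"
    for _ in range(1000):
        codon = "".join(rng.choice(list(bases), 3))
        got = variantio.is_fourfold_codon(codon)
        aas = {str(Seq(codon[:2] + b).translate()) for b in bases}
        assert got == (len(aas) == 1)


class TestNeutralPca:
    def _two_cluster_table(self, n_snps=2000, c=0.2, seed=0):
        rng = np.random.default_rng(seed)
        p0 = rng.uniform(0.1, 0.9, n_snps)
        f1 = rng.beta(p0 * (1 - c) / c, (1 - p0) * (1 - c) / c)
        f2 = rng.beta(p0 * (1 - c) / c, (1 - p0) * (1 - c) / c)
        dos = np.vstack([rng.binomial(2, f1, size=(8, n_snps)),
                         rng.binomial(2, f2, size=(8, n_snps))]).astype(np.int8)
        table = make_table(dos)
        classes = pd.DataFrame({
            "site_class": ["cds"] * n_snps,
            "gene_id": [""] * n_snps,
            "codon_pos": [3] * n_snps,
            "fourfold_degenerate": [True] * n_snps,
            "cds_flagged": [False] * n_snps})
        design = make_design([8, 8, 0, 0])
        return table, classes, design

    def test_pc1_separates_drifted_clusters(self):
        table, classes, design = self._two_cluster_table()
        coords, var = variantio.neutral_structure_pca(table, classes, design)
        a = coords.iloc[:8]["PC1"].to_numpy()
        b = coords.iloc[8:]["PC1"].to_numpy()
        assert a.max() < b.min() or b.max() < a.min()

    def test_duplicate_individuals_identical_coordinates(self):
        table, classes, design = self._two_cluster_table(n_snps=200)
        table.dosages[1] = table.dosages[0]
        coords, _ = variantio.neutral_structure_pca(table, classes, design)
        np.testing.assert_allclose(
            coords.iloc[0, :4].to_numpy(dtype=float),
            coords.iloc[1, :4].to_numpy(dtype=float), atol=1e-10)

    def test_variance_explained_is_a_decreasing_partition(self):
        table, classes, design = self._two_cluster_table(n_snps=300)
        _, var = variantio.neutral_structure_pca(table, classes, design)
        assert np.all(np.diff(var) <= 1e-12) and var.sum() <= 1.0 + 1e-9

    def test_no_variation_is_hard_error(self):
        table = make_table(np.ones((4, 3), dtype=np.int8))
        classes = pd.DataFrame({
            "site_class": ["cds"] * 3, "gene_id": [""] * 3,
            "codon_pos": [3] * 3, "fourfold_degenerate": [True] * 3,
            "cds_flagged": [False] * 3})
        with pytest.raises(ValueError, match="no neutral variation"):
            variantio.neutral_structure_pca(table, classes, make_design([4, 0, 0, 0]))
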