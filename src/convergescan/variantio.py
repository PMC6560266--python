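"""Input/output and site-level bookkeeping.

Reads VCF (cyvcf2), GFF3 (pyranges), FASTA (pyfaidx) and the two design
tables into the internal model; classifies sites against gene models
(coding / intron / splice region, fourfold degeneracy); derives per
population allele counts; polarizes alleles against an ancestral proxy;
and provides the neutral-structure PCA sanity check on fourfold-degenerate
sites.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pyranges
from cyvcf2 import VCF
from pyfaidx import Fasta

from .model import MISSING, AlleleCounts, GeneModel, GenotypeTable, StudyDesign

log = logging.getLogger(__name__)

# cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN (missing), 3 HOM_ALT
_GT_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
STANDARD_CODE = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    return "".join(STANDARD_CODE.get(cds[i:i + 3].upper(), "X")
                   for i in range(0, len(cds) - len(cds) % 3, 3))


def is_fourfold_codon(codon: str) -> bool:
    """True iff every base at the third position encodes the same amino acid."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        return False
    aas = {STANDARD_CODE[codon[:2] + b] for b in "ACGT"}
    return len(aas) == 1


# ---------------------------------------------------------------------------
# design / environment tables


def read_design(path) -> StudyDesign:
    return StudyDesign.from_table(pd.read_csv(path, sep="\t", dtype=str))


def read_environment(path) -> pd.DataFrame:
    """Long-format table: population, covariate, value."""
    df = pd.read_csv(path, sep="\t")
    required = {"population", "covariate", "value"}
    if missing := required - set(df.columns):
        raise ValueError(f"environment table lacks columns: {sorted(missing)}")
    df["value"] = df["value"].astype(float)
    return df


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path,
    design: StudyDesign,
    max_missing: float = 0.2,
    require_pass: bool = True,
) -> GenotypeTable:
    """Load biallelic records into a GenotypeTable.

    Non-biallelic records are skipped (counted in the log); a site is dropped
    when the missing-genotype fraction within any population exceeds
    ``max_missing``. Individuals named in the design must all be present.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    wanted = design.individuals["individual"].tolist()
    absent = [s for s in wanted if s not in samples]
    if absent:
        raise ValueError(f"samples missing from VCF: {absent}")
    col_of = {s: i for i, s in enumerate(samples)}
    take = np.array([col_of[s] for s in wanted])

    pop_of = design.population_of()
    pops = list(dict.fromkeys(pop_of[s] for s in wanted))
    pop_rows = {p: np.array([i for i, s in enumerate(wanted) if pop_of[s] == p])
                for p in pops}

    rows = []
    dosage_cols = []
    n_skipped = n_filtered = n_missing_drop = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        if require_pass and rec.FILTER is not None:  # None == PASS/'.'
            n_filtered += 1
            continue
        dos = _GT_TO_DOSAGE[rec.gt_types][take]
        keep = True
        for p, idx in pop_rows.items():
            if np.mean(dos[idx] == MISSING) > max_missing:
                keep = False
                break
        if not keep:
            n_missing_drop += 1
            continue
        ref, alt = rec.REF, rec.ALT[0]
        rows.append((rec.CHROM, rec.POS, ref, alt,
                     "snp" if len(ref) == len(alt) else "indel"))
        dosage_cols.append(dos)
    if n_skipped or n_filtered or n_missing_drop:
        log.info("read_vcf: skipped %d non-biallelic, %d failing FILTER, "
                 "%d above per-population missingness %.2f",
                 n_skipped, n_filtered, n_missing_drop, max_missing)
    sites = pd.DataFrame(rows, columns=["scaffold", "pos", "ref", "alt", "variant_class"])
    dosages = (np.column_stack(dosage_cols).astype(np.int8)
               if dosage_cols else np.zeros((len(wanted), 0), np.int8))
    table = GenotypeTable(sites=sites, dosages=dosages, individuals=wanted)
    order = np.lexsort((sites["pos"].to_numpy(), sites["scaffold"].to_numpy()))
    if not np.array_equal(order, np.arange(len(sites))):
        table = table.subset_sites(order)
    return table


def write_vcf(table: GenotypeTable, path) -> None:
    """Emit a minimal VCF 4.2 (GT only) that read_vcf round-trips exactly."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for scaf in dict.fromkeys(table.sites["scaffold"]):
            sub = table.sites.loc[table.sites["scaffold"] == scaf]
            length = int(sub["pos"].max()) + 1000
            fh.write(f"##contig=<ID={scaf},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.individuals) + "\n")
        dos = table.dosages
        for j, row in enumerate(table.sites.itertuples(index=False)):
            gts = "\t".join(gt_str[int(d)] for d in dos[:, j])
            fh.write(f"{row.scaffold}\t{row.pos}\t.\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path) -> list[GeneModel]:
    """Gene models from GFF3; CDS grouped by gene via Parent chains."""
    df = pyranges.read_gff3(str(path), full=True).df
    df["Start"] = df["Start"] + 1  # back to 1-based inclusive
    genes: dict[str, GeneModel] = {}
    parent_gene: dict[str, str] = {}
    for row in df[df.Feature == "gene"].itertuples(index=False):
        genes[row.ID] = GeneModel(
            gene_id=row.ID, scaffold=str(row.Chromosome), strand=row.Strand,
            start=int(row.Start), end=int(row.End),
        )
        parent_gene[row.ID] = row.ID
    for row in df[df.Feature.isin(["mRNA", "transcript"])].itertuples(index=False):
        parent_gene[row.ID] = parent_gene.get(row.Parent, row.Parent)
    for row in df[df.Feature == "exon"].itertuples(index=False):
        gid = parent_gene.get(row.Parent)
        if gid in genes:
            genes[gid].exons.append((int(row.Start), int(row.End)))
    for row in df[df.Feature == "CDS"].itertuples(index=False):
        gid = parent_gene.get(row.Parent)
        if gid in genes:
            frame = row.Frame
            phase = int(frame) if str(frame) in {"0", "1", "2"} else 0
            genes[gid].cds.append((int(row.Start), int(row.End), phase))
    out = []
    for g in genes.values():
        g.exons.sort()
        g.cds.sort()
        if not g.exons and g.cds:
            g.exons = [(s, e) for s, e, _ in g.cds]
        if g.cds and g.cds_length() % 3 != 0:
            g.flagged = True
        out.append(g)
    out.sort(key=lambda g: (g.scaffold, g.start))
    return out


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.scaffold}\tconvergescan\tgene\t{g.start}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={g.gene_id}\n")
            tid = f"{g.gene_id}.t1"
            fh.write(f"{g.scaffold}\tconvergescan\tmRNA\t{g.start}\t{g.end}\t."
                     f"\t{g.strand}\t.\tID={tid};Parent={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(f"{g.scaffold}\tconvergescan\texon\t{s}\t{e}\t."
                         f"\t{g.strand}\t.\tID={tid}.e{i};Parent={tid}\n")
            for i, (s, e, ph) in enumerate(g.cds, 1):
                fh.write(f"{g.scaffold}\tconvergescan\tCDS\t{s}\t{e}\t."
                         f"\t{g.strand}\t{ph}\tID={tid}.c{i};Parent={tid}\n")


# ---------------------------------------------------------------------------
# site classification


def cds_coordinate_map(gene: GeneModel) -> np.ndarray:
    """Genomic positions of the CDS in translation order (strand-aware)."""
    positions = np.concatenate(
        [np.arange(s, e + 1) for s, e, _ in sorted(gene.cds)]
    ) if gene.cds else np.array([], dtype=int)
    if gene.strand == "-":
        positions = positions[::-1]
    return positions


def gene_cds_sequence(gene: GeneModel, fasta: Fasta) -> str:
    """Reference CDS in translation order (reverse-complemented on minus strand)."""
    chunks = [str(fasta[gene.scaffold][s - 1:e]) for s, e, _ in sorted(gene.cds)]
    seq = "".join(chunks)
    return revcomp(seq) if gene.strand == "-" else seq


def classify_sites(
    table: GenotypeTable, genes: list[GeneModel], fasta: Fasta | str
) -> pd.DataFrame:
    """Per-site class (intergenic/intron/cds/splice_region), codon context and
    fourfold-degeneracy flag, derived deterministically from GFF3 + FASTA.

    Genes whose CDS length is not divisible by 3 are flagged: their sites are
    classed ``cds`` but receive no degeneracy/codon calls.
    """
    if isinstance(fasta, str):
        fasta = Fasta(fasta)
    n = table.n_sites
    cls = np.full(n, "intergenic", dtype=object)
    gene_of = np.full(n, "", dtype=object)
    codon_pos = np.zeros(n, dtype=np.int8)     # 1..3 within codon, 0 = n/a
    fourfold = np.zeros(n, dtype=bool)
    cds_flagged = np.zeros(n, dtype=bool)

    pos = table.sites["pos"].to_numpy()
    scaf = table.sites["scaffold"].to_numpy()
    by_scaffold: dict[str, np.ndarray] = {
        s: np.flatnonzero(scaf == s) for s in dict.fromkeys(scaf)
    }
    for gene in genes:
        idx_all = by_scaffold.get(gene.scaffold)
        if idx_all is None:
            if gene.scaffold not in fasta:
                raise ValueError(f"scaffold {gene.scaffold} absent from FASTA")
            continue
        if gene.scaffold not in fasta:
            raise ValueError(f"scaffold {gene.scaffold} absent from FASTA")
        p = pos[idx_all]
        lo, hi = np.searchsorted(p, [gene.start, gene.end + 1])
        idx = idx_all[lo:hi]
        if len(idx) == 0:
            continue
        gp = pos[idx]
        gene_of[idx] = gene.gene_id
        inside = np.ones(len(idx), dtype=bool)
        cls[idx[inside]] = "intron"
        # splice regions: first/last 2 nt of each intron
        for istart, iend in gene.introns():
            don = (gp >= istart) & (gp <= min(istart + 1, iend))
            acc = (gp >= max(iend - 1, istart)) & (gp <= iend)
            cls[idx[don | acc]] = "splice_region"
        flagged = gene.flagged or not gene.cds
        coord = cds_coordinate_map(gene)
        cds_seq = gene_cds_sequence(gene, fasta) if gene.cds else ""
        if gene.cds:
            pos_to_cidx = {int(gpos): ci for ci, gpos in enumerate(coord)}
            for k, gpos in enumerate(gp):
                ci = pos_to_cidx.get(int(gpos))
                if ci is None:
                    continue
                cls[idx[k]] = "cds"
                if flagged:
                    cds_flagged[idx[k]] = True
                    continue
                within = ci % 3
                codon_pos[idx[k]] = within + 1
                if within == 2:
                    codon = cds_seq[ci - 2:ci + 1]
                    fourfold[idx[k]] = is_fourfold_codon(codon)
    return pd.DataFrame({
        "site_class": cls,
        "gene_id": gene_of,
        "codon_pos": codon_pos,
        "fourfold_degenerate": fourfold,
        "cds_flagged": cds_flagged,
    })


# ---------------------------------------------------------------------------
# allele counts and polarization


def allele_counts(table: GenotypeTable, design: StudyDesign) -> AlleleCounts:
    """Alt-allele count and called-allele total per population x site."""
    pop_of = design.population_of()
    pops = list(dict.fromkeys(pop_of[s] for s in table.individuals))
    alt = np.zeros((len(pops), table.n_sites), dtype=np.int64)
    called = np.zeros_like(alt)
    dos = table.dosages
    for pi, p in enumerate(pops):
        rows = np.array([i for i, s in enumerate(table.individuals) if pop_of[s] == p])
        sub = dos[rows]
        miss = sub == MISSING
        alt[pi] = np.where(miss, 0, sub).sum(axis=0)
        called[pi] = 2 * (~miss).sum(axis=0)
    return AlleleCounts(populations=pops, alt=alt, called=called)


def polarize(
    counts: AlleleCounts,
    table: GenotypeTable,
    ancestral_source: str = "reference_allele",
    ancestral_tag: pd.Series | None = None,
) -> AlleleCounts:
    """Attach derived-allele counts.

    With the default ``reference_allele`` source the (heterologous, outgroup
    like) reference allele is treated as ancestral, so derived == alt at every
    site. With ``ancestral_tag`` an explicit per-site ancestral allele series
    is honoured; sites whose tag matches neither allele are left unpolarized
    and excluded from derived-allele statistics.
    """
    n = counts.alt.shape[1]
    if ancestral_source == "reference_allele":
        anc_is_ref = np.ones(n, dtype=bool)
        polarized = np.ones(n, dtype=bool)
    elif ancestral_source == "ancestral_tag":
        if ancestral_tag is None:
            raise ValueError("ancestral_tag series required")
        tag = ancestral_tag.to_numpy()
        ref = table.sites["ref"].to_numpy()
        alt_a = table.sites["alt"].to_numpy()
        anc_is_ref = tag == ref
        polarized = anc_is_ref | (tag == alt_a)
    else:
        raise ValueError(f"unknown ancestral_source {ancestral_source!r}")
    derived = np.where(anc_is_ref[None, :], counts.alt, counts.called - counts.alt)
    return AlleleCounts(
        populations=list(counts.populations),
        alt=counts.alt, called=counts.called,
        derived=derived, polarized=polarized, ancestral_is_ref=anc_is_ref,
    )


# ---------------------------------------------------------------------------
# neutral-structure PCA


def neutral_structure_pca(
    table: GenotypeTable, classes: pd.DataFrame, design: StudyDesign,
    n_components: int = 4,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of per-individual alt-allele fractions at fourfold-degenerate SNPs.

    Returns (coordinates indexed by individual, variance-explained fractions).
    """
    mask = classes["fourfold_degenerate"].to_numpy() & table.is_snp()
    dos = table.dosages[:, mask].astype(float)
    dos[dos == MISSING] = np.nan
    frac = dos / 2.0
    poly = np.nanstd(frac, axis=0) > 0
    frac = frac[:, poly]
    if frac.shape[1] < 2 or frac.shape[0] < 3:
        raise ValueError("no neutral variation: need >=2 polymorphic "
                         "fourfold-degenerate sites and >=3 individuals")
    col_mean = np.nanmean(frac, axis=0)
    inds = np.where(np.isnan(frac))
    frac[inds] = col_mean[inds[1]]
    centred = frac - frac.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    k = min(n_components, len(s))
    coords = u[:, :k] * s[:k]
    var_explained = (s ** 2) / np.sum(s ** 2)
    df = pd.DataFrame(coords, index=table.individuals,
                      columns=[f"PC{i+1}" for i in range(k)])
    df["population"] = [design.population_of()[i] for i in table.individuals]
    return df, var_explained[:k]
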