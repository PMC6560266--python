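"""End-to-end orchestration: dataset loading, per-contrast scans,
environmental association and convergence testing.

The stages mirror how the analysis is run on real data: ingest VCF + GFF3 +
FASTA + design tables, window each M/NM contrast, compute the metric matrix,
call outliers at the genome-scan (99.9th) and divergence-scan (99.5th)
percentiles, screen for large-effect variants, run the Bayes-factor
environmental association over divergence-scan candidate genes, apply the
stringent filter chain, and finally intersect candidate lists within and
between species.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from . import convergence, eaa, stats, sweepscan, variantio, windows
from .model import AlleleCounts, GeneModel, GenotypeTable, StudyDesign


@dataclass
class ScanConfig:
    window_size: int = 25
    window_step: int | None = None
    scan_q: float = 0.999
    dscan_q: float = 0.995
    afd_min: float = 0.9
    bf_min: float = 100.0
    beta_max: float = 1.0
    max_missing: float = 0.2
    fst_method: str = "mean"
    dd_population: str = "M"
    include_sweed: bool = True
    include_varld: bool = True
    include_sfs2d: bool = True
    universe: str = "screened"   # or 'annotation'
    covariates: tuple[str, ...] = ("Cd", "Zn")


@dataclass
class Dataset:
    table: GenotypeTable
    design: StudyDesign
    genes: list[GeneModel]
    fasta_path: str
    env: pd.DataFrame | None = None
    counts: AlleleCounts | None = None
    classes: pd.DataFrame | None = None
    effects: pd.DataFrame | None = None

    def ensure_counts(self) -> AlleleCounts:
        if self.counts is None:
            counts = variantio.allele_counts(self.table, self.design)
            self.counts = variantio.polarize(counts, self.table)
        return self.counts

    def ensure_classes(self) -> pd.DataFrame:
        if self.classes is None:
            self.classes = variantio.classify_sites(
                self.table, self.genes, Fasta(self.fasta_path))
        return self.classes

    def ensure_effects(self) -> pd.DataFrame:
        if self.effects is None:
            self.effects = sweepscan.annotate_effects(
                self.table, self.genes, Fasta(self.fasta_path))
        return self.effects


def load_dataset(directory, config: ScanConfig | None = None,
                 vcf=None, gff3=None, fasta=None, design=None,
                 environment=None) -> Dataset:
    """Read a dataset directory (as written by simdata) or explicit paths."""
    config = config or ScanConfig()
    d = Path(directory) if directory is not None else None
    vcf = vcf or d / "variants.vcf"
    gff3 = gff3 or d / "annotation.gff3"
    fasta = fasta or d / "reference.fasta"
    design = design or d / "design.tsv"
    environment = environment or (d / "environment.tsv" if d else None)
    sd = variantio.read_design(design)
    table = variantio.read_vcf(vcf, sd, max_missing=config.max_missing)
    genes = variantio.read_gff3(gff3)
    env = variantio.read_environment(environment) \
        if environment and Path(environment).exists() else None
    return Dataset(table=table, design=sd, genes=genes,
                   fasta_path=str(fasta), env=env)


@dataclass
class ContrastResult:
    species: str
    pair: str
    pop_m: str
    pop_nm: str
    windows: pd.DataFrame
    members: np.ndarray
    stats: pd.DataFrame
    scan_calls: pd.DataFrame
    dscan_calls: pd.DataFrame
    scan_candidates: pd.DataFrame
    dscan_candidates: dict
    large_effect: dict
    assembled: pd.DataFrame

    @property
    def label(self) -> str:
        return f"{self.species}:{self.pair}"

    def scan_gene_set(self) -> set:
        return set(self.scan_candidates["gene_id"])

    def screened_genes(self, genes: list[GeneModel]) -> set:
        """Genes overlapped by at least one analysis window."""
        out = set()
        spans = self.windows.groupby("scaffold").agg(
            lo=("pos_first", "min"), hi=("pos_last", "max"))
        by_scaf: dict[str, list] = {}
        for g in genes:
            by_scaf.setdefault(g.scaffold, []).append(g)
        for scaf, grp in self.windows.groupby("scaffold"):
            starts = grp["pos_first"].to_numpy()
            ends = grp["pos_last"].to_numpy()
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            for g in by_scaf.get(scaf, []):
                i = np.searchsorted(starts, g.end, side="right")
                if i > 0 and np.any(ends[:i] >= g.start):
                    out.add(g.gene_id)
        return out


def run_contrast(ds: Dataset, species: str, pair: str,
                 config: ScanConfig | None = None) -> ContrastResult:
    """Window one M/NM contrast, compute all metrics, call candidates."""
    config = config or ScanConfig()
    counts = ds.ensure_counts()
    contrast = [c for c in ds.design.contrasts(species) if c[1] == pair]
    if not contrast:
        raise ValueError(f"no contrast {species}/{pair} in the design")
    _, _, pop_m, pop_nm = contrast[0]
    usable = windows.usable_snps(ds.table, counts, pop_m, pop_nm)
    win, members = windows.make_windows(
        ds.table, usable, size=config.window_size, step=config.window_step)
    stat = stats.compute_window_stats(
        ds.table, counts, win, members, usable, pop_m, pop_nm,
        design=ds.design, fst_method=config.fst_method,
        dd_population=config.dd_population,
        include_sweed=config.include_sweed,
        include_varld=config.include_varld,
        include_sfs2d=config.include_sfs2d,
    )
    scan_calls = sweepscan.empirical_outliers(stat, q=config.scan_q)
    dscan_calls = sweepscan.divergence_signatures(stat, q=config.dscan_q)
    label = f"{species}:{pair}"
    scan_map = sweepscan.genes_overlapping(scan_calls, win, ds.genes,
                                           contrast=label)
    dscan_map = sweepscan.divergence_scan_candidates(dscan_calls, win,
                                                     ds.genes, contrast=label)
    effects = ds.ensure_effects()
    le_map = sweepscan.large_effect_screen(
        effects, counts, ds.table, pop_m, pop_nm, contrast=label,
        afd_min=config.afd_min)
    assembled = sweepscan.assemble_candidates(scan_map, dscan_map, le_map,
                                              genes=ds.genes)
    scan_candidates = sweepscan.assemble_candidates(scan_map, genes=ds.genes)
    return ContrastResult(
        species=species, pair=pair, pop_m=pop_m, pop_nm=pop_nm,
        windows=win, members=members, stats=stat,
        scan_calls=scan_calls, dscan_calls=dscan_calls,
        scan_candidates=scan_candidates, dscan_candidates=dscan_map,
        large_effect=le_map, assembled=assembled,
    )


@dataclass
class EaaResult:
    species: str
    covariance: eaa.CovarianceModel
    associations: pd.DataFrame
    survivors: pd.DataFrame
    per_contrast_union: dict
    intersect: set


def run_eaa(ds: Dataset, species: str,
            dscan_results: dict[str, ContrastResult],
            config: ScanConfig | None = None) -> EaaResult:
    """Bayes-factor association over SNPs in divergence-scan candidate genes,
    then the stringent filter chain and the union/intersect bookkeeping."""
    config = config or ScanConfig()
    if ds.env is None:
        raise ValueError("dataset has no environment table")
    counts = ds.ensure_counts()
    classes = ds.ensure_classes()
    effects = ds.ensure_effects()
    pops_m, pops_nm = ds.design.m_nm_populations(species)
    sp_pops = pops_m + pops_nm
    sp_counts = AlleleCounts(
        populations=sp_pops,
        alt=np.stack([counts.alt[counts.pop_index(p)] for p in sp_pops]),
        called=np.stack([counts.called[counts.pop_index(p)] for p in sp_pops]),
    )
    neutral = np.flatnonzero(classes["fourfold_degenerate"].to_numpy()
                             & ds.table.is_snp())
    model = eaa.estimate_covariance(sp_counts, neutral)

    dscan_genes = set()
    for res in dscan_results.values():
        dscan_genes |= set(res.dscan_candidates)
    gene_of = effects.set_index("site")["gene_id"]
    snp_sites = np.flatnonzero(ds.table.is_snp())
    in_cand = np.array([gene_of.get(int(s), "") in dscan_genes
                        and gene_of.get(int(s), "") != "" for s in snp_sites])
    test_idx = snp_sites[in_cand]
    assoc = eaa.associate(sp_counts, test_idx, ds.env, list(config.covariates),
                          model, beta_max=config.beta_max)
    survivors = eaa.stringent_filter(assoc, effects, counts, ds.design,
                                     species, bf_min=config.bf_min)
    ea_genes: dict[tuple[str, str], set] = {}
    contrasts = ds.design.contrasts(species)
    f = counts.freq()
    for _, pair, pop_m, pop_nm in contrasts:
        pm = f[counts.pop_index(pop_m)]
        pnm = f[counts.pop_index(pop_nm)]
        for cov in config.covariates:
            sub = survivors[survivors["covariate"] == cov]
            genes = {row.gene_id for row in sub.itertuples(index=False)
                     if pm[row.site] > pnm[row.site]}
            ea_genes[(pair, cov)] = genes
    union, intersect = eaa.union_and_intersect(ea_genes)
    return EaaResult(species=species, covariance=model, associations=assoc,
                     survivors=survivors, per_contrast_union=union,
                     intersect=intersect)


@dataclass
class FullResult:
    contrasts: dict
    eaa: dict
    overlap_tests: pd.DataFrame
    venn: dict
    universe_size: int


def run_all(ds: Dataset, config: ScanConfig | None = None,
            species: list[str] | None = None) -> FullResult:
    """Scan every contrast, run per-species EAA, test all overlaps."""
    config = config or ScanConfig()
    species = species or ds.design.species_list()
    contrasts: dict[tuple[str, str], ContrastResult] = {}
    for sp in species:
        for _, pair, _, _ in ds.design.contrasts(sp):
            contrasts[(sp, pair)] = run_contrast(ds, sp, pair, config)
    eaa_results = {}
    if ds.env is not None:
        for sp in species:
            per_pair = {pair: res for (s, pair), res in contrasts.items()
                        if s == sp}
            try:
                eaa_results[sp] = run_eaa(ds, sp, per_pair, config)
            except ValueError:
                pass
    universe = candidate_universe(ds, contrasts, config)
    cand_sets = {key: res.scan_gene_set() for key, res in contrasts.items()}
    tests, venn = convergence.convergence_matrix(cand_sets, universe)
    n_universe = universe if isinstance(universe, int) else len(universe)
    return FullResult(contrasts=contrasts, eaa=eaa_results,
                      overlap_tests=tests, venn=venn,
                      universe_size=n_universe)


def candidate_universe(ds: Dataset, contrasts: dict,
                       config: ScanConfig) -> set | int:
    """Gene universe for overlap tests: genes screened by >= 1 window in
    every contrast (default), or the full annotation."""
    if config.universe == "annotation":
        return {g.gene_id for g in ds.genes}
    screened = None
    for res in contrasts.values():
        s = res.screened_genes(ds.genes)
        screened = s if screened is None else (screened & s)
    # candidate genes always belong to the universe they were drawn from
    for res in contrasts.values():
        screened |= res.scan_gene_set()
    return screened or set()
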