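"""Core in-memory containers shared by every analysis stage.

Coordinates are 1-based inclusive throughout (the native convention of VCF
and GFF3); genotype dosages are diploid allele counts in {0, 1, 2} with -1
marking a missing call.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeTable:
    """Individuals x sites allele-dosage matrix with site metadata.

    sites columns: scaffold, pos, ref, alt, variant_class ('snp'|'indel').
    dosages: int8 array (n_individuals, n_sites), entries {0,1,2,-1}.
    """

    sites: pd.DataFrame
    dosages: np.ndarray
    individuals: list[str]
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.individuals), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.sites)} sites"
            )

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def is_snp(self) -> np.ndarray:
        return (self.sites["variant_class"] == "snp").to_numpy()

    def subset_sites(self, mask_or_idx: np.ndarray) -> "GenotypeTable":
        arr = np.asarray(mask_or_idx)
        idx = np.flatnonzero(arr) if arr.dtype == bool else arr
        return GenotypeTable(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
            individuals=list(self.individuals),
        )


@dataclass
class StudyDesign:
    """Individual -> population and population -> (site, soil class, species, pair)."""

    individuals: pd.DataFrame  # columns: individual, population
    populations: pd.DataFrame  # columns: population, site, soil_class, species, pair

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "StudyDesign":
        required = {"individual", "population", "site", "soil_class", "species", "pair"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"design table lacks columns: {sorted(missing)}")
        if df["individual"].duplicated().any():
            dups = df.loc[df["individual"].duplicated(), "individual"].tolist()
            raise ValueError(f"individuals mapped to more than one population: {dups}")
        pops = (
            df[["population", "site", "soil_class", "species", "pair"]]
            .drop_duplicates("population")
            .reset_index(drop=True)
        )
        bad = pops[~pops["soil_class"].isin(["M", "NM"])]
        if len(bad):
            raise ValueError(f"soil_class must be M or NM, got {bad['soil_class'].tolist()}")
        # contrast pairing (one M + one NM per species/pair) is validated
        # lazily in contrasts(): counting-only designs need no pairs
        return cls(individuals=df[["individual", "population"]].copy(),
                   populations=pops)

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.individuals["individual"], self.individuals["population"]))

    def members(self, population: str) -> list[str]:
        sel = self.individuals["population"] == population
        return self.individuals.loc[sel, "individual"].tolist()

    def species_list(self) -> list[str]:
        return list(dict.fromkeys(self.populations["species"]))

    def contrasts(self, species: str | None = None) -> list[tuple[str, str, str, str]]:
        """(species, pair, M population, NM population) for every contrast."""
        out = []
        pops = self.populations
        for (sp, pair), grp in pops.groupby(["species", "pair"], sort=False):
            m = grp.loc[grp["soil_class"] == "M", "population"].tolist()
            nm = grp.loc[grp["soil_class"] == "NM", "population"].tolist()
            if len(m) != 1 or len(nm) != 1:
                raise ValueError(
                    f"contrast {sp}/{pair} must pair exactly one M with one NM "
                    f"population (got M={m}, NM={nm})"
                )
            out.append((sp, pair, m[0], nm[0]))
        if species is not None:
            out = [c for c in out if c[0] == species]
        return out

    def m_nm_populations(self, species: str) -> tuple[list[str], list[str]]:
        rows = self.populations[self.populations["species"] == species]
        return (
            rows.loc[rows["soil_class"] == "M", "population"].tolist(),
            rows.loc[rows["soil_class"] == "NM", "population"].tolist(),
        )


@dataclass
class AlleleCounts:
    """Per population x site alt-allele counts and called-allele totals."""

    populations: list[str]
    alt: np.ndarray       # (P, S) int
    called: np.ndarray    # (P, S) int, even
    derived: np.ndarray | None = None   # (P, S) after polarize()
    polarized: np.ndarray | None = None  # (S,) bool
    ancestral_is_ref: np.ndarray | None = None  # (S,) bool

    def pop_index(self, population: str) -> int:
        return self.populations.index(population)

    def freq(self) -> np.ndarray:
        """Alt-allele frequency, NaN where no alleles were called."""
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.called > 0, self.alt / np.maximum(self.called, 1), np.nan)

    def derived_freq(self) -> np.ndarray:
        if self.derived is None:
            raise ValueError("counts are not polarized; call variantio.polarize first")
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(self.called > 0, self.derived / np.maximum(self.called, 1), np.nan)
        return np.where(self.polarized[None, :], f, np.nan)


@dataclass
class GeneModel:
    """One gene: span, strand, exons and CDS segments (1-based inclusive)."""

    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)
    flagged: bool = False  # CDS length not divisible by 3 etc.

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, genomic order."""
        ex = sorted(self.exons)
        return [(ex[i][1] + 1, ex[i + 1][0] - 1) for i in range(len(ex) - 1)
                if ex[i + 1][0] - ex[i][1] > 1]


EFFECT_IMPACT = {
    "stop_gained": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "frameshift": "HIGH",
    "splice_donor": "HIGH",
    "splice_acceptor": "HIGH",
    "missense": "MODERATE",
    "inframe_indel": "MODERATE",
    "synonymous": "LOW",
    "non_coding": "MODIFIER",
}

NONSYNONYMOUS_EFFECTS = frozenset({"missense", "stop_gained", "stop_lost", "start_lost"})
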