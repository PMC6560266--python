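"""Synthetic datasets with planted truth for every analysis stage.

The generator emulates the statistical structure the scan assumes: two
M/NM population pairs per species, neutral Balding-Nichols drift with
distinct structure per pair, selective sweeps (lowered diversity, elevated
differentiation, high-frequency derived excess) over designated genes,
large-effect variants at extreme allele-frequency differences, planted
environmentally associated coding SNPs, and >= 10-fold M/NM contrasts in
soil Zn and Cd. Frequency-level simulation (rather than a coalescent) gives
direct control over exactly the quantities each metric measures; linkage
inside sweep regions is induced by comonotone genotype draws over blocks of
adjacent SNPs.

Everything is emitted as plain files (VCF / GFF3 / FASTA / design TSV /
environment TSV / truth JSON+BED) that round-trip through the variantio
readers; outputs are byte-identical for a given seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import GeneModel
from .variantio import revcomp, write_gff3, STANDARD_CODE

_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP = sorted(set(STANDARD_CODE) - _STOPS)
_BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SweepSpec:
    name: str
    species: str
    pairs: tuple[str, ...]          # affected pairs; the M population sweeps
    reduction: float = 0.3          # fraction of sweep sites kept polymorphic
    push_mean: float = 0.95         # mean post-sweep alt frequency
    push_conc: float = 60.0
    flank: int = 2000               # bp of hitchhiking signal past the gene


@dataclass
class LargeEffectSpec:
    name: str
    species: str
    pair: str
    kind: str = "snp"               # 'snp' (stop gain) or 'indel' (frameshift)
    alt_count_m: int = 16           # of 2*n_individuals alleles in the M pop
    alt_count_nm: int = 0
    in_sweep_gene: str | None = None  # plant inside this sweep's gene


@dataclass
class EaSnpSpec:
    name: str
    species: str
    effect: str = "missense"        # or 'synonymous'
    pattern: str = "m_elevated"     # or 'nm_elevated'
    in_sweep_gene: str | None = None
    alt_count_high: int = 15
    alt_count_low: int = 1


@dataclass
class SimulationConfig:
    seed: int = 0
    species: tuple[str, ...] = ("halleri",)
    pairs: dict = field(default_factory=lambda: {
        "pair1": ("Mias", "Zapa"), "pair2": ("Klet", "Kowa")})
    n_individuals: int = 8
    n_snps: int = 20000             # across the variant scaffolds
    n_variant_scaffolds: int = 2
    n_genes: int = 400              # genes on variant scaffolds
    n_desert_genes: int = 0         # annotation padding on a variant-free scaffold
    c_pair: float = 0.1             # Balding-Nichols drift within a pair
    c_between: float = 0.2          # drift of pair ancestors from the root
    gap_range: tuple[int, int] = (800, 2000)  # intergenic gap between genes
    missing_rate: float = 0.02
    indel_rate: float = 0.01        # intergenic deletions among random sites
    ld_block: int = 25              # comonotone block length inside sweeps
    sweeps: list = field(default_factory=list)
    large_effects: list = field(default_factory=list)
    ea_snps: list = field(default_factory=list)
    covariates: dict = field(default_factory=lambda: {
        "Zn": {"pair1": 150.0, "pair2": 120.0},
        "Cd": {"pair1": 2.0, "pair2": 1.6}})
    env_ratio: float = 10.0         # exact M/NM covariate ratio


def config_from_yaml(path) -> SimulationConfig:
    """SimulationConfig from a YAML file; nested sweep / large-effect /
    EA-SNP specs are given as lists of mappings."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw["sweeps"] = [SweepSpec(**d) for d in raw.get("sweeps", [])]
    raw["large_effects"] = [LargeEffectSpec(**d)
                            for d in raw.get("large_effects", [])]
    raw["ea_snps"] = [EaSnpSpec(**d) for d in raw.get("ea_snps", [])]
    for spec in raw["sweeps"]:
        spec.pairs = tuple(spec.pairs)
    if "species" in raw:
        raw["species"] = tuple(raw["species"])
    if "gap_range" in raw:
        raw["gap_range"] = tuple(raw["gap_range"])
    return SimulationConfig(**raw)


@dataclass
class SimTruth:
    sweeps: list                    # dicts: name, species, gene, scaffold, start, end, pairs
    convergent_genes: dict          # species -> [gene ids swept in both pairs]
    ea_snps: list
    large_effects: list

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


@dataclass
class SimResult:
    paths: dict
    truth: SimTruth
    genes: list


# ---------------------------------------------------------------------------
# gene construction


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP), n))


def _build_gene(rng: np.random.Generator, gene_id: str, scaffold: str,
                strand: str, n_codons: int, n_exons: int):
    """Gene with a translatable CDS split over exons; returns
    (local genomic sequence, GeneModel with block-local 1-based coords)."""
    cds = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
    # exon cut points (mRNA sense), each exon >= 30 nt
    if n_exons > 1:
        cuts = sorted(rng.choice(
            np.arange(30, len(cds) - 30, 3), size=n_exons - 1, replace=False))
    else:
        cuts = []
    bounds = [0, *cuts, len(cds)]
    exon_seqs = [cds[bounds[i]:bounds[i + 1]] for i in range(n_exons)]
    intron_seqs = ["GT" + _random_codons(rng, max(1, int(rng.integers(20, 60)))) + "AG"
                   for _ in range(n_exons - 1)]
    parts, exons_local = [], []
    cursor = 0
    for i, ex in enumerate(exon_seqs):
        parts.append(ex)
        exons_local.append((cursor + 1, cursor + len(ex)))
        cursor += len(ex)
        if i < len(intron_seqs):
            parts.append(intron_seqs[i])
            cursor += len(intron_seqs[i])
    local_seq = "".join(parts)
    L = len(local_seq)
    if strand == "-":
        local_seq = revcomp(local_seq)
        exons_local = sorted((L - e + 1, L - s + 1) for s, e in exons_local)
    # phases in transcription order
    tx_order = exons_local if strand == "+" else exons_local[::-1]
    cds_local, cum = [], 0
    for s, e in tx_order:
        cds_local.append((s, e, (3 - cum % 3) % 3))
        cum += e - s + 1
    gene = GeneModel(gene_id=gene_id, scaffold=scaffold, strand=strand,
                     start=1, end=L, exons=sorted(exons_local),
                     cds=sorted(cds_local))
    return local_seq, gene


def _shift(gene: GeneModel, offset: int) -> GeneModel:
    gene.start += offset
    gene.end += offset
    gene.exons = [(s + offset, e + offset) for s, e in gene.exons]
    gene.cds = [(s + offset, e + offset, p) for s, e, p in gene.cds]
    return gene


# ---------------------------------------------------------------------------
# planting helpers


def _cds_positions(gene: GeneModel) -> np.ndarray:
    pos = np.concatenate([np.arange(s, e + 1) for s, e, _ in sorted(gene.cds)])
    return pos[::-1] if gene.strand == "-" else pos


def _find_codon_site(gene: GeneModel, seq: bytearray, want: str,
                     rng: np.random.Generator):
    """Genomic (pos, ref, alt) of a substitution creating the wanted effect."""
    coord = _cds_positions(gene)
    cds_seq = "".join(chr(seq[p - 1]) for p in coord)
    if gene.strand == "-":
        cds_seq = "".join(revcomp(chr(seq[p - 1])) for p in coord)
    n_codons = len(coord) // 3
    order = rng.permutation(np.arange(1, n_codons - 1))  # skip start & stop
    for ci in order:
        codon = cds_seq[3 * ci:3 * ci + 3]
        aa = STANDARD_CODE[codon]
        for within in (2, 0, 1):
            for b in "ACGT":
                if b == codon[within]:
                    continue
                alt_codon = codon[:within] + b + codon[within + 1:]
                alt_aa = STANDARD_CODE[alt_codon]
                hit = (
                    (want == "stop_gained" and alt_aa == "*" and aa != "*") or
                    (want == "missense" and alt_aa not in ("*", aa)) or
                    (want == "synonymous" and alt_aa == aa)
                )
                if hit:
                    gpos = int(coord[3 * ci + within])
                    ref = chr(seq[gpos - 1])
                    alt = b if gene.strand == "+" else revcomp(b)
                    return gpos, ref, alt
    raise RuntimeError(f"no {want} site available in {gene.gene_id}")


def _find_frameshift_site(gene: GeneModel, seq: bytearray):
    """A 2-bp deletion safely inside the longest CDS exon."""
    s, e, _ = max(gene.cds, key=lambda t: t[1] - t[0])
    mid = (s + e) // 2
    ref = "".join(chr(seq[p - 1]) for p in range(mid, mid + 3))
    return mid, ref, ref[0]


def _dosage_pattern(alt_count: int, n_ind: int) -> np.ndarray:
    """Deterministic diploid dosages realizing an exact alt-allele count."""
    if not 0 <= alt_count <= 2 * n_ind:
        raise ValueError("alt_count out of range")
    d = np.zeros(n_ind, dtype=np.int8)
    d[:alt_count // 2] = 2
    if alt_count % 2:
        d[alt_count // 2] = 1
    return d


# ---------------------------------------------------------------------------
# the generator


def _balding_nichols(rng, p: np.ndarray, c: float) -> np.ndarray:
    a = p * (1 - c) / c
    b = (1 - p) * (1 - c) / c
    out = rng.beta(np.maximum(a, 1e-3), np.maximum(b, 1e-3))
    return np.clip(out, 1e-4, 1 - 1e-4)


def _binom2_quantile(u: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Inverse CDF of Binomial(2, p) — shared-u draws are comonotone."""
    q0 = (1 - p) ** 2
    q1 = q0 + 2 * p * (1 - p)
    return ((u >= q0).astype(np.int8) + (u >= q1).astype(np.int8))


def simulate_dataset(config: SimulationConfig, out_dir) -> SimResult:
    """Build the genome, plant the truth, draw genotypes, write all files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # ---- genome layout -----------------------------------------------------
    scaffold_names = [f"scaffold_{i+1}" for i in range(config.n_variant_scaffolds)]
    special: dict[str, dict] = {}   # sweep name -> {"scaffold": .., ordinal slot}
    per_scaffold = config.n_genes // config.n_variant_scaffolds
    sweep_names = [sw.name for sw in config.sweeps]
    # distribute sweep genes across scaffolds at interior slots
    slot_plan: dict[str, list] = {s: [None] * per_scaffold for s in scaffold_names}
    for si, name in enumerate(sweep_names):
        scaf = scaffold_names[si % len(scaffold_names)]
        slot = int(per_scaffold * (0.25 + 0.5 * ((si // len(scaffold_names)) + 1)
                                   / (len(sweep_names) + 1)))
        slot = min(max(slot, 1), per_scaffold - 2)
        while slot_plan[scaf][slot] is not None:
            slot += 2
        slot_plan[scaf][slot] = name

    genes: list[GeneModel] = []
    gene_by_name: dict[str, GeneModel] = {}
    sequences: dict[str, bytearray] = {}
    gid = 0
    max_flank = max([sw.flank for sw in config.sweeps], default=0)
    for scaf in scaffold_names:
        chunks: list[bytes] = []
        cursor = 0
        for slot, sweep_name in enumerate(slot_plan[scaf]):
            isolated = sweep_name is not None
            gap = int(rng.integers(*config.gap_range)) \
                + (max_flank + 2000 if isolated else 0)
            chunks.append(_BASES[rng.integers(0, 4, gap)].tobytes())
            cursor += gap
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            # sweep-target genes are long, so that a good share of the
            # sweep's outlier windows genomically overlap the gene itself
            if isolated:
                n_codons = int(rng.integers(500, 700))
                n_exons = int(rng.integers(4, 7))
            else:
                n_codons = int(rng.integers(100, 260))
                n_exons = int(rng.integers(1, 5))
            local_seq, gene = _build_gene(
                rng, f"gene{gid:05d}", scaf, strand, n_codons, n_exons)
            _shift(gene, cursor)
            chunks.append(local_seq.encode())
            cursor += gene.end - gene.start + 1
            genes.append(gene)
            if isolated:
                gene_by_name[sweep_name] = gene
                tail = _BASES[rng.integers(0, 4, max_flank + 2000)].tobytes()
                chunks.append(tail)
                cursor += len(tail)
        chunks.append(
            _BASES[rng.integers(0, 4, int(rng.integers(*config.gap_range)))].tobytes())
        sequences[scaf] = bytearray(b"".join(chunks))

    if config.n_desert_genes:
        scaf = "scaffold_pad"
        chunks, cursor = [], 0
        for _ in range(config.n_desert_genes):
            gap = 40
            chunks.append(_BASES[rng.integers(0, 4, gap)].tobytes())
            cursor += gap
            gid += 1
            L = 300
            start, end = cursor + 1, cursor + L
            genes.append(GeneModel(
                gene_id=f"gene{gid:05d}", scaffold=scaf, strand="+",
                start=start, end=end, exons=[(start, end)],
                cds=[(start, end, 0)]))
            chunks.append(_BASES[rng.integers(0, 4, L)].tobytes())
            cursor += L
        sequences[scaf] = bytearray(b"".join(chunks))

    # ---- site placement ----------------------------------------------------
    planted: list[dict] = []   # scaffold,pos,ref,alt,kind,meta
    truth_sweeps, truth_ea, truth_le = [], [], []
    convergent: dict[str, list] = {sp: [] for sp in config.species}
    for sw in config.sweeps:
        g = gene_by_name[sw.name]
        truth_sweeps.append({
            "name": sw.name, "species": sw.species, "gene": g.gene_id,
            "scaffold": g.scaffold, "start": max(1, g.start - sw.flank),
            "end": g.end + sw.flank, "pairs": list(sw.pairs)})
        if len(sw.pairs) == len(config.pairs):
            convergent[sw.species].append(g.gene_id)
    for spec in config.ea_snps:
        g = gene_by_name[spec.in_sweep_gene]
        seq = sequences[g.scaffold]
        pos, ref, alt = _find_codon_site(g, seq, spec.effect, rng)
        planted.append({"scaffold": g.scaffold, "pos": pos, "ref": ref,
                        "alt": alt, "kind": "ea", "spec": spec, "gene": g.gene_id})
        truth_ea.append({"name": spec.name, "species": spec.species,
                         "gene": g.gene_id, "scaffold": g.scaffold, "pos": pos,
                         "effect": spec.effect, "pattern": spec.pattern})
    for spec in config.large_effects:
        if spec.in_sweep_gene is not None:
            g = gene_by_name[spec.in_sweep_gene]
        else:
            pool = [x for x in genes if x.scaffold in scaffold_names
                    and x.gene_id not in {t["gene"] for t in truth_sweeps}]
            g = pool[int(rng.integers(0, len(pool)))]
        seq = sequences[g.scaffold]
        if spec.kind == "snp":
            pos, ref, alt = _find_codon_site(g, seq, "stop_gained", rng)
        else:
            pos, ref, alt = _find_frameshift_site(g, seq)
        planted.append({"scaffold": g.scaffold, "pos": pos, "ref": ref,
                        "alt": alt, "kind": "le", "spec": spec, "gene": g.gene_id})
        n2 = 2 * config.n_individuals
        truth_le.append({"name": spec.name, "species": spec.species,
                         "pair": spec.pair, "gene": g.gene_id,
                         "scaffold": g.scaffold, "pos": pos, "kind": spec.kind,
                         "afd": abs(spec.alt_count_m - spec.alt_count_nm) / n2})

    planted_pos = {(p["scaffold"], p["pos"]) for p in planted}
    # avoid random sites inside any planted ref span (indels occupy several bp)
    blocked: dict[str, set] = {s: set() for s in scaffold_names}
    for p in planted:
        for q in range(p["pos"], p["pos"] + len(p["ref"])):
            blocked[p["scaffold"]].add(q)

    site_rows = []   # (scaffold, pos, ref, alt, kind, meta)
    gene_bounds = {}
    for scaf in scaffold_names:
        spans = [(g.start, g.end) for g in genes if g.scaffold == scaf]
        spans.sort()
        gene_bounds[scaf] = (np.array([s for s, _ in spans]),
                             np.array([e for _, e in spans]))
    per_scaf_snps = config.n_snps // config.n_variant_scaffolds
    for scaf in scaffold_names:
        L = len(sequences[scaf])
        pos = rng.choice(np.arange(10, L - 10), size=per_scaf_snps, replace=False)
        pos = np.sort(pos)
        starts, ends = gene_bounds[scaf]
        seq = sequences[scaf]
        for p in pos:
            p = int(p)
            if p in blocked[scaf]:
                continue
            ref = chr(seq[p - 1])
            if ref not in "ACGT":
                continue
            j = np.searchsorted(starts, p, side="right") - 1
            genic = j >= 0 and p <= ends[j]
            if not genic and rng.random() < config.indel_rate:
                d = int(rng.integers(1, 3))
                ref_full = "".join(chr(seq[q - 1]) for q in range(p, p + d + 1))
                if any(q in blocked[scaf] for q in range(p, p + d + 1)):
                    continue
                site_rows.append((scaf, p, ref_full, ref_full[0], "bg", None))
            else:
                alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
                site_rows.append((scaf, p, ref, alt, "bg", None))
    for p in planted:
        site_rows.append((p["scaffold"], p["pos"], p["ref"], p["alt"],
                          p["kind"], p))
    site_rows.sort(key=lambda r: (r[0], r[1]))
    S = len(site_rows)
    scafs = np.array([r[0] for r in site_rows])
    positions = np.array([r[1] for r in site_rows])

    # ---- populations, frequencies, genotypes -------------------------------
    pair_names = list(config.pairs)
    pop_meta = []   # (population, site, soil_class, species, pair)
    for sp in config.species:
        for pair in pair_names:
            m_site, nm_site = config.pairs[pair]
            pop_meta.append((f"{sp}_{m_site}", m_site, "M", sp, pair))
            pop_meta.append((f"{sp}_{nm_site}", nm_site, "NM", sp, pair))
    n_ind = config.n_individuals
    individuals, ind_pop = [], []
    for pop, *_ in pop_meta:
        for k in range(n_ind):
            individuals.append(f"{pop}_{k+1:02d}")
            ind_pop.append(pop)

    dosages = np.zeros((len(individuals), S), dtype=np.int8)
    pop_rows = {}
    row = 0
    for pop, *_ in pop_meta:
        pop_rows[pop] = np.arange(row, row + n_ind)
        row += n_ind

    planted_cols = {}
    for j, r in enumerate(site_rows):
        if r[4] in ("ea", "le"):
            planted_cols[j] = r[5]

    for sp in config.species:
        p0 = rng.uniform(0.05, 0.95, S)
        freqs = {}
        for pair in pair_names:
            anc = _balding_nichols(rng, p0, config.c_between)
            m_site, nm_site = config.pairs[pair]
            freqs[f"{sp}_{m_site}"] = _balding_nichols(rng, anc, config.c_pair)
            freqs[f"{sp}_{nm_site}"] = _balding_nichols(rng, anc, config.c_pair)
        # sweeps distort the affected M population's frequencies
        sweep_cols: dict[str, np.ndarray] = {}
        for sw, tr in zip(config.sweeps, truth_sweeps):
            if sw.species != sp:
                continue
            mask = (scafs == tr["scaffold"]) & (positions >= tr["start"]) \
                & (positions <= tr["end"])
            cols = np.flatnonzero(mask)
            for pair in sw.pairs:
                m_site = config.pairs[pair][0]
                pop = f"{sp}_{m_site}"
                keep = rng.random(len(cols)) < sw.reduction
                pushed = rng.beta(sw.push_mean * sw.push_conc,
                                  (1 - sw.push_mean) * sw.push_conc, len(cols))
                freqs[pop][cols] = np.where(keep, np.clip(pushed, 1e-4, 1 - 1e-4),
                                            1.0)
                sweep_cols.setdefault(pop, np.zeros(S, bool))[cols] = True
        # genotypes
        for pop, *_ in pop_meta:
            if not pop.startswith(f"{sp}_"):
                continue
            rows = pop_rows[pop]
            u = rng.random((n_ind, S))
            if pop in sweep_cols:
                cols = np.flatnonzero(sweep_cols[pop])
                for b0 in range(0, len(cols), config.ld_block):
                    block = cols[b0:b0 + config.ld_block]
                    u[:, block] = u[:, block[0]][:, None]
            dosages[rows] = _binom2_quantile(u, freqs[pop][None, :])
        # planted deterministic columns
        for j, meta in planted_cols.items():
            spec = meta["spec"]
            if spec.species != sp:
                continue
            if meta["kind"] == "ea":
                hi, lo = spec.alt_count_high, spec.alt_count_low
                if spec.pattern == "nm_elevated":
                    hi, lo = lo, hi
                for pop, _site, soil, psp, _pair in pop_meta:
                    if psp != sp:
                        continue
                    cnt = hi if soil == "M" else lo
                    dosages[pop_rows[pop], j] = _dosage_pattern(cnt, n_ind)
            else:
                for pop, _site, soil, psp, pair in pop_meta:
                    if psp != sp:
                        continue
                    if pair == spec.pair:
                        cnt = spec.alt_count_m if soil == "M" else spec.alt_count_nm
                    else:
                        cnt = min(spec.alt_count_nm + 1, 2 * n_ind)
                    dosages[pop_rows[pop], j] = _dosage_pattern(cnt, n_ind)

    # missingness (never on planted columns)
    miss = rng.random(dosages.shape) < config.missing_rate
    miss[:, list(planted_cols)] = False
    dosages[miss] = -1

    # ---- write files -------------------------------------------------------
    paths = {}
    fasta_path = out / "reference.fasta"
    with open(fasta_path, "w") as fh:
        for scaf, seq in sequences.items():
            fh.write(f">{scaf}\n")
            s = seq.decode()
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")
    paths["fasta"] = fasta_path

    gff_path = out / "annotation.gff3"
    write_gff3(genes, gff_path)
    paths["gff3"] = gff_path

    vcf_path = out / "variants.vcf"
    gt_lookup = np.array(["./.", "0/0", "0/1", "1/1"])
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for scaf, seq in sequences.items():
            fh.write(f"##contig=<ID={scaf},length={len(seq)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(individuals) + "\n")
        gt_idx = dosages + 1
        for j, (scaf, pos, ref, alt, _kind, _meta) in enumerate(site_rows):
            gts = "\t".join(gt_lookup[gt_idx[:, j]])
            fh.write(f"{scaf}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
    paths["vcf"] = vcf_path

    design_path = out / "design.tsv"
    with open(design_path, "w") as fh:
        fh.write("individual\tpopulation\tsite\tsoil_class\tspecies\tpair\n")
        for ind, pop in zip(individuals, ind_pop):
            meta = next(m for m in pop_meta if m[0] == pop)
            fh.write(f"{ind}\t{pop}\t{meta[1]}\t{meta[2]}\t{meta[3]}\t{meta[4]}\n")
    paths["design"] = design_path

    env_path = out / "environment.tsv"
    with open(env_path, "w") as fh:
        fh.write("population\tcovariate\tvalue\n")
        for cov, bases in config.covariates.items():
            for pop, _site, soil, _sp, pair in pop_meta:
                base = bases[pair]
                value = base * config.env_ratio if soil == "M" else base
                fh.write(f"{pop}\t{cov}\t{value:.6g}\n")
    paths["environment"] = env_path

    truth = SimTruth(sweeps=truth_sweeps, convergent_genes=convergent,
                     ea_snps=truth_ea, large_effects=truth_le)
    truth_path = out / "truth.json"
    truth_path.write_text(truth.to_json())
    paths["truth"] = truth_path
    bed_path = out / "truth_sweeps.bed"
    with open(bed_path, "w") as fh:
        for t in truth_sweeps:
            fh.write(f"{t['scaffold']}\t{t['start'] - 1}\t{t['end']}"
                     f"\t{t['name']}\n")
    paths["truth_bed"] = bed_path
    return SimResult(paths=paths, truth=truth, genes=genes)


# ---------------------------------------------------------------------------
# the standard convergent fixture


def make_convergent_fixture(
    out_dir,
    seed: int = 0,
    n_snps: int = 100000,
    n_genes: int = 1200,
    n_desert_genes: int = 28800,
    include_second_species: bool = True,
    reduction: float = 0.3,
) -> SimResult:
    """Dataset with one gene swept in both pairs of the first species, one
    gene swept in each single pair, a planted environmentally associated
    missense SNP chain in the convergent gene (plus a synonymous and an
    NM-elevated decoy), and a large-effect frameshift indel at allele
    frequency difference 0.875 in the second pair — the full evidence chain
    the pipeline is meant to recover."""
    species = ("halleri", "arenosa") if include_second_species else ("halleri",)
    sp = species[0]
    sweeps = [
        SweepSpec(name="conv", species=sp, pairs=("pair1", "pair2"),
                  reduction=reduction, flank=1000),
        SweepSpec(name="only1", species=sp, pairs=("pair1",),
                  reduction=reduction, flank=1000),
        SweepSpec(name="only2", species=sp, pairs=("pair2",),
                  reduction=reduction, flank=1000),
    ]
    ea_snps = [
        EaSnpSpec(name="ea_missense", species=sp, effect="missense",
                  pattern="m_elevated", in_sweep_gene="conv"),
        EaSnpSpec(name="ea_synonymous_decoy", species=sp, effect="synonymous",
                  pattern="m_elevated", in_sweep_gene="conv"),
        EaSnpSpec(name="ea_nm_decoy", species=sp, effect="missense",
                  pattern="nm_elevated", in_sweep_gene="conv"),
    ]
    large_effects = [
        LargeEffectSpec(name="stop_pair1", species=sp, pair="pair1",
                        kind="snp", alt_count_m=16, alt_count_nm=0,
                        in_sweep_gene="only1"),
        LargeEffectSpec(name="indel_pair2", species=sp, pair="pair2",
                        kind="indel", alt_count_m=14, alt_count_nm=0,
                        in_sweep_gene="conv"),
    ]
    config = SimulationConfig(
        seed=seed, species=species, n_snps=n_snps, n_genes=n_genes,
        n_desert_genes=n_desert_genes, gap_range=(5000, 7000),
        sweeps=sweeps, ea_snps=ea_snps, large_effects=large_effects,
    )
    return simulate_dataset(config, out_dir)
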