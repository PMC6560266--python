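# Methods

This note documents the statistical procedures implemented in
`convergescan`, their assumptions and defaults, what the synthetic-data
generator does and does not emulate, and the design choices made where the
design was genuinely open.

## Study design and data model

The unit of analysis is an M/NM *contrast*: one metallicolous (M) and one
non-metalliferous (NM) population of the same species from a geographically
proximal site pair. A design table maps individuals to populations and
populations to (site, soil class, species, pair); each species contributes
two contrasts, and the same four sites may host two species. Genotypes are
diploid allele dosages in {0, 1, 2, missing} at biallelic SNPs and short
indels read from VCF (FILTER = PASS, per-population missingness ≤ 0.2 by
default; both configurable). Coordinates are 1-based inclusive throughout,
matching VCF and GFF3; no half-open conversion layer exists. Indels enter
effect annotation and the allele-frequency-difference screen but never the
site-frequency-spectrum statistics or windows.

Alleles are polarized against the reference allele as an ancestral proxy by
default — appropriate when reads from both species are mapped to a
heterologous congener reference, which acts as an outgroup — or against an
explicit per-site ancestral tag; sites whose tag matches neither allele are
excluded from derived-allele statistics.

## Windows

Each contrast's usable SNPs — biallelic, called in both populations, and
polymorphic within the union of the pair (monomorphic-in-pair sites carry
no pairwise signal; configurable) — are tiled into non-overlapping windows
of 25 consecutive SNPs per scaffold, trailing remainders dropped. SNP-count
windows hold the per-window sampling variance constant where base-pair
windows would not. The step is configurable for overlapping scans.

## Per-window statistics

Per-site diversity is the unbiased estimator π = 2i(n−i)/(n(n−1)) with i
the alt count of n called alleles. Window π is the mean over member sites;
θ_W = S/(a₁·size) with S the segregating-site count and a₁ the harmonic
number at the window-mean called-allele number n̄ (rounded; missing data
makes the exact n site-specific, and the mean-n evaluation is the
documented approximation, exact for complete data). Tajima's *D* uses
window-summed π and θ_W with the 1989 variance constants at n̄; Fay & Wu's
*H* = Σ(π − θ_H), θ_H = 2i²/(n(n−1)) over polarized sites with i the
derived count.

Pairwise metrics are per-window means of per-SNP values. *F*_ST is the
Weir–Cockerham θ̂ in its counts-only form (alleles as the sampling unit;
the within-individual heterozygosity term needs genotype-level data that
allele counts do not carry); a ratio-of-sums variant is available and is
the right choice for multi-locus summaries, since the mean of per-SNP
ratios is Jensen-biased downward by a few points at n = 16 alleles. d_XY =
p₁(1−p₂) + p₂(1−p₁); d_A subtracts mean within-population diversity. AFD is
mean |p₁ − p₂|. DD residuals are ordinary least-squares residuals of window
π (M population by default; configurable to the pair mean) on window
*F*_ST across all windows of the contrast: strongly negative DD marks
diversity lower than the window's differentiation predicts. T_LK =
(M−1)·F_ST,SNP/F̄_ST with M = 2 populations — the Lewontin–Krakauer
statistic proper; the kinship-tree correction of the full FLK test is not
identifiable from a single pair and is out of scope.

**2D-SFS CLR.** Joint derived-count spectra are estimated after
hypergeometric projection of each site to fixed sample sizes (10, 10),
with add-one pseudocounts; site contributions use the expected projected
cell weights. The window score is CLR = 2·Σ C_w·(log Ĝ_w − log G), clamped
at zero, with G the genome-wide and Ĝ_w the window spectrum; windows with
fewer than 5 projectable sites are missing.

**Sweep CLR (SweepFinder-style).** At grid points placed every 10th
polarized site, the composite likelihood maximizes over a sweep-extent
parameter α (25-point log grid, 10⁻²–10⁴ bp) the product over the ±50
flanking sites of a mixture: with escape probability exp(−α/d) at distance
d bp the site follows the genome background spectrum, otherwise it sits in
the highest derived class. α → 0 makes every site escape and recovers the
background model exactly, so CLR = 2·(max_α log L − log L_bg) ≥ 0 and the
models are nested; larger α sweeps sites out to distance ~α, which is what
localizes the signal on the swept interval. This parameterization was
chosen over a distance-*multiplicative* escape exp(−α·d), under which
escape would *decrease* with distance and the model could not localize a
sweep. The per-window value is the maximum CLR over grid points inside the
window span. This is a deliberately simplified reimplementation of the
composite-likelihood sweep test; it is validated by simulation calibration
(null stability, planted-sweep localization), not by equivalence with any
external binary.

**LD contrast (VarLD-style).** Per population, the window's SNP×SNP
genotype correlation matrix (sign retained; constant SNPs get zero
off-diagonal and unit diagonal; missing dosages mean-imputed); the raw
score is Σ_k |λ₁k − λ₂k| over decreasingly sorted eigenvalues, standardized
genome-wide to mean 0, variance 1.

## Outliers and candidates

Empirical quantiles are nearest-rank with ties included: at quantile q over
m finite values, k = max(1, ⌊(1−q)·m⌋) windows are taken from the relevant
tail plus every window tied with the k-th — candidate counts depend on this
convention, hence it is pinned down here. The genome scan calls windows at
q = 0.999 on {DD (lower), F_ST, 2D-SFS CLR, d_XY, AFD, T_LK}; the
divergence scan calls signatures at q = 0.995 on {AFD, d_XY, F_ST, DD
(lower), Tajima's D (lower)}, and a gene becomes a divergence-scan
candidate only when a d_XY, F_ST or DD signature window overlaps it — AFD
and Tajima's D signatures are recorded as supporting evidence. Gene
attachment is closed-interval intersection of window span and gene span on
the same scaffold.

Effect annotation translates ref and alt codons strand-aware against the
GFF3+FASTA gene models (standard code): synonymous / missense /
stop_gained / stop_lost / start_lost; SNPs in the first or last two intron
bases are splice_donor/acceptor; CDS indels are frameshift when the length
difference is not divisible by 3, else inframe; indels crossing an exon
boundary are conservatively treated as frameshift-equivalent HIGH. Impact
classes follow the usual convention (HIGH = stop/start/frameshift/splice).
Genes whose concatenated CDS length is not divisible by 3 are flagged and
excluded from codon-level calls. The large-effect screen runs genome-wide
— sweeps can escape a windowed scan — and admits genes with a HIGH-impact
variant at |p_M − p_NM| > 0.9 (default; the variant's AFD is always
reported so near-threshold hits such as 0.86 remain visible, and the
threshold is a flag option).

Manual candidate curation in comparable studies is replaced here by
declared, configurable filters: minimum supporting windows (default 1) and
a site-density flag for possible paralog collapse.

## Environmental association

Step 1 estimates the among-population covariance Ω of standardized allele
frequencies x_l = (p_l − ε_l)/√(ε_l(1−ε_l)), ε_l the across-population mean,
from fourfold-degenerate SNPs (called in every population, polymorphic
overall; hard error below 50 SNPs, 500 recommended), with eigenvalue
clipping to the nearest PSD matrix. Because ε is the sample mean, Ω carries
a small negative between-group bias of order c/P; with P = 4 populations
this is visible as negative between-pair entries and is part of the model,
not an error.

Step 2 scores SNPs under a Gaussian working model x ~ N(βE, Ω), E the
standardized covariate, with BF = E_prior[L(β)]/L(0) under a uniform prior
on β ∈ [−β_max, β_max] evaluated by 201-point grid quadrature; the
association sign is the sign of the maximum-likelihood β. The latent
frequency MCMC of the original association tool is deliberately replaced by
this closed-form model; it is validated by null calibration (the fraction
of null SNPs at BF ≥ 100 stays well under 0.5%) and planted-effect
recovery, never by equivalence to the original software. **Default
β_max = 1.0**: on the standardized scale the maximum-likelihood β of a
fixed difference perfectly aligned with the covariate is ≈ 0.9, so a
narrower prior (e.g. 0.3) caps the attainable Bayes factor below the
very-strong-association threshold of 100 for *every* SNP and would make
the downstream filter chain vacuous. BF = 1 exactly when the grid is {0},
and BF → 1 as β_max → 0.

Associations are computed for SNPs in divergence-scan candidate genes
against each soil covariate (extractable Cd and Zn by default). The
stringent chain retains SNPs with BF ≥ 100 *and* a protein-changing effect
(missense, stop gained/lost, start lost) *and* the alternate (non-reference)
allele at strictly higher frequency in the M than the NM population of both
contrasts — "non-reference" is taken literally against the heterologous
reference rather than in the polarized sense. Per species, the gene lists
are the union over covariates within each contrast, then the intersection
across the two contrasts.

## Convergence tests

Overlap significance is the exact upper-tail hypergeometric probability
P(X ≥ k) for candidate sets of sizes K and n sharing k genes in a universe
of N; no approximation at any N used here. The default universe is the
*screened* gene space — genes overlapped by at least one analysis window in
every contrast, plus the candidates themselves — with the full annotation
as the configurable alternative; published analyses of this kind quote p
at annotation scale (N ≈ 20,000–35,000 for the reference annotation), and
the acceptance checks use that universe. All pairwise tests are reported:
within species between pairs, between species within pairs, and crossed.
Term enrichment is the same distribution per term over a user-supplied
gene→term table (ontology level filtering is the caller's responsibility;
no ontology is bundled), reported at fold ≥ 3 and p < 0.05, with a
Benjamini–Hochberg column for transparency.

## Synthetic data

The generator works at the allele-frequency level rather than through a
coalescent: ancestral frequencies ~ U(0.05, 0.95); per-pair ancestors by a
Balding–Nichols Beta draw with c_between = 0.2; populations by a further
draw with c_pair = 0.1 (the realized pairwise multi-locus Weir–Cockerham
F_ST matches c_pair within ±0.02 at 20,000 SNPs); genotypes ~ Binomial(2, p)
per individual (8 per population by default, matching field sample sizes of
7–10), 2% missingness. Sweeps overwrite the affected M population's
frequencies over the target gene ± flank: a fraction (1 − reduction,
default 0.7) of sites is fixed for the alt allele and the rest pushed to a
Beta with mean 0.95 — producing lowered π, elevated F_ST/d_XY/AFD, negative
Tajima's D, negative Fay & Wu's H and a high-frequency-derived excess.
Linkage inside sweeps is induced by comonotone genotype draws over blocks
of 25 adjacent SNPs, giving the LD-contrast score something to detect.
Genes are tiled with realistic exon/intron structure (GT..AG introns,
translatable CDS, both strands) so annotation is exercised end to end;
sweep-target genes are generated larger (500–700 codons) and isolated by
buffer gaps so that outlier windows genomically overlap the causal gene
rather than only its flanks. Soil covariates are emitted with an exact
(default 10×) M/NM ratio. Planted large-effect variants and environmentally
associated coding SNPs are written with deterministic genotype patterns so
their sample allele-frequency differences are exact (e.g. a frameshift at
AFD 0.875, below the 0.9 default threshold by design). All outputs are
byte-identical for a given seed.

The standard convergent fixture plants one gene swept in both pairs of the
first species, one gene swept in each single pair, an associated missense
SNP plus synonymous and NM-elevated decoys in the convergent gene, a stop
SNP at AFD 1.0 and the 0.875 frameshift — the full evidence chain the
pipeline should recover, with a second species carrying no planted signal
as the negative control.

What the generator does *not* emulate: linkage outside sweep regions,
recombination-rate variation, demographic history beyond two-level drift,
background selection, reference bias, genotyping error beyond missingness,
and paralog collapse. Passing the simulation suite therefore shows the
statistics and filters behave as specified under the assumed frequency
model, not that the pipeline is robust to every artefact of real
resequencing data.

## Problem sizes and numerical choices

The test suite and acceptance script run the null calibration at ~10,000
windows (≈ 340,000 simulated SNPs) and the replicate recovery at ~100,000
SNPs and a 30,000-gene annotation per replicate — sizes chosen so that
empirical 99.9th percentiles are meaningful (≥ 1,000 windows; below that a
warning is emitted) while a full replicate stays within seconds.
Tolerances: oracle equivalence at 1e−8; PSD repair tolerance 1e−8; the
sweep-CLR mixture floors probabilities at 1e−300 to keep logs finite; BF
quadrature uses a shifted log-sum-exp. Degenerate inputs are defined
behaviour: zero-variance F_ST degenerates DD to centred π with a warning;
all-tied outlier thresholds call everything with a warning; a population
with no called alleles yields (0, 0) counts and drops out of the affected
statistics.

## Known limitations

Two populations per contrast make the LK statistic a scaled per-SNP F_ST
rather than a genuine kinship-corrected test. The Gaussian association
model's BF scale is approximation-specific: the BF ≥ 100 convention is
reproduced, but absolute BF values are not comparable to MCMC-based
implementations. Window-level VarLD standardization assumes windows are
exchangeable under the null. Phase-based statistics (iHS, XP-EHH) and
polyploid genotypes are out of scope.
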