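"""Environmental association analysis across the populations of one species.

Two-step procedure in the spirit of Bayenv: (1) estimate the among
population covariance of standardized allele frequencies from putatively
neutral (fourfold-degenerate) SNPs; (2) score each candidate-gene SNP with
a Bayes factor contrasting a linear frequency-covariate effect against the
null, under a Gaussian working model

    x ~ Normal(beta * E, Omega),

where x are the standardized population frequencies, E the standardized
covariate and Omega the neutral covariance. The marginal likelihood uses a
uniform prior on beta over [-beta_max, beta_max], evaluated by fixed grid
quadrature. The latent-frequency MCMC of the original tool is deliberately
replaced by this closed working model; its calibration is checked on
simulations (null BF tail, planted-effect rank recovery), never by
equivalence to the original binary.

The stringent filter chain retains SNPs with BF >= 100 that change the
protein (missense / stop or start change) and whose alternate (non
reference) allele is at higher frequency in both M populations than in both
NM populations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import NONSYNONYMOUS_EFFECTS, AlleleCounts, StudyDesign


@dataclass
class CovarianceModel:
    """Among-population covariance of standardized allele frequencies."""

    populations: list[str]
    omega: np.ndarray  # (P, P), symmetric positive semi-definite

    def __post_init__(self) -> None:
        if not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be symmetric")
        if np.min(np.linalg.eigvalsh(self.omega)) < -1e-8:
            raise ValueError("omega must be positive semi-definite")


def _standardize_frequencies(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale per-SNP frequencies: x = (p - eps) / sqrt(eps(1-eps)).

    ``freqs`` is (S, P); eps is the across-population mean frequency per SNP.
    """
    eps = freqs.mean(axis=1)
    scale = np.sqrt(eps * (1.0 - eps))
    with np.errstate(divide="ignore", invalid="ignore"):
        x = (freqs - eps[:, None]) / scale[:, None]
    return x, eps


def estimate_covariance(
    counts: AlleleCounts,
    neutral_idx: np.ndarray,
    min_snps: int = 50,
) -> CovarianceModel:
    """Neutral among-population covariance from fourfold-degenerate SNPs.

    SNPs must be called in every population and polymorphic across the
    pooled sample. Omega is the average outer product of standardized
    frequency vectors, eigenvalue-clipped to the nearest PSD matrix.
    """
    f = counts.freq()[:, neutral_idx].T  # (S, P)
    ok = np.all(np.isfinite(f), axis=1)
    eps = f.mean(axis=1)
    ok &= (eps > 0) & (eps < 1)
    f = f[ok]
    if f.shape[0] < min_snps:
        raise ValueError(
            f"only {f.shape[0]} usable neutral SNPs (< {min_snps}); "
            "cannot estimate the population covariance"
        )
    x, _ = _standardize_frequencies(f)
    omega = (x.T @ x) / x.shape[0]
    # nearest-PSD repair by eigenvalue clipping
    w, v = np.linalg.eigh(omega)
    if w.min() < 0:
        omega = (v * np.clip(w, 0, None)) @ v.T
    omega = 0.5 * (omega + omega.T)
    return CovarianceModel(populations=list(counts.populations), omega=omega)


def standardize_covariate(env: pd.DataFrame, covariate: str,
                          populations: list[str]) -> np.ndarray:
    """Covariate vector over populations, standardized to mean 0 variance 1."""
    sub = env[env["covariate"] == covariate].set_index("population")["value"]
    missing = [p for p in populations if p not in sub.index]
    if missing:
        raise ValueError(f"covariate {covariate} missing for populations {missing}")
    e = sub.loc[populations].to_numpy(dtype=float)
    if np.std(e) == 0:
        raise ValueError(f"no environmental contrast: covariate {covariate} "
                         "constant across populations")
    return (e - e.mean()) / e.std()


def bayes_factors(
    freqs: np.ndarray,
    env_std: np.ndarray,
    model: CovarianceModel,
    beta_max: float = 1.0,
    n_grid: int = 201,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Bayes factor and association sign for each SNP (rows of ``freqs``).

    BF_l = mean over the beta grid of L(x_l | beta E, Omega) / L(x_l | 0, Omega)
    (uniform prior over [-beta_max, beta_max]); the sign is that of the
    maximum-likelihood beta. Restricting the grid to {0} gives BF = 1.
    The default prior half-width of 1 covers the attainable effect scale:
    the maximum-likelihood beta of a fixed difference perfectly aligned with
    the covariate is close to 1 on the standardized-frequency scale.
    """
    x, _ = _standardize_frequencies(freqs)
    omega = model.omega + ridge * np.eye(len(model.populations))
    L = np.linalg.cholesky(omega)
    y = np.linalg.solve(L, x.T)          # (P, S) whitened frequencies
    z = np.linalg.solve(L, env_std)      # (P,)
    zy = z @ y                            # (S,)
    zz = float(z @ z)
    betas = np.linspace(-beta_max, beta_max, n_grid) if n_grid > 1 \
        else np.array([0.0])
    # log L(beta) - log L(0) = beta*(z.y) - beta^2*(z.z)/2
    delta = betas[None, :] * zy[:, None] - 0.5 * (betas ** 2)[None, :] * zz
    # guard overflow: BF computed via shifted logsumexp
    dmax = delta.max(axis=1, keepdims=True)
    bf = np.exp(dmax[:, 0]) * np.mean(np.exp(delta - dmax), axis=1)
    sign = np.where(zy >= 0, 1, -1)
    return bf, sign


def associate(
    counts: AlleleCounts,
    site_idx: np.ndarray,
    env: pd.DataFrame,
    covariates: list[str],
    model: CovarianceModel,
    table=None,
    beta_max: float = 1.0,
    n_grid: int = 201,
) -> pd.DataFrame:
    """Score SNPs (by table index) against each covariate.

    Returns tidy rows: site, covariate, bf, sign. Sites not called in every
    population, or monomorphic across the pooled sample, are dropped.
    """
    f = counts.freq()[:, site_idx].T
    ok = np.all(np.isfinite(f), axis=1)
    eps = np.nanmean(f, axis=1)
    ok &= (eps > 0) & (eps < 1)
    idx = site_idx[ok]
    f = f[ok]
    frames = []
    for cov in covariates:
        e = standardize_covariate(env, cov, model.populations)
        bf, sign = bayes_factors(f, e, model, beta_max=beta_max, n_grid=n_grid)
        frames.append(pd.DataFrame({
            "site": idx, "covariate": cov, "bf": bf, "sign": sign,
        }))
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=["site", "covariate", "bf", "sign"]))


def stringent_filter(
    associations: pd.DataFrame,
    effects: pd.DataFrame,
    counts: AlleleCounts,
    design: StudyDesign,
    species: str,
    bf_min: float = 100.0,
) -> pd.DataFrame:
    """The three-gate filter chain.

    Retains associations with (1) BF >= bf_min, (2) a protein-changing
    effect, and (3) the alternate allele at strictly higher frequency in the
    M population than the NM population of *both* contrasts of the species.
    Raising ``bf_min`` can only shrink the result.
    """
    contrasts = design.contrasts(species)
    if len(contrasts) != 2:
        raise ValueError(f"species {species} must have exactly 2 contrasts")
    f = counts.freq()
    elevated = np.ones(f.shape[1], dtype=bool)
    for _, _, pop_m, pop_nm in contrasts:
        pm = f[counts.pop_index(pop_m)]
        pnm = f[counts.pop_index(pop_nm)]
        elevated &= np.isfinite(pm) & np.isfinite(pnm) & (pm > pnm)
    eff = effects.set_index("site")
    keep_rows = []
    for row in associations.itertuples(index=False):
        if row.bf < bf_min:
            continue
        if row.site not in eff.index:
            continue
        erow = eff.loc[row.site]
        if isinstance(erow, pd.DataFrame):  # site in several genes
            sub = erow[erow["effect"].isin(NONSYNONYMOUS_EFFECTS)]
            if sub.empty:
                continue
            erow = sub.iloc[0]
        elif erow["effect"] not in NONSYNONYMOUS_EFFECTS:
            continue
        if not elevated[row.site]:
            continue
        keep_rows.append({
            "site": row.site, "covariate": row.covariate, "bf": row.bf,
            "sign": row.sign, "effect": erow["effect"],
            "gene_id": erow["gene_id"],
        })
    return pd.DataFrame(keep_rows, columns=["site", "covariate", "bf", "sign",
                                            "effect", "gene_id"])


def union_and_intersect(
    ea_genes: dict[tuple[str, str], set[str]],
) -> tuple[dict[str, set[str]], set[str]]:
    """Per-contrast union over covariates, then the gene-level intersection
    of the two contrasts.

    ``ea_genes`` maps (contrast label, covariate) -> gene set for ONE species.
    Returns (per-contrast unions, intersection across contrasts).
    """
    unions: dict[str, set[str]] = {}
    for (contrast, _cov), genes in ea_genes.items():
        unions.setdefault(contrast, set()).update(genes)
    if not unions:
        return {}, set()
    sets = list(unions.values())
    intersect = set.intersection(*sets) if sets else set()
    return unions, intersect
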