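"""Per-window selective-sweep and differentiation statistics.

All metrics operate on allele counts (and, for the LD-contrast score, raw
dosages) over windows of consecutive SNPs; pairwise metrics are aggregated
as the per-window mean of per-SNP values.

Metrics
-------
pi, theta_w            within-population diversity (per-SNP scale)
tajimas_d, fay_wu_h    site-frequency-spectrum skew
fst                    Weir-Cockerham differentiation (per-SNP mean, or
                       ratio-of-sums by option)
dxy, d_a               absolute / net between-population divergence
afd_abs                mean absolute allele-frequency difference
dd_residuals           residuals of window diversity regressed on window FST
flk                    Lewontin-Krakauer standardized differentiation
sfs2d_clr              window vs genome 2D-SFS composite likelihood ratio
sweed_clr              SweepFinder-style sweep CLR profile
varld                  LD-matrix eigenvalue contrast between populations
"""
from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

from .model import AlleleCounts

# ---------------------------------------------------------------------------
# helpers


def _gather(counts: AlleleCounts, members: np.ndarray, pop: str):
    """(alt, called) arrays of shape (n_windows, window_size)."""
    i = counts.pop_index(pop)
    return counts.alt[i][members], counts.called[i][members]


def _gather_derived(counts: AlleleCounts, members: np.ndarray, pop: str):
    i = counts.pop_index(pop)
    if counts.derived is None:
        raise ValueError("counts not polarized")
    return counts.derived[i][members], counts.called[i][members], counts.polarized[members]


def per_site_pi(alt: np.ndarray, called: np.ndarray) -> np.ndarray:
    """Unbiased per-site nucleotide diversity 2*i*(n-i)/(n*(n-1))."""
    n = called.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * alt * (called - alt) / (n * (n - 1.0))
    return np.where(called >= 2, pi, np.nan)


def harmonic(k: int) -> float:
    """a1 = sum_{i=1}^{k} 1/i."""
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


# ---------------------------------------------------------------------------
# within-population diversity


def window_diversity(
    counts: AlleleCounts, members: np.ndarray, pop: str,
    flag_threshold: float = 0.2,
):
    """Window mean pi and per-SNP Watterson theta.

    theta_W = S / (a1 * size) with S the number of sites polymorphic in the
    population and a1 evaluated at the window-mean called-allele number.
    Sites with fewer than 2 called alleles are excluded; windows with more
    than ``flag_threshold`` of member sites excluded are flagged.

    Returns (pi, theta_w, flagged) arrays over windows.
    """
    alt, called = _gather(counts, members, pop)
    ok = called >= 2
    pi_site = per_site_pi(alt, called)
    n_ok = ok.sum(axis=1)
    pi = np.where(n_ok > 0, np.nansum(pi_site, axis=1) / np.maximum(n_ok, 1), np.nan)
    seg = (alt > 0) & (alt < called) & ok
    S = seg.sum(axis=1)
    with np.errstate(invalid="ignore"):
        nbar = np.where(n_ok > 0, called.sum(axis=1, where=ok) / np.maximum(n_ok, 1), 0)
    nbar_i = np.maximum(np.rint(nbar).astype(int), 2)
    a1 = np.array([harmonic(k - 1) for k in nbar_i])
    size = members.shape[1]
    theta = np.where((a1 > 0) & (n_ok > 0), S / np.maximum(a1, 1e-300) / size, np.nan)
    theta = np.where(S == 0, np.where(n_ok > 0, 0.0, np.nan), theta)
    flagged = (members.shape[1] - n_ok) > flag_threshold * members.shape[1]
    return pi, theta, flagged


def tajima_constants(n: int) -> dict[str, float]:
    """Variance constants of Tajima's D at sample size n (alleles)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    a1 = harmonic(n - 1)
    a2 = float(np.sum(1.0 / np.arange(1, n) ** 2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(counts: AlleleCounts, members: np.ndarray, pop: str) -> np.ndarray:
    """Window Tajima's D from summed pi and summed Watterson theta.

    Constants are evaluated at the window-mean called-allele number (missing
    data makes the exact n site-specific; the mean-n evaluation is the
    documented approximation). Windows with no segregating site are NaN.
    """
    alt, called = _gather(counts, members, pop)
    ok = called >= 2
    pi_site = per_site_pi(alt, called)
    pi_total = np.nansum(np.where(ok, pi_site, np.nan), axis=1)
    seg = (alt > 0) & (alt < called) & ok
    S = seg.sum(axis=1).astype(float)
    n_ok = ok.sum(axis=1)
    nbar = np.where(n_ok > 0, called.sum(axis=1, where=ok) / np.maximum(n_ok, 1), 0)
    nbar_i = np.maximum(np.rint(nbar).astype(int), 2)
    out = np.full(len(members), np.nan)
    for w in np.flatnonzero(S >= 1):
        c = tajima_constants(int(nbar_i[w]))
        var = c["e1"] * S[w] + c["e2"] * S[w] * (S[w] - 1.0)
        if var <= 0:
            continue
        out[w] = (pi_total[w] - S[w] / c["a1"]) / np.sqrt(var)
    return out


def fay_wu_h(counts: AlleleCounts, members: np.ndarray, pop: str) -> np.ndarray:
    """Window Fay & Wu's H = sum(pi) - sum(theta_H) over polarized sites.

    theta_H = 2*i^2 / (n*(n-1)) with i the derived-allele count; strongly
    negative H marks an excess of high-frequency derived alleles.
    """
    der, called, polarized = _gather_derived(counts, members, pop)
    ok = (called >= 2) & polarized
    n = called.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_site = 2.0 * der * (called - der) / (n * (n - 1.0))
        th_site = 2.0 * der.astype(float) ** 2 / (n * (n - 1.0))
    contrib = np.where(ok, pi_site - th_site, np.nan)
    any_ok = ok.any(axis=1)
    H = np.nansum(contrib, axis=1)
    return np.where(any_ok, H, np.nan)


# ---------------------------------------------------------------------------
# pairwise metrics


def per_snp_wc_fst(a1, n1, a2, n2):
    """Weir-Cockerham theta-hat per SNP from two populations' allele counts.

    Counts-only form: alleles are the sampling unit (r = 2 demes). Returns
    NaN where the denominator vanishes (both populations monomorphic for the
    same allele) or a population has no called alleles.
    """
    a1 = np.asarray(a1, float); n1 = np.asarray(n1, float)
    a2 = np.asarray(a2, float); n2 = np.asarray(n2, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = a1 / n1, a2 / n2
        ntot = n1 + n2
        pbar = (a1 + a2) / ntot
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2  # df = r-1 = 1
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2.0)
        nc = ntot - (n1 ** 2 + n2 ** 2) / ntot  # over df = 1
        denom = msp + (nc - 1.0) * msg
        theta = (msp - msg) / denom
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(theta)
    return np.where(bad, np.nan, theta)


def fst(
    counts: AlleleCounts, members: np.ndarray, pop1: str, pop2: str,
    method: str = "mean",
) -> np.ndarray:
    """Window Weir-Cockerham FST: mean of per-SNP values (default) or
    ratio-of-sums over the window ("ratio")."""
    A1, N1 = _gather(counts, members, pop1)
    A2, N2 = _gather(counts, members, pop2)
    if method == "mean":
        theta = per_snp_wc_fst(A1, N1, A2, N2)
        cnt = np.isfinite(theta).sum(axis=1)
        return np.where(cnt > 0, np.nansum(theta, axis=1) / np.maximum(cnt, 1), np.nan)
    if method == "ratio":
        a1 = A1.astype(float); n1 = N1.astype(float)
        a2 = A2.astype(float); n2 = N2.astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p1, p2 = a1 / n1, a2 / n2
            ntot = n1 + n2
            pbar = (a1 + a2) / ntot
            msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
            msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2.0)
            nc = ntot - (n1 ** 2 + n2 ** 2) / ntot
            num = np.nansum(msp - msg, axis=1)
            den = np.nansum(msp + (nc - 1.0) * msg, axis=1)
            return np.where(den != 0, num / den, np.nan)
    raise ValueError(f"unknown FST method {method!r}")


def dxy(counts: AlleleCounts, members: np.ndarray, pop1: str, pop2: str):
    """Window mean absolute divergence p1(1-p2)+p2(1-p1) and net divergence
    d_a = dxy - (pi1+pi2)/2."""
    A1, N1 = _gather(counts, members, pop1)
    A2, N2 = _gather(counts, members, pop2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(N1 > 0, A1 / np.maximum(N1, 1), np.nan)
        p2 = np.where(N2 > 0, A2 / np.maximum(N2, 1), np.nan)
    d_site = p1 * (1 - p2) + p2 * (1 - p1)
    cnt = np.isfinite(d_site).sum(axis=1)
    dxy_w = np.where(cnt > 0, np.nansum(d_site, axis=1) / np.maximum(cnt, 1), np.nan)
    pi1, _, _ = window_diversity(counts, members, pop1)
    pi2, _, _ = window_diversity(counts, members, pop2)
    return dxy_w, dxy_w - 0.5 * (pi1 + pi2)


def afd_abs(counts: AlleleCounts, members: np.ndarray, pop1: str, pop2: str):
    """Window mean |p1 - p2|."""
    A1, N1 = _gather(counts, members, pop1)
    A2, N2 = _gather(counts, members, pop2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(N1 > 0, A1 / np.maximum(N1, 1), np.nan)
        p2 = np.where(N2 > 0, A2 / np.maximum(N2, 1), np.nan)
    d = np.abs(p1 - p2)
    cnt = np.isfinite(d).sum(axis=1)
    return np.where(cnt > 0, np.nansum(d, axis=1) / np.maximum(cnt, 1), np.nan)


def dd_residuals(pi: np.ndarray, fst_vals: np.ndarray) -> np.ndarray:
    """Diversity-divergence residuals: OLS of window pi on window FST.

    Strongly negative residuals mark diversity lowered beyond what the
    window's differentiation predicts (sweep-like). With zero variance in
    FST the fit degenerates to the intercept (centred pi).
    """
    ok = np.isfinite(pi) & np.isfinite(fst_vals)
    if ok.sum() < 10:
        raise ValueError("need >= 10 windows with finite pi and FST")
    x, y = fst_vals[ok], pi[ok]
    out = np.full_like(pi, np.nan, dtype=float)
    if np.ptp(x) == 0:
        out[ok] = y - y.mean()
        return out
    slope, intercept = np.polyfit(x, y, 1)
    out[ok] = y - (slope * x + intercept)
    return out


def genome_mean_fst(counts: AlleleCounts, site_idx: np.ndarray,
                    pop1: str, pop2: str) -> float:
    """Genome-wide mean per-SNP Weir-Cockerham FST over the usable sites."""
    i1, i2 = counts.pop_index(pop1), counts.pop_index(pop2)
    theta = per_snp_wc_fst(counts.alt[i1][site_idx], counts.called[i1][site_idx],
                           counts.alt[i2][site_idx], counts.called[i2][site_idx])
    return float(np.nanmean(theta))


def flk(counts: AlleleCounts, members: np.ndarray, pop1: str, pop2: str,
        fst_bar: float) -> np.ndarray:
    """Window mean Lewontin-Krakauer statistic T = (M-1)*FST_snp / FST_bar.

    With M = 2 populations this is the LK statistic proper; the kinship-tree
    correction of the full FLK test is not identifiable from a single pair.
    """
    if fst_bar <= 0:
        raise ValueError("contrast shows no net differentiation (mean FST <= 0)")
    A1, N1 = _gather(counts, members, pop1)
    A2, N2 = _gather(counts, members, pop2)
    theta = per_snp_wc_fst(A1, N1, A2, N2)
    t = (2 - 1) * theta / fst_bar
    cnt = np.isfinite(t).sum(axis=1)
    return np.where(cnt > 0, np.nansum(t, axis=1) / np.maximum(cnt, 1), np.nan)


# ---------------------------------------------------------------------------
# 2D-SFS composite likelihood ratio


_proj_cache: dict[tuple[int, int, int], np.ndarray] = {}


def _projection(i: int, n: int, m: int) -> np.ndarray:
    """Hypergeometric downsampling of i derived out of n alleles to m."""
    key = (i, n, m)
    got = _proj_cache.get(key)
    if got is None:
        got = hypergeom.pmf(np.arange(m + 1), n, i, m)
        _proj_cache[key] = got
    return got


def projected_site_spectra(derived: np.ndarray, called: np.ndarray,
                           m: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-site projected derived-count distributions.

    Returns (W, projectable): W is (n_sites, m+1) float32, rows of
    non-projectable sites are zero.
    """
    S = len(derived)
    W = np.zeros((S, m + 1), dtype=np.float32)
    ok = called >= m
    pairs = {}
    for s in np.flatnonzero(ok):
        key = (int(derived[s]), int(called[s]))
        idx = pairs.setdefault(key, [])
        idx.append(s)
    for (i, n), idx in pairs.items():
        W[idx] = _projection(i, n, m).astype(np.float32)
    return W, ok


def sfs2d_clr(
    counts: AlleleCounts, members: np.ndarray, pop1: str, pop2: str,
    site_idx: np.ndarray, proj: tuple[int, int] = (10, 10),
    min_sites: int = 5,
) -> np.ndarray:
    """Composite likelihood ratio of the window's joint 2D-SFS against the
    genome-wide joint spectrum.

    Both spectra are estimated over derived-count classes after hypergeometric
    projection to fixed sample sizes, with add-one pseudocounts; site
    contributions use the expected projected cell weights. CLR is clamped at
    zero; windows with fewer than ``min_sites`` projectable members are NaN.
    """
    m1, m2 = proj
    i1, i2 = counts.pop_index(pop1), counts.pop_index(pop2)
    if counts.derived is None:
        raise ValueError("counts not polarized")
    d1, n1 = counts.derived[i1], counts.called[i1]
    d2, n2 = counts.derived[i2], counts.called[i2]
    pol = counts.polarized
    W1, ok1 = projected_site_spectra(d1, n1, m1)
    W2, ok2 = projected_site_spectra(d2, n2, m2)
    ok = ok1 & ok2 & pol
    # joint per-site cell weights, flattened (m1+1)*(m2+1)
    ncell = (m1 + 1) * (m2 + 1)
    # genome spectrum over usable sites
    gsel = site_idx[ok[site_idx]]
    G = np.zeros(ncell)
    # accumulate outer products in chunks to bound memory
    for chunk in np.array_split(gsel, max(1, len(gsel) // 20000)):
        if len(chunk) == 0:
            continue
        J = np.einsum("si,sj->sij", W1[chunk], W2[chunk]).reshape(len(chunk), ncell)
        G += J.sum(axis=0)
    G = (G + 1.0) / (G.sum() + ncell)
    logG = np.log(G)

    out = np.full(len(members), np.nan)
    for w, mem in enumerate(members):
        sel = mem[ok[mem]]
        if len(sel) < min_sites:
            continue
        J = np.einsum("si,sj->sij", W1[sel], W2[sel]).reshape(len(sel), ncell)
        C = J.sum(axis=0)
        Gw = (C + 1.0) / (C.sum() + ncell)
        clr = 2.0 * float(np.dot(C, np.log(Gw) - logG))
        out[w] = max(clr, 0.0)
    return out


# ---------------------------------------------------------------------------
# SweepFinder-style CLR


def sweed_clr(
    counts: AlleleCounts,
    positions: np.ndarray,
    site_idx: np.ndarray,
    pop: str,
    proj: int = 10,
    grid_step: int = 10,
    nearby: int = 50,
    alpha_grid: np.ndarray | None = None,
    min_sites: int = 25,
) -> tuple[np.ndarray, np.ndarray]:
    """Sweep composite likelihood ratio profile for one population.

    At each grid point (every ``grid_step``-th polarized site) the composite
    likelihood maximizes, over the sweep-extent parameter alpha, the product
    over the ``nearby`` flanking sites of a mixture model: a lineage class
    escapes the sweep with probability exp(-alpha/d) at distance d bp
    (escaped sites follow the genome background spectrum; swept sites sit in
    the highest derived class). alpha -> 0 recovers the background model, so
    CLR = 2*(max log L - background log L) >= 0.

    Returns (grid positions, CLR at each grid point); scaffolds are the
    caller's responsibility (pass per-scaffold site indices).
    """
    if alpha_grid is None:
        alpha_grid = np.logspace(-2, 4, 25)
    i = counts.pop_index(pop)
    if counts.derived is None:
        raise ValueError("counts not polarized")
    der = counts.derived[i][site_idx]
    cal = counts.called[i][site_idx]
    pol = counts.polarized[site_idx]
    W, ok = projected_site_spectra(der, cal, proj)
    keep = ok & pol
    W = W[keep]
    pos = positions[site_idx][keep]
    if len(pos) < min_sites:
        return np.array([]), np.array([])
    # genome background spectrum (small pseudocount keeps logs finite)
    B = W.sum(axis=0).astype(float)
    B = (B + 0.5) / (B.sum() + 0.5 * len(B))
    logB = np.log(B)
    bg_site = W @ logB  # per-site background log-likelihood

    top = proj  # highest derived class
    grid_idx = np.arange(0, len(pos), grid_step)
    clrs = np.zeros(len(grid_idx))
    for k, g in enumerate(grid_idx):
        lo, hi = max(0, g - nearby), min(len(pos), g + nearby + 1)
        d = np.abs(pos[lo:hi] - pos[g]).astype(float)
        d = np.maximum(d, 1.0)
        pe = np.exp(-alpha_grid[:, None] / d[None, :])     # (A, S)
        # mixture spectrum per (alpha, site, class); floor keeps logs finite
        P = pe[:, :, None] * B[None, None, :]
        P[:, :, top] += 1.0 - pe
        ll = np.einsum("asc,sc->a", np.log(np.maximum(P, 1e-300)), W[lo:hi])
        clrs[k] = max(0.0, 2.0 * (float(ll.max()) - float(bg_site[lo:hi].sum())))
    return pos[grid_idx], clrs


def sweed_window_max(grid_pos: np.ndarray, grid_clr: np.ndarray,
                     windows) -> np.ndarray:
    """Per-window SweeD value = max grid CLR inside the window span."""
    out = np.full(len(windows), np.nan)
    if len(grid_pos) == 0:
        return out
    order = np.argsort(grid_pos)
    gp, gc = grid_pos[order], grid_clr[order]
    for w, row in enumerate(windows.itertuples(index=False)):
        lo = np.searchsorted(gp, row.pos_first, side="left")
        hi = np.searchsorted(gp, row.pos_last, side="right")
        if hi > lo:
            out[w] = gc[lo:hi].max()
    return out


# ---------------------------------------------------------------------------
# VarLD-style LD contrast


def _ld_correlation(dos: np.ndarray) -> np.ndarray:
    """Signed genotype-correlation (composite LD) matrix of one window.

    Missing dosages are mean-imputed per SNP; a constant SNP gets zero
    correlation with everything and 1 on the diagonal.
    """
    X = dos.astype(float)
    X[X == -1] = np.nan
    mu = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(mu, inds[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    good = sd > 0
    Xn = np.zeros_like(X)
    Xn[:, good] = X[:, good] / sd[good]
    R = (Xn.T @ Xn) / X.shape[0]
    np.fill_diagonal(R, 1.0)
    return R


def varld_raw(dosages: np.ndarray, rows1: np.ndarray, rows2: np.ndarray,
              members: np.ndarray) -> np.ndarray:
    """Raw VarLD-style score per window: sum |lambda1_k - lambda2_k| of the
    two populations' LD-correlation eigenvalues (sorted decreasing)."""
    out = np.zeros(len(members))
    for w, mem in enumerate(members):
        R1 = _ld_correlation(dosages[np.ix_(rows1, mem)])
        R2 = _ld_correlation(dosages[np.ix_(rows2, mem)])
        l1 = np.sort(np.linalg.eigvalsh(R1))[::-1]
        l2 = np.sort(np.linalg.eigvalsh(R2))[::-1]
        out[w] = np.abs(l1 - l2).sum()
    return out


def compute_window_stats(
    table,
    counts: AlleleCounts,
    windows,
    members: np.ndarray,
    site_idx: np.ndarray,
    pop_m: str,
    pop_nm: str,
    design=None,
    fst_method: str = "mean",
    dd_population: str = "M",
    include_sweed: bool = True,
    include_varld: bool = True,
    include_sfs2d: bool = True,
    proj: tuple[int, int] = (10, 10),
) -> "pd.DataFrame":
    """All per-window metrics for one M/NM contrast.

    Returns a DataFrame aligned with ``windows`` (window_id, scaffold, span
    columns plus one column per metric). Heavier metrics can be switched off.
    """
    import pandas as pd

    out = windows.copy()
    pi_m, th_m, _ = window_diversity(counts, members, pop_m)
    pi_nm, th_nm, _ = window_diversity(counts, members, pop_nm)
    out["pi_m"], out["theta_w_m"] = pi_m, th_m
    out["pi_nm"], out["theta_w_nm"] = pi_nm, th_nm
    out["tajimas_d_m"] = tajimas_d(counts, members, pop_m)
    out["tajimas_d_nm"] = tajimas_d(counts, members, pop_nm)
    if counts.derived is not None:
        out["fay_wu_h_m"] = fay_wu_h(counts, members, pop_m)
        out["fay_wu_h_nm"] = fay_wu_h(counts, members, pop_nm)
    out["fst"] = fst(counts, members, pop_m, pop_nm, method=fst_method)
    dxy_w, da_w = dxy(counts, members, pop_m, pop_nm)
    out["dxy"], out["d_a"] = dxy_w, da_w
    out["afd_abs"] = afd_abs(counts, members, pop_m, pop_nm)
    pi_dd = pi_m if dd_population == "M" else 0.5 * (pi_m + pi_nm)
    out["dd"] = dd_residuals(pi_dd, out["fst"].to_numpy())
    fbar = genome_mean_fst(counts, site_idx, pop_m, pop_nm)
    out["flk"] = flk(counts, members, pop_m, pop_nm, fbar)
    if include_sfs2d and counts.derived is not None:
        out["sfs2d_clr"] = sfs2d_clr(counts, members, pop_m, pop_nm, site_idx,
                                     proj=proj)
    if include_sweed and counts.derived is not None:
        positions = table.sites["pos"].to_numpy()
        scaf_all = table.sites["scaffold"].to_numpy()[site_idx]
        sweed = np.full(len(windows), np.nan)
        for s in dict.fromkeys(scaf_all):
            sub = site_idx[scaf_all == s]
            gp, gc = sweed_clr(counts, positions, sub, pop_m, proj=proj[0])
            wsel = windows["scaffold"] == s
            vals = sweed_window_max(gp, gc, windows.loc[wsel])
            sweed[wsel.to_numpy()] = vals
        out["sweed_clr_m"] = sweed
    if include_varld and design is not None:
        ind_index = {ind: i for i, ind in enumerate(table.individuals)}
        rows_m = np.array([ind_index[i] for i in design.members(pop_m)])
        rows_nm = np.array([ind_index[i] for i in design.members(pop_nm)])
        raw = varld_raw(table.dosages, rows_m, rows_nm, members)
        out["varld"] = standardize(raw)
    return out


def standardize(values: np.ndarray) -> np.ndarray:
    """Genome-wide z-standardization (mean 0, variance 1 over finite values)."""
    ok = np.isfinite(values)
    mu = values[ok].mean()
    sd = values[ok].std()
    if sd == 0:
        return np.where(ok, 0.0, np.nan)
    return (values - mu) / sd
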