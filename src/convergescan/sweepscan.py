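"""Outlier-window calling, gene mapping, effect annotation and candidate lists.

Two candidate flavours are produced per contrast:

* the genome scan — windows at or beyond the empirical 99.9th percentile
  (0.1st for the diversity-divergence residual) of any one pairwise metric;
* the divergence scan — 99.5th-percentile signatures on AFD, dXY, FST, DD
  and Tajima's D, where only dXY / FST / DD signatures promote a gene to
  candidate status (AFD and Tajima's D are supporting evidence).

Independently, a genome-wide large-effect screen flags genes carrying a
HIGH-impact variant at extreme allele-frequency difference between the M
and NM population of the contrast.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .model import (EFFECT_IMPACT, AlleleCounts, GeneModel, GenotypeTable,
                    StudyDesign)
from .variantio import STANDARD_CODE, cds_coordinate_map, gene_cds_sequence, revcomp

log = logging.getLogger(__name__)

SCAN_METRICS: dict[str, str] = {
    # metric -> outlier tail for the 99.9%ile genome scan
    "dd": "lower",
    "fst": "upper",
    "sfs2d_clr": "upper",
    "dxy": "upper",
    "afd_abs": "upper",
    "flk": "upper",
}

DIVERGENCE_METRICS: dict[str, str] = {
    "afd_abs": "upper",
    "dxy": "upper",
    "fst": "upper",
    "dd": "lower",
    "tajimas_d_m": "lower",
}

# only these metrics promote a gene to divergence-scan candidate status
DIVERGENCE_CANDIDATE_METRICS = ("dxy", "fst", "dd")


def empirical_outliers(
    stats: pd.DataFrame,
    metrics: dict[str, str] | None = None,
    q: float = 0.999,
) -> pd.DataFrame:
    """Windows at or beyond the empirical q-quantile per metric.

    Quantiles are nearest-rank with ties included: k = floor((1-q)*m) windows
    are taken from the relevant tail (at least one), plus every window tied
    with the k-th. Missing metric values are ignored; an entirely missing
    metric is skipped with a warning.
    """
    metrics = SCAN_METRICS if metrics is None else metrics
    if len(stats) < 1000:
        log.warning("only %d windows; empirical %.4f quantiles are coarse",
                    len(stats), q)
    calls = []
    for metric, tail in metrics.items():
        if metric not in stats.columns:
            log.warning("metric %s absent from stats; skipped", metric)
            continue
        v = stats[metric].to_numpy(dtype=float)
        ok = np.isfinite(v)
        m = int(ok.sum())
        if m == 0:
            log.warning("metric %s entirely missing; skipped", metric)
            continue
        vals = v[ok]
        k = max(1, int(np.floor((1.0 - q) * m)))
        srt = np.sort(vals)
        if tail == "upper":
            thr = srt[m - k]
            hit = ok & (v >= thr)
        else:
            thr = srt[k - 1]
            hit = ok & (v <= thr)
        if np.all(vals == vals[0]):
            log.warning("metric %s constant across windows; all tied at "
                        "threshold", metric)
        method = "max" if tail == "upper" else "min"
        quant = np.full(len(v), np.nan)
        quant[ok] = pd.Series(vals).rank(pct=True, method=method).to_numpy()
        for w in np.flatnonzero(hit):
            calls.append((int(stats["window_id"].iloc[w]), metric, float(v[w]),
                          float(quant[w]), tail))
    return pd.DataFrame(calls, columns=["window_id", "metric", "value",
                                        "quantile", "tail"])


def divergence_signatures(stats: pd.DataFrame, q: float = 0.995,
                          metrics: dict[str, str] | None = None) -> pd.DataFrame:
    """99.5th-percentile divergence signatures (AFD, dXY, FST, DD, Tajima's D)."""
    return empirical_outliers(stats, metrics or DIVERGENCE_METRICS, q=q)


@dataclass
class CandidateGene:
    gene_id: str
    contrast: str
    provenance: set = field(default_factory=set)
    windows: list = field(default_factory=list)   # (window_id, metric) pairs
    variants: list = field(default_factory=list)  # (scaffold, pos, effect, afd)


def genes_overlapping(
    calls: pd.DataFrame,
    windows: pd.DataFrame,
    genes: list[GeneModel],
    contrast: str = "",
    provenance: str = "scan_999",
) -> dict[str, CandidateGene]:
    """Attach genes whose span intersects an outlier window's genomic span
    (closed-interval intersection on the same scaffold)."""
    out: dict[str, CandidateGene] = {}
    if calls.empty:
        return out
    wmeta = windows.set_index("window_id")
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold, []).append(g)
    for row in calls.itertuples(index=False):
        w = wmeta.loc[row.window_id]
        for g in by_scaffold.get(w["scaffold"], []):
            if g.start <= w["pos_last"] and g.end >= w["pos_first"]:
                cand = out.setdefault(
                    g.gene_id, CandidateGene(g.gene_id, contrast, set()))
                cand.provenance.add(provenance)
                cand.windows.append((int(row.window_id), row.metric))
    return out


# ---------------------------------------------------------------------------
# effect annotation (SnpEff-style, simplified)


def _snp_effect(gene: GeneModel, cds_seq: str, coord: np.ndarray,
                pos: int, ref: str, alt: str) -> str | None:
    """Effect of a SNP inside the CDS of a translatable gene."""
    hits = np.flatnonzero(coord == pos)
    if len(hits) == 0:
        return None
    ci = int(hits[0])
    base = alt if gene.strand == "+" else revcomp(alt)
    codon_i = ci // 3
    within = ci % 3
    ref_codon = cds_seq[3 * codon_i:3 * codon_i + 3]
    alt_codon = ref_codon[:within] + base + ref_codon[within + 1:]
    ref_aa = STANDARD_CODE.get(ref_codon.upper(), "X")
    alt_aa = STANDARD_CODE.get(alt_codon.upper(), "X")
    if codon_i == 0 and ref_codon.upper() == "ATG" and alt_codon.upper() != "ATG":
        return "start_lost"
    if ref_aa != "*" and alt_aa == "*":
        return "stop_gained"
    if ref_aa == "*" and alt_aa != "*":
        return "stop_lost"
    return "synonymous" if ref_aa == alt_aa else "missense"


def annotate_effects(
    table: GenotypeTable,
    genes: list[GeneModel],
    fasta: Fasta | str,
) -> pd.DataFrame:
    """Predict variant effects against the gene models (strand-aware codon
    translation for CDS SNPs, +-2 nt splice regions, frameshift-by-length for
    CDS indels). Genes with untranslatable CDS are skipped.

    Returns columns: site (index into table), gene_id, effect, impact.
    """
    if isinstance(fasta, str):
        fasta = Fasta(fasta)
    pos = table.sites["pos"].to_numpy()
    scaf = table.sites["scaffold"].to_numpy()
    ref = table.sites["ref"].to_numpy()
    alt = table.sites["alt"].to_numpy()
    is_indel = (table.sites["variant_class"] == "indel").to_numpy()
    by_scaffold = {s: np.flatnonzero(scaf == s) for s in dict.fromkeys(scaf)}
    rows = []
    seen = np.zeros(table.n_sites, dtype=bool)
    for gene in genes:
        idx_all = by_scaffold.get(gene.scaffold)
        if idx_all is None:
            continue
        p = pos[idx_all]
        lo, hi = np.searchsorted(p, [gene.start, gene.end + 1])
        idx = idx_all[lo:hi]
        if len(idx) == 0:
            continue
        translatable = bool(gene.cds) and not gene.flagged
        coord = cds_coordinate_map(gene) if translatable else np.array([], int)
        cds_seq = gene_cds_sequence(gene, fasta) if translatable else ""
        cds_set = set(int(x) for x in coord)
        introns = gene.introns()
        for j in idx:
            pj = int(pos[j])
            effect = None
            if is_indel[j]:
                span_end = pj + max(len(ref[j]), 1) - 1
                in_cds = any(s <= span_end and e >= pj for s, e, _ in gene.cds)
                crosses = any((pj < s <= span_end) or (pj <= e < span_end)
                              for s, e, _ in gene.cds)
                if in_cds:
                    if crosses:
                        effect = "frameshift"  # spans an exon boundary: conservative
                    else:
                        delta = abs(len(ref[j]) - len(alt[j]))
                        effect = "frameshift" if delta % 3 else "inframe_indel"
            elif translatable and pj in cds_set:
                effect = _snp_effect(gene, cds_seq, coord, pj, ref[j], alt[j])
            if effect is None:
                for istart, iend in introns:
                    if istart <= pj <= iend:
                        donor_end = (istart, min(istart + 1, iend))
                        accept_end = (max(iend - 1, istart), iend)
                        five_prime = donor_end if gene.strand == "+" else accept_end
                        three_prime = accept_end if gene.strand == "+" else donor_end
                        if five_prime[0] <= pj <= five_prime[1]:
                            effect = "splice_donor"
                        elif three_prime[0] <= pj <= three_prime[1]:
                            effect = "splice_acceptor"
                        break
            if effect is not None:
                rows.append((int(j), gene.gene_id, effect, EFFECT_IMPACT[effect]))
                seen[j] = True
    for j in np.flatnonzero(~seen):
        rows.append((int(j), "", "non_coding", "MODIFIER"))
    df = pd.DataFrame(rows, columns=["site", "gene_id", "effect", "impact"])
    return df.sort_values("site", kind="stable").reset_index(drop=True)


def large_effect_screen(
    effects: pd.DataFrame,
    counts: AlleleCounts,
    table: GenotypeTable,
    pop_m: str,
    pop_nm: str,
    contrast: str = "",
    afd_min: float = 0.9,
) -> dict[str, CandidateGene]:
    """Genes with >= 1 HIGH-impact variant at |p_M - p_NM| > afd_min.

    Run genome-wide, not only in scan candidates, so sweeps that escaped the
    windowed scan can still surface. The AFD of every qualifying variant is
    reported alongside, since hits just under the default 0.9 can matter.
    """
    i_m, i_nm = counts.pop_index(pop_m), counts.pop_index(pop_nm)
    f = counts.freq()
    afd = np.abs(f[i_m] - f[i_nm])
    is_indel = (table.sites["variant_class"] == "indel").to_numpy()
    out: dict[str, CandidateGene] = {}
    high = effects[(effects["impact"] == "HIGH") & (effects["gene_id"] != "")]
    for row in high.itertuples(index=False):
        a = afd[row.site]
        if not np.isfinite(a) or a <= afd_min:
            continue
        tag = "large_effect_indel" if is_indel[row.site] else "large_effect_snp"
        cand = out.setdefault(row.gene_id,
                              CandidateGene(row.gene_id, contrast, set()))
        cand.provenance.add(tag)
        site = table.sites.iloc[row.site]
        cand.variants.append((site["scaffold"], int(site["pos"]),
                              row.effect, float(a)))
    return out


def assemble_candidates(
    *streams: dict[str, CandidateGene],
    genes: list[GeneModel] | None = None,
) -> pd.DataFrame:
    """Union of provenance streams, one record per gene, ordered by locus."""
    merged: dict[str, CandidateGene] = {}
    for stream in streams:
        for gid, cand in stream.items():
            if gid not in merged:
                merged[gid] = CandidateGene(gid, cand.contrast, set())
            tgt = merged[gid]
            tgt.provenance |= cand.provenance
            tgt.windows.extend(cand.windows)
            tgt.variants.extend(cand.variants)
    order = {}
    if genes:
        order = {g.gene_id: (g.scaffold, g.start) for g in genes}
    rows = [
        {
            "gene_id": c.gene_id,
            "contrast": c.contrast,
            "provenance": ",".join(sorted(c.provenance)),
            "n_windows": len(set(c.windows)),
            "metrics": ",".join(sorted({m for _, m in c.windows})),
            "best_afd": max((a for *_, a in c.variants), default=np.nan),
        }
        for c in merged.values()
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "contrast", "provenance",
                                     "n_windows", "metrics", "best_afd"])
    if len(df):
        df["_key"] = df["gene_id"].map(lambda g: order.get(g, ("", 0)))
        df = df.sort_values(["_key", "gene_id"]).drop(columns="_key")
    return df.reset_index(drop=True)


def divergence_scan_candidates(
    signatures: pd.DataFrame,
    windows: pd.DataFrame,
    genes: list[GeneModel],
    contrast: str = "",
) -> dict[str, CandidateGene]:
    """Divergence-scan candidates: gene overlapped by a dXY, FST or DD
    signature window (AFD / Tajima's D signatures support but never promote)."""
    promoting = signatures[signatures["metric"].isin(DIVERGENCE_CANDIDATE_METRICS)]
    cands = genes_overlapping(promoting, windows, genes, contrast,
                              provenance="divergence_scan_995")
    supporting = signatures[~signatures["metric"].isin(DIVERGENCE_CANDIDATE_METRICS)]
    support_map = genes_overlapping(supporting, windows, genes, contrast,
                                    provenance="divergence_scan_995")
    for gid, cand in cands.items():
        if gid in support_map:
            cand.windows.extend(support_map[gid].windows)
    return cands
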