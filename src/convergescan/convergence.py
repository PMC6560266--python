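"""Convergence tests: gene-set overlaps and functional over-representation.

The probability of observing at least the realized overlap between two
candidate lists drawn without replacement from a gene universe is the exact
upper-tail hypergeometric probability; the same distribution drives the
term-level enrichment test (reported at >= 3-fold over-representation and
p < 0.05, mirroring the screening convention for GO biological processes).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class OverlapTest:
    label1: str
    label2: str
    K: int          # size of set 1
    n: int          # size of set 2
    k: int          # observed overlap
    N: int          # universe size
    expected: float
    p_value: float
    overlap_genes: tuple = ()


def hypergeom_overlap(
    set1: set, set2: set, universe: set | int,
    label1: str = "set1", label2: str = "set2",
) -> OverlapTest:
    """Exact upper-tail hypergeometric test P(X >= k) of a set overlap.

    ``universe`` may be an explicit gene set (membership is validated) or a
    plain count when only the universe size is known (e.g. the annotation
    scale of the reference genome).
    """
    set1, set2 = set(set1), set(set2)
    if isinstance(universe, int):
        N = universe
        if N < len(set1 | set2):
            raise ValueError("universe smaller than the union of the sets")
    else:
        universe = set(universe)
        stray = (set1 | set2) - universe
        if stray:
            raise ValueError(f"genes outside the universe: {sorted(stray)[:10]}")
        N = len(universe)
    K, n = len(set1), len(set2)
    k = len(set1 & set2)
    # P(X >= k); sf is exclusive, hence k-1
    p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return OverlapTest(label1, label2, K, n, k, N,
                       expected=K * n / N if N else 0.0, p_value=p,
                       overlap_genes=tuple(sorted(set1 & set2)))


def venn_counts(lists: dict[str, set]) -> dict[str, int]:
    """Exclusive region counts of the Venn diagram over the given sets.

    Keys are '+'-joined sorted label combinations; values sum to |union|.
    """
    labels = sorted(lists)
    all_genes = set().union(*lists.values()) if lists else set()
    regions: dict[str, int] = {}
    for g in all_genes:
        member = tuple(sorted(lab for lab in labels if g in lists[lab]))
        key = "+".join(member)
        regions[key] = regions.get(key, 0) + 1
    return regions


def convergence_matrix(
    candidates: dict[tuple[str, str], set],
    universe: set | int,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """All pairwise overlap tests between per-(species, pair) candidate lists.

    Within-species between-pair overlaps quantify convergence between sites;
    between-species overlaps (same pair and crossed) quantify convergence
    between species. Returns (tests table, Venn region counts).
    """
    if len(candidates) < 2:
        raise ValueError("need >= 2 candidate lists")
    labels = {key: f"{key[0]}:{key[1]}" for key in candidates}
    rows = []
    for key1, key2 in combinations(candidates, 2):
        sp1, pair1 = key1
        sp2, pair2 = key2
        if sp1 == sp2:
            kind = "within_species"
        elif pair1 == pair2:
            kind = "between_species_same_pair"
        else:
            kind = "between_species_crossed"
        t = hypergeom_overlap(candidates[key1], candidates[key2], universe,
                              labels[key1], labels[key2])
        rows.append({
            "set1": labels[key1], "set2": labels[key2], "kind": kind,
            "K": t.K, "n": t.n, "overlap": t.k, "N": t.N,
            "expected": t.expected, "p_value": t.p_value,
            "overlap_genes": ",".join(t.overlap_genes),
        })
    tests = pd.DataFrame(rows)
    venn = venn_counts({labels[k]: set(v) for k, v in candidates.items()})
    return tests, venn


def functional_enrichment(
    candidates: set,
    gene2term: pd.DataFrame,
    universe: set,
    fold_min: float = 3.0,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Per-term hypergeometric over-representation among candidate genes.

    ``gene2term`` has columns gene_id, term (already filtered to the ontology
    levels of interest upstream; no ontology traversal happens here). A term
    is flagged ``reported`` iff fold >= fold_min and p < p_max; a
    Benjamini-Hochberg column is emitted for transparency.
    """
    universe = set(universe)
    candidates = set(candidates) & universe
    g2t = gene2term[gene2term["gene_id"].isin(universe)]
    N, n = len(universe), len(candidates)
    rows = []
    for term, grp in g2t.groupby("term"):
        annotated = set(grp["gene_id"])
        K = len(annotated)
        if K == 0:
            continue
        k = len(annotated & candidates)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        fold = (k / n) / (K / N) if n and K else 0.0
        rows.append({"term": term, "universe_count": K, "candidate_count": k,
                     "fold": fold, "p_value": p})
    skipped = set(gene2term["term"]) - {r["term"] for r in rows}
    df = pd.DataFrame(rows, columns=["term", "universe_count",
                                     "candidate_count", "fold", "p_value"])
    if skipped and len(df) == 0:
        import logging
        logging.getLogger(__name__).warning(
            "terms with no universe annotation skipped: %d", len(skipped))
    if len(df):
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
        m = len(df)
        ranked = df["p_value"].to_numpy() * m / np.arange(1, m + 1)
        df["p_bh"] = np.minimum.accumulate(ranked[::-1])[::-1].clip(0, 1)
        df["reported"] = (df["fold"] >= fold_min) & (df["p_value"] < p_max)
    else:
        df["p_bh"] = pd.Series(dtype=float)
        df["reported"] = pd.Series(dtype=bool)
    return df
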