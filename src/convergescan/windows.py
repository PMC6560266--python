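"""Fixed-size windows of consecutive SNPs.

The unit of all outlier calling is a window of (default) 25 consecutive
usable SNPs on one scaffold; windows never span scaffolds and a trailing
remainder shorter than the window size is dropped. SNP-count windows keep
per-window sampling variance comparable, unlike base-pair windows.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import AlleleCounts, GenotypeTable

log = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZE = 25


def usable_snps(
    table: GenotypeTable,
    counts: AlleleCounts,
    pop1: str,
    pop2: str,
    require_polymorphic: bool = True,
) -> np.ndarray:
    """Indices of biallelic SNPs usable for one contrast.

    A usable SNP is called in both populations and (by default) polymorphic
    within the union of the two; monomorphic-in-pair sites carry no pairwise
    signal. Indels never enter windows.
    """
    i1, i2 = counts.pop_index(pop1), counts.pop_index(pop2)
    mask = table.is_snp()
    mask &= (counts.called[i1] > 0) & (counts.called[i2] > 0)
    if require_polymorphic:
        tot_alt = counts.alt[i1] + counts.alt[i2]
        tot_called = counts.called[i1] + counts.called[i2]
        mask &= (tot_alt > 0) & (tot_alt < tot_called)
    return np.flatnonzero(mask)


def make_windows(
    table: GenotypeTable,
    site_idx: np.ndarray,
    size: int = DEFAULT_WINDOW_SIZE,
    step: int | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Tile consecutive-SNP windows over each scaffold.

    Returns (windows, members): ``windows`` has one row per window
    (window_id, scaffold, pos_first, pos_last, snp_count), ``members`` is an
    (n_windows, size) array of site indices into the genotype table.
    """
    if size < 2:
        raise ValueError("window size must be >= 2")
    step = size if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    scaf = table.sites["scaffold"].to_numpy()[site_idx]
    pos = table.sites["pos"].to_numpy()[site_idx]
    rows, member_rows = [], []
    dropped = 0
    wid = 0
    for s in dict.fromkeys(scaf):
        sel = scaf == s
        local = site_idx[sel]
        lpos = pos[sel]
        n = len(local)
        if n < size:
            log.warning("scaffold %s has %d < %d usable SNPs: no windows", s, n, size)
            dropped += n
            continue
        starts = np.arange(0, n - size + 1, step)
        for st in starts:
            rows.append((wid, s, int(lpos[st]), int(lpos[st + size - 1]), size))
            member_rows.append(local[st:st + size])
            wid += 1
        dropped += n - (starts[-1] + size)
    if dropped:
        log.info("make_windows: %d trailing SNPs dropped", dropped)
    windows = pd.DataFrame(
        rows, columns=["window_id", "scaffold", "pos_first", "pos_last", "snp_count"]
    )
    members = (np.vstack(member_rows) if member_rows
               else np.zeros((0, size), dtype=np.int64))
    return windows, members
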