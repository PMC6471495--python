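"""Locus-level QC: completeness and MAF screens, sliding-window LD pruning."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["PruneParams", "filter_complete", "filter_maf", "ld_prune"]


@dataclass(frozen=True)
class PruneParams:
    """Sliding-window pruning parameters (window in loci, not basepairs)."""

    window_size: int = 50
    step: int = 5
    r2_threshold: float = 0.2

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if not 1 <= self.step <= self.window_size:
            raise ValueError("step must satisfy 1 <= step <= window_size")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in [0, 1]")


def filter_complete(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only loci with zero missing calls; order and samples unchanged."""
    keep = ~(gm.dosage == MISSING).any(axis=0)
    return gm.subset_loci([l for l, k in zip(gm.locus_ids, keep) if k])


def filter_maf(gm: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Keep loci whose minor-allele frequency over typed samples is >= min_maf."""
    keep: list[str] = []
    for j, locus in enumerate(gm.locus_ids):
        col = gm.dosage[:, j]
        typed = col != MISSING
        n = int(typed.sum())
        if n == 0:
            continue
        p = col[typed].sum() / (2.0 * n)
        if min(p, 1.0 - p) >= min_maf:
            keep.append(locus)
    return gm.subset_loci(keep)


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over samples typed at
    both loci; 0 when fewer than 2 complete pairs or either vector is constant."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        logger.warning("fewer than 2 complete sample pairs for a locus pair; r2 := 0")
        return 0.0
    xs = x[ok].astype(float)
    ys = y[ok].astype(float)
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r)


def ld_prune(gm: GenotypeMatrix, params: PruneParams) -> GenotypeMatrix:
    """Greedy sliding-window LD pruning on dosage r².

    Windows of ``window_size`` loci advance by ``step`` over the input order.
    Within a window, while any surviving pair (scanned in order) exceeds the
    threshold, one member is removed: the locus with the higher missing rate,
    breaking ties toward the later locus in input order.
    """
    n_loci = gm.n_loci
    keep = np.ones(n_loci, dtype=bool)
    miss_rate = (gm.dosage == MISSING).mean(axis=0)
    D = gm.dosage

    starts = range(0, max(n_loci - 1, 1), params.step)
    for start in starts:
        window = [j for j in range(start, min(start + params.window_size, n_loci)) if keep[j]]
        changed = True
        while changed and len(window) > 1:
            changed = False
            for a_pos in range(len(window)):
                ja = window[a_pos]
                for jb in window[a_pos + 1 :]:
                    if pairwise_r2(D[:, ja], D[:, jb]) > params.r2_threshold:
                        if miss_rate[ja] > miss_rate[jb]:
                            drop = ja
                        elif miss_rate[jb] > miss_rate[ja]:
                            drop = jb
                        else:
                            drop = max(ja, jb)
                        keep[drop] = False
                        window.remove(drop)
                        changed = True
                        break
                if changed:
                    break
    return gm.subset_loci([l for l, k in zip(gm.locus_ids, keep) if k])
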