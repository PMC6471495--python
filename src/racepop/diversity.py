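"""Per-locus and per-population diversity statistics for biallelic SNPs.

Definitions (p = alt-allele frequency, q = 1 - p, n = typed samples):

* maf = min(p, q)
* ho = heterozygote count / n
* he = 2pq (expected heterozygosity)
* nei = 2n/(2n - 1) * 2pq (unbiased gene diversity)
* shannon_i = -(p ln p + q ln q), with 0 ln 0 := 0
* pic = 1 - (p^2 + q^2) - 2 p^2 q^2  (two-allele Botstein form)

All statistics are computed over typed samples only; loci with fewer than two
typed samples are skipped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_genotypes import MISSING, GenotypeMatrix, SamplePanel

logger = logging.getLogger(__name__)

__all__ = [
    "LocusDiversity",
    "PopulationDiversity",
    "allele_freq",
    "locus_diversity",
    "matrix_diversity",
    "population_diversity",
    "wc_fst",
]

_STATS = ("maf", "ho", "he", "nei", "shannon_i", "pic")


@dataclass(frozen=True)
class LocusDiversity:
    locus_id: str
    n_typed: int
    p_alt: float
    maf: float
    ho: float
    he: float
    nei: float
    shannon_i: float
    pic: float


@dataclass(frozen=True)
class PopulationDiversity:
    population: str
    n_samples: int
    n_loci: int
    maf: float
    ho: float
    he: float
    nei: float
    shannon_i: float
    pic: float


def allele_freq(
    gm: GenotypeMatrix, locus: str, samples: Sequence[str] | None = None
) -> tuple[float, int]:
    """Alt-allele frequency and typed-sample count over a sample subset.

    Returns ``(nan, 0)`` when every call is missing.
    """
    j = gm.locus_index([locus])[0]
    col = gm.dosage[:, j]
    if samples is not None:
        if len(samples) == 0:
            raise ValueError("sample subset must be non-empty")
        col = col[gm.sample_index(samples)]
    typed = col != MISSING
    n = int(typed.sum())
    if n == 0:
        return float("nan"), 0
    return float(col[typed].sum() / (2.0 * n)), n


def _stats_from_counts(n: int, n_het: int, p: float) -> dict[str, float]:
    q = 1.0 - p
    he = 2.0 * p * q
    plogp = p * math.log(p) if p > 0.0 else 0.0
    qlogq = q * math.log(q) if q > 0.0 else 0.0
    return {
        "maf": min(p, q),
        "ho": n_het / n,
        "he": he,
        "nei": (2.0 * n / (2.0 * n - 1.0)) * he,
        "shannon_i": -(plogp + qlogq),
        "pic": 1.0 - (p * p + q * q) - 2.0 * p * p * q * q,
    }


def locus_diversity(
    gm: GenotypeMatrix, locus: str, samples: Sequence[str] | None = None
) -> LocusDiversity:
    """Full per-locus statistics block; requires >= 2 typed samples."""
    j = gm.locus_index([locus])[0]
    col = gm.dosage[:, j]
    if samples is not None:
        col = col[gm.sample_index(samples)]
    typed = col != MISSING
    n = int(typed.sum())
    if n < 2:
        raise ValueError(f"locus {locus!r} has {n} typed samples; need >= 2")
    p = float(col[typed].sum() / (2.0 * n))
    n_het = int((col[typed] == 1).sum())
    s = _stats_from_counts(n, n_het, p)
    return LocusDiversity(locus_id=locus, n_typed=n, p_alt=p, **s)


def matrix_diversity(
    gm: GenotypeMatrix, samples: Sequence[str] | None = None
) -> list[LocusDiversity]:
    """Per-locus statistics for every locus with >= 2 typed samples."""
    idx = gm.sample_index(samples) if samples is not None else slice(None)
    D = gm.dosage[idx]
    out: list[LocusDiversity] = []
    for j, locus in enumerate(gm.locus_ids):
        col = D[:, j]
        typed = col != MISSING
        n = int(typed.sum())
        if n < 2:
            logger.info("skipping locus %s: %d typed samples", locus, n)
            continue
        p = float(col[typed].sum() / (2.0 * n))
        n_het = int((col[typed] == 1).sum())
        s = _stats_from_counts(n, n_het, p)
        out.append(LocusDiversity(locus_id=locus, n_typed=n, p_alt=p, **s))
    return out


def population_diversity(
    gm: GenotypeMatrix,
    panel: SamplePanel,
    grouping: Mapping[str, str] | None = None,
) -> list[PopulationDiversity]:
    """Unweighted across-locus means of the per-locus statistics, per population.

    ``grouping`` maps sample -> population; defaults to the panel's population
    column (falling back to race labels). Every population needs >= 2 samples.
    """
    if grouping is None:
        grouping = panel.population_map()
    pops: dict[str, list[str]] = {}
    for s in gm.sample_ids:
        if s in grouping:
            pops.setdefault(grouping[s], []).append(s)
    out: list[PopulationDiversity] = []
    for pop in sorted(pops):
        members = pops[pop]
        if len(members) < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 samples")
        rows = matrix_diversity(gm, samples=members)
        if not rows:
            raise ValueError(f"population {pop!r} has no loci with >= 2 typed samples")
        means = {
            stat: sum(getattr(r, stat) for r in rows) / len(rows) for stat in _STATS
        }
        out.append(
            PopulationDiversity(
                population=pop, n_samples=len(members), n_loci=len(rows), **means
            )
        )
    return out


def wc_fst(gm: GenotypeMatrix, grouping: Mapping[str, str]) -> float:
    """Weir-Cockerham theta across populations, component sums over loci.

    The 1984 a/b/c variance components for diploid genotype data, ratio of
    summed numerators to summed denominators; loci represented in fewer than
    two populations are skipped.
    """
    labels = np.array([grouping[s] for s in gm.sample_ids])
    names = sorted(set(labels))
    num = den = 0.0
    for j in range(gm.n_loci):
        col = gm.dosage[:, j]
        typed = col != MISSING
        ns, ps, hs = [], [], []
        for name in names:
            m = (labels == name) & typed
            n = int(m.sum())
            if n == 0:
                continue
            ns.append(n)
            ps.append(col[m].sum() / (2.0 * n))
            hs.append(float((col[m] == 1).mean()))
        r = len(ns)
        if r < 2:
            continue
        ns_a = np.array(ns, dtype=float)
        ps_a = np.array(ps)
        hs_a = np.array(hs)
        nbar = ns_a.mean()
        if nbar <= 1:
            continue
        nc = (ns_a.sum() - (ns_a**2).sum() / ns_a.sum()) / (r - 1)
        pbar = (ns_a * ps_a).sum() / ns_a.sum()
        s2 = (ns_a * (ps_a - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (ns_a * hs_a).sum() / ns_a.sum()
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    if den == 0.0:
        raise ValueError("Weir-Cockerham denominator is zero (no polymorphism?)")
    return num / den
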