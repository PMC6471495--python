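"""Supervised ancestry-proportion estimation and the Evanno delta-K utility.

Ancestry proportions q over the three races are fit per sample by maximizing
the binomial genotype likelihood under a mixture allele frequency
``p_mix = sum_r q_r * p_r`` with reference frequencies taken from the pure
accessions of each race. The maximizer is an EM iteration (each allele copy's
source race is the latent variable), which increases the log-likelihood
monotonically.

``delta_k`` post-processes a K -> log-likelihood table (from any clustering
program) with the second-difference statistic; ``k_scan_loglik`` produces such
a table from genotypes via seeded K-means clustering so the utility can be
demonstrated end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io_genotypes import MISSING, PURE_RACES, GenotypeMatrix, Race, SamplePanel

logger = logging.getLogger(__name__)

__all__ = [
    "AncestryEstimate",
    "DeltaKTable",
    "reference_freqs",
    "estimate_q",
    "estimate_panel_q",
    "delta_k",
    "k_scan_loglik",
]

_RACE_ORDER = (Race.M, Race.G, Race.WI)
_FREQ_EPS = 1e-3
_GRAD_TOL = 1e-8
_LL_TOL = 1e-8
_MAX_ITER = 10_000


@dataclass
class AncestryEstimate:
    sample_id: str
    q: np.ndarray  # proportions over (M, G, WI)
    loglik: float
    n_loci_used: int
    loglik_trace: np.ndarray


def reference_freqs(
    gm: GenotypeMatrix, panel: SamplePanel
) -> dict[Race, np.ndarray]:
    """Per-race alt-allele frequency per locus from the pure accessions.

    Frequencies are clamped to [1e-3, 1 - 1e-3] to keep likelihoods finite;
    loci with no typed pure accession in a race get NaN (excluded downstream).
    """
    out: dict[Race, np.ndarray] = {}
    for race in PURE_RACES:
        members = [s for s in panel.samples_of(race) if s in set(gm.sample_ids)]
        if not members:
            raise ValueError(f"no pure accessions of race {race.value} in panel")
        D = gm.dosage[gm.sample_index(members)]
        typed = D != MISSING
        n = typed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, np.where(typed, D, 0).sum(axis=0) / (2.0 * n), np.nan)
        out[race] = np.clip(p, _FREQ_EPS, 1.0 - _FREQ_EPS)
    return out


def _projected_gradient_norm(grad: np.ndarray, q: np.ndarray) -> float:
    # project onto the simplex tangent space, zeroing descent directions
    # blocked by active nonnegativity constraints
    g = grad - grad.mean()
    blocked = (q <= 1e-12) & (g < 0)
    g = np.where(blocked, 0.0, g)
    g -= g[~blocked].mean() if (~blocked).any() else 0.0
    return float(np.linalg.norm(g))


def estimate_q(
    gm: GenotypeMatrix,
    freqs: Mapping[Race, np.ndarray],
    sample: str,
    min_loci: int = 50,
) -> AncestryEstimate:
    """EM fit of ancestry proportions for one sample.

    Uses loci where the sample is typed and all three race frequencies are
    finite; errors if fewer than ``min_loci`` remain. Initialization is the
    uniform simplex point, so an unidentifiable (flat) likelihood returns
    q = (1/3, 1/3, 1/3).
    """
    i = gm.sample_index([sample])[0]
    dos = gm.dosage[i].astype(float)
    P = np.stack([np.asarray(freqs[r], dtype=float) for r in _RACE_ORDER])  # (3, L)
    usable = (gm.dosage[i] != MISSING) & np.isfinite(P).all(axis=0)
    if usable.sum() < min_loci:
        raise ValueError(
            f"sample {sample!r} has {int(usable.sum())} usable loci; need >= {min_loci}"
        )
    g = dos[usable]  # alt copies per locus
    P = P[:, usable]  # (3, L)
    L = g.size

    q = np.full(3, 1.0 / 3.0)
    trace: list[float] = []
    for _ in range(_MAX_ITER):
        p_mix = q @ P
        p_mix = np.clip(p_mix, 1e-12, 1 - 1e-12)
        ll = float((g * np.log(p_mix) + (2 - g) * np.log1p(-p_mix)).sum())
        trace.append(ll)
        # stop on a vanishing projected gradient or (EM being linearly
        # convergent) a vanishing log-likelihood improvement
        grad = (P * (g / p_mix - (2 - g) / (1 - p_mix))[None, :]).sum(axis=1)
        if _projected_gradient_norm(grad, q) < _GRAD_TOL:
            break
        if len(trace) > 1 and trace[-1] - trace[-2] < _LL_TOL:
            break
        # E-step responsibilities per allele copy, M-step closed form
        w_alt = q[:, None] * P / p_mix[None, :]  # (3, L)
        w_ref = q[:, None] * (1 - P) / (1 - p_mix)[None, :]
        counts = (w_alt * g[None, :] + w_ref * (2 - g)[None, :]).sum(axis=1)
        q = counts / (2.0 * L)
        q = np.clip(q, 0.0, 1.0)
        q /= q.sum()
    return AncestryEstimate(
        sample_id=sample,
        q=q,
        loglik=trace[-1],
        n_loci_used=int(L),
        loglik_trace=np.array(trace),
    )


def estimate_panel_q(
    gm: GenotypeMatrix,
    panel: SamplePanel,
    samples: Sequence[str] | None = None,
    min_loci: int = 50,
) -> list[AncestryEstimate]:
    freqs = reference_freqs(gm, panel)
    targets = list(samples) if samples is not None else list(gm.sample_ids)
    return [estimate_q(gm, freqs, s, min_loci=min_loci) for s in targets]


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass
class DeltaKTable:
    ks: list[int]
    mean_l: dict[int, float]
    sd_l: dict[int, float]
    l_prime: dict[int, float]  # mean L(K) - mean L(K-1)
    l_double: dict[int, float]  # |mean L(K+1) - 2 mean L(K) + mean L(K-1)|
    delta_k: dict[int, float]
    best_k: int | None


def delta_k(table: Mapping[int, Sequence[float]]) -> DeltaKTable:
    """Second-difference statistic over replicate log-likelihoods per K.

    Requires >= 3 consecutive K values with >= 2 replicates each. K values
    with zero replicate spread have undefined delta-K and are excluded from
    the argmax (logged).
    """
    ks = sorted(table)
    if len(ks) < 3:
        raise ValueError("need >= 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    for k in ks:
        if len(table[k]) < 2:
            raise ValueError(f"K={k} has fewer than 2 replicates")
    mean_l = {k: float(np.mean(table[k])) for k in ks}
    sd_l = {k: float(np.std(table[k], ddof=1)) for k in ks}
    l_prime = {k: mean_l[k] - mean_l[k - 1] for k in ks[1:]}
    l_double: dict[int, float] = {}
    dk: dict[int, float] = {}
    for k in ks[1:-1]:
        l_double[k] = abs(mean_l[k + 1] - 2.0 * mean_l[k] + mean_l[k - 1])
        if sd_l[k] == 0.0:
            logger.warning("sd(L(K=%d)) = 0; delta-K undefined there", k)
            continue
        dk[k] = l_double[k] / sd_l[k]
    best = max(dk, key=dk.__getitem__) if dk else None
    return DeltaKTable(
        ks=ks,
        mean_l=mean_l,
        sd_l=sd_l,
        l_prime=l_prime,
        l_double=l_double,
        delta_k=dk,
        best_k=best,
    )


def _kmeans(X: np.ndarray, k: int, rng: np.random.Generator, n_iter: int = 50) -> np.ndarray:
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)]
    assign = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        dists = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = dists.argmin(axis=1)
        if (new_assign == assign).all() and _ > 0:
            break
        assign = new_assign
        for c in range(k):
            members = X[assign == c]
            if len(members):
                centers[c] = members.mean(axis=0)
    return assign


def _assignment_loglik(
    assign: np.ndarray, typed: np.ndarray, dosage: np.ndarray, k: int
) -> float:
    """Binomial genotype log-likelihood under per-cluster allele frequencies."""
    ll = 0.0
    for c in range(k):
        members = np.flatnonzero(assign == c)
        if members.size == 0:
            continue
        t = typed[members]
        g = np.where(t, dosage[members], 0.0)
        n2 = 2.0 * t.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n2 > 0, g.sum(axis=0) / n2, 0.5)
        p = np.clip(p, _FREQ_EPS, 1 - _FREQ_EPS)
        ll += float(
            np.where(
                t,
                dosage[members] * np.log(p) + (2 - dosage[members]) * np.log1p(-p),
                0.0,
            ).sum()
        )
    return ll


def k_scan_loglik(
    gm: GenotypeMatrix,
    ks: Sequence[int],
    n_replicates: int = 3,
    seed: int = 0,
    locus_fraction: float = 0.8,
    restarts: int = 8,
) -> dict[int, list[float]]:
    """Binomial log-likelihood of K-cluster hard assignments, per K.

    Each replicate subsamples ``locus_fraction`` of the loci (providing the
    replicate spread delta-K divides by), clusters samples by K-means on
    dosages (best of ``restarts`` seeded restarts by log-likelihood), sets
    per-cluster allele frequencies, and scores the subsampled genotypes.
    Feed the result to :func:`delta_k`.
    """
    rng = np.random.default_rng(seed)
    D = gm.dosage.astype(float)
    typed = gm.dosage != MISSING
    Dz = np.where(typed, D, 1.0)  # mean-ish fill for clustering only
    out: dict[int, list[float]] = {int(k): [] for k in ks}
    n_loci = gm.n_loci
    for _ in range(n_replicates):
        sub = rng.choice(n_loci, size=max(2, int(locus_fraction * n_loci)), replace=False)
        Xs = Dz[:, sub]
        ts = typed[:, sub]
        gs = D[:, sub]
        for k in sorted(out):
            best = -np.inf
            for _r in range(restarts if k > 1 else 1):
                assign = (
                    np.zeros(gm.n_samples, dtype=int) if k == 1 else _kmeans(Xs, k, rng)
                )
                best = max(best, _assignment_loglik(assign, ts, gs, k))
            out[k].append(best)
    return out
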