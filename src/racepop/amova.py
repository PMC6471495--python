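"""Two-level analysis of molecular variance from a squared-distance matrix.

Excoffier-style decomposition: total and within-group sums of squares are
computed from squared pairwise distances, variance components from the mean
squares with the standard unequal-size coefficient, and the Phi-statistic is
the among-group fraction. Significance is assessed by permuting sample labels
across groups (group sizes fixed) with an add-one permutation p-value.

Convention: samples (not haplotypes) are the experimental unit, so
``df_total = N - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .distance_tree import DistanceMatrix
from .io_genotypes import MISSING, GenotypeMatrix

__all__ = ["AmovaResult", "amova_two_level", "amova_allele_level"]


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    sigma2_a: float
    sigma2_b: float
    phi_st: float
    pct_among: float
    p_value: float
    n_permutations: int

    def table(self) -> str:
        return "\n".join(
            [
                "Source of variation     df      SS            Variance     %",
                f"Among populations      {self.df_among:>4d}  {self.ss_among:>12.6f}"
                f"  {self.sigma2_a:>10.6f}  {self.pct_among:>6.2f}",
                f"Within populations     {self.df_within:>4d}  {self.ss_within:>12.6f}"
                f"  {self.sigma2_b:>10.6f}  {100 - self.pct_among:>6.2f}",
                f"Phi_ST = {self.phi_st:.6f}   "
                f"p = {self.p_value:.6g} ({self.n_permutations} permutations)",
                "(df convention: samples as experimental units, df_total = N - 1)",
            ]
        )


def _ss_decomposition(
    d2: np.ndarray, labels: np.ndarray, group_ids: np.ndarray
) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in group_ids:
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return float(ss_total), float(ss_within)


def _phi_from_labels(
    d2: np.ndarray, labels: np.ndarray, group_ids: np.ndarray
) -> tuple[float, float, float, float, float]:
    """(phi, sigma2_a, sigma2_b, ss_among, ss_within)."""
    n = d2.shape[0]
    g = len(group_ids)
    sizes = np.array([(labels == gid).sum() for gid in group_ids])
    ss_total, ss_within = _ss_decomposition(d2, labels, group_ids)
    ss_among = ss_total - ss_within
    df_among = g - 1
    df_within = n - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n - (sizes**2).sum() / n) / df_among
    sigma2_b = ms_within
    sigma2_a = (ms_among - ms_within) / n0
    denom = sigma2_a + sigma2_b
    phi = sigma2_a / denom if denom != 0.0 else 0.0
    return float(phi), float(sigma2_a), float(sigma2_b), float(ss_among), float(ss_within)


def amova_two_level(
    dm: DistanceMatrix,
    grouping: Mapping[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> AmovaResult:
    """Two-level AMOVA with a seeded permutation test.

    ``grouping`` maps every sample in ``dm`` to a population; each population
    needs >= 2 samples and there must be >= 2 populations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    try:
        pops = [grouping[s] for s in dm.sample_ids]
    except KeyError as exc:
        raise KeyError(f"sample {exc.args[0]!r} missing from grouping") from None
    pop_names = sorted(set(pops))
    if len(pop_names) < 2:
        raise ValueError("need >= 2 populations")
    labels = np.array([pop_names.index(p) for p in pops])
    for gid, name in enumerate(pop_names):
        if (labels == gid).sum() < 2:
            raise ValueError(f"population {name!r} has fewer than 2 samples")
    group_ids = np.arange(len(pop_names))

    d2 = dm.d**2
    n = d2.shape[0]
    phi, s2a, s2b, ss_among, ss_within = _phi_from_labels(d2, labels, group_ids)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        phi_p = _phi_from_labels(d2, rng.permutation(labels), group_ids)[0]
        if phi_p >= phi:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_perm)

    return AmovaResult(
        df_among=len(pop_names) - 1,
        df_within=n - len(pop_names),
        ss_among=ss_among,
        ss_within=ss_within,
        sigma2_a=s2a,
        sigma2_b=s2b,
        phi_st=phi,
        pct_among=100.0 * phi,
        p_value=p_value,
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# allele-level AMOVA (haplotype-unit convention)
# ---------------------------------------------------------------------------

def _allele_components(
    dosage: np.ndarray, typed: np.ndarray, member: np.ndarray
) -> tuple[float, float, float, float]:
    """Summed-over-loci allele-unit variance components.

    ``member`` is a (G, N) 0/1 group indicator. Per locus, units are the 2n
    typed allele copies and the distance between two copies is 0/1 identity;
    sums of squares reduce to closed forms in the per-group alt counts.
    Returns (sigma2_a, sigma2_b, ss_among, ss_within) summed across loci.
    """
    n2 = 2.0 * (member @ typed)  # (G, L) typed allele copies per group
    a = member @ np.where(typed, dosage, 0)  # (G, L) alt copies per group
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_w_g = np.where(n2 > 0, a * (n2 - a) / n2, 0.0)
    ss_w = ss_w_g.sum(axis=0)  # (L,)
    N2 = n2.sum(axis=0)
    A = a.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss_t = np.where(N2 > 0, A * (N2 - A) / N2, 0.0)
    ss_a = ss_t - ss_w
    r = (n2 > 0).sum(axis=0).astype(float)  # groups represented per locus
    df_a = r - 1.0
    df_w = N2 - r
    ok = (df_a >= 1.0) & (df_w >= 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ms_a = np.where(ok, ss_a / df_a, 0.0)
        ms_w = np.where(ok, ss_w / df_w, 0.0)
        n0 = np.where(ok, (N2 - (n2**2).sum(axis=0) / N2) / df_a, 1.0)
        s2a = np.where(ok, (ms_a - ms_w) / n0, 0.0)
    s2b = np.where(ok, ms_w, 0.0)
    return float(s2a.sum()), float(s2b.sum()), float(ss_a[ok].sum()), float(ss_w[ok].sum())


def amova_allele_level(
    gm: GenotypeMatrix,
    grouping: Mapping[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> AmovaResult:
    """AMOVA with allele copies as units, locus components summed.

    This is the convention of haplotype-oriented AMOVA software applied to
    unphased SNP genotypes: within-individual heterozygosity contributes to
    the within-population component, so Phi recovers the divergence parameter
    of the generating model (the distance-based two-level variant does not).
    Degrees of freedom are reported for a single average locus (r - 1 and
    2N - r). Permutations move individuals (both allele copies) across groups.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    try:
        pops = [grouping[s] for s in gm.sample_ids]
    except KeyError as exc:
        raise KeyError(f"sample {exc.args[0]!r} missing from grouping") from None
    pop_names = sorted(set(pops))
    if len(pop_names) < 2:
        raise ValueError("need >= 2 populations")
    labels = np.array([pop_names.index(p) for p in pops])
    for gid, name in enumerate(pop_names):
        if (labels == gid).sum() < 2:
            raise ValueError(f"population {name!r} has fewer than 2 samples")

    typed = gm.dosage != MISSING
    dosage = gm.dosage.astype(float)
    G = len(pop_names)
    N = gm.n_samples

    def indicator(lab: np.ndarray) -> np.ndarray:
        M = np.zeros((G, N))
        M[lab, np.arange(N)] = 1.0
        return M

    s2a, s2b, ss_a, ss_w = _allele_components(dosage, typed, indicator(labels))
    denom = s2a + s2b
    phi = s2a / denom if denom != 0.0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p_s2a, p_s2b, _, _ = _allele_components(
            dosage, typed, indicator(rng.permutation(labels))
        )
        p_denom = p_s2a + p_s2b
        phi_p = p_s2a / p_denom if p_denom != 0.0 else 0.0
        if phi_p >= phi:
            exceed += 1
    p_value = (1 + exceed) / (1 + n_perm)

    n_typed_mean = typed.sum() / gm.n_loci
    return AmovaResult(
        df_among=G - 1,
        df_within=int(round(2 * n_typed_mean)) - G,
        ss_among=ss_a,
        ss_within=ss_w,
        sigma2_a=s2a,
        sigma2_b=s2b,
        phi_st=float(phi),
        pct_among=100.0 * float(phi),
        p_value=p_value,
        n_permutations=n_perm,
    )
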