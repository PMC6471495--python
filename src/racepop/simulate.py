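"""Synthetic multi-race SNP panel generator with known ground truth.

Race allele frequencies diverge from a shared ancestral frequency under the
Balding-Nichols model (Beta with mean p and variance F*p*(1-p)). Pure-race
individuals draw alleles binomially from their race frequency; hybrids draw
each allele copy either from an ancestry-weighted mixture ("admixed" mode) or
one copy from each parent race ("f1" mode). Race-diagnostic loci are planted
by overwriting frequencies to fixed differences, and accidental diagnostic
loci are resampled away so the planted set is the exact answer key for marker
discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .io_genotypes import MISSING, PURE_RACES, GenotypeMatrix, Race, SamplePanel

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_panel",
    "mimic_paper_panel",
    "diagnostic_contexts",
]

HybridMode = Literal["admixed", "f1"]

# hybrid class -> (primary parent, secondary parent); hybrid_q ranges apply to
# the primary parent: the M fraction for GxM, the WI fraction for GxWI
_HYBRID_PARENTS = {Race.GXM: (Race.M, Race.G), Race.GXWI: (Race.WI, Race.G)}
_RACE_ORDER = (Race.M, Race.G, Race.WI)


@dataclass
class SimulationConfig:
    n_per_group: dict[Race, int]
    n_loci: int
    divergence_F: float
    n_diagnostic_per_race: int = 0
    missing_rate: float = 0.0
    hybrid_q: dict[Race, tuple[float, float]] = field(
        default_factory=lambda: {Race.GXM: (0.51, 0.84), Race.GXWI: (0.51, 0.84)}
    )
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    hybrid_mode: HybridMode = "admixed"
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not 0.0 <= self.divergence_F < 1.0:
            raise ValueError("divergence_F must be in [0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if 3 * self.n_diagnostic_per_race > self.n_loci:
            raise ValueError("3 * n_diagnostic_per_race exceeds n_loci")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("ancestral_freq_range must lie within (0, 1)")
        for race, (qlo, qhi) in self.hybrid_q.items():
            if not (0.0 <= qlo <= qhi <= 1.0):
                raise ValueError(f"hybrid_q range for {race} outside [0, 1]")
        if self.hybrid_mode not in ("admixed", "f1"):
            raise ValueError(f"unknown hybrid_mode {self.hybrid_mode!r}")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be nonnegative")


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a simulated panel."""

    race_freqs: dict[Race, np.ndarray]  # alt-allele frequency per locus
    diagnostic_loci: dict[Race, list[tuple[str, str]]]  # race -> [(locus_id, allele)]
    sample_q: dict[str, np.ndarray]  # proportions over (M, G, WI)


def _balding_nichols(
    rng: np.random.Generator, p: np.ndarray, F: float
) -> np.ndarray:
    if F == 0.0:
        return p.copy()
    scale = (1.0 - F) / F
    return rng.beta(scale * p, scale * (1.0 - p))


def _draw_genotypes(
    rng: np.random.Generator,
    q: np.ndarray,
    race_freqs: dict[Race, np.ndarray],
    n_loci: int,
    mode: HybridMode,
    parents: tuple[Race, Race] | None,
) -> np.ndarray:
    """Dosage vector for one individual with ancestry q over (M, G, WI)."""
    freq_mat = np.stack([race_freqs[r] for r in _RACE_ORDER])  # (3, L)
    if mode == "f1" and parents is not None:
        a = rng.random(n_loci) < race_freqs[parents[0]]
        b = rng.random(n_loci) < race_freqs[parents[1]]
        return (a.astype(np.int8) + b.astype(np.int8)).astype(np.int8)
    # each of the two allele copies picks a source race from q, then an allele
    dosage = np.zeros(n_loci, dtype=np.int8)
    for _ in range(2):
        src = rng.choice(3, size=n_loci, p=q)
        p_copy = freq_mat[src, np.arange(n_loci)]
        dosage += (rng.random(n_loci) < p_copy).astype(np.int8)
    return dosage


def _pure_fixed_difference(
    dosage_cols: np.ndarray, pure_idx: dict[Race, np.ndarray]
) -> bool:
    """True if any race's pure accessions are fixed for an allele the other two
    pure races completely lack (the realized step-2 predicate)."""
    for race in PURE_RACES:
        own = dosage_cols[pure_idx[race]]
        others = np.concatenate(
            [dosage_cols[pure_idx[r]] for r in PURE_RACES if r is not race]
        )
        if own.size == 0 or others.size == 0:
            continue
        if (own == 2).all() and (others == 0).all():
            return True
        if (own == 0).all() and (others == 2).all():
            return True
    return False


def simulate_panel(
    cfg: SimulationConfig,
) -> tuple[GenotypeMatrix, SamplePanel, SimulationTruth]:
    """Generate a genotype matrix, panel and truth record from ``cfg``.

    Deterministic for a fixed config and seed. Non-planted loci that happen to
    realize a race-wise fixed difference among the pure accessions are redrawn
    so the planted diagnostic set is exactly the discoverable set.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci

    lo, hi = cfg.ancestral_freq_range
    ancestral = rng.uniform(lo, hi, size=L)
    race_freqs = {r: _balding_nichols(rng, ancestral, cfg.divergence_F) for r in _RACE_ORDER}

    # plant diagnostic loci: alt fixed in the target race, ref elsewhere
    diag_idx: dict[Race, np.ndarray] = {}
    cursor = 0
    for race in _RACE_ORDER:
        idx = np.arange(cursor, cursor + cfg.n_diagnostic_per_race)
        diag_idx[race] = idx
        cursor += cfg.n_diagnostic_per_race
        for r in _RACE_ORDER:
            race_freqs[r][idx] = 1.0 if r is race else 0.0
    planted = np.zeros(L, dtype=bool)
    for idx in diag_idx.values():
        planted[idx] = True

    # build sample roster and true ancestries
    sample_ids: list[str] = []
    race_labels: list[Race] = []
    q_true: list[np.ndarray] = []
    parent_pairs: list[tuple[Race, Race] | None] = []
    for race in (Race.M, Race.G, Race.WI, Race.GXM, Race.GXWI, Race.UNKNOWN):
        n = cfg.n_per_group.get(race, 0)
        for k in range(n):
            sample_ids.append(f"{race.value}_{k + 1}")
            race_labels.append(race)
            if race in PURE_RACES:
                q = np.zeros(3)
                q[_RACE_ORDER.index(race)] = 1.0
                parent_pairs.append(None)
            else:
                # UNKNOWN samples are simulated as GxWI hybrids (the panel
                # design this generator mirrors resolved all unknowns as GxWI)
                hclass = race if race in _HYBRID_PARENTS else Race.GXWI
                pa, pb = _HYBRID_PARENTS[hclass]
                qlo, qhi = cfg.hybrid_q.get(hclass, (0.5, 0.5))
                qa = rng.uniform(qlo, qhi)
                q = np.zeros(3)
                q[_RACE_ORDER.index(pa)] = qa
                q[_RACE_ORDER.index(pb)] = 1.0 - qa
                parent_pairs.append((pa, pb))
            q_true.append(q)

    n_samples = len(sample_ids)
    dosage = np.zeros((n_samples, L), dtype=np.int8)
    for i in range(n_samples):
        dosage[i] = _draw_genotypes(
            rng, q_true[i], race_freqs, L, cfg.hybrid_mode, parent_pairs[i]
        )

    # resample accidental diagnostic columns among non-planted loci
    pure_idx = {
        r: np.array([i for i, lab in enumerate(race_labels) if lab is r], dtype=int)
        for r in PURE_RACES
    }
    if all(idx.size > 0 for idx in pure_idx.values()):
        for j in np.flatnonzero(~planted):
            for _ in range(100):
                if not _pure_fixed_difference(dosage[:, j], pure_idx):
                    break
                p = rng.uniform(lo, hi)
                for r in _RACE_ORDER:
                    race_freqs[r][j] = _balding_nichols(
                        rng, np.array([p]), cfg.divergence_F
                    )[0]
                for i in range(n_samples):
                    dosage[i, j] = _draw_genotypes(
                        rng,
                        q_true[i],
                        {r: race_freqs[r][j : j + 1] for r in _RACE_ORDER},
                        1,
                        cfg.hybrid_mode,
                        parent_pairs[i],
                    )[0]
            else:  # pragma: no cover - defensive
                raise RuntimeError(f"could not de-diagnose locus index {j}")

    if cfg.missing_rate > 0.0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING

    locus_ids = [f"chr1:{j + 1}:A:G" for j in range(L)]
    gm = GenotypeMatrix(
        sample_ids,
        locus_ids,
        dosage,
        np.array(["A"] * L),
        np.array(["G"] * L),
    )
    panel = SamplePanel(list(sample_ids), list(race_labels))
    truth = SimulationTruth(
        race_freqs=race_freqs,
        diagnostic_loci={
            race: [(locus_ids[j], "G") for j in diag_idx[race]]
            for race in _RACE_ORDER
        },
        sample_q={s: q for s, q in zip(sample_ids, q_true)},
    )
    return gm, panel, truth


def mimic_paper_panel(
    divergence_F: float,
    seed: int,
    n_loci: int = 2000,
    n_diagnostic_per_race: int = 0,
    missing_rate: float = 0.0,
    hybrid_mode: HybridMode = "admixed",
    n_unknown: int = 0,
) -> tuple[GenotypeMatrix, SamplePanel, SimulationTruth]:
    """21-accession panel: 2 M, 2 G, 3 WI, 7 GxM, 7 GxWI.

    Hybrid ancestry fractions for the first-listed parent race are sampled
    uniformly from [0.51, 0.84]. ``n_unknown`` appends accessions labelled
    UNKNOWN whose true class is GxWI, for classification demos.
    """
    counts = {
        Race.M: 2,
        Race.G: 2,
        Race.WI: 3,
        Race.GXM: 7,
        Race.GXWI: 7,
        Race.UNKNOWN: n_unknown,
    }
    cfg = SimulationConfig(
        n_per_group=counts,
        n_loci=n_loci,
        divergence_F=divergence_F,
        n_diagnostic_per_race=n_diagnostic_per_race,
        missing_rate=missing_rate,
        hybrid_q={Race.GXM: (0.51, 0.84), Race.GXWI: (0.51, 0.84)},
        hybrid_mode=hybrid_mode,
        seed=seed,
    )
    return simulate_panel(cfg)


_BASES = np.array(list("ACGT"))


def diagnostic_contexts(
    gm: GenotypeMatrix,
    truth: SimulationTruth,
    flank: int = 60,
    seed: int = 0,
) -> dict[str, str]:
    """Random flanking sequences with bracketed-SNP notation for planted loci.

    Returns locus_id -> ``"ACGT...[R/A]...TTGC"`` strings (ref listed first),
    suitable input for KASP assay construction.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    pos = {l: j for j, l in enumerate(gm.locus_ids)}
    for loci in truth.diagnostic_loci.values():
        for locus_id, _allele in loci:
            j = pos[locus_id]
            up = "".join(rng.choice(_BASES, size=flank))
            down = "".join(rng.choice(_BASES, size=flank))
            out[locus_id] = f"{up}[{gm.ref[j]}/{gm.alt[j]}]{down}"
    return out
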