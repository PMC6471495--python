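"""Race-diagnostic SNP discovery, KASP assay construction, race classification.

The three-step filter:

1. keep loci with zero missing calls across all labelled (non-UNKNOWN)
   accessions;
2. keep loci where one allele is fixed (frequency 1.00, i.e. all homozygous)
   in the pure accessions of one race and completely absent (0.00) from the
   pure accessions of the other two races;
3. race-conditional hybrid check: a Mexican-diagnostic allele must be carried
   (>= 1 copy) by every GxM hybrid, a West-Indian-diagnostic allele by every
   GxWI hybrid, and a Guatemalan-diagnostic allele by at least
   ceil(11/14 * n_hybrids) of the combined GxM + GxWI hybrids (the 11-of-14
   rule generalized proportionally).

KASP assays attach the standard FAM/VIC tails to allele-specific oligos whose
3' terminal base is the targeted allele; the common primer is a positional
reverse-complement downstream of the SNP. PCR cycling conditions are recorded
as metadata only.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .io_genotypes import (
    MISSING,
    PURE_RACES,
    GenotypeMatrix,
    Race,
    SamplePanel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RaceSpecificLocus",
    "KaspAssay",
    "RaceCall",
    "PCR_PROFILE",
    "FAM_TAIL",
    "VIC_TAIL",
    "find_race_specific_loci",
    "build_kasp_assays",
    "parse_context_fasta",
    "classify_race",
]

FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
VIC_TAIL = "GAAGGTCGGAGTCAACGGATT"

# cycling conditions recorded as assay metadata (no thermodynamics modelled)
PCR_PROFILE: dict[str, str] = {
    "hot_start": "94C 15min",
    "touchdown": "10 cycles: 94C 20s; 61C->58C 60s (-0.8C/cycle)",
    "amplification": "35 cycles: 94C 20s; 57C 60s",
}

_ASSAY_PREFIX = {Race.M: "PaMsSNP", Race.G: "PaGsSNP", Race.WI: "PaWIsSNP"}


@dataclass(frozen=True)
class RaceSpecificLocus:
    locus_id: str
    race: Race
    diagnostic_allele: str  # "ref" or "alt"
    hybrid_support: int


@dataclass(frozen=True)
class KaspAssay:
    assay_name: str
    fam_oligo: str
    vic_oligo: str
    common_primer: str
    target_locus: str
    fam_allele: str
    vic_allele: str
    pcr_profile: Mapping[str, str] = field(default_factory=lambda: dict(PCR_PROFILE))


@dataclass(frozen=True)
class RaceCall:
    sample_id: str
    detected_races: frozenset[Race]
    agreement: dict[Race, float]
    call: str
    reason: str = ""


def _hybrid_threshold(n_hybrids: int) -> int:
    """Generalize the >= 11-of-14 rule proportionally."""
    return math.ceil(11.0 * n_hybrids / 14.0)


def find_race_specific_loci(
    gm: GenotypeMatrix, panel: SamplePanel
) -> list[RaceSpecificLocus]:
    """Apply the three-step filter; output ordered by input locus order."""
    race_map = panel.race_map()
    labelled = [
        s for s in gm.sample_ids if race_map.get(s, Race.UNKNOWN) is not Race.UNKNOWN
    ]
    if not labelled:
        raise ValueError("no labelled accessions in the panel")
    pure_idx = {}
    for race in PURE_RACES:
        members = [s for s in labelled if race_map[s] is race]
        if not members:
            raise ValueError(f"no pure accessions of race {race.value}")
        pure_idx[race] = gm.sample_index(members)
    gxm_idx = gm.sample_index([s for s in labelled if race_map[s] is Race.GXM])
    gxwi_idx = gm.sample_index([s for s in labelled if race_map[s] is Race.GXWI])
    labelled_idx = gm.sample_index(labelled)

    results: list[RaceSpecificLocus] = []
    for j in range(gm.n_loci):
        col = gm.dosage[:, j]
        # step 1: no missing call among labelled accessions
        if (col[labelled_idx] == MISSING).any():
            continue
        # step 2: one race fixed for an allele the other two pure races lack
        hit: tuple[Race, str] | None = None
        for race in PURE_RACES:
            own = col[pure_idx[race]]
            others = [col[pure_idx[r]] for r in PURE_RACES if r is not race]
            if (own == 2).all() and all((o == 0).all() for o in others):
                hit = (race, "alt")
                break
            if (own == 0).all() and all((o == 2).all() for o in others):
                hit = (race, "ref")
                break
        if hit is None:
            continue
        race, allele = hit

        def carries(idx) -> int:
            sub = col[idx]
            if allele == "alt":
                return int((sub >= 1).sum())
            return int((sub <= 1).sum())

        # step 3: race-conditional hybrid presence
        if race is Race.M:
            if len(gxm_idx) == 0:
                logger.warning("no GxM hybrids: step-3 check skipped for M locus %s", gm.locus_ids[j])
                support = 0
            else:
                support = carries(gxm_idx)
                if support < len(gxm_idx):
                    continue
        elif race is Race.WI:
            if len(gxwi_idx) == 0:
                logger.warning("no GxWI hybrids: step-3 check skipped for WI locus %s", gm.locus_ids[j])
                support = 0
            else:
                support = carries(gxwi_idx)
                if support < len(gxwi_idx):
                    continue
        else:  # Guatemalan
            n_hyb = len(gxm_idx) + len(gxwi_idx)
            if n_hyb == 0:
                logger.warning("no hybrids: step-3 check skipped for G locus %s", gm.locus_ids[j])
                support = 0
            else:
                support = carries(gxm_idx) + carries(gxwi_idx)
                if support < _hybrid_threshold(n_hyb):
                    continue
        results.append(
            RaceSpecificLocus(
                locus_id=gm.locus_ids[j],
                race=race,
                diagnostic_allele=allele,
                hybrid_support=support,
            )
        )
    return results


# ---------------------------------------------------------------------------
# KASP assay construction
# ---------------------------------------------------------------------------

_CONTEXT_RE = re.compile(r"^([ACGTacgt]*)\[([ACGT])/([ACGT])\]([ACGTacgt]*)$")


def parse_context_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA of flanking contexts with bracketed-SNP notation."""
    contexts: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                contexts[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line)
    if name is not None:
        contexts[name] = "".join(chunks)
    return contexts


def build_kasp_assays(
    loci: Sequence[RaceSpecificLocus],
    contexts: Mapping[str, str],
    oligo_len: int = 22,
    common_offset: int = 20,
    common_len: int = 22,
) -> list[KaspAssay]:
    """Tailed allele-specific oligos plus a positional common primer.

    The allele-specific oligo is tail + the (oligo_len - 1) bases immediately
    5' of the SNP + the allele base, so the target allele sits at the 3' end.
    FAM reports the first bracketed allele, VIC the second. The common primer
    is the reverse complement of ``common_len`` bases starting
    ``common_offset`` bases 3' of the SNP.
    """
    assays: list[KaspAssay] = []
    counters = {race: 0 for race in _ASSAY_PREFIX}
    for locus in loci:
        ctx = contexts.get(locus.locus_id)
        if ctx is None:
            raise KeyError(f"no flanking context for locus {locus.locus_id!r}")
        m = _CONTEXT_RE.match(ctx.strip())
        if m is None:
            raise ValueError(
                f"context for {locus.locus_id!r} lacks bracketed-SNP notation [X/Y]"
            )
        up, allele1, allele2, down = m.group(1).upper(), m.group(2), m.group(3), m.group(4).upper()
        if len(up) < oligo_len - 1:
            raise ValueError(
                f"insufficient 5' flank for locus {locus.locus_id!r}: "
                f"{len(up)} < {oligo_len - 1}"
            )
        if len(down) < common_offset + common_len:
            raise ValueError(
                f"insufficient 3' flank for locus {locus.locus_id!r}: "
                f"{len(down)} < {common_offset + common_len}"
            )
        stem = up[-(oligo_len - 1):]
        common_template = down[common_offset : common_offset + common_len]
        common = str(Seq(common_template).reverse_complement())
        counters[locus.race] += 1
        assays.append(
            KaspAssay(
                assay_name=f"{_ASSAY_PREFIX[locus.race]}{counters[locus.race]}",
                fam_oligo=FAM_TAIL + stem + allele1,
                vic_oligo=VIC_TAIL + stem + allele2,
                common_primer=common,
                target_locus=locus.locus_id,
                fam_allele=allele1,
                vic_allele=allele2,
            )
        )
    return assays


# ---------------------------------------------------------------------------
# race classification
# ---------------------------------------------------------------------------

_HYBRID_CALL = {
    frozenset((Race.G, Race.M)): "GxM",
    frozenset((Race.G, Race.WI)): "GxWI",
    frozenset((Race.M, Race.WI)): "MxWI",
}


def classify_race(
    gm: GenotypeMatrix,
    markers: Sequence[RaceSpecificLocus],
    samples: Sequence[str] | None = None,
    agreement: float = 1.0,
) -> list[RaceCall]:
    """Score samples against diagnostic markers and call a race or hybrid.

    For each race the agreement fraction is the share of that race's markers
    (non-missing in the sample) at which the sample carries >= 1 copy of the
    diagnostic allele. A race is detected when the fraction >= ``agreement``.
    Exactly one detected race yields a pure call if the sample is homozygous
    diagnostic at >= ``agreement`` of that race's scored markers; exactly two
    yield the corresponding hybrid call; anything else is AMBIGUOUS.
    """
    if not 0.5 < agreement <= 1.0:
        raise ValueError("agreement must be in (0.5, 1]")
    by_race: dict[Race, list[RaceSpecificLocus]] = {}
    for m in markers:
        by_race.setdefault(m.race, []).append(m)
    if len(by_race) < 2:
        raise ValueError("need markers for >= 2 races")
    targets = list(samples) if samples is not None else list(gm.sample_ids)

    calls: list[RaceCall] = []
    for s in targets:
        i = gm.sample_index([s])[0]
        fractions: dict[Race, float] = {}
        hom_fractions: dict[Race, float] = {}
        any_scored = False
        for race, mlist in by_race.items():
            n_scored = carried = hom = 0
            for m in mlist:
                j = gm.locus_index([m.locus_id])[0]
                d = gm.dosage[i, j]
                if d == MISSING:
                    continue
                n_scored += 1
                if m.diagnostic_allele == "alt":
                    carried += int(d >= 1)
                    hom += int(d == 2)
                else:
                    carried += int(d <= 1)
                    hom += int(d == 0)
            if n_scored == 0:
                fractions[race] = 0.0
                hom_fractions[race] = 0.0
                continue
            any_scored = True
            fractions[race] = carried / n_scored
            hom_fractions[race] = hom / n_scored
        if not any_scored:
            calls.append(
                RaceCall(s, frozenset(), fractions, "AMBIGUOUS", "all marker calls missing")
            )
            continue
        detected = frozenset(r for r, f in fractions.items() if f >= agreement)
        if len(detected) == 1:
            (race,) = detected
            if hom_fractions[race] >= agreement:
                calls.append(RaceCall(s, detected, fractions, race.value))
            else:
                calls.append(
                    RaceCall(
                        s,
                        detected,
                        fractions,
                        "AMBIGUOUS",
                        "single race detected but not homozygous diagnostic",
                    )
                )
        elif len(detected) == 2:
            calls.append(RaceCall(s, detected, fractions, _HYBRID_CALL[detected]))
        else:
            calls.append(
                RaceCall(
                    s,
                    detected,
                    fractions,
                    "AMBIGUOUS",
                    f"{len(detected)} races detected",
                )
            )
    return calls
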