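"""Genotype matrix and sample panel containers plus VCF/TSV readers and writers.

All downstream modules consume :class:`GenotypeMatrix` (biallelic, unphased,
with an explicit missing state) and :class:`SamplePanel` (accession -> race
label, optional population grouping). Genotypes are stored internally as
alt-allele dosage (0/1/2) with ``-1`` for missing; the unordered call view
(ref/ref, ref/alt, alt/alt, MISSING) and the dosage view are interconvertible
without information loss.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "Race",
    "GenotypeMatrix",
    "SamplePanel",
    "read_vcf",
    "write_vcf",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "read_panel",
    "write_panel",
]


class Race(str, Enum):
    """Race/hybrid class labels for avocado accessions."""

    M = "M"
    G = "G"
    WI = "WI"
    GXM = "GxM"
    GXWI = "GxWI"
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


PURE_RACES = (Race.M, Race.G, Race.WI)

# accepted spellings, after uppercasing and stripping spaces / unicode times sign
_LABEL_ALIASES = {
    "M": Race.M,
    "MEXICAN": Race.M,
    "G": Race.G,
    "GUATEMALAN": Race.G,
    "WI": Race.WI,
    "WESTINDIAN": Race.WI,
    "GXM": Race.GXM,
    "MXG": Race.GXM,
    "GXWI": Race.GXWI,
    "WIXG": Race.GXWI,
    "UNKNOWN": Race.UNKNOWN,
    "UNK": Race.UNKNOWN,
}


def normalize_race_label(label: str) -> Race:
    """Map a free-form race label to the canonical six-value enum.

    Case-insensitive; spaces and the unicode multiplication sign are ignored,
    so ``"G × M"``, ``"gxm"`` and ``"GxM"`` are equivalent.
    """
    key = label.strip().upper().replace("×", "X").replace(" ", "")
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        admissible = sorted({r.value for r in Race})
        raise ValueError(
            f"unknown race label {label!r}; admissible labels: {admissible}"
        ) from None


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic loci with an explicit missing state.

    Parameters
    ----------
    sample_ids, locus_ids:
        Unique ordered identifiers.
    dosage:
        ``(n_samples, n_loci)`` int8 array of alt-allele counts, ``-1`` for
        missing.
    ref, alt:
        Per-locus single-base allele symbols.
    """

    sample_ids: list[str]
    locus_ids: list[str]
    dosage: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.ref = np.asarray(self.ref, dtype="U8")
        self.alt = np.asarray(self.alt, dtype="U8")
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus_ids are not unique")
        if self.dosage.shape != (self.n_samples, self.n_loci):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"({self.n_samples}, {self.n_loci})"
            )
        bad = ~np.isin(self.dosage, (MISSING, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosage[i, j]} at sample "
                f"{self.sample_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )
        if self.ref.shape != (self.n_loci,) or self.alt.shape != (self.n_loci,):
            raise ValueError("ref/alt allele arrays must have one entry per locus")

    # -- views ----------------------------------------------------------
    def calls(self) -> list[list[tuple[str, str] | None]]:
        """Unordered allele-pair view; ``None`` marks a missing call."""
        out: list[list[tuple[str, str] | None]] = []
        for i in range(self.n_samples):
            row: list[tuple[str, str] | None] = []
            for j in range(self.n_loci):
                d = self.dosage[i, j]
                r, a = self.ref[j], self.alt[j]
                if d == MISSING:
                    row.append(None)
                elif d == 0:
                    row.append((r, r))
                elif d == 1:
                    row.append((r, a))
                else:
                    row.append((a, a))
            out.append(row)
        return out

    @classmethod
    def from_calls(
        cls,
        sample_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: Sequence[Sequence[tuple[str, str] | None]],
        ref: Sequence[str],
        alt: Sequence[str],
    ) -> "GenotypeMatrix":
        """Inverse of :meth:`calls`; the pair order within a call is ignored."""
        dosage = np.full((len(sample_ids), len(locus_ids)), MISSING, dtype=np.int8)
        for i, row in enumerate(calls):
            for j, call in enumerate(row):
                if call is None:
                    continue
                dosage[i, j] = sum(1 for allele in call if allele == alt[j])
        return cls(list(sample_ids), list(locus_ids), dosage, np.array(ref), np.array(alt))

    # -- subsetting ------------------------------------------------------
    def sample_index(self, sample_ids: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown sample {exc.args[0]!r}") from None

    def locus_index(self, locus_ids: Iterable[str]) -> np.ndarray:
        pos = {l: j for j, l in enumerate(self.locus_ids)}
        try:
            return np.array([pos[l] for l in locus_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown locus {exc.args[0]!r}") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(sample_ids)
        return GenotypeMatrix(
            list(sample_ids), list(self.locus_ids), self.dosage[idx], self.ref, self.alt
        )

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.locus_index(locus_ids)
        return GenotypeMatrix(
            list(self.sample_ids),
            list(locus_ids),
            self.dosage[:, idx],
            self.ref[idx],
            self.alt[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.locus_ids == other.locus_ids
            and np.array_equal(self.dosage, other.dosage)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
        )


@dataclass
class SamplePanel:
    """Accession metadata: race label and optional population assignment."""

    sample_ids: list[str]
    race_labels: list[Race]
    populations: list[str | None] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.populations is None:
            self.populations = [None] * len(self.sample_ids)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = sorted(
                {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            )
            raise ValueError(f"duplicate sample ids in panel: {dupes}")
        if not (len(self.sample_ids) == len(self.race_labels) == len(self.populations)):
            raise ValueError("panel columns must have equal length")

    def race_of(self, sample_id: str) -> Race:
        return self.race_labels[self.sample_ids.index(sample_id)]

    def samples_of(self, race: Race) -> list[str]:
        return [s for s, r in zip(self.sample_ids, self.race_labels) if r == race]

    def race_map(self) -> dict[str, Race]:
        return dict(zip(self.sample_ids, self.race_labels))

    def population_map(self) -> dict[str, str]:
        """sample -> population, falling back to the race label."""
        return {
            s: (p if p is not None else r.value)
            for s, r, p in zip(self.sample_ids, self.race_labels, self.populations)
        }

    def subset(self, sample_ids: Sequence[str]) -> "SamplePanel":
        keep = set(sample_ids)
        rows = [
            (s, r, p)
            for s, r, p in zip(self.sample_ids, self.race_labels, self.populations)
            if s in keep
        ]
        return SamplePanel(
            [s for s, _, _ in rows], [r for _, r, _ in rows], [p for _, _, p in rows]
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_SNP_BASES = {"A", "C", "G", "T"}
_LOCUS_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+)(?::(?P<rest>.*))?$")


def read_vcf(path: str | Path, strict: bool = False) -> GenotypeMatrix:
    """Read a VCF v4.x file into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are retained. Multiallelic or non-SNP records
    are skipped with a warning, or rejected when ``strict`` is true. Phased
    separators are treated as unphased; half-calls and ``./.`` map to MISSING.
    """
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    locus_ids: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1 or variant.REF not in _SNP_BASES or variant.ALT[0] not in _SNP_BASES:
            locus = f"{variant.CHROM}:{variant.POS}"
            if strict:
                raise ValueError(f"non-biallelic-SNP record at {locus}")
            logger.warning("skipping non-biallelic-SNP record at %s", locus)
            continue
        vid = variant.ID
        if vid is None or vid == ".":
            vid = f"{variant.CHROM}:{variant.POS}:{variant.REF}:{variant.ALT[0]}"
        locus_ids.append(vid)
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(variant.gt_types)
        col = np.full(len(sample_ids), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        rows.append(col)
    dosage = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypeMatrix(sample_ids, locus_ids, dosage, np.array(refs), np.array(alts))


_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal GT-only VCF v4.2.

    CHROM/POS are parsed from ``chrom:pos[:...]`` locus ids when possible;
    otherwise a synthetic contig with 1-based running positions is used.
    """
    records = []
    contigs: list[str] = []
    for j, locus in enumerate(gm.locus_ids):
        m = _LOCUS_ID_RE.match(locus)
        if m:
            chrom, pos = m.group("chrom"), m.group("pos")
        else:
            chrom, pos = "synthetic_1", str(j + 1)
        if chrom not in contigs:
            contigs.append(chrom)
        gts = "\t".join(_GT_STRINGS[int(d)] for d in gm.dosage[:, j])
        row = f"{chrom}\t{pos}\t{locus}\t{gm.ref[j]}\t{gm.alt[j]}\t.\t.\t.\tGT"
        if gts:
            row += "\t" + gts
        records.append(row)
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    if gm.sample_ids:
        header += "\t" + "\t".join(gm.sample_ids)
    lines = (
        ["##fileformat=VCFv4.2"]
        + [f"##contig=<ID={c}>" for c in contigs]
        + ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">', header]
        + records
    )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# TSV dialects
# ---------------------------------------------------------------------------

def read_tsv_matrix(path: str | Path) -> GenotypeMatrix:
    """Read the project TSV dosage dialect.

    First column is the locus id, remaining columns are samples; cells are
    alt-allele dosage in ``{0, 1, 2, NA}``. Allele symbols are not carried by
    this format and default to ref=A, alt=B placeholders.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    locus_ids = df.iloc[:, 0].tolist()
    sample_ids = list(df.columns[1:])
    dosage = np.full((len(sample_ids), len(locus_ids)), MISSING, dtype=np.int8)
    for j, (_, row) in enumerate(df.iterrows()):
        for i, sample in enumerate(sample_ids):
            cell = row[sample].strip()
            if cell == "NA":
                continue
            if cell not in {"0", "1", "2"}:
                raise ValueError(
                    f"invalid cell {cell!r} at locus {locus_ids[j]!r}, "
                    f"sample {sample!r}: expected one of 0,1,2,NA"
                )
            dosage[i, j] = int(cell)
    n = len(locus_ids)
    return GenotypeMatrix(
        sample_ids, locus_ids, dosage, np.array(["A"] * n), np.array(["B"] * n)
    )


def write_tsv_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dosage dialect (allele symbols are not preserved)."""
    with open(path, "w") as fh:
        fh.write("locus_id\t" + "\t".join(gm.sample_ids) + "\n")
        for j, locus in enumerate(gm.locus_ids):
            cells = [
                "NA" if d == MISSING else str(int(d)) for d in gm.dosage[:, j]
            ]
            fh.write(locus + "\t" + "\t".join(cells) + "\n")


def read_panel(path: str | Path) -> SamplePanel:
    """Read a sample panel TSV with columns sample_id, race_label[, population]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "race_label" not in cols:
        raise ValueError("panel must have columns sample_id and race_label")
    sample_ids = df[cols["sample_id"]].tolist()
    races = [normalize_race_label(x) for x in df[cols["race_label"]]]
    populations: list[str | None]
    if "population" in cols:
        populations = [x if x != "" else None for x in df[cols["population"]]]
    else:
        populations = [None] * len(sample_ids)
    return SamplePanel(sample_ids, races, populations)


def write_panel(panel: SamplePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\trace_label\tpopulation\n")
        for s, r, p in zip(panel.sample_ids, panel.race_labels, panel.populations):
            fh.write(f"{s}\t{r.value}\t{p if p is not None else ''}\n")


def check_panel_covers(gm: GenotypeMatrix, panel: SamplePanel) -> None:
    """Every matrix sample must appear exactly once in the panel."""
    missing = [s for s in gm.sample_ids if s not in set(panel.sample_ids)]
    if missing:
        raise ValueError(f"samples absent from panel: {missing}")
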