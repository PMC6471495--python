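"""End-to-end orchestration: filter -> prune -> diversity -> tree -> PCoA ->
AMOVA -> ancestry -> markers -> classification, from a single YAML config.

Outputs are plain text (TSV, Newick, JSON); a manifest records every produced
file with the stage parameters and input checksums so identical config +
inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .amova import amova_two_level
from .ancestry import delta_k, estimate_panel_q, k_scan_loglik
from .distance_tree import ibs_distance, upgma, write_distance_tsv, write_newick
from .diversity import population_diversity
from .io_genotypes import (
    GenotypeMatrix,
    Race,
    SamplePanel,
    check_panel_covers,
    read_panel,
    read_tsv_matrix,
    read_vcf,
)
from .ordination import pcoa, write_pcoa_tsv
from .qc_filters import PruneParams, filter_complete, ld_prune
from .race_markers import (
    build_kasp_assays,
    classify_race,
    find_race_specific_loci,
    parse_context_fasta,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_ALL_STAGES = (
    "filter",
    "prune",
    "diversity",
    "tree",
    "pcoa",
    "amova",
    "ancestry",
    "markers",
    "classify",
)


@dataclass
class PipelineConfig:
    genotypes: str
    panel: str
    out_dir: str
    contexts: str | None = None
    unknowns: str | None = None
    stages: list[str] = field(default_factory=lambda: list(_ALL_STAGES))
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.2
    amova_permutations: int = 1000
    pcoa_axes: int = 3
    marker_agreement: float = 1.0
    ancestry_min_loci: int = 50
    deltak_ks: list[int] = field(default_factory=lambda: [1, 2, 3, 4, 5])
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.genotypes, self.panel, self.contexts, self.unknowns):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _load_genotypes(path: str) -> GenotypeMatrix:
    if path.endswith((".tsv", ".txt")):
        return read_tsv_matrix(path)
    return read_vcf(path)


def run_pipeline(cfg: PipelineConfig) -> dict[str, Any]:
    """Execute enabled stages in dependency order; returns the manifest."""
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "racepop_version": __version__,
        "seed": cfg.seed,
        "inputs": {
            "genotypes": {"path": cfg.genotypes, "sha256": _sha256(cfg.genotypes)},
            "panel": {"path": cfg.panel, "sha256": _sha256(cfg.panel)},
        },
        "stages": {},
        "outputs": {},
    }
    if cfg.contexts:
        manifest["inputs"]["contexts"] = {
            "path": cfg.contexts,
            "sha256": _sha256(cfg.contexts),
        }

    gm = _load_genotypes(cfg.genotypes)
    panel = read_panel(cfg.panel)
    check_panel_covers(gm, panel)
    enabled = set(cfg.stages)

    def record(stage: str, name: str, path: Path, params: dict[str, Any]) -> None:
        manifest["stages"][stage] = {"params": params}
        manifest["outputs"][name] = str(path)

    def fail_fast(stage: str, needs: str) -> None:
        raise RuntimeError(f"stage {stage!r} requires disabled stage {needs!r}")

    gm_work = gm
    if "filter" in enabled:
        gm_work = filter_complete(gm_work)
        path = out_dir / "filtered.counts.txt"
        path.write_text(
            f"input_loci\t{gm.n_loci}\nretained_loci\t{gm_work.n_loci}\n"
        )
        record("filter", "filter_counts", path, {})

    if "prune" in enabled:
        params = PruneParams(cfg.prune_window, cfg.prune_step, cfg.prune_r2)
        gm_work = ld_prune(gm_work, params)
        path = out_dir / "pruned.loci.txt"
        path.write_text("\n".join(gm_work.locus_ids) + "\n")
        record(
            "prune",
            "pruned_loci",
            path,
            {"window": params.window_size, "step": params.step, "r2": params.r2_threshold},
        )

    labelled = [
        s
        for s, r in zip(panel.sample_ids, panel.race_labels)
        if r is not Race.UNKNOWN and s in set(gm_work.sample_ids)
    ]
    gm_labelled = gm_work.subset_samples(labelled) if labelled else gm_work

    dm = None
    if {"tree", "pcoa", "amova"} & enabled:
        dm = ibs_distance(gm_labelled)
        path = out_dir / "distances.tsv"
        write_distance_tsv(dm, path)
        manifest["outputs"]["distances"] = str(path)

    if "diversity" in enabled:
        rows = population_diversity(gm_labelled, panel.subset(labelled))
        path = out_dir / "diversity.tsv"
        with open(path, "w") as fh:
            fh.write("population\tn_samples\tn_loci\tHo\tHe\tNei\tI\tPIC\tMAF\n")
            for r in rows:
                fh.write(
                    f"{r.population}\t{r.n_samples}\t{r.n_loci}\t{r.ho:.4f}\t"
                    f"{r.he:.4f}\t{r.nei:.4f}\t{r.shannon_i:.4f}\t{r.pic:.4f}\t"
                    f"{r.maf:.4f}\n"
                )
        record("diversity", "diversity", path, {})

    if "tree" in enabled:
        if dm is None:  # pragma: no cover - defensive
            fail_fast("tree", "distances")
        tree = upgma(dm)
        path = out_dir / "tree.nwk"
        write_newick(tree, path)
        record("tree", "tree", path, {})

    if "pcoa" in enabled:
        if dm is None:  # pragma: no cover - defensive
            fail_fast("pcoa", "distances")
        res = pcoa(dm, n_axes=cfg.pcoa_axes)
        path = out_dir / "pcoa.tsv"
        write_pcoa_tsv(res, path)
        record("pcoa", "pcoa", path, {"axes": cfg.pcoa_axes})

    if "amova" in enabled:
        if dm is None:  # pragma: no cover - defensive
            fail_fast("amova", "distances")
        grouping = panel.subset(labelled).population_map()
        res = amova_two_level(
            dm,
            grouping,
            n_perm=cfg.amova_permutations,
            seed=cfg.stage_seed("amova"),
        )
        path = out_dir / "amova.txt"
        path.write_text(res.table() + "\n")
        record(
            "amova",
            "amova",
            path,
            {"permutations": cfg.amova_permutations, "seed": cfg.stage_seed("amova")},
        )

    if "ancestry" in enabled:
        estimates = estimate_panel_q(
            gm_work, panel, min_loci=cfg.ancestry_min_loci
        )
        path = out_dir / "q.tsv"
        with open(path, "w") as fh:
            fh.write("sample_id\tq_M\tq_G\tq_WI\tloglik\tn_loci\n")
            for e in estimates:
                fh.write(
                    f"{e.sample_id}\t{e.q[0]:.6f}\t{e.q[1]:.6f}\t{e.q[2]:.6f}\t"
                    f"{e.loglik:.4f}\t{e.n_loci_used}\n"
                )
        table = k_scan_loglik(
            gm_labelled, cfg.deltak_ks, seed=cfg.stage_seed("deltak")
        )
        dk = delta_k(table)
        dk_path = out_dir / "deltak.tsv"
        with open(dk_path, "w") as fh:
            fh.write("K\tmean_L\tsd_L\tdeltaK\n")
            for k in dk.ks:
                dkv = dk.delta_k.get(k)
                fh.write(
                    f"{k}\t{dk.mean_l[k]:.4f}\t{dk.sd_l[k]:.4f}\t"
                    f"{dkv if dkv is None else f'{dkv:.4f}'}\n"
                )
        record("ancestry", "ancestry_q", path, {"min_loci": cfg.ancestry_min_loci})
        manifest["outputs"]["deltak"] = str(dk_path)
        manifest["stages"]["ancestry"]["best_k"] = dk.best_k

    markers = None
    if "markers" in enabled:
        markers = find_race_specific_loci(gm, panel)
        path = out_dir / "markers.tsv"
        with open(path, "w") as fh:
            fh.write("locus_id\trace\tdiagnostic_allele\thybrid_support\n")
            for m in markers:
                fh.write(
                    f"{m.locus_id}\t{m.race.value}\t{m.diagnostic_allele}\t"
                    f"{m.hybrid_support}\n"
                )
        record("markers", "markers", path, {})
        if cfg.contexts:
            contexts = parse_context_fasta(cfg.contexts)
            assays = build_kasp_assays(
                [m for m in markers if m.locus_id in contexts], contexts
            )
            apath = out_dir / "kasp_assays.tsv"
            with open(apath, "w") as fh:
                fh.write(
                    "assay_name\ttarget_locus\tfam_oligo\tvic_oligo\tcommon_primer\n"
                )
                for a in assays:
                    fh.write(
                        f"{a.assay_name}\t{a.target_locus}\t{a.fam_oligo}\t"
                        f"{a.vic_oligo}\t{a.common_primer}\n"
                    )
            manifest["outputs"]["kasp_assays"] = str(apath)

    if "classify" in enabled:
        if markers is None:
            fail_fast("classify", "markers")
        if cfg.unknowns:
            targets = [
                s
                for s in Path(cfg.unknowns).read_text().split()
                if s in set(gm.sample_ids)
            ]
        else:
            targets = [
                s
                for s, r in zip(panel.sample_ids, panel.race_labels)
                if r is Race.UNKNOWN and s in set(gm.sample_ids)
            ]
        calls = classify_race(gm, markers, targets, agreement=cfg.marker_agreement)
        path = out_dir / "calls.tsv"
        with open(path, "w") as fh:
            fh.write("sample_id\tcall\tdetected_races\treason\n")
            for c in calls:
                races = ",".join(sorted(r.value for r in c.detected_races))
                fh.write(f"{c.sample_id}\t{c.call}\t{races}\t{c.reason}\n")
        record("classify", "calls", path, {"agreement": cfg.marker_agreement})

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
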