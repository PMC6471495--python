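# racepop

Analysis toolkit for race-structured SNP panels, built around the workflow of
a multi-race germplasm study: genotype I/O, a synthetic multi-race panel
simulator with planted ground truth, locus QC and LD pruning, diversity
statistics, IBS distance + UPGMA trees, PCoA, AMOVA with permutation testing,
supervised ancestry proportions with an Evanno delta-K utility, and a
three-step race-diagnostic SNP filter with KASP assay construction and race
classification of unknown accessions.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the oracle-equivalence, parameter-recovery
and qualitative-structure checks (one test class per criterion); the other
modules have unit and property tests alongside.

## Library overview

| module | contents |
| --- | --- |
| `racepop.io_genotypes` | `GenotypeMatrix` (biallelic, unphased, explicit missing state), `SamplePanel`, VCF + TSV readers/writers |
| `racepop.simulate` | `simulate_panel` (Balding–Nichols race divergence, admixed or F1 hybrids, planted diagnostic loci), `mimic_paper_panel` (21-accession design: 2 M, 2 G, 3 WI, 7 GxM, 7 GxWI) |
| `racepop.qc_filters` | `filter_complete`, `filter_maf`, sliding-window `ld_prune` (window 50 / step 5 / r² 0.2 defaults) |
| `racepop.diversity` | per-locus and per-population MAF/Ho/He/Nei/I/PIC, Weir–Cockerham FST |
| `racepop.distance_tree` | IBS distance, UPGMA with deterministic tie-breaking, Newick export |
| `racepop.ordination` | classical PCoA (Gower centering; negative eigenvalues excluded, logged) |
| `racepop.amova` | distance-based two-level AMOVA and allele-unit AMOVA, both with seeded permutation p-values |
| `racepop.ancestry` | supervised EM ancestry proportions over (M, G, WI), Evanno delta-K, K-scan likelihood helper |
| `racepop.race_markers` | three-step race-specific locus filter, KASP oligo construction (FAM/VIC tails, 3' SNP), race calling |
| `racepop.pipeline` | YAML-configured end-to-end run with manifest + checksums |

## CLI

```bash
racepop simulate --config sim.yaml --out panel      # VCF + panel TSV + truth JSON
racepop validate panel.vcf panel.panel.tsv
racepop prune panel.vcf pruned.vcf --window 50 --step 5 --r2 0.2
racepop diversity pruned.vcf panel.panel.tsv --out diversity.tsv
racepop tree pruned.vcf --out tree.nwk --distances dist.tsv
racepop pcoa dist.tsv --axes 3 --out pcoa.tsv
racepop amova dist.tsv panel.panel.tsv --perms 10000 --seed 7 --out amova.txt
racepop ancestry pruned.vcf panel.panel.tsv --out q.tsv
racepop deltak likelihoods.tsv --out deltak.tsv
racepop markers panel.vcf panel.panel.tsv --out markers.tsv
racepop kasp markers.tsv contexts.fasta --out assays.tsv
racepop classify panel.vcf markers.tsv --out calls.tsv
racepop run --config pipeline.yaml                  # full pipeline + manifest
```

Marker contexts are FASTA records with bracketed-SNP notation in the
sequence, e.g. `ACGT...[A/G]...TTGC`.

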