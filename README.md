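# rnasomatic

Tumor-only RNA-seq somatic mutation calling as a tested library + CLI:
annotation-driven negative/rescue variant filtering, DNA-truth-guided filter
optimization, and downstream cohort statistics (mutation landscape, tumor
mutational burden per expressed megabase, pathway mutation status, and
survival analysis), together with a synthetic-cohort simulator that stands in
for non-distributable patient sequencing data.

## What it does

The pipeline consumes lenient tumor RNA-seq variant calls (VCF) plus
annotation resources and applies stringent post-hoc filtering:

- **Negative filters**: low-complexity regions, SNP status (database-common
  SNPs not present in the somatic catalogue, SweGen, high population allele
  frequency), VAF >= 0.05, depth >= 8, homopolymer context, RNA-editing
  sites, and a panel of normals built from non-tumoral tissue callsets.
- **Rescue filters**: curated clinical-database membership and recurrent
  somatic-catalogue hotspots reinstate filtered variants.
- **Filter optimization**: RNA variants are partitioned against matched DNA
  callsets (somatic-in-DNA / germline-in-DNA / RNA-unique) and the filter
  variable space is grid-searched for the best sensitivity/specificity
  balance (Youden's J by default).
- **Cohort analysis**: substitution spectra, gene x sample matrices and
  waterfall ordering, hotspot tables, druggable fraction, Fisher association
  tests, TMB per expressed megabase with median high/low stratification,
  binary pathway status with Ward/Euclidean clustering, and Kaplan-Meier /
  Cox survival analysis across treatment and biomarker subgroups.
- **Simulation**: expression-proportional coverage, class-specific VAF and
  recurrence signatures for somatic/germline/editing/artifact variants,
  nonsense-mediated-decay dropout of truncating tumor-suppressor variants,
  and proportional-hazards survival linked to mutation status.

## CLI

```bash
# generate a synthetic cohort bundle
rnasomatic simulate --seed 7 --n-samples 60 --out bundle/

# derive filter thresholds against DNA truth
rnasomatic optimize --rna-vcfs bundle/rna --dna-somatic bundle/dna_somatic \
    --dna-germline bundle/dna_germline --resources bundle/resources \
    --reference bundle/reference.fa --grid grid.yaml --out opt/

# apply filters, then downstream analyses
rnasomatic filter --vcf-dir bundle/rna --resources bundle/resources \
    --reference bundle/reference.fa --out filtered/
rnasomatic landscape --vcf-dir filtered/passed --clinical bundle/clinical.tsv \
    --resources bundle/resources --out landscape/
rnasomatic tmb --vcf-dir filtered/passed --track-dir bundle/tracks --out tmb.tsv
rnasomatic pathways --vcf-dir filtered/passed --gmt bundle/pathways.gmt \
    --clinical bundle/clinical.tsv --out pathways/
rnasomatic survive --vcf-dir filtered/passed --clinical bundle/clinical.tsv \
    --by gene:GENE01 --subgroup endo_only --out surv/
rnasomatic report --analysis-dir . --out report.html
```

Every subcommand writes a `manifest.json` recording the command, config
hash, input checksums, tool version, and seed.

## Layout

```
src/rnasomatic/
  io_core.py    domain types; VCF/BED/FASTA/TSV/GMT IO; variant normalization
  annotate.py   annotation index joins, homopolymer runs, coding effects, PoN
  filters.py    negative/rescue predicate engine with per-variant audits
  optimize.py   DNA-truth concordance, config scoring, grid search
  landscape.py  spectra, matrices, hotspot tables, Fisher tests
  burden.py     callable regions and TMB per expressed megabase
  pathways.py   binary pathway status + Ward clustering
  survival.py   subgroups, KM/log-rank, Cox (Efron ties, PH check)
  simulate.py   synthetic cohort generator (the test substrate)
  cli.py        `rnasomatic` entry point and run manifests
```
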