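# solphos

Solubility proteome profiling and condensate-specific phosphosite analysis,
re-implemented as a tested, reusable Python pipeline.  Every stage can be
exercised end-to-end on synthetic data with planted ground truth — no
external downloads are required.

## What it does

The pipeline quantifies which subpools of a proteome are condensate-bound
and which phosphorylation events are specific to those subpools:

- **`solphos.simulate`** — generators for every input the pipeline
  consumes: a 2×2 solubility design (NP-40/SDS detergent × RNA-preserved/
  RNA-digested lysate, 3 replicates) with lognormal intensity noise and
  planted protein classes; substoichiometric phosphopeptides with planted
  solubility/RNA-bound shifts and MS quality-control fields; random protein
  sequences; perturbation fold-change matrices; disk-shaped nucleoli on
  noisy images with known partition coefficients.  Deterministic per seed,
  with a fixed per-stage seed derivation.
- **`solphos.normalization`** — selection of a "predominantly soluble"
  calibration subset (raw NP-40/SDS ratio in [0.8, 1.2]) and a
  variance-stabilizing normalization (per-sample scale + generalized-log
  transform + median alignment) fit on that subset and applied to all
  features.  A pure median-scaling mode is available for exactness checks.
- **`solphos.diffsol`** — solubility S = log2(NP-40/SDS) per replicate and
  lysate, RNA-bound fraction RBF = S_preserved − S_digested, moderated
  t-tests with empirical-Bayes variance shrinkage (method-of-moments on log
  residual variances), Benjamini–Hochberg adjustment, three-way protein
  classification (predominantly soluble / RNase-sensitive insoluble /
  RNase-insensitive insoluble), and phosphopeptide-vs-parent-protein
  differential tests.
- **`solphos.phospho`** — peptide QC (signal-to-interference ≥ 0.5,
  precursor-to-threshold ≥ 4, quantified in all replicates), collapsing to
  unique phosphorylation patterns by summing variant intensities,
  reproducibility filter (replicate solubility s.d. < 1), and rule-based
  site categories: soluble / insoluble / facilitates_RNA / represses_RNA /
  not_changing / ambiguous.
- **`solphos.seqfeat`** — 31-residue windows around phosphosites:
  Kyte–Doolittle hydropathy, f+/f−/FCR/NCPR with phospho-adjusted charges
  (−2 per phosphosite), the charge-patterning parameter κ (blob sizes 5 and
  6, δ_max by exact enumeration for small compositions and by the
  maximally-segregated construction otherwise), charge–hydropathy disorder
  classification, and sliding NCPR profiles.
- **`solphos.enrich`** — hypergeometric over-representation with BH
  correction (GMT annotation sets) and phosphosite-activity z-tests of a
  subgroup's fold changes against all sites per condition.
- **`solphos.imaging`** — nucleolus partition coefficients from intensity
  images + label masks: Euclidean-distance rims (inner 1, outer 6 px),
  background ROI subtraction, area (> 1,000 px²) and intensity (20×
  background) filters, WT-median normalization, and per-nucleus coefficient
  of variation.
- **`solphos.ipquant`** — pulldown arithmetic: interactor definition
  (log2FC > 1, adj. p < 0.01 vs tag-only), input- and bait-corrected
  mutant/WT fold changes, and phosphodeficient-vs-phosphomimetic t-tests.
- **`solphos.pipeline` / `solphos.cli`** — orchestration and a `solphos`
  command-line entry point.

## CLI

```sh
solphos simulate solubility --seed 1 --out out/sim
solphos normalize --table out/sim/proteins.tsv --out out/norm
solphos diffsol --table out/norm/normalized.tsv --out out/diff
solphos simulate sequences --n 20 --seed 1 --out out/seqs
solphos seqfeat --fasta out/seqs/sequences.fasta --sites out/seqs/sites.tsv --out out/feat
solphos simulate image --seed 1 --out out/img
solphos imaging --intensity out/img/intensity.tiff --labels out/img/labels.tiff --out out/part
solphos run --seed 1 --out out/full     # full simulated workflow
```

Intensity tables are TSVs with a sibling `<name>.samples.tsv` describing
each column (detergent, lysate, replicate).  Annotation sets are GMT;
sequences FASTA; images TIFF; configs YAML.

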