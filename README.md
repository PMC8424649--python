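# repeatlens

Toolkit for quantifying somatic repeat instability from capillary-
electrophoresis fragment data, with companion modules for expansion
kinetics statistics, microsatellite-instability (MSI/EMAST) panel
classification, crosslinking-MS post-processing against protein
structures, and a synthetic-data generator so the whole pipeline is
testable without any external downloads.

## What it does

- **`repeatlens.fragio`** — read/write tab-delimited peak-table exports
  (GeneMapper-style "Genotypes table" layout, configurable column names)
  and sample manifests.
- **`repeatlens.repeatcall`** — calibrated bp → repeat-unit conversion,
  biallelic allele splitting at the repeat-space midpoint, modal allele
  calling (ties break low, with a review warning), and the inclusive
  20%-of-modal-peak-height inclusion threshold that suppresses PCR
  stutter.
- **`repeatlens.instability`** — signed instability index and
  non-negative expansion index (normalized height-weighted change from
  the modal allele over the included peaks), modal change vs baseline,
  and time-course assembly.
- **`repeatlens.cohortstats`** — per-replicate OLS expansion rates,
  trapezoidal AUC, one-way ANOVA on slopes (ANCOVA interaction test as
  an alternative mode), Benjamini–Hochberg FDR (two-stage BKY
  selectable), Brown–Forsythe homogeneity check, independent t tests.
- **`repeatlens.msi`** — per-locus allele calling and stable/unstable
  classification against a matched baseline over an 18-locus panel
  (mono/di/tetra markers + pentanucleotide controls), with an EMAST flag
  and control-locus QC.
- **`repeatlens.xlinkseq`** — crosslink-table parsing, strict score
  filtering, unique residue-pair counting, Cα–Cα distance measurement on
  PDB/mmCIF structures via chain/offset maps, crosslinker-span
  consistency flagging, alignment consensus profiles, motif scanning and
  residue-span arithmetic.
- **`repeatlens.synthgen`** — a per-day biased unit-step random-walk
  population model, rendering to realistic peak tables (geometric
  stutter ladders, sizing jitter, height noise), plus packaged fixtures:
  a biallelic 20/118-repeat cell-line-like time course, MSI panel tables
  with injected shifts, and a crosslink table + toy structure.

## CLI

```sh
repeatlens simulate --out fixture/ --seed 1
repeatlens call --peaks fixture/FL_like_r1_d0.tsv ... --config panel.yaml --out calls.csv
repeatlens index --calls calls.csv --manifest fixture/manifest.csv --out indices.csv
repeatlens kinetics --indices indices.csv --manifest fixture/manifest.csv \
    --metric modal_repeat --allele 118 --out rates.csv,comparisons.csv
repeatlens msi --peaks followup.tsv --baseline baseline.tsv --out msi.csv
repeatlens xlink --links links.tsv --structure toy.pdb --map map.yaml --out xl.csv
```

The `call` config YAML carries the calibration and expected alleles:

```yaml
calibration: {reference_repeat: 20, reference_size_bp: 160.0, repeat_unit_bp: 3}
expected_alleles: [20, 118]
threshold_fraction: 0.20
```

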