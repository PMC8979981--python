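# qaseq

UMI-based absolute molecule quantitation for amplicon sequencing:
copy-number calling across ensembles of quantitation modules, UMI-consensus
mutation calling, cfDNA tumor-fraction / tumor-ploidy inference, and
targeted RNA expression profiling — plus a synthetic library simulator with
ground-truth bookkeeping so every stage is testable without external data.

## How it works

- **Counting.** Every input DNA molecule is tagged with a unique molecular
  identifier (UMI) before amplification, so all reads sharing a
  (module, UMI) pair form one *UMI family* and the number of distinct
  families — not read depth — is the absolute input molecule count.
  Families below `max(3, 0.05 × mean(top-3 family sizes))` reads are
  discarded as polymerase/sequencing error products.
- **CNV.** Gene ploidy is `2 × mean(gene module counts) / mean(reference
  module counts)`. Genes with ≥ 3 modules are tested against the reference
  modules with Mann–Whitney U rank tests (Benjamini–Hochberg corrected);
  non-significant genes are reported at exactly 2.00. Pooling many modules
  per gene shrinks the Poisson sampling CV like 1/√m, enabling e.g.
  2.05-vs-2.00 ploidy discrimination.
- **Mutations.** Each size-filtered family is collapsed to a consensus
  sequence; VAF is counted in units of families (molecules), which
  suppresses per-read sequencing error down to ~0.1% VAF.
- **Tumor inference.** Plasma ploidy is modeled as a tumor/normal mixture;
  with a monoallelic somatic mutation as anchor, tumor fraction = 2 × VAF
  and tumor gene ploidy follows by inversion.
- **Simulator.** Poisson molecule sampling from a mass/ploidy model,
  binomial barcoding (conversion yield), Galton–Watson PCR amplification
  with per-cycle efficiency jitter (log-normal family sizes emerge rather
  than being assumed), multinomial depth allocation, per-base substitution
  errors, off-target reads, and variants spiked at known molecule-level VAF.

## CLI

One `qaseq` executable with per-stage subcommands:

```bash
qaseq panel validate panel.tsv
qaseq simulate --panel panel.tsv --config sim.yaml \
    --out-fastq run.fastq.gz --out-truth truth.tsv --seed 1
qaseq assign   --panel panel.tsv --fastq run.fastq.gz --out assigned.tsv
qaseq count    --assigned assigned.tsv --panel panel.tsv \
    --out counts.tsv --expected-copies 2790
qaseq cnv      --counts counts.tsv --panel panel.tsv --out calls.tsv --alpha 0.05
qaseq cv-curve --counts c1.tsv --counts c2.tsv --panel panel.tsv \
    --gene ERBB2 --modules 1,4,16,49 --out cv.tsv --seed 1
qaseq variants --assigned assigned.tsv --panel panel.tsv --out variants.tsv
qaseq rna      --counts counts.tsv --panel rna_panel.tsv \
    --reference-genes R1,R2,R3,R4,R5 --out expression.tsv
qaseq infer-tumor --cfdna-ploidy 2.18 --cfdna-vaf 0.005
qaseq run      --panel panel.tsv --config sim.yaml --outdir out/ --seed 1
```

The panel is a TSV with columns `module_id, gene, role, chrom, start, end,
fwd_primer, rev_primer, amplicon_seq, variant_loci`; `role` is one of
`target | reference | excluded`. Simulated reads are single-end with layout
`[UMI][fwd_primer][amplicon_seq]`. All tables carry a `#` metadata header
with tool version and parameters; identical config + seed gives
byte-identical outputs.

## Layout

```
src/qaseq/
  panel.py        panel model, validation, TSV I/O
  simulate.py     synthetic run generator + ground truth
  read_proc.py    FASTQ streaming, primer assignment, UMI extraction
  umi_quant.py    UMI families, size cutoff, molecule counts
  cnv.py          ploidy, Mann–Whitney CNV calls, CV/LoD analysis
  variants.py     family consensus + molecule-level variant calls
  tumor_infer.py  cfDNA mixture model and inversion
  rna_expr.py     reference-normalized log2 expression
  cli.py          click CLI
  io.py, errors.py
```
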