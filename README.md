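# altprot-curator

Identification curation and label-free quantification of **alternative
proteins** (AltProts / microproteins / sORF-encoded peptides) alongside
canonical proteomes, for combined DDA + DIA mass-spectrometry workflows.

AltProts are translated from ORFs missing from reference annotations —
on lncRNAs, in mRNA UTRs (uORF/dORF), out-of-frame within CDSs (intORF),
or from unannotated isoforms. Because they are short, they usually yield a
single tryptic peptide, so one peptide-spectrum match (PSM) often carries
the entire identification and ordinary FDR control is not stringent
enough. This package implements the informatics core such studies need:

- **Search space** — merge a canonical proteome, an OpenProt-style
  AltProt/Isoform FASTA (`IP_`/`II_` accessions) and a contaminant list
  into one indexed database; classify each AltProt's RNA source from a
  sidecar metadata table (`sequence_db`).
- **Mass arithmetic** — monoisotopic tryptic digestion (cleave after K/R,
  not before P), modification handling (carbamidomethyl-C fixed, Met
  oxidation and protein N-terminal acetyl variable), precursor and b/y
  fragment m/z (`mass_core`).
- **PSM curation** — annotate spectra with theoretical b/y ions at 20 ppm
  and keep a PSM only when matched ions evidence **≥ 75 %** of the n−1
  backbone fragmentation sites of its length-n peptide; screen every
  AltProt peptide for **proteotypicity** (unique substring of exactly one
  database protein, I/L collapsed) (`psm_curation`).
- **Spectral library & DIA design** — export curated PSMs as a
  DIA-NN-compatible OpenSWATH-style TSV with linear 0–100 normalized
  retention times, and generate staggered DIA isolation-window schemes
  (default 2 × 75 windows of 8 Th, 4 Th offset, 400–1000 Th)
  (`speclib`).
- **Differential quantification** — pivot a long-format DIA report to a
  protein × run matrix, median-center each run on the log2 scale, test
  two groups per protein with **Welch's t-test** on log2 intensities, and
  classify a volcano at p < 0.05 and |log2FC| > 1 (p < 0.01 for deep
  canonical proteomes) plus presence/absence "exclusive" calls — with
  **no imputation**: missing values stay missing (`dia_quant`).
- **Profiling** — length distribution, Henderson–Hasselbalch isoelectric
  points by bisection (pluggable pKa sets, EMBOSS default), RNA-source
  proportions (`profiling`).
- **Synthetic fixtures** — seeded generators for all four input kinds
  (FASTA, MGF, PSM TSV, DIA report) with exact ground truth: planted
  shared peptides, spectra with controlled fragment coverage, planted
  log2 effects (`fixtures`).

## Worked example

The library is used from Python; `examples/` holds one short script per
capability. Curation, for instance (`examples/03_curate_psms.py`) builds
spectra with known fragment coverage and applies the 75 % rule and the
proteotypicity screen:

```text
spectrum      peptide          coverage  verdict
scan_00001  GSCMREAGALDKR      1.000  kept
scan_00002  KNWAIEHLR          0.875  kept
scan_00003  GVKQDDEVATNILR     0.769  kept
scan_00004  TKVNSLQHLFDAR      0.750  kept
scan_00005  VTIYMRIEEEMK       0.727  rejected
scan_00006  ATDKLNLVRLR        0.500  rejected
-> 4 of 6 PSMs reach >= 75% b/y backbone coverage.

peptide DPDTALVK         of IP_700000: 2 database hits -> proteotypic=False
```

Coverage is the fraction of backbone sites evidenced by at least one
matched b or y ion — 0.750 sits exactly on the inclusive boundary and is
kept; the planted shared peptide hits two proteins and therefore cannot
uniquely evidence its AltProt. The differential example
(`examples/05_differential_analysis.py`) recovers 39 of 40 planted
effects, all with the correct direction, at zero false positives:

```text
200 protein groups classified:
  not_significant    159
  untestable         2
  up_in_group1       20
  up_in_group2       19
```

A thin CLI wraps the same functions
(`altprot-curator db merge | curate | speclib | windows | diff | profile |
fixtures`).

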