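# Methods

This note documents the models, rules and numerical choices behind
altprot-curator, what the synthetic fixtures do and do not emulate, and
the design decisions taken where the problem was genuinely open.

## Search space and RNA-source classes

The database model mirrors proteogenomic practice for microprotein
discovery: a canonical proteome, a predicted AltProt/novel-isoform set
with OpenProt-style accessions (`IP_` = alternative protein, `II_` =
novel isoform; the prefix is authoritative for the record category), and
common contaminants, merged under a uniqueness constraint on accessions.
RNA-source metadata (transcript accession, biotype, ORF location) is a
four-column sidecar TSV rather than being scraped from FASTA headers:
header layouts vary between database releases, and an explicit contract
is more robust than dialect sniffing. Classification maps novel isoforms
to `novel_isoform`; AltProts on protein-coding transcripts to
uORF/intORF/dORF by ORF location; AltProts on lncRNA **or pseudogene**
transcripts to `lncRNA` (pseudogene-derived transcripts behave as
non-coding for this summary; the raw biotype is retained on the record);
and misc_RNA to `misc_RNA`. Sequences containing X are accepted into the
search space but excluded from digestion, mass and pI arithmetic, where
X has no defined composition.

## Mass model

All masses are monoisotopic (high-resolution Orbitrap-type data):
6-decimal residue masses, water 18.010565 Da, proton 1.007276 Da.
Digestion follows classical trypsin — cleave C-terminal to K/R except
before P — with the proline exception exposed as a flag
(`proline_rule=False`) because some search engines disable it. Products
carry 0..k internal missed cleavages and an optional length filter; with
no missed cleavages and no filter the products concatenate back to the
input, which is the invariant the property tests enforce.

Fragments are b/y only (the ion series the curation rule is defined on;
a/c/x/z ions, neutral losses and isotope envelopes are out of scope):
`b_i = (sum of first i residues + N-terminal mods + z·proton)/z`,
`y_j = (sum of last j residues + water + z·proton)/z`. N-terminal
modifications count toward b ions only. Default fragment charges are
{1, 2}; higher charges are rarely informative for tryptic peptides of
these lengths. The three shipped modifications match a standard search
configuration: carbamidomethyl-C +57.02146 (fixed), Met oxidation
+15.99491, N-terminal acetyl +42.01057 (restricted to protein N-termini;
whether peptide N-termini should also accept it is acquisition-pipeline
dependent, and the restrictive default is the conservative one).
Modified peptides serialize to an inline-tag grammar
(`AC[+57.02146]K`, `[+42.01057]-MK...`, deltas at 5 decimals) used in
PSM tables and the library format. Implementation masses are verified in
the test suite against pyteomics' elemental-composition calculator (an
independent derivation from molecular formulas) to 1e-4 Da, and the b/y
complementarity identity `b_i + y_{n-i} = M + 2·proton` holds to 1e-9 Da.

## Coverage semantics and the 75 % rule

A length-n peptide has n−1 backbone fragmentation sites. A matched b-ion
of index i evidences site i; a matched y-ion of index j evidences site
n−j. Coverage = |evidenced sites| / (n−1). This site-based definition
was chosen over a residue-based one because b/y indices map one-to-one
onto sites, complementary pairs are naturally not double-counted, and
100 % is achievable by either ladder alone. A residue-based variant
(fraction of residues inside at least one matched fragment) is available
via `semantics="residue"`. The b and y ladders are counted jointly
(union); requiring a single series to reach the threshold alone is
expressible by passing only one series' charges but is not the default.
The filter boundary is inclusive: coverage exactly 0.75 passes.

Matching assigns each theoretical ion to its nearest peak within 20 ppm
(HCD at ~15k resolution; configurable), ties broken toward the lower-m/z
peak so results are deterministic and independent of peak order. A peak
may serve several ions; an ion matches at most one peak. The manual
two-operator review step that real studies add on top is represented
only as a `validated` flag importable from a review table — software
never sets it.

Proteotypicity is a substring scan of the merged database with I/L
collapsed by default (isobaric, indistinguishable by fragment mass); a
peptide is proteotypic iff it occurs in exactly one protein. A PSM whose
peptide is absent from its claimed parent is rejected as internally
inconsistent rather than silently scored.

## Spectral library and window schemes

One library entry per (modified sequence, precursor charge); duplicate
precursors resolve by highest coverage, then most matched ions, then
lexicographic spectrum id — fully deterministic. Fragment rows take
their intensities from the matched experimental peaks, renormalized to
max = 1 per precursor; entries with fewer than 3 fragments are dropped
(configurable floor). No external iRT standard is assumed: normalized
retention time is a linear rescale of empirical RT to [0, 100] over the
run span (default 0 → latest observed RT), declared by the
`#irt=linear0-100` meta line. The TSV dialect is the OpenSWATH-style
header that DIA-NN accepts as a library input
(`PrecursorMz … FragmentCharge`, one row per fragment); columns are
located by name on read, so column order is free.

Staggered window schemes tile [lo, hi) with `ceil((hi−lo)/width)`
contiguous half-open windows; a non-zero offset adds a second pass
shifted by +offset. The default (400–1000 Th, 8 Th, 4 Th) yields the
2 × 75 staggered scheme typical of Orbitrap DIA; note the second pass
necessarily extends offset Th past `hi`.

## Differential analysis

The DIA report is pivoted to a protein × run matrix in which an absent
(protein, run) row is a missing cell — never zero. No step of the
pipeline imputes: normalization, means, tests and classification all
operate on observed values only (a property test scans for created
values). Normalization is median-centering on the log2 scale — each
run's log2 intensities are shifted so all run medians equal the grand
median of run medians — chosen as the plain intensity normalization of
mainstream LFQ post-processors; quantile normalization was considered
and rejected as stronger than the evidence warrants for 8-run designs.

Welch's unequal-variance t-test runs per protein **on log2
intensities**, where multiplicative replicate noise is near-Gaussian
(testing raw linear intensities is miscalibrated under lognormal noise
and measurably less powerful). t, Welch–Satterthwaite df and two-sided p
come from the closed-form expressions with scipy's Student-t CDF; groups
with fewer than two observations, or two zero-variance groups, are
untestable. Fold changes are log2 ratios of linear-scale group means of
observed values. Volcano classes use raw p with symmetric cuts —
up/down at p < p_cut and |log2FC| > fc_cut (defaults 0.05 and 1;
0.01 conventional for deep canonical proteomes) — after presence/absence
precedence: a protein seen in ≥ min_n runs (default 3, matching 3–4
replicate designs) of one group and none of the other is "exclusive" to
that group. No multiple-testing correction enters the classification,
mirroring the raw-p + fold-change gate convention for small AltProt
panels; a Benjamini–Hochberg column is emitted for information.

## Isoelectric points

Net charge is the Henderson–Hasselbalch sum over nine ionizable groups
(termini, D, E, C, Y, H, K, R). The charge function is strictly
decreasing in pH and bracketed by the always-present termini, so a
unique root exists; bisection over [0, 14] runs until the bracket is
below 1e-4 pH *and* the residual charge is below 1e-4 — the second
condition matters for long sequences, whose charge curve is steep near
the root. The pKa set is pluggable (EMBOSS default, Bjellqvist shipped)
because published sets disagree by up to ~0.5 pH units; cohort summaries
therefore report which set produced them. Length histograms use 50-aa
bins from 1; pI histograms use width-1 bins over [3, 13) with end bins
absorbing overflow.

## Synthetic fixtures: what they emulate, and what they do not

One integer seed drives all generators through fixed substreams
(`default_rng([stream, seed])`), so outputs are byte-reproducible and
adding one fixture never perturbs another.

- **Proteome**: random-composition canonical proteins (150–600 aa);
  AltProts with lognormal lengths targeting a median of 84 aa (the
  typical microproteome median) clipped to 20–300 aa; biotype weights
  skewed toward non-coding sources as observed for human microproteomes.
  A stated fraction of AltProts carries a fully tryptic peptide copied
  from a canonical protein and spliced between K/R anchors so it is a
  tryptic product of both parents — exact planted non-proteotypic cases.
- **Spectra**: each PSM evidences exactly `round(target·(n−1))` chosen
  sites with singly charged b/y peaks at their exact m/z. Peptides whose
  theoretical ladders contain cross-site m/z collisions within twice the
  match tolerance are rejected at generation time, and noise peaks are
  kept at least twice the tolerance from every theoretical ion — so the
  recovered coverage equals ground truth *exactly*, not probabilistically.
- **DIA report**: per-protein baseline ~ U(20, 30) log2; group-1 runs add
  a planted δ; every cell adds N(0, σ) log2 noise. Defaults are the
  regime of a small multi-cell-line comparison: 500 proteins, δ ∈
  {0, +1.5, −1.5} (400/50/50), 4 vs 4 runs, σ = 0.3, 10 % missingness
  (`random` drops cells independently; `group_exclusive` blanks one
  whole group per selected protein).

The fixtures deliberately do **not** model fragmentation-intensity
patterns, chromatographic peak shape, interference, run-to-run RT drift,
charge-state distributions, or intensity-dependent missingness. Passing
tests therefore demonstrate the correctness of the *rules and
arithmetic* on ideal inputs, not identification performance on real
spectra.

Under the default DIA design, the pipeline's measured operating
characteristics (recomputed by `scripts/acceptance.py`) are: sensitivity
≈ 0.95, false-positive rate ≈ 0 at p < 0.05 and |log2FC| > 1. The
fold-change estimate itself carries sampling error of sd
σ·√(2/4) ≈ 0.21 log2 units plus ≈ 0.17 from median estimation during
normalization, so roughly three quarters of non-null proteins land
within ±0.3 of their planted δ — an estimator-variance floor at these
replicate counts, not an implementation artifact.

## Known limitations

- No database search, rescoring or FDR estimation: the package consumes
  already-searched PSM tables (those steps sit upstream in real
  pipelines).
- No DIA-NN execution or staggered-window demultiplexing; the library
  and scheme are designs, not acquisitions.
- Proteotypicity is screened against the merged database only, not
  against all external proteomes.
- Problem sizes in tests and the acceptance script (hundreds of PSMs,
  500-protein reports, 1,000-entry libraries, 10,000 pI sequences) are
  the package's chosen desk-scale study conditions; the algorithms are
  linear or near-linear in their inputs.
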