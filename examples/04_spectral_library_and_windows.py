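"""Spectral-library construction and staggered DIA window design.

Curated PSMs become a DIA-NN-compatible library (one row per fragment);
the staggered scheme is the acquisition pattern the library is scored
against: two interleaved passes of 8-Th windows offset by 4 Th.
"""

import numpy as np

from altprot_curator import (
    apply_coverage_filter,
    build_library,
    make_window_scheme,
    match_fragments,
    parse_modified_sequence,
    write_library_tsv,
)
from altprot_curator.fixtures import FixtureSpec, make_spectra, random_clean_peptide

spec = FixtureSpec(seed=3)
rng = np.random.default_rng(3)
peptides = [random_clean_peptide(rng) for _ in range(5)]
sf = make_spectra(spec, peptides, [1.0, 1.0, 0.9, 0.85, 0.8])
psms = [
    match_fragments(sp, parse_modified_sequence(p), tol_ppm=spec.tol_ppm)
    for sp, p in zip(sf.spectra, sf.psm_rows["peptide"])
]
kept, _ = apply_coverage_filter(psms)
entries = build_library(kept, sf.spectra, sf.rt_map)
write_library_tsv(entries, "library_example.tsv")
print(f"library: {len(entries)} precursors, "
      f"{sum(len(e.fragments) for e in entries)} fragment rows -> library_example.tsv")
for e in entries[:3]:
    print(f"  {e.modified_sequence:20s} {e.precursor_charge}+  "
          f"precursor {e.precursor_mz:9.4f} Th  iRT {e.irt:6.2f}  "
          f"{len(e.fragments)} fragments")

scheme = make_window_scheme(400, 1000, 8, 4)
print(f"\nstaggered DIA scheme: {len(scheme.passes)} passes x "
      f"{scheme.windows_per_pass} windows of {scheme.width} Th "
      f"(offset {scheme.offset} Th) over {scheme.range[0]}-{scheme.range[1]} Th")
print(f"  pass 1 starts {scheme.passes[0][0]}, pass 2 starts {scheme.passes[1][0]}")
print("Interleaving the two passes halves the effective isolation width "
      "after demultiplexing.")
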