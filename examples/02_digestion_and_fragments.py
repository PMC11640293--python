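"""Tryptic digestion and b/y fragment m/z arithmetic for one microprotein.

Digests a short protein with up to one missed cleavage, then prints the
singly charged b/y ladder of one peptide. The b/y ions are what the PSM
curation stage matches against observed MS/MS peaks.
"""

from altprot_curator import (
    Peptide,
    digest,
    enumerate_fragments,
    peptide_neutral_mass,
    precursor_mz,
)

PROTEIN = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEK"

peptides = digest(PROTEIN, missed_cleavages_max=1, length_range=(6, 30))
print(f"{len(peptides)} tryptic peptides (6-30 aa, <=1 missed cleavage):")
for p in peptides:
    print(f"  {p.sequence:30s} mc={p.missed_cleavages}  "
          f"M={peptide_neutral_mass(p):10.5f} Da  m/z(2+)={precursor_mz(p, 2):9.4f}")

pep = Peptide("QISFVK")
print(f"\nfragment ladder of {pep.sequence} "
      f"(each index is one backbone cleavage site):")
for ion in enumerate_fragments(pep, charges=(1,)):
    print(f"  {ion.annotation:6s} {ion.mz:10.5f} Th")
print("A PSM whose matched b/y ions evidence >= 75% of these sites passes "
      "the curation filter.")
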