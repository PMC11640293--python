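"""Protein sequence databases: canonical + AltProt/Isoform + contaminants.

The search space mirrors proteogenomic practice for microprotein discovery:
a reference proteome (e.g. UniProt), a predicted alternative-protein and
novel-isoform database using OpenProt-style accessions (``IP_`` for
alternative proteins, ``II_`` for novel isoforms), and a common-contaminant
list. RNA-source metadata (which transcript and which region an ORF lives
on) travels in a sidecar TSV rather than being scraped from FASTA headers,
whose layout differs between database releases.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


class Category(str, Enum):
    CANONICAL = "canonical"
    ALTPROT = "altprot"
    ISOFORM = "isoform"
    CONTAMINANT = "contaminant"


class Biotype(str, Enum):
    PROTEIN_CODING = "protein_coding"
    LNCRNA = "lncRNA"
    PSEUDOGENE = "pseudogene"
    MISC_RNA = "misc_RNA"


class OrfLocation(str, Enum):
    FIVE_PRIME_UTR = "five_prime_utr"
    CDS_OTHER_FRAME = "cds_other_frame"
    THREE_PRIME_UTR = "three_prime_utr"
    NOVEL_ISOFORM = "novel_isoform"
    NCRNA_ORF = "ncRNA_orf"


class RnaSourceClass(str, Enum):
    """Where the ORF encoding an alternative protein lives.

    uORF/intORF/dORF = 5'UTR / out-of-frame CDS / 3'UTR of an mRNA;
    lncRNA and misc_RNA = unannotated ORFs on non-coding RNAs (pseudogene
    transcripts are folded into the lncRNA class for summaries);
    novel_isoform = an unannotated isoform of a known protein.
    """

    UORF = "uORF"
    INTORF = "intORF"
    DORF = "dORF"
    LNCRNA = "lncRNA"
    MISC_RNA = "misc_RNA"
    NOVEL_ISOFORM = "novel_isoform"


@dataclass
class ProteinRecord:
    """One database entry.

    ``has_undetermined`` flags sequences containing X; such records are kept
    in the database (they are legitimate search-space members) but excluded
    from digestion and mass arithmetic, where X has no defined mass.
    """

    accession: str
    description: str
    sequence: str
    category: Category
    transcript_accession: str | None = None
    transcript_biotype: Biotype | None = None
    orf_location: OrfLocation | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        is_alt = self.accession.startswith("IP_")
        is_iso = self.accession.startswith("II_")
        if is_alt != (self.category is Category.ALTPROT):
            raise ValueError(
                f"{self.accession}: IP_ prefix and category {self.category.value} disagree"
            )
        if is_iso != (self.category is Category.ISOFORM):
            raise ValueError(
                f"{self.accession}: II_ prefix and category {self.category.value} disagree"
            )

    @property
    def has_undetermined(self) -> bool:
        return "X" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


def _infer_category(accession: str, default: Category) -> Category:
    if accession.startswith("IP_"):
        return Category.ALTPROT
    if accession.startswith("II_"):
        return Category.ISOFORM
    return default


def read_fasta(path: str | Path, category: Category | str) -> list[ProteinRecord]:
    """Read a FASTA database, assigning ``category`` to each entry.

    The accession is the first whitespace-delimited header token; the rest
    of the header line is the description. ``IP_``/``II_`` accession
    prefixes override ``category`` with altprot/isoform respectively.
    Raises on an empty file, a duplicate accession, or any residue outside
    the 20 standard letters and X.
    """
    category = Category(category)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        accession = entry.id
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        sequence = str(entry.seq).upper()
        for i, c in enumerate(sequence):
            if c not in VALID_RESIDUES and c != "X":
                raise ValueError(
                    f"{accession}: invalid residue {c!r} at position {i + 1}"
                )
        description = entry.description[len(entry.id) :].strip()
        records.append(
            ProteinRecord(
                accession=accession,
                description=description,
                sequence=sequence,
                category=_infer_category(accession, category),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# sidecar metadata
# ---------------------------------------------------------------------------

METADATA_COLUMNS = ("accession", "transcript_accession", "biotype", "orf_location")


def read_metadata_tsv(path: str | Path) -> dict[str, dict[str, str]]:
    """Read the 4-column RNA-source sidecar TSV keyed by accession."""
    meta: dict[str, dict[str, str]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(METADATA_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"metadata TSV missing columns: {sorted(missing)}")
        for row in reader:
            acc = row["accession"]
            if acc in meta:
                raise ValueError(f"duplicate metadata row for {acc!r}")
            meta[acc] = row
    return meta


def attach_metadata(
    records: Iterable[ProteinRecord], meta: dict[str, dict[str, str]]
) -> list[ProteinRecord]:
    """Return copies of ``records`` with sidecar fields filled in where present."""
    out = []
    for rec in records:
        row = meta.get(rec.accession)
        if row is None:
            out.append(rec)
            continue
        out.append(
            replace(
                rec,
                transcript_accession=row["transcript_accession"] or None,
                transcript_biotype=Biotype(row["biotype"]) if row["biotype"] else None,
                orf_location=OrfLocation(row["orf_location"])
                if row["orf_location"]
                else None,
            )
        )
    return out


def write_metadata_tsv(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(METADATA_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.accession,
                    rec.transcript_accession or "",
                    rec.transcript_biotype.value if rec.transcript_biotype else "",
                    rec.orf_location.value if rec.orf_location else "",
                ]
            )


# ---------------------------------------------------------------------------
# merged, indexed database
# ---------------------------------------------------------------------------

class ProteinDatabase:
    """An accession-indexed collection of :class:`ProteinRecord`."""

    def __init__(self, records: Iterable[ProteinRecord] = ()) -> None:
        self._records: dict[str, ProteinRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: ProteinRecord) -> None:
        if record.accession in self._records:
            raise ValueError(f"accession collision: {record.accession!r}")
        self._records[record.accession] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self._records.values())

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._records[accession]

    def get(self, accession: str) -> ProteinRecord | None:
        return self._records.get(accession)

    def by_category(self, category: Category) -> list[ProteinRecord]:
        return [r for r in self if r.category is category]

    def search_substring(self, peptide: str, il_equivalent: bool = True) -> set[str]:
        """Accessions of every protein containing ``peptide`` as a substring.

        With ``il_equivalent`` (the default, since I and L are isobaric and
        indistinguishable by mass), I and L are collapsed before matching.
        """
        needle = peptide.replace("I", "J").replace("L", "J") if il_equivalent else peptide
        hits = set()
        for rec in self:
            hay = (
                rec.sequence.replace("I", "J").replace("L", "J")
                if il_equivalent
                else rec.sequence
            )
            if needle in hay:
                hits.add(rec.accession)
        return hits


def merge_databases(
    canonical: Iterable[ProteinRecord],
    altprot: Iterable[ProteinRecord] = (),
    contaminants: Iterable[ProteinRecord] = (),
) -> ProteinDatabase:
    """Merge the three database components into one indexed collection.

    Accession sets must be pairwise disjoint; a collision raises naming the
    offending accession. The merged size equals the sum of the inputs.
    """
    db = ProteinDatabase()
    for group in (canonical, altprot, contaminants):
        for rec in group:
            db.add(rec)
    return db


def classify_rna_source(record: ProteinRecord) -> RnaSourceClass:
    """Assign the RNA-source class of an AltProt or novel-isoform record.

    Novel isoforms map to ``novel_isoform`` regardless of transcript.
    AltProts on protein-coding transcripts map by ORF location (5'UTR ->
    uORF, out-of-frame CDS -> intORF, 3'UTR -> dORF); AltProts on lncRNA or
    pseudogene transcripts -> lncRNA; on misc_RNA -> misc_RNA.
    """
    if record.category is Category.ISOFORM:
        return RnaSourceClass.NOVEL_ISOFORM
    if record.category is not Category.ALTPROT:
        raise ValueError(
            f"{record.accession}: RNA source is defined only for altprot/isoform "
            f"records, not {record.category.value}"
        )
    bt = record.transcript_biotype
    if bt is None:
        raise ValueError(f"{record.accession}: unclassifiable (missing biotype metadata)")
    if bt is Biotype.PROTEIN_CODING:
        loc = record.orf_location
        mapping = {
            OrfLocation.FIVE_PRIME_UTR: RnaSourceClass.UORF,
            OrfLocation.CDS_OTHER_FRAME: RnaSourceClass.INTORF,
            OrfLocation.THREE_PRIME_UTR: RnaSourceClass.DORF,
        }
        if loc not in mapping:
            raise ValueError(
                f"{record.accession}: unclassifiable (protein_coding transcript "
                f"with orf_location {loc.value if loc else None!r})"
            )
        return mapping[loc]
    if bt in (Biotype.LNCRNA, Biotype.PSEUDOGENE):
        return RnaSourceClass.LNCRNA
    if bt is Biotype.MISC_RNA:
        return RnaSourceClass.MISC_RNA
    raise ValueError(f"{record.accession}: unclassifiable (biotype {bt.value!r})")
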