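"""PSM annotation, backbone-coverage filtering, and proteotypicity screening.

Microproteins typically yield a single tryptic peptide, so a single
peptide-spectrum match often carries the whole identification. The curation
rule implemented here demands that matched b/y fragment ions cover at least
75% of the peptide backbone before a PSM is trusted, and that the peptide
be proteotypic — found in exactly one protein of the search space.

Coverage semantics: a length-n peptide has n-1 inter-residue fragmentation
sites; a matched b-ion of index i evidences site i, a matched y-ion of
index j evidences site n-j (counting from the N-terminus). Coverage is the
fraction of distinct sites evidenced, so a complete b or y ladder alone
reaches 1.0 and complementary b/y pairs are not double-counted. An
alternative residue-based definition (fraction of residues contained in at
least one matched fragment) is available via ``semantics="residue"``.
"""

from __future__ import annotations

import bisect
import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from pyteomics import mgf as _mgf

from .mass_core import (
    FragmentIon,
    Peptide,
    enumerate_fragments,
    parse_modified_sequence,
)
from .sequence_db import ProteinDatabase, Category

DEFAULT_TOL_PPM = 20.0
DEFAULT_COVERAGE_THRESHOLD = 0.75
DEFAULT_MGF_CHARGE = 2


@dataclass
class Spectrum:
    """A centroided MS/MS spectrum; peaks kept sorted by m/z."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    peaks: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError(f"{self.spectrum_id}: precursor charge must be >= 1")
        if any(inten < 0 for _, inten in self.peaks):
            raise ValueError(f"{self.spectrum_id}: negative peak intensity")
        self.peaks = sorted(self.peaks)


@dataclass
class MatchedIon:
    ion: FragmentIon
    peak_index: int
    error_ppm: float


@dataclass
class AnnotatedPSM:
    """A peptide-spectrum match with its fragment annotation and coverage."""

    spectrum_id: str
    peptide: Peptide
    matched_ions: list[MatchedIon] = field(default_factory=list)
    coverage: float = 0.0
    proteotypic: bool | None = None
    hit_accessions: set[str] = field(default_factory=set)
    validated: bool = False


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF peak list (BEGIN IONS/END IONS blocks).

    A block without a CHARGE line is assigned charge 2+ with a warning;
    a block without PEPMASS is an error.
    """
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            params = entry["params"]
            title = str(params.get("title", f"spectrum_{i}"))
            if "pepmass" not in params or params["pepmass"][0] is None:
                raise ValueError(f"{path}: spectrum {title!r} has no PEPMASS")
            charges = params.get("charge")
            if charges:
                charge = int(charges[0])
            else:
                warnings.warn(
                    f"{path}: spectrum {title!r} has no CHARGE; assuming "
                    f"{DEFAULT_MGF_CHARGE}+",
                    stacklevel=2,
                )
                charge = DEFAULT_MGF_CHARGE
            peaks = list(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            spectra.append(
                Spectrum(
                    spectrum_id=title,
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    peaks=peaks,
                )
            )
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={sp.spectrum_id}\n")
            fh.write(f"PEPMASS={sp.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={sp.precursor_charge}+\n")
            for mz, inten in sp.peaks:
                fh.write(f"{mz:.6f} {inten:.2f}\n")
            fh.write("END IONS\n\n")


# ---------------------------------------------------------------------------
# fragment matching and coverage
# ---------------------------------------------------------------------------

def _nearest_peak_within(
    mzs: Sequence[float], target: float, tol_ppm: float
) -> tuple[int, float] | None:
    """Index and ppm error of the peak nearest ``target`` within tolerance.

    Ties in absolute error break toward the lower-m/z peak for determinism.
    """
    tol = target * tol_ppm * 1e-6
    i = bisect.bisect_left(mzs, target)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(mzs):
            err = abs(mzs[j] - target)
            if err <= tol and (best is None or err < best[1]):
                best = (j, err)
    if best is None:
        return None
    return best[0], (mzs[best[0]] - target) / target * 1e6


def coverage_fraction(
    matched_ions: Sequence[MatchedIon | FragmentIon],
    peptide_length: int,
    semantics: str = "site",
) -> float:
    """Backbone coverage from a set of matched fragment ions.

    ``semantics="site"`` (default): fraction of the n-1 fragmentation sites
    evidenced. ``semantics="residue"``: fraction of residues inside at least
    one matched fragment.
    """
    n = peptide_length
    if n < 2:
        raise ValueError("coverage undefined for peptides shorter than 2 residues")
    ions = [m.ion if isinstance(m, MatchedIon) else m for m in matched_ions]
    if semantics == "site":
        sites = set()
        for ion in ions:
            sites.add(ion.index if ion.series == "b" else n - ion.index)
        return len(sites) / (n - 1)
    if semantics == "residue":
        residues: set[int] = set()
        for ion in ions:
            if ion.series == "b":
                residues.update(range(1, ion.index + 1))
            else:
                residues.update(range(n - ion.index + 1, n + 1))
        return len(residues) / n
    raise ValueError(f"unknown coverage semantics {semantics!r}")


def match_fragments(
    spectrum: Spectrum,
    peptide: Peptide,
    tol_ppm: float = DEFAULT_TOL_PPM,
    charges: Iterable[int] = (1, 2),
    semantics: str = "site",
) -> AnnotatedPSM:
    """Annotate a spectrum with the peptide's theoretical b/y ions.

    Each theoretical ion is matched to its nearest peak within ``tol_ppm``
    (at most one peak per ion; a peak may serve several ions). The result is
    deterministic and independent of input peak order.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    mzs = [mz for mz, _ in spectrum.peaks]
    matched = []
    for ion in enumerate_fragments(peptide, charges):
        hit = _nearest_peak_within(mzs, ion.mz, tol_ppm)
        if hit is not None:
            matched.append(MatchedIon(ion, hit[0], hit[1]))
    cov = coverage_fraction(matched, len(peptide), semantics) if matched else 0.0
    return AnnotatedPSM(
        spectrum_id=spectrum.spectrum_id,
        peptide=peptide,
        matched_ions=matched,
        coverage=cov,
    )


def apply_coverage_filter(
    psms: Iterable[AnnotatedPSM], threshold: float = DEFAULT_COVERAGE_THRESHOLD
) -> tuple[list[AnnotatedPSM], list[AnnotatedPSM]]:
    """Partition PSMs into (kept, rejected) at ``coverage >= threshold``.

    The boundary is inclusive: a PSM at exactly the threshold is kept.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    kept, rejected = [], []
    for psm in psms:
        (kept if psm.coverage >= threshold else rejected).append(psm)
    return kept, rejected


# ---------------------------------------------------------------------------
# proteotypicity
# ---------------------------------------------------------------------------

def check_proteotypicity(
    peptide: Peptide | str,
    database: ProteinDatabase,
    il_equivalent: bool = True,
    parent_accession: str | None = None,
) -> tuple[bool, set[str]]:
    """Screen a peptide for uniqueness within the merged search space.

    Returns ``(proteotypic, hits)`` where hits is the set of accessions
    whose sequence contains the peptide (I/L collapsed when
    ``il_equivalent``). The peptide is proteotypic iff it maps to exactly
    one protein. If the peptide claims a parent accession that does not
    contain it, the PSM is internally inconsistent and an error is raised.
    """
    if isinstance(peptide, Peptide):
        seq = peptide.sequence
        parents = peptide.parent_accessions or (
            {parent_accession} if parent_accession else set()
        )
    else:
        seq = peptide
        parents = {parent_accession} if parent_accession else set()
    hits = database.search_substring(seq, il_equivalent=il_equivalent)
    for parent in parents:
        if parent in database and parent not in hits:
            raise ValueError(
                f"inconsistent PSM: peptide {seq!r} absent from claimed parent {parent!r}"
            )
    return len(hits) == 1, hits


# ---------------------------------------------------------------------------
# PSM table I/O
# ---------------------------------------------------------------------------

PSM_TABLE_COLUMNS = ("spectrum_id", "peptide", "charge", "accessions")


def read_psm_table(path: str | Path) -> list[dict]:
    """Read the 4-column input PSM TSV; ``peptide`` uses inline-tag notation
    and ``accessions`` is semicolon-separated."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(PSM_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"PSM table missing columns: {sorted(missing)}")
        for row in reader:
            peptide = parse_modified_sequence(row["peptide"])
            peptide.parent_accessions = {
                a for a in row["accessions"].split(";") if a
            }
            rows.append(
                {
                    "spectrum_id": row["spectrum_id"],
                    "peptide": peptide,
                    "charge": int(row["charge"]),
                }
            )
    return rows


def curate_psms(
    spectra: Iterable[Spectrum],
    psm_rows: Iterable[dict],
    database: ProteinDatabase | None = None,
    tol_ppm: float = DEFAULT_TOL_PPM,
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    charges: Iterable[int] = (1, 2),
    il_equivalent: bool = True,
) -> list[AnnotatedPSM]:
    """Full curation pass: annotate, compute coverage, screen proteotypicity.

    Returns all PSMs annotated; the coverage partition is re-derivable with
    :func:`apply_coverage_filter`. Proteotypicity is screened only for
    AltProt/Isoform parents (canonical identifications are routinely shared
    across isoforms and are not required to be unique).
    """
    by_id = {sp.spectrum_id: sp for sp in spectra}
    out = []
    for row in psm_rows:
        spectrum = by_id.get(row["spectrum_id"])
        if spectrum is None:
            raise KeyError(f"PSM references unknown spectrum {row['spectrum_id']!r}")
        psm = match_fragments(spectrum, row["peptide"], tol_ppm=tol_ppm, charges=charges)
        if database is not None:
            parents = row["peptide"].parent_accessions
            alt_parent = any(
                database[a].category in (Category.ALTPROT, Category.ISOFORM)
                for a in parents
                if a in database
            )
            if alt_parent:
                psm.proteotypic, psm.hit_accessions = check_proteotypicity(
                    row["peptide"], database, il_equivalent=il_equivalent
                )
        out.append(psm)
    return out


def write_curation_report(
    psms: Iterable[AnnotatedPSM],
    path: str | Path,
    threshold: float = DEFAULT_COVERAGE_THRESHOLD,
) -> None:
    from .mass_core import format_modified_sequence

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            [
                "spectrum_id",
                "peptide",
                "accessions",
                "coverage",
                "matched_ion_count",
                "proteotypic",
                "hit_accessions",
                "kept",
            ]
        )
        for psm in psms:
            writer.writerow(
                [
                    psm.spectrum_id,
                    format_modified_sequence(psm.peptide),
                    ";".join(sorted(psm.peptide.parent_accessions)),
                    f"{psm.coverage:.6f}",
                    len(psm.matched_ions),
                    "" if psm.proteotypic is None else str(psm.proteotypic).lower(),
                    ";".join(sorted(psm.hit_accessions)),
                    str(psm.coverage >= threshold).lower(),
                ]
            )
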