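"""Spectral-library construction and staggered DIA window schemes.

The library is emitted as a DIA-NN-compatible tab-separated file in the
OpenSWATH-style dialect (one row per fragment ion, columns below). The
normalized retention time ("iRT") axis is a linear 0-100 rescaling of the
empirical retention time over the run span, declared in the file's leading
``#irt=linear0-100`` meta line — no external iRT standard is assumed.

Window schemes model staggered DIA acquisition: two interleaved passes of
fixed-width isolation windows, the second offset by half a window, which
doubles the effective precursor selectivity after demultiplexing. The
default scheme (400-1000 Th, 8 Th wide, 4 Th offset) gives 2 x 75 windows.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .mass_core import (
    Peptide,
    format_modified_sequence,
    parse_modified_sequence,
    precursor_mz as _precursor_mz,
)
from .psm_curation import AnnotatedPSM, Spectrum

LIBRARY_COLUMNS = (
    "PrecursorMz",
    "ProductMz",
    "Annotation",
    "ProteinId",
    "GeneName",
    "PeptideSequence",
    "ModifiedPeptideSequence",
    "PrecursorCharge",
    "LibraryIntensity",
    "NormalizedRetentionTime",
    "FragmentType",
    "FragmentSeriesNumber",
    "FragmentCharge",
)

IRT_META_LINE = "#irt=linear0-100"

MIN_FRAGMENTS_PER_PRECURSOR = 3


@dataclass
class LibraryFragment:
    fragment_type: str  # "b" or "y"
    fragment_series_number: int
    fragment_charge: int
    product_mz: float
    library_intensity: float


@dataclass
class SpectralLibraryEntry:
    """One precursor of the spectral library with its fragment rows."""

    peptide_sequence: str
    modified_sequence: str
    precursor_charge: int
    precursor_mz: float
    irt: float
    protein_id: str
    gene: str = ""
    fragments: list[LibraryFragment] = field(default_factory=list)


def build_library(
    curated_psms: Iterable[AnnotatedPSM],
    spectra: Iterable[Spectrum],
    rt_map: Mapping[str, float],
    run_span: tuple[float, float] | None = None,
    precursor_charge_map: Mapping[str, int] | None = None,
    min_fragments: int = MIN_FRAGMENTS_PER_PRECURSOR,
) -> list[SpectralLibraryEntry]:
    """Assemble library entries from curated PSMs.

    One entry per (modified peptide, precursor charge); duplicate precursors
    resolve to the PSM with the highest coverage, then most matched ions,
    then lexicographically smallest spectrum id. Fragment intensities come
    from the matched experimental peaks, renormalized to a maximum of 1
    within each precursor. iRT is the retention time linearly rescaled to
    [0, 100] over ``run_span`` (default: 0 to the latest observed RT).
    Entries with fewer than ``min_fragments`` matched ions are dropped with
    a warning; a PSM whose spectrum has no RT entry is an error.
    """
    spectra_by_id = {sp.spectrum_id: sp for sp in spectra}

    def sort_key(psm: AnnotatedPSM):
        return (-psm.coverage, -len(psm.matched_ions), psm.spectrum_id)

    best: dict[tuple[str, int], AnnotatedPSM] = {}
    for psm in curated_psms:
        sp = spectra_by_id.get(psm.spectrum_id)
        if sp is None:
            raise KeyError(f"PSM references unknown spectrum {psm.spectrum_id!r}")
        if psm.spectrum_id not in rt_map:
            raise KeyError(f"no retention time for spectrum {psm.spectrum_id!r}")
        key = (format_modified_sequence(psm.peptide), sp.precursor_charge)
        if key not in best or sort_key(psm) < sort_key(best[key]):
            best[key] = psm

    if run_span is None:
        run_span = (0.0, max(rt_map.values()))
    lo, hi = run_span
    if hi <= lo:
        raise ValueError("run span must have positive duration")

    entries = []
    for (modseq, charge), psm in sorted(best.items()):
        if len(psm.matched_ions) < min_fragments:
            warnings.warn(
                f"precursor {modseq}/{charge}+ has only {len(psm.matched_ions)} "
                f"matched ions (< {min_fragments}); skipped",
                stacklevel=2,
            )
            continue
        sp = spectra_by_id[psm.spectrum_id]
        intensities = [sp.peaks[m.peak_index][1] for m in psm.matched_ions]
        top = max(intensities)
        if top <= 0:
            top = 1.0
        fragments = [
            LibraryFragment(
                fragment_type=m.ion.series,
                fragment_series_number=m.ion.index,
                fragment_charge=m.ion.charge,
                product_mz=m.ion.mz,
                library_intensity=inten / top,
            )
            for m, inten in zip(psm.matched_ions, intensities)
        ]
        fragments.sort(key=lambda f: f.product_mz)
        rt = rt_map[psm.spectrum_id]
        entries.append(
            SpectralLibraryEntry(
                peptide_sequence=psm.peptide.sequence,
                modified_sequence=modseq,
                precursor_charge=charge,
                precursor_mz=_precursor_mz(psm.peptide, charge),
                irt=(rt - lo) / (hi - lo) * 100.0,
                protein_id=";".join(sorted(psm.peptide.parent_accessions)),
                fragments=fragments,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def write_library_tsv(entries: Iterable[SpectralLibraryEntry], path: str | Path) -> None:
    """Write the library in the DIA-NN-accepted tab-separated dialect,
    one row per fragment ion."""
    with open(path, "w", newline="") as fh:
        fh.write(IRT_META_LINE + "\n")
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(LIBRARY_COLUMNS)
        for e in entries:
            for f in e.fragments:
                writer.writerow(
                    [
                        f"{e.precursor_mz:.6f}",
                        f"{f.product_mz:.6f}",
                        f"{f.fragment_type}{f.fragment_series_number}^{f.fragment_charge}",
                        e.protein_id,
                        e.gene,
                        e.peptide_sequence,
                        e.modified_sequence,
                        e.precursor_charge,
                        f"{f.library_intensity:.6f}",
                        f"{e.irt:.6f}",
                        f.fragment_type,
                        f.fragment_series_number,
                        f.fragment_charge,
                    ]
                )


def read_library_tsv(path: str | Path) -> list[SpectralLibraryEntry]:
    """Inverse of :func:`write_library_tsv`; columns are located by name, so
    column order is free. Raises listing any missing column."""
    with open(path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    missing = set(LIBRARY_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise ValueError(f"library TSV missing columns: {sorted(missing)}")
    entries: dict[tuple[str, int], SpectralLibraryEntry] = {}
    for row in reader:
        key = (row["ModifiedPeptideSequence"], int(row["PrecursorCharge"]))
        if key not in entries:
            entries[key] = SpectralLibraryEntry(
                peptide_sequence=row["PeptideSequence"],
                modified_sequence=row["ModifiedPeptideSequence"],
                precursor_charge=int(row["PrecursorCharge"]),
                precursor_mz=float(row["PrecursorMz"]),
                irt=float(row["NormalizedRetentionTime"]),
                protein_id=row["ProteinId"],
                gene=row["GeneName"],
            )
        entries[key].fragments.append(
            LibraryFragment(
                fragment_type=row["FragmentType"],
                fragment_series_number=int(row["FragmentSeriesNumber"]),
                fragment_charge=int(row["FragmentCharge"]),
                product_mz=float(row["ProductMz"]),
                library_intensity=float(row["LibraryIntensity"]),
            )
        )
    return list(entries.values())


def recompute_product_mz(entry: SpectralLibraryEntry) -> list[float]:
    """Re-derive each stored fragment m/z from the modified sequence;
    used to audit a library for internal mass consistency."""
    from .mass_core import fragment_mz

    peptide = parse_modified_sequence(entry.modified_sequence)
    return [
        fragment_mz(peptide, f.fragment_type, f.fragment_series_number, f.fragment_charge)
        for f in entry.fragments
    ]


# ---------------------------------------------------------------------------
# staggered DIA windows
# ---------------------------------------------------------------------------

@dataclass
class WindowScheme:
    """A (possibly staggered) DIA isolation-window scheme."""

    passes: list[list[tuple[float, float]]]
    width: float
    offset: float
    range: tuple[float, float]

    @property
    def windows_per_pass(self) -> int:
        return len(self.passes[0])

    def covering(self, mz: float, pass_index: int) -> list[int]:
        """Indices of the pass's windows containing ``mz`` (half-open)."""
        return [
            i
            for i, (lo, hi) in enumerate(self.passes[pass_index])
            if lo <= mz < hi
        ]


def make_window_scheme(
    lo: float, hi: float, width: float, offset: float
) -> WindowScheme:
    """Build a staggered isolation-window scheme over [lo, hi).

    Pass 1 tiles [lo, hi) with contiguous half-open windows of the given
    width (``ceil((hi - lo) / width)`` of them); a non-zero offset adds a
    second pass of the same count shifted by +offset. The default
    acquisition scheme, ``make_window_scheme(400, 1000, 8, 4)``, yields the
    2 x 75 staggered 8-Th windows with a 4-Th offset used for 400-1000 Th.
    """
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    if width <= 0:
        raise ValueError("width must be positive")
    if not 0 <= offset < width:
        raise ValueError("offset must satisfy 0 <= offset < width")
    count = math.ceil((hi - lo) / width)
    passes = [[(lo + k * width, lo + (k + 1) * width) for k in range(count)]]
    if offset > 0:
        passes.append(
            [(lo + offset + k * width, lo + offset + (k + 1) * width) for k in range(count)]
        )
    return WindowScheme(passes=passes, width=width, offset=offset, range=(lo, hi))


def write_window_scheme_tsv(scheme: WindowScheme, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["pass", "index", "lower_mz", "upper_mz"])
        for p, windows in enumerate(scheme.passes, start=1):
            for i, (wlo, whi) in enumerate(windows, start=1):
                writer.writerow([p, i, f"{wlo:.4f}", f"{whi:.4f}"])
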