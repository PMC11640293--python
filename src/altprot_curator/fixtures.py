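"""Synthetic, fully ground-truthed inputs for every stage of the pipeline.

Real microprotein studies hinge on data this package cannot ship: searched
raw files, curated databases, DIA reports. This module fabricates small
stand-ins for all four input kinds — proteome FASTAs with planted
alternative proteins, MGF spectra with *controlled* fragment-ion coverage,
PSM tables, and DIA quantification reports with planted log2 effects — and
returns the exact ground truth alongside, so every downstream module can
be scored against known answers rather than eyeballed.

Design notes
------------
* One integer seed drives everything; each generator draws from its own
  substream (``default_rng([stream, seed])``) so adding one fixture never
  perturbs another.
* Spectra are built so recovered coverage is *exact*: the evidenced sites
  are chosen, peaks are placed at the exact theoretical m/z, peptides whose
  theoretical b/y ions collide within twice the match tolerance are
  rejected at generation time, and noise peaks are kept at least twice the
  tolerance away from every theoretical ion.
* DIA reports plant a per-protein log2 effect delta on a protein-specific
  baseline with Gaussian replicate noise; missing cells are simply absent
  rows (never zeros). Defaults: 500 proteins with delta in {0, +1.5, -1.5}
  (400/50/50), 4 vs 4 runs, sigma = 0.3 log2 units, 10% random missingness
  — the regime of a small multi-cell-line label-free comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .mass_core import (
    Peptide,
    digest,
    enumerate_fragments,
    format_modified_sequence,
    fragment_mz,
    precursor_mz,
)
from .psm_curation import Spectrum, write_mgf
from .sequence_db import (
    Biotype,
    Category,
    OrfLocation,
    ProteinRecord,
    write_fasta,
    write_metadata_tsv,
)

# roughly vertebrate-like amino-acid frequencies (no X)
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_AA_FREQ = np.array(
    [
        0.074, 0.025, 0.054, 0.054, 0.047, 0.074, 0.026, 0.068, 0.058, 0.099,
        0.025, 0.045, 0.039, 0.034, 0.052, 0.057, 0.051, 0.073, 0.013, 0.032,
    ]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_STREAM_PROTEOME = 1
_STREAM_SPECTRA = 2
_STREAM_DIA = 3


@dataclass
class DiaSpec:
    """Planted-effect design for the synthetic DIA report."""

    n_proteins: int = 500
    n_up: int = 50
    n_down: int = 50
    delta: float = 1.5  # planted |log2 fold change| of non-null proteins
    sigma: float = 0.3  # replicate noise, log2 units
    n_group1: int = 4
    n_group2: int = 4
    missing_rate: float = 0.1
    missing_mode: str = "random"  # or "group_exclusive"
    group1_label: str = "pancreatic"
    group2_label: str = "other"


@dataclass
class FixtureSpec:
    """Reproducible recipe for one synthetic dataset."""

    seed: int = 0
    n_canonical: int = 20
    n_altprot: int = 12
    n_isoform: int = 3
    n_contaminant: int = 2
    canonical_length_range: tuple[int, int] = (150, 600)
    altprot_length_range: tuple[int, int] = (20, 300)
    altprot_length_median: int = 84  # typical microproteome median size
    shared_peptide_fraction: float = 0.25
    noise_peaks_per_spectrum: int = 10
    tol_ppm: float = 20.0
    dia: DiaSpec = dc_field(default_factory=DiaSpec)

    def __post_init__(self) -> None:
        if not 0 <= self.shared_peptide_fraction <= 1:
            raise ValueError("shared_peptide_fraction must be in [0, 1]")
        if not 0 <= self.dia.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, spec_seed])


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_FREQ))


# ---------------------------------------------------------------------------
# proteome fixture
# ---------------------------------------------------------------------------

@dataclass
class ProteomeFixture:
    canonical: list[ProteinRecord]
    altprot: list[ProteinRecord]  # includes II_ isoform records
    contaminants: list[ProteinRecord]
    shared_peptides: pd.DataFrame  # altprot_accession, canonical_accession, peptide

    def all_records(self) -> list[ProteinRecord]:
        return [*self.canonical, *self.altprot, *self.contaminants]


def _tryptic_shared_candidate(sequence: str, rng: np.random.Generator) -> str | None:
    """A fully tryptic peptide of a canonical protein suitable for planting
    (length 7-15, ends K/R, does not start with P)."""
    peptides = [
        p.sequence
        for p in digest(sequence, 0)
        if 7 <= len(p.sequence) <= 15
        and p.sequence[-1] in "KR"
        and p.sequence[0] != "P"
    ]
    if not peptides:
        return None
    return peptides[int(rng.integers(len(peptides)))]


def _altprot_length(spec: FixtureSpec, rng: np.random.Generator) -> int:
    lo, hi = spec.altprot_length_range
    length = int(round(rng.lognormal(math.log(spec.altprot_length_median), 0.45)))
    return int(np.clip(length, lo, hi))


def make_proteome(spec: FixtureSpec) -> ProteomeFixture:
    """Generate the canonical/AltProt/contaminant FASTA trio with metadata.

    ``round(shared_peptide_fraction * n_altprot)`` of the AltProts carry a
    tryptic peptide copied verbatim from a canonical protein, spliced in so
    it is a tryptic product of both parents — planted non-proteotypic
    cases, enumerated in ``shared_peptides``.
    """
    rng = _rng(spec.seed, _STREAM_PROTEOME)
    n_shared = int(round(spec.shared_peptide_fraction * spec.n_altprot))
    if n_shared > 0 and spec.n_canonical == 0:
        raise ValueError("cannot plant shared peptides without canonical proteins")

    canonical = []
    for i in range(spec.n_canonical):
        length = int(rng.integers(*spec.canonical_length_range))
        canonical.append(
            ProteinRecord(
                accession=f"CP{i + 1:05d}",
                description=f"synthetic canonical protein {i + 1}",
                sequence=_random_sequence(rng, length),
                category=Category.CANONICAL,
            )
        )

    biotype_choices = [
        (Biotype.LNCRNA, None),
        (Biotype.PSEUDOGENE, None),
        (Biotype.MISC_RNA, None),
        (Biotype.PROTEIN_CODING, OrfLocation.FIVE_PRIME_UTR),
        (Biotype.PROTEIN_CODING, OrfLocation.CDS_OTHER_FRAME),
        (Biotype.PROTEIN_CODING, OrfLocation.THREE_PRIME_UTR),
    ]
    # weighted toward non-coding sources, as observed for human microproteomes
    biotype_probs = np.array([0.45, 0.20, 0.08, 0.09, 0.09, 0.09])

    altprot: list[ProteinRecord] = []
    shared_rows = []
    for i in range(spec.n_altprot):
        length = _altprot_length(spec, rng)
        sequence = _random_sequence(rng, length)
        shared_with = None
        if i < n_shared:
            donor = canonical[int(rng.integers(len(canonical)))]
            peptide = _tryptic_shared_candidate(donor.sequence, rng)
            while peptide is None:
                donor = canonical[int(rng.integers(len(canonical)))]
                peptide = _tryptic_shared_candidate(donor.sequence, rng)
            # splice after a K/R anchor so the copy is tryptic here too
            anchor = "K" if rng.random() < 0.5 else "R"
            cut = int(rng.integers(0, max(1, length - 1)))
            tail = sequence[cut:]
            if tail.startswith("P"):
                tail = "A" + tail[1:]
            sequence = sequence[:cut] + anchor + peptide + tail
            shared_with = (donor.accession, peptide)
        biotype, loc = biotype_choices[
            int(rng.choice(len(biotype_choices), p=biotype_probs))
        ]
        acc = f"IP_{700000 + i}"
        altprot.append(
            ProteinRecord(
                accession=acc,
                description=f"synthetic alternative protein {i + 1}",
                sequence=sequence,
                category=Category.ALTPROT,
                transcript_accession=f"TX{i + 1:05d}",
                transcript_biotype=biotype,
                orf_location=loc,
            )
        )
        if shared_with is not None:
            shared_rows.append(
                {
                    "altprot_accession": acc,
                    "canonical_accession": shared_with[0],
                    "peptide": shared_with[1],
                }
            )

    for i in range(spec.n_isoform):
        length = _altprot_length(spec, rng)
        altprot.append(
            ProteinRecord(
                accession=f"II_{600000 + i}",
                description=f"synthetic novel isoform {i + 1}",
                sequence=_random_sequence(rng, length),
                category=Category.ISOFORM,
                transcript_accession=f"TXI{i + 1:05d}",
                transcript_biotype=Biotype.PROTEIN_CODING,
                orf_location=OrfLocation.NOVEL_ISOFORM,
            )
        )

    contaminants = []
    for i in range(spec.n_contaminant):
        length = int(rng.integers(100, 400))
        contaminants.append(
            ProteinRecord(
                accession=f"CON_{i + 1:03d}",
                description=f"synthetic contaminant {i + 1}",
                sequence=_random_sequence(rng, length),
                category=Category.CONTAMINANT,
            )
        )

    shared = pd.DataFrame(
        shared_rows, columns=["altprot_accession", "canonical_accession", "peptide"]
    )
    return ProteomeFixture(canonical, altprot, contaminants, shared)


def write_proteome(fixture: ProteomeFixture, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "canonical": outdir / "canonical.fasta",
        "altprot": outdir / "altprot.fasta",
        "contaminants": outdir / "contaminants.fasta",
        "metadata": outdir / "metadata.tsv",
        "shared_peptides": outdir / "shared_peptides.tsv",
    }
    write_fasta(fixture.canonical, paths["canonical"])
    write_fasta(fixture.altprot, paths["altprot"])
    write_fasta(fixture.contaminants, paths["contaminants"])
    write_metadata_tsv(fixture.altprot, paths["metadata"])
    fixture.shared_peptides.to_csv(paths["shared_peptides"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# spectra fixture
# ---------------------------------------------------------------------------

@dataclass
class SpectraFixture:
    spectra: list[Spectrum]
    psm_rows: pd.DataFrame  # spectrum_id, peptide, charge, accessions
    ground_truth: pd.DataFrame  # spectrum_id, peptide, target/achieved coverage
    rt_map: dict[str, float]


def _site_safe_ions(peptide: Peptide, tol_ppm: float):
    """For each backbone site, the (series, index) single-charge ions whose
    m/z is at least 2x the tolerance away from every ion of another site
    (charges 1-2 considered); None if the peptide has an unresolvable site."""
    n = len(peptide)
    all_ions = enumerate_fragments(peptide, charges=(1, 2))

    def site_of(ion):
        return ion.index if ion.series == "b" else n - ion.index

    safe: dict[int, list[tuple[str, int]]] = {}
    for site in range(1, n):
        options = []
        for series, index in (("b", site), ("y", n - site)):
            mz = fragment_mz(peptide, series, index, 1)
            clash = any(
                site_of(other) != site and abs(other.mz - mz) <= 2 * tol_ppm * mz * 1e-6
                for other in all_ions
            )
            if not clash:
                options.append((series, index))
        if not options:
            return None
        safe[site] = options
    return safe


def random_clean_peptide(
    rng: np.random.Generator,
    length_range: tuple[int, int] = (8, 15),
    tol_ppm: float = 20.0,
    max_tries: int = 200,
) -> Peptide:
    """A random tryptic-looking peptide whose b/y ladder is free of
    within-tolerance m/z collisions between different backbone sites."""
    for _ in range(max_tries):
        length = int(rng.integers(*length_range))
        body = _random_sequence(rng, length - 1).replace("P", "A")
        seq = body + ("K" if rng.random() < 0.5 else "R")
        peptide = Peptide(seq)
        if _site_safe_ions(peptide, tol_ppm) is not None:
            return peptide
    raise RuntimeError("could not generate a collision-free peptide")


def make_spectra(
    spec: FixtureSpec,
    peptides: Sequence[Peptide] | None = None,
    target_coverages: Sequence[float] | None = None,
) -> SpectraFixture:
    """MGF spectra + PSM table with exact ground-truth coverage per PSM.

    For each PSM, ``k = round(target * (n - 1))`` backbone sites are chosen
    and evidenced by one singly-charged b or y peak at its exact m/z (a
    target not representable as k/(n-1) is recorded at the nearest
    achievable value); noise peaks are kept >= 2x tolerance away from every
    theoretical ion so they can never match.
    """
    rng = _rng(spec.seed, _STREAM_SPECTRA)
    if target_coverages is None:
        target_coverages = [0.5, 0.74, 0.75, 0.76, 1.0]
    if peptides is None:
        peptides = [
            random_clean_peptide(rng, tol_ppm=spec.tol_ppm)
            for _ in target_coverages
        ]
    if len(peptides) != len(target_coverages):
        raise ValueError("one target coverage per peptide required")

    spectra = []
    psm_rows = []
    truth_rows = []
    rt_map = {}
    for i, (peptide, target) in enumerate(zip(peptides, target_coverages)):
        safe = _site_safe_ions(peptide, spec.tol_ppm)
        if safe is None:
            raise ValueError(
                f"peptide {peptide.sequence} has within-tolerance fragment "
                "collisions; coverage ground truth would not be exact"
            )
        n = len(peptide)
        k = int(round(float(target) * (n - 1)))
        k = int(np.clip(k, 0, n - 1))
        achieved = k / (n - 1)
        sites = rng.choice(np.arange(1, n), size=k, replace=False)
        peaks = []
        theoretical = [ion.mz for ion in enumerate_fragments(peptide, charges=(1, 2))]
        for site in sorted(int(s) for s in sites):
            series, index = safe[site][int(rng.integers(len(safe[site])))]
            peaks.append(
                (fragment_mz(peptide, series, index, 1), float(rng.uniform(1e3, 1e5)))
            )
        n_noise = 0
        while n_noise < spec.noise_peaks_per_spectrum:
            mz = float(rng.uniform(150.0, 1500.0))
            if all(abs(mz - t) > 2 * spec.tol_ppm * t * 1e-6 for t in theoretical):
                peaks.append((mz, float(rng.uniform(1e2, 1e4))))
                n_noise += 1
        sid = f"scan_{i + 1:05d}"
        charge = 2
        spectra.append(
            Spectrum(
                spectrum_id=sid,
                precursor_mz=precursor_mz(peptide, charge),
                precursor_charge=charge,
                peaks=peaks,
            )
        )
        psm_rows.append(
            {
                "spectrum_id": sid,
                "peptide": format_modified_sequence(peptide),
                "charge": charge,
                "accessions": ";".join(sorted(peptide.parent_accessions)),
            }
        )
        truth_rows.append(
            {
                "spectrum_id": sid,
                "peptide": peptide.sequence,
                "target_coverage": float(target),
                "achieved_coverage": achieved,
                "n_sites_evidenced": k,
            }
        )
        rt_map[sid] = float(rng.uniform(5.0, 90.0))

    return SpectraFixture(
        spectra=spectra,
        psm_rows=pd.DataFrame(
            psm_rows, columns=["spectrum_id", "peptide", "charge", "accessions"]
        ),
        ground_truth=pd.DataFrame(truth_rows),
        rt_map=rt_map,
    )


def write_spectra(fixture: SpectraFixture, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mgf": outdir / "spectra.mgf",
        "psms": outdir / "psms.tsv",
        "coverage_truth": outdir / "coverage_truth.tsv",
        "rt": outdir / "retention_times.tsv",
    }
    write_mgf(fixture.spectra, paths["mgf"])
    fixture.psm_rows.to_csv(paths["psms"], sep="\t", index=False)
    fixture.ground_truth.to_csv(paths["coverage_truth"], sep="\t", index=False)
    pd.DataFrame(
        [{"spectrum_id": k, "rt_minutes": v} for k, v in fixture.rt_map.items()]
    ).to_csv(paths["rt"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# DIA report fixture
# ---------------------------------------------------------------------------

@dataclass
class DiaFixture:
    report: pd.DataFrame  # long format: Run, Protein.Group, PG.MaxLFQ
    group_of_run: dict[str, str]
    ground_truth: pd.DataFrame  # accession, delta, exclusive_group


def make_dia_report(spec: FixtureSpec) -> DiaFixture:
    """Long-format DIA report with planted log2 effects.

    Each protein gets a baseline log2 abundance ~ U(20, 30); group-1 runs
    add the planted delta; every cell adds N(0, sigma) noise and is emitted
    on the linear scale. Missingness: ``random`` drops cells independently
    at ``missing_rate``; ``group_exclusive`` instead blanks one whole group
    for ``round(missing_rate * n_proteins)`` proteins (alternating groups).
    """
    d = spec.dia
    rng = _rng(spec.seed, _STREAM_DIA)
    if d.n_up + d.n_down > d.n_proteins:
        raise ValueError("more non-null proteins than proteins")
    if (d.n_group1 < 2 or d.n_group2 < 2) and (d.n_up or d.n_down):
        import warnings

        warnings.warn("fewer than 2 runs per group: planted effects untestable")

    runs1 = [f"{d.group1_label}_{i + 1}" for i in range(d.n_group1)]
    runs2 = [f"{d.group2_label}_{i + 1}" for i in range(d.n_group2)]
    group_of_run = {**{r: d.group1_label for r in runs1}, **{r: d.group2_label for r in runs2}}

    deltas = np.zeros(d.n_proteins)
    deltas[: d.n_up] = d.delta
    deltas[d.n_up : d.n_up + d.n_down] = -d.delta
    order = rng.permutation(d.n_proteins)
    deltas = deltas[order]

    accessions = [f"PG_{i + 1:05d}" for i in range(d.n_proteins)]
    baselines = rng.uniform(20.0, 30.0, size=d.n_proteins)

    exclusive = [""] * d.n_proteins
    if d.missing_mode == "group_exclusive":
        n_excl = int(round(d.missing_rate * d.n_proteins))
        excl_idx = rng.choice(d.n_proteins, size=n_excl, replace=False)
        for j, idx in enumerate(excl_idx):
            exclusive[int(idx)] = d.group1_label if j % 2 == 0 else d.group2_label
    elif d.missing_mode != "random":
        raise ValueError(f"unknown missing_mode {d.missing_mode!r}")

    rows = []
    for i, acc in enumerate(accessions):
        for run in (*runs1, *runs2):
            in_group1 = run in runs1
            if exclusive[i] == d.group1_label and not in_group1:
                continue
            if exclusive[i] == d.group2_label and in_group1:
                continue
            if d.missing_mode == "random" and rng.random() < d.missing_rate:
                continue
            log2_intensity = (
                baselines[i]
                + (deltas[i] if in_group1 else 0.0)
                + rng.normal(0.0, d.sigma)
            )
            rows.append(
                {"Run": run, "Protein.Group": acc, "PG.MaxLFQ": 2.0 ** log2_intensity}
            )

    report = pd.DataFrame(rows, columns=["Run", "Protein.Group", "PG.MaxLFQ"])
    truth = pd.DataFrame(
        {
            "accession": accessions,
            "delta": deltas,
            "exclusive_group": exclusive,
        }
    )
    return DiaFixture(report=report, group_of_run=group_of_run, ground_truth=truth)


def write_dia_report(fixture: DiaFixture, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": outdir / "dia_report.tsv",
        "groups": outdir / "groups.tsv",
        "effects_truth": outdir / "effects_truth.tsv",
    }
    fixture.report.to_csv(paths["report"], sep="\t", index=False, float_format="%.6f")
    pd.DataFrame(
        [{"run": r, "group": g} for r, g in fixture.group_of_run.items()]
    ).to_csv(paths["groups"], sep="\t", index=False)
    fixture.ground_truth.to_csv(
        paths["effects_truth"], sep="\t", index=False, float_format="%.6f"
    )
    return paths
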