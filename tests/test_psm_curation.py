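"""Fragment matching, backbone coverage, the 75% filter, proteotypicity."""

import numpy as np
import pytest

from altprot_curator.mass_core import Peptide, enumerate_fragments, fragment_mz
from altprot_curator.psm_curation import (
    AnnotatedPSM,
    Spectrum,
    apply_coverage_filter,
    check_proteotypicity,
    coverage_fraction,
    match_fragments,
    read_mgf,
    write_mgf,
)
from altprot_curator.sequence_db import Category, ProteinDatabase, ProteinRecord

PEPTIDE = Peptide("ELVISLIVESK")  # length 11, 10 backbone sites


def spectrum_with(ions, spectrum_id="s1", noise=(), peptide=PEPTIDE):
    peaks = [(fragment_mz(peptide, s, i, z), 100.0) for s, i, z in ions]
    peaks += [(mz, 10.0) for mz in noise]
    return Spectrum(spectrum_id, 600.0, 2, peaks)


# ---------------------------------------------------------------------------
# MGF I/O
# ---------------------------------------------------------------------------

def test_mgf_round_trip(tmp_path):
    sp = Spectrum("scan_1", 523.77, 2, [(200.1, 5.0), (300.2, 9.0), (150.0, 1.0)])
    path = tmp_path / "one.mgf"
    write_mgf([sp], path)
    back = read_mgf(path)
    assert len(back) == 1
    assert back[0].spectrum_id == "scan_1"
    assert back[0].precursor_charge == 2
    assert len(back[0].peaks) == 3
    # peaks come back sorted regardless of written order
    assert back[0].peaks == sorted(back[0].peaks)


def test_mgf_without_charge_defaults_with_warning(tmp_path):
    path = tmp_path / "nocharge.mgf"
    path.write_text(
        "BEGIN IONS\nTITLE=t1\nPEPMASS=500.0\n100.0 1.0\nEND IONS\n"
    )
    with pytest.warns(UserWarning, match="no CHARGE"):
        spectra = read_mgf(path)
    assert spectra[0].precursor_charge == 2


def test_mgf_without_pepmass_is_an_error(tmp_path):
    path = tmp_path / "nopepmass.mgf"
    path.write_text("BEGIN IONS\nTITLE=t1\nCHARGE=2+\n100.0 1.0\nEND IONS\n")
    with pytest.raises(Exception):
        read_mgf(path)


# ---------------------------------------------------------------------------
# coverage semantics
# ---------------------------------------------------------------------------

def ions(*specs):
    """FragmentIon stand-ins from (series, index) pairs at charge 1."""
    return [
        type("Ion", (), {"series": s, "index": i, "charge": 1, "mz": 1.0})()
        for s, i in specs
    ]


def test_full_b_ladder_is_complete_coverage():
    assert coverage_fraction(ions(*[("b", i) for i in range(1, 8)]), 8) == 1.0


def test_complementary_pair_covers_one_site():
    # b3 and y5 of an 8-mer both evidence site 3
    assert coverage_fraction(ions(("b", 3), ("y", 5)), 8) == pytest.approx(1 / 7)


def test_mixed_ladder_site_count():
    # n=8: b1,b2,b3 cover sites 1-3; y1,y2,y3 cover sites 7,6,5 -> 6 of 7
    cov = coverage_fraction(ions(("b", 1), ("b", 2), ("b", 3), ("y", 1), ("y", 2), ("y", 3)), 8)
    assert cov == pytest.approx(6 / 7)


def test_coverage_requires_two_residues():
    with pytest.raises(ValueError):
        coverage_fraction([], 1)


def test_residue_semantics_variant():
    # b3 of an 8-mer contains residues 1-3
    assert coverage_fraction(ions(("b", 3)), 8, semantics="residue") == pytest.approx(3 / 8)


# ---------------------------------------------------------------------------
# fragment matching
# ---------------------------------------------------------------------------

def test_complete_ladder_gives_coverage_one():
    sp = spectrum_with([("b", i, 1) for i in range(1, len(PEPTIDE))])
    psm = match_fragments(sp, PEPTIDE)
    assert psm.coverage == 1.0


def test_no_matching_peaks_gives_zero_coverage():
    sp = Spectrum("s1", 600.0, 2, [(3000.0, 5.0), (3100.0, 5.0)])
    assert match_fragments(sp, PEPTIDE).coverage == 0.0


def test_empty_spectrum_is_not_an_error():
    assert match_fragments(Spectrum("s1", 600.0, 2, []), PEPTIDE).coverage == 0.0


def test_partial_ladder_site_arithmetic():
    # length 10: b1..b4 cover sites 1-4, y1..y2 cover sites 9,8 -> 6/9
    pep = Peptide("ACDEFGHIKR")
    sp = spectrum_with(
        [("b", i, 1) for i in range(1, 5)] + [("y", 1, 1), ("y", 2, 1)],
        peptide=pep,
    )
    assert match_fragments(sp, pep).coverage == pytest.approx(6 / 9)


def test_matching_is_permutation_invariant(rng):
    sp = spectrum_with(
        [("b", 2, 1), ("y", 3, 1), ("b", 5, 2)], noise=[333.3, 777.7, 1234.5]
    )
    base = match_fragments(sp, PEPTIDE)
    for _ in range(5):
        peaks = list(sp.peaks)
        rng.shuffle(peaks)
        again = match_fragments(Spectrum("s1", 600.0, 2, peaks), PEPTIDE)
        assert again.coverage == base.coverage
        assert [(m.ion.annotation, m.peak_index) for m in again.matched_ions] == [
            (m.ion.annotation, m.peak_index) for m in base.matched_ions
        ]


def test_each_ion_matches_at_most_one_peak_within_tolerance():
    mz = fragment_mz(PEPTIDE, "b", 3, 1)
    # two peaks inside tolerance; the nearer one must win
    sp = Spectrum("s1", 600.0, 2, [(mz - 2e-3, 5.0), (mz + 3e-3, 5.0)])
    psm = match_fragments(sp, PEPTIDE, tol_ppm=20)
    b3 = [m for m in psm.matched_ions if m.ion.annotation == "b3^1"]
    assert len(b3) == 1
    assert b3[0].peak_index == 0


def test_coverage_monotone_in_matched_ions(rng):
    """Adding evidenced sites never decreases coverage; coverage stays in [0,1]."""
    pep = Peptide("ACDEFGHIKR")
    sites = [("b", i, 1) for i in range(1, len(pep))]
    prev = 0.0
    for k in range(len(sites) + 1):
        psm = match_fragments(spectrum_with(sites[:k], peptide=pep), pep)
        assert 0.0 <= psm.coverage <= 1.0
        assert psm.coverage >= prev
        prev = psm.coverage


# ---------------------------------------------------------------------------
# the >= 75% filter
# ---------------------------------------------------------------------------

def psm_with_coverage(cov, sid="s"):
    return AnnotatedPSM(spectrum_id=sid, peptide=PEPTIDE, coverage=cov)


def test_threshold_boundary_is_inclusive():
    kept, rejected = apply_coverage_filter(
        [psm_with_coverage(0.75), psm_with_coverage(0.7499)]
    )
    assert [p.coverage for p in kept] == [0.75]
    assert [p.coverage for p in rejected] == [0.7499]


def test_filter_partition_is_exhaustive_and_nested():
    psms = [psm_with_coverage(c, str(i)) for i, c in enumerate(np.linspace(0, 1, 21))]
    kept, rejected = apply_coverage_filter(psms)
    assert len(kept) + len(rejected) == len(psms)
    loose_kept, _ = apply_coverage_filter(psms, threshold=0.5)
    strict_kept, _ = apply_coverage_filter(psms, threshold=0.9)
    assert {p.spectrum_id for p in strict_kept} <= {p.spectrum_id for p in loose_kept}
    assert apply_coverage_filter([]) == ([], [])


def test_filter_threshold_validation():
    with pytest.raises(ValueError):
        apply_coverage_filter([], threshold=0.0)


# ---------------------------------------------------------------------------
# proteotypicity
# ---------------------------------------------------------------------------

def db_of(*entries):
    return ProteinDatabase(
        ProteinRecord(acc, "", seq, cat) for acc, seq, cat in entries
    )


def test_shared_peptide_is_not_proteotypic():
    db = db_of(
        ("IP_1", "MMMSIKMMM", Category.ALTPROT),
        ("P1", "AAASIKAAA", Category.CANONICAL),
    )
    proteotypic, hits = check_proteotypicity("SIK", db, parent_accession="IP_1")
    assert not proteotypic
    assert hits == {"IP_1", "P1"}


def test_unique_peptide_is_proteotypic():
    db = db_of(
        ("IP_1", "MMMSWKMMM", Category.ALTPROT),
        ("P1", "AAAGGGAAA", Category.CANONICAL),
    )
    proteotypic, hits = check_proteotypicity("SWK", db, parent_accession="IP_1")
    assert proteotypic and hits == {"IP_1"}


def test_il_equivalence_collapses_isobaric_hits():
    db = db_of(
        ("IP_1", "MMMSIKMMM", Category.ALTPROT),
        ("P1", "AAASLKAAA", Category.CANONICAL),
    )
    assert check_proteotypicity("SIK", db, il_equivalent=True)[0] is False
    assert check_proteotypicity("SIK", db, il_equivalent=False)[0] is True


def test_inconsistent_parent_claim_is_an_error():
    db = db_of(("IP_1", "MMMM", Category.ALTPROT))
    with pytest.raises(ValueError, match="inconsistent PSM"):
        check_proteotypicity("SIK", db, parent_accession="IP_1")


def brute_force_hits(peptide, db, il_equivalent):
    def collapse(s):
        return s.replace("I", "J").replace("L", "J") if il_equivalent else s

    needle = collapse(peptide)
    hits = set()
    for rec in db:
        hay = collapse(rec.sequence)
        for start in range(len(hay) - len(needle) + 1):
            if hay[start : start + len(needle)] == needle:
                hits.add(rec.accession)
                break
    return hits


def test_proteotypicity_agrees_with_brute_force_scan(rng):
    """Substring hits match an exhaustive all-positions scan on random
    databases, with and without I/L collapse."""
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    for trial in range(20):
        db = ProteinDatabase(
            ProteinRecord(
                f"P{j}", "", "".join(rng.choice(aa, size=int(rng.integers(20, 80)))),
                Category.CANONICAL,
            )
            for j in range(int(rng.integers(5, 40)))
        )
        donor = db[f"P{int(rng.integers(len(db)))}"]
        start = int(rng.integers(0, len(donor.sequence) - 6))
        peptide = donor.sequence[start : start + 6]
        for il in (True, False):
            _, hits = check_proteotypicity(peptide, db, il_equivalent=il)
            assert hits == brute_force_hits(peptide, db, il)


def test_planted_shared_peptides_flagged_non_proteotypic(proteome, database):
    for _, row in proteome.shared_peptides.iterrows():
        proteotypic, hits = check_proteotypicity(
            row["peptide"], database, parent_accession=row["altprot_accession"]
        )
        assert not proteotypic
        assert {row["altprot_accession"], row["canonical_accession"]} <= hits
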