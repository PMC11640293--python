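"""The synthetic generators: determinism, ground truth, reader round trips."""

import math

import numpy as np
import pandas as pd
import pytest

from altprot_curator import fixtures as fx
from altprot_curator.dia_quant import (
    DifferentialClass,
    differential_analysis,
    normalize_median,
    read_dia_report,
)
from altprot_curator.mass_core import parse_modified_sequence
from altprot_curator.psm_curation import (
    apply_coverage_filter,
    match_fragments,
    read_mgf,
    read_psm_table,
)
from altprot_curator.sequence_db import Category, merge_databases, read_fasta


def hash_dir(path):
    return {p.name: p.read_bytes() for p in sorted(path.iterdir())}


def test_same_seed_gives_byte_identical_outputs(tmp_path):
    spec = fx.FixtureSpec(seed=5, dia=fx.DiaSpec(n_proteins=40, n_up=4, n_down=4))
    a, b = tmp_path / "a", tmp_path / "b"
    for out in (a, b):
        fx.write_proteome(fx.make_proteome(spec), out)
        fx.write_spectra(fx.make_spectra(spec), out)
        fx.write_dia_report(fx.make_dia_report(spec), out)
    assert hash_dir(a) == hash_dir(b)


def test_different_seeds_differ(tmp_path):
    specs = [fx.FixtureSpec(seed=s) for s in (1, 2)]
    seqs = [fx.make_proteome(s).canonical[0].sequence for s in specs]
    assert seqs[0] != seqs[1]


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

def test_shared_peptide_count_follows_spec():
    spec = fx.FixtureSpec(seed=1, n_canonical=10, n_altprot=5, shared_peptide_fraction=0.4)
    fixture = fx.make_proteome(spec)
    assert len(fixture.shared_peptides) == 2


def test_shared_fraction_without_canonicals_is_an_error():
    with pytest.raises(ValueError):
        fx.make_proteome(
            fx.FixtureSpec(seed=1, n_canonical=0, n_altprot=5, shared_peptide_fraction=0.4)
        )


def test_planted_peptides_are_substrings_of_both_parents(proteome, database):
    for _, row in proteome.shared_peptides.iterrows():
        assert row["peptide"] in database[row["altprot_accession"]].sequence
        assert row["peptide"] in database[row["canonical_accession"]].sequence


def test_proteome_round_trips_through_fasta_readers(tmp_path, proteome):
    paths = fx.write_proteome(proteome, tmp_path)
    can = read_fasta(paths["canonical"], Category.CANONICAL)
    alt = read_fasta(paths["altprot"], Category.ALTPROT)
    con = read_fasta(paths["contaminants"], Category.CONTAMINANT)
    db = merge_databases(can, alt, con)
    assert len(db) == len(proteome.all_records())
    assert len([r for r in db if r.category is Category.ISOFORM]) > 0


def test_altprot_lengths_within_requested_range(proteome, fixture_spec):
    lo, hi = fixture_spec.altprot_length_range
    for rec in proteome.altprot:
        # planted shared peptides may extend a sequence slightly beyond hi
        assert lo <= len(rec) <= hi + 20


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def test_recovered_coverage_equals_ground_truth_exactly():
    spec = fx.FixtureSpec(seed=11)
    rng = np.random.default_rng(11)
    peptides = [fx.random_clean_peptide(rng) for _ in range(20)]
    targets = list(np.tile([0.5, 0.74, 0.75, 0.76, 1.0], 4))
    sf = fx.make_spectra(spec, peptides, targets)
    for sp, (_, truth), pep_text in zip(
        sf.spectra, sf.ground_truth.iterrows(), sf.psm_rows["peptide"]
    ):
        psm = match_fragments(sp, parse_modified_sequence(pep_text), tol_ppm=spec.tol_ppm)
        assert psm.coverage == pytest.approx(truth["achieved_coverage"], abs=0)


def test_filter_partition_matches_ground_truth():
    spec = fx.FixtureSpec(seed=12)
    rng = np.random.default_rng(12)
    peptides = [fx.random_clean_peptide(rng) for _ in range(25)]
    targets = list(np.tile([0.5, 0.74, 0.75, 0.76, 1.0], 5))
    sf = fx.make_spectra(spec, peptides, targets)
    psms = [
        match_fragments(sp, parse_modified_sequence(p), tol_ppm=spec.tol_ppm)
        for sp, p in zip(sf.spectra, sf.psm_rows["peptide"])
    ]
    kept, rejected = apply_coverage_filter(psms, 0.75)
    truth = sf.ground_truth.set_index("spectrum_id")["achieved_coverage"]
    assert {p.spectrum_id for p in kept} == set(truth.index[truth >= 0.75])
    assert {p.spectrum_id for p in rejected} == set(truth.index[truth < 0.75])


def test_spectra_round_trip_through_mgf_and_psm_readers(tmp_path):
    spec = fx.FixtureSpec(seed=13)
    sf = fx.make_spectra(spec)
    paths = fx.write_spectra(sf, tmp_path)
    spectra = read_mgf(paths["mgf"])
    assert [sp.spectrum_id for sp in spectra] == [s.spectrum_id for s in sf.spectra]
    rows = read_psm_table(paths["psms"])
    assert len(rows) == len(sf.psm_rows)
    for row, sp in zip(rows, spectra):
        assert row["spectrum_id"] == sp.spectrum_id


def test_unachievable_target_snaps_to_nearest_representable():
    spec = fx.FixtureSpec(seed=14)
    rng = np.random.default_rng(14)
    pep = fx.random_clean_peptide(rng, length_range=(9, 10))  # 8 or 9 sites
    sf = fx.make_spectra(spec, [pep], [0.72])
    truth = sf.ground_truth.iloc[0]
    n_sites = len(pep) - 1
    assert truth["achieved_coverage"] == round(0.72 * n_sites) / n_sites


# ---------------------------------------------------------------------------
# DIA report
# ---------------------------------------------------------------------------

def run_pipeline(dia_fixture, tmp_path, **kwargs):
    paths = fx.write_dia_report(dia_fixture, tmp_path)
    table = read_dia_report(paths["report"], dia_fixture.group_of_run)
    table = normalize_median(table)
    return differential_analysis(table, group1="pancreatic", **kwargs)


def test_zero_effect_zero_noise_report(tmp_path):
    spec = fx.FixtureSpec(
        seed=3,
        dia=fx.DiaSpec(n_proteins=30, n_up=0, n_down=0, sigma=0.0, missing_rate=0.0),
    )
    dia = fx.make_dia_report(spec)
    results = run_pipeline(dia, tmp_path)
    for r in results:
        assert r.log2fc == pytest.approx(0.0, abs=1e-9)
        # zero variance in both groups -> untestable
        assert r.klass is DifferentialClass.UNTESTABLE


def test_group_exclusive_proteins_are_called_exclusive(tmp_path):
    spec = fx.FixtureSpec(
        seed=4,
        dia=fx.DiaSpec(
            n_proteins=40, n_up=0, n_down=0, missing_rate=0.2,
            missing_mode="group_exclusive",
        ),
    )
    dia = fx.make_dia_report(spec)
    results = {r.accession: r for r in run_pipeline(dia, tmp_path)}
    truth = dia.ground_truth.set_index("accession")["exclusive_group"]
    called = {
        "pancreatic": DifferentialClass.EXCLUSIVE_GROUP1,
        "other": DifferentialClass.EXCLUSIVE_GROUP2,
    }
    n_exclusive = 0
    for acc, group in truth.items():
        if group:
            assert results[acc].klass is called[group]
            n_exclusive += 1
    assert n_exclusive == 8  # round(0.2 * 40)


def test_planted_effects_recovered_with_high_sensitivity(tmp_path):
    """Sensitivity >= 0.9 and FPR <= 0.05 at p < 0.05, |log2fc| > 1 on the
    default planted-effect design."""
    spec = fx.FixtureSpec(seed=0)
    dia = fx.make_dia_report(spec)
    results = run_pipeline(dia, tmp_path)
    truth = dia.ground_truth.set_index("accession")["delta"]
    sig_classes = (DifferentialClass.UP_IN_GROUP1, DifferentialClass.UP_IN_GROUP2)
    tp = sum(
        1 for r in results if truth[r.accession] != 0 and r.klass in sig_classes
    )
    fp = sum(
        1 for r in results if truth[r.accession] == 0 and r.klass in sig_classes
    )
    n_nonnull = (truth != 0).sum()
    assert tp / n_nonnull >= 0.9
    assert fp / (len(results) - n_nonnull) <= 0.05


def test_signs_of_recovered_effects_match_truth(tmp_path):
    spec = fx.FixtureSpec(seed=0)
    dia = fx.make_dia_report(spec)
    results = run_pipeline(dia, tmp_path)
    truth = dia.ground_truth.set_index("accession")["delta"]
    for r in results:
        if r.klass is DifferentialClass.UP_IN_GROUP1:
            assert truth[r.accession] > 0
        elif r.klass is DifferentialClass.UP_IN_GROUP2:
            assert truth[r.accession] < 0


def test_report_has_no_zero_filled_cells(tmp_path):
    spec = fx.FixtureSpec(seed=6, dia=fx.DiaSpec(n_proteins=50, n_up=5, n_down=5))
    dia = fx.make_dia_report(spec)
    assert (dia.report["PG.MaxLFQ"] > 0).all()
    n_cells = 50 * 8
    assert len(dia.report) < n_cells  # some cells genuinely absent
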