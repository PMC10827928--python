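"""Generators: determinism, planted ground truth, round-trips."""

import numpy as np
import pytest

from proteoconcord import ihc
from proteoconcord.concordance import calls_from_table, match_tables, summarize
from proteoconcord.synthetic import (
    ConcordanceTruth,
    ModuleTruth,
    StainImageTruth,
    gen_category_scenario,
    gen_disease_tables,
    gen_expression,
    gen_stain_image,
    gen_study_reports,
    plant_reference_set,
)
from proteoconcord.tables_io import read_diff_table, write_diff_table

CANON = {"uniprot": "uniprot", "gene": "gene", "log2fc": "log2fc", "direction": "direction"}


def test_disease_tables_determinism_byte_identical(tmp_path):
    truth = ConcordanceTruth(seed=7)
    for run in ("one", "two"):
        a, b, _ = gen_disease_tables(truth)
        write_diff_table(a, tmp_path / f"a_{run}.tsv")
        write_diff_table(b, tmp_path / f"b_{run}.tsv")
    assert (tmp_path / "a_one.tsv").read_bytes() == (tmp_path / "a_two.tsv").read_bytes()
    assert (tmp_path / "b_one.tsv").read_bytes() == (tmp_path / "b_two.tsv").read_bytes()


def test_disease_tables_roundtrip_through_readers(tmp_path):
    a, _, _ = gen_disease_tables(ConcordanceTruth(seed=1))
    path = tmp_path / "a.tsv"
    write_diff_table(a, path)
    again = read_diff_table(path, CANON)
    assert len(again) == len(a)
    assert again.keys() == a.keys()


def test_disease_tables_invariant_violations():
    with pytest.raises(ValueError, match="n_overlap"):
        ConcordanceTruth(n_a=10, n_b=10, n_overlap=20)
    with pytest.raises(ValueError, match="n_universe"):
        ConcordanceTruth(n_universe=50, n_a=100)
    with pytest.raises(ValueError, match="frac_same_direction"):
        ConcordanceTruth(frac_same_direction=1.5)


def test_disease_tables_overlap_is_exact():
    truth = ConcordanceTruth(n_a=80, n_b=60, n_overlap=33, frac_same_direction=0.7, seed=5)
    a, b, answer = gen_disease_tables(truth)
    shared = set(a.keys()) & set(b.keys())
    assert len(shared) == 33
    assert answer["summary"]["n_same"] == round(0.7 * 33)


def test_category_scenario_plants_exact_composition():
    a, b_calls, answer = gen_category_scenario(3, 4, 5, 2, 6, seed=8)
    summary = summarize(match_tables(a, b_calls))
    assert summary.__dict__ | answer["summary"] == summary.__dict__  # planted counts recovered
    assert summary.n_same_up == 3 and summary.n_a_only == 6


def test_plant_reference_set_hits_are_exact():
    a, b_calls, answer = gen_category_scenario(10, 10, 10, 5, 5, seed=0)
    rs = plant_reference_set(
        a, n_hits=7, size=50, name="lesion", seed=3,
        categories=answer["categories"], hit_categories=("same_up", "same_down"),
    )
    assert len(rs) == 50
    table_keys = set(a.keys())
    assert len(rs.keys & table_keys) == 7


def test_study_reports_classes_and_errors():
    reports, answer = gen_study_reports(100, (2, 10), inconsistency_rate=1.0, seed=0)
    assert all(v["call"] == "inconsistent" for v in answer.values())
    reports, answer = gen_study_reports(100, (1, 10), inconsistency_rate=0.0, seed=0)
    assert all(v["call"] in ("increased", "decreased") for v in answer.values())
    with pytest.raises(ValueError, match="report_count_range"):
        gen_study_reports(10, (0, 5))
    with pytest.raises(ValueError, match="inconsistency_rate"):
        gen_study_reports(10, (1, 5), inconsistency_rate=2.0)


def test_expression_noiseless_module_is_perfectly_correlated():
    m, _, key = gen_expression(
        ModuleTruth(n_proteins=20, module_sizes=(10,), noise_sd=0.0, within_module_cor=0.6, n_samples=12, seed=0)
    )
    members = m.values[np.array(key["labels"]) == 1]
    cor = np.corrcoef(members)
    assert np.allclose(cor, 1.0)


def test_expression_within_module_correlation_near_target():
    m, _, key = gen_expression(ModuleTruth(n_proteins=60, module_sizes=(60,), n_samples=500, seed=2))
    cor = np.corrcoef(m.values)
    off = cor[~np.eye(60, dtype=bool)]
    assert off.mean() == pytest.approx(0.8, abs=0.05)


def test_expression_trait_correlation_near_target():
    rs = []
    for seed in range(10):
        truth = ModuleTruth(n_proteins=40, module_sizes=(40,), n_samples=400, trait_cor=0.9, seed=seed)
        m, trait, _ = gen_expression(truth)
        latent_proxy = m.values.mean(axis=0)
        rs.append(np.corrcoef(latent_proxy, trait)[0, 1])
    assert np.mean(rs) == pytest.approx(0.9, abs=0.05)


def test_expression_validation():
    with pytest.raises(ValueError, match="n_samples"):
        ModuleTruth(n_samples=3)
    with pytest.raises(ValueError, match="module sizes"):
        ModuleTruth(n_proteins=10, module_sizes=(20,))


def test_stain_image_exact_pixel_counts():
    truth = StainImageTruth(positive_fraction=0.25)
    img, mask, answer = gen_stain_image(truth)
    painted = np.all(img == np.array(truth.positive_color), axis=-1).sum()
    assert painted == answer["n_positive"] == 2500


def test_stain_image_determinism_and_validation():
    t = StainImageTruth(seed=4)
    img1, _, _ = gen_stain_image(t)
    img2, _, _ = gen_stain_image(t)
    assert np.array_equal(img1, img2)
    with pytest.raises(ValueError, match="positive_fraction"):
        StainImageTruth(positive_fraction=1.5)
    with pytest.raises(ValueError, match="colors"):
        StainImageTruth(positive_color=(1, 2, 3), negative_color=(1, 2, 3))


def test_stain_image_jitter_preserves_classification():
    t = StainImageTruth(positive_fraction=0.4, seed=0)
    plain, mask, _ = gen_stain_image(t)
    jittered, _, _ = gen_stain_image(t, jitter_sd=3.0)
    cfg = ihc.PixelClassifierConfig()
    assert np.array_equal(ihc.classify_image(plain, cfg) > 0, ihc.classify_image(jittered, cfg) > 0)
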