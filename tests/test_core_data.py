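"""Readers, prevalence filtering, brain-volume normalization, and the
cohort-assembly (datapoint pairing) rules."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutbrain.core_data import (
    BrainVolumeTable,
    FeatureTable,
    SubjectRecord,
    assemble_concurrent,
    assemble_future,
    normalize_brain_volumes,
    prevalence_filter,
    read_gene_profiles,
    read_gene_sets,
    read_taxonomic_profiles,
)
from gutbrain.synthetic import SimConfig, simulate_cohort, write_cohort


# ---------------------------------------------------------------------------
# taxonomic profile reader


def _write(path, text):
    path.write_text(text)
    return path


def test_taxonomic_reader_keeps_species_and_renormalizes(tmp_path):
    path = _write(tmp_path / "taxa.tsv", (
        "#comment line\n"
        "clade_name\tsampleA\n"
        "k__A\t100\n"
        "k__A|s__X\t60\n"
        "k__B|s__Y\t40\n"
        "k__B|s__Y|t__Y_strain\t40\n"
    ))
    table = read_taxonomic_profiles(path)
    assert table.feature_ids == ["X", "Y"]
    assert table.normalized
    np.testing.assert_allclose(table.values, [[0.6, 0.4]])


def test_taxonomic_reader_rejects_duplicate_sample_headers(tmp_path):
    path = _write(tmp_path / "dup.tsv", (
        "clade_name\tS1\tS1\n"
        "k__A|s__X\t60\t70\n"
    ))
    with pytest.raises(ValueError, match="duplicated sample headers"):
        read_taxonomic_profiles(path)


def test_taxonomic_reader_rejects_duplicate_species(tmp_path):
    path = _write(tmp_path / "dupsp.tsv", (
        "clade_name\tS1\n"
        "k__A|g__G1|s__X\t60\n"
        "k__B|g__G2|s__X\t40\n"
    ))
    with pytest.raises(ValueError, match="X"):
        read_taxonomic_profiles(path)


def test_taxonomic_reader_rejects_empty_sample(tmp_path):
    path = _write(tmp_path / "empty.tsv", (
        "clade_name\tS1\tS2\n"
        "k__A|s__X\t60\t0\n"
        "k__B|s__Y\t40\t0\n"
    ))
    with pytest.raises(ValueError, match="empty sample"):
        read_taxonomic_profiles(path)


def test_reader_accepts_gzip(tmp_path):
    path = tmp_path / "taxa.tsv.gz"
    with gzip.open(path, "wt") as fh:
        fh.write("clade_name\tS1\nk__A|s__X\t60\nk__B|s__Y\t40\n")
    table = read_taxonomic_profiles(path)
    np.testing.assert_allclose(table.values, [[0.6, 0.4]])


# ---------------------------------------------------------------------------
# gene profile reader


def test_gene_reader_drops_stratified_and_unmapped(tmp_path):
    path = _write(tmp_path / "genes.tsv", (
        "# Gene Family\tS1\n"
        "U1\t10\n"
        "U1|g__X.s__Y\t7\n"
        "U2\t30\n"
    ))
    table = read_gene_profiles(path)
    assert table.feature_ids == ["U1", "U2"]
    np.testing.assert_allclose(table.values, [[0.25, 0.75]])

    path2 = _write(tmp_path / "genes2.tsv", (
        "# Gene Family\tS1\nUNMAPPED\t90\nU1\t10\n"
    ))
    table2 = read_gene_profiles(path2)
    assert table2.feature_ids == ["U1"]
    np.testing.assert_allclose(table2.values, [[1.0]])


def test_gene_reader_errors_when_everything_stratified(tmp_path):
    path = _write(tmp_path / "genes.tsv", (
        "# Gene Family\tS1\n"
        "U1|g__X.s__Y\t7\n"
        "UNMAPPED\t90\n"
    ))
    with pytest.raises(ValueError, match="no community-total"):
        read_gene_profiles(path)


def test_profile_round_trip_is_value_identical(tmp_path):
    config = SimConfig(n_subjects=5, n_species=20, n_gene_functions=15, seed=3, sparsity=0.4)
    cohort = simulate_cohort(config)
    paths = write_cohort(cohort, tmp_path)
    taxa = read_taxonomic_profiles(paths["taxa"])
    genes = read_gene_profiles(paths["genes"])
    assert taxa.sample_ids == cohort[0].sample_ids
    np.testing.assert_allclose(taxa.values, cohort[0].values, atol=1e-9)
    np.testing.assert_allclose(genes.values, cohort[1].values, atol=1e-9)
    sets = read_gene_sets(paths["gene_sets"])
    assert dict(sets) == dict(cohort[4])


# ---------------------------------------------------------------------------
# prevalence filter


def _table(values, kind="taxon", normalized=False):
    values = np.asarray(values, dtype=float)
    return FeatureTable(
        [f"S{i}" for i in range(values.shape[0])],
        [f"F{j}" for j in range(values.shape[1])],
        values, kind, normalized=normalized,
    )


def test_prevalence_filter_threshold_behaviour():
    t = _table([[0.2, 0.8], [0.0, 1.0], [0.0, 1.0]], normalized=True)
    kept_low = prevalence_filter(t, 0.15)
    assert kept_low.feature_ids == ["F0", "F1"]
    kept_high = prevalence_filter(t, 0.5)
    assert kept_high.feature_ids == ["F1"]
    assert prevalence_filter(t, 0.0).feature_ids == ["F0", "F1"]
    with pytest.raises(ValueError):
        prevalence_filter(t, 1.5)


def test_prevalence_filter_does_not_renormalize():
    t = _table([[0.2, 0.8], [0.0, 1.0], [0.0, 1.0]], normalized=True)
    out = prevalence_filter(t, 0.5)
    np.testing.assert_allclose(out.values[:, 0], [0.8, 1.0, 1.0])
    assert not out.normalized  # rows no longer sum to 1


def test_prevalence_filter_matches_direct_count(rng):
    values = rng.uniform(0, 1, size=(40, 25))
    values[rng.uniform(size=values.shape) < 0.5] = 0.0
    values /= values.sum(axis=1, keepdims=True)
    t = _table(values, normalized=True)
    for thresh in (0.1, 0.3, 0.6):
        kept = set(prevalence_filter(t, thresh).feature_ids)
        expected = {
            f"F{j}" for j in range(25)
            if (values[:, j] > 0).sum() / 40 >= thresh
        }
        assert kept == expected


@settings(max_examples=25, deadline=None)
@given(
    st.integers(0, 2**31 - 1),
    st.floats(0.0, 1.0),
    st.floats(0.0, 1.0),
)
def test_prevalence_filter_idempotent_and_monotone(seed, p1, p2):
    g = np.random.default_rng(seed)
    values = g.uniform(0, 1, size=(10, 8))
    values[g.uniform(size=values.shape) < 0.4] = 0.0
    values[:, 0] = np.maximum(values[:, 0], 1e-3)  # avoid empty rows
    t = _table(values)
    lo, hi = sorted((p1, p2))
    once = prevalence_filter(t, hi)
    again = prevalence_filter(once, hi)
    assert once.feature_ids == again.feature_ids
    assert set(prevalence_filter(t, hi).feature_ids) <= set(prevalence_filter(t, lo).feature_ids)


# ---------------------------------------------------------------------------
# brain volumes


def test_normalize_brain_volumes_arithmetic():
    bv = BrainVolumeTable(
        ["S1"], ["r1", "r2"], [[50.0, 1000.0]],
        white_matter_total=[500.0], gray_matter_total=[500.0],
    )
    out = normalize_brain_volumes(bv)
    assert out.loc["S1", "r1"] == pytest.approx(0.05)
    assert out.loc["S1", "r2"] == pytest.approx(1.0)


def test_normalize_brain_volumes_matches_hand_division(rng):
    vols = rng.uniform(10, 100, size=(3, 5))
    white = rng.uniform(400, 600, size=3)
    gray = rng.uniform(400, 600, size=3)
    bv = BrainVolumeTable(["a", "b", "c"], [f"r{k}" for k in range(5)], vols, white, gray)
    out = normalize_brain_volumes(bv).to_numpy()
    for i in range(3):
        for j in range(5):
            assert out[i, j] == pytest.approx(vols[i, j] / (white[i] + gray[i]))


# ---------------------------------------------------------------------------
# cohort assembly


def _rec(subject, sample, stool, assess, score=100.0):
    return SubjectRecord(
        subject_id=subject, sample_id=sample, age_months=stool,
        assessment_age_months=assess, sex="F", maternal_education=3,
        sequencing_depth=1e7, cognitive_score=score,
    )


def _table_for(records):
    n = len(records)
    vals = np.full((n, 2), 0.5)
    return FeatureTable([r.sample_id for r in records], ["F0", "F1"], vals, "taxon", True)


def test_concurrent_selects_earliest_viable_stool():
    recs = [
        _rec("s1", "a20", 20.0, 20.1),
        _rec("s1", "a30", 30.0, 30.1),
    ]
    cohort = assemble_concurrent(recs, _table_for(recs), (18.0, 120.0), max_gap_days=7)
    assert [r.sample_id for r in cohort.records] == ["a20"]


def test_concurrent_excludes_out_of_window_and_wide_gaps():
    recs = [
        _rec("young", "y10", 10.0, 10.1),  # stool age below window
        _rec("gap", "g20", 20.0, 26.0),    # assessment 6 months away
        _rec("ok", "k20", 20.0, 20.1),
    ]
    cohort = assemble_concurrent(recs, _table_for(recs), (18.0, 120.0), max_gap_days=7)
    assert [r.subject_id for r in cohort.records] == ["ok"]
    with pytest.raises(ValueError, match="no viable datapoints"):
        assemble_concurrent(recs[:2], _table_for(recs[:2]), (18.0, 120.0), max_gap_days=7)


def test_concurrent_matches_per_subject_brute_force(rng):
    recs = []
    for s in range(25):
        for k in range(rng.integers(1, 5)):
            stool = float(rng.uniform(1, 130))
            assess = stool + float(rng.normal(0, 0.4))
            recs.append(_rec(f"subj{s}", f"subj{s}_v{k}", stool, max(assess, 0.1)))
    table = _table_for(recs)
    window, gap_days = (18.0, 120.0), 7.0
    gap_months = gap_days / 30.4375
    cohort = assemble_concurrent(recs, table, window, max_gap_days=gap_days)
    # exhaustive per-subject search
    expected = {}
    for r in recs:
        if window[0] <= r.age_months < window[1] and abs(r.assessment_age_months - r.age_months) <= gap_months:
            cur = expected.get(r.subject_id)
            if cur is None or r.age_months < cur.age_months:
                expected[r.subject_id] = r
    got = {r.subject_id: r.sample_id for r in cohort.records}
    assert got == {s: r.sample_id for s, r in expected.items()}


def test_future_pairs_latest_stool_with_latest_assessment():
    recs = [
        _rec("s1", "m3", 3.0, 4.0, score=90.0),
        _rec("s1", "m6", 6.0, 24.0, score=110.0),
    ]
    cohort = assemble_future(recs, _table_for(recs), (0.0, 12.0), min_lead_months=6)
    (rec,) = cohort.records
    assert rec.sample_id == "m6"
    assert rec.assessment_age_months == 24.0
    assert rec.cognitive_score == 110.0


def test_future_excludes_short_lead():
    recs = [_rec("s1", "m6", 6.0, 8.0)]
    with pytest.raises(ValueError, match="no viable datapoints"):
        assemble_future(recs, _table_for(recs), (0.0, 12.0), min_lead_months=6)


def test_future_matches_max_max_brute_force(rng):
    recs = []
    for s in range(30):
        for k in range(rng.integers(1, 5)):
            stool = float(rng.uniform(0.5, 18))
            assess = stool + float(rng.uniform(0, 30))
            recs.append(_rec(f"subj{s}", f"subj{s}_v{k}", stool, assess, score=float(rng.normal(100, 15))))
    table = _table_for(recs)
    cohort = assemble_future(recs, table, (0.0, 12.0), min_lead_months=6)
    got = {r.subject_id: (r.age_months, r.assessment_age_months) for r in cohort.records}
    expected = {}
    for subject in {r.subject_id for r in recs}:
        mine = [r for r in recs if r.subject_id == subject]
        assessments = [(r.assessment_age_months, r.cognitive_score) for r in mine]
        best = None
        for stool in sorted((r for r in mine if 0 < r.age_months <= 12.0),
                            key=lambda r: r.age_months, reverse=True):
            eligible = [a for a in assessments if a[0] - stool.age_months >= 6.0]
            if eligible:
                best = (stool.age_months, max(a[0] for a in eligible))
                break
        if best is not None:
            expected[subject] = best
    assert got == expected


def test_cohort_is_one_row_per_subject(planted_cohort):
    subjects = [r.subject_id for r in planted_cohort.records]
    assert len(subjects) == len(set(subjects))
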