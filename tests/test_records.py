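"""Record I/O, eye normalisation, pattern conversion, reliability, staging."""
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vfgrade.patterns import PatternId, get_pattern
from vfgrade.records import (Eye, HPAStage, MirrorError, VFFormatError,
                             VFRecord, convert_30_2_to_24_2, hpa_stage,
                             load_vf_csv, mean_deviation, mirror_record,
                             reliability_filter, to_right_eye, write_vf_csv)
from vfgrade.simulate import generate_dataset


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _write_minimal_csv(path, n_dev, pattern="HFA24_2", dev_value="0.00"):
    header = "patient_id,eye,exam_date,pattern_id,fp_rate,fn_rate,fl_rate," \
        + ",".join(f"d{i + 1:03d}" for i in range(n_dev))
    row = f"A1,R,2021-01-02,{pattern},0.1,0.2,," + ",".join([dev_value] * n_dev)
    path.write_text(header + "\n" + row + "\n")


def test_load_single_row(tmp_path):
    f = tmp_path / "vf.csv"
    _write_minimal_csv(f, 54)
    recs = load_vf_csv(f, PatternId.HFA24_2)
    assert len(recs) == 1
    assert recs[0].deviations.shape == (54,)
    assert recs[0].fl_rate is None


def test_declared_count_mismatch(tmp_path):
    f = tmp_path / "vf.csv"
    _write_minimal_csv(f, 54, pattern="G1")
    with pytest.raises(VFFormatError, match="expected 59 deviation columns"):
        load_vf_csv(f, PatternId.G1)


def test_non_numeric_deviation_reports_row_and_column(tmp_path):
    f = tmp_path / "vf.csv"
    _write_minimal_csv(f, 54, dev_value="0.00")
    text = f.read_text().splitlines()
    cells = text[1].split(",")
    cells[7 + 11] = "oops"
    f.write_text(text[0] + "\n" + ",".join(cells) + "\n")
    with pytest.raises(VFFormatError, match=r":2.*d012.*oops"):
        load_vf_csv(f, PatternId.HFA24_2)


def test_row_pattern_must_match_declared(tmp_path):
    f = tmp_path / "vf.csv"
    _write_minimal_csv(f, 54, pattern="HFA30_2")
    with pytest.raises(VFFormatError, match="does not match declared"):
        load_vf_csv(f, PatternId.HFA24_2)


def test_round_trip_bit_exact(tmp_path):
    fields = generate_dataset(4, PatternId.G1, noise_sd=2.0, seed=3)
    records = [f.record for f in fields]
    path = tmp_path / "vf.csv"
    write_vf_csv(records, path)
    loaded = load_vf_csv(path, PatternId.G1)
    assert len(loaded) == len(records)
    for a, b in zip(records, loaded):
        assert a.patient_id == b.patient_id
        assert a.eye == b.eye and a.exam_date == b.exam_date
        assert np.array_equal(a.deviations, b.deviations)
        assert a.fp_rate == b.fp_rate and a.fn_rate == b.fn_rate
        assert a.fl_rate == b.fl_rate


def test_deviations_clamped_with_warning(make_record):
    dev = np.zeros(54)
    dev[0] = -50.0
    dev[1] = 20.0
    with pytest.warns(UserWarning, match="clamped"):
        rec = make_record(deviations=dev)
    assert rec.deviations[0] == -40.0
    assert rec.deviations[1] == 10.0


def test_rates_validated(make_record):
    with pytest.raises(VFFormatError, match="fp_rate"):
        make_record(fp=1.5)


# ---------------------------------------------------------------------------
# eye normalisation
# ---------------------------------------------------------------------------

def test_right_eye_record_unchanged(make_record):
    rec = make_record(deviations=np.arange(54, dtype=float) / 10 - 2)
    out = to_right_eye(rec)
    assert np.array_equal(out.deviations, rec.deviations)
    assert out.right_eye_format


def test_mirror_is_involution_on_symmetric_patterns(make_record):
    rng = np.random.default_rng(5)
    for pid in (PatternId.HFA30_2, PatternId.G1):
        n = get_pattern(pid).n_points
        rec = make_record(pattern_id=pid, deviations=rng.uniform(-30, 5, n))
        twice = mirror_record(mirror_record(rec))
        assert np.array_equal(twice.deviations, rec.deviations)


def test_mirror_preserves_deviation_multiset(make_record):
    rng = np.random.default_rng(6)
    rec = make_record(pattern_id=PatternId.G1,
                      deviations=rng.uniform(-30, 5, 59))
    out = mirror_record(rec)
    assert np.allclose(np.sort(out.deviations), np.sort(rec.deviations))


def test_left_eye_depressed_point_moves_across_midline(make_record):
    """A nasal defect listed at (-27, 3) lands at (27, 3) after conversion."""
    p30 = get_pattern(PatternId.HFA30_2)
    dev = np.zeros(76)
    dev[p30.index_at(-27, 3)] = -30.0
    rec = make_record(pattern_id=PatternId.HFA30_2, deviations=dev, eye=Eye.L,
                      right_eye_format=False)
    out = to_right_eye(rec)
    assert out.right_eye_format
    assert out.deviations[p30.index_at(27, 3)] == -30.0
    assert out.deviations[p30.index_at(-27, 3)] == 0.0


def test_left_eye_24_2_lacks_mirror_symmetry(make_record):
    rec = make_record(eye=Eye.L, right_eye_format=False)
    with pytest.raises(MirrorError, match=r"-27"):
        to_right_eye(rec)


# ---------------------------------------------------------------------------
# 30-2 -> 24-2
# ---------------------------------------------------------------------------

def test_conversion_yields_54_point_coordinate_subset(make_record):
    rng = np.random.default_rng(7)
    rec = make_record(pattern_id=PatternId.HFA30_2,
                      deviations=rng.uniform(-35, 5, 76))
    out = convert_30_2_to_24_2(rec)
    assert out.pattern_id is PatternId.HFA24_2
    assert out.deviations.shape == (54,)
    p24, p30 = get_pattern(PatternId.HFA24_2), get_pattern(PatternId.HFA30_2)
    for i, (x, y) in enumerate(p24.points):
        assert out.deviations[i] == rec.deviations[p30.index_at(x, y)]


def test_conversion_keeps_nasal_27_values(make_record):
    p30 = get_pattern(PatternId.HFA30_2)
    dev = np.zeros(76)
    dev[p30.index_at(-27, 3)] = -21.5
    dev[p30.index_at(-27, -3)] = -13.0
    out = convert_30_2_to_24_2(make_record(pattern_id=PatternId.HFA30_2,
                                           deviations=dev))
    p24 = get_pattern(PatternId.HFA24_2)
    assert out.deviations[p24.index_at(-27, 3)] == -21.5
    assert out.deviations[p24.index_at(-27, -3)] == -13.0


def test_conversion_rejects_other_patterns(make_record):
    with pytest.raises(VFFormatError, match="HFA30_2"):
        convert_30_2_to_24_2(make_record())


def test_subset_mean_matches_brute_force(make_record):
    rng = np.random.default_rng(8)
    rec = make_record(pattern_id=PatternId.HFA30_2,
                      deviations=rng.uniform(-35, 5, 76))
    out = convert_30_2_to_24_2(rec)
    p24, p30 = get_pattern(PatternId.HFA24_2), get_pattern(PatternId.HFA30_2)
    keep = [p30.index_at(x, y) for x, y in p24.points[p24.non_blind_spot]]
    assert mean_deviation(out) == pytest.approx(
        float(np.mean(rec.deviations[keep])))


# ---------------------------------------------------------------------------
# reliability filter
# ---------------------------------------------------------------------------

def test_reliability_bounds_inclusive_and_reasons(make_record):
    r_bad_fp = make_record(fp=0.31)
    r_edge = make_record(fp=0.30, fn=0.30, fl=0.33)
    r_clean = make_record(fp=0.0, fn=0.0, fl=0.0)
    kept, rejected = reliability_filter([r_bad_fp, r_edge, r_clean])
    assert kept == [r_edge, r_clean]
    assert len(rejected) == 1
    rec, reasons = rejected[0]
    assert rec is r_bad_fp
    assert reasons == ["false-positive rate > 0.30"]


def test_reliability_filter_partitions_input(make_record):
    rng = np.random.default_rng(9)
    recs = [make_record(fp=float(a), fn=float(b), fl=float(c),
                        patient_id=f"P{i}")
            for i, (a, b, c) in enumerate(rng.uniform(0, 0.6, (30, 3)).round(2))]
    kept, rejected = reliability_filter(recs)
    assert len(kept) + len(rejected) == len(recs)
    assert {id(r) for r in kept}.isdisjoint({id(r) for r, _ in rejected})
    for r, reasons in rejected:
        assert reasons
        assert r.fp_rate > 0.30 or r.fn_rate > 0.30 or r.fl_rate > 0.33


def test_reliability_filter_absent_fixation_loss_kept(make_record):
    rec = make_record(fl=None)
    kept, rejected = reliability_filter([rec])
    assert kept == [rec]
    assert reliability_filter([]) == ([], [])


# ---------------------------------------------------------------------------
# MD and H-P-A staging
# ---------------------------------------------------------------------------

def test_mean_deviation_examples(make_record):
    assert mean_deviation(make_record()) == 0.0
    assert mean_deviation(make_record(deviations=np.full(54, -6.0))) == -6.0


def test_mean_deviation_excludes_blind_spot(make_record):
    p = get_pattern(PatternId.HFA24_2)
    dev = np.zeros(54)
    dev[p.blind_spot] = -30.0
    assert mean_deviation(make_record(deviations=dev)) == 0.0


def test_mean_deviation_matches_summation_oracle(make_record):
    rng = np.random.default_rng(10)
    dev = rng.uniform(-35, 5, 54)
    rec = make_record(deviations=dev)
    p = get_pattern(PatternId.HFA24_2)
    total, count = 0.0, 0
    for i in range(54):
        if i not in set(p.blind_spot.tolist()):
            total += rec.deviations[i]
            count += 1
    assert mean_deviation(rec) == pytest.approx(total / count)


@pytest.mark.parametrize("md,stage", [
    (-15.0, HPAStage.SEVERE),
    (-12.0, HPAStage.SEVERE),   # boundary to the worse stage
    (-8.0, HPAStage.MODERATE),
    (-6.0, HPAStage.MODERATE),
    (-5.9, HPAStage.MILD),
    (0.0, HPAStage.MILD),
])
def test_hpa_stage_bounds(md, stage):
    assert hpa_stage(md) is stage


def test_hpa_stage_rejects_non_finite():
    with pytest.raises(ValueError):
        hpa_stage(float("nan"))


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.floats(-40, 10), st.floats(-40, 10))
def test_hpa_stage_monotone(md1, md2):
    """Worse MD never maps to a milder stage."""
    if md1 <= md2:
        assert hpa_stage(md1) >= hpa_stage(md2) or hpa_stage(md1) == hpa_stage(md2)
        assert not (hpa_stage(md1) < hpa_stage(md2))
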