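import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from polypseg import (boundary_points, confusion_counts, dice, evaluate_frame,
                      hausdorff, hausdorff_masks, jaccard, mask_circularity,
                      precision, recall, stratify, summarize)


# -- confusion counts -------------------------------------------------------

def test_identical_masks_counts():
    m = np.zeros((6, 6), np.uint8)
    m[2:4, 2:5] = 1
    tp, fp, fn, tn = confusion_counts(m, m)
    assert (tp, fp, fn) == (6, 0, 0)
    assert tp + fp + fn + tn == 36


def test_disjoint_masks_counts():
    a = np.zeros((5, 5), np.uint8)
    b = np.zeros((5, 5), np.uint8)
    a[0, 0] = 1
    b[4, 4] = 1
    tp, fp, fn, tn = confusion_counts(a, b)
    assert tp == 0 and fp == 1 and fn == 1 and tn == 23


def test_counts_against_enumeration():
    pred = np.array([[1, 1, 0, 0], [0, 1, 1, 0], [0, 0, 0, 0], [1, 0, 0, 1]], np.uint8)
    truth = np.array([[1, 0, 0, 0], [0, 1, 0, 1], [0, 0, 0, 0], [0, 0, 0, 1]], np.uint8)
    tp = sum(int(p and t) for p, t in zip(pred.flat, truth.flat))
    fp = sum(int(p and not t) for p, t in zip(pred.flat, truth.flat))
    fn = sum(int(t and not p) for p, t in zip(pred.flat, truth.flat))
    tn = 16 - tp - fp - fn
    assert confusion_counts(pred, truth) == (tp, fp, fn, tn)


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion_counts(np.zeros((3, 3)), np.zeros((4, 4)))


# -- overlap measures -------------------------------------------------------

def test_metric_values_on_known_counts():
    counts = (8, 2, 2, 0)
    assert dice(counts) == pytest.approx(0.8)
    assert precision(counts) == pytest.approx(0.8)
    assert recall(counts) == pytest.approx(0.8)
    assert jaccard(counts) == pytest.approx(2 / 3)


def test_perfect_prediction_scores_one():
    counts = (10, 0, 0, 90)
    assert dice(counts) == precision(counts) == recall(counts) == jaccard(counts) == 1.0


def test_empty_mask_conventions():
    both_empty = (0, 0, 0, 25)
    assert dice(both_empty) == 1.0
    only_pred = (0, 3, 0, 22)
    assert dice(only_pred) == 0.0
    assert precision(only_pred) == 0.0
    only_truth = (0, 0, 3, 22)
    assert recall(only_truth) == 0.0


@given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
def test_jaccard_dice_identity(tp, fp, fn):
    counts = (tp, fp, fn, 0)
    d = dice(counts)
    assert jaccard(counts) == pytest.approx(d / (2 - d), abs=1e-12)


@given(st.integers(0, 40))
def test_symmetry_properties(seed):
    rng = np.random.default_rng(seed)
    a = (rng.random((8, 8)) > 0.6).astype(np.uint8)
    b = (rng.random((8, 8)) > 0.6).astype(np.uint8)
    assert dice(confusion_counts(a, b)) == pytest.approx(dice(confusion_counts(b, a)))
    assert precision(confusion_counts(a, b)) == pytest.approx(recall(confusion_counts(b, a)))


def test_translation_invariance():
    rng = np.random.default_rng(1)
    a = np.zeros((20, 20), np.uint8)
    b = np.zeros((20, 20), np.uint8)
    a[4:9, 5:11] = rng.random((5, 6)) > 0.4
    b[5:10, 4:9] = rng.random((5, 5)) > 0.4
    base = evaluate_frame("x", a, b)
    shifted = evaluate_frame("x", np.roll(a, (3, 2), (0, 1)), np.roll(b, (3, 2), (0, 1)))
    assert shifted.dice == pytest.approx(base.dice)
    assert shifted.hausdorff == pytest.approx(base.hausdorff)


# -- Hausdorff --------------------------------------------------------------

def test_hausdorff_identical_contours_zero():
    m = np.zeros((10, 10), np.uint8)
    m[3:7, 3:7] = 1
    assert hausdorff_masks(m, m) == 0.0


def test_hausdorff_two_points():
    assert hausdorff(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])) == pytest.approx(5.0)


def test_hausdorff_offset_squares_brute_force():
    g = [(r, c) for r in (0, 1, 2) for c in (0, 1, 2) if r in (0, 2) or c in (0, 2)]
    s = [(r, c + 3) for (r, c) in g]
    bf = max(max(min(math.dist(p, q) for q in s) for p in g),
             max(min(math.dist(p, q) for q in g) for p in s))
    assert hausdorff(np.array(g, float), np.array(s, float)) == pytest.approx(bf)


@given(st.integers(0, 60))
def test_hausdorff_matches_brute_force_random_masks(seed):
    rng = np.random.default_rng(seed)
    a = (rng.random((12, 16)) > 0.7).astype(np.uint8)
    b = (rng.random((12, 16)) > 0.7).astype(np.uint8)
    ga, gb = boundary_points(a), boundary_points(b)
    h = hausdorff(ga, gb)
    if len(ga) == 0 or len(gb) == 0:
        assert h == math.inf
    else:
        bf = max(max(min(np.hypot(*(p - q)) for q in gb) for p in ga),
                 max(min(np.hypot(*(p - q)) for q in ga) for p in gb))
        assert h == pytest.approx(bf, abs=1e-12)


def test_hausdorff_empty_boundary_is_infinite():
    empty = np.zeros((5, 5), np.uint8)
    full = np.ones((5, 5), np.uint8)
    assert hausdorff_masks(empty, full) == math.inf


# -- circularity ------------------------------------------------------------

def test_square_circularity_near_pi_over_4():
    m = np.zeros((120, 120), np.uint8)
    m[10:110, 10:110] = 1
    assert mask_circularity(m) == pytest.approx(math.pi / 4, rel=0.05)


def test_large_disc_circularity_near_one():
    yy, xx = np.mgrid[0:220, 0:220]
    d = ((yy - 110) ** 2 + (xx - 110) ** 2 <= 100 ** 2).astype(np.uint8)
    assert mask_circularity(d) >= 0.9


def test_ngon_circularity_increases_with_sides():
    def ngon(n, r=80):
        yy, xx = np.mgrid[0:200, 0:200]
        ang = np.arctan2(yy - 100, xx - 100)
        rho = np.hypot(yy - 100, xx - 100)
        apo = r * np.cos(np.pi / n) / np.cos((ang % (2 * np.pi / n)) - np.pi / n)
        return (rho <= apo).astype(np.uint8)
    vals = [mask_circularity(ngon(n)) for n in (3, 4, 6, 12)]
    assert vals == sorted(vals)
    assert vals[-1] > 0.93


def test_empty_mask_circularity_rejected():
    with pytest.raises(ValueError):
        mask_circularity(np.zeros((5, 5)))


# -- stratification ---------------------------------------------------------

def _records_with_areas(areas):
    recs = []
    for i, a in enumerate(areas):
        m = np.zeros((60, 60), np.uint8)
        side = max(1, int(round(math.sqrt(a))))
        m[:side, :side] = 1
        r = evaluate_frame(f"f{i}", m, m)
        recs.append(r)
    return recs


def test_stratify_uniform_sizes_25_50_25():
    recs = _records_with_areas(range(1, 101))
    # override measured areas with the exact 1..100 values
    for r, a in zip(recs, range(1, 101)):
        r.gt_area = float(a)
    stratify(recs, list(range(1, 101)), [0.5] * 100)
    groups = [r.size_group for r in recs]
    assert groups.count("Small") == 25
    assert groups.count("Normal") == 50
    assert groups.count("Large") == 25


def test_stratify_degenerate_distribution_all_normal():
    recs = _records_with_areas([50] * 5)
    for r in recs:
        r.gt_area = 50.0
    stratify(recs, [50.0] * 8, [0.7] * 8)
    assert all(r.size_group == "Normal" for r in recs)


def test_stratify_partitions_records():
    rng = np.random.default_rng(0)
    areas = rng.integers(10, 500, 40)
    recs = _records_with_areas(areas)
    stratify(recs, areas.astype(float), rng.uniform(0.3, 1.0, 40))
    assert all(r.size_group in ("Small", "Normal", "Large") for r in recs)


# -- summaries --------------------------------------------------------------

def test_summary_single_record():
    recs = _records_with_areas([100])
    stratify(recs, [100.0], [0.8])
    s = summarize(recs, "size_group")
    row = s.table[s.table.metric == "dice"].iloc[0]
    assert row["median"] == row["mean"] == 1.0
    assert row["std"] == 0.0


def test_summary_quartiles_match_percentile_oracle():
    recs = _records_with_areas([10, 20, 30, 40, 50])
    vals = [0.1, 0.3, 0.5, 0.7, 0.9]
    for r, v in zip(recs, vals):
        r.dice = v
        r.size_group = "Normal"
        r.circularity_group = "Normal"
    s = summarize(recs, "size_group")
    row = s.table[s.table.metric == "dice"].iloc[0]
    assert row["q25"] == pytest.approx(np.percentile(vals, 25))
    assert row["median"] == pytest.approx(0.5)
    assert row["q75"] == pytest.approx(np.percentile(vals, 75))


def test_summary_groups_keyed_independently():
    recs = _records_with_areas([10, 20, 400, 500])
    for r, g in zip(recs, ["Small", "Small", "Large", "Large"]):
        r.size_group = g
        r.circularity_group = "Normal"
    s = summarize(recs, "size_group")
    assert set(s.table["group"]) == {"Small", "Large"}
    assert set(s.scatter.columns) >= {"dice", "hausdorff", "recall", "precision"}
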