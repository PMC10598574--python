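"""Loss shape, splitting, metric identities, grouped evaluation."""

import numpy as np
import pytest

from synergraph.evaluation import grouped_eval, metrics, smooth_l1, split_622
from synergraph.exceptions import ConfigError, ValidationError
from synergraph.io import SynergyRecord, SCORE_COLUMNS


# -- loss ---------------------------------------------------------------


@pytest.mark.parametrize("r,expected", [(0.0, 0.0), (1.0, 0.5), (-1.0, 0.5),
                                        (3.0, 2.5), (-3.0, 2.5), (0.5, 0.125)])
def test_smooth_l1_closed_form(r, expected):
    assert smooth_l1(r, 0.0) == pytest.approx(expected, abs=1e-15)


def test_smooth_l1_properties_on_grid():
    r = np.linspace(-5, 5, 2001)
    loss = smooth_l1(r, np.zeros_like(r))
    # even in the residual
    np.testing.assert_allclose(loss, loss[::-1], rtol=1e-12)
    # continuous: adjacent values differ by at most grid * max|gradient|
    assert np.abs(np.diff(loss)).max() <= (r[1] - r[0]) + 1e-9
    # numerical gradient bounded by 1
    grad = np.gradient(loss, r)
    assert np.abs(grad).max() <= 1.0 + 1e-6
    # quadratic branch equals half the squared error
    inner = np.abs(r) < 1
    np.testing.assert_allclose(loss[inner], 0.5 * r[inner] ** 2, rtol=1e-12)


def test_smooth_l1_rejects_non_finite():
    with pytest.raises(ValidationError):
        smooth_l1(np.nan, 0.0)


# -- splitting ----------------------------------------------------------


def test_split_sizes_6_2_2_on_ten_records():
    train, val, test = split_622(list(range(10)), seed=0)
    assert (len(train), len(val), len(test)) == (6, 2, 2)


def test_split_is_disjoint_exhaustive_and_seeded():
    recs = list(range(23))
    a = split_622(recs, seed=5)
    b = split_622(recs, seed=5)
    assert [x for s in a for x in s] == [x for s in b for x in s]
    union = sorted(x for s in a for x in s)
    assert union == recs
    c = split_622(recs, seed=6)
    assert [x for s in a for x in s] != [x for s in c for x in s]


def test_split_normalizes_ratios_and_validates():
    train, val, test = split_622(list(range(10)), ratios=(3, 1, 1), seed=0)
    assert (len(train), len(val), len(test)) == (6, 2, 2)
    with pytest.raises(ValidationError):
        split_622([1, 2, 3], seed=0)
    with pytest.raises(ConfigError):
        split_622(list(range(10)), ratios=(0.5, 0.5, 0.0), seed=0)


# -- metrics ------------------------------------------------------------


def test_perfect_prediction_metrics():
    m = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert m["MSE"] == 0 and m["RMSE"] == 0
    assert m["R2"] == pytest.approx(1.0) and m["PCC"] == pytest.approx(1.0)


def test_scaled_prediction_hand_values():
    # pred = 2*true, true=[1,2,3]: residuals [1,2,3], MSE=14/3;
    # SS_res = 14, SS_tot = 2, R2 = 1 - 14/2 = -6; correlation still perfect.
    m = metrics([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
    assert m["PCC"] == pytest.approx(1.0)
    assert m["MSE"] == pytest.approx(14 / 3)
    assert m["R2"] == pytest.approx(1 - 14 / 2)
    assert m["R2"] < 1


def test_rmse_is_root_mse_and_pcc_affine_invariant(rng):
    true = rng.normal(size=50)
    pred = rng.normal(size=50)
    m = metrics(pred, true)
    assert m["RMSE"] == pytest.approx(np.sqrt(m["MSE"]), rel=1e-12)
    m2 = metrics(2.5 * pred + 1.0, true)
    assert m2["PCC"] == pytest.approx(m["PCC"], rel=1e-9)


def test_r2_equals_pcc_squared_for_least_squares_fit(rng):
    true = rng.normal(size=80)
    pred_raw = true + rng.normal(size=80)
    slope, intercept = np.polyfit(true, pred_raw, 1)
    # invert the fit so pred is the least-squares affine regression of true on pred_raw
    a, b = np.polyfit(pred_raw, true, 1)
    m = metrics(a * pred_raw + b, true)
    assert m["R2"] == pytest.approx(m["PCC"] ** 2, rel=1e-9)


def test_constant_truth_reports_nan_with_warning(caplog):
    m = metrics([1.0, 2.0], [3.0, 3.0])
    assert np.isnan(m["PCC"]) and np.isnan(m["R2"])


# -- grouped evaluation -------------------------------------------------


def rec(a, b, c, loewe):
    scores = dict.fromkeys(SCORE_COLUMNS, 0.0)
    scores["loewe"] = loewe
    return SynergyRecord(a, b, c, scores)


def test_single_group_matches_global_metrics(rng):
    recs = [rec("d1", "d2", "c1", v) for v in rng.normal(size=6)]
    pred = rng.normal(size=6)
    table = grouped_eval(pred, recs, "cell_line")
    glob = metrics(pred, [r.scores["loewe"] for r in recs])
    assert table.loc["c1", "MSE"] == pytest.approx(glob["MSE"])
    assert len(table) == 1


def test_global_mse_is_weighted_mean_of_group_mses(rng):
    recs = ([rec("d1", "d2", "c1", v) for v in rng.normal(size=4)]
            + [rec("d1", "d2", "c2", v) for v in rng.normal(size=8)])
    pred = rng.normal(size=12)
    table = grouped_eval(pred, recs, "cell_line")
    weighted = (table["MSE"] * table["n"]).sum() / table["n"].sum()
    glob = metrics(pred, [r.scores["loewe"] for r in recs])
    assert weighted == pytest.approx(glob["MSE"], rel=1e-12)


def test_missing_tissue_maps_to_unknown(rng):
    recs = ([rec("d1", "d2", "c1", v) for v in rng.normal(size=3)]
            + [rec("d1", "d2", "c2", v) for v in rng.normal(size=3)])
    table = grouped_eval(rng.normal(size=6), recs, "tissue", tissue_map={"c1": "lung"})
    assert set(table.index) == {"lung", "unknown"}


def test_grouped_eval_validates_group_key(rng):
    with pytest.raises(ConfigError):
        grouped_eval(np.zeros(2), [], "organ")
    with pytest.raises(ConfigError):
        grouped_eval(np.zeros(2), [], "tissue")  # tissue_map required


def test_small_groups_skipped(rng):
    recs = ([rec("d1", "d2", "c1", v) for v in rng.normal(size=5)]
            + [rec("d1", "d2", "c2", 1.0)])
    table = grouped_eval(rng.normal(size=6), recs, "cell_line")
    assert list(table.index) == ["c1"]
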