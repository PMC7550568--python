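"""Log-log fitting and the four scaling-interval selection strategies."""

import decimal
import math

import numpy as np
import pytest

import voxelfd as v
from voxelfd.boxcount import BoxCountCurve, ScaleSet
from voxelfd.errors import (
    BoundsNotSampledError,
    InvalidBoundsError,
    TooFewScalesError,
)
from voxelfd.scaleselect import (
    ScaleInterval, enumerate_intervals, fit_loglog, round_half_away,
    select_apriori_bbox, select_apriori_fixed, select_auto_fractalbrain,
    select_auto_max_r2adj, width_decades, _round_pow2,
)

from conftest import powerlaw_curve

NINE = ScaleSet((1, 2, 4, 8, 16, 32, 64, 128, 256), 1.0)


# ---------------------------------------------------------------- fitting

def make_curve(scales, counts):
    return BoxCountCurve(scale_set=ScaleSet(scales, 1.0),
                         mean_counts=np.asarray(counts, float), n_offsets=0)


@pytest.mark.parametrize("fd", [2.0, 3.0])
def test_exact_power_law_recovered(fd):
    sc = ScaleSet((1, 2, 4, 8, 16, 32), 1.0)
    curve = make_curve(sc.scales, [(64 / s) ** fd for s in sc.scales])
    fit = fit_loglog(curve, ScaleInterval.from_indices(sc, 0, 5))
    assert fit.fd == pytest.approx(fd, abs=1e-12)
    assert fit.r2 == pytest.approx(1.0)
    assert fit.r2_adj == pytest.approx(1.0)
    assert fit.prefactor == pytest.approx(64 ** fd, rel=1e-9)


def test_fit_matches_closed_form_ols():
    """Slope and intercept must equal the textbook least-squares formulas
    computed independently on a noisy 5-point curve."""
    rng = np.random.default_rng(42)
    sc = ScaleSet((1, 2, 4, 8, 16), 1.0)
    y = 5.0 - 2.5 * np.log10(sc.scales_mm) + rng.normal(0, 0.05, 5)
    curve = make_curve(sc.scales, 10.0 ** y)
    fit = fit_loglog(curve, ScaleInterval.from_indices(sc, 0, 4))
    x = np.log10(sc.scales_mm)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
    intercept = y.mean() - slope * x.mean()
    r = np.corrcoef(x, y)[0, 1]
    assert fit.slope == pytest.approx(slope, abs=1e-12)
    assert fit.intercept == pytest.approx(intercept, abs=1e-12)
    assert fit.r2 == pytest.approx(r ** 2, abs=1e-10)
    assert fit.r2_adj == pytest.approx(1 - (1 - r ** 2) * 4 / 3, abs=1e-10)
    assert fit.fd == abs(fit.slope)


def test_fd_invariant_to_logarithm_base():
    """The slope of log N vs log s does not depend on the base as long as
    both axes use the same one."""
    rng = np.random.default_rng(7)
    sc = ScaleSet((1, 2, 4, 8, 16, 32), 1.0)
    y = 4.0 - 2.3 * np.log10(sc.scales_mm) + rng.normal(0, 0.02, 6)
    curve = make_curve(sc.scales, 10.0 ** y)
    fit = fit_loglog(curve, ScaleInterval.from_indices(sc, 0, 5))
    ln_x, ln_y = np.log(sc.scales_mm), np.log(curve.mean_counts)
    slope_ln = (np.sum((ln_x - ln_x.mean()) * (ln_y - ln_y.mean()))
                / np.sum((ln_x - ln_x.mean()) ** 2))
    assert fit.fd == pytest.approx(abs(slope_ln), abs=1e-10)


def test_r2adj_leq_r2_with_equality_only_at_one():
    rng = np.random.default_rng(11)
    sc = ScaleSet((1, 2, 4, 8, 16), 1.0)
    y = 3.0 - 2.0 * np.log10(sc.scales_mm) + rng.normal(0, 0.1, 5)
    fit = fit_loglog(make_curve(sc.scales, 10.0 ** y),
                     ScaleInterval.from_indices(sc, 0, 4))
    assert fit.r2_adj < fit.r2 < 1.0


# ------------------------------------------------------------- intervals

@pytest.mark.parametrize("min_points,expected", [(5, 15), (4, 21), (2, 36)])
def test_enumerate_interval_counts(min_points, expected):
    assert len(enumerate_intervals(NINE, min_points)) == expected


def test_enumerate_single_window_when_all_points_needed():
    sc = ScaleSet((1, 2, 4, 8, 16), 1.0)
    ivs = enumerate_intervals(sc, 5)
    assert len(ivs) == 1 and ivs[0].n_points == 5
    with pytest.raises(TooFewScalesError):
        enumerate_intervals(sc, 6)


@pytest.mark.parametrize("mfs,Mfs,raw,reported", [
    (1, 8, 0.9030899869919435, 0.9),
    (1, 16, 1.2041199826559248, 1.2),
    (1, 32, 1.505149978319906, 1.5),
])
def test_width_decades_matches_printed_values(mfs, Mfs, raw, reported):
    w = width_decades(mfs, Mfs)
    assert w == pytest.approx(raw, abs=1e-12)
    assert round(w, 1) == reported


def test_width_decades_invalid_bounds():
    for mfs, Mfs in [(0, 8), (8, 8), (16, 8), (-1, 8)]:
        with pytest.raises(InvalidBoundsError):
            width_decades(mfs, Mfs)


# ------------------------------------------------------------- a priori

def test_apriori_fixed_default_selects_4_to_256():
    iv = select_apriori_fixed(NINE)
    assert (iv.mfs, iv.Mfs, iv.n_points) == (4.0, 256.0, 7)


def test_apriori_fixed_custom_and_unsampled_bounds():
    iv = select_apriori_fixed(NINE, 1, 8)
    assert iv.n_points == 4
    with pytest.raises(BoundsNotSampledError):
        select_apriori_fixed(NINE, 4, 512)
    with pytest.raises(BoundsNotSampledError):
        select_apriori_fixed(NINE, 3, 256)


@pytest.mark.parametrize("shortest,expected", [
    (140, (8.0, 64.0)),   # 7 -> 8, 56 -> 64
    (100, (4.0, 32.0)),   # 5 -> 4, 40 -> 32
    (160, (8.0, 64.0)),   # 8 and 64 are exact powers
])
def test_bbox_strategy_rounds_5_and_40_percent_to_powers_of_two(shortest, expected):
    data = np.zeros((shortest, shortest + 10, shortest + 20), np.uint8)
    data[:shortest, :shortest + 10, :shortest + 20] = 1
    vol = v.VoxelVolume(data)
    iv = select_apriori_bbox(vol, NINE)
    assert (iv.mfs, iv.Mfs) == expected


def test_bbox_uses_foreground_not_array_extent():
    data = np.zeros((200, 200, 200), np.uint8)
    data[10:110, 20:180, 30:190] = 1  # shortest foreground side: 100
    iv = select_apriori_bbox(v.VoxelVolume(data), NINE)
    assert (iv.mfs, iv.Mfs) == (4.0, 32.0)


def test_pow2_rounding_modes():
    assert _round_pow2(7, "nearest") == 8     # log2 distance favours 8
    assert _round_pow2(5, "nearest") == 4
    assert _round_pow2(5, "next") == 8
    assert _round_pow2(8, "next") == 8
    # geometric ties round up: sqrt(2) is equidistant from 1 and 2 in log2
    assert _round_pow2(math.sqrt(2.0), "nearest") == 2


# ------------------------------------------------------------- automated

def oracle_round(x, places=3):
    """Independent tie-away rounding via decimal arithmetic."""
    q = decimal.Decimal(10) ** -places
    return float(decimal.Decimal(repr(x)).quantize(q, decimal.ROUND_HALF_UP))


def oracle_select(curve, min_points, rounded):
    """Brute-force reference: enumerate, fit with numpy.polyfit, rank."""
    x_all = np.log10(curve.scales_mm)
    y_all = np.log10(curve.mean_counts)
    n = len(x_all)
    best_key, best_win = None, None
    for start in range(n):
        for stop in range(start + min_points - 1, n):
            x, y = x_all[start:stop + 1], y_all[start:stop + 1]
            m = stop - start + 1
            slope, intercept = np.polyfit(x, y, 1)
            ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 1.0
            r2a = 1 - (1 - r2) * (m - 1) / (m - 2)
            if rounded:
                key = (-oracle_round(r2a), -(x[-1] - x[0]), x[0])
            else:
                key = (-r2a, start, stop)
            if best_key is None or key < best_key:
                best_key, best_win = key, (start, stop)
    return best_win


def test_automated_strategies_match_brute_force_on_random_curves():
    """Oracle equivalence on 200 noisy synthetic power-law curves: both
    automated strategies must select exactly the window chosen by an
    independent enumerate-fit-rank reference."""
    rng = np.random.default_rng(20240918)
    for _ in range(200):
        curve = powerlaw_curve(NINE, fd=rng.uniform(1.5, 3.0),
                               noise_sd=rng.uniform(0.01, 0.2), rng=rng)
        iv_m, _ = select_auto_max_r2adj(curve, min_points=4)
        assert (iv_m.start, iv_m.stop) == oracle_select(curve, 4, rounded=False)
        iv_f, _ = select_auto_fractalbrain(curve, min_points=5)
        assert (iv_f.start, iv_f.stop) == oracle_select(curve, 5, rounded=True)


def test_exact_power_law_tie_breaks():
    curve = powerlaw_curve(NINE, fd=2.5)
    # every window fits perfectly: the unrounded strategy keeps the first
    # enumerated window, the rounded one takes the widest interval
    iv_m, fit_m = select_auto_max_r2adj(curve, min_points=4)
    assert (iv_m.start, iv_m.stop) == (0, 3)
    iv_f, fit_f = select_auto_fractalbrain(curve, min_points=5)
    assert (iv_f.mfs, iv_f.Mfs) == (1.0, 256.0)
    assert fit_m.r2_adj == pytest.approx(1.0)
    assert fit_f.fd == pytest.approx(2.5, abs=1e-12)


def test_piecewise_curve_confines_selection_to_linear_segment():
    """Counts follow slope -3 up to s=8 and are strongly distorted beyond;
    the unrounded strategy must select a window inside the linear part."""
    counts = np.array([(64 / s) ** 3 for s in NINE.scales], float)
    counts[4:] *= [3.0, 12.0, 80.0, 600.0, 4000.0]  # break linearity
    curve = make_curve(NINE.scales, counts)
    iv, fit = select_auto_max_r2adj(curve, min_points=4)
    assert iv.stop <= 3
    assert fit.fd == pytest.approx(3.0, abs=1e-9)


def test_rounding_tie_prefers_wider_window():
    """An 8-point window with an exact fit and the full 9-point window with
    r2_adj ~ 0.99999 both round to 1.000, so the widest (9-point) window
    must win even though its unrounded score is lower."""
    counts = np.array([(64 / s) ** 2.7 for s in NINE.scales], float)
    counts[8] *= 1.05  # slightly bend only the largest scale
    curve = make_curve(NINE.scales, counts)
    full = fit_loglog(curve, ScaleInterval.from_indices(NINE, 0, 8))
    sub = fit_loglog(curve, ScaleInterval.from_indices(NINE, 0, 7))
    assert sub.r2_adj == pytest.approx(1.0) and full.r2_adj < sub.r2_adj
    assert oracle_round(full.r2_adj) == oracle_round(sub.r2_adj) == 1.0
    iv, _ = select_auto_fractalbrain(curve)
    assert (iv.start, iv.stop) == (0, 8)
    # the unrounded strategy is free to keep a perfectly fitting sub-window
    iv_m, fit_m = select_auto_max_r2adj(curve, min_points=5)
    assert iv_m.stop <= 7 and fit_m.r2_adj == pytest.approx(1.0)


def test_higher_rounded_r2adj_beats_width():
    """When a narrower window has a strictly higher rounded r2_adj than the
    widest one, the narrower window wins."""
    counts = np.array([(64 / s) ** 2.6 for s in NINE.scales], float)
    counts[6:] *= [1.6, 3.5, 9.0]  # corrupt the three largest scales
    curve = make_curve(NINE.scales, counts)
    iv, _ = select_auto_fractalbrain(curve)
    full_fit = fit_loglog(curve, ScaleInterval.from_indices(NINE, 0, 8))
    chosen_fit = fit_loglog(curve, iv)
    assert iv.n_points < 9
    assert oracle_round(chosen_fit.r2_adj) > oracle_round(full_fit.r2_adj)


def test_fractalbrain_interval_always_spans_at_least_1_2_decades():
    rng = np.random.default_rng(5)
    for _ in range(50):
        curve = powerlaw_curve(NINE, fd=rng.uniform(1.8, 3.0),
                               noise_sd=rng.uniform(0.0, 0.3), rng=rng)
        iv, _ = select_auto_fractalbrain(curve)
        assert iv.width_decades >= math.log10(16) - 1e-12


def test_strategies_agree_when_unrounded_max_is_widest_rounding_tie():
    """Whenever the window with the best unrounded r2_adj is also strictly
    the widest among the windows sharing its rounded value, both automated
    strategies must return it."""
    rng = np.random.default_rng(17)
    checked = 0
    for _ in range(100):
        curve = powerlaw_curve(NINE, fd=2.4, noise_sd=0.05, rng=rng)
        fits = [(iv, fit_loglog(curve, iv)) for iv in enumerate_intervals(NINE, 5)]
        best_iv, best_fit = max(fits, key=lambda t: t[1].r2_adj)
        top = oracle_round(best_fit.r2_adj)
        ties = [iv for iv, f in fits if oracle_round(f.r2_adj) == top]
        if any(t.width_decades >= best_iv.width_decades for t in ties
               if (t.start, t.stop) != (best_iv.start, best_iv.stop)):
            continue
        iv_m, _ = select_auto_max_r2adj(curve, min_points=5)
        iv_f, _ = select_auto_fractalbrain(curve, min_points=5)
        assert (iv_m.start, iv_m.stop) == (best_iv.start, best_iv.stop)
        assert (iv_f.start, iv_f.stop) == (best_iv.start, best_iv.stop)
        checked += 1
    assert checked > 10


def test_round_half_away_behaviour():
    assert round_half_away(0.9995, 3) == 1.0
    assert round_half_away(0.99949, 3) == 0.999
    assert round_half_away(-0.0005, 3) == -0.001
    assert round_half_away(0.12345, 3) == 0.123
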