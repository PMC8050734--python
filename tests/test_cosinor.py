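import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.signal import lombscargle

from circashift import (
    benjamini_hochberg,
    detect_rhythms,
    detect_ultradian,
    fit_cosinor,
    scan_period,
)
from circashift.cosinor import _TemplateTest, _lombscargle_p
from circashift.simulate import SyntheticSpec, generate_dataset


def test_noiseless_fit_recovers_exact_parameters(t_grid, cosine_fn):
    y = cosine_fn(t_grid, 10.0, 2.0, 6.0)
    fit = fit_cosinor(t_grid, y, 24.0)
    assert fit.mesor == pytest.approx(10.0, rel=1e-12)
    assert fit.amplitude == pytest.approx(2.0, rel=1e-12)
    assert fit.acrophase == pytest.approx(6.0, abs=1e-10)
    assert fit.p_value == 0.0


def test_constant_series_gives_zero_amplitude_p_one(t_grid):
    fit = fit_cosinor(t_grid, np.full_like(t_grid, 5.0), 24.0)
    assert fit.amplitude == 0.0
    assert fit.p_value == 1.0


def test_too_few_distinct_timepoints_errors():
    with pytest.raises(ValueError, match="distinct timepoints"):
        fit_cosinor([2.0, 2.0, 14.0, 14.0], [1.0, 2.0, 3.0, 4.0], 24.0)


def test_fit_matches_brute_force_grid_search(t_grid, cosine_fn):
    """(A, phi) from the linearized fit agree with an exhaustive
    RSS-minimizing search over acrophase at 0.01-h resolution."""
    rng = np.random.default_rng(11)
    y = cosine_fn(t_grid, 8.0, 1.5, 17.3) + rng.normal(0, 0.7, t_grid.size)
    fit = fit_cosinor(t_grid, y, 24.0)

    best = None
    w = 2 * np.pi / 24.0
    for phi in np.arange(0, 24, 0.01):
        X = np.column_stack([np.ones_like(t_grid), np.cos(w * (t_grid - phi))])
        coef, rss, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(rss[0]) if rss.size else float(np.sum((y - X @ coef) ** 2))
        if coef[1] >= 0 and (best is None or rss < best[0]):
            best = (rss, coef[0], coef[1], phi)
    _, m_grid, a_grid, phi_grid = best
    assert fit.acrophase == pytest.approx(phi_grid, abs=0.011)
    assert fit.amplitude == pytest.approx(a_grid, rel=1e-3)
    assert fit.mesor == pytest.approx(m_grid, rel=1e-3)


@given(st.floats(-24, 24), st.floats(0.1, 50))
def test_acrophase_and_scale_equivariance(shift, scale):
    """Shifting timestamps shifts phi (mod tau); scaling y scales M, A."""
    t = np.tile([2.0, 6.0, 10.0, 14.0, 18.0, 22.0], 4)
    rng = np.random.default_rng(7)
    y = 10 + 3 * np.cos(2 * np.pi * (t - 5) / 24) + rng.normal(0, 1, t.size)
    base = fit_cosinor(t, y, 24.0)
    shifted = fit_cosinor(t + shift, y, 24.0)
    assert shifted.amplitude == pytest.approx(base.amplitude, rel=1e-9)
    assert shifted.mesor == pytest.approx(base.mesor, rel=1e-9)
    assert shifted.p_value == pytest.approx(base.p_value, rel=1e-9, abs=1e-12)
    d = (shifted.acrophase - base.acrophase - shift) % 24
    assert min(d, 24 - d) == pytest.approx(0.0, abs=1e-8)
    scaled = fit_cosinor(t, scale * y, 24.0)
    assert scaled.mesor == pytest.approx(scale * base.mesor, rel=1e-9)
    assert scaled.amplitude == pytest.approx(scale * base.amplitude, rel=1e-9)
    assert scaled.acrophase == pytest.approx(base.acrophase, abs=1e-9)
    assert scaled.p_value == pytest.approx(base.p_value, rel=1e-9, abs=1e-12)


def test_lombscargle_component_matches_scipy(t_grid):
    rng = np.random.default_rng(3)
    Y = rng.lognormal(2, 0.5, size=(20, t_grid.size))
    ours = _lombscargle_p(t_grid, Y, 24.0)
    w = 2 * np.pi / 24.0
    n = t_grid.size
    for i in range(Y.shape[0]):
        yc = Y[i] - Y[i].mean()
        frac = float(lombscargle(t_grid, yc, [w], normalize=True))
        expected = np.exp(-frac * (n - 1) / 2.0)
        assert ours[i] == pytest.approx(expected, rel=1e-9)


def test_template_kendall_matches_scipy(t_grid):
    """Our vectorized tie-corrected Kendall z reproduces scipy's p-values
    template by template (one-sided = two-sided / 2 for positive S)."""
    rng = np.random.default_rng(4)
    y = rng.normal(10, 2, t_grid.size)
    template_test = _TemplateTest(t_grid, 24.0)
    ours = template_test.pvalues(y[None, :])[0]
    w = 2 * np.pi / 24.0
    ps = []
    for phi in np.arange(0, 24.0, 1.0):
        x = np.round(np.cos(w * (t_grid - phi)), 12)
        res = stats.kendalltau(y, x)
        one_sided = res.pvalue / 2 if res.statistic > 0 else 1 - res.pvalue / 2
        ps.append(one_sided)
    expected = min(1.0, 24 * min(ps))
    assert ours == pytest.approx(expected, rel=1e-6)


def test_bh_hand_example():
    qs = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    np.testing.assert_allclose(qs, [0.04, 0.04, 0.04, 0.04])


def _bh_oracle(p):
    """Independent sort-based BH step-up."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@given(st.integers(0, 2**31 - 1))
def test_bh_matches_sort_based_oracle(seed):
    p = np.random.default_rng(seed).uniform(size=37) ** 2
    np.testing.assert_allclose(benjamini_hochberg(p), _bh_oracle(p), rtol=1e-12)


@pytest.fixture(scope="module")
def small_dataset():
    spec = SyntheticSpec(n_features=60, frac_rhythmic=0.5, seed=21)
    return generate_dataset(spec)


def test_detect_rhythms_identical_features_get_identical_p(small_dataset):
    matrix, design, _ = small_dataset
    clones = pd.DataFrame(
        np.tile(matrix.iloc[0].to_numpy(), (5, 1)),
        index=[f"c{i}" for i in range(5)],
        columns=matrix.columns,
    )
    fits = detect_rhythms(clones, design, "NRF", seed=0)
    assert fits.p_value.nunique() == 1
    assert fits.q_value.nunique() == 1


def test_detect_rhythms_flags_and_errors(small_dataset):
    matrix, design, truth = small_dataset
    with pytest.raises(ValueError, match="unknown condition"):
        detect_rhythms(matrix, design, "ADF")
    with pytest.raises(ValueError, match="sampling span"):
        detect_rhythms(matrix, design, "NRF", tau=30.0)
    fits = detect_rhythms(matrix, design, "NRF", seed=0)
    assert set(fits.index) == set(matrix.index)
    assert ((fits.q_value >= 0.05) == fits.phase_low_confidence).all()
    # BH flagged set equals the oracle's flagged set
    oracle_q = _bh_oracle(fits.p_value.to_numpy())
    assert ((oracle_q < 0.05) == (fits.q_value < 0.05).to_numpy()).all()


def test_detect_rhythms_finds_planted_rhythms(small_dataset):
    matrix, design, truth = small_dataset
    truth = truth.set_index("feature_id")
    fits = detect_rhythms(matrix, design, "NRF", seed=0)
    rhythmic = truth.rhythmic_NRF
    sensitivity = (fits.loc[rhythmic[rhythmic].index, "q_value"] < 0.05).mean()
    assert sensitivity > 0.9


def test_detect_handles_missing_values(small_dataset):
    matrix, design, _ = small_dataset
    holed = matrix.copy()
    holed.iloc[0, 0] = np.nan
    holed.iloc[1, 5] = np.nan
    fits = detect_rhythms(holed, design, "NRF", seed=0)
    assert fits.n_used.iloc[0] == 23
    assert np.isfinite(fits.p_value.iloc[:2]).all()


def test_scan_period_recovers_long_period(cosine_fn):
    t = np.tile([2.0, 6.0, 10.0, 14.0, 18.0, 22.0], 4)
    y = cosine_fn(t, 10.0, 2.0, 3.0, tau=25.6)
    scan = scan_period(t, y, tau_range=(20, 28), step=0.1)
    assert abs(scan.period - 25.6) <= 0.1 + 1e-9
    y24 = cosine_fn(t, 10.0, 2.0, 3.0, tau=24.0)
    assert scan_period(t, y24).period == pytest.approx(24.0)


def test_scan_period_selection_penalty_on_noise():
    rng = np.random.default_rng(9)
    t = np.tile([2.0, 6.0, 10.0, 14.0, 18.0, 22.0], 4)
    y = rng.normal(size=t.size)
    scan = scan_period(t, y)
    assert scan.selection_adjusted
    assert scan.p_value >= scan.p_raw
    with pytest.raises(ValueError, match="span"):
        scan_period(t, y, tau_range=(20, 100))


def test_ultradian_detection_is_period_specific():
    spec = SyntheticSpec(
        n_features=60, frac_rhythmic=0.3, frac_ultradian=0.3, seed=31
    )
    matrix, design, truth = generate_dataset(spec)
    truth = truth.set_index("feature_id")
    fits12 = detect_ultradian(matrix, design, "DRF", seed=0)
    fits24 = detect_rhythms(matrix, design, "DRF", tau=24.0, seed=0)
    ultra = truth[truth.ultradian].index
    diurnal = truth[truth.role == "rhythmic"].index
    assert (fits12.loc[ultra, "q_value"] < 0.05).mean() >= 0.9
    # 24-h cosines are near-orthogonal to the 12-h harmonic on this grid
    assert (fits12.loc[diurnal, "q_value"] < 0.05).mean() < 0.3
    assert (fits24.loc[ultra, "q_value"] < 0.05).mean() < 0.3
    flat = truth[truth.role == "flat"].index
    assert (fits12.loc[flat, "p_value"] > 0.05).mean() > 0.8
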