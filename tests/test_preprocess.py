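"""Background correction and quantile normalization."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from xmask.preprocess import (
    NormExpParams,
    background_correct,
    estimate_normexp_params,
    normexp_signal,
    quantile_normalize,
)
from conftest import make_matrix, make_sheet


def _posterior_mean_by_integration(x, p):
    """Numerical oracle: E[S | X=x] for S~Exp(alpha), B~N(mu, sigma^2).

    The posterior density concentrates near max(0, x - mu); integrating on
    a finite window around it keeps quad well conditioned for large x.
    """
    f = lambda s: s * p.alpha * np.exp(-p.alpha * s) * stats.norm.pdf(x - s, p.mu, p.sigma)
    g = lambda s: p.alpha * np.exp(-p.alpha * s) * stats.norm.pdf(x - s, p.mu, p.sigma)
    hi = max(x - p.mu, 0) + 12 * p.sigma + 12 / p.alpha
    peak = min(max(x - p.mu, 0), hi)
    num, _ = quad(f, 0, hi, limit=400, points=[peak])
    den, _ = quad(g, 0, hi, limit=400, points=[peak])
    return num / den


def test_normexp_posterior_mean_matches_integration_oracle():
    """The closed form agrees with brute-force integration to 1e-6 relative."""
    params = NormExpParams(mu=100.0, sigma=30.0, alpha=1 / 400)
    xs = np.array([5.0, 20.0, 50.0, 90.0, 120.0, 180.0, 300.0, 600.0, 1200.0])
    got = normexp_signal(xs, params)
    want = np.array([_posterior_mean_by_integration(x, params) for x in xs])
    assert np.allclose(got, want, rtol=1e-6)


def test_normexp_on_estimated_params_from_synthetic_sample():
    """On a 1000-probe sample the corrected values match the oracle."""
    rng = np.random.default_rng(3)
    x = rng.exponential(400, 1000) + rng.normal(100, 25, 1000)
    params = estimate_normexp_params(x)
    sub = np.sort(x)[::100]
    got = normexp_signal(sub, params)
    want = np.array([_posterior_mean_by_integration(v, params) for v in sub])
    assert np.allclose(got, want, rtol=1e-6)


def test_background_correct_none_is_identity():
    m = make_matrix(np.arange(1, 25).reshape(2, 12))
    out = background_correct(m, "none")
    assert out.values.equals(m.values)


def test_background_correct_preserves_rank_and_positivity():
    rng = np.random.default_rng(5)
    sheet = make_sheet(n_genotypes=1, replicates=1)
    m = make_matrix(rng.exponential(300, (500, 2)) + rng.normal(80, 15, (500, 2)),
                    sheet)
    out = background_correct(m, "rma_convolution")
    assert (out.values.to_numpy() > 0).all()
    for col in m.values.columns:
        assert (np.argsort(out.values[col].to_numpy())
                == np.argsort(m.values[col].to_numpy())).all()


def test_background_correct_rejects_log2_input():
    m = make_matrix(np.full((3, 12), 8.0), scale="log2")
    with pytest.raises(ValueError, match="linear"):
        background_correct(m, "rma_convolution")


def test_quantile_normalize_two_sample_example():
    """[1,2,3] and [4,5,6] both become the mean order statistics [2.5,3.5,4.5]."""
    sheet = make_sheet(n_genotypes=1, replicates=1)
    m = make_matrix(np.array([[1, 4], [2, 5], [3, 6]]), sheet)
    out = quantile_normalize(m).values.to_numpy()
    assert np.allclose(out, [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])


def test_quantile_normalize_identical_samples_unchanged():
    sheet = make_sheet(n_genotypes=1, replicates=1)
    m = make_matrix(np.array([[3.0, 3.0], [1.0, 1.0], [7.0, 7.0]]), sheet)
    out = quantile_normalize(m).values.to_numpy()
    assert np.allclose(out, m.values.to_numpy())


def test_quantile_normalize_sorted_columns_identical_and_idempotent():
    rng = np.random.default_rng(7)
    sheet = make_sheet(n_genotypes=2, replicates=1)  # 4 samples
    m = make_matrix(rng.lognormal(5, 1, (50, 4)), sheet)
    once = quantile_normalize(m)
    X = once.values.to_numpy()
    ref = np.sort(X[:, 0])
    for j in range(X.shape[1]):
        assert np.allclose(np.sort(X[:, j]), ref, rtol=0, atol=1e-12)
    twice = quantile_normalize(once)
    assert np.allclose(twice.values.to_numpy(), X)
    # within-sample rank order preserved
    for j in range(X.shape[1]):
        orig = m.values.to_numpy()[:, j]
        assert (np.argsort(X[:, j], kind="stable")
                == np.argsort(orig, kind="stable")).all()


def test_quantile_normalize_ties_get_mean_of_spanned_quantiles():
    sheet = make_sheet(n_genotypes=1, replicates=1)
    m = make_matrix(np.array([[1.0, 10.0], [1.0, 20.0], [4.0, 30.0]]), sheet)
    out = quantile_normalize(m).values.to_numpy()
    ref = np.array([(1 + 10) / 2, (1 + 20) / 2, (4 + 30) / 2])
    # tied pair in sample 1 spans quantiles 1-2 -> mean of ref[0:2]
    assert np.allclose(out[:, 0], [ref[:2].mean(), ref[:2].mean(), ref[2]])
    assert np.allclose(out[:, 1], ref)


def test_quantile_normalize_single_sample_warns_noop():
    import pandas as pd

    from xmask.io import ProbeIntensityMatrix, SampleSheet
    sheet = SampleSheet(pd.DataFrame({"sample_id": ["s1"], "species": ["target"],
                                      "genotype": ["A"], "tissue": ["ES"],
                                      "replicate": [1]}))
    m = ProbeIntensityMatrix(
        pd.DataFrame({"s1": [1.0, 2.0]}, index=pd.Index(["a", "b"], name="probe_id")),
        sheet)
    with pytest.warns(UserWarning):
        out = quantile_normalize(m)
    assert out.values.equals(m.values)
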