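"""Statistical window features against brute-force oracles and invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstate.stat_features import magnitude, stat_features


# --- independent brute-force oracle: direct formula evaluation ------------

def oracle_features(x, block):
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in x) / n)

    def median(vals):
        vals = sorted(vals)
        m = len(vals)
        return vals[m // 2] if m % 2 else (vals[m // 2 - 1] + vals[m // 2]) / 2

    med = median(x)
    mad = median([abs(v - med) for v in x])
    energy = sum(abs(v) ** 2 for v in x) / n
    # quartiles as medians of the lower/upper halves, median shared when odd
    s_sorted = sorted(x)
    half = (n + 1) // 2
    iqr = median(s_sorted[n - half:]) - median(s_sorted[:half])
    sma = sum(abs(a) + abs(b) + abs(c) for a, b, c in block) / n
    s = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    if s == 0:
        skew = kurt = 0.0
    else:
        skew = n / ((n - 1) * (n - 2)) * sum(((v - mean) / s) ** 3 for v in x)
        m2 = sum((v - mean) ** 2 for v in x) / n
        m4 = sum((v - mean) ** 4 for v in x) / n
        kurt = m4 / m2**2 - 3.0
    return (mean, std, mad, min(x), max(x), energy, iqr, sma, skew, kurt)


def test_magnitude_closed_forms():
    ones = np.ones((5, 3))
    np.testing.assert_allclose(magnitude(ones), np.sqrt(3))
    np.testing.assert_allclose(magnitude(np.zeros((4, 3))), 0.0)
    e1 = np.zeros((7, 3))
    e1[:, 0] = 1.0
    np.testing.assert_allclose(magnitude(e1), 1.0)
    with pytest.raises(ValueError):
        magnitude(np.zeros((0, 3)))


def test_constant_window():
    c = 2.5
    x = np.full(320, c)
    block = np.full((320, 3), c / np.sqrt(3))
    f = stat_features(x, block)
    assert f.mean == pytest.approx(c)
    assert f.std == 0 and f.mad == 0 and f.iqr == 0
    assert f.energy == pytest.approx(c**2)
    assert f.skewness == 0 and f.kurtosis == 0
    assert f.minimum == f.maximum == pytest.approx(c)


def test_hand_example_one_to_five():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    f = stat_features(x, np.ones((5, 3)))
    assert f.mad == pytest.approx(1.0)
    assert f.iqr == pytest.approx(2.0)  # medians of {1,2,3} and {3,4,5}
    assert f.sma == pytest.approx(3.0)  # |1|+|1|+|1| per sample


def test_agreement_with_bruteforce_oracle():
    """All ten formulas match direct evaluation to 1e-10 relative."""
    rng = np.random.default_rng(42)
    for _ in range(60):
        n = int(rng.integers(4, 400))
        block = rng.normal(0, 1.5, (n, 3))
        x = magnitude(block)
        got = stat_features(x, block).as_tuple()
        want = oracle_features(x, block)
        np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)


def test_short_windows_and_degenerate():
    with pytest.raises(ValueError):
        stat_features(np.array([1.0]), np.ones((1, 3)))
    f = stat_features(np.array([1.0, 2.0, 4.0]), np.ones((3, 3)))
    assert f.skewness == 0.0 and f.kurtosis == 0.0  # n < 4 convention
    assert f.mean == pytest.approx(7 / 3)


@given(
    scale=st.floats(0.1, 10),
    shift=st.floats(-5, 5),
    seed=st.integers(0, 2**16),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_scale_and_translation_equivariance(scale, shift, seed):
    rng = np.random.default_rng(seed)
    block = rng.normal(0, 1, (64, 3))
    x = magnitude(block)
    base = stat_features(x, block)

    scaled = stat_features(scale * x, scale * block)
    assert scaled.mean == pytest.approx(scale * base.mean, rel=1e-9)
    assert scaled.std == pytest.approx(scale * base.std, rel=1e-9)
    assert scaled.energy == pytest.approx(scale**2 * base.energy, rel=1e-9)
    assert scaled.skewness == pytest.approx(base.skewness, rel=1e-7, abs=1e-9)
    assert scaled.kurtosis == pytest.approx(base.kurtosis, rel=1e-7, abs=1e-9)

    shifted = stat_features(x + shift, block)
    assert shifted.mean == pytest.approx(base.mean + shift, rel=1e-9, abs=1e-9)
    assert shifted.std == pytest.approx(base.std, rel=1e-9, abs=1e-12)
    assert shifted.mad == pytest.approx(base.mad, rel=1e-9, abs=1e-12)
    assert shifted.iqr == pytest.approx(base.iqr, rel=1e-9, abs=1e-12)
    assert shifted.minimum == pytest.approx(base.minimum + shift, rel=1e-9, abs=1e-9)
    assert shifted.maximum == pytest.approx(base.maximum + shift, rel=1e-9, abs=1e-9)
    assert shifted.skewness == pytest.approx(base.skewness, rel=1e-6, abs=1e-8)
    assert shifted.kurtosis == pytest.approx(base.kurtosis, rel=1e-6, abs=1e-8)
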