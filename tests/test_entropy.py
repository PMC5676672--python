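"""Wavelet decomposition, subband energies and the entropy statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioradar import (
    ConfigError,
    EchoMatrix,
    WaveletParams,
    ZeroEnergyError,
    dwt_decompose,
    entropy_spectrum,
    relative_energies,
    shannon_wavelet_entropy,
    subband_energies,
    vector_entropy,
)
from bioradar.entropy import EnergyDistribution

LN7 = float(np.log(7))


# --- decomposition ----------------------------------------------------------


def test_six_levels_give_seven_subbands(rng):
    d = dwt_decompose(rng.normal(size=2048), WaveletParams(n_levels=6))
    assert d.n_levels == 6
    assert len(d.subbands()) == 7
    assert d.level_lengths == [1024, 512, 256, 128, 64, 32, 32]


def test_constant_vector_has_vanishing_details():
    d = dwt_decompose(np.full(512, 3.7), WaveletParams(n_levels=5))
    for band in d.detail_coeffs:
        assert np.abs(band).max() < 1e-10


def test_parseval_energy_identity(rng):
    x = rng.normal(size=2048)
    d = dwt_decompose(x, WaveletParams(n_levels=6))
    assert d.total_energy() == pytest.approx((x**2).sum(), rel=1e-6)


def test_round_trip_reconstruction(rng):
    x = rng.normal(size=1024)
    d = dwt_decompose(x, WaveletParams(n_levels=6))
    err = np.linalg.norm(d.reconstruct() - x)
    assert err <= 1e-8 * np.linalg.norm(x)


def test_too_deep_decomposition_names_max_depth():
    with pytest.raises(ConfigError, match="at most 5"):
        dwt_decompose(np.zeros(32), WaveletParams(n_levels=8))


# --- subband energies -------------------------------------------------------


def test_single_coefficient_energy_is_its_square():
    e = EnergyDistribution(
        E=np.array([[9.0]]), counts=np.array([[1]]), energy_mode="raw_sum"
    )
    assert e.E_total[0] == 9.0


def test_energies_from_decomposition_square_coefficients(rng):
    x = rng.normal(size=256)
    params = WaveletParams(n_levels=4, energy_mode="raw_sum")
    d = dwt_decompose(x, params)
    e = subband_energies(d, params)
    expected = [float((band**2).sum()) for band in d.subbands()]
    np.testing.assert_allclose(e.E[0], expected, rtol=1e-12)


def test_zero_signal_gives_zero_energy_and_undefined_distribution():
    params = WaveletParams(n_levels=4)
    d = dwt_decompose(np.zeros(256), params)
    e = subband_energies(d, params)
    assert np.all(e.E == 0.0)
    with pytest.raises(ZeroEnergyError):
        relative_energies(e)


def test_white_noise_mean_energy_is_flat_across_subbands():
    """Orthonormal DWT of white noise: equal per-coefficient variance in
    every subband (200-replicate Monte-Carlo)."""
    rng = np.random.default_rng(99)
    params = WaveletParams(n_levels=6)
    acc = np.zeros(7)
    reps = 200
    for _ in range(reps):
        d = dwt_decompose(rng.normal(size=2048), params)
        acc += subband_energies(d, params).E[0]
    acc /= reps
    np.testing.assert_allclose(acc, 1.0, atol=5.0 / np.sqrt(reps))


def test_windowed_energies_partition_the_record(rng):
    x = rng.normal(size=512)
    params = WaveletParams(n_levels=4, window_len=128, energy_mode="raw_sum")
    d = dwt_decompose(x, params)
    e = subband_energies(d, params)
    assert e.E.shape == (4, 5)
    # windowed energies resum to the whole-record energies
    whole = subband_energies(d, WaveletParams(n_levels=4, energy_mode="raw_sum"))
    np.testing.assert_allclose(e.E.sum(axis=0), whole.E[0], rtol=1e-12)
    assert e.counts.sum() == sum(d.level_lengths)


def test_window_must_divide_record(rng):
    params = WaveletParams(n_levels=4, window_len=100)
    with pytest.raises(ConfigError, match="divide"):
        dwt_decompose(rng.normal(size=512), params)


# --- relative energies ------------------------------------------------------


def test_relative_energies_worked_example():
    e = EnergyDistribution(
        E=np.array([[2.0, 1.0, 1.0]]),
        counts=np.ones((1, 3), int),
        energy_mode="raw_sum",
    )
    p = relative_energies(e).P[0]
    np.testing.assert_allclose(p, [0.5, 0.25, 0.25])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    e=st.lists(st.floats(0.0, 1e6), min_size=2, max_size=8).filter(
        lambda v: sum(v) > 1e-6
    ),
    c=st.floats(1e-3, 1e3),
)
def test_relative_energies_sum_to_one_and_are_scale_free(e, c):
    E = np.array([e])
    dist = EnergyDistribution(E=E, counts=np.ones_like(E, int), energy_mode="raw_sum")
    p = relative_energies(dist).P[0]
    assert p.sum() == pytest.approx(1.0, abs=1e-12)
    scaled = EnergyDistribution(
        E=c * E, counts=np.ones_like(E, int), energy_mode="raw_sum"
    )
    np.testing.assert_allclose(relative_energies(scaled).P[0], p, rtol=1e-9)


# --- Shannon entropy --------------------------------------------------------


def test_degenerate_distribution_has_zero_entropy():
    p = np.zeros(7)
    p[0] = 1.0
    assert shannon_wavelet_entropy(p) == 0.0


def test_uniform_over_seven_subbands_reaches_ln7():
    assert shannon_wavelet_entropy(np.full(7, 1 / 7)) == pytest.approx(LN7, abs=1e-12)


def test_worked_example_half_quarter_quarter():
    p = np.array([0.5, 0.25, 0.25])
    assert shannon_wavelet_entropy(p) == pytest.approx(1.0397, abs=1e-4)


def test_invalid_probability_vectors_rejected():
    with pytest.raises(ConfigError):
        shannon_wavelet_entropy(np.array([0.5, 0.4]))  # does not sum to 1
    with pytest.raises(ConfigError):
        shannon_wavelet_entropy(np.array([1.2, -0.2]))


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    weights=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=7).filter(
        lambda v: sum(v) > 1e-3
    )
)
def test_entropy_bounds(weights):
    p = np.array(weights) / sum(weights)
    h = shannon_wavelet_entropy(p)
    assert 0.0 <= h <= np.log(len(p)) + 1e-12


@settings(max_examples=20, deadline=None, derandomize=True)
@given(c=st.floats(1e-3, 1e3))
def test_entropy_invariant_under_amplitude_scaling(c):
    rng = np.random.default_rng(21)
    x = rng.normal(size=512)
    params = WaveletParams(n_levels=5)
    assert vector_entropy(c * x, params) == pytest.approx(
        vector_entropy(x, params), rel=1e-9
    )


def test_narrowband_versus_broadband_separation():
    """The contrast that drives detection: a tone confined to one subband
    scores below 0.35 ln(J+1); white noise scores above 0.9 ln(J+1)."""
    params = WaveletParams(n_levels=6)
    t = np.arange(2048) / 64.0
    tone = np.sin(2 * np.pi * 0.25 * t)  # inside the 0-0.5 Hz approximation band
    assert vector_entropy(tone, params) < 0.35 * LN7
    rng = np.random.default_rng(17)
    noise_h = [vector_entropy(rng.normal(size=2048), params) for _ in range(200)]
    assert min(noise_h) > 0.9 * LN7


def test_raw_sum_white_noise_approaches_2ln2():
    """raw-sum mode on white noise: P_j halves per level, so H -> 2 ln 2.

    At J=10 the exact expectation of the band shares gives
    ln2 * (sum_j j 2^-j + 10 * 2^-10) = 1.38494...; the Monte-Carlo mean
    must sit within its sampling error of the limit.
    """
    params = WaveletParams(n_levels=10, energy_mode="raw_sum")
    rng = np.random.default_rng(5)
    hs = [vector_entropy(rng.normal(size=4096), params) for _ in range(60)]
    assert np.mean(hs) == pytest.approx(2 * np.log(2), abs=0.02)


# --- entropy spectrum over a matrix ----------------------------------------


def test_spectrum_is_deterministic_and_flags_zero_rows(rng):
    data = rng.normal(size=(6, 512))
    data[2] = 0.0
    m = EchoMatrix(data=data, fast_dt_ns=1.0, slow_fs_hz=64.0)
    params = WaveletParams(n_levels=5)
    a = entropy_spectrum(m, params)
    b = entropy_spectrum(m, params)
    np.testing.assert_array_equal(a.H, b.H)
    assert a.zero_energy[2]
    assert a.H[2] == pytest.approx(np.log(6))  # maximal disorder convention
    assert np.all((a.H >= 0) & (a.H <= a.h_max + 1e-12))


def test_window_combine_mean_and_max(rng):
    x = rng.normal(size=(1, 1024))
    m = EchoMatrix(data=x, fast_dt_ns=1.0, slow_fs_hz=64.0)
    mean_h = entropy_spectrum(
        m, WaveletParams(n_levels=4, window_len=256, window_combine="mean")
    ).H[0]
    max_h = entropy_spectrum(
        m, WaveletParams(n_levels=4, window_len=256, window_combine="max")
    ).H[0]
    assert max_h >= mean_h
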