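"""Dyadic wavelet decomposition and the wavelet-entropy statistic.

Each (autocorrelated) slow-time vector is decomposed with a J-level discrete
wavelet transform into detail subbands D_1..D_J plus the approximation A_J.
The energy E_j = sum_k |C_j(k)|^2 of each subband, normalised to a
probability vector P_j = E_j / sum_j E_j, measures how the signal's energy
is spread across octave frequency bands; its Shannon entropy

    H = -sum_j P_j ln P_j        (nats, 0 <= H <= ln(J+1))

is low for an ordered narrow-band signal (breathing: energy piles into one
band) and high for disordered broadband noise (energy spread evenly).  The
entropy evaluated per range bin yields a range profile whose *pits* mark
breathing targets — including targets whose absolute echo energy is buried
in the noise floor, because H is invariant to amplitude.

Two energy conventions are provided: ``mean_per_coeff`` divides each
subband energy by its coefficient count.  Because an orthonormal DWT of
white noise has equal per-coefficient variance in every subband, this
convention makes the noise energy distribution uniform and pushes noise
entropy to its ceiling, maximising the contrast with breathing bins; it is
the default.  ``raw_sum`` keeps plain coefficient-energy sums, under which
white noise yields P_j proportional to subband bandwidth (halving per
level) and H -> 2 ln 2 as J grows.

An optional non-overlapping temporal windowing follows the time evolution
of the statistic; per-window entropies are combined by mean (default) or
max.  The approximation band A_J is included as a (J+1)-th band: the
respiration line lives in the lowest octave and excluding it would discard
precisely the ordered component the statistic keys on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.special import xlogy

from .exceptions import ConfigError, ZeroEnergyError
from .matrix import EchoMatrix


@dataclass
class WaveletParams:
    """Wavelet-entropy settings.

    ``wavelet_name`` any orthogonal PyWavelets family member (default db4,
    4 vanishing moments); ``n_levels`` decomposition depth J (7 subbands at
    the default 6, entropy ceiling ln 7 ~ 1.946); ``window_len`` temporal
    window L in samples (None = one window spanning the record);
    ``energy_mode`` 'mean_per_coeff' or 'raw_sum'; ``window_combine``
    'mean' or 'max' across windows; ``boundary_mode`` the PyWavelets signal
    extension (periodization keeps the transform orthonormal so subband
    energies obey Parseval exactly).
    """

    wavelet_name: str = "db4"
    n_levels: int = 6
    window_len: int | None = None
    energy_mode: str = "mean_per_coeff"
    window_combine: str = "mean"
    boundary_mode: str = "periodization"

    def validate(self, n: int) -> None:
        if self.n_levels < 1:
            raise ConfigError("n_levels must be >= 1")
        max_level = int(np.floor(np.log2(n))) if n > 1 else 0
        if self.n_levels > max_level:
            raise ConfigError(
                f"signal of length {n} supports at most {max_level} "
                f"decomposition levels, requested {self.n_levels}"
            )
        if self.window_len is not None:
            if self.window_len < 1 or n % self.window_len != 0:
                raise ConfigError(
                    f"window_len={self.window_len} must divide the signal "
                    f"length {n}"
                )
        if self.energy_mode not in ("mean_per_coeff", "raw_sum"):
            raise ConfigError(f"unknown energy_mode {self.energy_mode!r}")
        if self.window_combine not in ("mean", "max"):
            raise ConfigError(f"unknown window_combine {self.window_combine!r}")


@dataclass
class WaveletDecomposition:
    """Subband coefficients of one vector: details D_1..D_J plus A_J."""

    detail_coeffs: list[np.ndarray]  # index 0 = level 1 (finest)
    approx_coeffs: np.ndarray
    n_samples: int
    params: WaveletParams

    @property
    def n_levels(self) -> int:
        return len(self.detail_coeffs)

    @property
    def level_lengths(self) -> list[int]:
        return [len(c) for c in self.detail_coeffs] + [len(self.approx_coeffs)]

    def subbands(self) -> list[np.ndarray]:
        """Bands ordered D_1 (finest) .. D_J, then A_J."""
        return list(self.detail_coeffs) + [self.approx_coeffs]

    def total_energy(self) -> float:
        return float(sum(np.sum(c**2) for c in self.subbands()))

    def reconstruct(self) -> np.ndarray:
        coeffs = [self.approx_coeffs] + list(reversed(self.detail_coeffs))
        rec = pywt.waverec(
            coeffs, self.params.wavelet_name, mode=self.params.boundary_mode
        )
        return rec[: self.n_samples]


@dataclass
class EnergyDistribution:
    """Per-window subband energies E[i, j] and relative energies P[i, j].

    ``j`` runs over D_1..D_J then A_J.  ``counts[i, j]`` is N_j(i), the
    number of coefficients of band j inside window i (zero counts are
    flagged and contribute zero energy).
    """

    E: np.ndarray  # (n_windows, n_bands)
    counts: np.ndarray  # (n_windows, n_bands) int
    energy_mode: str
    P: np.ndarray | None = None

    @property
    def n_windows(self) -> int:
        return self.E.shape[0]

    @property
    def n_bands(self) -> int:
        return self.E.shape[1]

    @property
    def E_total(self) -> np.ndarray:
        return self.E.sum(axis=1)


@dataclass
class EntropySpectrum:
    """Wavelet entropy per range bin with provenance."""

    H: np.ndarray
    range_axis_m: np.ndarray
    params: WaveletParams
    zero_energy: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.zero_energy is None:
            self.zero_energy = np.zeros(self.H.shape, dtype=bool)

    @property
    def h_max(self) -> float:
        return float(np.log(self.params.n_levels + 1))


def dwt_decompose(
    x: np.ndarray, params: WaveletParams | None = None
) -> WaveletDecomposition:
    """J-level discrete wavelet transform of a vector.

    Returns J detail subbands plus one approximation subband.  With the
    default periodization extension the transform is orthonormal: the total
    coefficient energy equals the signal energy and the round trip is exact
    to floating point.
    """
    params = params or WaveletParams()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ConfigError("dwt_decompose expects a 1-D vector")
    params.validate(x.size)
    with warnings.catch_warnings():
        # pywt warns for depths beyond its conservative default; with
        # periodization any depth down to one coefficient per band is valid.
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(
            x, params.wavelet_name, mode=params.boundary_mode, level=params.n_levels
        )
    # pywt order: [cA_J, cD_J, ..., cD_1] -> store details finest-first.
    details = list(reversed(coeffs[1:]))
    return WaveletDecomposition(
        detail_coeffs=details,
        approx_coeffs=coeffs[0],
        n_samples=x.size,
        params=params,
    )


def _window_of_coeff(n_coeff: int, n_samples: int, window_len: int) -> np.ndarray:
    """Window index for each coefficient of a subband.

    Coefficient k of a band with n_coeff coefficients covers samples around
    k * n_samples / n_coeff; it is assigned to the window containing that
    location.
    """
    centres = (np.arange(n_coeff) + 0.5) * (n_samples / n_coeff)
    return np.minimum(
        (centres // window_len).astype(int), n_samples // window_len - 1
    )


def subband_energies(
    d: WaveletDecomposition, params: WaveletParams | None = None
) -> EnergyDistribution:
    """Per-window, per-band energies of a decomposition.

    ``raw_sum``: E[i, j] = sum of |C_j(n)|^2 over window i's coefficients.
    ``mean_per_coeff``: the same sum divided by the coefficient count
    N_j(i).  An empty band/window combination contributes zero energy and
    is recorded in ``counts``.
    """
    params = params or d.params
    bands = d.subbands()
    window_len = params.window_len or d.n_samples
    if d.n_samples % window_len != 0:
        raise ConfigError(
            f"window_len={window_len} must divide signal length {d.n_samples}"
        )
    n_windows = d.n_samples // window_len
    n_bands = len(bands)
    E = np.zeros((n_windows, n_bands))
    counts = np.zeros((n_windows, n_bands), dtype=int)
    for j, band in enumerate(bands):
        w = _window_of_coeff(len(band), d.n_samples, window_len)
        np.add.at(E[:, j], w, band**2)
        np.add.at(counts[:, j], w, 1)
    if params.energy_mode == "mean_per_coeff":
        with np.errstate(invalid="ignore"):
            E = np.where(counts > 0, E / np.maximum(counts, 1), 0.0)
    return EnergyDistribution(E=E, counts=counts, energy_mode=params.energy_mode)


def relative_energies(e: EnergyDistribution) -> EnergyDistribution:
    """Fill the relative energies P[i, j] = E[i, j] / E_total(i).

    Raises :class:`ZeroEnergyError` if any window has zero total energy
    (the probability distribution is undefined there; the caller decides).
    """
    total = e.E_total
    if np.any(total <= 0.0):
        bad = int(np.argmax(total <= 0.0))
        raise ZeroEnergyError(
            f"window {bad} has zero total wavelet energy; relative energies "
            "are undefined"
        )
    e.P = e.E / total[:, None]
    return e


def shannon_wavelet_entropy(p: np.ndarray, atol: float = 1e-8) -> float:
    """Shannon entropy -sum p ln p (nats) of a probability vector.

    Uses the convention 0 ln 0 = 0.  Rejects vectors with negative entries
    or a sum away from 1 beyond ``atol``.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < -atol):
        raise ConfigError("probability vector has negative entries")
    p = np.clip(p, 0.0, None)
    s = p.sum()
    if abs(s - 1.0) > atol:
        raise ConfigError(f"probability vector sums to {s}, not 1")
    return float(-xlogy(p, p).sum())


def vector_entropy(x: np.ndarray, params: WaveletParams | None = None) -> float:
    """Wavelet entropy of one vector: decompose -> energies -> P -> H,
    combined across temporal windows per ``params.window_combine``."""
    params = params or WaveletParams()
    d = dwt_decompose(x, params)
    e = relative_energies(subband_energies(d, params))
    h = np.array([shannon_wavelet_entropy(row) for row in e.P])
    return float(h.max() if params.window_combine == "max" else h.mean())


def entropy_spectrum(
    m: EchoMatrix, params: WaveletParams | None = None
) -> EntropySpectrum:
    """Wavelet entropy of every range bin of an (autocorrelated) matrix.

    A bin whose slow-time vector has zero wavelet energy carries no
    structure at all; it is reported at the maximum entropy ln(J+1)
    (no structure = maximal disorder) and flagged in ``zero_energy``.
    """
    params = params or WaveletParams()
    params.validate(m.n_slow)
    h = np.empty(m.n_range)
    flags = np.zeros(m.n_range, dtype=bool)
    h_max = float(np.log(params.n_levels + 1))
    for i in range(m.n_range):
        try:
            h[i] = vector_entropy(m.data[i], params)
        except ZeroEnergyError:
            h[i] = h_max
            flags[i] = True
    return EntropySpectrum(
        H=h, range_axis_m=m.range_axis_m.copy(), params=params, zero_energy=flags
    )
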