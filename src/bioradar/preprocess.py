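"""Three-step pre-processing of a raw echo matrix.

1. range accumulation — sum contiguous fast-time blocks, compressing 2048
   rows to 200 range bins while conserving total sample sum;
2. static clutter removal — subtract a centered sliding-window mean along
   slow time (window truncated symmetrically at the record edges), which
   maps any slow-time-constant row (walls, rubble) to exactly zero;
3. FIR low-pass along slow time — linear-phase filter with the group delay
   compensated so the output stays phase-aligned with the input.

The whole chain is linear in the input samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .exceptions import ConfigError
from .matrix import SPEED_OF_LIGHT_M_S, EchoMatrix


@dataclass
class PreprocessParams:
    """Pre-processing parameters.

    ``n_range_bins`` output rows after accumulation; ``clutter_window``
    sliding-window width in slow-time samples; ``lp_cutoff_hz`` FIR low-pass
    cutoff (the default keeps the respiration line and leaves the noise
    broadband enough to occupy most dyadic subbands, preserving the
    entropy contrast between breathing and noise range bins); ``lp_order``
    FIR filter order (taps = order + 1, rounded up to an odd count so the
    group delay is an integer number of samples).
    """

    n_range_bins: int = 200
    clutter_window: int = 100
    lp_cutoff_hz: float = 16.0
    lp_order: int = 64

    def validate(self, n_rows: int, n_slow: int, slow_fs_hz: float) -> None:
        if self.n_range_bins <= 0 or self.n_range_bins > n_rows:
            raise ConfigError(
                f"n_range_bins={self.n_range_bins} must be in [1, {n_rows}]"
            )
        if self.clutter_window < 2:
            raise ConfigError("clutter_window must be >= 2")
        if n_slow < self.clutter_window:
            raise ConfigError(
                f"record length {n_slow} shorter than clutter window "
                f"{self.clutter_window}"
            )
        if not 0.0 < self.lp_cutoff_hz < slow_fs_hz / 2.0:
            raise ConfigError(
                f"lp_cutoff_hz={self.lp_cutoff_hz} must lie in "
                f"(0, {slow_fs_hz / 2.0}) Hz"
            )
        if self.lp_order < 2:
            raise ConfigError("lp_order must be >= 2")


def fast_time_to_range(tau_ns: float) -> float:
    """Convert a two-way delay in nanoseconds to range in metres, r = c*tau/2."""
    if tau_ns < 0:
        raise ConfigError(f"two-way delay must be >= 0, got {tau_ns} ns")
    return SPEED_OF_LIGHT_M_S * (tau_ns * 1e-9) / 2.0


def block_boundaries(n_rows: int, n_bins: int) -> np.ndarray:
    """Row indices partitioning ``n_rows`` into ``n_bins`` contiguous blocks.

    Blocks differ in size by at most one and the large blocks are evenly
    interleaved (floor-of-linear scheme).  Returns ``n_bins + 1`` edges.
    """
    return (np.arange(n_bins + 1) * n_rows) // n_bins


def range_accumulate(m: EchoMatrix, n_range_bins: int = 200) -> EchoMatrix:
    """Compress the fast-time axis by summing contiguous row blocks.

    Summation (rather than averaging) preserves the absolute energy of weak
    targets; the total sample sum of the matrix is conserved.  The output
    range axis carries block-centre ranges.
    """
    if n_range_bins <= 0 or n_range_bins > m.n_range:
        raise ConfigError(
            f"n_range_bins={n_range_bins} must be in [1, {m.n_range}]"
        )
    edges = block_boundaries(m.n_range, n_range_bins)
    acc = np.add.reduceat(m.data, edges[:-1], axis=0)
    centres = np.array(
        [m.range_axis_m[lo:hi].mean() for lo, hi in zip(edges[:-1], edges[1:])]
    )
    return EchoMatrix(
        data=acc,
        fast_dt_ns=m.fast_dt_ns * m.n_range / n_range_bins,
        slow_fs_hz=m.slow_fs_hz,
        range_axis_m=centres,
    )


def sliding_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along the last axis, truncated at the edges.

    At index i the window is ``[i-h, i+h]`` with ``h = min(window//2, i,
    N-1-i)``: full interior windows span ``2*(window//2)+1`` samples and
    edge windows shrink symmetrically, so no data is fabricated at the
    record boundaries.
    """
    n = x.shape[-1]
    half = window // 2
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate(
        [np.zeros(x.shape[:-1] + (1,)), np.cumsum(x, axis=-1)], axis=-1
    )
    lo = idx - h
    hi = idx + h
    return (csum[..., hi + 1] - csum[..., lo]) / (2 * h + 1)


def remove_static_clutter(m: EchoMatrix, clutter_window: int = 100) -> EchoMatrix:
    """Subtract each row's centered sliding-window mean along slow time.

    A slow-time-constant row (static clutter) maps to the zero row exactly.
    """
    if clutter_window < 2:
        raise ConfigError("clutter_window must be >= 2")
    if m.n_slow < clutter_window:
        raise ConfigError(
            f"record length {m.n_slow} shorter than clutter window {clutter_window}"
        )
    return m.with_data(m.data - sliding_mean(m.data, clutter_window))


def lowpass_taps(lp_cutoff_hz: float, lp_order: int, slow_fs_hz: float) -> np.ndarray:
    """Linear-phase FIR low-pass taps (Hamming window design, odd length)."""
    if lp_order < 2:
        raise ConfigError("lp_order must be >= 2")
    if not 0.0 < lp_cutoff_hz < slow_fs_hz / 2.0:
        raise ConfigError(
            f"cutoff {lp_cutoff_hz} Hz must lie below Nyquist {slow_fs_hz / 2.0} Hz"
        )
    numtaps = lp_order + 1
    if numtaps % 2 == 0:
        numtaps += 1
    return signal.firwin(numtaps, lp_cutoff_hz, fs=slow_fs_hz)


def lowpass_slow_time(
    m: EchoMatrix, lp_cutoff_hz: float = 16.0, lp_order: int = 64
) -> EchoMatrix:
    """FIR low-pass each row along slow time, compensating the group delay.

    The filter is applied once forward (a causal FIR, as in a streaming
    receiver) and the output is advanced by the integer group delay so it is
    phase-aligned with the input for the windowed entropy stage.
    """
    taps = lowpass_taps(lp_cutoff_hz, lp_order, m.slow_fs_hz)
    delay = (len(taps) - 1) // 2
    # edge-pad the start to warm the filter state up (no startup transient)
    # and the end so the delay-compensated output covers the whole record
    warm = len(taps) - 1
    padded = np.pad(m.data, ((0, 0), (warm, delay)), mode="edge")
    filtered = signal.lfilter(taps, [1.0], padded, axis=-1)[:, warm + delay :]
    return m.with_data(filtered)


def preprocess(m: EchoMatrix, params: PreprocessParams | None = None) -> EchoMatrix:
    """Run the full chain: accumulate -> clutter removal -> low-pass."""
    params = params or PreprocessParams()
    params.validate(m.n_range, m.n_slow, m.slow_fs_hz)
    out = range_accumulate(m, params.n_range_bins)
    out = remove_static_clutter(out, params.clutter_window)
    out = lowpass_slow_time(out, params.lp_cutoff_hz, params.lp_order)
    return out
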