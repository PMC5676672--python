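"""Target calls from an entropy-versus-range profile, plus the
power-spectrum baseline.

A breathing target shows up as an *entropy pit*: a contiguous dip in the
wavelet-entropy range profile whose width reflects the torso thickness.
Pits are located with a robust relative threshold, median(H) - k*MAD(H)
(relative, so detection is invariant to adding a constant to the whole
profile), and gated on physical width: a genuine torso produces a pit a few
decimetres wide, while ground-bounce multipath trailing behind a target
produces a dip whose extent does not match a human body.  The gated width
is measured at half depth — where the profile crosses midway between the
pit minimum and the profile median — so that a weak (shadowed) target's
pit measures its torso extent rather than shrinking with depth.  A
width-failing pit that starts just behind an accepted target is classified
as that target's ghost rather than as a separate rejection.

The respiration-band power profile (the conventional energy detector) is
provided as the baseline: it finds targets whose band power rises above the
noise floor, and by construction misses targets in a shadowing region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np

from .entropy import EntropySpectrum
from .exceptions import ConfigError
from .matrix import EchoMatrix


@dataclass
class DetectionParams:
    """Pit detection and classification settings.

    ``blind_range_m`` excludes the near-field wall reflection band;
    ``pit_k`` the k in the median - k*MAD threshold; ``min/max_pit_width_m``
    the accepted pit extent, bracketing a human torso; ``ghost_window_m``
    how far behind an accepted target a width-failing pit is attributed to
    trailing; ``power_k`` the k of the baseline's median + k*MAD threshold;
    ``power_band_hz`` the respiration band integrated by the baseline.
    """

    blind_range_m: float = 1.0
    pit_k: float = 3.0
    min_pit_width_m: float = 0.2
    max_pit_width_m: float = 0.8
    ghost_window_m: float = 1.0
    power_k: float = 8.0
    power_floor_ratio: float = 2.5
    power_band_hz: tuple[float, float] = (0.1, 1.0)

    def validate(self) -> None:
        if not 0.0 < self.min_pit_width_m < self.max_pit_width_m:
            raise ConfigError("need 0 < min_pit_width_m < max_pit_width_m")
        if self.pit_k <= 0:
            raise ConfigError("pit_k must be > 0")
        if self.blind_range_m < 0:
            raise ConfigError("blind_range_m must be >= 0")


@dataclass
class Pit:
    """A candidate entropy pit: a maximal below-threshold run of bins.

    ``lo_m``/``hi_m`` are the half-depth crossings around the minimum (the
    pit's width at half depth); ``range_m`` is the centre of that interval,
    which localises a flat-bottomed deep pit far more stably than the raw
    argmin; ``argmin_m`` keeps the minimum's own bin (nearer bin on exact
    ties); ``bin_lo``/``bin_hi`` delimit the below-threshold run itself.
    """

    range_m: float
    lo_m: float
    hi_m: float
    h_min: float
    argmin_m: float
    bin_lo: int
    bin_hi: int  # inclusive
    status: str = "candidate"

    @property
    def width_m(self) -> float:
        return self.hi_m - self.lo_m


@dataclass
class DetectionReport:
    """Classified pits plus the parameters and threshold that produced them."""

    detections: List[Pit]
    threshold: float
    params: DetectionParams

    @property
    def accepted(self) -> List[Pit]:
        return [p for p in self.detections if p.status == "accepted"]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "params": {
                "blind_range_m": self.params.blind_range_m,
                "pit_k": self.params.pit_k,
                "min_pit_width_m": self.params.min_pit_width_m,
                "max_pit_width_m": self.params.max_pit_width_m,
                "ghost_window_m": self.params.ghost_window_m,
            },
            "detections": [
                {
                    "range_m": p.range_m,
                    "argmin_m": p.argmin_m,
                    "interval_m": [p.lo_m, p.hi_m],
                    "width_m": p.width_m,
                    "h_min": p.h_min,
                    "status": p.status,
                }
                for p in self.detections
            ],
        }


def robust_threshold(values: np.ndarray, k: float) -> float:
    """median - k * MAD of ``values`` (MAD = median absolute deviation)."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med - k * mad


def find_entropy_pits(
    h: EntropySpectrum, params: DetectionParams | None = None
) -> tuple[List[Pit], float]:
    """Candidate pits: maximal runs of contiguous bins with H below the
    robust threshold, outside the blind range.

    Returns the pits (sorted by range) and the threshold used.  Each pit's
    interval is measured at half depth: walking outward from the minimum,
    the crossings of (median + h_min)/2 delimit it (linearly interpolated
    between bins).  This makes the gated width track the physical extent
    of the dip independently of how deep it is.  The pit minimum reports
    the nearer bin on exact ties.
    """
    params = params or DetectionParams()
    params.validate()
    beyond = h.range_axis_m > params.blind_range_m
    if beyond.sum() < 8:
        raise ConfigError(
            f"only {int(beyond.sum())} bins beyond the blind range; "
            "need >= 8 for a robust threshold"
        )
    median = float(np.median(h.H[beyond]))
    thr = robust_threshold(h.H[beyond], params.pit_k)

    below = (h.H < thr) & beyond
    pits: List[Pit] = []
    edges = np.diff(below.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if below[0]:
        starts.insert(0, 0)
    if below[-1]:
        ends.append(len(below) - 1)
    for lo, hi in zip(starts, ends):
        run = h.H[lo : hi + 1]
        i_min = lo + int(np.argmin(run))  # argmin -> first = nearer bin
        h_min = float(h.H[i_min])
        h_mid = 0.5 * (median + h_min)
        lo_m, hi_m = _half_depth_interval(h.H, h.range_axis_m, i_min, h_mid)
        pits.append(
            Pit(
                range_m=0.5 * (lo_m + hi_m),
                lo_m=lo_m,
                hi_m=hi_m,
                h_min=h_min,
                argmin_m=float(h.range_axis_m[i_min]),
                bin_lo=lo,
                bin_hi=hi,
            )
        )
    return pits, thr


def _half_depth_interval(
    H: np.ndarray, r: np.ndarray, i_min: int, h_mid: float
) -> tuple[float, float]:
    """Interval around bin ``i_min`` where H stays below ``h_mid``,
    with the boundary crossings linearly interpolated between bins."""
    n = len(H)
    j = i_min
    while j - 1 >= 0 and H[j - 1] < h_mid:
        j -= 1
    if j == 0:
        lo_m = r[0] - (r[1] - r[0]) / 2.0
    else:
        frac = (h_mid - H[j]) / (H[j - 1] - H[j])
        lo_m = r[j] - frac * (r[j] - r[j - 1])
    j = i_min
    while j + 1 < n and H[j + 1] < h_mid:
        j += 1
    if j == n - 1:
        hi_m = r[-1] + (r[-1] - r[-2]) / 2.0
    else:
        frac = (h_mid - H[j]) / (H[j + 1] - H[j])
        hi_m = r[j] + frac * (r[j + 1] - r[j])
    return float(lo_m), float(hi_m)


def classify_pits(
    pits: List[Pit], params: DetectionParams | None = None, threshold: float = np.nan
) -> DetectionReport:
    """Accept pits whose width matches a torso; label the rest.

    A pit is accepted iff its width lies in [min_pit_width_m,
    max_pit_width_m].  A width-failing pit whose interval starts within
    ``ghost_window_m`` behind an already-accepted pit is labelled
    ``rejected_ghost`` (trailing artifact); otherwise ``rejected_width``.
    Classification proceeds in range order, so ghosts attach only to nearer
    accepted targets.
    """
    params = params or DetectionParams()
    params.validate()
    ordered = sorted(pits, key=lambda p: p.lo_m)
    accepted: List[Pit] = []
    for pit in ordered:
        if params.min_pit_width_m <= pit.width_m <= params.max_pit_width_m:
            pit.status = "accepted"
            accepted.append(pit)
        else:
            behind = any(
                0.0 <= pit.lo_m - a.hi_m <= params.ghost_window_m for a in accepted
            )
            pit.status = "rejected_ghost" if behind else "rejected_width"
    ordered.sort(key=lambda p: p.range_m)
    return DetectionReport(detections=ordered, threshold=float(threshold), params=params)


def detect_targets(
    h: EntropySpectrum, params: DetectionParams | None = None
) -> DetectionReport:
    """find_entropy_pits followed by classify_pits."""
    params = params or DetectionParams()
    pits, thr = find_entropy_pits(h, params)
    return classify_pits(pits, params, threshold=thr)


def power_spectrum_profile(
    m: EchoMatrix, band_hz: tuple[float, float] = (0.1, 1.0)
) -> np.ndarray:
    """Respiration-band power of each range bin's slow-time signal.

    Sums the one-sided periodogram of each row over ``band_hz``; the
    conventional energy-detection baseline.
    """
    lo, hi = band_hz
    nyquist = m.slow_fs_hz / 2.0
    if not 0.0 <= lo < hi <= nyquist:
        raise ConfigError(
            f"band {band_hz} Hz must lie within [0, {nyquist}] Hz"
        )
    spec = np.fft.rfft(m.data, axis=-1)
    freqs = np.fft.rfftfreq(m.n_slow, d=1.0 / m.slow_fs_hz)
    sel = (freqs >= lo) & (freqs <= hi)
    return (np.abs(spec[:, sel]) ** 2).sum(axis=-1) / m.n_slow


def find_power_peaks(
    profile: np.ndarray,
    range_axis_m: np.ndarray,
    params: DetectionParams | None = None,
) -> List[float]:
    """Baseline target calls: peak ranges of runs where the band power
    rises visibly above the noise floor, outside the blind range.

    The threshold is max(median + power_k*MAD, power_floor_ratio*median):
    a peak must both be a statistical outlier and exceed the floor by a
    meaningful factor — an energy reader does not call a bump that sits at
    the noise floor, however smooth the floor is.  Runs must span at least
    two bins (single-bin excursions are noise).
    """
    params = params or DetectionParams()
    beyond = range_axis_m > params.blind_range_m
    vals = profile[beyond]
    med = float(np.median(vals))
    mad = float(np.median(np.abs(vals - med)))
    thr = max(med + params.power_k * mad, params.power_floor_ratio * med)
    above = (profile > thr) & beyond
    peaks: List[float] = []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above) - 1)
    for lo, hi in zip(starts, ends):
        if hi - lo + 1 < 2:
            continue
        i_max = lo + int(np.argmax(profile[lo : hi + 1]))
        peaks.append(float(range_axis_m[i_max]))
    return peaks
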