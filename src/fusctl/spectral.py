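"""Frequency bands and per-pulse acoustic-emission feature extraction.

Harmonic and ultra-harmonic bands are centred at half-integer multiples of
the excitation frequency ``0.5 * n * f0`` with a narrow half-width
(0.3 kHz by default); the broadband-emission bin sits at ``7.22 * f0``,
close to the passive detector's peak sensitivity.  Band levels are reported
in dB relative to a per-band baseline power, and a pulse is flagged as a
broadband event when the broadband bin rises at least 6 dB above baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Band",
    "PulseSpectrum",
    "AEFrame",
    "BandOverlapError",
    "EVENT_THRESHOLD_DB",
    "BROADBAND_MULTIPLE",
    "DEFAULT_HALF_WIDTH_KHZ",
    "HIGHPASS_CUTOFF_MHZ",
    "HARMONIC_ORDERS",
    "ULTRAHARMONIC_ORDERS",
    "BAND_KEYS",
    "make_band",
    "harmonic_band",
    "ultraharmonic_band",
    "broadband_band",
    "standard_bands",
    "band_level_db",
    "detect_broadband",
    "extract_frame",
    "baselines_from_spectra",
    "default_frequency_grid",
]

#: Event rule: broadband level at or above this many dB over baseline.
EVENT_THRESHOLD_DB = 6.0

#: Broadband bin centre as a multiple of f0 (near the PCD sensitivity peak).
BROADBAND_MULTIPLE = 7.22

DEFAULT_HALF_WIDTH_KHZ = 0.3
HIGHPASS_CUTOFF_MHZ = 0.6

#: Harmonic orders n*f0 carried in an AEFrame (7 entries).
HARMONIC_ORDERS = (2, 3, 4, 5, 6, 7, 8)
#: Ultra-harmonic indices k, meaning (k + 0.5)*f0 (7 entries: 1.5f0 .. 7.5f0).
ULTRAHARMONIC_ORDERS = (1, 2, 3, 4, 5, 6, 7)

#: Canonical baseline-dictionary keys: h2..h8, uh1..uh7, bb.
BAND_KEYS = tuple(
    [f"h{n}" for n in HARMONIC_ORDERS]
    + [f"uh{k}" for k in ULTRAHARMONIC_ORDERS]
    + ["bb"]
)


class BandOverlapError(ValueError):
    """Raised when a band does not overlap the spectrum's frequency grid."""


@dataclass(frozen=True)
class Band:
    """A narrow spectral bin: centre (MHz) and half-width (kHz)."""

    center_mhz: float
    half_width_khz: float = DEFAULT_HALF_WIDTH_KHZ

    def __post_init__(self) -> None:
        if not (self.center_mhz > 0):
            raise ValueError(f"center_mhz must be > 0, got {self.center_mhz}")
        if not (self.half_width_khz > 0):
            raise ValueError(
                f"half_width_khz must be > 0, got {self.half_width_khz}"
            )

    @property
    def half_width_mhz(self) -> float:
        return self.half_width_khz * 1e-3

    @property
    def lo_mhz(self) -> float:
        return self.center_mhz - self.half_width_mhz

    @property
    def hi_mhz(self) -> float:
        return self.center_mhz + self.half_width_mhz


def make_band(
    n: int, f0_mhz: float, half_width_khz: float = DEFAULT_HALF_WIDTH_KHZ
) -> Band:
    """Band centred at ``0.5 * n * f0``.

    Even ``n`` gives harmonics (n=4 -> 2 f0), odd ``n`` gives
    ultra-harmonics (n=3 -> 1.5 f0).  ``n`` must be at least 2.
    """
    if int(n) != n or n < 2:
        raise ValueError(f"n must be an integer >= 2, got {n!r}")
    if not (f0_mhz > 0):
        raise ValueError(f"f0_mhz must be > 0, got {f0_mhz}")
    return Band(center_mhz=0.5 * n * f0_mhz, half_width_khz=half_width_khz)


def harmonic_band(
    order: int, f0_mhz: float, half_width_khz: float = DEFAULT_HALF_WIDTH_KHZ
) -> Band:
    """Band at ``order * f0`` for integer order >= 1."""
    return make_band(2 * order, f0_mhz, half_width_khz)


def ultraharmonic_band(
    k: int, f0_mhz: float, half_width_khz: float = DEFAULT_HALF_WIDTH_KHZ
) -> Band:
    """Band at ``(k + 0.5) * f0``; k=1 is the first ultra-harmonic 1.5 f0."""
    return make_band(2 * k + 1, f0_mhz, half_width_khz)


def broadband_band(
    f0_mhz: float, half_width_khz: float = DEFAULT_HALF_WIDTH_KHZ
) -> Band:
    """The broadband-emission bin at ``7.22 * f0`` (3.61 MHz for f0=0.5)."""
    if not (f0_mhz > 0):
        raise ValueError(f"f0_mhz must be > 0, got {f0_mhz}")
    return Band(center_mhz=BROADBAND_MULTIPLE * f0_mhz, half_width_khz=half_width_khz)


def standard_bands(
    f0_mhz: float, half_width_khz: float = DEFAULT_HALF_WIDTH_KHZ
) -> dict[str, Band]:
    """All 15 bands carried in an AEFrame, keyed by :data:`BAND_KEYS`."""
    bands: dict[str, Band] = {}
    for n in HARMONIC_ORDERS:
        bands[f"h{n}"] = harmonic_band(n, f0_mhz, half_width_khz)
    for k in ULTRAHARMONIC_ORDERS:
        bands[f"uh{k}"] = ultraharmonic_band(k, f0_mhz, half_width_khz)
    bands["bb"] = broadband_band(f0_mhz, half_width_khz)
    return bands


@dataclass(frozen=True)
class PulseSpectrum:
    """Power spectrum of one recorded pulse on a uniform frequency grid."""

    frequencies_mhz: np.ndarray
    power: np.ndarray
    pulse_index: int = 1

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies_mhz, dtype=float)
        p = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "frequencies_mhz", f)
        object.__setattr__(self, "power", p)
        if f.ndim != 1 or p.ndim != 1 or f.size != p.size or f.size < 2:
            raise ValueError("frequency grid and power must be equal-length 1-D")
        df = np.diff(f)
        if not np.all(df > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.allclose(df, df[0], rtol=1e-6, atol=0.0):
            raise ValueError("frequency grid must be uniform")
        if not np.all(np.isfinite(p)) or np.any(p < 0):
            raise ValueError("power must be finite and non-negative")
        if int(self.pulse_index) < 1:
            raise ValueError("pulse_index must be >= 1")

    @property
    def resolution_mhz(self) -> float:
        return float(self.frequencies_mhz[1] - self.frequencies_mhz[0])


def default_frequency_grid(
    record_length_ms: float = 11.0, f_max_mhz: float = 5.0
) -> np.ndarray:
    """Uniform grid with the resolution of an ``record_length_ms`` record.

    An 11 ms record gives ~0.0909 kHz bin spacing.
    """
    if record_length_ms <= 0 or f_max_mhz <= 0:
        raise ValueError("record_length_ms and f_max_mhz must be > 0")
    df_mhz = 1e-3 / record_length_ms  # 1/T in kHz -> MHz
    n = int(math.floor(f_max_mhz / df_mhz)) + 1
    return np.arange(n) * df_mhz


def _band_mask(spectrum: PulseSpectrum, band: Band) -> np.ndarray:
    f = spectrum.frequencies_mhz
    mask = (f >= band.lo_mhz) & (f <= band.hi_mhz)
    if not mask.any():
        raise BandOverlapError(
            f"band [{band.lo_mhz:.6f}, {band.hi_mhz:.6f}] MHz does not "
            f"overlap grid [{f[0]:.6f}, {f[-1]:.6f}] MHz "
            f"(resolution {spectrum.resolution_mhz:.6f} MHz)"
        )
    return mask


def band_level_db(
    spectrum: PulseSpectrum, band: Band, baseline_power: float
) -> float:
    """Mean in-band linear power relative to baseline, in dB.

    ``10 * log10(mean(power in band) / baseline_power)``.  The band
    statistic is the mean (not max) so results are stable under grid
    resolution changes.
    """
    if not (baseline_power > 0):
        raise ValueError(f"baseline_power must be > 0, got {baseline_power}")
    mask = _band_mask(spectrum, band)
    mean_power = float(spectrum.power[mask].mean())
    if mean_power <= 0.0:
        return -math.inf
    return 10.0 * math.log10(mean_power / baseline_power)


def detect_broadband(broadband_db: float) -> bool:
    """Event rule: True iff the broadband level is >= 6.0 dB above baseline.

    A tie at exactly 6.0 dB counts as an event.
    """
    if math.isnan(broadband_db):
        raise ValueError("broadband_db is NaN")
    return broadband_db >= EVENT_THRESHOLD_DB


@dataclass(frozen=True)
class AEFrame:
    """Calibrated per-pulse feature record.

    ``harmonic_db`` holds orders 2..8 of f0; ``ultraharmonic_db`` holds
    1.5 f0 .. 7.5 f0.  ``h4_db`` is the 4th-harmonic microbubble-tracking
    level used by the controller gate (from the low-pressure tracker pulse
    when one exists, otherwise the pulse's own 4th harmonic).  All levels
    are dB re per-band baseline.
    """

    pulse_index: int
    time_s: float
    pressure_mpa: float
    harmonic_db: tuple[float, ...]
    ultraharmonic_db: tuple[float, ...]
    h4_db: float
    broadband_db: float
    is_event: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "harmonic_db", tuple(float(v) for v in self.harmonic_db))
        object.__setattr__(
            self, "ultraharmonic_db", tuple(float(v) for v in self.ultraharmonic_db)
        )
        if len(self.harmonic_db) != 7:
            raise ValueError("harmonic_db must have exactly 7 entries (orders 2-8)")
        if len(self.ultraharmonic_db) != 7:
            raise ValueError("ultraharmonic_db must have exactly 7 entries (1.5-7.5 f0)")
        levels = self.harmonic_db + self.ultraharmonic_db + (self.h4_db, self.broadband_db)
        if not all(math.isfinite(v) for v in levels):
            raise ValueError("all levels must be finite")
        if self.is_event != (self.broadband_db >= EVENT_THRESHOLD_DB):
            raise ValueError(
                "is_event inconsistent with the 6 dB broadband rule: "
                f"broadband_db={self.broadband_db}, is_event={self.is_event}"
            )


def extract_frame(
    spectrum: PulseSpectrum,
    baselines: Mapping[str, float],
    f0_mhz: float,
    pressure_mpa: float,
    time_s: float = 0.0,
    half_width_khz: float = DEFAULT_HALF_WIDTH_KHZ,
) -> AEFrame:
    """Convert one pulse spectrum into an :class:`AEFrame`.

    ``baselines`` maps each of the 15 band keys (:data:`BAND_KEYS`) to its
    baseline linear power.
    """
    missing = [k for k in BAND_KEYS if k not in baselines]
    if missing:
        raise KeyError(f"missing baseline(s) for band(s): {missing}")
    bands = standard_bands(f0_mhz, half_width_khz)
    levels = {
        key: band_level_db(spectrum, bands[key], float(baselines[key]))
        for key in BAND_KEYS
    }
    harmonic = tuple(levels[f"h{n}"] for n in HARMONIC_ORDERS)
    ultra = tuple(levels[f"uh{k}"] for k in ULTRAHARMONIC_ORDERS)
    bb = levels["bb"]
    return AEFrame(
        pulse_index=int(spectrum.pulse_index),
        time_s=float(time_s),
        pressure_mpa=float(pressure_mpa),
        harmonic_db=harmonic,
        ultraharmonic_db=ultra,
        h4_db=levels["h4"],
        broadband_db=bb,
        is_event=detect_broadband(bb),
    )


def baselines_from_spectra(
    spectra: Sequence[PulseSpectrum],
    f0_mhz: float,
    half_width_khz: float = DEFAULT_HALF_WIDTH_KHZ,
) -> dict[str, float]:
    """Per-band median power over pre-microbubble pulses.

    Operationalises the "dB above baseline" reference: feed the pulses
    recorded before microbubble arrival (before the +10 dB H4 rise).
    """
    if len(spectra) == 0:
        raise ValueError("need at least one baseline spectrum")
    bands = standard_bands(f0_mhz, half_width_khz)
    out: dict[str, float] = {}
    for key in BAND_KEYS:
        powers = []
        for s in spectra:
            mask = _band_mask(s, bands[key])
            powers.append(float(s.power[mask].mean()))
        med = float(np.median(powers))
        if med <= 0:
            raise ValueError(f"non-positive baseline power for band {key}")
        out[key] = med
    return out
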