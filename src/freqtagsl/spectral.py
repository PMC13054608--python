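"""Amplitude spectra of 20-s EEG blocks and the neighbour-bin SNR spectrum.

A 20-s block sampled at 1000 Hz gives a frequency resolution of
fs/N = 0.05 Hz, so every tagged frequency (3, 6, 9, ... Hz) falls exactly
on a bin and a rectangular window is leakage-free for the signals of
interest.  The SNR at bin k is the amplitude at k divided by the mean
amplitude of the 10 surrounding bins (5 per side, excluding the 2 bins
immediately adjacent to k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .paradigm import InvalidInputError

#: sampling rate (Hz) and samples per analysed block
FS_HZ = 1000.0
N_SAMPLES = 20000
#: resulting bin spacing (Hz)
BIN_SPACING_HZ = FS_HZ / N_SAMPLES
#: neighbour offsets used for the SNR noise floor (±2..±6 bins)
NEIGHBOUR_OFFSETS = tuple(o for o in range(-6, 7) if abs(o) >= 2)


@dataclass(frozen=True)
class AmplitudeSpectrum:
    """One-sided amplitude spectrum, [channels x bins], spacing 0.05 Hz."""

    freqs: np.ndarray
    amp: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.amp.shape[0]

    def bin_of(self, freq_hz: float) -> int:
        spacing = self.freqs[1] - self.freqs[0]
        k = int(round(freq_hz / spacing))
        if not np.isclose(k * spacing, freq_hz, atol=1e-9):
            raise InvalidInputError(f"{freq_hz} Hz does not fall on a spectral bin")
        if not 0 <= k < self.freqs.size:
            raise InvalidInputError(f"{freq_hz} Hz outside the spectrum")
        return k


@dataclass(frozen=True)
class SNRSpectrum:
    """Neighbour-ratio SNR per channel and bin; edge bins are undefined."""

    freqs: np.ndarray
    snr: np.ndarray          # NaN where undefined
    valid: np.ndarray        # bool per bin: neighbourhood fully inside spectrum

    @property
    def n_channels(self) -> int:
        return self.snr.shape[0]

    def bin_of(self, freq_hz: float) -> int:
        return AmplitudeSpectrum.bin_of(self, freq_hz)  # type: ignore[arg-type]

    def snr_at(self, freq_hz: float) -> np.ndarray:
        """SNR of every channel at one tagged frequency."""
        k = self.bin_of(freq_hz)
        if not self.valid[k]:
            raise InvalidInputError(f"SNR undefined at {freq_hz} Hz (edge bin)")
        return self.snr[:, k]


def amplitude_spectrum(block) -> AmplitudeSpectrum:
    """FFT amplitude spectrum of a 20-s block.

    Per-channel mean is removed, a rectangular window is used, and the
    one-sided amplitude is 2|X_k|/N (DC and Nyquist not doubled).

    `block` is anything with `.data` [channels x 20000] and `.fs`; a bare
    array is treated as fs = 1000 Hz.
    """
    if hasattr(block, "fs"):
        data, fs = np.asarray(block.data, dtype=float), float(block.fs)
    else:
        data, fs = np.asarray(block, dtype=float), FS_HZ
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[-1] != N_SAMPLES or fs != FS_HZ:
        raise InvalidInputError(
            f"expected [channels x {N_SAMPLES}] at {FS_HZ:g} Hz, "
            f"got shape {data.shape} at {fs:g} Hz"
        )
    x = data - data.mean(axis=-1, keepdims=True)
    coef = np.fft.rfft(x, axis=-1)
    amp = 2.0 * np.abs(coef) / N_SAMPLES
    amp[:, 0] /= 2.0
    amp[:, -1] /= 2.0  # N even: last bin is Nyquist
    freqs = np.fft.rfftfreq(N_SAMPLES, d=1.0 / fs)
    return AmplitudeSpectrum(freqs=freqs, amp=amp)


def snr_spectrum(spec: AmplitudeSpectrum) -> SNRSpectrum:
    """Neighbour-bin SNR: amp[k] / mean(amp[k±2..k±6]).

    Bins whose neighbourhood exits the spectrum (first/last 6 bins) are
    masked undefined, as is any bin with a zero neighbourhood mean.
    """
    amp = np.asarray(spec.amp, dtype=float)
    if np.any(amp < 0):
        raise InvalidInputError("amplitudes must be non-negative")
    n_bins = amp.shape[1]
    margin = max(abs(o) for o in NEIGHBOUR_OFFSETS)
    noise = np.full_like(amp, np.nan)
    interior = slice(margin, n_bins - margin)
    acc = np.zeros_like(amp[:, interior])
    for o in NEIGHBOUR_OFFSETS:
        acc += amp[:, margin + o : n_bins - margin + o]
    noise[:, interior] = acc / len(NEIGHBOUR_OFFSETS)

    with np.errstate(divide="ignore", invalid="ignore"):
        snr = amp / noise
    snr[~np.isfinite(snr)] = np.nan

    valid = np.zeros(n_bins, dtype=bool)
    valid[interior] = True
    return SNRSpectrum(freqs=spec.freqs, snr=snr, valid=valid)
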