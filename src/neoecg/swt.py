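"""Undecimated (stationary) wavelet transform via the "algorithme à trous".

The transform passes the signal through the Daubechies analysis filter pair
at every level without decimation, upsampling the filters by 2**(level-1)
("holes") instead.  All coefficient arrays therefore keep the full signal
length, which makes the transform translation-invariant — the property that
motivates its use over the decimated DWT for ECG work, where beat morphology
must not depend on where a block boundary falls.

Conventions
-----------
* Analysis is circular correlation with the orthonormal db8 filter taps
  (taken from PyWavelets); synthesis is circular convolution with the same
  taps, averaging the redundant low-pass/high-pass branches.  With
  orthonormal filters |H|^2 + |G|^2 = 2, so the round trip is exact to
  floating-point precision for any signal length.
* ``periodic`` boundary mode wraps the signal; it is the default because it
  makes circular-shift invariance exact.  ``symmetric`` mode reflects the
  signal into a margin wide enough to cover the deepest filter support,
  runs the periodic transform on the extended signal, and exposes the
  central ``n`` samples of every coefficient array; the margins are kept on
  the coefficient object so reconstruction stays exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

__all__ = [
    "WaveletConfig",
    "WaveletCoefficients",
    "swt_decompose",
    "swt_reconstruct",
    "energy_distribution",
]

BOUNDARY_MODES = ("periodic", "symmetric")


@dataclass(frozen=True)
class WaveletConfig:
    """Mother wavelet, decomposition depth and boundary handling."""

    wavelet_name: str = "db8"
    levels: int = 5
    boundary_mode: str = "periodic"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError(f"levels must be >= 1, got {self.levels}")
        if self.boundary_mode not in BOUNDARY_MODES:
            raise ValueError(
                f"boundary_mode must be one of {BOUNDARY_MODES}, "
                f"got {self.boundary_mode!r}"
            )
        try:
            pywt.Wavelet(self.wavelet_name)
        except ValueError as exc:
            raise ValueError(f"unknown wavelet {self.wavelet_name!r}") from exc

    @property
    def filters(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal (low-pass, high-pass) analysis taps."""
        w = pywt.Wavelet(self.wavelet_name)
        return np.asarray(w.dec_lo, dtype=float), np.asarray(w.dec_hi, dtype=float)


@dataclass
class WaveletCoefficients:
    """Full-length à trous coefficients: details cD_1..cD_k plus cA_k.

    Internally the arrays may carry a symmetric-extension margin of
    ``margin`` samples on each side (zero in periodic mode); the public
    ``details`` / ``approximation`` views expose exactly ``n`` samples.
    In-place edits through the views propagate to the stored arrays.
    """

    _details_ext: list[np.ndarray]
    _approx_ext: np.ndarray
    config: WaveletConfig
    n: int
    margin: int = 0
    _baseline_correction: np.ndarray | None = field(default=None, repr=False)

    @property
    def levels(self) -> int:
        return len(self._details_ext)

    @property
    def details(self) -> list[np.ndarray]:
        m = self.margin
        return [d[m : m + self.n] for d in self._details_ext]

    @property
    def approximation(self) -> np.ndarray:
        return self._approx_ext[self.margin : self.margin + self.n]

    def copy(self) -> "WaveletCoefficients":
        return WaveletCoefficients(
            [d.copy() for d in self._details_ext],
            self._approx_ext.copy(),
            self.config,
            self.n,
            self.margin,
        )

    def validate(self) -> None:
        n_ext = self.n + 2 * self.margin
        if self._approx_ext.shape != (n_ext,):
            raise ValueError("approximation length inconsistent with n/margin")
        for i, d in enumerate(self._details_ext):
            if d.shape != (n_ext,):
                raise ValueError(f"detail level {i + 1} length inconsistent")
        if self.levels != self.config.levels:
            raise ValueError("level count does not match config.levels")


def _validate_signal(x: np.ndarray, levels: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError(f"expected a 1-D signal, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    if x.size < 2**levels:
        raise ValueError(
            f"signal length {x.size} too short for {levels} levels "
            f"(need at least {2**levels} samples)"
        )
    return x


def _analysis_step(a: np.ndarray, h: np.ndarray, g: np.ndarray, step: int):
    """One à trous level: circular correlation with the upsampled filters."""
    n = a.size
    idx = (np.arange(n)[:, None] + step * np.arange(h.size)[None, :]) % n
    taps = a[idx]
    return taps @ g, taps @ h  # detail, next approximation


def _synthesis_step(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray, step: int):
    """Inverse level: circular convolution, averaging the two branches."""
    n = a.size
    idx = (np.arange(n)[:, None] - step * np.arange(h.size)[None, :]) % n
    return 0.5 * (a[idx] @ h + d[idx] @ g)


def _periodic_decompose(x: np.ndarray, config: WaveletConfig):
    h, g = config.filters
    a = x
    details = []
    for i in range(config.levels):
        d, a = _analysis_step(a, h, g, 2**i)
        details.append(d)
    return details, a


def swt_decompose(signal, config: WaveletConfig = WaveletConfig()) -> WaveletCoefficients:
    """Decompose ``signal`` into full-length detail and approximation arrays.

    Raises
    ------
    ValueError
        If the signal is shorter than ``2**config.levels`` or contains
        non-finite samples.
    """
    x = _validate_signal(signal, config.levels)
    n = x.size
    if config.boundary_mode == "periodic":
        details, approx = _periodic_decompose(x, config)
        return WaveletCoefficients(details, approx, config, n)
    # symmetric: reflect into a margin covering the deepest filter support
    filt_len = config.filters[0].size
    margin = (filt_len - 1) * (2**config.levels - 1)
    x_ext = np.pad(x, margin, mode="symmetric")
    details, approx = _periodic_decompose(x_ext, config)
    return WaveletCoefficients(details, approx, config, n, margin=margin)


def swt_reconstruct(coeffs: WaveletCoefficients) -> np.ndarray:
    """Invert :func:`swt_decompose`; linear in the coefficient arrays."""
    coeffs.validate()
    h, g = coeffs.config.filters
    a = coeffs._approx_ext
    for i in reversed(range(coeffs.levels)):
        a = _synthesis_step(a, coeffs._details_ext[i], h, g, 2**i)
    return a[coeffs.margin : coeffs.margin + coeffs.n].copy()


def energy_distribution(coeffs: WaveletCoefficients, fs: float):
    """Per-level energy shares and nominal dyadic frequency bands.

    Returns a list of dicts, one per detail level plus one for the
    approximation, with keys ``level`` (1..k or "approximation"),
    ``energy_percent`` and ``band_hz`` = (low, high).  Level ``i`` details
    nominally occupy [fs/2**(i+1), fs/2**i]; the approximation occupies
    [0, fs/2**(k+1)].  The analysis filters are not ideal brick-walls, so
    the bands are labels rather than guarantees.

    Raises
    ------
    ValueError
        If the total coefficient energy is zero (degenerate input).
    """
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    energies = [float(np.sum(d**2)) for d in coeffs.details]
    energies.append(float(np.sum(coeffs.approximation ** 2)))
    total = sum(energies)
    if total <= 0:
        raise ValueError("zero-energy coefficients: energy shares undefined")
    k = coeffs.levels
    out = []
    for i, e in enumerate(energies[:-1], start=1):
        out.append(
            {
                "level": i,
                "energy_percent": 100.0 * e / total,
                "band_hz": (fs / 2 ** (i + 1), fs / 2**i),
            }
        )
    out.append(
        {
            "level": "approximation",
            "energy_percent": 100.0 * energies[-1] / total,
            "band_hz": (0.0, fs / 2 ** (k + 1)),
        }
    )
    return out
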