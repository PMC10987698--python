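"""Acquisition protocol for the diffusion-weighted STEAM experiment.

The protocol fixes the diffusion dimension (b-values and how many single
shots are acquired at each) and the spectral grid (width, number of complex
points, field strength). All downstream stages — the simulator, the shot
preprocessing and the spectral fit — share one protocol instance so that
time/frequency/ppm axes are defined in exactly one place.
"""

from __future__ import annotations

from functools import cached_property

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator


class AcquisitionProtocol(BaseModel):
    """Diffusion-weighted spectroscopy acquisition parameters.

    Parameters
    ----------
    b_values
        Diffusion weightings in ms/μm², strictly ascending.
    shots_per_b
        Number of single-shot acquisitions at each b-value.
    delta
        Diffusion gradient duration δ in ms.
    big_delta
        Diffusion time Δ in ms.
    spectral_width
        Acquisition bandwidth in Hz.
    n_points
        Number of complex points per shot.
    te, tm
        Echo and mixing time of the STEAM sequence in ms (bookkeeping only;
        no relaxation is modelled).
    field_mhz
        Proton Larmor frequency in MHz (9.4 T → ≈400.2 MHz); converts ppm
        offsets to Hz.
    carrier_ppm
        Chemical shift of the transmitter/carrier (water, 4.7 ppm).
    """

    model_config = ConfigDict(frozen=True)

    b_values: tuple[float, ...]
    shots_per_b: tuple[int, ...]
    delta: float = 6.0
    big_delta: float = 120.0
    spectral_width: float = 5000.0
    n_points: int = 4096
    te: float = 15.0
    tm: float = 112.0
    field_mhz: float = 400.2
    carrier_ppm: float = 4.7

    @model_validator(mode="after")
    def _check(self) -> "AcquisitionProtocol":
        b = np.asarray(self.b_values, dtype=float)
        if b.size == 0:
            raise ValueError("b_values must be non-empty")
        if np.any(b < 0):
            raise ValueError("b_values must be non-negative")
        if b.size > 1 and np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly ascending")
        if len(self.shots_per_b) != len(self.b_values):
            raise ValueError("shots_per_b must match b_values in length")
        if any(s <= 0 for s in self.shots_per_b):
            raise ValueError("shots_per_b must be positive")
        for name in ("delta", "big_delta", "spectral_width", "field_mhz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_points < 8:
            raise ValueError("n_points must be >= 8")
        return self

    # -- derived axes -----------------------------------------------------

    @property
    def dwell(self) -> float:
        """Sampling interval in seconds."""
        return 1.0 / self.spectral_width

    @cached_property
    def time_axis(self) -> np.ndarray:
        """FID time axis in seconds, length ``n_points``."""
        return np.arange(self.n_points) * self.dwell

    @cached_property
    def freq_axis(self) -> np.ndarray:
        """Frequency axis in Hz relative to the carrier, fftshifted/ascending."""
        return np.fft.fftshift(np.fft.fftfreq(self.n_points, d=self.dwell))

    @cached_property
    def ppm_axis(self) -> np.ndarray:
        """Chemical-shift axis in ppm, ascending with frequency."""
        return self.carrier_ppm + self.freq_axis / self.field_mhz

    @property
    def hz_per_point(self) -> float:
        return self.spectral_width / self.n_points

    @property
    def b_min(self) -> float:
        return self.b_values[0]

    def ppm_slice(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask selecting ppm ∈ [lo, hi]."""
        ppm = self.ppm_axis
        return (ppm >= lo) & (ppm <= hi)


#: The in vivo protocol used throughout: nine b-values (ms/μm²) with the
#: number of shots rising at high b to compensate for signal attenuation.
DEFAULT_PROTOCOL = AcquisitionProtocol(
    b_values=(0.4, 1.5, 6.0, 7.6, 9.3, 13.3, 15.6, 20.8, 25.1),
    shots_per_b=(160, 160, 160, 160, 160, 320, 480, 480, 480),
)
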