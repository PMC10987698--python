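"""Simplified metabolite basis set.

Each metabolite is represented by one to three Lorentzian resonances at
fixed chemical shifts with fixed relative areas (in proton-count units), a
deliberately transparent stand-in for a quantum-mechanically simulated
basis: sufficient for exercising a linear-combination fitting chain, not
for modelling J-evolution. A broad macromolecule background is built the
same way from wide Lorentzian humps.

Unit-concentration normalization: the basis FID for metabolite *m* at
concentration 1 (mM-equivalent) is ``sum_k area_k * exp(2πi f_k t - t/T2)``
with ``area_k`` the proton count of line *k*; signal areas therefore scale
linearly with concentration and with proton count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocol import AcquisitionProtocol

# name -> ((ppm, relative area in proton units), ...); 1-3 lines each.
CATALOGUE: dict[str, tuple[tuple[float, float], ...]] = {
    "NAA": ((2.01, 3.0), (2.58, 1.0)),
    "tCr": ((3.03, 3.0), (3.93, 2.0)),
    "tCho": ((3.21, 9.0), (3.54, 2.0)),
    "Ins": ((3.52, 4.0), (3.61, 2.0), (4.06, 1.0)),
    "Gln": ((2.45, 2.0), (2.14, 2.0), (3.77, 1.0)),
    "Glu": ((2.35, 2.0), (2.05, 2.0), (3.75, 1.0)),
    "Tau": ((3.25, 2.0), (3.42, 2.0)),
    "Lac": ((1.31, 3.0), (4.10, 1.0)),
    "GABA": ((1.89, 2.0), (2.28, 2.0), (3.01, 2.0)),
    "GSH": ((2.93, 2.0), (2.55, 2.0), (4.56, 1.0)),
    "Glc": ((3.43, 1.0), (3.80, 2.0), (5.22, 1.0)),
    "Ala": ((1.47, 3.0), (3.78, 1.0)),
    "Scyllo": ((3.35, 6.0),),
    "PE": ((3.22, 2.0), (3.98, 2.0)),
}

#: Reported metabolites that survive the strict diffusion-series CRLB filter.
REPORTED_METABOLITES = ("Gln", "Glu", "Ins", "Tau", "NAA", "tCr", "tCho")

# Macromolecule background: (ppm, area, linewidth Hz). Broad humps spanning
# the aliphatic-to-methine region, scaled to sit well below the major
# metabolite singlets at unit mm_scale.
MM_LINES: tuple[tuple[float, float, float], ...] = (
    (0.91, 5.0, 40.0),
    (1.21, 7.0, 45.0),
    (1.40, 5.0, 45.0),
    (1.65, 3.0, 50.0),
    (2.05, 7.0, 55.0),
    (2.29, 4.0, 60.0),
    (3.00, 5.0, 60.0),
    (3.21, 3.0, 60.0),
    (3.75, 5.0, 70.0),
)


def lorentzian_fid(
    protocol: AcquisitionProtocol,
    lines: tuple[tuple[float, float], ...],
    linewidth: float,
) -> np.ndarray:
    """Time-domain signal of a sum of Lorentzian lines.

    ``linewidth`` is the full width at half maximum in Hz; the FID decay
    rate is π·FWHM.
    """
    if linewidth <= 0:
        raise ValueError("linewidth must be > 0")
    t = protocol.time_axis
    decay = np.exp(-np.pi * linewidth * t)
    fid = np.zeros(protocol.n_points, dtype=complex)
    for ppm, area in lines:
        f_hz = (ppm - protocol.carrier_ppm) * protocol.field_mhz
        fid += area * np.exp(2j * np.pi * f_hz * t)
    return fid * decay


def fid_to_spectrum(fid: np.ndarray) -> np.ndarray:
    """FFT with the zero-frequency bin moved to the centre (ascending ppm)."""
    return np.fft.fftshift(np.fft.fft(fid, axis=-1), axes=-1)


def spectrum_to_fid(spectrum: np.ndarray) -> np.ndarray:
    return np.fft.ifft(np.fft.ifftshift(spectrum, axes=-1), axis=-1)


@dataclass(frozen=True)
class BasisSet:
    """Unit-concentration reference spectra on the protocol grid."""

    protocol: AcquisitionProtocol
    linewidth: float
    spectra: dict[str, np.ndarray]  # metabolite -> complex spectrum
    fids: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    mm_spectrum: np.ndarray | None = None
    mm_fid: np.ndarray | None = field(repr=False, default=None)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.spectra)

    def reference_spectrum(self) -> np.ndarray:
        """Sum of all unit-concentration spectra plus the macromolecule
        background — used as an alignment target for frequency registration."""
        total = sum(self.spectra.values()) + (
            self.mm_spectrum if self.mm_spectrum is not None else 0.0
        )
        return np.asarray(total)


def make_basis(
    metabolites: list[str] | tuple[str, ...],
    protocol: AcquisitionProtocol,
    linewidth: float = 6.0,
    include_mm: bool = True,
) -> BasisSet:
    """Build the simplified Lorentzian basis for the given metabolites.

    Raises
    ------
    ValueError
        If a metabolite name is not in the catalogue; the message lists the
        supported names.
    """
    unknown = [m for m in metabolites if m not in CATALOGUE]
    if unknown:
        raise ValueError(
            f"unknown metabolite(s) {unknown}; supported: {sorted(CATALOGUE)}"
        )
    if len(set(metabolites)) != len(metabolites):
        raise ValueError("duplicate metabolite names")
    fids = {m: lorentzian_fid(protocol, CATALOGUE[m], linewidth) for m in metabolites}
    spectra = {m: fid_to_spectrum(f) for m, f in fids.items()}
    mm_fid = None
    mm_spectrum = None
    if include_mm:
        mm_fid = np.zeros(protocol.n_points, dtype=complex)
        for ppm, area, lw in MM_LINES:
            mm_fid += lorentzian_fid(protocol, ((ppm, area),), lw)
        mm_spectrum = fid_to_spectrum(mm_fid)
    return BasisSet(
        protocol=protocol,
        linewidth=linewidth,
        spectra=spectra,
        fids=fids,
        mm_spectrum=mm_spectrum,
        mm_fid=mm_fid,
    )
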