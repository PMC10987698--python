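"""Synthetic shot-level diffusion-weighted spectra with known ground truth.

The generator emulates the measurement chain of a paired longitudinal
rodent study: for each animal and timepoint (pre-surgery "week0", diseased
"week6"), single-shot spectra are built at every b-value as the sum of
metabolite basis signals attenuated by the randomly-oriented-sticks model,
a broad macromolecule background, shot-to-shot phase/frequency drift and
amplitude-dropout artifacts, and complex Gaussian time-domain noise.

The default effect configuration encodes the disease contrast of chronic
hepatic encephalopathy at week 6: a ×2.78 glutamine concentration increase
(+178%), a −29% myo-inositol decrease, and a ×1.58 increase of glutamine
intra-stick diffusivity, with the remaining metabolites carrying milder
trends. Week-0 diffusivities are chosen so that the cumulant fit over the
acquired b-grid yields apparent diffusion coefficients near 0.11 μm²/ms,
typical of the healthy rodent brain; the ×1.58 glutamine diffusivity effect
then propagates to a ≈+35% ADC change through the restricted-range
cumulant fit.

Animal-level variability is log-normal and mean-preserving, both on the
week-0 baselines and on the week-6/week-0 effect ratios, with coefficients
of variation set to roughly reproduce the reported across-animal spreads of
the percent changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .basis import BasisSet, fid_to_spectrum, make_basis
from .diffusion import sticks_attenuation
from .protocol import DEFAULT_PROTOCOL, AcquisitionProtocol

WEEKS = ("week0", "week6")
SIGNAL_WINDOW = (0.5, 4.2)  # ppm, metabolite region
NOISE_WINDOW = (7.0, 10.0)  # ppm, signal-free region


class MetaboliteTruth(BaseModel):
    """Ground truth for one metabolite: week-0 values and week-6 effects."""

    model_config = ConfigDict(frozen=True)

    conc: float  # mM-equivalent, week 0
    d_intra: float  # μm²/ms, week 0
    conc_ratio: float = 1.0  # week6 / week0
    d_ratio: float = 1.0
    conc_ratio_cv: float = 0.0  # per-animal lognormal CV of the effect
    d_ratio_cv: float = 0.0

    @model_validator(mode="after")
    def _check(self):
        if self.conc <= 0 or self.conc_ratio <= 0:
            raise ValueError("concentrations must be > 0")
        if not (0 < self.d_intra <= 3) or not (0 < self.d_intra * self.d_ratio <= 3):
            raise ValueError("d_intra must lie in (0, 3] at both timepoints")
        if self.conc_ratio_cv < 0 or self.d_ratio_cv < 0:
            raise ValueError("CVs must be >= 0")
        return self


class GroundTruth(BaseModel):
    """Cohort-level generator configuration."""

    model_config = ConfigDict(frozen=True)

    metabolites: dict[str, MetaboliteTruth]
    mm_scale: float = 1.0
    mm_attenuates: bool = False  # macromolecule diffusion not modelled by default
    mm_d: float = 0.005  # μm²/ms, used only if mm_attenuates
    conc_cv: float = 0.08  # animal-level baseline CV (week 0)
    d_cv: float = 0.06
    linewidth: float = 6.0  # Hz
    # Spectral SNR target (max real peak / noise SD) at the lowest b after
    # shot averaging. Note the LCModel convention divides the peak by twice
    # the RMS noise, so 60 here corresponds to an LCModel-style SNR of ~30,
    # the middle of the 15-45 range typical of in vivo diffusion spectra.
    target_snr: float = 60.0
    noise_sd: float | None = None  # per-shot time-domain SD; overrides target_snr
    phase_drift: float = 0.002  # rad/shot, cumulative
    freq_drift: float = 0.02  # Hz/shot, cumulative
    dropout_p: float = 0.01
    dropout_depth: float = 0.7
    seed: int = Field(..., description="root seed; all randomness flows from it")

    @model_validator(mode="after")
    def _check(self):
        if not self.metabolites:
            raise ValueError("at least one metabolite required")
        if not (0 <= self.dropout_p <= 1):
            raise ValueError("dropout_p must be a probability")
        if not (0 <= self.dropout_depth <= 1):
            raise ValueError("dropout_depth must lie in [0, 1]")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.target_snr <= 0:
            raise ValueError("target_snr must be > 0")
        return self


def default_truth(seed: int = 0, **overrides) -> GroundTruth:
    """The paired-cohort study configuration (week-6 disease effects)."""
    metabolites = {
        "Gln": MetaboliteTruth(conc=4.0, d_intra=0.40, conc_ratio=2.78,
                               d_ratio=1.58, conc_ratio_cv=0.34, d_ratio_cv=0.10),
        "Glu": MetaboliteTruth(conc=9.0, d_intra=0.42, conc_ratio=0.95,
                               d_ratio=1.15, conc_ratio_cv=0.08, d_ratio_cv=0.10),
        "Ins": MetaboliteTruth(conc=5.8, d_intra=0.38, conc_ratio=0.71,
                               d_ratio=1.45, conc_ratio_cv=0.197, d_ratio_cv=0.15),
        "Tau": MetaboliteTruth(conc=6.0, d_intra=0.40, conc_ratio=0.92,
                               d_ratio=1.26, conc_ratio_cv=0.10, d_ratio_cv=0.15),
        "NAA": MetaboliteTruth(conc=8.5, d_intra=0.38, conc_ratio=1.00,
                               d_ratio=1.10, conc_ratio_cv=0.08, d_ratio_cv=0.10),
        "tCr": MetaboliteTruth(conc=8.0, d_intra=0.41, conc_ratio=0.97,
                               d_ratio=1.12, conc_ratio_cv=0.08, d_ratio_cv=0.10),
        "tCho": MetaboliteTruth(conc=1.4, d_intra=0.37, conc_ratio=0.92,
                                d_ratio=1.32, conc_ratio_cv=0.10, d_ratio_cv=0.15),
    }
    return GroundTruth(metabolites=metabolites, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# artifacts


@dataclass(frozen=True)
class ArtifactRecord:
    """What was injected per shot (ground truth for the corrector)."""

    phase: np.ndarray  # rad, cumulative offset applied to each shot
    freq: np.ndarray  # Hz
    dropped: np.ndarray  # bool, amplitude-dropout flag


def inject_artifacts(
    fids: np.ndarray,
    protocol: AcquisitionProtocol,
    phase_drift: float,
    freq_drift: float,
    dropout_p: float,
    dropout_depth: float,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, ArtifactRecord]:
    """Apply cumulative phase/frequency drift and Bernoulli amplitude
    dropouts to a stack of time-domain shots (n_shots, n_points).

    Shot *k* is modulated by exp(i·(2π·k·freq_drift·t + k·phase_drift));
    dropped shots are scaled by (1 − dropout_depth).
    """
    if not (0 <= dropout_p <= 1):
        raise ValueError("dropout_p must be a probability")
    if not (0 <= dropout_depth <= 1):
        raise ValueError("dropout_depth must lie in [0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    fids = np.atleast_2d(np.asarray(fids, dtype=complex))
    n_shots = fids.shape[0]
    k = np.arange(n_shots)
    phase = k * phase_drift
    freq = k * freq_drift
    t = protocol.time_axis
    mod = np.exp(1j * (2.0 * np.pi * freq[:, None] * t[None, :] + phase[:, None]))
    out = fids * mod
    dropped = rng.random(n_shots) < dropout_p
    out[dropped] *= 1.0 - dropout_depth
    return out, ArtifactRecord(phase=phase, freq=freq, dropped=dropped)


# ---------------------------------------------------------------------------
# noise calibration


def measure_snr(
    spectrum: np.ndarray,
    protocol: AcquisitionProtocol,
    signal_window: tuple[float, float] = SIGNAL_WINDOW,
    noise_window: tuple[float, float] = NOISE_WINDOW,
) -> float:
    """Spectral SNR: maximum of the real part in the metabolite window over
    the SD of the (detrended) real part in a signal-free window."""
    sig = np.max(spectrum.real[protocol.ppm_slice(*signal_window)])
    noise_region = spectrum.real[protocol.ppm_slice(*noise_window)]
    noise = np.std(np.diff(noise_region)) / np.sqrt(2.0)
    return float(sig / noise)


def noiseless_spectrum(
    basis: BasisSet,
    concs: dict[str, float],
    d_intra: dict[str, float],
    b: float,
    mm_scale: float,
    mm_attenuates: bool = False,
    mm_d: float = 0.005,
) -> np.ndarray:
    """Expected averaged spectrum at one b-value (no noise, no artifacts)."""
    spec = np.zeros(basis.protocol.n_points, dtype=complex)
    for m, c in concs.items():
        spec += c * sticks_attenuation(b, d_intra[m]) * basis.spectra[m]
    if basis.mm_spectrum is not None and mm_scale != 0:
        att = sticks_attenuation(b, mm_d) if mm_attenuates else 1.0
        spec += mm_scale * att * basis.mm_spectrum
    return spec


def noise_sd_for_target_snr(
    protocol: AcquisitionProtocol, basis: BasisSet, truth: GroundTruth
) -> float:
    """Per-shot time-domain noise SD giving ``target_snr`` at the lowest
    b-value after averaging its full complement of shots.

    An unnormalized FFT of i.i.d. complex noise with per-component SD σ_t
    has per-bin real-part SD σ_t·√n_points; averaging N shots divides by √N.
    """
    concs = {m: t.conc for m, t in truth.metabolites.items()}
    d = {m: t.d_intra for m, t in truth.metabolites.items()}
    spec0 = noiseless_spectrum(
        basis, concs, d, protocol.b_min, truth.mm_scale, truth.mm_attenuates, truth.mm_d
    )
    peak = np.max(spec0.real[protocol.ppm_slice(*SIGNAL_WINDOW)])
    sigma_avg = peak / truth.target_snr
    n_shots = protocol.shots_per_b[0]
    return float(sigma_avg * np.sqrt(n_shots) / np.sqrt(protocol.n_points))


# ---------------------------------------------------------------------------
# cohort generation


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Mean-preserving multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=size))


@dataclass(frozen=True)
class ShotSet:
    """All shots of one animal/timepoint: b-value -> (n_shots, n_points)
    complex spectra plus the injected-artifact ground truth."""

    animal: str
    week: str
    spectra: dict[float, np.ndarray]
    artifacts: dict[float, ArtifactRecord]


class CohortDataset:
    """Paired two-timepoint cohort with lazily generated shots.

    Animal-level truth (concentrations and diffusivities per timepoint) is
    drawn eagerly at construction and exposed as :attr:`truth_table`; the
    heavy shot-level data are generated deterministically on demand per
    (animal, week) from seeds derived from the root seed, so a full cohort
    never has to be held in memory at once.
    """

    def __init__(
        self,
        protocol: AcquisitionProtocol,
        truth: GroundTruth,
        n_animals: int,
        seed: int | None = None,
    ):
        if n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        self.protocol = protocol
        self.truth = truth
        self.n_animals = n_animals
        self.seed = int(truth.seed if seed is None else seed)
        self.animals = tuple(f"rat{i + 1:02d}" for i in range(n_animals))
        self.basis = make_basis(list(truth.metabolites), protocol, truth.linewidth)
        if truth.noise_sd is not None:
            self.noise_sd = float(truth.noise_sd)
        else:
            self.noise_sd = noise_sd_for_target_snr(protocol, self.basis, truth)

        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0]))
        rows = []
        for animal in self.animals:
            for m, t in truth.metabolites.items():
                conc0 = t.conc * _lognormal_factor(rng, truth.conc_cv)
                d0 = t.d_intra * _lognormal_factor(rng, truth.d_cv)
                conc_ratio = t.conc_ratio * _lognormal_factor(rng, t.conc_ratio_cv)
                d_ratio = t.d_ratio * _lognormal_factor(rng, t.d_ratio_cv)
                d6 = min(d0 * d_ratio, 3.0)
                rows.append((animal, "week0", m, conc0, d0))
                rows.append((animal, "week6", m, conc0 * conc_ratio, d6))
        self.truth_table = pd.DataFrame(
            rows, columns=["animal", "week", "metabolite", "conc", "d_intra"]
        )

    def _animal_truth(self, animal: str, week: str) -> tuple[dict, dict]:
        sub = self.truth_table.query("animal == @animal and week == @week")
        if sub.empty:
            raise KeyError(f"no such animal/week: {animal}/{week}")
        concs = dict(zip(sub["metabolite"], sub["conc"]))
        d = dict(zip(sub["metabolite"], sub["d_intra"]))
        return concs, d

    def shots(self, animal: str, week: str) -> ShotSet:
        """Generate (deterministically) all shots for one animal/timepoint."""
        concs, d = self._animal_truth(animal, week)
        a_idx = self.animals.index(animal)
        w_idx = WEEKS.index(week)
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 1, a_idx, w_idx])
        )
        tr = self.truth
        base_fids = {}
        for b in self.protocol.b_values:
            fid = np.zeros(self.protocol.n_points, dtype=complex)
            for m, c in concs.items():
                fid += c * sticks_attenuation(b, d[m]) * self.basis.fids[m]
            if self.basis.mm_fid is not None and tr.mm_scale != 0:
                att = sticks_attenuation(b, tr.mm_d) if tr.mm_attenuates else 1.0
                fid += tr.mm_scale * att * self.basis.mm_fid
            base_fids[b] = fid
        spectra: dict[float, np.ndarray] = {}
        artifacts: dict[float, ArtifactRecord] = {}
        for b, n_shots in zip(self.protocol.b_values, self.protocol.shots_per_b):
            fids = np.broadcast_to(
                base_fids[b], (n_shots, self.protocol.n_points)
            ).copy()
            fids, record = inject_artifacts(
                fids, self.protocol, tr.phase_drift, tr.freq_drift,
                tr.dropout_p, tr.dropout_depth, rng,
            )
            if self.noise_sd > 0:
                noise = rng.standard_normal((n_shots, self.protocol.n_points, 2))
                fids += self.noise_sd * (noise[..., 0] + 1j * noise[..., 1])
            spectra[b] = fid_to_spectrum(fids)
            artifacts[b] = record
        return ShotSet(animal=animal, week=week, spectra=spectra, artifacts=artifacts)

    def noiseless_average(self, animal: str, week: str, b: float) -> np.ndarray:
        """Artifact- and noise-free expected spectrum for reference."""
        concs, d = self._animal_truth(animal, week)
        return noiseless_spectrum(
            self.basis, concs, d, b, self.truth.mm_scale,
            self.truth.mm_attenuates, self.truth.mm_d,
        )


def simulate_cohort(
    protocol: AcquisitionProtocol = DEFAULT_PROTOCOL,
    truth: GroundTruth | None = None,
    n_animals: int = 5,
    seed: int = 0,
) -> CohortDataset:
    """Build a paired two-timepoint cohort dataset with known ground truth."""
    if truth is None:
        truth = default_truth(seed=seed)
    return CohortDataset(protocol, truth, n_animals, seed=seed)
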