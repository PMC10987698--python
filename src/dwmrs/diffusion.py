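"""Microstructure models for metabolite diffusion decays.

Two descriptions of the powder-averaged signal attenuation S(b)/S(0) are
fitted to normalized metabolite decay curves:

* randomly oriented sticks: metabolites diffuse freely with diffusivity
  ``d_intra`` along one-dimensional segments (neurites, astrocytic
  processes) whose orientations are isotropically distributed. The
  orientation average gives

      S/S0 = sqrt(π / (4 b d_intra)) · erf( sqrt(b d_intra) ),

* the cumulant expansion truncated at second order,

      ln(S/S0) = −b D + (1/6) (b D)² K,

  giving the apparent diffusion coefficient D and apparent kurtosis K.

The cumulant series for the sticks signal converges only up to a critical
b-value set by the first zero of the error function in the complex plane:
b_c = |z₁|²/D with |z₁|² ≈ 5.6422, so the kurtosis fit is restricted to
b ≤ b_c (19 ms/μm² for an assumed D of 0.3 μm²/ms). In the b→0 limit of
sticks data the cumulant parameters tend to D = d_intra/3 and K = 12/5.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import erf

__all__ = [
    "sticks_attenuation",
    "radius_of_convergence",
    "erf_first_complex_zero",
    "diffusion_length",
    "DecayCurve",
    "SticksFit",
    "CumulantFit",
    "GroupFit",
    "build_decay",
    "fit_sticks",
    "fit_cumulant",
    "fit_group",
]

D_INTRA_BOUNDS = (1e-4, 3.0)
ADC_BOUNDS = (1e-4, 3.0)
KURTOSIS_BOUNDS = (-1.0, 10.0)


def sticks_attenuation(b, d_intra):
    """Powder-averaged signal fraction of randomly oriented sticks.

    Parameters are the b-value (ms/μm², scalar or array) and the
    intra-stick diffusivity (μm²/ms). Evaluated through a series expansion
    for b·d < 1e-6 so the b → 0 limit is exactly 1 with no 0/0.
    """
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    if not np.all(np.asarray(d_intra) > 0):
        raise ValueError("d_intra must be > 0")
    bd = b * d_intra
    out = np.empty_like(bd)
    small = bd < 1e-6
    # sqrt(pi/(4x))·erf(sqrt x) = Σ_k (-x)^k / (k! (2k+1))
    x = bd[small]
    out[small] = 1.0 - x / 3.0 + x**2 / 10.0
    x = bd[~small]
    out[~small] = np.sqrt(np.pi / (4.0 * x)) * erf(np.sqrt(x))
    if out.ndim == 0:
        return float(out)
    return out


@lru_cache(maxsize=1)
def erf_first_complex_zero() -> complex:
    """First zero of erf in the upper-right complex quadrant, by Newton
    iteration (erf'(z) = 2/√π · exp(−z²))."""
    z = 1.45 + 1.88j
    for _ in range(60):
        step = erf(z) / (2.0 / np.sqrt(np.pi) * np.exp(-z * z))
        z = z - step
        if abs(step) < 1e-15:
            break
    assert abs(erf(z)) < 1e-12
    return complex(z)


def radius_of_convergence(d_assumed: float) -> float:
    """Largest b (ms/μm²) at which the cumulant series of the powder-averaged
    sticks signal converges, for an assumed diffusivity (μm²/ms)."""
    if d_assumed <= 0:
        raise ValueError("d_assumed must be > 0")
    z1 = erf_first_complex_zero()
    return abs(z1) ** 2 / d_assumed


def diffusion_length(d: float, big_delta: float) -> float:
    """Characteristic 2D diffusion length sqrt(4·D·Δ) in μm
    (D in μm²/ms, Δ in ms)."""
    if d < 0:
        raise ValueError("d must be >= 0")
    if big_delta <= 0:
        raise ValueError("big_delta must be > 0")
    return float(np.sqrt(4.0 * d * big_delta))


# ---------------------------------------------------------------------------
# decay curves


@dataclass(frozen=True)
class DecayCurve:
    """Normalized metabolite signal decay versus b-value."""

    metabolite: str
    b: np.ndarray
    s_norm: np.ndarray
    b_ref: float  # normalization b-value (the lowest acquired b)

    def __post_init__(self):
        b = np.asarray(self.b, dtype=float)
        s = np.asarray(self.s_norm, dtype=float)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "s_norm", s)
        if b.shape != s.shape or b.ndim != 1:
            raise ValueError("b and s_norm must be 1-D arrays of equal length")
        if b.size > 1 and np.any(np.diff(b) <= 0):
            raise ValueError("b must be strictly ascending")
        if np.any(s <= 0):
            raise ValueError("s_norm must be > 0")
        iref = int(np.argmin(np.abs(b - self.b_ref)))
        if not np.isclose(b[iref], self.b_ref) or not np.isclose(s[iref], 1.0):
            raise ValueError("s_norm must equal 1 at the normalization b-value")


def build_decay(
    quant: pd.DataFrame, metabolite: str, b_values=None
) -> DecayCurve:
    """Normalized decay curve from a tidy quantification table.

    ``quant`` must hold one animal/timepoint with columns
    (b_value, metabolite, amplitude); normalization is to the lowest
    b-value present (or the lowest of ``b_values`` if given, in which case
    every listed b must be present).
    """
    sub = quant[quant["metabolite"] == metabolite]
    if sub.empty:
        raise ValueError(f"no rows for metabolite {metabolite!r}")
    sub = sub.sort_values("b_value")
    b = sub["b_value"].to_numpy(dtype=float)
    amp = sub["amplitude"].to_numpy(dtype=float)
    if b_values is not None:
        want = np.asarray(sorted(b_values), dtype=float)
        missing = [float(x) for x in want if not np.any(np.isclose(b, x))]
        if missing:
            raise ValueError(f"missing b-value(s) {missing} for {metabolite!r}")
        keep = np.array([np.any(np.isclose(bb, want)) for bb in b])
        b, amp = b[keep], amp[keep]
    if np.unique(b).size != b.size:
        raise ValueError("duplicate b-values in quantification table")
    if amp[0] <= 0:
        raise ValueError(
            f"non-positive amplitude at the normalization b-value for {metabolite!r}"
        )
    return DecayCurve(metabolite=metabolite, b=b, s_norm=amp / amp[0], b_ref=float(b[0]))


# ---------------------------------------------------------------------------
# model fits


@dataclass(frozen=True)
class SticksFit:
    d_intra: float
    se: float
    converged: bool
    residual_norm: float


@dataclass(frozen=True)
class CumulantFit:
    adc: float
    kurtosis: float
    b_max_used: float
    se_adc: float
    se_kurtosis: float
    converged: bool
    residual_norm: float


def _round_sig(x: float, sig: int = 3) -> float:
    if x == 0:
        return 0.0
    return float(np.round(x, sig - 1 - int(np.floor(np.log10(abs(x))))))


def _initial_adc(b: np.ndarray, s: np.ndarray) -> float:
    """Log-slope of the first two points, clipped to the ADC bounds."""
    d0 = -(np.log(s[1]) - np.log(s[0])) / (b[1] - b[0])
    return float(np.clip(d0, ADC_BOUNDS[0] * 2, ADC_BOUNDS[1] / 2))


def _param_se(res, n_params: int) -> np.ndarray:
    """Standard errors from the Jacobian at the solution (Gauss–Newton
    covariance, residual variance with n − p degrees of freedom)."""
    n = res.fun.size
    dof = max(n - n_params, 1)
    s2 = 2.0 * res.cost / dof
    try:
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(n_params, np.nan)


def fit_sticks(curve: DecayCurve) -> SticksFit:
    """Trust-region least-squares fit of the sticks model over the full
    b-range; the amplitude factor is fixed by normalization at ``b_ref``."""
    b, s = curve.b, curve.s_norm
    if b.size < 3:
        raise ValueError("need at least 3 points to fit the sticks model")

    def resid(p):
        d = p[0]
        return sticks_attenuation(b, d) / sticks_attenuation(curve.b_ref, d) - s

    d0 = np.clip(3.0 * _initial_adc(b, s), *D_INTRA_BOUNDS)
    res = least_squares(
        resid, x0=[d0], bounds=([D_INTRA_BOUNDS[0]], [D_INTRA_BOUNDS[1]]),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    se = _param_se(res, 1)[0]
    return SticksFit(
        d_intra=float(res.x[0]),
        se=float(se),
        converged=bool(res.success),
        residual_norm=float(np.linalg.norm(res.fun)),
    )


def fit_cumulant(curve: DecayCurve, d_assumed: float = 0.3) -> CumulantFit:
    """Second-order cumulant fit of ln(S/S0) restricted to b ≤ b_c.

    The convergence radius b_c(d_assumed) is rounded to 3 significant
    figures before the strict ≤ comparison with the acquired b grid. The
    model is referenced to the curve's normalization b-value, so normalized
    data are fitted without a free amplitude.
    """
    b_c = _round_sig(radius_of_convergence(d_assumed), 3)
    mask = curve.b <= b_c
    b, s = curve.b[mask], curve.s_norm[mask]
    if b.size < 3:
        raise ValueError(
            f"need >= 3 points with b <= b_c={b_c}; have {b.size}"
        )
    bad = np.where(s <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive s_norm at b={b[bad[0]]}: log undefined")
    y = np.log(s)

    def model(p, bb):
        D, K = p
        return -bb * D + (bb * D) ** 2 * K / 6.0

    def resid(p):
        return (model(p, b) - model(p, curve.b_ref)) - y

    x0 = [_initial_adc(b, s), 0.0]
    res = least_squares(
        resid, x0=x0,
        bounds=([ADC_BOUNDS[0], KURTOSIS_BOUNDS[0]], [ADC_BOUNDS[1], KURTOSIS_BOUNDS[1]]),
        method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    se = _param_se(res, 2)
    return CumulantFit(
        adc=float(res.x[0]),
        kurtosis=float(res.x[1]),
        b_max_used=float(b[-1]),
        se_adc=float(se[0]),
        se_kurtosis=float(se[1]),
        converged=bool(res.success),
        residual_norm=float(np.linalg.norm(res.fun)),
    )


@dataclass(frozen=True)
class GroupFit:
    """Both aggregation routes over a cohort of per-animal decay curves."""

    metabolite: str
    model: str
    per_animal: dict[str, SticksFit | CumulantFit]
    mean_params: dict[str, float]
    sd_params: dict[str, float]
    average_curve_fit: SticksFit | CumulantFit


def fit_group(
    curves: dict[str, DecayCurve],
    metabolite: str,
    model: str = "sticks",
    d_assumed: float = 0.3,
) -> GroupFit:
    """Fit every animal's curve and the group-averaged curve.

    The group-average curve is the pointwise mean of the *normalized*
    per-animal curves on a common b grid.
    """
    if len(curves) < 2:
        raise ValueError("need >= 2 animals")
    items = sorted(curves.items())
    b0 = items[0][1].b
    for animal, c in items[1:]:
        if c.b.shape != b0.shape or not np.allclose(c.b, b0):
            raise ValueError(f"mismatched b-grid for animal {animal!r}")
    if model == "sticks":
        fitter = lambda c: fit_sticks(c)
        keys = {"d_intra": "d_intra"}
    elif model == "cumulant":
        fitter = lambda c: fit_cumulant(c, d_assumed=d_assumed)
        keys = {"adc": "adc", "kurtosis": "kurtosis"}
    else:
        raise ValueError("model must be 'sticks' or 'cumulant'")
    per_animal = {a: fitter(c) for a, c in items}
    mean_params = {
        k: float(np.mean([getattr(f, attr) for f in per_animal.values()]))
        for k, attr in keys.items()
    }
    sd_params = {
        k: float(np.std([getattr(f, attr) for f in per_animal.values()], ddof=1))
        for k, attr in keys.items()
    }
    s_mean = np.mean([c.s_norm for _, c in items], axis=0)
    avg_curve = DecayCurve(
        metabolite=metabolite, b=b0, s_norm=s_mean / s_mean[0],
        b_ref=items[0][1].b_ref,
    )
    return GroupFit(
        metabolite=metabolite,
        model=model,
        per_animal=per_animal,
        mean_params=mean_params,
        sd_params=sd_params,
        average_curve_fit=fitter(avg_curve),
    )
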