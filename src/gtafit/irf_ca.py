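"""Dispersed Gaussian IRF, damped-oscillation coherent artifact, scatter.

The instrument response is a Gaussian whose center varies with detection
position (chirp/dispersion), parameterized by a polynomial in the scaled
offset from a reference pixel.  Prezero resonance signals (perturbed free
induction decay of the probe in the presence of the picosecond Raman pump,
halted by the actinic pump) are modelled as damped oscillations whose
frequency at detection wavenumber w is (w - w_n) for each ground-state Raman
resonance w_n; each oscillation contributes two conditionally linear basis
vectors (cosine- and sine-like) per pixel, from whose fitted amplitudes the
damped-oscillation-associated spectrum DOAS_n(w) and phase phi_n(w) follow.
An IRF-shaped scatter component (amplitude IRFAS(w)) describes the dispersive
signal at the Raman line maximum and is restricted to wavenumbers at or below
a mask threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinetics import convolved_exponential

__all__ = [
    "IRFModel",
    "Oscillation",
    "OscillationSpectra",
    "FWHM_TO_SIGMA",
    "SPEED_OF_LIGHT_CM_PS",
    "dispersion_center",
    "irf_value",
    "damped_oscillation_basis",
    "amp_phase_from_coefficients",
    "scatter_column",
]

#: fwhm = 2 sqrt(2 ln 2) sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
#: speed of light in cm/ps, for cm^-1 -> rad/ps conversion
SPEED_OF_LIGHT_CM_PS = 0.0299792458
#: dispersion polynomial argument scaling (spectral units per unit argument)
DISPERSION_SCALE = 100.0


@dataclass
class IRFModel:
    """Gaussian IRF with a polynomial dispersion of its center.

    Parameters
    ----------
    mu0 : float
        Center (ps) at the reference spectral position.
    sigma : float
        Width (standard deviation, ps); fwhm = 2 sqrt(2 ln 2) sigma.
    dispersion : sequence of float
        Polynomial coefficients d_1..d_P (ps per scaled unit^p); the center at
        position x is mu0 + sum_p d_p ((x - center) / 100)^p.
    center : float
        Reference spectral position x_c (same unit as the dataset axis).
    link_group : str or None
        Label used to share the width across datasets during fitting.
    """

    mu0: float = 0.0
    sigma: float = 0.05
    dispersion: tuple[float, ...] = field(default_factory=tuple)
    center: float = 0.0
    link_group: str | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("IRF sigma must be > 0")
        self.dispersion = tuple(float(d) for d in self.dispersion)

    @property
    def fwhm(self) -> float:
        return self.sigma / FWHM_TO_SIGMA

    @classmethod
    def from_fwhm(cls, fwhm: float, **kwargs) -> "IRFModel":
        return cls(sigma=fwhm * FWHM_TO_SIGMA, **kwargs)


def dispersion_center(irf: IRFModel, x) -> np.ndarray | float:
    """IRF center mu(x) in ps at spectral position(s) ``x``."""
    x = np.asarray(x, dtype=float)
    mu = np.full(x.shape, irf.mu0)
    if irf.dispersion:
        s = (x - irf.center) / DISPERSION_SCALE
        for p, d in enumerate(irf.dispersion, start=1):
            mu = mu + d * s**p
    return mu if mu.shape else float(mu)


def irf_value(irf: IRFModel, t, x=0.0) -> np.ndarray:
    """Unit-area Gaussian IRF density (ps^-1) at delay(s) t, position x."""
    if irf.sigma <= 0:
        raise ValueError("IRF sigma must be > 0")
    t = np.asarray(t, dtype=float)
    mu = dispersion_center(irf, x)
    z = (t - mu) / irf.sigma
    return np.exp(-0.5 * z**2) / (irf.sigma * np.sqrt(2.0 * np.pi))


@dataclass
class Oscillation:
    """One damped oscillation of the coherent artifact.

    ``omega`` is the Raman resonance frequency in cm^-1; at detection
    wavenumber w the signal oscillates at the difference frequency (w - omega).
    ``gamma`` is the damping rate in ps^-1.  ``direction="backward"`` is the
    perturbed-free-induction-decay kernel: the oscillation exists before the
    arrival of the actinic pump and is halted at the IRF; ``"forward"`` is the
    mirrored, post-zero variant.
    """

    omega: float  # cm^-1
    gamma: float  # ps^-1
    direction: str = "backward"
    label: str | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("oscillation damping gamma must be > 0")
        if self.direction not in ("backward", "forward"):
            raise ValueError(f"unknown oscillation direction {self.direction!r}")
        if self.label is None:
            self.label = f"osc{int(round(self.omega))}"


@dataclass
class OscillationSpectra:
    """Fitted DOAS amplitude (mOD) and phase (rad) per oscillation, per pixel."""

    axis: np.ndarray
    amplitudes: np.ndarray  # (n_pixels, n_osc), >= 0
    phases: np.ndarray  # (n_pixels, n_osc), in (-pi, pi]
    labels: list[str]


def delta_omega_rad_ps(x, omega_cm: float) -> np.ndarray:
    """Difference frequency (x - omega_n) converted from cm^-1 to rad/ps."""
    x = np.asarray(x, dtype=float)
    return 2.0 * np.pi * SPEED_OF_LIGHT_CM_PS * (x - omega_cm)


def damped_oscillation_basis(
    osc: Oscillation,
    delays: np.ndarray,
    irf: IRFModel,
    x,
) -> tuple[np.ndarray, np.ndarray]:
    """Cosine- and sine-like IRF-convolved basis vectors of one oscillation.

    For the backward (PFID) direction the underlying kernel is the reversed
    complex exponential ``exp((gamma + i dw) t') Theta(-t')`` with
    ``dw = 2 pi c (x - omega_n)`` and ``t' = t - mu(x)``; its Gaussian
    convolution has the same closed form as a decay evaluated at reflected
    time.  The fitted linear combination ``A_c cos_basis + A_s sin_basis``
    realizes ``DOAS(w) cos(dw t' - phi(w)) exp(gamma t')`` (halted at the
    pump) with ``DOAS = sqrt(A_c^2 + A_s^2)`` and ``phi = atan2(A_s, A_c)``.

    Returns
    -------
    (cos_basis, sin_basis) : arrays shaped like ``delays`` (x scalar) or
        (n_delays, n_pixels) for an array ``x``.
    """
    delays = np.asarray(delays, dtype=float)
    mu = dispersion_center(irf, x)
    dw = delta_omega_rad_ps(x, osc.omega)
    d = delays[..., None] - np.atleast_1d(mu)[None, :] if np.ndim(dw) else delays - mu
    if osc.direction == "backward":
        kappa = osc.gamma + 1j * dw
        b = convolved_exponential(kappa, -d, mu=0.0, sigma=irf.sigma)
    else:
        k = osc.gamma - 1j * dw
        b = convolved_exponential(k, d, mu=0.0, sigma=irf.sigma)
    return np.real(b), np.imag(b)


def amp_phase_from_coefficients(a_cos, a_sin) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude and phase from fitted cosine/sine coefficients.

    ``amplitude = sqrt(a_cos^2 + a_sin^2)``, ``phase = atan2(a_sin, a_cos)``
    in (-pi, pi]; reconstructing ``a_cos = amp cos(phase)`` and
    ``a_sin = amp sin(phase)`` round-trips exactly.
    """
    a_cos = np.asarray(a_cos, dtype=float)
    a_sin = np.asarray(a_sin, dtype=float)
    phase = np.arctan2(a_sin, a_cos)
    phase = np.where(phase <= -np.pi, phase + 2 * np.pi, phase)  # (-pi, pi]
    return np.hypot(a_cos, a_sin), phase


def scatter_column(
    irf: IRFModel,
    delays: np.ndarray,
    x: float,
    mask_threshold: float = np.inf,
) -> np.ndarray:
    """IRF-shaped scatter basis vector at one pixel.

    Returns the IRF time profile when ``x <= mask_threshold`` and an all-zero
    column otherwise (the IRF-associated spectrum is constrained to zero above
    the threshold to avoid interference with the fastest species spectrum).
    """
    delays = np.asarray(delays, dtype=float)
    if x > mask_threshold:
        return np.zeros_like(delays)
    return irf_value(irf, delays, x)
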