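"""Synthetic FSRS / transient-absorption surfaces with known ground truth.

No measured lycopene data accompany the methodology, so every stage of the
pipeline is exercised on simulated surfaces that carry the statistical
structure the analysis assumes: IRF-convolved populations of a branched
seven-compartment scheme times stylized Gaussian-band species spectra, three
backward damped oscillations at the ground-state Raman resonances, an
IRF-shaped scatter term below 1100 cm^-1, and additive iid Gaussian noise on
a 421-point linear/logarithmic delay axis.

:func:`lycopene_preset` encodes the study conditions: target-scheme rates
reconstructed from the published lifetimes (71, 175 fs; 0.8, 3.3, 5, 6.7 ps)
and branching fractions (25% ground-state loss from hot S1; 14% of relaxed S1
to the slow S1' subpopulation, 64% to S*; 5 ns^-1 triplet formation),
oscillations at 913 (solvent), 1154 and 1511 cm^-1 (lycopene nu2/nu1), FSRS
IRF of 180 fs fwhm with quadratic dispersion and TA IRF of 97 fs fwhm.  The
band shapes of the species spectra are stylized (no numeric spectra are
published); recovery experiments therefore target the nonlinear parameters
and component-matrix reconstruction, not absolute band amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import SpectroDataset
from .irf_ca import IRFModel, Oscillation, damped_oscillation_basis, dispersion_center, irf_value
from .kinetics import Channel, KineticScheme, concentration_stack, sequential_scheme

__all__ = [
    "BandSpec",
    "OscillationTruth",
    "DatasetSpec",
    "SimulationConfig",
    "make_time_axis",
    "make_band_spectrum",
    "simulate_dataset",
    "lycopene_preset",
    "lycopene_sequential_preset",
    "lycopene_scheme",
]

_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band: center and fwhm in axis units, amplitude in mOD."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be > 0")


@dataclass
class OscillationTruth:
    """A coherent-artifact oscillation plus its true DOAS/phase profile.

    The amplitude profile is Lorentzian-like around the resonance,
    ``amplitude0 / (1 + ((w - omega)/width)^2)``, with a slowly varying phase
    ``phase0 + phase_slope (w - omega)/100`` — a qualitative stand-in for
    measured damped-oscillation-associated spectra.
    """

    oscillation: Oscillation
    amplitude0: float  # mOD at resonance
    width: float = 25.0  # cm^-1
    phase0: float = 0.3  # rad
    phase_slope: float = 0.3  # rad per 100 cm^-1

    def profiles(self, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dw = axis - self.oscillation.omega
        amp = self.amplitude0 / (1.0 + (dw / self.width) ** 2)
        phase = self.phase0 + self.phase_slope * dw / 100.0
        phase = np.angle(np.exp(1j * phase))  # wrap to (-pi, pi]
        return amp, phase


@dataclass
class DatasetSpec:
    """Everything needed to synthesize one experiment."""

    name: str
    domain: str  # "wavenumber" | "wavelength"
    axis: np.ndarray
    irf: IRFModel
    irf_group: str
    bands: dict[str, list[BandSpec]]
    use_oscillations: bool = False
    scatter_threshold: float | None = None
    irfas_amplitude: float = 0.0  # mOD, dispersive scatter peak
    irfas_center: float = 913.0
    irfas_width: float = 15.0
    weight: float = 1.0
    sign: float = 1.0  # -1 for raw anti-Stokes data

    def irfas_profile(self, axis: np.ndarray) -> np.ndarray:
        """Dispersive (derivative-of-Lorentzian) scatter spectrum, masked."""
        if self.irfas_amplitude == 0.0 or self.scatter_threshold is None:
            return np.zeros_like(axis)
        s = (axis - self.irfas_center) / self.irfas_width
        prof = self.irfas_amplitude * (-2.0 * s) / (1.0 + s**2) ** 2
        prof[axis > self.scatter_threshold] = 0.0
        return prof


@dataclass
class SimulationConfig:
    """Full description of a reproducible multi-experiment simulation."""

    scheme: KineticScheme
    datasets: dict[str, DatasetSpec]
    oscillations: list[OscillationTruth] = field(default_factory=list)
    delays: np.ndarray = field(default_factory=lambda: make_time_axis())
    noise_sigma: float = 0.05  # mOD
    seed: int = 0

    def truth_parameters(self, which: str) -> dict[str, float]:
        """Generating nonlinear parameters, keyed by fit parameter names."""
        spec = self.datasets[which]
        out = {ch.name: ch.rate for ch in self.scheme.channels}
        g = spec.irf_group
        out[f"irf_{g}_mu0"] = spec.irf.mu0
        out[f"irf_{g}_sigma"] = spec.irf.sigma
        for p, d in enumerate(spec.irf.dispersion, start=1):
            out[f"irf_{g}_d{p}"] = d
        if spec.use_oscillations:
            for ot in self.oscillations:
                o = ot.oscillation
                out[f"{o.label}_omega"] = o.omega
                out[f"{o.label}_gamma"] = o.gamma
        return out


def make_time_axis(
    n_linear: int = 201,
    linear_range: tuple[float, float] = (-1.0, 1.0),
    n_log: int = 220,
    t_max: float = 100.0,
) -> np.ndarray:
    """Delay axis: uniform on ``linear_range``, log-spaced up to ``t_max``.

    The default is the 421-point axis of the emulated experiments: linear
    from -1 to 1 ps, logarithmic from 1 to 100 ps.
    """
    lo, hi = linear_range
    if not lo < hi:
        raise ValueError("linear_range must be ordered (lo < hi)")
    if n_linear < 2:
        raise ValueError("n_linear must be >= 2")
    lin = np.linspace(lo, hi, n_linear)
    if n_log == 0:
        return lin
    if hi <= 0:
        raise ValueError("log segment requires the linear range to end at t > 0")
    if t_max <= hi:
        raise ValueError("t_max must exceed the end of the linear range")
    log = np.geomspace(hi, t_max, n_log + 1)[1:]
    return np.concatenate([lin, log])


def make_band_spectrum(bands: list[BandSpec], axis: np.ndarray) -> np.ndarray:
    """Sum of Gaussian bands evaluated on a spectral axis."""
    axis = np.asarray(axis, dtype=float)
    if axis.size == 0:
        raise ValueError("spectral axis is empty")
    out = np.zeros_like(axis)
    for b in bands:
        s = b.fwhm / _FWHM
        out += b.amplitude * np.exp(-0.5 * ((axis - b.center) / s) ** 2)
    return out


def simulate_dataset(
    config: SimulationConfig,
    which: str,
    rng: np.random.Generator | None = None,
) -> tuple[SpectroDataset, dict]:
    """Synthesize one experiment of a config; returns (dataset, ground truth).

    The ground-truth record holds the generating nonlinear parameters (keyed
    by fit parameter names), the species spectra, DOAS/phase and scatter
    profiles, and the three noiseless component matrices (populations,
    coherent artifact, scatter), so recovery tests can compare any stage.
    """
    spec = config.datasets[which]
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t = config.delays
    x = np.asarray(spec.axis, dtype=float)
    irf = spec.irf

    sads = np.column_stack(
        [
            make_band_spectrum(spec.bands.get(c, []), x)
            for c in config.scheme.compartments
        ]
    )
    mu = np.atleast_1d(dispersion_center(irf, x))
    conc = concentration_stack(config.scheme, t, mu, irf.sigma)
    populations = np.einsum("tpl,pl->tp", conc, sads)

    ca = np.zeros_like(populations)
    doas_amp = doas_phase = None
    if spec.use_oscillations and config.oscillations:
        doas_amp = np.zeros((x.size, len(config.oscillations)))
        doas_phase = np.zeros_like(doas_amp)
        for i, ot in enumerate(config.oscillations):
            amp, phase = ot.profiles(x)
            doas_amp[:, i] = amp
            doas_phase[:, i] = phase
            cb, sb = damped_oscillation_basis(ot.oscillation, t, irf, x)
            ca += (amp * np.cos(phase)) * cb + (amp * np.sin(phase)) * sb

    scatter = np.zeros_like(populations)
    irfas = spec.irfas_profile(x)
    if np.any(irfas):
        scatter = irfas[None, :] * irf_value(irf, t[:, None], x[None, :])

    clean = spec.sign * (populations + ca + scatter)
    noise = rng.normal(0.0, config.noise_sigma, size=clean.shape)
    dataset = SpectroDataset(
        name=spec.name,
        delays=t,
        axis=x,
        data=clean + noise,
        domain=spec.domain,
        weight=spec.weight,
        sign_convention="raw",
        scatter_threshold=spec.scatter_threshold,
        use_oscillations=spec.use_oscillations,
        irf_group=spec.irf_group,
    )
    truth = {
        "parameters": config.truth_parameters(which),
        "sads": sads,
        "doas_amplitude": doas_amp,
        "doas_phase": doas_phase,
        "irfas": irfas,
        "populations": spec.sign * populations,
        "coherent_artifact": spec.sign * ca,
        "scatter": spec.sign * scatter,
        "clean": clean,
        "noise_sigma": config.noise_sigma,
        "sign": spec.sign,
    }
    return dataset, truth


# ----------------------------------------------------------------------
# lycopene preset
# ----------------------------------------------------------------------

#: published lifetimes (ps) backing the preset rates
LIFETIME_S2 = 0.071
LIFETIME_S1VH = 0.175
LIFETIME_S1H = 0.8
LIFETIME_S1 = 3.3
LIFETIME_S1P = 5.0
LIFETIME_SSTAR = 6.7
#: sequential-analysis lifetimes (ps)
SEQUENTIAL_LIFETIMES = (0.071, 0.175, 0.8, 3.3, 5.9, np.inf)
#: branching fractions
FRAC_S1H_GS = 0.25
FRAC_S1_S1P = 0.14
FRAC_S1_SSTAR = 0.64
#: triplet formation rate (ns^-1)
RATE_TO_TRIPLET = 5.0
#: IRF widths (fwhm, ps)
FSRS_IRF_FWHM = 0.180
TA_IRF_FWHM = 0.097
#: coherent-artifact resonances (cm^-1): THF solvent, lycopene nu2, nu1
OSC_FREQUENCIES = (913.0, 1154.0, 1511.0)
OSC_DAMPINGS = (2.0, 1.7, 1.4)  # ps^-1, set by Raman pulse/linewidth scales


def lycopene_scheme() -> KineticScheme:
    """Branched 7-compartment target scheme S2->S1vh->S1h->S1->{S1',S*,T}.

    Rates (ns^-1) are reconstructed from the published lifetimes and
    branching fractions; the S1->GS channel takes the remainder of the
    1/3.3 ps total rate so the S1'/S* fractions are exact by construction.
    """
    k_s1_total = 1e3 / LIFETIME_S1  # ns^-1
    k_s1h_total = 1e3 / LIFETIME_S1H
    k_s1p_total = 1e3 / LIFETIME_S1P
    channels = [
        Channel("S2", "S1vh", 1e3 / LIFETIME_S2),
        Channel("S1vh", "S1h", 1e3 / LIFETIME_S1VH),
        Channel("S1h", "S1", (1.0 - FRAC_S1H_GS) * k_s1h_total),
        Channel("S1h", "GS", FRAC_S1H_GS * k_s1h_total),
        Channel("S1", "Sstar", FRAC_S1_SSTAR * k_s1_total),
        Channel("S1", "S1p", FRAC_S1_S1P * k_s1_total),
        Channel(
            "S1",
            "GS",
            (1.0 - FRAC_S1_SSTAR - FRAC_S1_S1P) * k_s1_total - RATE_TO_TRIPLET,
        ),
        Channel("S1", "T", RATE_TO_TRIPLET),
        Channel("S1p", "GS", k_s1p_total - RATE_TO_TRIPLET),
        Channel("S1p", "T", RATE_TO_TRIPLET),
        Channel("Sstar", "GS", 1e3 / LIFETIME_SSTAR),
    ]
    return KineticScheme(
        ["S2", "S1vh", "S1h", "S1", "S1p", "Sstar", "T"], channels
    )


def _ta_bands() -> dict[str, list[BandSpec]]:
    """Stylized visible-TA species spectra: bleach 450/480/510 nm, ESA 545-565."""
    bleach = [
        BandSpec(450.0, 22.0, -3.0),
        BandSpec(480.0, 24.0, -5.0),
        BandSpec(510.0, 26.0, -4.0),
    ]
    s1_like = bleach + [BandSpec(565.0, 42.0, 10.0)]
    return {
        "S2": bleach
        + [BandSpec(610.0, 120.0, -6.0), BandSpec(745.0, 70.0, 7.0)],
        "S1vh": bleach + [BandSpec(585.0, 110.0, 8.0)],
        "S1h": bleach + [BandSpec(570.0, 60.0, 9.0)],
        "S1": s1_like,
        "S1p": s1_like,  # identical spectra for the slow S1 subpopulation
        "Sstar": bleach + [BandSpec(545.0, 38.0, 8.0)],
        "T": [BandSpec(515.0, 30.0, 2.0), BandSpec(480.0, 24.0, -1.0)],
    }


def _fsrs_bands() -> dict[str, list[BandSpec]]:
    """Stylized FSRS species spectra: nu1/nu2/nu3 bleaches, upshifting ES nu1."""
    gs_bleach = [
        BandSpec(1520.0, 18.0, -6.0),
        BandSpec(1160.0, 14.0, -4.0),
        BandSpec(1010.0, 12.0, -2.0),
    ]
    s1_like = gs_bleach + [BandSpec(1800.0, 35.0, 6.0)]
    return {
        "S2": gs_bleach + [BandSpec(1800.0, 80.0, 3.0)],
        "S1vh": gs_bleach + [BandSpec(1650.0, 150.0, 4.0)],
        "S1h": gs_bleach
        + [BandSpec(1780.0, 60.0, 5.0), BandSpec(1260.0, 40.0, 2.0)],
        "S1": s1_like,
        "S1p": s1_like,
        "Sstar": [
            BandSpec(1505.0, 18.0, -5.0),
            BandSpec(1145.0, 14.0, -3.5),
            BandSpec(995.0, 12.0, -2.0),
            BandSpec(1800.0, 30.0, 1.0),
        ],
        "T": [BandSpec(1520.0, 18.0, -2.0), BandSpec(1000.0, 50.0, 0.5)],
    }


def _preset_oscillations() -> list[OscillationTruth]:
    # CA amplitude about 5x the population peak near the resonances
    amps = (40.0, 30.0, 30.0)
    phases = (0.5, 0.2, -0.3)
    out = []
    for w, g, a, p in zip(OSC_FREQUENCIES, OSC_DAMPINGS, amps, phases):
        out.append(
            OscillationTruth(
                Oscillation(omega=w, gamma=g, direction="backward"),
                amplitude0=a,
                width=25.0,
                phase0=p,
                phase_slope=0.3,
            )
        )
    return out


def lycopene_preset(
    n_pixels_fsrs: int = 576,
    n_pixels_ta: int = 200,
    noise_sigma: float = 0.05,
    seed: int = 0,
    delays: np.ndarray | None = None,
) -> SimulationConfig:
    """Full study-conditions preset: Stokes/anti-Stokes FSRS + visible TA.

    FSRS axes span 750-1900 cm^-1 (180 fs fwhm IRF, quadratic dispersion,
    scatter below 1100 cm^-1, three backward oscillations); the TA axis spans
    420-770 nm (97 fs fwhm IRF, no oscillations or scatter, weight 10).  The
    anti-Stokes surface reuses the Stokes structure with inverted raw sign.
    """
    fsrs_axis = np.linspace(750.0, 1900.0, n_pixels_fsrs)
    ta_axis = np.linspace(420.0, 770.0, n_pixels_ta)
    fsrs_irf = lambda group: IRFModel(  # noqa: E731 — two identical groups
        mu0=0.0,
        sigma=FSRS_IRF_FWHM / _FWHM,
        dispersion=(0.03, -0.004),
        center=1300.0,
        link_group="fsrs_width",
    )
    ta_irf = IRFModel(mu0=0.0, sigma=TA_IRF_FWHM / _FWHM)
    fsrs_bands = _fsrs_bands()
    datasets = {
        "stokes": DatasetSpec(
            name="stokes",
            domain="wavenumber",
            axis=fsrs_axis,
            irf=fsrs_irf("stokes"),
            irf_group="stokes",
            bands=fsrs_bands,
            use_oscillations=True,
            scatter_threshold=1100.0,
            irfas_amplitude=50.0,
            weight=1.0,
            sign=1.0,
        ),
        "antistokes": DatasetSpec(
            name="antistokes",
            domain="wavenumber",
            axis=fsrs_axis.copy(),
            irf=fsrs_irf("antistokes"),
            irf_group="antistokes",
            bands=fsrs_bands,
            use_oscillations=True,
            scatter_threshold=1100.0,
            irfas_amplitude=50.0,
            weight=1.0,
            sign=-1.0,  # raw Stokes and anti-Stokes are of opposite sign
        ),
        "ta": DatasetSpec(
            name="ta",
            domain="wavelength",
            axis=ta_axis,
            irf=ta_irf,
            irf_group="ta",
            bands=_ta_bands(),
            use_oscillations=False,
            scatter_threshold=None,
            weight=10.0,
        ),
    }
    return SimulationConfig(
        scheme=lycopene_scheme(),
        datasets=datasets,
        oscillations=_preset_oscillations(),
        delays=make_time_axis() if delays is None else delays,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def lycopene_sequential_preset(
    n_pixels_ta: int = 200,
    noise_sigma: float = 0.05,
    seed: int = 0,
    delays: np.ndarray | None = None,
) -> SimulationConfig:
    """TA-only preset generated from the six-component loss-free cascade.

    Uses the published sequential lifetimes (71, 175 fs, 0.8, 3.3, 5.9 ps,
    long-lived) with stylized evolution-associated spectra.
    """
    labels = ["E1", "E2", "E3", "E4", "E5", "E6"]
    scheme = sequential_scheme(list(SEQUENTIAL_LIFETIMES), labels)
    ta = _ta_bands()
    bands = {
        "E1": ta["S2"],
        "E2": ta["S1vh"],
        "E3": ta["S1h"],
        "E4": ta["S1"],
        "E5": ta["Sstar"],
        "E6": ta["T"],
    }
    spec = DatasetSpec(
        name="ta",
        domain="wavelength",
        axis=np.linspace(420.0, 770.0, n_pixels_ta),
        irf=IRFModel(mu0=0.0, sigma=TA_IRF_FWHM / _FWHM),
        irf_group="ta",
        bands=bands,
        weight=10.0,
    )
    return SimulationConfig(
        scheme=scheme,
        datasets={"ta": spec},
        oscillations=[],
        delays=make_time_axis() if delays is None else delays,
        noise_sigma=noise_sigma,
        seed=seed,
    )
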