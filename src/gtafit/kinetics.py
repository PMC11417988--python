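"""Compartmental kinetic schemes and analytic IRF-convolved populations.

A :class:`KineticScheme` is a set of first-order transfer channels between
named compartments; losses to the ground state are routed to the implicit
sink label ``"GS"``.  Channel rates are declared in ns^-1 (the unit used for
branched target schemes in the carotenoid literature) while all kinetics
computations run in ps, matching the delay axis of femtosecond experiments.

Populations follow dc/dt = K c with an instantaneous excitation smeared by a
Gaussian instrument response; the solution is a linear combination of
exponentials convolved with the Gaussian, for which a closed form in terms of
the (scaled) complementary error function exists and is evaluated here in an
overflow-safe way, also for complex decay rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfcx, wofz

__all__ = [
    "Channel",
    "KineticScheme",
    "ConcentrationMatrix",
    "SpectraMatrix",
    "GS",
    "build_k_matrix",
    "convolved_exponential",
    "solve_concentrations",
    "sequential_scheme",
    "transform_spectra",
]

GS = "GS"
#: rate unit conversion: 1 ns^-1 = 1e-3 ps^-1
NS_TO_PS = 1e-3
_SQRT2 = np.sqrt(2.0)
#: eigenvalue separation (ps^-1) below which the scheme is treated as degenerate
DEGENERACY_TOL = 1e-9


class SchemeError(ValueError):
    """Raised for ill-formed kinetic schemes."""


@dataclass(frozen=True)
class Channel:
    """First-order transfer ``source -> target`` with rate in ns^-1.

    ``target`` may be the implicit ground-state sink :data:`GS`.
    """

    source: str
    target: str
    rate: float  # ns^-1

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise SchemeError(f"channel {self.source}->{self.target}: rate < 0")

    @property
    def name(self) -> str:
        return f"k_{self.source}_{self.target}"


@dataclass
class KineticScheme:
    """Compartments, channels and the excitation input vector.

    Parameters
    ----------
    compartments : list of str
        Ordered compartment labels; :data:`GS` may not be a compartment.
    channels : list of Channel
        Transfer channels; targets may be compartments or :data:`GS`.
    inputs : array-like or None
        Excitation fraction per compartment (sums to 1).  Default: all
        excitation enters the first compartment.
    """

    compartments: list[str]
    channels: list[Channel] = field(default_factory=list)
    inputs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if GS in self.compartments:
            raise SchemeError("the ground-state sink 'GS' is not a compartment")
        if len(set(self.compartments)) != len(self.compartments):
            raise SchemeError("duplicate compartment labels")
        known = set(self.compartments)
        for ch in self.channels:
            if ch.source not in known:
                raise SchemeError(
                    f"channel {ch.source}->{ch.target}: unknown source "
                    f"compartment {ch.source!r}"
                )
            if ch.target != GS and ch.target not in known:
                raise SchemeError(
                    f"channel {ch.source}->{ch.target}: unknown target "
                    f"compartment {ch.target!r}"
                )
        if self.inputs is None:
            self.inputs = np.zeros(len(self.compartments))
            self.inputs[0] = 1.0
        else:
            self.inputs = np.asarray(self.inputs, dtype=float)
            if self.inputs.shape != (len(self.compartments),):
                raise SchemeError("inputs length must equal compartment count")
            if abs(self.inputs.sum() - 1.0) > 1e-12:
                raise SchemeError("input fractions must sum to 1 (within 1e-12)")

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def index(self, label: str) -> int:
        return self.compartments.index(label)

    def with_rates(self, rates: dict[str, float]) -> "KineticScheme":
        """Return a copy with channel rates replaced by ``rates[channel.name]``."""
        new = [
            Channel(ch.source, ch.target, rates.get(ch.name, ch.rate))
            for ch in self.channels
        ]
        return KineticScheme(list(self.compartments), new, self.inputs.copy())

    def outgoing(self, label: str) -> list[Channel]:
        return [ch for ch in self.channels if ch.source == label]

    def total_rate(self, label: str) -> float:
        """Total outgoing rate of a compartment in ns^-1."""
        return sum(ch.rate for ch in self.outgoing(label))

    def lifetime(self, label: str) -> float:
        """Compartment lifetime 1/(total outgoing rate), in ps."""
        k = self.total_rate(label) * NS_TO_PS
        return np.inf if k == 0 else 1.0 / k

    def branching_fractions(self, label: str) -> dict[str, float]:
        """Per-channel fraction rate_i / total outgoing rate of ``label``."""
        out = self.outgoing(label)
        total = sum(ch.rate for ch in out)
        if total == 0:
            return {}
        return {ch.target: ch.rate / total for ch in out}


@dataclass
class ConcentrationMatrix:
    """IRF-convolved populations on a delay axis (delay x compartment)."""

    delays: np.ndarray  # ps
    values: np.ndarray  # (n_delays, n_compartments), unitless
    compartments: list[str]

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.delays.size, len(self.compartments)):
            raise ValueError("concentration matrix shape mismatch")


@dataclass
class SpectraMatrix:
    """Component spectra on a spectral axis (pixel x component), in mOD.

    Holds SADS for a target scheme or EADS for a sequential one.
    """

    axis: np.ndarray
    values: np.ndarray  # (n_pixels, n_components)
    components: list[str]

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.axis.size, len(self.components)):
            raise ValueError("spectra matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra matrix contains non-finite values")


def build_k_matrix(scheme: KineticScheme, unit: str = "ps") -> np.ndarray:
    """Compile the transfer matrix K of a scheme.

    ``K[j, l]`` is the rate of transfer l -> j for j != l; the diagonal holds
    minus the total outgoing rate of each compartment (including losses to the
    ground-state sink, which make the column sums negative).

    Parameters
    ----------
    scheme : KineticScheme
    unit : {"ps", "ns"}
        Unit of the returned rates (ps^-1 default, matching the delay axis).
    """
    n = scheme.n_compartments
    idx = {c: i for i, c in enumerate(scheme.compartments)}
    K = np.zeros((n, n))
    for ch in scheme.channels:
        l = idx[ch.source]
        K[l, l] -= ch.rate
        if ch.target != GS:
            K[idx[ch.target], l] += ch.rate
    if unit == "ps":
        K = K * NS_TO_PS
    elif unit != "ns":
        raise ValueError(f"unknown rate unit {unit!r}")
    return K


def convolved_exponential(k, t, mu=0.0, sigma=0.05):
    """Exponential decay exp(-k t) Theta(t) convolved with a unit-area Gaussian.

    Closed form::

        E(k, t) = 1/2 exp(k^2 s^2/2 - k (t-mu)) erfc((k s^2 - (t-mu)) / (s sqrt 2))

    evaluated through the scaled complementary error function so it never
    overflows, also for complex ``k`` (damped oscillations), where the
    Faddeeva function supplies erfcx of complex argument.

    Parameters
    ----------
    k : float or complex
        Decay rate in ps^-1; Re(k) >= 0 is assumed for stability.
    t : array-like
        Delays in ps.
    mu : float or array-like
        IRF center in ps (broadcast against ``t``).
    sigma : float
        IRF width (standard deviation) in ps; must be > 0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    t = np.asarray(t, dtype=float)
    d = t - mu
    u = d / (sigma * _SQRT2)
    a = k * sigma / _SQRT2
    z = a - u
    complex_k = np.iscomplexobj(np.asarray(k)) or isinstance(k, complex)

    def _erfcx(w):
        return wofz(1j * w) if complex_k else erfcx(w)

    re_z = np.real(z)
    neg = re_z < 0.0
    # Re(z) >= 0: 1/2 erfcx(z) exp(-u^2) — both factors bounded.
    # Re(z) <  0: erfc(z) = 2 - erfc(-z); the explicit exponential term has
    # nonpositive real exponent there for Re(k) >= 0.
    z_safe = np.where(neg, -z, z)
    ex = _erfcx(z_safe)
    gauss = np.exp(-(u**2))
    pos_branch = 0.5 * ex * gauss
    exparg = np.where(neg, a**2 - 2 * a * u, 0.0)
    neg_branch = np.exp(exparg) - 0.5 * ex * gauss
    out = np.where(neg, neg_branch, pos_branch)
    if not complex_k:
        out = out.real
    return out


def _eigensystem(scheme: KineticScheme) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvalues (ps^-1), eigenvectors and input-projected amplitudes."""
    K = build_k_matrix(scheme, unit="ps")
    lam, V = np.linalg.eig(K)
    n = lam.size
    if n > 1:
        diffs = np.abs(lam[:, None] - lam[None, :])[~np.eye(n, dtype=bool)]
        if diffs.min() < DEGENERACY_TOL:
            raise SchemeError(
                "near-degenerate eigenvalues (separation < "
                f"{DEGENERACY_TOL} ps^-1); perturb one of the rates slightly"
            )
    amp = np.linalg.solve(V, scheme.inputs.astype(complex))
    return lam, V, amp


def solve_concentrations(
    scheme: KineticScheme,
    delays: np.ndarray,
    mu: float | np.ndarray = 0.0,
    sigma: float = 0.05,
) -> ConcentrationMatrix:
    """Analytic IRF-convolved populations of a scheme on a delay axis.

    Each eigenmode of K contributes a Gaussian-convolved exponential
    ``E(-lambda_j, t; mu, sigma)``; populations are their linear combination
    through the eigenvectors and the excitation input vector.

    ``mu`` may be a scalar or an array (per-pixel IRF center from the
    dispersion model); for an array the result gains a trailing pixel axis
    only internally — use :func:`concentration_stack` for that case.
    """
    lam, V, amp = _eigensystem(scheme)
    delays = np.asarray(delays, dtype=float)
    modes = np.empty((lam.size, delays.size), dtype=complex)
    for j, lj in enumerate(lam):
        kj = -lj
        if abs(kj.imag) < 1e-300:
            kj = kj.real
        modes[j] = convolved_exponential(kj, delays, mu=mu, sigma=sigma)
    values = np.real(np.einsum("lj,j,jt->tl", V, amp, modes))
    return ConcentrationMatrix(delays, values, list(scheme.compartments))


def concentration_stack(
    scheme: KineticScheme,
    delays: np.ndarray,
    mu: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Populations with a per-pixel IRF center: (n_delays, n_pixels, n_comp)."""
    lam, V, amp = _eigensystem(scheme)
    delays = np.asarray(delays, dtype=float)
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    d = delays[:, None] - mu[None, :]
    modes = np.empty((lam.size,) + d.shape, dtype=complex)
    for j, lj in enumerate(lam):
        kj = -lj
        if abs(kj.imag) < 1e-300:
            kj = kj.real
        modes[j] = convolved_exponential(kj, d, mu=0.0, sigma=sigma)
    return np.real(np.einsum("lj,j,jtp->tpl", V, amp, modes))


def sequential_scheme(
    lifetimes: list[float], labels: list[str] | None = None
) -> KineticScheme:
    """Unbranched, loss-free cascade 1 -> 2 -> ... -> N from lifetimes in ps.

    The final lifetime may be ``inf`` (a long-lived terminal compartment).
    The eigenvalues of the compiled K matrix are exactly ``-1/tau_i``.
    """
    if labels is None:
        labels = [f"C{i + 1}" for i in range(len(lifetimes))]
    if len(labels) != len(lifetimes):
        raise SchemeError("labels and lifetimes length mismatch")
    channels = []
    for i, tau in enumerate(lifetimes):
        if np.isinf(tau):
            if i != len(lifetimes) - 1:
                raise SchemeError("only the final lifetime may be infinite")
            continue
        if tau <= 0:
            raise SchemeError(f"lifetime {tau} ps is not positive")
        rate_ns = 1.0 / (tau * NS_TO_PS)
        target = labels[i + 1] if i + 1 < len(labels) else GS
        channels.append(Channel(labels[i], target, rate_ns))
    return KineticScheme(list(labels), channels)


def transform_spectra(
    c_source: ConcentrationMatrix,
    s_source: SpectraMatrix,
    c_dest: ConcentrationMatrix,
    cond_limit: float = 1e12,
) -> SpectraMatrix:
    """Re-express component spectra under a different kinetic representation.

    Finds the spectra ``S_dest`` minimizing
    ``|| C_source S_source^T - C_dest S_dest^T ||_F``.  When both schemes share
    the same eigenvalue set (e.g. a sequential scheme matched to a target
    scheme), the reconstruction is exact and this is the standard EADS <->
    SADS linear transform.
    """
    if c_source.delays.shape != c_dest.delays.shape or not np.allclose(
        c_source.delays, c_dest.delays
    ):
        raise ValueError("source and destination concentrations need one delay axis")
    cond = np.linalg.cond(c_dest.values)
    if cond > cond_limit:
        raise ValueError(
            f"destination concentration matrix is rank deficient "
            f"(condition number {cond:.3g})"
        )
    # S_dest^T = pinv(C_dest) C_source S_source^T
    surface = c_source.values @ s_source.values.T
    s_dest_t, *_ = np.linalg.lstsq(c_dest.values, surface, rcond=None)
    return SpectraMatrix(s_source.axis, s_dest_t.T, list(c_dest.compartments))
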