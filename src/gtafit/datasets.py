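"""Container for one time-resolved spectral surface (delay x pixel, mOD)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectroDataset"]


@dataclass
class SpectroDataset:
    """One experiment: a data matrix on a delay axis and a spectral axis.

    Parameters
    ----------
    name : str
        Identifier used in parameter names, reports and error messages.
    delays : array
        Delay axis in ps, strictly ascending.
    axis : array
        Spectral axis, strictly monotone; wavenumber (cm^-1) for Raman data,
        wavelength (nm) for transient absorption.
    data : array
        Signal matrix (n_delays, n_pixels) in mOD.
    domain : {"wavenumber", "wavelength"}
    weight : float
        Nonnegative scalar weight applied to this dataset's residuals in the
        simultaneous fit.
    sign_convention : {"raw", "flipped"}
        ``"flipped"`` marks data whose sign was inverted on ingest (e.g.
        Stokes Raman gain plotted positive).
    scatter_threshold : float or None
        Include an IRF-shaped scatter column at pixels with axis value at or
        below this threshold; ``None`` disables the scatter component (as for
        transient-absorption surfaces).
    use_oscillations : bool
        Whether the damped-oscillation coherent-artifact columns enter this
        dataset's model.
    irf_group : str
        Key selecting which IRF parameter group applies to this dataset.
    """

    name: str
    delays: np.ndarray
    axis: np.ndarray
    data: np.ndarray
    domain: str = "wavenumber"
    weight: float = 1.0
    sign_convention: str = "raw"
    scatter_threshold: float | None = None
    use_oscillations: bool = False
    irf_group: str = "default"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delays = np.asarray(self.delays, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.delays.size, self.axis.size):
            raise ValueError(
                f"dataset {self.name!r}: data shape {self.data.shape} does not "
                f"match ({self.delays.size}, {self.axis.size})"
            )
        if np.any(np.diff(self.delays) <= 0):
            raise ValueError(f"dataset {self.name!r}: delays must be ascending")
        if np.any(np.diff(self.axis) <= 0):
            raise ValueError(f"dataset {self.name!r}: spectral axis must be ascending")
        if np.isnan(self.data).any():
            raise ValueError(f"dataset {self.name!r}: data contain NaNs")
        if self.weight < 0:
            raise ValueError(f"dataset {self.name!r}: weight must be >= 0")
        if self.domain not in ("wavenumber", "wavelength"):
            raise ValueError(f"dataset {self.name!r}: unknown domain {self.domain!r}")
        if self.sign_convention not in ("raw", "flipped"):
            raise ValueError(
                f"dataset {self.name!r}: unknown sign convention "
                f"{self.sign_convention!r}"
            )

    @property
    def n_delays(self) -> int:
        return self.delays.size

    @property
    def n_pixels(self) -> int:
        return self.axis.size

    def flipped(self) -> "SpectroDataset":
        """Copy with the signal sign inverted and the convention toggled."""
        new_sign = "flipped" if self.sign_convention == "raw" else "raw"
        return SpectroDataset(
            name=self.name,
            delays=self.delays.copy(),
            axis=self.axis.copy(),
            data=-self.data,
            domain=self.domain,
            weight=self.weight,
            sign_convention=new_sign,
            scatter_threshold=self.scatter_threshold,
            use_oscillations=self.use_oscillations,
            irf_group=self.irf_group,
            meta=dict(self.meta),
        )
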