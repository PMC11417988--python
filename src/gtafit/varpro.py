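"""Simultaneous target analysis by variable projection.

The superposition model for one time-resolved surface reads, per detection
pixel x,

    TRS(t, x) = sum_l c_l(t; theta) SADS_l(x)
              + sum_n [A_c,n(x) cosbasis_n(t, x; theta)
                       + A_s,n(x) sinbasis_n(t, x; theta)]
              + IRFAS(x) irf(t, x; theta) + residual(t, x)

where theta collects the nonlinear parameters (channel rates, IRF center,
width and dispersion, oscillation frequencies and damping rates) and the
spectra SADS, (A_c, A_s) -> (DOAS, phi) and IRFAS are conditionally linear:
for any theta they are solved per pixel by linear least squares (variable
projection), so the nonlinear optimizer only sees theta.  Several experiments
(Stokes/anti-Stokes Raman, transient absorption) are fitted simultaneously
with scalar per-dataset weights and linked parameters.

The user-facing surface is :class:`TargetAnalysisModel` (construct from
datasets + scheme + IRF models + oscillations) whose :meth:`fit` returns a
:class:`TargetAnalysisResults` carrying estimates, standard errors, spectra,
residuals and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .datasets import SpectroDataset
from .irf_ca import (
    IRFModel,
    Oscillation,
    OscillationSpectra,
    amp_phase_from_coefficients,
    damped_oscillation_basis,
    dispersion_center,
    irf_value,
    scatter_column,
)
from .kinetics import (
    KineticScheme,
    SpectraMatrix,
    concentration_stack,
    sequential_scheme,
    solve_concentrations,
    transform_spectra,
)
from .parameters import Parameter, ParameterSet

__all__ = [
    "TargetAnalysisModel",
    "TargetAnalysisResults",
    "build_design_matrix",
    "solve_conditionally_linear",
    "fit_model",
]

#: relative singular-value cutoff for the rank-revealing linear solves
LINEAR_RCOND = 1e-10


def solve_conditionally_linear(design, observations, rcond: float = LINEAR_RCOND):
    """Minimum-norm least-squares amplitudes and the exact residual.

    Parameters
    ----------
    design : array (..., n_delays, n_components)
        Design matrix (may be stacked over pixels in leading dimensions).
    observations : array (..., n_delays)
    rcond : float
        Singular values below ``rcond * s_max`` are truncated, so duplicated
        or fully damped columns degrade gracefully to the minimum-norm
        solution.

    Returns
    -------
    amplitudes : array (..., n_components)
    residual : array (..., n_delays)
        Exactly ``observations - design @ amplitudes``.
    """
    design = np.asarray(design, dtype=float)
    observations = np.asarray(observations, dtype=float)
    n_rows, n_cols = design.shape[-2:]
    if n_rows < n_cols:
        raise ValueError(
            f"underdetermined linear system: {n_rows} delays < {n_cols} "
            "components (too few delays)"
        )
    pinv = np.linalg.pinv(design, rcond=rcond)
    amplitudes = np.einsum("...ct,...t->...c", pinv, observations)
    residual = observations - np.einsum("...tc,...c->...t", design, amplitudes)
    return amplitudes, residual


def build_design_matrix(
    delays: np.ndarray,
    x: float,
    scheme: KineticScheme,
    irf: IRFModel,
    oscillations: tuple[Oscillation, ...] = (),
    scatter_threshold: float | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for one pixel: delay x component, with column labels.

    Column order (deterministic): compartment concentrations in scheme order,
    then per oscillation a cosine and a sine basis, then the scatter column if
    a threshold is given.  An all-zero column (fully damped oscillation,
    masked scatter) is retained; rank handling is the linear solver's job.
    """
    mu = float(dispersion_center(irf, x))
    conc = solve_concentrations(scheme, delays, mu=mu, sigma=irf.sigma)
    cols = [conc.values[:, i] for i in range(scheme.n_compartments)]
    labels = list(scheme.compartments)
    for osc in oscillations:
        c, s = damped_oscillation_basis(osc, delays, irf, x)
        cols += [c, s]
        labels += [f"{osc.label}_cos", f"{osc.label}_sin"]
    if scatter_threshold is not None:
        cols.append(scatter_column(irf, delays, x, scatter_threshold))
        labels.append("scatter")
    return np.column_stack(cols), labels


class TargetAnalysisModel:
    """Simultaneous kinetic-scheme fit of one or more time-resolved surfaces.

    Parameters
    ----------
    datasets : list of SpectroDataset
        Experiments fitted simultaneously.  Each dataset's ``irf_group``
        selects an entry of ``irfs``; ``use_oscillations`` and
        ``scatter_threshold`` control its coherent-artifact columns.
    scheme : KineticScheme
        The kinetic scheme (shared by all datasets; its channel rates become
        the parameters ``k_<from>_<to>`` in ns^-1).
    irfs : dict[str, IRFModel] or IRFModel
        IRF per group.  IRFs sharing a ``link_group`` share one width
        parameter.
    oscillations : sequence of Oscillation
        Damped oscillations of the coherent artifact (parameters
        ``<label>_omega`` in cm^-1 and ``<label>_gamma`` in ps^-1), applied to
        datasets with ``use_oscillations=True``.
    parameters : ParameterSet or None
        Starting parameters; built from the supplied objects when omitted
        (see :meth:`default_parameters`).
    """

    def __init__(
        self,
        datasets: list[SpectroDataset],
        scheme: KineticScheme,
        irfs: dict[str, IRFModel] | IRFModel,
        oscillations: tuple[Oscillation, ...] = (),
        parameters: ParameterSet | None = None,
    ):
        if not datasets:
            raise ValueError("at least one dataset is required")
        self.datasets = list(datasets)
        self.scheme = scheme
        if isinstance(irfs, IRFModel):
            irfs = {d.irf_group: irfs for d in datasets}
        self.irfs = dict(irfs)
        for d in self.datasets:
            if d.irf_group not in self.irfs:
                raise ValueError(
                    f"dataset {d.name!r}: no IRF for group {d.irf_group!r}"
                )
        self.oscillations = tuple(oscillations)
        labels = [o.label for o in self.oscillations]
        if len(set(labels)) != len(labels):
            raise ValueError("oscillation labels must be unique")
        self.parameters = (
            parameters if parameters is not None else self.default_parameters()
        )

    # ------------------------------------------------------------------
    def default_parameters(self) -> ParameterSet:
        """ParameterSet built from the scheme, IRFs and oscillations.

        Rates and damping constants are log-scale and strictly positive; IRF
        centers and dispersion coefficients are linear.  Dispersion
        coefficients default to ``vary=False`` (enable explicitly when the
        chirp is to be estimated); widths sharing an IRF ``link_group`` are
        linked.
        """
        params = ParameterSet()
        for ch in self.scheme.channels:
            if ch.name in params:
                raise ValueError(f"duplicate channel parameter {ch.name}")
            params.add(
                Parameter(ch.name, ch.rate, minimum=1e-12, scale="log")
            )
        for group, irf in self.irfs.items():
            params.add(Parameter(f"irf_{group}_mu0", irf.mu0, scale="lin"))
            params.add(
                Parameter(
                    f"irf_{group}_sigma",
                    irf.sigma,
                    minimum=1e-6,
                    scale="log",
                    link=irf.link_group,
                )
            )
            for p, d in enumerate(irf.dispersion, start=1):
                params.add(
                    Parameter(f"irf_{group}_d{p}", d, scale="lin", vary=False)
                )
        for osc in self.oscillations:
            params.add(Parameter(f"{osc.label}_omega", osc.omega, scale="lin"))
            params.add(
                Parameter(f"{osc.label}_gamma", osc.gamma, minimum=1e-6, scale="log")
            )
        return params

    # ------------------------------------------------------------------
    def _scheme_at(self, params: ParameterSet) -> KineticScheme:
        rates = {
            ch.name: params.value(ch.name)
            for ch in self.scheme.channels
            if ch.name in params
        }
        return self.scheme.with_rates(rates)

    def _irf_at(self, params: ParameterSet, group: str) -> IRFModel:
        base = self.irfs[group]
        disp = tuple(
            params.value(f"irf_{group}_d{p}")
            if f"irf_{group}_d{p}" in params
            else base.dispersion[p - 1]
            for p in range(1, len(base.dispersion) + 1)
        )
        return IRFModel(
            mu0=params.value(f"irf_{group}_mu0"),
            sigma=params.value(f"irf_{group}_sigma"),
            dispersion=disp,
            center=base.center,
            link_group=base.link_group,
        )

    def _oscillations_at(self, params: ParameterSet) -> tuple[Oscillation, ...]:
        return tuple(
            Oscillation(
                omega=params.value(f"{o.label}_omega"),
                gamma=params.value(f"{o.label}_gamma"),
                direction=o.direction,
                label=o.label,
            )
            for o in self.oscillations
        )

    def design_stack(
        self, dataset: SpectroDataset, params: ParameterSet | None = None
    ) -> tuple[np.ndarray, list[str]]:
        """Vectorized design over all pixels: (n_pixels, n_delays, n_cols)."""
        params = self.parameters if params is None else params
        scheme = self._scheme_at(params)
        irf = self._irf_at(params, dataset.irf_group)
        oscs = self._oscillations_at(params) if dataset.use_oscillations else ()
        t, x = dataset.delays, dataset.axis
        mu = np.atleast_1d(dispersion_center(irf, x))
        blocks: list[np.ndarray] = []
        labels: list[str] = []
        conc = concentration_stack(scheme, t, mu, irf.sigma)  # (n_t, n_px, n_c)
        blocks.append(conc)
        labels += list(scheme.compartments)
        for osc in oscs:
            c, s = damped_oscillation_basis(osc, t, irf, x)
            blocks.append(np.stack([c, s], axis=-1))
            labels += [f"{osc.label}_cos", f"{osc.label}_sin"]
        if dataset.scatter_threshold is not None:
            prof = irf_value(irf, t[:, None], x[None, :])
            prof = np.where(x[None, :] <= dataset.scatter_threshold, prof, 0.0)
            blocks.append(prof[:, :, None])
            labels.append("scatter")
        design = np.concatenate(blocks, axis=-1)  # (n_t, n_px, n_cols)
        return np.transpose(design, (1, 0, 2)), labels

    def evaluate(self, params: ParameterSet | None = None) -> dict[str, dict]:
        """Solve the conditionally linear amplitudes for every dataset.

        Returns a dict keyed by dataset name with ``design`` (pixel-stacked),
        ``labels``, ``amplitudes`` (n_pixels, n_cols), ``model`` and
        ``residual`` matrices (n_delays, n_pixels).
        """
        params = self.parameters if params is None else params
        out: dict[str, dict] = {}
        for d in self.datasets:
            design, labels = self.design_stack(d, params)
            obs = d.data.T  # (n_px, n_t)
            amps, resid = solve_conditionally_linear(design, obs)
            model = d.data - resid.T
            out[d.name] = {
                "design": design,
                "labels": labels,
                "amplitudes": amps,
                "model": model,
                "residual": resid.T,
            }
        return out

    @property
    def n_residuals(self) -> int:
        return sum(d.data.size for d in self.datasets)

    def objective(self, x: np.ndarray) -> np.ndarray:
        """Stacked weighted residual vector at internal free values ``x``.

        A parameter vector that renders the scheme eigen-degenerate (the
        optimizer may drive two compartments' total rates together while
        exploring) yields a uniformly large residual so the step is
        rejected, rather than aborting the fit.
        """
        from .kinetics import SchemeError

        try:
            return self._objective(x)
        except SchemeError:
            return np.full(self.n_residuals, 1e6)

    def _objective(self, x: np.ndarray) -> np.ndarray:
        params = self.parameters.with_internal(x)
        pieces = []
        for d in self.datasets:
            design, _ = self.design_stack(d, params)
            _, resid = solve_conditionally_linear(design, d.data.T)
            if not np.all(np.isfinite(resid)):
                bad = np.argwhere(~np.isfinite(resid))
                raise FloatingPointError(
                    f"non-finite residual in dataset {d.name!r} at "
                    f"(pixel, delay) {tuple(bad[0])}"
                )
            pieces.append(d.weight * resid.ravel())
        return np.concatenate(pieces)

    # ------------------------------------------------------------------
    def fit(
        self,
        max_iter: int = 200,
        ftol: float = 1e-8,
        xtol: float = 1e-8,
        gtol: float = 1e-8,
        diff_step: float = 1e-6,
        anchor: float | None = None,
        verbose: int = 0,
    ) -> "TargetAnalysisResults":
        """Trust-region nonlinear least squares over the free parameters.

        Amplitudes are re-solved at the optimum and split into SADS,
        DOAS/phase and IRFAS; standard errors come from the projected
        Jacobian at the optimum.  Non-convergence within ``max_iter``
        returns a result with ``success=False`` plus diagnostics.

        Parameters
        ----------
        anchor : float or None
            Minimum-norm tie-break for rank-deficient nonlinear directions.
            Target schemes contain parameter combinations the data cannot
            determine — e.g. branching between a spectrally free state and a
            dark ground-state loss rescales a population that its free
            spectrum absorbs exactly, so the objective is flat along that
            combination and an unregularized trust-region step drifts
            arbitrarily along it.  With ``anchor=a`` the residual vector is
            augmented with ``a * (x - x0)`` in the internal (log) parameter
            space, selecting the point of the optimal manifold nearest the
            starting values; ``a`` should be negligible against the data
            residuals (1e-3 is ample — data residual norms are O(10-100))
            so determined directions are untouched.
        """
        params = self.parameters.copy()
        x0 = params.to_internal()
        if x0.size == 0:
            opt = None
            x_opt = x0
        else:
            lo, hi = params.internal_bounds()
            if anchor is None:
                fun = self.objective
            else:
                a = float(anchor)

                def fun(x, _x0=x0.copy()):
                    return np.concatenate([self.objective(x), a * (x - _x0)])

            opt = least_squares(
                fun,
                x0,
                bounds=(lo, hi),
                method="trf",
                max_nfev=max_iter * max(1, x0.size + 1),
                ftol=ftol,
                xtol=xtol,
                gtol=gtol,
                diff_step=diff_step,
                verbose=verbose,
            )
            x_opt = opt.x
        params_opt = params.with_internal(x_opt) if x_opt.size else params

        cov = None
        if opt is not None:
            m, n = opt.jac.shape
            if m > n:
                s2 = 2.0 * opt.cost / (m - n)
                jtj_inv = np.linalg.pinv(opt.jac.T @ opt.jac, rcond=1e-14)
                cov = s2 * jtj_inv
                params_opt.set_stderr_from_internal(np.sqrt(np.diag(cov)))
        return TargetAnalysisResults(self, params_opt, opt, cov)


def fit_model(
    datasets,
    scheme,
    irfs,
    oscillations=(),
    parameters=None,
    **fit_options,
) -> "TargetAnalysisResults":
    """One-call convenience: construct a :class:`TargetAnalysisModel` and fit."""
    model = TargetAnalysisModel(datasets, scheme, irfs, oscillations, parameters)
    return model.fit(**fit_options)


@dataclass
class _DatasetFit:
    labels: list[str]
    amplitudes: np.ndarray
    model: np.ndarray
    residual: np.ndarray


class TargetAnalysisResults:
    """Estimates, uncertainties, spectra and diagnostics of a fit."""

    def __init__(self, model: TargetAnalysisModel, parameters, optimizer, cov):
        self.model = model
        self.parameters = parameters
        self._optimizer = optimizer
        self.cov_internal = cov
        self.success = bool(optimizer.success) if optimizer is not None else True
        self.nfev = int(optimizer.nfev) if optimizer is not None else 0
        self.message = optimizer.message if optimizer is not None else "no free parameters"
        ev = model.evaluate(parameters)
        self._fits = {
            name: _DatasetFit(
                e["labels"], e["amplitudes"], e["model"], e["residual"]
            )
            for name, e in ev.items()
        }
        sq = 0.0
        npts = 0
        for d in model.datasets:
            r = self._fits[d.name].residual
            sq += float(np.sum((d.weight * r) ** 2))
            npts += r.size
        self.n_data = npts
        self.cost = 0.5 * sq
        self.rmse = np.sqrt(sq / npts)

    # -- accessors ------------------------------------------------------
    def _dataset(self, name: str) -> SpectroDataset:
        for d in self.model.datasets:
            if d.name == name:
                return d
        raise KeyError(f"unknown dataset {name!r}")

    def _fit(self, name: str) -> _DatasetFit:
        return self._fits[name]

    def residual(self, name: str) -> np.ndarray:
        return self._fit(name).residual

    def model_matrix(self, name: str) -> np.ndarray:
        return self._fit(name).model

    def dataset_rmse(self, name: str) -> float:
        return float(np.sqrt(np.mean(self._fit(name).residual ** 2)))

    def sads(self, name: str) -> SpectraMatrix:
        """Species-associated difference spectra of one dataset (mOD)."""
        d = self._dataset(name)
        f = self._fit(name)
        n_c = self.model.scheme.n_compartments
        return SpectraMatrix(
            d.axis, f.amplitudes[:, :n_c], list(self.model.scheme.compartments)
        )

    def oscillation_spectra(self, name: str) -> OscillationSpectra | None:
        """DOAS amplitude and phase spectra of one dataset, or None."""
        d = self._dataset(name)
        if not d.use_oscillations or not self.model.oscillations:
            return None
        f = self._fit(name)
        amps, phases, labels = [], [], []
        for osc in self.model.oscillations:
            i_c = f.labels.index(f"{osc.label}_cos")
            i_s = f.labels.index(f"{osc.label}_sin")
            a, p = amp_phase_from_coefficients(
                f.amplitudes[:, i_c], f.amplitudes[:, i_s]
            )
            amps.append(a)
            phases.append(p)
            labels.append(osc.label)
        return OscillationSpectra(
            d.axis, np.column_stack(amps), np.column_stack(phases), labels
        )

    def irfas(self, name: str) -> np.ndarray | None:
        """IRF-associated (scatter) spectrum of one dataset, or None."""
        f = self._fit(name)
        if "scatter" not in f.labels:
            return None
        return f.amplitudes[:, f.labels.index("scatter")]

    def fitted_scheme(self) -> KineticScheme:
        return self.model._scheme_at(self.parameters)

    def fitted_irf(self, group: str) -> IRFModel:
        return self.model._irf_at(self.parameters, group)

    def fitted_oscillations(self) -> tuple[Oscillation, ...]:
        return self.model._oscillations_at(self.parameters)

    # -- derived quantities --------------------------------------------
    def lifetimes(self) -> dict[str, float]:
        """Compartment lifetimes 1/(total outgoing rate), ps."""
        scheme = self.fitted_scheme()
        return {c: scheme.lifetime(c) for c in scheme.compartments}

    def branching_fractions(self) -> dict[str, dict[str, float]]:
        """Per-compartment channel fractions rate_i / total outgoing rate."""
        scheme = self.fitted_scheme()
        return {
            c: scheme.branching_fractions(c)
            for c in scheme.compartments
            if scheme.outgoing(c)
        }

    def derived_stderr(self, func) -> float:
        """Delta-method standard error of ``func(parameters)`` (scalar).

        ``func`` maps a ParameterSet to a scalar; the gradient is taken by
        central differences in the internal (optimizer) space and propagated
        through the parameter covariance.
        """
        if self.cov_internal is None:
            return float("nan")
        x = self.parameters.to_internal()
        h = 1e-6
        grad = np.zeros_like(x)
        for i in range(x.size):
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            grad[i] = (
                func(self.parameters.with_internal(xp))
                - func(self.parameters.with_internal(xm))
            ) / (2 * h)
        return float(np.sqrt(grad @ self.cov_internal @ grad))

    def lifetime_stderr(self, compartment: str) -> float:
        def f(params):
            return self.model._scheme_at(params).lifetime(compartment)

        return self.derived_stderr(f)

    def branching_stderr(self, compartment: str, target: str) -> float:
        def f(params):
            return self.model._scheme_at(params).branching_fractions(compartment)[
                target
            ]

        return self.derived_stderr(f)

    # -- representations ------------------------------------------------
    def eads(self, name: str) -> SpectraMatrix:
        """Evolution-associated difference spectra via the matched cascade.

        Builds the loss-free sequential scheme whose lifetimes are the
        eigen-lifetimes of the fitted target scheme and linearly transforms
        the SADS into that representation.
        """
        d = self._dataset(name)
        scheme = self.fitted_scheme()
        irf = self.fitted_irf(d.irf_group)
        from .kinetics import build_k_matrix

        lam = np.linalg.eigvals(build_k_matrix(scheme, unit="ps"))
        lam = np.sort(np.real(lam))  # most negative (fastest) first
        lifetimes = [np.inf if abs(l) < 1e-15 else -1.0 / l for l in lam]
        lifetimes = sorted(lifetimes)
        seq = sequential_scheme(lifetimes)
        mu_mid = float(np.median(np.atleast_1d(dispersion_center(irf, d.axis))))
        c_target = solve_concentrations(scheme, d.delays, mu_mid, irf.sigma)
        c_seq = solve_concentrations(seq, d.delays, mu_mid, irf.sigma)
        return transform_spectra(c_target, self.sads(name), c_seq)

    def decompose(self, name: str) -> dict[str, np.ndarray]:
        """Split the fitted surface into population, CA and scatter terms.

        The three matrices sum to the model surface exactly, and model +
        residual reproduces the data elementwise.
        """
        d = self._dataset(name)
        f = self._fit(name)
        design, labels = self.model.design_stack(d, self.parameters)
        n_c = self.model.scheme.n_compartments
        amps = f.amplitudes

        def recombine(idx: list[int]) -> np.ndarray:
            if not idx:
                return np.zeros_like(d.data)
            sub = design[:, :, idx]  # (n_px, n_t, k)
            return np.einsum("ptk,pk->tp", sub, amps[:, idx])

        pop_idx = list(range(n_c))
        ca_idx = [i for i, lab in enumerate(labels) if "_cos" in lab or "_sin" in lab]
        sc_idx = [i for i, lab in enumerate(labels) if lab == "scatter"]
        return {
            "populations": recombine(pop_idx),
            "coherent_artifact": recombine(ca_idx),
            "scatter": recombine(sc_idx),
        }

    # -- reporting ------------------------------------------------------
    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        lines = []
        lines.append("Simultaneous target analysis".center(72))
        lines.append("=" * 72)
        for d in self.model.datasets:
            lines.append(
                f"dataset {d.name}: {d.n_delays} delays x {d.n_pixels} pixels "
                f"({d.domain}), weight {d.weight:g}, "
                f"rmse {self.dataset_rmse(d.name):.4g} mOD"
            )
        lines.append(
            f"free nonlinear parameters: {self.parameters.n_free}   "
            f"data points: {self.n_data}   nfev: {self.nfev}"
        )
        lines.append(
            f"converged: {self.success}   weighted rmse: {self.rmse:.4g} mOD"
        )
        lines.append("-" * 72)
        lines.append(f"{'parameter':<24}{'value':>14}{'stderr':>14}  linked")
        for p in self.parameters:
            se = f"{p.stderr:.3g}" if p.stderr is not None else "-"
            link = p.link or ""
            flag = "" if p.vary else " (fixed)"
            lines.append(f"{p.name:<24}{p.value:>14.6g}{se:>14}  {link}{flag}")
        lines.append("-" * 72)
        scheme = self.fitted_scheme()
        taus = ", ".join(
            f"{c}: {scheme.lifetime(c):.4g} ps" for c in scheme.compartments
        )
        lines.append(f"lifetimes 1/sum(k): {taus}")
        for c, fr in self.branching_fractions().items():
            if len(fr) > 1:
                txt = ", ".join(f"->{t}: {100 * v:.1f}%" for t, v in fr.items())
                lines.append(f"branching from {c}: {txt}")
        lines.append("=" * 72)
        return "\n".join(lines)

    # -- plotting -------------------------------------------------------
    def plot_sads(self, name: str, ax=None):
        """Plot SADS of one dataset; returns the matplotlib Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.sads(name)
        for i, comp in enumerate(s.components):
            ax.plot(s.axis, s.values[:, i], label=comp)
        d = self._dataset(name)
        ax.set_xlabel("wavenumber (cm$^{-1}$)" if d.domain == "wavenumber" else "wavelength (nm)")
        ax.set_ylabel("SADS (mOD)")
        ax.legend(fontsize="small")
        return ax

    def plot_doas(self, name: str, ax=None):
        """Plot DOAS amplitude spectra of one dataset; returns the Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        spec = self.oscillation_spectra(name)
        if spec is None:
            raise ValueError(f"dataset {name!r} has no oscillations")
        for i, lab in enumerate(spec.labels):
            ax.plot(spec.axis, spec.amplitudes[:, i], label=lab)
        ax.set_xlabel("wavenumber (cm$^{-1}$)")
        ax.set_ylabel("DOAS (mOD)")
        ax.legend(fontsize="small")
        return ax

    def plot_residual(self, name: str, ax=None):
        """Residual surface heat map; returns the Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = self._dataset(name)
        r = self.residual(name)
        im = ax.pcolormesh(d.axis, d.delays, r, shading="auto", cmap="RdBu_r")
        ax.figure.colorbar(im, ax=ax, label="residual (mOD)")
        ax.set_ylabel("delay (ps)")
        return ax
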