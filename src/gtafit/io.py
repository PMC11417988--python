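"""Reading/writing time-resolved spectral matrices, configs and reports.

Data files are plain tab-separated matrices — the field's legacy
"time x wavelength" layout: the first header cell names the delay column,
the remaining header cells are the spectral axis values; each subsequent row
starts with the delay (ps) followed by the signal in mOD.  A JSON sidecar
(same path + ``.json``) records the domain, sign convention, weight and
model flags.  Run configs are YAML documents validated against a strict
schema (unknown keys rejected) before any computation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .datasets import SpectroDataset
from .irf_ca import IRFModel, Oscillation
from .kinetics import Channel, KineticScheme
from .varpro import TargetAnalysisModel, TargetAnalysisResults

logger = logging.getLogger("gtafit")

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_matrix",
    "write_matrix",
    "load_config",
    "RunConfig",
    "RunSummary",
    "build_model_from_config",
    "report",
]

_FLOAT_FMT = "%.17g"


# ----------------------------------------------------------------------
# matrices
# ----------------------------------------------------------------------
def write_matrix(
    path: str | Path,
    delays: np.ndarray,
    axis: np.ndarray,
    values: np.ndarray,
    index_label: str = "delay_ps",
) -> None:
    """Write a delay x pixel matrix as tab-separated text."""
    df = pd.DataFrame(values, index=delays, columns=axis)
    df.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def read_matrix(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a tab-separated matrix; returns (delays, axis, values)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
        axis = df.columns.to_numpy(dtype=float)
        delays = df.index.to_numpy(dtype=float)
        values = df.to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: cannot parse matrix file: {exc}") from exc
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a rectangular matrix")
    return delays, axis, values


def write_dataset(dataset: SpectroDataset, path: str | Path) -> None:
    """Write a dataset as TSV matrix + JSON sidecar (``path + '.json'``)."""
    path = Path(path)
    write_matrix(path, dataset.delays, dataset.axis, dataset.data)
    sidecar = {
        "name": dataset.name,
        "domain": dataset.domain,
        "delay_unit": "ps",
        "axis_unit": "cm-1" if dataset.domain == "wavenumber" else "nm",
        "signal_unit": "mOD",
        "weight": dataset.weight,
        "sign_convention": dataset.sign_convention,
        "scatter_threshold": dataset.scatter_threshold,
        "use_oscillations": dataset.use_oscillations,
        "irf_group": dataset.irf_group,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_dataset(
    path: str | Path,
    sidecar: dict | str | Path | None = None,
    flip_sign: bool = False,
) -> SpectroDataset:
    """Read a TSV matrix (+ sidecar metadata) into a :class:`SpectroDataset`.

    Axes are sorted ascending if needed (with a logged warning); with
    ``flip_sign`` the signal sign is inverted on ingest and the convention
    recorded as ``"flipped"`` (e.g. to plot anti-Stokes loss as positive).
    """
    path = Path(path)
    delays, axis, values = read_matrix(path)
    if sidecar is None:
        default = Path(str(path) + ".json")
        meta = json.loads(default.read_text()) if default.exists() else {}
    elif isinstance(sidecar, (str, Path)):
        meta = json.loads(Path(sidecar).read_text())
    else:
        meta = dict(sidecar)

    order_t = np.argsort(delays)
    if not np.array_equal(order_t, np.arange(delays.size)):
        logger.warning("%s: delay rows were not sorted; sorting ascending", path)
        delays, values = delays[order_t], values[order_t]
    order_x = np.argsort(axis)
    if not np.array_equal(order_x, np.arange(axis.size)):
        logger.warning("%s: spectral columns were not sorted; sorting", path)
        axis, values = axis[order_x], values[:, order_x]
    if np.any(np.diff(delays) <= 0) or np.any(np.diff(axis) <= 0):
        raise ValueError(f"{path}: axis not strictly monotone after sorting")
    nan_cols = np.isnan(values).any(axis=0)
    if nan_cols.any():
        logger.warning(
            "%s: dropping %d pixels containing NaNs", path, int(nan_cols.sum())
        )
        axis, values = axis[~nan_cols], values[:, ~nan_cols]

    sign_convention = meta.get("sign_convention", "raw")
    if flip_sign:
        values = -values
        sign_convention = "flipped" if sign_convention == "raw" else "raw"
    return SpectroDataset(
        name=meta.get("name", path.stem),
        delays=delays,
        axis=axis,
        data=values,
        domain=meta.get("domain", "wavenumber"),
        weight=meta.get("weight", 1.0),
        sign_convention=sign_convention,
        scatter_threshold=meta.get("scatter_threshold"),
        use_oscillations=meta.get("use_oscillations", False),
        irf_group=meta.get("irf_group", "default"),
        meta=meta,
    )


# ----------------------------------------------------------------------
# run configuration (strict schema)
# ----------------------------------------------------------------------
class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ChannelConfig(_Strict):
    source: str
    target: str
    rate: float = Field(ge=0, description="ns^-1")
    vary: bool = True


class SchemeConfig(_Strict):
    compartments: list[str]
    channels: list[ChannelConfig]
    inputs: dict[str, float] | None = None


class IRFConfig(_Strict):
    mu0: float = 0.0
    fwhm_ps: float = Field(gt=0, description="IRF fwhm in ps")
    dispersion: list[float] = Field(default_factory=list)
    center: float = 0.0
    link_group: str | None = None
    vary_mu0: bool = True
    vary_sigma: bool = True
    vary_dispersion: bool = False


class OscillationConfig(_Strict):
    omega: float = Field(description="cm^-1")
    gamma: float = Field(gt=0, description="ps^-1")
    direction: str = "backward"
    label: str | None = None
    vary: bool = True


class DatasetConfig(_Strict):
    name: str
    path: str
    domain: str = "wavenumber"
    weight: float = 1.0
    flip_sign: bool = False
    scatter_threshold: float | None = None
    oscillations: bool = False
    irf: str = "default"


class OptimizerConfig(_Strict):
    max_iter: int = 200
    ftol: float = 1e-8
    xtol: float = 1e-8
    gtol: float = 1e-8
    diff_step: float = 1e-4
    anchor: float | None = None


class RunConfig(_Strict):
    """Schema of a fit run: datasets, scheme, IRFs, oscillations, optimizer."""

    seed: int = 0
    scheme: SchemeConfig
    irf: dict[str, IRFConfig]
    oscillations: list[OscillationConfig] = Field(default_factory=list)
    datasets: list[DatasetConfig]
    optimizer: OptimizerConfig = Field(default_factory=OptimizerConfig)


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML run config (unknown keys rejected)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))


def build_model_from_config(
    config: RunConfig, data_dir: str | Path
) -> TargetAnalysisModel:
    """Assemble a :class:`TargetAnalysisModel` from a validated config."""
    data_dir = Path(data_dir)
    scheme = KineticScheme(
        compartments=list(config.scheme.compartments),
        channels=[
            Channel(c.source, c.target, c.rate) for c in config.scheme.channels
        ],
        inputs=(
            None
            if config.scheme.inputs is None
            else np.array(
                [
                    config.scheme.inputs.get(c, 0.0)
                    for c in config.scheme.compartments
                ]
            )
        ),
    )
    irfs = {
        group: IRFModel(
            mu0=c.mu0,
            sigma=c.fwhm_ps / _FWHM,
            dispersion=tuple(c.dispersion),
            center=c.center,
            link_group=c.link_group,
        )
        for group, c in config.irf.items()
    }
    oscillations = tuple(
        Oscillation(o.omega, o.gamma, o.direction, o.label)
        for o in config.oscillations
    )
    datasets = []
    for dc in config.datasets:
        ds = read_dataset(data_dir / dc.path, flip_sign=dc.flip_sign)
        ds.name = dc.name
        ds.domain = dc.domain
        ds.weight = dc.weight
        ds.scatter_threshold = dc.scatter_threshold
        ds.use_oscillations = dc.oscillations
        ds.irf_group = dc.irf
        datasets.append(ds)
    model = TargetAnalysisModel(datasets, scheme, irfs, oscillations)
    for c in config.scheme.channels:
        model.parameters[f"k_{c.source}_{c.target}"].vary = c.vary
    for group, c in config.irf.items():
        model.parameters[f"irf_{group}_mu0"].vary = c.vary_mu0
        model.parameters[f"irf_{group}_sigma"].vary = c.vary_sigma
        for p in range(1, len(c.dispersion) + 1):
            model.parameters[f"irf_{group}_d{p}"].vary = c.vary_dispersion
    for o, oc in zip(oscillations, config.oscillations):
        model.parameters[f"{o.label}_omega"].vary = oc.vary
        model.parameters[f"{o.label}_gamma"].vary = oc.vary
    return model


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------
class LifetimeEntry(_Strict):
    value_ps: float | None  # None encodes a non-decaying (long-lived) state
    stderr_ps: float | None = None


class BranchingEntry(_Strict):
    fraction: float
    stderr: float | None = None


class ReproducibilityBlock(_Strict):
    config_sha256: str | None = None
    seed: int | None = None
    version: str


class RunSummary(_Strict):
    """Schema of the JSON run summary written by :func:`report`."""

    rmse: float
    n_iterations: int
    converged: bool
    n_free_parameters: int
    n_data_points: int
    dataset_rmse: dict[str, float]
    lifetimes_ps: dict[str, LifetimeEntry]
    branching: dict[str, dict[str, BranchingEntry]]
    reproducibility: ReproducibilityBlock


def report(
    results: TargetAnalysisResults,
    out_dir: str | Path,
    config_path: str | Path | None = None,
    seed: int | None = None,
) -> RunSummary:
    """Write parameter/spectra/decomposition tables and the JSON summary.

    Outputs per dataset: SADS, EADS, DOAS amplitude and phase, IRFAS,
    residual matrix and the population/coherent-artifact/scatter
    decomposition; globally: the parameter table (value, stderr, link) and a
    schema-validated JSON summary with derived lifetimes (1/sum of outgoing
    rates) and branching fractions (rate over total) with linearized
    standard errors, plus a reproducibility block (config hash, seed,
    version).
    """
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise IOError(f"cannot write to {out}")

    rows = [
        {
            "name": p.name,
            "value": p.value,
            "stderr": p.stderr,
            "vary": p.vary,
            "linked_to": p.link or "",
        }
        for p in results.parameters
    ]
    pd.DataFrame(rows).to_csv(out / "parameters.tsv", sep="\t", index=False)

    for d in results.model.datasets:
        name = d.name
        sads = results.sads(name)
        pd.DataFrame(
            sads.values, index=sads.axis, columns=sads.components
        ).to_csv(out / f"{name}_sads.tsv", sep="\t", index_label="axis")
        eads = results.eads(name)
        pd.DataFrame(
            eads.values, index=eads.axis, columns=eads.components
        ).to_csv(out / f"{name}_eads.tsv", sep="\t", index_label="axis")
        osc = results.oscillation_spectra(name)
        if osc is not None:
            pd.DataFrame(
                osc.amplitudes, index=osc.axis, columns=osc.labels
            ).to_csv(out / f"{name}_doas.tsv", sep="\t", index_label="axis")
            pd.DataFrame(
                osc.phases, index=osc.axis, columns=osc.labels
            ).to_csv(out / f"{name}_phase.tsv", sep="\t", index_label="axis")
        irfas = results.irfas(name)
        if irfas is not None:
            pd.DataFrame({"irfas": irfas}, index=d.axis).to_csv(
                out / f"{name}_irfas.tsv", sep="\t", index_label="axis"
            )
        write_matrix(out / f"{name}_residual.tsv", d.delays, d.axis,
                     results.residual(name))
        for term, mat in results.decompose(name).items():
            write_matrix(out / f"{name}_{term}.tsv", d.delays, d.axis, mat)

    scheme = results.fitted_scheme()
    lifetimes = {
        c: LifetimeEntry(
            value_ps=(
                scheme.lifetime(c) if np.isfinite(scheme.lifetime(c)) else None
            ),
            stderr_ps=(
                results.lifetime_stderr(c)
                if np.isfinite(scheme.lifetime(c))
                else None
            ),
        )
        for c in scheme.compartments
    }
    branching = {
        c: {
            target: BranchingEntry(
                fraction=frac, stderr=results.branching_stderr(c, target)
            )
            for target, frac in scheme.branching_fractions(c).items()
        }
        for c in scheme.compartments
        if scheme.outgoing(c)
    }
    sha = None
    if config_path is not None:
        sha = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    summary = RunSummary(
        rmse=results.rmse,
        n_iterations=results.nfev,
        converged=results.success,
        n_free_parameters=results.parameters.n_free,
        n_data_points=results.n_data,
        dataset_rmse={
            d.name: results.dataset_rmse(d.name) for d in results.model.datasets
        },
        lifetimes_ps=lifetimes,
        branching=branching,
        reproducibility=ReproducibilityBlock(
            config_sha256=sha, seed=seed, version=__version__
        ),
    )
    (out / "summary.json").write_text(summary.model_dump_json(indent=1))
    (out / "summary.txt").write_text(results.summary() + "\n")
    return summary
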