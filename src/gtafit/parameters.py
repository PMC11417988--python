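"""Named nonlinear parameters with bounds, linking and optimizer transforms.

The nonlinear parameters of a simultaneous target analysis (channel rates,
IRF centers and widths, dispersion coefficients, oscillation frequencies and
damping rates) are held in a :class:`ParameterSet`.  Parameters that share a
``link`` label share one underlying free value in the optimizer, which is how
e.g. a single IRF width is estimated across several experiments.  Rates and
damping constants are optimized in log space so positivity never becomes an
active bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

import numpy as np

__all__ = ["Parameter", "ParameterSet"]


@dataclass
class Parameter:
    """One named scalar with bounds, a vary flag and an optional link group.

    Parameters
    ----------
    name : str
        Unique identifier, e.g. ``"k_S1_Sstar"`` or ``"irf.fsrs.sigma"``.
    value : float
        Current value in natural (untransformed) units.
    minimum, maximum : float
        Box bounds in natural units.
    vary : bool
        Whether the optimizer may move this parameter.
    scale : {"lin", "log"}
        ``"log"`` parameters are optimized as ``log(value)``; requires a
        strictly positive value and lower bound.
    link : str or None
        Parameters sharing a link label share a single free value.
    """

    name: str
    value: float
    minimum: float = -np.inf
    maximum: float = np.inf
    vary: bool = True
    scale: str = "lin"
    link: str | None = None
    stderr: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.scale not in ("lin", "log"):
            raise ValueError(f"parameter {self.name!r}: unknown scale {self.scale!r}")
        if self.scale == "log" and self.value <= 0:
            raise ValueError(f"parameter {self.name!r}: log scale requires value > 0")
        if not (self.minimum <= self.value <= self.maximum):
            raise ValueError(
                f"parameter {self.name!r}: value {self.value} outside "
                f"bounds [{self.minimum}, {self.maximum}]"
            )

    def to_internal(self, value: float | None = None) -> float:
        v = self.value if value is None else value
        return float(np.log(v)) if self.scale == "log" else float(v)

    def from_internal(self, x: float) -> float:
        return float(np.exp(x)) if self.scale == "log" else float(x)

    def internal_bounds(self) -> tuple[float, float]:
        if self.scale == "log":
            lo = -np.inf if self.minimum <= 0 else np.log(self.minimum)
            hi = np.inf if np.isinf(self.maximum) else np.log(self.maximum)
            return lo, hi
        return self.minimum, self.maximum


class ParameterSet:
    """Ordered collection of :class:`Parameter` with link-group resolution."""

    def __init__(self, parameters: Iterable[Parameter] = ()):
        self._params: dict[str, Parameter] = {}
        for p in parameters:
            self.add(p)

    # -- container protocol -------------------------------------------------
    def add(self, param: Parameter) -> None:
        if param.name in self._params:
            raise ValueError(f"duplicate parameter name {param.name!r}")
        self._params[param.name] = param

    def __getitem__(self, name: str) -> Parameter:
        return self._params[name]

    def __contains__(self, name: str) -> bool:
        return name in self._params

    def __iter__(self) -> Iterator[Parameter]:
        return iter(self._params.values())

    def __len__(self) -> int:
        return len(self._params)

    def names(self) -> list[str]:
        return list(self._params)

    def copy(self) -> "ParameterSet":
        return ParameterSet(replace(p) for p in self)

    def value(self, name: str) -> float:
        return self._params[name].value

    def set_value(self, name: str, value: float) -> None:
        p = self._params[name]
        if not (p.minimum <= value <= p.maximum):
            raise ValueError(
                f"parameter {name!r}: value {value} outside bounds "
                f"[{p.minimum}, {p.maximum}]"
            )
        p.value = float(value)
        if p.link is not None:  # keep the whole link group coherent
            for q in self:
                if q.link == p.link:
                    q.value = float(value)

    # -- free-vector mapping ------------------------------------------------
    def _free_groups(self) -> list[list[Parameter]]:
        """Varying parameters grouped so each group maps to one free value."""
        groups: dict[str, list[Parameter]] = {}
        order: list[list[Parameter]] = []
        for p in self:
            if not p.vary:
                continue
            if p.link is None:
                order.append([p])
            elif p.link not in groups:
                groups[p.link] = [p]
                order.append(groups[p.link])
            else:
                groups[p.link].append(p)
        return order

    @property
    def n_free(self) -> int:
        return len(self._free_groups())

    def free_names(self) -> list[str]:
        """One representative name per free value (first member of each group)."""
        return [g[0].name for g in self._free_groups()]

    def to_internal(self) -> np.ndarray:
        return np.array([g[0].to_internal() for g in self._free_groups()])

    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        los, his = zip(*(g[0].internal_bounds() for g in self._free_groups()))
        return np.array(los), np.array(his)

    def set_internal(self, x: np.ndarray) -> None:
        groups = self._free_groups()
        if len(x) != len(groups):
            raise ValueError(f"expected {len(groups)} free values, got {len(x)}")
        for xi, group in zip(x, groups):
            v = group[0].from_internal(float(xi))
            for p in group:
                p.value = v

    def with_internal(self, x: np.ndarray) -> "ParameterSet":
        out = self.copy()
        out.set_internal(x)
        return out

    def internal_jacobian_scale(self) -> np.ndarray:
        """d(value)/d(internal) per free value — chain-rule factor for errors."""
        out = []
        for g in self._free_groups():
            p = g[0]
            out.append(p.value if p.scale == "log" else 1.0)
        return np.array(out)

    def set_stderr_from_internal(self, stderr_internal: np.ndarray) -> None:
        scale = self.internal_jacobian_scale()
        for se, g in zip(stderr_internal * scale, self._free_groups()):
            for p in g:
                p.stderr = float(se)

    def values_dict(self) -> dict[str, float]:
        return {p.name: p.value for p in self}

    def __repr__(self) -> str:
        rows = ", ".join(f"{p.name}={p.value:.6g}" for p in self)
        return f"ParameterSet({rows})"
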