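"""Catalog of two-population divergence scenarios.

All nine scenarios share a common backbone: an ancestral population of
relative size 1 at mutation-drift equilibrium splits at time ``T_total``
before the present into two descendant populations.  They differ in how
the ancestral size is partitioned, whether the founded deme grows, and in
which epoch (if any) gene flow occurs.

Families
--------
vicariance
    The ancestor fragments into constant-size pieces ``s`` (population 1)
    and ``1 - s`` (population 2); no post-split growth.
founder
    Population 1 (the source) keeps size ``1 - s``; population 2 (the
    founded deme) starts at size ``s`` and grows exponentially to ``nu2``
    over the whole divergence time (both epochs for two-epoch models).

Units follow the diffusion convention: sizes are relative to the ancestral
effective size ``N_ref``, times are in units of ``2 N_ref`` generations,
and migration rates ``M_ij = 2 N_ref m_ij`` scale the per-generation
fraction ``m_ij`` of population ``i`` replaced by migrants from ``j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

#: Default optimization box constraints, by parameter kind.
DEFAULT_BOUNDS = {
    "s": (0.01, 0.99),
    "nu": (1e-3, 100.0),
    "M": (0.0, 20.0),
    "T": (1e-3, 15.0),
}


def param_kind(name: str) -> str:
    if name == "s":
        return "s"
    if name.startswith("nu"):
        return "nu"
    if name.startswith("M"):
        return "M"
    if name.startswith("T"):
        return "T"
    raise ValueError(f"unknown parameter name {name!r}")


def default_bounds(param_names: Sequence[str]) -> list[tuple[float, float]]:
    return [DEFAULT_BOUNDS[param_kind(p)] for p in param_names]


@dataclass(frozen=True)
class Epoch:
    """One interval of constant demographic regime.

    ``nu1``/``nu2`` are either constants or callables of global time since
    the split (so that founder growth is continuous across epochs).
    """

    duration: float
    nu1: float | Callable[[float], float]
    nu2: float | Callable[[float], float]
    m12: float = 0.0  # migration into pop1 from pop2, units 2*N_ref*m
    m21: float = 0.0

    def size(self, which: int, tau: float) -> float:
        nu = self.nu1 if which == 1 else self.nu2
        return nu(tau) if callable(nu) else nu


def _founder_growth(s: float, nu2: float, t_total: float):
    """Continuous exponential trajectory from ``s`` at the split to
    ``nu2`` at the present."""
    if t_total <= 0:
        return lambda tau: nu2
    rate = np.log(nu2 / s) / t_total
    return lambda tau: s * np.exp(rate * tau)


@dataclass(frozen=True)
class ModelSpec:
    """A named divergence scenario with its free parameters."""

    name: str
    family: str  # "vicariance" | "founder"
    param_names: tuple[str, ...]
    _builder: Callable[..., list[Epoch]] = field(repr=False)

    @property
    def k(self) -> int:
        """Free-parameter count used by AIC."""
        return len(self.param_names)

    def validate(self, params: Mapping[str, float]) -> dict[str, float]:
        p = {}
        for name in self.param_names:
            if name not in params:
                raise ValueError(f"{self.name}: missing parameter {name!r}")
            v = float(params[name])
            lo, hi = DEFAULT_BOUNDS[param_kind(name)]
            if param_kind(name) == "s" and not (0.0 < v < 1.0):
                raise ValueError(f"{self.name}: s={v} outside (0, 1)")
            if param_kind(name) == "nu" and v <= 0:
                raise ValueError(f"{self.name}: {name}={v} must be > 0")
            if param_kind(name) == "M" and v < 0:
                raise ValueError(f"{self.name}: {name}={v} must be >= 0")
            if param_kind(name) == "T" and v < 0:
                raise ValueError(f"{self.name}: {name}={v} must be >= 0")
            p[name] = v
        extra = set(params) - set(self.param_names)
        if extra:
            raise ValueError(f"{self.name}: unknown parameters {sorted(extra)}")
        return p

    def epochs(self, params: Mapping[str, float]) -> list[Epoch]:
        """Epoch sequence (oldest first) for a parameter assignment."""
        return self._builder(**self.validate(params))

    def total_time(self, params: Mapping[str, float]) -> float:
        return sum(e.duration for e in self.epochs(params))

    def as_vector(self, params: Mapping[str, float]) -> np.ndarray:
        p = self.validate(params)
        return np.array([p[n] for n in self.param_names])

    def as_dict(self, vector: Sequence[float]) -> dict[str, float]:
        if len(vector) != len(self.param_names):
            raise ValueError("parameter vector length mismatch")
        return dict(zip(self.param_names, map(float, vector)))


# -- the nine catalog scenarios ------------------------------------------


def _vic_no_mig(s, T):
    return [Epoch(T, s, 1 - s)]


def _vic_anc_sym_mig(s, M, T1, T2):
    return [Epoch(T1, s, 1 - s, M, M), Epoch(T2, s, 1 - s)]


def _vic_sec_contact_sym_mig(s, M, T1, T2):
    return [Epoch(T1, s, 1 - s), Epoch(T2, s, 1 - s, M, M)]


def _founder_epochs(s, nu2, durations, migrations):
    t_total = sum(durations)
    growth = _founder_growth(s, nu2, t_total)
    return [Epoch(d, 1 - s, growth, m12, m21)
            for d, (m12, m21) in zip(durations, migrations)]


def _founder_nomig(s, nu2, T):
    return _founder_epochs(s, nu2, [T], [(0, 0)])


def _founder_sym(s, nu2, M, T):
    return _founder_epochs(s, nu2, [T], [(M, M)])


def _founder_asym(s, nu2, M12, M21, T):
    return _founder_epochs(s, nu2, [T], [(M12, M21)])


def _founder_anc_sym_mig(s, nu2, M, T1, T2):
    return _founder_epochs(s, nu2, [T1, T2], [(M, M), (0, 0)])


def _founder_sec_contact_sym(s, nu2, M, T1, T2):
    return _founder_epochs(s, nu2, [T1, T2], [(0, 0), (M, M)])


def _founder_sec_contact_asym(s, nu2, M12, M21, T1, T2):
    return _founder_epochs(s, nu2, [T1, T2], [(0, 0), (M12, M21)])


_CATALOG = [
    ModelSpec("vic_no_mig", "vicariance", ("s", "T"), _vic_no_mig),
    ModelSpec("vic_anc_sym_mig", "vicariance", ("s", "M", "T1", "T2"),
              _vic_anc_sym_mig),
    ModelSpec("vic_sec_contact_sym_mig", "vicariance", ("s", "M", "T1", "T2"),
              _vic_sec_contact_sym_mig),
    ModelSpec("founder_nomig", "founder", ("s", "nu2", "T"), _founder_nomig),
    ModelSpec("founder_sym", "founder", ("s", "nu2", "M", "T"), _founder_sym),
    ModelSpec("founder_asym", "founder", ("s", "nu2", "M12", "M21", "T"),
              _founder_asym),
    ModelSpec("founder_anc_sym_mig", "founder", ("s", "nu2", "M", "T1", "T2"),
              _founder_anc_sym_mig),
    ModelSpec("founder_sec_contact_sym", "founder",
              ("s", "nu2", "M", "T1", "T2"), _founder_sec_contact_sym),
    ModelSpec("founder_sec_contact_asym", "founder",
              ("s", "nu2", "M12", "M21", "T1", "T2"),
              _founder_sec_contact_asym),
]


def model_catalog() -> list[ModelSpec]:
    """The nine competing divergence scenarios (three vicariance, six
    founder-event), in canonical order."""
    return list(_CATALOG)


def get_model(name: str) -> ModelSpec:
    for m in _CATALOG:
        if m.name == name:
            return m
    raise ValueError(
        f"unknown model {name!r}; catalog: {[m.name for m in _CATALOG]}")
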