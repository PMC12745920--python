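"""Model/Results interface for two-population divergence inference.

A :class:`DivergenceModel` couples an observed joint SFS with one of the
nine catalog scenarios (optionally with the populations swapped, to test
the opposite colonisation direction); ``fit()`` runs the staged
multi-start optimization and returns a :class:`DivergenceResult` that
carries the estimates, model comparison quantities, bootstrap
goodness-of-fit, time conversion and plotting.

``fit_model_set`` runs the full competition -- every catalog scenario,
founder scenarios in both orientations -- and ranks the fits by AIC with
Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .demography import ModelSpec, get_model, model_catalog
from .engine import DEFAULT_ENGINE, EngineConfig
from .inference import (DEFAULT_SCHEDULE, ConversionConstants, FitResult,
                        GofResult, OptimSchedule, composite_loglik,
                        default_start, expected_for_data, goodness_of_fit,
                        optimize_fit, select_models, test_pre_lgm)
from .spectrum import Spectrum2D


class DivergenceModel:
    """One divergence scenario confronted with an observed joint SFS.

    Parameters
    ----------
    data:
        Observed spectrum of integer site counts (typically folded).
    scenario:
        Catalog name or :class:`ModelSpec`.
    orientation:
        "as-is" keeps the data's population order (population 2 is the
        founded deme in founder scenarios); "swapped" evaluates the
        scenario with the populations exchanged.
    engine:
        Diffusion-engine controls.
    """

    def __init__(self, data: Spectrum2D, scenario: ModelSpec | str,
                 orientation: str = "as-is",
                 engine: EngineConfig = DEFAULT_ENGINE):
        if orientation not in ("as-is", "swapped"):
            raise ValueError("orientation must be 'as-is' or 'swapped'")
        self.data = data
        self.scenario = (get_model(scenario) if isinstance(scenario, str)
                         else scenario)
        self.orientation = orientation
        self.engine = engine

    @classmethod
    def from_genotypes(cls, gm, popA: str, popB: str,
                       scenario: ModelSpec | str, n1: int | None = None,
                       n2: int | None = None, fold: bool = True,
                       **kwargs) -> "DivergenceModel":
        """Build the observed spectrum from a filtered genotype matrix
        (full sample sizes unless ``n1``/``n2`` are given)."""
        from .sfs import build_jsfs

        if n1 is None:
            n1 = 2 * len(gm.sample_indices(popA))
        if n2 is None:
            n2 = 2 * len(gm.sample_indices(popB))
        data = build_jsfs(gm, popA, popB, n1, n2, fold=fold)
        return cls(data, scenario, **kwargs)

    # -- evaluation -------------------------------------------------------

    def expected(self, params) -> Spectrum2D:
        """Per-unit-theta model spectrum matching the data's shape,
        orientation and folding."""
        return expected_for_data(self.scenario, params, self.data,
                                 engine=self.engine,
                                 swap=self.orientation == "swapped")

    def loglik(self, params) -> tuple[float, float]:
        """Composite log-likelihood and optimal theta at ``params``."""
        return composite_loglik(self.data, self.expected(params))

    # -- fitting ----------------------------------------------------------

    def fit(self, start=None, schedule: OptimSchedule = DEFAULT_SCHEDULE,
            seed: int = 0, bounds=None) -> "DivergenceResult":
        """Staged multi-start maximum-composite-likelihood fit."""
        if start is None:
            start = default_start(self.scenario)
        res = optimize_fit(self.data, self.scenario, start,
                           schedule=schedule, engine=self.engine, seed=seed,
                           bounds=bounds, orientation=self.orientation)
        return DivergenceResult(self, res)


@dataclass
class DivergenceResult:
    """Fit outcome with the diagnostics that hang off it."""

    model: DivergenceModel
    fit: FitResult
    gof_result: GofResult | None = field(default=None, repr=False)

    @property
    def params(self) -> dict[str, float]:
        return self.fit.params

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def theta_hat(self) -> float:
        return self.fit.theta_hat

    @property
    def aic(self) -> float:
        return self.fit.aic

    @property
    def k(self) -> int:
        return self.fit.k

    @property
    def orientation(self) -> str:
        return self.fit.orientation

    def expected_counts(self) -> Spectrum2D:
        """Fitted spectrum scaled to expected site counts."""
        m = self.model.expected(self.params)
        return Spectrum2D(self.theta_hat * m.data, m.mask, m.folded,
                          m.pop_labels)

    # -- diagnostics ------------------------------------------------------

    def gof(self, n_sims: int = 100, refit: bool = False, seed: int = 0,
            schedule: OptimSchedule | None = None) -> GofResult:
        """Parametric-bootstrap goodness of fit (cached on the result)."""
        from .inference import REDUCED_SCHEDULE

        self.gof_result = goodness_of_fit(
            self.model.data, self.fit, n_sims=n_sims, refit=refit,
            schedule=schedule or REDUCED_SCHEDULE,
            engine=self.model.engine, seed=seed)
        return self.gof_result

    def divergence_time_years(self, cc: ConversionConstants,
                              param: str | None = None) -> float:
        """Point estimate of (total) divergence time in years."""
        from .inference import convert_time

        if param is not None:
            t = self.params[param]
        else:
            t = sum(v for k, v in self.params.items() if k.startswith("T"))
        return convert_time(t, self.theta_hat, cc)

    def simulated_times_years(self, cc: ConversionConstants) -> np.ndarray:
        """Per-bootstrap total divergence times in years.

        In refit mode each simulation contributes its re-estimated total
        time and theta; in evaluate mode the best-fit time is rescaled by
        each simulation's theta (N_ref varies with theta only).
        """
        if self.gof_result is None:
            raise ValueError("run .gof() first")
        g = self.gof_result
        if g.refit:
            t = sum(g.sim_params[p] for p in g.sim_params
                    if p.startswith("T"))
        else:
            t = sum(v for k, v in self.params.items() if k.startswith("T"))
        return t * 2 * g.sim_thetas / (4 * cc.mu * cc.L) * cc.g

    def pre_lgm_test(self, cc: ConversionConstants,
                     null_ka: float = 20.0) -> dict:
        """One-sided Wilcoxon test of the simulated divergence times
        against the Last Glacial Maximum null (times converted to ka)."""
        times_ka = self.simulated_times_years(cc) / 1e3
        return test_pre_lgm(times_ka, null_ka=null_ka)

    # -- presentation -----------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Divergence scenario fit",
            "=" * 55,
            f"scenario:        {self.fit.model} "
            f"({self.model.scenario.family})",
            f"orientation:     {self.orientation}",
            f"populations:     {self.model.data.pop_labels[0]} / "
            f"{self.model.data.pop_labels[1]}",
            f"sample sizes:    ({self.model.data.n1}, {self.model.data.n2})"
            f"{' folded' if self.model.data.folded else ''}",
            f"segregating mass: {self.model.data.sum():.1f}",
            "-" * 55,
        ]
        for name in self.model.scenario.param_names:
            lines.append(f"{name:>6s} = {self.params[name]:.4g}")
        lines += [
            "-" * 55,
            f"log-likelihood:  {self.loglik:.3f}",
            f"theta_hat:       {self.theta_hat:.4g}",
            f"k (free params): {self.k}",
            f"AIC:             {self.aic:.3f}",
        ]
        if self.fit.akaike_weight is not None:
            lines.append(f"Akaike weight:   {self.fit.akaike_weight:.4f}")
        if self.gof_result is not None:
            g = self.gof_result
            lines += [
                "-" * 55,
                f"GOF loglik inside 95% band: {g.loglik_inside}",
                f"GOF chi2 inside 95% band:   {g.chi2_inside}",
            ]
        return "\n".join(lines)

    def plot_comparison(self, ax=None):
        """Data, fitted model and Poisson residuals side by side."""
        import matplotlib.pyplot as plt

        exp = self.expected_counts()
        d = np.ma.masked_where(self.model.data.mask, self.model.data.data)
        e = np.ma.masked_where(exp.mask, exp.data)
        with np.errstate(divide="ignore", invalid="ignore"):
            resid = (d - e) / np.sqrt(e)
        if ax is None:
            _, ax = plt.subplots(1, 3, figsize=(12, 3.6))
        for a, mat, title in zip(
                ax, [np.log10(np.maximum(d, 0.3)),
                     np.log10(np.maximum(e, 0.3)), resid],
                ["data (log10)", "model (log10)", "Poisson residuals"]):
            im = a.imshow(mat.T, origin="lower", aspect="auto",
                          cmap="viridis" if "resid" not in title else "RdBu_r")
            a.set_title(title)
            a.set_xlabel(self.model.data.pop_labels[0])
            a.set_ylabel(self.model.data.pop_labels[1])
            plt.colorbar(im, ax=a)
        return ax


def fit_model_set(data: Spectrum2D, models="all", orientations: str = "both",
                  schedule: OptimSchedule = DEFAULT_SCHEDULE,
                  engine: EngineConfig = DEFAULT_ENGINE, seed: int = 0,
                  starts=None):
    """Fit the scenario catalog to one spectrum and rank by AIC.

    Founder scenarios are fitted in both orientations when
    ``orientations="both"`` (each population in turn as the founded
    deme); vicariance scenarios are direction-free (the split fraction
    ``s`` covers both assignments).  Returns ``(results, table)`` where
    ``results`` maps fit labels to :class:`DivergenceResult` and
    ``table`` is the AIC ranking with Akaike weights.
    """
    if models == "all":
        models = [m.name for m in model_catalog()]
    rng = np.random.default_rng(seed)
    results: dict[str, DivergenceResult] = {}
    for name in models:
        spec = get_model(name)
        orients = ["as-is"]
        if orientations == "both" and spec.family == "founder":
            orients.append("swapped")
        for orient in orients:
            dm = DivergenceModel(data, spec, orientation=orient,
                                 engine=engine)
            start = None if starts is None else starts.get(name)
            res = dm.fit(start=start, schedule=schedule,
                         seed=int(rng.integers(2 ** 31)))
            results[res.fit.label] = res
    table = select_models([r.fit for r in results.values()])
    return results, table
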