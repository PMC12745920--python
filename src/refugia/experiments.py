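"""Validation experiments for the inference pipeline.

These are the package's own end-to-end checks, sized for a desk-scale
single-CPU run: closed-form limits of the diffusion engine, entrywise
agreement with the structured-coalescent oracle across the full scenario
catalog, parameter-recovery and model-selection calibration on synthetic
spectra, and the coverage of the parametric-bootstrap band.  The same
functions back the acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import comb

from .engine import EngineConfig, expected_sfs, expected_sfs_1d
from .inference import (REDUCED_SCHEDULE, OptimSchedule, akaike_weights,
                        composite_loglik, optimize_fit)
from .simulate import SimConfig, simulate_coalescent_jsfs
from .spectrum import poisson_sample

#: engine preset used for fitting experiments (accuracy ~0.7%, ~8 ms/eval)
FIT_ENGINE = EngineConfig(grid_sizes=(25, 35, 45), time_step_factor=0.015)

#: ultra-light schedule for the many-replicate calibration experiments
CALIBRATION_SCHEDULE = OptimSchedule(folds=(2, 1), reps=(6, 8),
                                     maxiters=(6, 10))

#: three representative parameter sets per catalog scenario
ORACLE_PARAM_SETS: dict[str, list[dict]] = {
    "vic_no_mig": [
        {"s": 0.3, "T": 0.4}, {"s": 0.5, "T": 0.1}, {"s": 0.7, "T": 1.0}],
    "vic_anc_sym_mig": [
        {"s": 0.5, "M": 1.0, "T1": 0.2, "T2": 0.1},
        {"s": 0.3, "M": 3.0, "T1": 0.3, "T2": 0.2},
        {"s": 0.6, "M": 0.5, "T1": 0.5, "T2": 0.3}],
    "vic_sec_contact_sym_mig": [
        {"s": 0.4, "M": 1.0, "T1": 0.3, "T2": 0.1},
        {"s": 0.5, "M": 2.0, "T1": 0.2, "T2": 0.2},
        {"s": 0.25, "M": 5.0, "T1": 0.4, "T2": 0.05}],
    "founder_nomig": [
        {"s": 0.1, "nu2": 1.0, "T": 0.1},
        {"s": 0.3, "nu2": 2.0, "T": 0.3},
        {"s": 0.5, "nu2": 0.5, "T": 0.6}],
    "founder_sym": [
        {"s": 0.3, "nu2": 1.5, "M": 5.0, "T": 0.2},
        {"s": 0.1, "nu2": 1.0, "M": 1.0, "T": 0.1},
        {"s": 0.4, "nu2": 3.0, "M": 0.5, "T": 0.5}],
    "founder_asym": [
        {"s": 0.2, "nu2": 2.0, "M12": 2.0, "M21": 0.3, "T": 0.3},
        {"s": 0.35, "nu2": 1.0, "M12": 0.5, "M21": 2.0, "T": 0.2},
        {"s": 0.15, "nu2": 0.8, "M12": 3.0, "M21": 1.0, "T": 0.4}],
    "founder_anc_sym_mig": [
        {"s": 0.25, "nu2": 0.8, "M": 2.0, "T1": 0.25, "T2": 0.15},
        {"s": 0.4, "nu2": 1.5, "M": 1.0, "T1": 0.2, "T2": 0.2},
        {"s": 0.1, "nu2": 1.0, "M": 4.0, "T1": 0.1, "T2": 0.1}],
    "founder_sec_contact_sym": [
        {"s": 0.15, "nu2": 1.2, "M": 1.5, "T1": 0.3, "T2": 0.1},
        {"s": 0.3, "nu2": 2.0, "M": 0.5, "T1": 0.2, "T2": 0.2},
        {"s": 0.5, "nu2": 1.0, "M": 3.0, "T1": 0.4, "T2": 0.1}],
    "founder_sec_contact_asym": [
        {"s": 0.2, "nu2": 1.5, "M12": 1.0, "M21": 0.5, "T1": 0.3,
         "T2": 0.1},
        {"s": 0.4, "nu2": 0.7, "M12": 2.0, "M21": 0.2, "T1": 0.2,
         "T2": 0.15},
        {"s": 0.1, "nu2": 2.0, "M12": 0.5, "M21": 1.5, "T1": 0.35,
         "T2": 0.05}],
}


def single_pool_sfs(n1: int, n2: int) -> np.ndarray:
    """Closed-form T=0 spectrum: S(i,j) = C(n1,i)C(n2,j)/(C(n,i+j)(i+j))."""
    out = np.zeros((n1 + 1, n2 + 1))
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            if 0 < i + j < n1 + n2:
                out[i, j] = comb(n1, i) * comb(n2, j) / (
                    comb(n1 + n2, i + j) * (i + j))
    return out


def closed_form_errors() -> dict[str, float]:
    """Worst relative error of the engine against its closed-form limits:
    the single-population equilibrium spectrum theta*nu/i (reached by
    relaxation from the standard equilibrium) and the T=0 two-population
    single-pool formula."""
    errs_eq = []
    for nu, T in ((0.5, 6.0), (2.0, 16.0)):
        s = expected_sfs_1d(nu, T, 10)
        i = np.arange(1, 10)
        errs_eq.append(np.abs(s[1:10] * i / nu - 1).max())
    errs_t0 = []
    for model, params in (("vic_no_mig", {"s": 0.5, "T": 0.0}),
                          ("founder_nomig",
                           {"s": 0.2, "nu2": 1.5, "T": 0.0})):
        spec = expected_sfs(model, params, 2, 2)
        exact = single_pool_sfs(2, 2)
        m = ~spec.mask
        errs_t0.append(np.abs(spec.data[m] / exact[m] - 1).max())
    return {"equilibrium_max_rel_err": float(max(errs_eq)),
            "t0_max_rel_err": float(max(errs_t0))}


def oracle_agreement(n_replicates: int = 30_000, n: int = 8,
                     seed: int = 0) -> dict[str, list[float]]:
    """Fraction of unmasked spectrum entries within 3 Monte-Carlo SEs of
    the structured-coalescent oracle, per scenario and parameter set."""
    rng = np.random.default_rng(seed)
    out: dict[str, list[float]] = {}
    for model, param_sets in ORACLE_PARAM_SETS.items():
        fracs = []
        for params in param_sets:
            cfg = SimConfig(model_name=model, params=params, n1=n, n2=n,
                            seed=int(rng.integers(1, 2 ** 31)))
            orc = simulate_coalescent_jsfs(cfg, n_replicates)
            eng = expected_sfs(model, params, n, n)
            m = ~orc.mask
            z = np.abs(eng.data[m] - orc.data[m]) / np.maximum(
                orc.mc_se[m], 1e-12)
            fracs.append(float(np.mean(z <= 3)))
        out[model] = fracs
    return out


RECOVERY_TRUTHS = {
    "vic_no_mig": {"s": 0.3, "T": 0.4},
    "founder_nomig": {"s": 0.1, "nu2": 1.0, "T": 0.2},
}


def parameter_recovery(model_name: str, n_replicates: int = 10,
                       n_sites: float = 5000.0, seed: int = 0,
                       schedule: OptimSchedule = REDUCED_SCHEDULE,
                       engine: EngineConfig = FIT_ENGINE) -> dict:
    """Refit synthetic folded (10,10) spectra of ~n_sites segregating
    sites drawn from a known truth; success = s within +-0.05 and every
    T within 15% of truth."""
    truth = RECOVERY_TRUTHS[model_name]
    exp = expected_sfs(model_name, truth, 10, 10, fold=True, config=engine)
    theta = n_sites / exp.sum()
    rng = np.random.default_rng(seed)
    estimates, successes = [], 0
    for _ in range(n_replicates):
        data = poisson_sample(exp, theta, seed=int(rng.integers(2 ** 31)))
        fit = optimize_fit(data, model_name, truth, schedule=schedule,
                           engine=engine, seed=int(rng.integers(2 ** 31)))
        est = fit.params
        ok_s = abs(est["s"] - truth["s"]) <= 0.05
        ok_t = all(abs(est[p] - truth[p]) <= 0.15 * truth[p]
                   for p in truth if p.startswith("T"))
        successes += bool(ok_s and ok_t)
        estimates.append(est)
    return {"model": model_name, "n_replicates": n_replicates,
            "successes": successes, "estimates": estimates}


def _family_competition(data, engine, schedule, seed, with_orientation):
    """Fit vic_no_mig and founder_nomig (both orientations for the
    founder scenario when requested) and return the AIC table inputs."""
    rng = np.random.default_rng(seed)
    fits = []
    for model, orientation in [("vic_no_mig", "as-is"),
                               ("founder_nomig", "as-is")] + (
            [("founder_nomig", "swapped")] if with_orientation else []):
        from .inference import default_start

        fits.append(optimize_fit(
            data, model, default_start(model), schedule=schedule,
            engine=engine, seed=int(rng.integers(2 ** 31)),
            orientation=orientation))
    return fits


def model_selection_calibration(n_per_family: int = 20,
                                n_sites: float = 5000.0, n: int = 8,
                                seed: int = 0,
                                schedule: OptimSchedule =
                                CALIBRATION_SCHEDULE,
                                engine: EngineConfig = FIT_ENGINE) -> dict:
    """Simulate data under each family (no migration) and check that the
    generating family wins the Akaike competition, and that the founder
    orientation is recovered by likelihood.

    The founder truth places population 2 as the founded deme, so the
    "as-is" orientation is correct.
    """
    rng = np.random.default_rng(seed)
    generating = {
        "vicariance": ("vic_no_mig", {"s": 0.3, "T": 0.4}),
        "founder": ("founder_nomig", {"s": 0.1, "nu2": 1.0, "T": 0.2}),
    }
    wins = {"vicariance": 0, "founder": 0}
    orientation_correct = 0
    for family, (model, truth) in generating.items():
        exp = expected_sfs(model, truth, n, n, fold=True, config=engine)
        theta = n_sites / exp.sum()
        for _ in range(n_per_family):
            data = poisson_sample(exp, theta,
                                  seed=int(rng.integers(2 ** 31)))
            fits = _family_competition(
                data, engine, schedule, int(rng.integers(2 ** 31)),
                with_orientation=family == "founder")
            w = akaike_weights([f.aic for f in fits])
            top = fits[int(np.argmax(w))]
            top_family = ("vicariance" if top.model.startswith("vic")
                          else "founder")
            wins[family] += top_family == family
            if family == "founder":
                ll = {f.orientation: f.loglik for f in fits
                      if f.model == "founder_nomig"}
                orientation_correct += ll["as-is"] > ll["swapped"]
    return {"n_per_family": n_per_family, "wins": wins,
            "orientation_correct": orientation_correct}


def gof_calibration(n_repetitions: int = 40, n_boot: int = 100,
                    n_sites: float = 5000.0, seed: int = 0,
                    engine: EngineConfig = FIT_ENGINE) -> dict:
    """Coverage of the central-95% bootstrap log-likelihood band when the
    data really do come from the fitted model.

    Data and bootstrap replicates are drawn from the same Poisson law
    and evaluated at the same parameters, so the empirical log-likelihood
    should fall inside the band ~95% of the time.
    """
    truth = {"s": 0.3, "T": 0.4}
    exp = expected_sfs("vic_no_mig", truth, 10, 10, fold=True,
                       config=engine)
    theta = n_sites / exp.sum()
    rng = np.random.default_rng(seed)
    inside = 0
    for _ in range(n_repetitions):
        data = poisson_sample(exp, theta, seed=int(rng.integers(2 ** 31)))
        ll_emp, _ = composite_loglik(data, exp)
        sims = np.empty(n_boot)
        for b in range(n_boot):
            sim = poisson_sample(exp, theta,
                                 seed=int(rng.integers(2 ** 31)))
            sims[b], _ = composite_loglik(sim, exp)
        lo, hi = np.percentile(sims, [2.5, 97.5])
        inside += bool(lo <= ll_emp <= hi)
    return {"n_repetitions": n_repetitions, "inside": inside,
            "coverage": inside / n_repetitions}
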