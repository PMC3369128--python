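"""Sequential naive-pooled maximum-likelihood estimation.

Stage 1 (plasma) fits the sixteen structural plasma parameters to plasma
concentrations of both drugs; stage 2 (brain) fixes plasma parameters and
fits brain distribution and receptor-binding parameters to brain
concentrations and D2 / 5-HT2A occupancies simultaneously.

The objective is -2 log likelihood (OFV) with exact log-normal residuals on
log-transformed concentrations and additive Gaussian residuals (percentage
points) on occupancy. Each animal's prediction is the noiseless population
simulation of its arm (naive pooling: no per-animal random effects; the
destructive designs give too few observations per animal to support
conditional estimation, and inter-individual variability only inflates the
fitted residual sigmas). Residual sigmas have closed-form conditional MLEs
(sigma^2 = RSS/n per observation class) and are profiled out analytically
during optimization.

All positive parameters are optimized on the log scale and fractions on the
logit scale; fits are multi-started from log-uniform perturbations of the
initial values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import DoseEvent
from .params import ModelParameters, default_parameters
from .simulate import (IntegrationError, plasma_concentrations_linear,
                       simulate)

logger = logging.getLogger(__name__)

__all__ = [
    "FitResult",
    "ProfileCI",
    "neg2ll",
    "fit_plasma",
    "fit_brain",
    "profile_likelihood",
    "profile_ci_from_objective",
    "bootstrap",
    "derived_parameters",
    "lr_test",
    "PLASMA_PARAMETERS",
    "BRAIN_PARAMETERS",
]

LOG2PI = math.log(2.0 * math.pi)
PENALTY = 1e12

PLASMA_PARAMETERS = (
    "F_IP", "F_SC", "Fr_FPM", "Ka_SC_R", "Ka_SC_P", "DR_SC_R", "DR_SC_P",
    "V_c_R", "CL_R", "CL_met", "V_p_R", "Q_R", "V_c_P", "CL_P", "V_p_P",
    "Q_P",
)
FRACTION_PARAMETERS = ("F_IP", "F_SC", "Fr_FPM")

BRAIN_PARAMETERS = (
    "CL_bev", "CL_eff_R", "CL_eff_P", "Kd_D2", "koff_D2", "Bmax_D2",
    "Kd_5HT2A", "koff_5HT2A", "Bmax_5HT2A",
)
D2_ONLY_PARAMETERS = (
    "CL_bev", "CL_eff_R", "CL_eff_P", "Kd_D2", "koff_D2", "Bmax_D2",
)

SIGMA_NAMES = (
    "sigma_prop_plasma_R", "sigma_prop_plasma_P",
    "sigma_prop_brain_R", "sigma_prop_brain_P",
    "sigma_add_RO_D2", "sigma_add_RO_5HT2A",
)

#: residual-error class per (TYPE, DRUG_MEAS); value = (sigma field, additive)
_CLASS = {
    ("conc_plasma", "RIS"): ("sigma_prop_plasma_R", False),
    ("conc_plasma", "PALI"): ("sigma_prop_plasma_P", False),
    ("conc_brain", "RIS"): ("sigma_prop_brain_R", False),
    ("conc_brain", "PALI"): ("sigma_prop_brain_P", False),
    ("ro_d2", ""): ("sigma_add_RO_D2", True),
    ("ro_5ht2a", ""): ("sigma_add_RO_5HT2A", True),
}

_STAGE_TYPES = {
    "plasma": ("conc_plasma",),
    "brain": ("conc_brain", "ro_d2", "ro_5ht2a"),
}


def _set_params(base: ModelParameters, theta: Mapping[str, float]
                ) -> ModelParameters:
    """Apply named overrides (plasma, brain or sigma fields) to ``base``."""
    pl = {k: v for k, v in theta.items() if k in PLASMA_PARAMETERS}
    br = {k: v for k, v in theta.items() if k in BRAIN_PARAMETERS}
    er = {k: v for k, v in theta.items() if k in SIGMA_NAMES}
    unknown = set(theta) - set(pl) - set(br) - set(er)
    if unknown:
        raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
    out = base
    if pl:
        out = out.with_plasma(**pl)
    if br:
        out = out.with_brain(**br)
    if er:
        out = out.with_error(**er)
    return out


# ---------------------------------------------------------------------------
# Prepared data: group observation rows by arm and observable
# ---------------------------------------------------------------------------

@dataclass
class _Group:
    arm: int
    obs_type: str
    drug: str
    region: str
    sigma_field: str
    additive: bool
    tidx: np.ndarray
    y: np.ndarray
    log_y: np.ndarray


@dataclass
class _Prepared:
    stage: str
    arms: list            # (regimen, times ndarray)
    groups: list          # of _Group
    n_obs: int


def prepare_stage(data: pd.DataFrame, stage: str) -> _Prepared:
    """Index rows of a stage by dose arm; below-LOQ rows are excluded."""
    if stage not in _STAGE_TYPES:
        raise ValueError(f"unknown stage {stage!r}")
    sub = data[(data["TYPE"].isin(_STAGE_TYPES[stage]))
               & (data["BLOQ"] == 0)].copy()
    if sub.empty:
        raise ValueError(f"no usable observations for stage {stage!r}")
    arms: list = []
    arm_index: dict = {}
    groups: list = []
    for (drug_adm, route, dose), arm_rows in sub.groupby(
            ["DRUG_ADMIN", "ROUTE", "DOSE"]):
        times = np.sort(arm_rows["TIME"].unique())
        arm_index[(drug_adm, route, dose)] = len(arms)
        arms.append(([DoseEvent(drug_adm, route, float(dose))], times))
        tpos = {t: i for i, t in enumerate(times)}
        for (otype, drug, region), g in arm_rows.groupby(
                ["TYPE", "DRUG_MEAS", "REGION"]):
            sigma_field, additive = _CLASS[(otype, drug)]
            y = g["DV"].to_numpy(float)
            if not additive and np.any(y <= 0):
                raise ValueError(
                    "non-positive concentration observation cannot enter the "
                    "log-normal likelihood")
            groups.append(_Group(
                arm=len(arms) - 1, obs_type=otype, drug=drug, region=region,
                sigma_field=sigma_field, additive=additive,
                tidx=np.array([tpos[t] for t in g["TIME"]], dtype=int),
                y=y, log_y=np.log(y) if not additive else np.empty(0)))
    return _Prepared(stage=stage, arms=arms, groups=groups, n_obs=len(sub))


def _predictions(params: ModelParameters, prep: _Prepared,
                 rtol: float, atol: float) -> list:
    """Per-group predicted observable vectors (aligned with group.tidx)."""
    preds = []
    if prep.stage == "plasma":
        arm_conc = [plasma_concentrations_linear(params, reg, times)
                    for reg, times in prep.arms]
        for g in prep.groups:
            c_r, c_p = arm_conc[g.arm]
            preds.append((c_r if g.drug == "RIS" else c_p)[g.tidx])
        return preds
    arm_res = [simulate(params, reg, times, rtol=rtol, atol=atol)
               for reg, times in prep.arms]
    for g in prep.groups:
        res = arm_res[g.arm]
        if g.obs_type == "conc_brain":
            v = res.brain_conc(g.region, g.drug)
        elif g.obs_type == "ro_d2":
            v = res.occupancy()[0]
        else:
            v = res.occupancy()[1]
        preds.append(v[g.tidx])
    return preds


def _ofv_from_predictions(prep: _Prepared, preds: list,
                          sigmas: Mapping[str, float] | None):
    """(OFV, per-class MLE sigmas). With ``sigmas`` None they are profiled."""
    res_by_class: dict = {}
    for g, yhat in zip(prep.groups, preds):
        if g.additive:
            r = g.y - yhat
        else:
            if np.any(yhat <= 0):
                return PENALTY, {}
            r = g.log_y - np.log(yhat)
        res_by_class.setdefault(g.sigma_field, []).append(r)
    ofv = 0.0
    sig_hat = {}
    for cls, parts in res_by_class.items():
        r = np.concatenate(parts)
        n = len(r)
        if sigmas is None:
            s2 = max(float(np.mean(r * r)), 1e-20)
            ofv += n * (LOG2PI + math.log(s2) + 1.0)
        else:
            s2 = float(sigmas[cls]) ** 2
            if s2 <= 0:
                return PENALTY, {}
            ofv += n * (LOG2PI + math.log(s2)) + float(np.sum(r * r)) / s2
        sig_hat[cls] = math.sqrt(max(float(np.mean(r * r)), 0.0))
    return ofv, sig_hat


def neg2ll(theta: Mapping[str, float], data: pd.DataFrame, stage: str,
           fixed: ModelParameters, rtol: float = 1e-6, atol: float = 1e-9
           ) -> float:
    """-2 log likelihood of ``data`` at the named parameter values.

    ``theta`` overrides structural and/or sigma fields of ``fixed``; sigmas
    not overridden are taken from ``fixed.error`` (they are explicit
    parameters here, not profiled).
    """
    params = _set_params(fixed, theta)
    prep = data if isinstance(data, _Prepared) else prepare_stage(data, stage)
    try:
        preds = _predictions(params, prep, rtol, atol)
    except (IntegrationError, FloatingPointError):
        logger.warning("prediction failure at theta=%s; penalty OFV", theta)
        return PENALTY
    sigmas = {f: getattr(params.error, f) for f in SIGMA_NAMES}
    ofv, _ = _ofv_from_predictions(prep, preds, sigmas)
    return ofv


# ---------------------------------------------------------------------------
# Transforms and the optimizer driver
# ---------------------------------------------------------------------------

def _to_internal(name: str, value: float) -> float:
    if name in FRACTION_PARAMETERS:
        v = min(max(value, 1e-12), 1 - 1e-12)
        return math.log(v / (1.0 - v))
    return math.log(value)


def _from_internal(name: str, x: float) -> float:
    if name in FRACTION_PARAMETERS:
        return 1.0 / (1.0 + math.exp(-x))
    return math.exp(x)


DEFAULT_BOUND_FACTOR = 50.0


@dataclass
class FitResult:
    """Maximum-likelihood fit of one estimation stage."""

    stage: str
    estimates: dict
    sigmas: dict
    ofv: float
    converged: bool
    n_eval: int
    fixed: ModelParameters
    free_names: tuple
    weakly_identified: list = field(default_factory=list)
    message: str = ""
    profiles: dict = field(default_factory=dict)

    @property
    def params(self) -> ModelParameters:
        """Fixed parameters with the stage estimates and sigmas applied."""
        out = _set_params(self.fixed, self.estimates)
        return _set_params(out, {k: v for k, v in self.sigmas.items()})

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "estimates": dict(self.estimates),
            "sigmas": dict(self.sigmas),
            "ofv": self.ofv,
            "converged": bool(self.converged),
            "n_eval": int(self.n_eval),
            "weakly_identified": list(self.weakly_identified),
            "message": self.message,
        }


def _make_objective(prep: _Prepared, base: ModelParameters,
                    names: Sequence[str], rtol: float, atol: float,
                    counter: list) -> Callable:
    def obj(x: np.ndarray) -> float:
        counter[0] += 1
        theta = {n: _from_internal(n, xi) for n, xi in zip(names, x)}
        try:
            params = _set_params(base, theta)
            preds = _predictions(params, prep, rtol, atol)
        except (IntegrationError, FloatingPointError, ValueError):
            return PENALTY
        ofv, _ = _ofv_from_predictions(prep, preds, None)
        return ofv
    return obj


def _fit_stage(prep: _Prepared, base: ModelParameters,
               names: Sequence[str], init: Mapping[str, float],
               bounds: Mapping[str, tuple] | None,
               n_starts: int, seed: int, maxiter: int,
               explore_maxiter: int | None,
               rtol: float, atol: float) -> FitResult:
    names = tuple(names)
    counter = [0]
    obj = _make_objective(prep, base, names, rtol, atol, counter)
    x0 = np.array([_to_internal(n, init[n]) for n in names])
    bnds = []
    for n in names:
        if bounds and n in bounds:
            lo, hi = bounds[n]
        else:
            lo, hi = init[n] / DEFAULT_BOUND_FACTOR, init[n] * DEFAULT_BOUND_FACTOR
            if n in FRACTION_PARAMETERS:
                lo, hi = max(lo, 1e-4), min(hi, 1.0 - 1e-9)
        bnds.append((_to_internal(n, lo), _to_internal(n, hi)))
    bnds = np.array(bnds)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        pert = rng.uniform(-math.log(3.0), math.log(3.0), size=len(names))
        starts.append(np.clip(x0 + pert, bnds[:, 0], bnds[:, 1]))

    best = None
    results = []
    for i, xs in enumerate(starts):
        it = explore_maxiter if (explore_maxiter and i > 0) else maxiter
        r = minimize(obj, xs, method="L-BFGS-B", bounds=list(bnds),
                     options={"maxiter": it, "eps": 1e-3,
                              "maxfun": it * (len(names) + 1) * 3})
        results.append(r)
        if best is None or r.fun < best.fun:
            best = r
    if explore_maxiter:
        # polish the best exploratory result at full iteration budget
        r = minimize(obj, best.x, method="L-BFGS-B", bounds=list(bnds),
                     options={"maxiter": maxiter, "eps": 1e-3,
                              "maxfun": maxiter * (len(names) + 1) * 3})
        if r.fun <= best.fun:
            best = r
    converged = any(r.success for r in results) or best.success
    estimates = {n: _from_internal(n, xi) for n, xi in zip(names, best.x)}
    params = _set_params(base, estimates)
    preds = _predictions(params, prep, rtol, atol)
    ofv, sig_hat = _ofv_from_predictions(prep, preds, None)

    # flat-likelihood diagnostic: a parameter whose +/-20% perturbation moves
    # the OFV by < 0.05 units is flagged as weakly identified
    weak = []
    for j, n in enumerate(names):
        dmax = 0.0
        for f in (1.2, 1 / 1.2):
            x = best.x.copy()
            x[j] = np.clip(_to_internal(n, estimates[n] * f),
                           bnds[j, 0], bnds[j, 1])
            dmax = max(dmax, obj(x) - best.fun)
        if dmax < 0.05:
            weak.append(n)
    if weak:
        logger.warning("weakly identified parameters: %s", weak)

    return FitResult(
        stage=prep.stage, estimates=estimates, sigmas=sig_hat,
        ofv=float(ofv), converged=bool(converged), n_eval=counter[0],
        fixed=base, free_names=names, weakly_identified=weak,
        message=str(best.message))


def fit_plasma(data: pd.DataFrame,
               init: ModelParameters | None = None,
               bounds: Mapping[str, tuple] | None = None,
               n_starts: int = 8,
               seed: int = 0,
               maxiter: int = 400,
               explore_maxiter: int | None = 40) -> FitResult:
    """Fit the sixteen structural plasma parameters (plus two profiled
    proportional sigmas) to plasma concentrations of both drugs."""
    init = init or default_parameters()
    prep = prepare_stage(data, "plasma")
    init_vals = {n: getattr(init.plasma, n) for n in PLASMA_PARAMETERS}
    return _fit_stage(prep, init, PLASMA_PARAMETERS, init_vals, bounds,
                      n_starts, seed, maxiter, explore_maxiter,
                      rtol=1e-6, atol=1e-9)


def fit_brain(data: pd.DataFrame,
              plasma_fit: "FitResult | ModelParameters",
              init: ModelParameters | None = None,
              bounds: Mapping[str, tuple] | None = None,
              n_starts: int = 5,
              seed: int = 0,
              maxiter: int = 80,
              explore_maxiter: int | None = 12,
              receptors: tuple = ("D2", "5HT2A"),
              rtol: float = 1e-6,
              atol: float = 1e-9) -> FitResult:
    """Fit brain distribution and binding parameters with plasma fixed.

    ``plasma_fit`` supplies the fixed plasma parameters (a stage-1 FitResult
    or explicit ModelParameters). With ``receptors=("D2",)`` the 5-HT2A pool
    is removed (Bmax_5HT2A = 0) and only the six D2-model parameters are
    estimated — the reduced model variant. kon values are derived as
    koff/Kd throughout, never free.
    """
    base = plasma_fit.params if isinstance(plasma_fit, FitResult) else plasma_fit
    init = init or default_parameters()
    if receptors == ("D2",):
        names = D2_ONLY_PARAMETERS
        base = base.with_brain(Bmax_5HT2A=0.0)
    elif set(receptors) == {"D2", "5HT2A"}:
        names = BRAIN_PARAMETERS
    else:
        raise ValueError(f"unsupported receptor set {receptors!r}")
    prep = prepare_stage(data, "brain")
    init_vals = {n: getattr(init.brain, n) for n in names}
    return _fit_stage(prep, base, names, init_vals, bounds,
                      n_starts, seed, maxiter, explore_maxiter, rtol, atol)


def lr_test(ofv_reduced: float, ofv_full: float,
            threshold: float = 6.64) -> bool:
    """Nested-model likelihood-ratio check: does the richer model earn its
    extra parameter (delta OFV above ``threshold``, default the p<0.01
    chi-square cut for one parameter)?"""
    return (ofv_reduced - ofv_full) > threshold


# ---------------------------------------------------------------------------
# Likelihood profiling
# ---------------------------------------------------------------------------

@dataclass
class ProfileCI:
    name: str
    mle: float
    lower: float               # -inf if unbounded below search range
    upper: float               # +inf if unbounded above search range
    delta_ofv: float = 3.84


def profile_ci_from_objective(profile_fun: Callable[[float], float],
                              mle: float, ofv0: float,
                              delta_ofv: float = 3.84,
                              rel_tol: float = 1e-2,
                              expand: float = 1.6,
                              max_expansions: int = 14,
                              name: str = "") -> ProfileCI:
    """Confidence bounds where ``profile_fun`` crosses ``ofv0 + delta_ofv``.

    ``profile_fun(value)`` must return the profiled OFV with the parameter
    fixed at ``value`` (others re-optimized by the caller). The crossing is
    bracketed by multiplicative expansion from the MLE and located by
    bisection to relative tolerance ``rel_tol``; a bound the OFV never
    reaches within the search range is reported as unbounded (inf).
    """
    target = ofv0 + delta_ofv

    def search(direction: int) -> float:
        lo, hi = mle, mle
        f_hi = ofv0
        for _ in range(max_expansions):
            lo = hi
            hi = hi * (expand ** direction)
            f_hi = profile_fun(hi)
            if f_hi >= target:
                break
        else:
            return math.inf * direction
        # bisect in log space between lo (below target) and hi (above)
        a, b = (lo, hi) if direction > 0 else (hi, lo)
        while b / a > 1.0 + rel_tol:
            m = math.sqrt(a * b)
            if profile_fun(m) >= target:
                if direction > 0:
                    b = m
                else:
                    a = m
            else:
                if direction > 0:
                    a = m
                else:
                    b = m
        return b if direction > 0 else a

    up = search(+1)
    lo = search(-1)
    return ProfileCI(name=name, mle=mle,
                     lower=0.0 if lo == -math.inf else lo,
                     upper=up, delta_ofv=delta_ofv)


def profile_likelihood(fit: FitResult, data: pd.DataFrame, stage: str,
                       name: str, delta_ofv: float = 3.84,
                       rel_tol: float = 1e-2,
                       refit_maxiter: int = 30,
                       max_expansions: int = 14) -> ProfileCI:
    """Log-likelihood profile CI for one parameter of a converged fit.

    At each probed value the parameter is fixed and all other stage
    parameters are re-optimized (warm-started from the MLE, single start).
    """
    if not fit.converged:
        raise ValueError("profile_likelihood requires a converged fit")
    if name not in fit.free_names:
        raise ValueError(f"{name!r} was not a free parameter of this fit")
    prep = prepare_stage(data, stage)
    others = tuple(n for n in fit.free_names if n != name)
    rtol, atol = (1e-6, 1e-9)
    skipped = [0, 0]  # probes attempted / failed

    def profile_fun(value: float) -> float:
        base = _set_params(fit.fixed, {name: value})
        init_vals = {n: fit.estimates[n] for n in others}
        skipped[0] += 1
        try:
            r = _fit_stage(prep, base, others, init_vals, None,
                           n_starts=1, seed=0, maxiter=refit_maxiter,
                           explore_maxiter=None, rtol=rtol, atol=atol)
            return r.ofv
        except (IntegrationError, ValueError) as exc:
            skipped[1] += 1
            logger.warning("profile point %s=%g skipped: %s", name, value, exc)
            if skipped[1] > 0.5 * max(skipped[0], 1):
                raise RuntimeError(
                    f"more than half of profile points failed for {name}")
            return math.nan

    ci = profile_ci_from_objective(
        profile_fun, fit.estimates[name], fit.ofv, delta_ofv=delta_ofv,
        rel_tol=rel_tol, max_expansions=max_expansions, name=name)
    return ci


# ---------------------------------------------------------------------------
# Nonparametric bootstrap
# ---------------------------------------------------------------------------

def resample_animals(data: pd.DataFrame, rng: np.random.Generator,
                     stratify_by_study: bool = True) -> pd.DataFrame:
    """One bootstrap resample: animals drawn with replacement, all their
    observation rows moving together; with stratification the per-study
    animal counts are preserved exactly. Resampled animals get fresh ids."""
    ids = data[["STUDY", "ID"]].drop_duplicates()
    by_id = dict(tuple(data.groupby("ID")))
    parts = []
    strata = ids.groupby("STUDY") if stratify_by_study else [(None, ids)]
    new_id = 0
    for _, stratum in strata:
        pool = stratum["ID"].to_numpy()
        draw = rng.choice(pool, size=len(pool), replace=True)
        for aid in draw:
            new_id += 1
            part = by_id[aid].copy()
            part["ID"] = new_id
            parts.append(part)
    return pd.concat(parts, ignore_index=True)


@dataclass
class BootstrapResult:
    summary: pd.DataFrame       # index: parameter; cols median/p5/p95
    n_requested: int
    n_failed: int
    replicates: pd.DataFrame    # one row per successful replicate


def bootstrap(data: pd.DataFrame, stage: str, n_replicates: int,
              seed: int = 0, stratify_by_study: bool = True,
              point: FitResult | None = None,
              fit_kwargs: dict | None = None) -> BootstrapResult:
    """Resample animals with replacement (within study strata by default),
    refit, and summarize parameter percentiles (median, 5th, 95th).

    Refits are warm-started from the point estimate when given; replicates
    that fail to converge are excluded and counted.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("n_starts", 1)
    fit_fn = fit_plasma if stage == "plasma" else fit_brain
    if stage == "brain" and point is not None:
        fit_kwargs.setdefault("plasma_fit", point.fixed)
    if point is not None:
        fit_kwargs.setdefault("init", point.params)

    rows = []
    n_failed = 0
    for rep in range(n_replicates):
        rep_data = resample_animals(data, rng, stratify_by_study)
        try:
            fr = fit_fn(rep_data, **fit_kwargs)
        except (IntegrationError, ValueError) as exc:
            logger.warning("bootstrap replicate %d failed: %s", rep, exc)
            n_failed += 1
            continue
        if not fr.converged:
            n_failed += 1
            continue
        rows.append({"replicate": rep, **fr.estimates, **fr.sigmas})
    reps = pd.DataFrame(rows)
    if reps.empty:
        raise RuntimeError("all bootstrap replicates failed")
    cols = [c for c in reps.columns if c != "replicate"]
    summary = pd.DataFrame({
        "median": reps[cols].median(),
        "p5": reps[cols].quantile(0.05),
        "p95": reps[cols].quantile(0.95),
    })
    return BootstrapResult(summary=summary, n_requested=n_replicates,
                           n_failed=n_failed, replicates=reps)


# ---------------------------------------------------------------------------
# Derived parameters
# ---------------------------------------------------------------------------

def derived_parameters(fit: "FitResult | ModelParameters",
                       constants=None) -> dict:
    """Secondary quantities: kon per receptor, efflux-to-passive clearance
    ratios, and the brain/plasma unbound-fraction ratio for risperidone.

    Values are returned at full precision; use :func:`round_sig` for the
    3-significant-figure reporting convention.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    br = params.brain
    ph = constants or params.physiological
    for name, den in (("Kd_D2", br.Kd_D2), ("Kd_5HT2A", br.Kd_5HT2A),
                      ("CL_bev", br.CL_bev), ("fu_plasma_R", ph.fu_plasma_R)):
        if den == 0:
            raise ZeroDivisionError(f"{name} is zero")
    return {
        "kon_D2": br.koff_D2 / br.Kd_D2,
        "kon_5HT2A": br.koff_5HT2A / br.Kd_5HT2A,
        "ratio_R": br.CL_eff_R / br.CL_bev,
        "ratio_P": br.CL_eff_P / br.CL_bev,
        "fu_ratio_R": ph.fu_brain_R / ph.fu_plasma_R,
    }


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
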