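"""Likelihood arithmetic, optimization, profiling and bootstrap."""

import math

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from rispkpd.datasets import default_study_designs, generate_dataset
from rispkpd.fitting import (bootstrap, derived_parameters, fit_brain,
                             fit_plasma, lr_test, neg2ll, prepare_stage,
                             profile_ci_from_objective, profile_likelihood,
                             resample_animals, round_sig)
from rispkpd.params import ErrorModel, IIVModel
from rispkpd.simulate import plasma_concentrations_linear
from rispkpd.datasets import OBS_COLUMNS
from rispkpd.model import DoseEvent


def _row(study, aid, drug_adm, route, dose, time, otype, drug, region, dv,
         bloq=0):
    return dict(zip(OBS_COLUMNS,
                    (study, aid, drug_adm, route, dose, time, otype, drug,
                     region, dv, bloq)))


@pytest.fixture(scope="module")
def clean_params(params):
    return replace(params, iiv=IIVModel(cv_percent={}),
                   error=ErrorModel(0, 0, 0, 0, 0, 0))


@pytest.fixture(scope="module")
def clean_dataset(clean_params, designs):
    return generate_dataset(designs, clean_params, seed=0)


class TestNeg2ll:
    def test_single_exact_observation_gives_log_2pi(self, params):
        (c_r,), _ = plasma_concentrations_linear(
            params, [DoseEvent("RIS", "IV", 2.5)], np.array([1.0]))
        data = pd.DataFrame([_row("1", 1, "RIS", "IV", 2.5, 1.0,
                                  "conc_plasma", "RIS", "", c_r)])
        ofv = neg2ll({"sigma_prop_plasma_R": 1.0}, data, "plasma", params)
        assert ofv == pytest.approx(math.log(2 * math.pi), abs=1e-9)

    def test_vectorized_ofv_matches_per_row_loop(self, params, small_dataset):
        ofv = neg2ll({}, small_dataset, "plasma", params)
        # independent per-row accumulation of the same likelihood
        prep = prepare_stage(small_dataset, "plasma")
        total = 0.0
        for g in prep.groups:
            regimen, times = prep.arms[g.arm]
            c_r, c_p = plasma_concentrations_linear(params, regimen, times)
            yhat = (c_r if g.drug == "RIS" else c_p)[g.tidx]
            sigma = getattr(params.error, g.sigma_field)
            for y, f in zip(g.y, yhat):
                total += (math.log(2 * math.pi * sigma ** 2)
                          + (math.log(y) - math.log(f)) ** 2 / sigma ** 2)
        assert ofv == pytest.approx(total, abs=1e-9)

    def test_brain_stage_ignores_plasma_sigma(self, params, small_dataset):
        a = neg2ll({}, small_dataset, "brain", params)
        b = neg2ll({"sigma_prop_plasma_R": 17.0}, small_dataset, "brain",
                   params)
        assert a == b

    def test_below_loq_rows_are_excluded(self, params, small_dataset):
        flagged = small_dataset.copy()
        idx = flagged[flagged["TYPE"] == "conc_plasma"].index[:25]
        flagged.loc[idx, "BLOQ"] = 1
        assert neg2ll({}, flagged, "plasma", params) != \
            neg2ll({}, small_dataset, "plasma", params)
        assert prepare_stage(flagged, "plasma").n_obs == \
            prepare_stage(small_dataset, "plasma").n_obs - 25

    def test_unknown_parameter_rejected(self, params, small_dataset):
        with pytest.raises(KeyError):
            neg2ll({"CL_total": 1.0}, small_dataset, "plasma", params)


class TestFitPlasma:
    def test_recovers_truth_from_noise_free_data(self, clean_dataset, params):
        fit = fit_plasma(clean_dataset, n_starts=2, maxiter=60,
                         explore_maxiter=15, seed=0)
        for name, est in fit.estimates.items():
            assert est == pytest.approx(getattr(params.plasma, name), rel=0.02)

    def test_truth_is_optimal_on_self_consistent_noiseless_data(self, params):
        # noiseless observations generated by the plasma prediction path
        # itself: no perturbed start may beat the truth's profiled OFV
        rows = []
        aid = 0
        for drug, route, dose in (("RIS", "IV", 2.5), ("RIS", "IP", 1.0),
                                  ("RIS", "SC", 5.0), ("PALI", "SC", 5.0)):
            times = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0])
            c_r, c_p = plasma_concentrations_linear(
                params, [DoseEvent(drug, route, dose)], times)
            for t, cr, cp in zip(times, c_r, c_p):
                for meas, c in (("RIS", cr), ("PALI", cp)):
                    if c <= 0:
                        continue
                    aid += 1
                    rows.append(_row("x", aid, drug, route, dose, t,
                                     "conc_plasma", meas, "", c))
        data = pd.DataFrame(rows)
        prep = prepare_stage(data, "plasma")
        from rispkpd.fitting import _ofv_from_predictions, _predictions
        preds = _predictions(params, prep, 1e-6, 1e-9)
        ofv_truth, _ = _ofv_from_predictions(prep, preds, None)
        fit = fit_plasma(data, n_starts=3, maxiter=60, explore_maxiter=15,
                         seed=0)
        assert ofv_truth <= fit.ofv + 1e-3

    def test_metabolite_free_data_flags_unidentifiable_volume(
            self, clean_params, clean_dataset):
        ris_only = clean_dataset[clean_dataset["DRUG_MEAS"] != "PALI"]
        noisy = ris_only.copy()
        rng = np.random.default_rng(0)
        noisy["DV"] *= np.exp(rng.normal(0, 0.1, len(noisy)))
        fit = fit_plasma(noisy, n_starts=1, maxiter=40, explore_maxiter=None,
                         seed=0)
        assert "V_c_P" in fit.weakly_identified


class TestProfiles:
    def test_quadratic_surface_reproduces_wald_interval(self):
        # on an exactly quadratic profile the 3.84-crossing equals the
        # 1.96*SE Wald bounds
        mle, se, ofv0 = 1.0, 0.1, 100.0
        ci = profile_ci_from_objective(
            lambda v: ofv0 + ((v - mle) / se) ** 2, mle, ofv0,
            rel_tol=1e-3)
        assert ci.lower == pytest.approx(mle - 1.959964 * se, rel=0.01)
        assert ci.upper == pytest.approx(mle + 1.959964 * se, rel=0.01)

    def test_fixing_at_mle_changes_nothing(self):
        f = lambda v: 10.0 + ((v - 2.0) / 0.5) ** 2
        assert f(2.0) == 10.0  # delta OFV at the MLE is zero by construction
        ci = profile_ci_from_objective(f, 2.0, 10.0)
        assert ci.lower < 2.0 < ci.upper

    def test_flat_direction_reports_unbounded_limit(self):
        # OFV that never rises on the upper side
        ci = profile_ci_from_objective(
            lambda v: 50.0 + (4.0 / v if v < 1 else 0.0) ** 2, 1.0, 50.0,
            max_expansions=8)
        assert ci.upper == math.inf

    def test_passive_clearance_profile_is_unbounded_above(self, params,
                                                          designs):
        # only the ratio of active to passive BBB transport is identifiable:
        # pushing CL_bev up while re-optimizing efflux leaves the fit flat
        sub = [d for d in designs if d.study in ("5", "6")]
        data = generate_dataset(sub, params, seed=2)
        fit = fit_brain(data, params, n_starts=1, maxiter=150,
                        explore_maxiter=None, seed=0)
        ci = profile_likelihood(fit, data, "brain", "CL_bev",
                                refit_maxiter=10, max_expansions=6)
        assert ci.upper == math.inf


@pytest.fixture(scope="module")
def duplicated_animal_data(params, designs):
    """Each stratum holds two exact copies of one animal, so stratified
    resampling necessarily reproduces the same dataset."""
    sub = [d for d in designs if d.study in ("1", "2", "4")]
    data = generate_dataset(sub, params, seed=0)
    parts = []
    new_id = 0
    for aid, grp in data.groupby("ID"):
        for _ in range(2):
            new_id += 1
            part = grp.copy()
            part["ID"] = new_id
            part["STUDY"] = f"{grp['STUDY'].iloc[0]}-{aid}"
            parts.append(part)
    return pd.concat(parts, ignore_index=True)


class TestBootstrap:
    def test_stratified_resampling_preserves_study_counts(self, small_dataset):
        rng = np.random.default_rng(0)
        rep = resample_animals(small_dataset, rng, stratify_by_study=True)
        orig = small_dataset.groupby("STUDY")["ID"].nunique()
        new = rep.groupby("STUDY")["ID"].nunique()
        assert (orig.sort_index() == new.sort_index()).all()

    def test_duplicated_identical_animals_collapse_percentiles(
            self, duplicated_animal_data):
        point = fit_plasma(duplicated_animal_data, n_starts=1, maxiter=250,
                           explore_maxiter=None, seed=0)
        res = bootstrap(duplicated_animal_data, "plasma", n_replicates=3,
                        seed=0, point=point,
                        fit_kwargs=dict(maxiter=120, explore_maxiter=None))
        assert res.n_failed == 0
        span = (res.summary["p95"] - res.summary["p5"]).abs()
        assert (span / res.summary["median"].abs().clip(lower=1e-12) < 0.02).all()

    def test_same_seed_reproduces_summary(self, duplicated_animal_data):
        point = fit_plasma(duplicated_animal_data, n_starts=1, maxiter=250,
                           explore_maxiter=None, seed=0)
        kw = dict(maxiter=60, explore_maxiter=None)
        a = bootstrap(duplicated_animal_data, "plasma", 2, seed=9,
                      point=point, fit_kwargs=kw)
        b = bootstrap(duplicated_animal_data, "plasma", 2, seed=9,
                      point=point, fit_kwargs=kw)
        pd.testing.assert_frame_equal(a.summary, b.summary)

    def test_rejects_nonpositive_replicates(self, small_dataset):
        with pytest.raises(ValueError):
            bootstrap(small_dataset, "plasma", 0)


class TestDerivedParameters:
    def test_association_rates_and_fu_ratio(self, params):
        d = derived_parameters(params)
        assert round_sig(d["kon_D2"]) == 1.45
        assert round_sig(d["kon_5HT2A"]) == 2.40
        assert round_sig(d["fu_ratio_R"]) == 0.876

    def test_zero_denominator_raises(self, params):
        bad = params.with_brain(Kd_D2=0.0)
        with pytest.raises(ZeroDivisionError):
            derived_parameters(bad)

    def test_nested_model_selection_threshold(self):
        assert lr_test(107.0, 100.0)          # delta 7 > 6.64
        assert not lr_test(106.0, 100.0)      # delta 6 < 6.64
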