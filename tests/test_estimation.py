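"""Likelihood correctness, MAP estimation, shrinkage and SIR."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mdzpopkit as mk
from mdzpopkit.config import design_preset
from mdzpopkit.datasim import EVENT_COLUMNS
from mdzpopkit.estimation import SirSchedule, run_sir
from mdzpopkit.parameters import InvalidParameterError


def _subject_frame(times, dv_mdz, trt="constitutive", dose=("oral", 3.0)):
    """A minimal one-subject event table with MDZ observations only."""
    rows = [dict(ID=1, OCC=1, TIME=0.0, EVID=1, AMT=dose[1], ROUTE=dose[0],
                 CMT=".", DV=np.nan, MDV=1, BLQ=0, LLOQ=np.nan, WT=70.0,
                 AGE=26.5, SEX="M", TRT=trt)]
    for t, dv in zip(times, dv_mdz):
        rows.append(dict(ID=1, OCC=1, TIME=t, EVID=0, AMT=0.0, ROUTE=".",
                         CMT="MDZ", DV=dv, MDV=0, BLQ=0, LLOQ=0.0, WT=70.0,
                         AGE=26.5, SEX="M", TRT=trt))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


class TestNeg2llIndividual:
    def test_matches_hand_computed_two_observation_case(self, pop, re_zero, effects):
        # all random effects clamped (zero variances): -2LL is the plain
        # Gaussian sum evaluated by independent arithmetic
        times = [2.0, 4.0]
        prof = mk.solve_profile(pop, mk.DoseRegimen.oral(3.0), times)
        pred = prof.concentration("MDZ")
        dv = pred * np.array([1.1, 0.9])
        frame = _subject_frame(times, dv)
        val = mk.neg2ll_individual({}, [{}], frame, pop, re_zero,
                                   effects["constitutive"])
        sd = 0.149 * pred  # late proportional error for MDZ
        oracle = np.sum(np.log(2 * np.pi) + 2 * np.log(sd)
                        + ((dv - pred) / sd) ** 2)
        assert val == pytest.approx(oracle, rel=1e-10)

    def test_zero_residual_leaves_normalization_constant(self, pop, re_zero, effects):
        times = [2.0, 4.0]
        pred = mk.solve_profile(pop, mk.DoseRegimen.oral(3.0), times).concentration("MDZ")
        frame = _subject_frame(times, pred)
        val = mk.neg2ll_individual({}, [{}], frame, pop, re_zero,
                                   effects["constitutive"])
        sd = 0.149 * pred
        assert val == pytest.approx(np.sum(np.log(2 * np.pi * sd**2)), rel=1e-10)

    def test_doubling_sigma_shifts_by_analytic_amount(self, pop, re_zero, effects):
        times = [2.0, 4.0, 6.0]
        pred = mk.solve_profile(pop, mk.DoseRegimen.oral(3.0),
                                times).concentration("MDZ")
        dv = pred * 1.05
        frame = _subject_frame(times, dv)
        v1 = mk.neg2ll_individual({}, [{}], frame, pop, re_zero, effects["constitutive"])
        doubled = dataclasses.replace(pop, err_late_mdz=2 * 0.149)
        v2 = mk.neg2ll_individual({}, [{}], frame, doubled, re_zero,
                                  effects["constitutive"])
        resid = np.sum(((dv - pred) / (0.149 * pred)) ** 2)
        assert v2 - v1 == pytest.approx(2 * 3 * np.log(2) + resid * (0.25 - 1.0),
                                        rel=1e-8)

    def test_prior_term_added_for_nonzero_eta(self, pop, re_spec, effects):
        times = [2.0, 4.0]
        pred = mk.solve_profile(pop, mk.DoseRegimen.oral(3.0), times).concentration("MDZ")
        frame = _subject_frame(times, pred)
        v0 = mk.neg2ll_individual({p: 0.0 for p in re_spec.omega2},
                                  [{}], frame, pop, re_spec, effects["constitutive"])
        v1 = mk.neg2ll_individual({**{p: 0.0 for p in re_spec.omega2}, "Qp1": 0.3},
                                  [{}], frame, pop, re_spec, effects["constitutive"])
        # Qp1's eta is independent, so the difference includes its prior
        # quadratic plus the data-term change from the perturbed profile
        assert v1 > v0

    def test_brute_force_density_cross_check(self, pop, re_zero, effects):
        # independent evaluation through scipy.stats on a 3-point profile
        times = [1.0, 3.0, 8.0]
        pred = mk.solve_profile(pop, mk.DoseRegimen.oral(3.0), times).concentration("MDZ")
        dv = pred * np.array([0.8, 1.3, 1.02])
        frame = _subject_frame(times, dv)
        val = mk.neg2ll_individual({}, [{}], frame, pop, re_zero,
                                   effects["constitutive"])
        sig = np.full(3, 0.149)  # all three times are past the 0.5 h split
        oracle = -2 * np.sum(stats.norm.logpdf(dv, loc=pred, scale=sig * pred))
        assert val == pytest.approx(oracle, abs=1e-10)


class TestMapIndividual:
    def test_noiseless_subject_has_zero_modes(self, noiseless_dataset, re_spec, effects):
        pop0, table = noiseless_dataset
        res = mk.map_individual(table[table["ID"] == 1], pop0, re_spec,
                                effects["constitutive"])
        assert res.converged
        assert np.max(np.abs(list(res.eta.values()))) < 1e-3

    def test_known_eta_recovered_from_rich_low_noise_profile(self, pop, re_spec, effects):
        # simulate one subject with a known eta and tiny residual error;
        # IOV disabled so the occasion deviates cannot absorb the eta
        re_iiv = mk.RandomEffectsSpec(omega2=re_spec.omega2,
                                      corr_Vc_Vmet=re_spec.corr_Vc_Vmet,
                                      iov2={k: 0.0 for k in re_spec.iov2})
        quiet = dataclasses.replace(pop, err_early_mdz=0.01, err_late_mdz=0.01,
                                    err_early_ohmdz=0.01, err_late_ohmdz=0.01)
        eta_true = {"Vc": 0.25, "F": -0.3, "Qmet": 0.2}
        from mdzpopkit.parameters import individual_from_effects
        subj = mk.Subject(id=1)
        ind = individual_from_effects(quiet, subj, effects["constitutive"],
                                      eta_true, {})
        times = np.array(mk.SAMPLING_SCHEDULES["rich_24h"][1:])
        rows = []
        rng = np.random.default_rng(3)
        for reg, occ in ((mk.DoseRegimen.oral(3.0), 1), (mk.DoseRegimen.iv(1.0), 2)):
            prof = mk.solve_profile(ind, reg, times)
            rows.append(dict(ID=1, OCC=occ, TIME=reg.events[0].time_h, EVID=1,
                             AMT=reg.events[0].amount_mg,
                             ROUTE=reg.events[0].route, CMT=".", DV=np.nan,
                             MDV=1, BLQ=0, LLOQ=np.nan, WT=70.0, AGE=26.5,
                             SEX="M", TRT="constitutive"))
            for analyte in ("MDZ", "OHMDZ"):
                for t, c in zip(times, prof.concentration(analyte)):
                    dv = c * (1 + rng.normal(0, 0.01))
                    rows.append(dict(ID=1, OCC=occ, TIME=float(t), EVID=0,
                                     AMT=0.0, ROUTE=".", CMT=analyte, DV=dv,
                                     MDV=0, BLQ=0, LLOQ=0.0, WT=70.0,
                                     AGE=26.5, SEX="M", TRT="constitutive"))
        frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        res = mk.map_individual(frame, quiet, re_iiv, effects["constitutive"])
        for name, true in eta_true.items():
            assert res.eta[name] == pytest.approx(true, abs=0.05)

    def test_sparse_schedule_shrinks_harder_than_rich(self, pop, re_spec, effects,
                                                      small_dataset):
        sub = small_dataset[(small_dataset["ID"] == 2)
                            & (small_dataset["OCC"] == 1)].copy()
        rich = mk.map_individual(sub, pop, re_spec, effects["constitutive"])
        sparse = sub[(sub["EVID"] == 1) | sub["TIME"].isin([2.0, 2.5, 3.0, 4.0])]
        thin = mk.map_individual(sparse, pop, re_spec, effects["constitutive"])
        rich_norm = np.linalg.norm(list(rich.eta.values()))
        thin_norm = np.linalg.norm(list(thin.eta.values()))
        assert thin_norm < rich_norm

    def test_no_observations_rejected(self, pop, re_spec, effects, small_dataset):
        empty = small_dataset[small_dataset["EVID"] == 1]
        with pytest.raises(InvalidParameterError):
            mk.map_individual(empty[empty["ID"] == 1], pop, re_spec,
                              effects["constitutive"])


class TestFitPopulation:
    def test_noiseless_single_parameter_recovered_exactly(self, noiseless_dataset,
                                                          re_zero, effects):
        pop0, table = noiseless_dataset
        init = dataclasses.replace(pop0, Qmet=31.0)
        fit = mk.fit_population(table, init, re_zero, free=["Qmet"],
                                effects_map=effects, laplace=False)
        assert fit.converged
        assert fit.estimates["Qmet"] == pytest.approx(24.1, rel=1e-4)

    def test_profile_grid_brackets_optimizer_estimate(self, noiseless_dataset,
                                                      re_zero, effects):
        from mdzpopkit.estimation import _ProfiledObjective, prepare_dataset

        pop0, table = noiseless_dataset
        sdatas = prepare_dataset(table, pop0, effects)
        obj = _ProfiledObjective(
            sdatas, re_zero,
            lambda th: (dataclasses.replace(pop0, Qmet=float(th[0])), effects),
            laplace=False,
        )
        grid = np.array([20.0, 22.0, 24.1, 26.0, 28.0])
        vals = [obj(np.array([g])) for g in grid]
        assert grid[int(np.argmin(vals))] == pytest.approx(24.1)

    def test_ofv_trace_attains_minimum_at_accepted_optimum(self, noiseless_dataset,
                                                           re_zero, effects):
        pop0, table = noiseless_dataset
        init = dataclasses.replace(pop0, Qmet=31.0)
        fit = mk.fit_population(table, init, re_zero, free=["Qmet"],
                                effects_map=effects, laplace=False)
        assert fit.ofv == pytest.approx(min(fit.ofv_trace), abs=1e-6)

    def test_unknown_parameter_rejected(self, small_dataset, pop, re_spec, effects):
        with pytest.raises(InvalidParameterError):
            mk.fit_population(small_dataset, pop, re_spec, free=["Kzzz"],
                              effects_map=effects)

    def test_two_subjects_required(self, small_dataset, pop, re_spec, effects):
        one = small_dataset[small_dataset["ID"] == 1]
        with pytest.raises(InvalidParameterError):
            mk.fit_population(one, pop, re_spec, free=["Qmet"], effects_map=effects)


class TestFitTreatmentEffects:
    def test_zero_generated_delta_estimated_near_zero(self, pop, re_zero, effects):
        # induction arm simulated WITHOUT any induction effect: the
        # estimated delta must be ~0 (tiny residual error retained)
        quiet = dataclasses.replace(pop, err_early_mdz=0.02, err_late_mdz=0.02,
                                    err_early_ohmdz=0.02, err_late_ohmdz=0.02)
        null_effects = dict(effects)
        null_effects["induction"] = mk.TreatmentEffects(category="induction")
        design = design_preset("induction_two_arm")
        table = mk.simulate_dataset(design, quiet, re_zero, null_effects, rng_seed=2)
        fit = mk.fit_treatment_effects(table, quiet, re_zero, null_effects,
                                       free=[("induction", "d_Qmet")], laplace=False)
        assert abs(fit.estimates["induction.d_Qmet"]) < 0.5

    def test_missing_arm_rejected(self, small_dataset, pop, re_spec, effects):
        with pytest.raises(InvalidParameterError):
            mk.fit_treatment_effects(small_dataset, pop, re_spec, effects,
                                     free=[("induction", "d_Qmet")])


class TestEtaShrinkage:
    def test_all_zero_ebes_give_full_shrinkage(self, re_spec):
        ebes = pd.DataFrame(dict(ID=np.arange(50), OCC=1, TRT="constitutive",
                                 parameter="F", eta=0.0, kappa=0.0, value=0.276))
        shr = mk.eta_shrinkage(ebes, re_spec)
        assert shr["F"] == pytest.approx(1.0)

    def test_unshrunken_normal_draws_give_near_zero(self, re_spec, rng):
        etas = rng.normal(0, np.sqrt(0.234), 4000)
        ebes = pd.DataFrame(dict(ID=np.arange(4000), OCC=1, TRT="constitutive",
                                 parameter="F", eta=etas, kappa=0.0, value=0.276))
        assert abs(mk.eta_shrinkage(ebes, re_spec)["F"]) < 0.05

    def test_sparse_design_shrinks_more_than_rich(self, pop, re_spec, effects,
                                                  small_dataset):
        rich = mk.compute_ebes(small_dataset, pop, re_spec, effects)
        sparse_tab = small_dataset[(small_dataset["EVID"] == 1)
                                   | small_dataset["TIME"].isin([2.0, 2.5, 3.0, 4.0])]
        sparse = mk.compute_ebes(sparse_tab, pop, re_spec, effects)
        s_rich = mk.eta_shrinkage(rich, re_spec)
        s_sparse = mk.eta_shrinkage(sparse, re_spec)
        # bioavailability is only informed by the observations themselves,
        # so four samples per profile must shrink its EBEs harder
        assert s_sparse["F"] > s_rich["F"]


class TestSir:
    def test_default_schedule_matches_published_iterations(self):
        sched = SirSchedule()
        assert [m for m, _ in sched.iterations] == [1000, 1000, 1000, 2000, 2000]
        assert [n for _, n in sched.iterations] == [200, 400, 500, 1000, 1000]

    def test_resamples_cannot_exceed_samples(self):
        with pytest.raises(InvalidParameterError):
            SirSchedule(iterations=((100, 200),))

    def test_flat_likelihood_returns_proposal_percentiles(self):
        res = run_sir(lambda th: np.zeros(th.shape[0]), {"x": 0.0},
                      np.array([[1.0]]), rng_seed=1)
        lo, hi = res.ci95["x"]
        # resampling a flat posterior reproduces the proposal itself
        assert lo == pytest.approx(-1.96, abs=0.25)
        assert hi == pytest.approx(1.96, abs=0.25)

    def test_gaussian_loglik_matches_conjugate_ci(self):
        mu, sd = 3.0, 0.7

        def loglik(th):
            return -0.5 * ((np.atleast_2d(th)[:, 0] - mu) / sd) ** 2

        # wide proposal/prior so the prior contribution is negligible
        res = run_sir(loglik, {"x": 2.8}, np.array([[25.0]]), rng_seed=4)
        lo, hi = res.ci95["x"]
        assert res.n_iterations == 5
        assert lo == pytest.approx(mu - 1.96 * sd, abs=0.15)
        assert hi == pytest.approx(mu + 1.96 * sd, abs=0.15)

    def test_degenerate_weights_trigger_inflation_warning(self):
        def spiky(th):
            return -5e3 * (np.atleast_2d(th)[:, 0] - 5.0) ** 2

        with pytest.warns(UserWarning, match="inflating"):
            run_sir(spiky, {"x": 0.0}, np.array([[0.001]]),
                    SirSchedule(iterations=((500, 100),)), rng_seed=0)
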