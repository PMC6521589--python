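"""Parameter estimation: self-consistency, sequential scheme, markers."""

import math

import numpy as np
import pandas as pd
import pytest

from chiralpk import estimation as est
from chiralpk.estimation import (
    OneCompartmentParams,
    TwoCompartmentParams,
    biexp_clearance,
    secondary_parameters,
    summarize_group,
    two_compartment_curve,
)
from chiralpk.model import DoseEvent, EnantiomerParams, ValidationError, simulate_iv_bolus, simulate_oral

from conftest import records_from_curves

IV = DoseEvent(0.0, "iv", 5.0)
PO = DoseEvent(0.0, "oral", 5.0)


def iv_records(params, schedule):
    t = np.asarray(schedule.iv[1:], float)
    r, s = simulate_iv_bolus(params, IV, t)
    return records_from_curves({"R": r.concentrations, "S": s.concentrations}, t)


def oral_records(params, schedule):
    t = np.asarray(schedule.oral_rich[1:], float)
    r, s = simulate_oral(params, PO, t)
    return records_from_curves({"R": r.concentrations, "S": s.concentrations}, t)


class TestIVFit:
    def test_noiseless_recovery_per_age_group(self, age_group_params, schedule):
        """fit(simulate(theta)) = theta at the study IV sampling times."""
        _, p = age_group_params
        res = est.fit_iv_enantiomers(iv_records(p, schedule), IV)
        assert res.converged
        q = res.params
        for name in ("V_R", "Cl_R", "Cl_RtoS", "V_S", "Cl_S"):
            assert getattr(q, name) == pytest.approx(getattr(p, name), rel=1e-6), name

    def test_absent_inversion_estimated_at_lower_bound(self, schedule):
        p = EnantiomerParams(V_R=300, Cl_R=8, Cl_RtoS=0.0, V_S=250, Cl_S=3)
        res = est.fit_iv_enantiomers(iv_records(p, schedule), IV)
        assert res.params.Cl_RtoS == pytest.approx(0.0, abs=1e-6)

    def test_too_few_observations_rejected(self):
        rec = records_from_curves({"R": [5.0, 3.0], "S": [4.0, 2.0]}, [5.0, 10.0])
        with pytest.raises(ValidationError):
            est.fit_iv_enantiomers(rec, IV)

    def test_blq_records_excluded_from_fit(self, schedule):
        p = EnantiomerParams(V_R=300, Cl_R=8, Cl_RtoS=4, V_S=250, Cl_S=3)
        rec = iv_records(p, schedule)
        rec["blq_flag"] = False
        # corrupt two rows but mark them BLQ: the fit must ignore them
        poisoned = rec.copy()
        poisoned.loc[poisoned.index[:2], "conc_ug_per_ml"] = 99.0
        poisoned.loc[poisoned.index[:2], "blq_flag"] = True
        res = est.fit_iv_enantiomers(poisoned, IV)
        assert res.params.V_R == pytest.approx(300, rel=1e-5)


class TestOralFit:
    def test_noiseless_ka_f_recovery(self, age_group_params, schedule):
        _, p = age_group_params
        res = est.fit_oral_enantiomers(
            oral_records(p, schedule), PO, cl_r_to_s=p.Cl_RtoS, iv_params=p
        )
        for name in ("ka_R", "ka_S", "F_R", "F_S"):
            assert getattr(res.params, name) == pytest.approx(getattr(p, name), rel=1e-5), name

    def test_f_above_one_not_clipped(self, schedule):
        """The neonatal group reports F_R = 126.2%; estimates above 1 must
        survive unclipped."""
        p = EnantiomerParams(V_R=329.9, Cl_R=10.6, Cl_RtoS=9.3, V_S=248.5, Cl_S=1.9,
                             ka_R=0.1, ka_S=0.07, F_R=1.262, F_S=0.869)
        res = est.fit_oral_enantiomers(oral_records(p, schedule), PO,
                                       cl_r_to_s=p.Cl_RtoS, iv_params=p)
        assert res.params.F_R == pytest.approx(1.262, rel=1e-5)
        assert res.params.F_R > 1.0

    def test_concentration_scale_equivariance(self, schedule):
        """Halving all concentrations halves F and leaves ka unchanged."""
        p = EnantiomerParams(V_R=300, Cl_R=8, Cl_RtoS=4, V_S=250, Cl_S=3,
                             ka_R=0.06, ka_S=0.04, F_R=0.9, F_S=0.8)
        rec = oral_records(p, schedule)
        half = rec.copy()
        half["conc_ug_per_ml"] *= 0.5
        full = est.fit_oral_enantiomers(rec, PO, cl_r_to_s=4.0, iv_params=p)
        halved = est.fit_oral_enantiomers(half, PO, cl_r_to_s=4.0, iv_params=p)
        assert halved.params.F_R == pytest.approx(0.5 * full.params.F_R, rel=1e-5)
        assert halved.params.F_S == pytest.approx(0.5 * full.params.F_S, rel=1e-5)
        assert halved.params.ka_R == pytest.approx(full.params.ka_R, rel=1e-5)
        assert halved.params.ka_S == pytest.approx(full.params.ka_S, rel=1e-5)

    def test_frozen_inversion_clearance_bit_identical(self, schedule):
        p = EnantiomerParams(V_R=300, Cl_R=8, Cl_RtoS=4, V_S=250, Cl_S=3,
                             ka_R=0.06, ka_S=0.04, F_R=0.9, F_S=0.8)
        frozen = 4.000000000000123
        res = est.fit_oral_enantiomers(oral_records(p, schedule), PO,
                                       cl_r_to_s=frozen, iv_params=p)
        assert res.params.Cl_RtoS == frozen  # exact, not approx

    def test_missing_inversion_clearance_rejected(self, schedule):
        p = EnantiomerParams(V_R=300, Cl_R=8, Cl_RtoS=4, V_S=250, Cl_S=3,
                             ka_R=0.06, ka_S=0.04, F_R=0.9, F_S=0.8)
        with pytest.raises(ValidationError):
            est.fit_oral_enantiomers(oral_records(p, schedule), PO)


class TestTotalFit:
    def test_noiseless_monoexponential_recovery(self, schedule):
        t = np.asarray(schedule.iv[1:], float)
        v, cl = 280.0, 4.0
        rec = records_from_curves({"total": 5000.0 / v * np.exp(-(cl / v) * t)}, t)
        res = est.fit_total_one_compartment(rec, IV)
        assert res.params.V == pytest.approx(v, rel=1e-6)
        assert res.params.Cl == pytest.approx(cl, rel=1e-6)

    def test_all_zero_rejected(self, schedule):
        t = np.asarray(schedule.iv[1:], float)
        rec = records_from_curves({"total": np.zeros_like(t)}, t)
        with pytest.raises(ValidationError):
            est.fit_total_one_compartment(rec, IV)

    def test_symmetric_enantiomer_sum_reduces_to_one_compartment(self, schedule):
        """R+S of a symmetric pair without inversion is a one-compartment
        curve with the same V and Cl at the full racemic dose."""
        p = EnantiomerParams(V_R=300, Cl_R=6, Cl_RtoS=0.0, V_S=300, Cl_S=6)
        t = np.asarray(schedule.iv[1:], float)
        r, s = simulate_iv_bolus(p, IV, t)
        rec = records_from_curves({"total": r.concentrations + s.concentrations}, t)
        res = est.fit_total_one_compartment(rec, IV)
        assert res.params.V == pytest.approx(300, rel=1e-6)
        assert res.params.Cl == pytest.approx(6, rel=1e-6)


class TestMarkers:
    def test_iohexol_noiseless_recovery(self, schedule):
        truth = TwoCompartmentParams(V1=180.0, Cl=2.5, Cl_d=5.0, V2=120.0)
        t = np.asarray(schedule.marker[1:], float)
        c = two_compartment_curve(truth, 64.7, t).concentrations
        rec = records_from_curves({"iohexol": c}, t)
        res = est.fit_iohexol_gfr(rec)
        assert res.extras["gfr"] == pytest.approx(2.5, rel=1e-6)
        assert res.params.V1 == pytest.approx(180.0, rel=1e-5)
        a, alpha, b, beta = (res.extras[k] for k in ("A", "alpha", "B", "beta"))
        assert alpha > beta > 0

    def test_biexp_clearance_reduces_to_one_compartment_when_b_zero(self):
        assert biexp_clearance(10.0, 0.05, 0.0, 0.01, 64700.0) == pytest.approx(
            64700.0 * 0.05 / 10.0
        )

    def test_pah_noiseless_recovery(self, schedule):
        t = np.asarray(schedule.marker[1:], float)
        v, erpf = 300.0, 12.0
        rec = records_from_curves({"pah": 10000.0 / v * np.exp(-(erpf / v) * t)}, t)
        res = est.fit_pah_erpf(rec)
        assert res.extras["erpf"] == pytest.approx(erpf, rel=1e-6)
        assert res.params.V == pytest.approx(v, rel=1e-6)

    def test_pah_zero_concentrations_rejected(self, schedule):
        t = np.asarray(schedule.marker[1:], float)
        rec = records_from_curves({"pah": np.zeros_like(t)}, t)
        with pytest.raises(ValidationError):
            est.fit_pah_erpf(rec)

    def test_unchanged_gfr_between_occasions_yields_zero_difference(self, schedule):
        """Two noiseless occasions from the same kidney function: the
        paired GFR difference vanishes (the null the trial observed)."""
        truth = TwoCompartmentParams(V1=180.0, Cl=3.5, Cl_d=5.0, V2=120.0)
        t = np.asarray(schedule.marker[1:], float)
        c = two_compartment_curve(truth, 64.7, t).concentrations
        rec = records_from_curves({"iohexol": c}, t)
        g1 = est.fit_iohexol_gfr(rec).extras["gfr"]
        g2 = est.fit_iohexol_gfr(rec.copy()).extras["gfr"]
        assert g2 - g1 == pytest.approx(0.0, abs=1e-12)


class TestSecondaryParameters:
    def test_half_life_consistent_with_study_summary(self):
        """ln2 * V_R / Cl_R for the neonatal group: 21.6 min, within one
        reported SD of the published 22.6 (5.5) min."""
        sp = secondary_parameters(
            EnantiomerParams(V_R=329.9, Cl_R=10.6, Cl_RtoS=9.3, V_S=248.5, Cl_S=1.9),
            IV,
        )
        assert sp["R"].t_half == pytest.approx(21.57, abs=0.01)
        assert abs(sp["R"].t_half - 22.6) < 5.5

    def test_unit_case_half_life_is_ln2(self):
        sp = secondary_parameters(OneCompartmentParams(V=100.0, Cl=100.0), IV)
        assert sp.t_half == pytest.approx(math.log(2.0), rel=1e-12)

    def test_iv_c0_and_auc(self):
        sp = secondary_parameters(OneCompartmentParams(V=250.0, Cl=5.0), IV)
        assert sp.c_peak == pytest.approx(5000.0 / 250.0)
        assert sp.auc_inf == pytest.approx(5000.0 / 5.0)
        assert sp.t_max == 0.0

    def test_oral_tmax_matches_closed_form(self):
        """Bracketed maximization vs ln(ka/ke)/(ka-ke) to 1e-8."""
        v, cl, ka = 300.0, 6.0, 0.05
        ke = cl / v
        sp = secondary_parameters(OneCompartmentParams(V=v, Cl=cl, ka=ka, F=0.9), PO)
        assert sp.t_max == pytest.approx(math.log(ka / ke) / (ka - ke), abs=1e-8)


class TestSummarizeGroup:
    def test_single_subject_has_zero_sd(self):
        df = pd.DataFrame({"age_group": ["1wk"], "Cl_R": [10.0]})
        out = summarize_group(df, ["Cl_R"])
        assert out.loc[0, "Cl_R_mean"] == 10.0
        assert out.loc[0, "Cl_R_std"] == 0.0
        assert out.loc[0, "Cl_R_count"] == 1

    def test_symmetric_pair_mean_and_sd(self):
        a, d = 7.0, 1.5
        df = pd.DataFrame({"age_group": ["4wk", "4wk"], "x": [a - d, a + d]})
        out = summarize_group(df, ["x"])
        assert out.loc[0, "x_mean"] == pytest.approx(a)
        assert out.loc[0, "x_std"] == pytest.approx(d * math.sqrt(2.0))

    def test_matches_numpy_moments_on_random_input(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "age_group": rng.choice(["1wk", "4wk"], 60),
            "v": rng.lognormal(1.0, 0.4, 60),
        })
        out = summarize_group(df, ["v"]).set_index("age_group")
        for g, sub in df.groupby("age_group"):
            x = sub["v"].to_numpy()
            assert out.loc[g, "v_mean"] == pytest.approx(x.mean(), rel=1e-12)
            assert out.loc[g, "v_std"] == pytest.approx(x.std(ddof=1), rel=1e-12)
            assert out.loc[g, "v_median"] == pytest.approx(np.median(x), rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            summarize_group(pd.DataFrame(columns=["age_group", "x"]), ["x"])
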