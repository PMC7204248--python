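"""Datasets, CSV I/O, administrative data cuts and the Kaplan-Meier estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import survcuts as sc
from survcuts.data import FormatError, OutOfSupportError, ValidationError

from conftest import make_censored_dataset


def _write(tmp_path, text, name="d.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadDataset:
    def test_basic_parse(self, tmp_path):
        p = _write(tmp_path, "time,event\n3,1\n5,0\n")
        ds = sc.read_dataset(p)
        assert ds.n == 2 and ds.n_events == 1
        assert ds.times == (3.0, 5.0)

    def test_column_map_and_entry(self, tmp_path):
        p = _write(tmp_path, "t,d,start\n3,1,0\n5,0,2\n")
        ds = sc.read_dataset(p, column_map={"time": "t", "event": "d", "entry": "start"})
        assert ds.entries == (0.0, 2.0)

    def test_missing_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, "time,status\n3,1\n")
        with pytest.raises(FormatError, match="event"):
            sc.read_dataset(p)

    def test_negative_time_names_the_row(self, tmp_path):
        rows = "\n".join(f"{t},1" for t in (3, 4, 5, 6))
        p = _write(tmp_path, f"time,event\n{rows}\n-1,1\n")
        with pytest.raises(ValidationError, match="row 4"):
            sc.read_dataset(p)

    def test_bad_event_value(self, tmp_path):
        p = _write(tmp_path, "time,event\n3,2\n")
        with pytest.raises(ValidationError, match="event"):
            sc.read_dataset(p)

    def test_trial_sized_file(self, tmp_path):
        rows = "\n".join(f"{1 + 0.5 * i},{i % 2}" for i in range(88))
        p = _write(tmp_path, f"time,event\n{rows}\n")
        assert sc.read_dataset(p).n == 88

    def test_roundtrip(self, tmp_path):
        ds = sc.SurvivalDataset((1.5, 2.0), (1, 0), (0.0, 0.5))
        ds.to_csv(tmp_path / "out.csv")
        back = sc.read_dataset(tmp_path / "out.csv")
        assert back.times == ds.times and back.entries == ds.entries


class TestDataCut:
    def test_hand_computed_administrative_censoring(self):
        ds = sc.SurvivalDataset(times=(10.0,), events=(1,), entries=(2.0,))
        cut = sc.apply_data_cut(ds, sc.DataCutSpec(lock_time=7.0))
        assert cut.times == (5.0,) and cut.events == (0,)

    def test_noop_cut_preserves_observations(self):
        ds = sc.SurvivalDataset((5.0, 8.0), (1, 0), (1.0, 2.0))
        cut = sc.apply_data_cut(ds, sc.DataCutSpec(lock_time=100.0))
        assert cut.times == (4.0, 6.0)
        assert cut.events == (1, 0)

    def test_lock_before_entry_errors(self):
        ds = sc.SurvivalDataset((10.0,), (1,), (8.0,))
        with pytest.raises(ValidationError, match="not yet enrolled"):
            sc.apply_data_cut(ds, sc.DataCutSpec(lock_time=5.0))

    def test_cut_composition_is_idempotent(self):
        """Cutting at L1 then re-cutting at L0 < L1 equals a single cut at L0."""
        rng = np.random.default_rng(3)
        n = 50
        entries = rng.uniform(0, 10, n)
        deaths = rng.exponential(15, n)
        cal = sc.SurvivalDataset(tuple(entries + deaths), tuple([1] * n), tuple(entries))
        l0, l1 = 18.0, 30.0
        # intermediate cut kept on the calendar scale
        t1 = np.minimum(np.asarray(cal.times), l1)
        e1 = [e if t < l1 else 0 for t, e in zip(cal.times, cal.events)]
        inter = sc.SurvivalDataset(tuple(t1), tuple(e1), cal.entries)
        once = sc.apply_data_cut(cal, sc.DataCutSpec(l0))
        twice = sc.apply_data_cut(inter, sc.DataCutSpec(l0))
        assert once.times == twice.times and once.events == twice.events


class TestKaplanMeier:
    def test_toy_product_limit(self, toy_curve):
        assert toy_curve.event_times == (3.0, 7.0)
        assert toy_curve.survival == pytest.approx((0.75, 0.375))
        assert toy_curve.at_risk == (4, 2)

    def test_no_events_flat_curve(self):
        km = sc.km_estimate(sc.SurvivalDataset((2, 4, 6), (0, 0, 0)))
        assert km.event_times == ()
        for t in (0, 3, 6):
            assert sc.survival_at(km, t) == 1.0

    def test_all_events_closed_form(self):
        n = 7
        km = sc.km_estimate(sc.SurvivalDataset(tuple(range(1, n + 1)), tuple([1] * n)))
        for k, s in enumerate(km.survival, start=1):
            assert s == pytest.approx((n - k) / n)

    def test_censoring_after_death_at_tied_time(self):
        # death and censoring at t=5: the censored patient is still at risk
        km = sc.km_estimate(sc.SurvivalDataset((5, 5, 8), (1, 0, 1)))
        assert km.at_risk[0] == 3
        assert km.survival[0] == pytest.approx(2 / 3)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.1, 50.0), min_size=1, max_size=25))
    def test_uncensored_km_is_empirical_survivor(self, times):
        ds = sc.SurvivalDataset(tuple(times), tuple([1] * len(times)))
        km = sc.km_estimate(ds)
        t = np.asarray(times)
        for q in np.linspace(0, max(times), 13):
            assert sc.survival_at(km, q) == pytest.approx((t > q).mean(), abs=1e-12)

    def test_reference_agreement_small_batch(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(11)
        for _ in range(20):
            ds = make_censored_dataset(rng, n=rng.integers(5, 40))
            km = sc.km_estimate(ds)
            kmf = KaplanMeierFitter().fit(ds.times_array(), ds.events_array())
            for t, s in zip(km.event_times, km.survival):
                assert abs(kmf.predict(t) - s) < 1e-10


class TestPointEstimateAndRmst:
    def test_step_lookup(self, toy_curve):
        assert sc.survival_at(toy_curve, 6.0) == 0.75
        assert sc.survival_at(toy_curve, 0.0) == 1.0
        assert sc.survival_at(toy_curve, 2.999) == 1.0
        assert sc.survival_at(toy_curve, 3.0) == 0.75  # right-continuous

    def test_out_of_support(self, toy_curve):
        with pytest.raises(OutOfSupportError):
            sc.survival_at(toy_curve, 9.5)
        with pytest.raises(OutOfSupportError):
            sc.rmst_km(toy_curve, 10.0)

    def test_toy_rmst_hand_integration(self, toy_curve):
        assert sc.rmst_km(toy_curve, 9.0) == pytest.approx(6.75)

    def test_rmst_degenerate_horizons(self, toy_curve):
        assert sc.rmst_km(toy_curve, 0.0) == 0.0
        km = sc.km_estimate(sc.SurvivalDataset((4, 7), (0, 0)))
        assert sc.rmst_km(km, 7.0) == pytest.approx(7.0)  # unit survival

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_rmst_monotone_and_bounded(self, seed):
        ds = make_censored_dataset(np.random.default_rng(seed), n=30)
        km = sc.km_estimate(ds)
        taus = np.linspace(0, km.max_follow_up, 9)
        vals = [sc.rmst_km(km, tau) for tau in taus]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
        assert all(v <= tau + 1e-12 for v, tau in zip(vals, taus))
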