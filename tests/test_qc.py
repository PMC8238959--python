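import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ranevs.fixation import Fixation, ivt_classify
from ranevs.qc import (METRIC_COLUMNS, QCParams, RunMetrics,
                       aggregate_conditions, evaluate_run_qc,
                       exclusion_accounting, positional_exclusion_mask,
                       run_metrics_frame)
from ranevs.simulate import SimParams, simulate_run
from ranevs.stimuli import RunSpec


def fake_fixations(n, spacing=0.4, dur=0.2):
    return [Fixation(i * spacing, i * spacing + dur, 100.0, 100.0, 12)
            for i in range(n)]


class TestPositionalExclusion:
    def test_default_mask_retains_2_through_31(self):
        mask = positional_exclusion_mask(36)
        assert mask.sum() == 30
        assert not mask[:2].any() and not mask[-4:].any()
        assert mask[2:32].all()

    def test_zero_exclusions_is_identity(self):
        params = QCParams(exclude_first_items=0, exclude_last_items=0)
        assert positional_exclusion_mask(36, params).all()

    @settings(deadline=None, max_examples=100)
    @given(n=st.integers(1, 60), first=st.integers(0, 10), last=st.integers(0, 10))
    def test_retained_size_is_n_minus_exclusions(self, n, first, last):
        params = QCParams(exclude_first_items=first, exclude_last_items=last)
        if n <= first + last:
            with pytest.raises(ValueError):
                positional_exclusion_mask(n, params)
        else:
            assert positional_exclusion_mask(n, params).sum() == n - first - last


class TestRunQC:
    def test_track_loss_exclusion(self, array, screen, run_spec):
        run = simulate_run(SimParams(seed=3, track_loss_frac=0.4), array,
                           run_spec=run_spec)
        fixes = ivt_classify(run.trace, screen)
        passed, reasons = evaluate_run_qc(run.trace, fixes, run_spec)
        assert not passed and "track_loss" in reasons

    def test_fixation_count_bounds_are_per_condition(self, trace_factory):
        tr = trace_factory(np.arange(0, 30, 1 / 60), np.full(1800, 1.0),
                           np.full(1800, 1.0))
        sym = RunSpec("p", "number", 1)
        non = RunSpec("p", "color", 1)
        _, r = evaluate_run_qc(tr, fake_fixations(55), sym)
        assert "fixation_count" in r
        passed, r = evaluate_run_qc(tr, fake_fixations(55), non)
        assert "fixation_count" not in r
        _, r = evaluate_run_qc(tr, fake_fixations(14), sym)
        assert "fixation_count" in r

    def test_fixation_free_gap_exclusion(self, trace_factory):
        tr = trace_factory(np.arange(0, 30, 1 / 60), np.full(1800, 1.0),
                           np.full(1800, 1.0))
        spec = RunSpec("p", "color", 1)
        # 25 fixations packed into the first 5 s leave a 25 s trailing gap
        fixes = fake_fixations(25, spacing=0.2, dur=0.15)
        _, reasons = evaluate_run_qc(tr, fixes, spec)
        assert "fixation_gap" in reasons

    def test_reasons_accumulate(self, trace_factory):
        t = np.arange(0, 30, 1 / 60)
        valid = np.zeros(t.size, bool)
        valid[: t.size // 2] = True  # 50% loss
        tr = trace_factory(t, np.full(t.size, 1.0), np.full(t.size, 1.0),
                           valid=valid)
        spec = RunSpec("p", "number", 1)
        _, reasons = evaluate_run_qc(tr, fake_fixations(5, spacing=0.3), spec)
        assert set(reasons) >= {"track_loss", "fixation_count", "fixation_gap"}

    def test_clean_simulated_run_passes(self, array, screen, run_spec):
        run = simulate_run(SimParams(seed=3), array, run_spec=run_spec)
        fixes = ivt_classify(run.trace, screen)
        passed, reasons = evaluate_run_qc(run.trace, fixes, run_spec)
        assert passed and reasons == []

    def test_failed_classification_is_a_reason(self, trace_factory):
        tr = trace_factory([0, 0.1], [1, 1], [1, 1])
        passed, reasons = evaluate_run_qc(tr, None, RunSpec("p", "color", 1))
        assert not passed and "classification" in reasons


def metrics(pid, stype, run_index, qc_pass=True, **kw):
    m = RunMetrics(run_spec=RunSpec(pid, stype, run_index))
    for k, v in kw.items():
        setattr(m, k, v)
    m.qc_reasons = [] if qc_pass else ["track_loss"]
    m.qc_pass = qc_pass
    return m


class TestAggregation:
    def test_two_stage_mean(self):
        rows = [metrics("p", "number", 1, naming_time_s=10.0),
                metrics("p", "number", 2, naming_time_s=12.0),
                metrics("p", "letter", 1, naming_time_s=11.0),
                metrics("p", "letter", 2, naming_time_s=13.0)]
        out = aggregate_conditions(rows)
        assert out.loc[0, "naming_time_s"] == pytest.approx(11.5)

    def test_excluded_run_drops_from_type_mean(self):
        rows = [metrics("p", "number", 1, naming_time_s=10.0),
                metrics("p", "number", 2, naming_time_s=12.0),
                metrics("p", "letter", 1, naming_time_s=11.0),
                metrics("p", "letter", 2, naming_time_s=99.0, qc_pass=False)]
        out = aggregate_conditions(rows)
        # letter mean = surviving run (11); symbolic = mean(11, 11) = 11
        assert out.loc[0, "naming_time_s"] == pytest.approx(11.0)

    def test_no_passing_runs_yields_no_row(self):
        rows = [metrics("p", "number", 1, naming_time_s=10.0, qc_pass=False)]
        assert aggregate_conditions(rows).empty

    def test_excluded_runs_never_leak(self):
        rows = [metrics("p", "color", 1, refixations=5, perseverations=5,
                        regressions=0),
                metrics("p", "color", 2, refixations=500, perseverations=500,
                        regressions=0, qc_pass=False)]
        out = aggregate_conditions(rows)
        assert out.loc[0, "refixations"] == 5

    def test_matches_group_by_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        rows = []
        for pid in ("a", "b", "c"):
            for stype in ("color", "object", "number", "letter"):
                for ri in (1, 2):
                    rows.append(metrics(
                        pid, stype, ri, qc_pass=bool(rng.random() > 0.2),
                        naming_time_s=float(rng.uniform(10, 30)),
                        refixations=int(rng.integers(0, 20)),
                        perseverations=0, regressions=0))
        rows[-1].refixations = rows[-1].perseverations + rows[-1].regressions
        out = aggregate_conditions(rows)
        df = run_metrics_frame(rows)
        kept = df[df.qc_pass]
        for _, r in out.iterrows():
            sub = kept[(kept.participant_id == r.participant_id)
                       & (kept.condition == r.condition)]
            expect = sub.groupby("stimulus_type")["naming_time_s"].mean().mean()
            assert r.naming_time_s == pytest.approx(expect)

    def test_mean_lies_within_contributing_range(self, array):
        runs = [simulate_run(SimParams(seed=s), array) for s in range(4)]
        from ranevs.pipeline import score_run
        ms = [score_run(r.trace, r.track, array) for r in runs]
        for i, m in enumerate(ms):
            m.run_spec = RunSpec("p", "object", 1 + i % 2)
        # force distinct stimulus types for two-stage structure
        vals = [m.naming_time_s for m in ms]
        out = aggregate_conditions(ms[:2])
        assert min(vals[:2]) <= out.loc[0, "naming_time_s"] <= max(vals[:2])


class TestExclusionAccounting:
    def make_table(self, flags):
        rows = []
        for i, (dx, cu, ok) in enumerate(flags):
            rows.append({"participant_id": f"p{i}", "diagnosis": dx,
                         "culture": cu, "qc_pass": ok})
        return pd.DataFrame(rows)

    def test_no_exclusions(self):
        t = self.make_table([("ASD", "HK", True), ("control", "US", True)])
        out = exclusion_accounting(t)
        assert (out["fraction_excluded"] == 0).all()

    def test_forty_percent(self):
        t = self.make_table([("ASD", "HK", i >= 4) for i in range(10)])
        out = exclusion_accounting(t)
        assert out.loc[0, "n_excluded"] == 4
        assert out.loc[0, "fraction_excluded"] == pytest.approx(0.4)

    def test_matches_per_run_tally(self):
        rng = np.random.default_rng(1)
        flags = [(dx, cu, bool(rng.random() > 0.3))
                 for dx in ("ASD", "control") for cu in ("HK", "US")
                 for _ in range(25)]
        t = self.make_table(flags)
        out = exclusion_accounting(t).set_index(["diagnosis", "culture"])
        for (dx, cu), grp in t.groupby(["diagnosis", "culture"]):
            assert out.loc[(dx, cu), "n_excluded"] == (~grp.qc_pass).sum()
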