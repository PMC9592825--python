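"""Outlier flagging: history gates, direction semantics, scoring rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sstmon.anomaly import (
    INSUFFICIENT,
    OK,
    OUTLIER,
    AnomalyConfig,
    classify_run,
    iforest_flags,
    quantile_flags,
    quantile_intervals,
    reevaluate_history,
    score_run,
)
from sstmon.errors import SchemaError
from sstmon.indicators import DIRECTIONS, HIGHER_BETTER

NAMES = list(DIRECTIONS)


def _history(n: int, seed: int = 0) -> pd.DataFrame:
    """Unit-variance baseline history over all 16 indicators."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        10.0 + rng.standard_normal((n, 16)), columns=NAMES,
        index=[f"run{i:03d}" for i in range(n)],
    )


def _harmful_shift(name: str, sds: float = 10.0) -> float:
    """Shift in the direction that should worry the operator."""
    return -sds if DIRECTIONS[name] == HIGHER_BETTER else sds


class TestHistoryGates:
    def test_quantile_needs_60_runs(self):
        assert quantile_intervals(_history(59)) is None
        assert quantile_intervals(_history(60)) is not None
        flags = quantile_flags(_history(59), _history(1).iloc[0])
        assert set(flags.values()) == {INSUFFICIENT}

    def test_iforest_needs_20_runs(self):
        flags = iforest_flags(_history(19), _history(1).iloc[0])
        assert set(flags.values()) == {INSUFFICIENT}
        flags = iforest_flags(_history(20), _history(1, seed=9).iloc[0])
        assert INSUFFICIENT not in flags.values()

    def test_insufficient_history_leaves_run_unscored(self):
        verdict = classify_run(_history(5), _history(1).iloc[0])
        assert verdict.quality == "unscored"


class TestQuantileMethod:
    def test_bounds_match_normal_quantiles(self):
        history = _history(1000, seed=3) - 10.0
        intervals = quantile_intervals(history)
        lo, hi = intervals["s2n"]  # higher_better: only a lower bound
        assert lo == pytest.approx(-1.645, abs=0.15)
        assert hi == np.inf
        lo, hi = intervals["average_accuracy"]  # lower_better: upper bound
        assert lo == -np.inf
        assert hi == pytest.approx(1.645, abs=0.15)

    def test_beneficial_extreme_not_flagged(self):
        history = _history(100, seed=1)
        run = history.iloc[0].copy()
        run["average_accuracy"] = -50.0  # extremely accurate: good news
        run["s2n"] = 1e6  # huge signal-to-noise: good news
        flags = quantile_flags(history, run)
        assert flags["average_accuracy"] == OK
        assert flags["s2n"] == OK

    def test_harmful_extreme_flagged(self):
        history = _history(100, seed=1)
        run = history.iloc[0].copy()
        run["average_accuracy"] = 10.0 + 10.0
        flags = quantile_flags(history, run)
        assert flags["average_accuracy"] == OUTLIER


class TestIsolationForestMethod:
    def test_ten_sd_shift_flagged_and_beneficial_side_rescinded(self):
        history = _history(60, seed=5)
        run = history.mean()
        run["chemical_dirt"] += 10.0  # lower_better, harmful side
        run["s2n"] += 10.0  # higher_better, beneficial side
        flags = iforest_flags(history, run, AnomalyConfig(seed=1))
        assert flags["chemical_dirt"] == OUTLIER
        assert flags["s2n"] == OK

    def test_methods_agree_on_gross_anomalies(self):
        hits_q = hits_f = 0
        for seed in range(10):
            history = _history(60, seed=seed)
            run = history.mean()
            run["signal"] += _harmful_shift("signal")
            hits_q += quantile_flags(history, run)["signal"] == OUTLIER
            hits_f += iforest_flags(history, run, AnomalyConfig(seed=seed))["signal"] == OUTLIER
        assert hits_q == 10 and hits_f == 10

    def test_deterministic_given_seed(self):
        history = _history(40, seed=2)
        run = history.iloc[-1]
        cfg = AnomalyConfig(seed=7)
        assert iforest_flags(history, run, cfg) == iforest_flags(history, run, cfg)

    def test_degenerate_constant_indicator_never_flagged(self):
        history = _history(30, seed=0)
        history["signal"] = 5.0
        run = history.iloc[0].copy()
        run["signal"] = 5.0
        flags = iforest_flags(history, run, AnomalyConfig(seed=0))
        assert flags["signal"] == OK

    def test_reevaluation_covers_whole_history(self):
        history = _history(40, seed=8)
        history.iloc[10, NAMES.index("chemical_dirt")] += 12.0
        mat = reevaluate_history(history, AnomalyConfig(seed=0))
        assert mat.shape == history.shape
        assert bool(mat.iloc[10]["chemical_dirt"])
        # cap: at most ceil(n/10) flags per indicator
        assert int(mat.sum(axis=0).max()) <= int(np.ceil(len(history) / 10))


class TestScoreRun:
    @pytest.mark.parametrize(
        "n_outliers,quality,score",
        [(0, "good", 16), (4, "good", 12), (5, "bad", 11), (16, "bad", 0)],
    )
    def test_printed_rule_boundary(self, n_outliers, quality, score):
        flags = {
            name: OUTLIER if i < n_outliers else OK
            for i, name in enumerate(NAMES)
        }
        verdict = score_run(flags)
        assert verdict.quality == quality
        assert verdict.score == score

    def test_any_insufficient_flag_means_unscored(self):
        flags = {name: OK for name in NAMES}
        flags[NAMES[0]] = INSUFFICIENT
        assert score_run(flags).quality == "unscored"

    def test_wrong_flag_count_rejected(self):
        with pytest.raises(SchemaError):
            score_run({"signal": OK})

    def test_unknown_flag_value_rejected(self):
        flags = {name: OK for name in NAMES}
        flags[NAMES[0]] = "maybe"
        with pytest.raises(SchemaError):
            score_run(flags)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.sampled_from([OK, OUTLIER, INSUFFICIENT]),
            min_size=16, max_size=16,
        )
    )
    def test_score_quality_consistency_for_any_flags(self, flag_values):
        """For every flag assignment: score counts ok flags, quality follows
        the >4 rule unless any indicator lacks history."""
        flags = dict(zip(NAMES, flag_values))
        verdict = score_run(flags)
        assert verdict.score == sum(f == OK for f in flag_values)
        n_out = sum(f == OUTLIER for f in flag_values)
        if INSUFFICIENT in flag_values:
            assert verdict.quality == "unscored"
        else:
            assert verdict.quality == ("bad" if n_out > 4 else "good")

    def test_five_harmful_shifts_make_run_bad(self):
        """60-run baseline, new run with 5 indicators shifted 10 SD."""
        history = _history(60, seed=4)
        run = history.mean()
        for name in NAMES[:5]:
            run[name] += _harmful_shift(name)
        verdict = classify_run(history, run, AnomalyConfig(seed=0))
        assert verdict.quality == "bad"
        assert verdict.n_outliers() >= 5
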