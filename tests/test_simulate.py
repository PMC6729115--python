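"""Phase patterns and the dropout-walk simulator."""

import numpy as np
import pytest
from scipy import stats

import attriphase as ap
from attriphase.evaluate import STUDY_GRID


class TestMakePattern:
    def test_constant_patterns_are_flat(self):
        mild = ap.make_pattern("constant", "mild", "none", K=20)
        severe = ap.make_pattern("constant", "severe", "none", K=20)
        assert np.all(mild.hazards == ap.DEFAULT_RATES["stable"])
        assert np.all(severe.hazards == ap.DEFAULT_RATES["severe"])
        assert mild.true_n_phases == severe.true_n_phases == 1
        assert mild.true_transitions == ()

    def test_two_phase_middle_switches_at_question_10(self):
        p = ap.make_pattern("two_phase", "severe", "middle", K=20)
        assert np.all(p.hazards[:9] == ap.DEFAULT_RATES["stable"])
        assert np.all(p.hazards[9:] == ap.DEFAULT_RATES["severe"])
        assert p.true_n_phases == 2 and p.true_transitions == (10,)

    def test_two_phase_reverse_starts_with_dropout_phase(self):
        p = ap.make_pattern("two_phase_reverse", "mild", "start", K=20)
        assert np.all(p.hazards[:4] == ap.DEFAULT_RATES["mild"])
        assert np.all(p.hazards[4:] == ap.DEFAULT_RATES["stable"])

    def test_three_phase_middle_has_two_transitions(self):
        p = ap.make_pattern("three_phase", "severe", "middle", K=20)
        assert p.true_n_phases == 3 and p.true_transitions == (8, 14)
        assert np.all(p.hazards[7:13] == ap.DEFAULT_RATES["severe"])
        assert np.all(p.hazards[:7] == ap.DEFAULT_RATES["stable"])
        assert np.all(p.hazards[13:] == ap.DEFAULT_RATES["stable"])

    @pytest.mark.parametrize(
        "shape,location",
        [("constant", "middle"), ("two_phase", "none"), ("two_phase", "ends"),
         ("three_phase", "start")],
    )
    def test_incompatible_shape_location_rejected(self, shape, location):
        with pytest.raises(ValueError, match="location"):
            ap.make_pattern(shape, "mild", location, K=20)

    def test_rate_override_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="rate"):
            ap.make_pattern("constant", "mild", "none", K=20, rates={"stable": 1.5})

    def test_rate_override_merging_regimes_recomputes_truth(self):
        p = ap.make_pattern("two_phase", "severe", "middle", K=20,
                            rates={"stable": 0.04})
        assert p.true_n_phases == 1 and p.true_transitions == ()


class TestSimulateDataset:
    def test_zero_hazard_everyone_completes(self, rng):
        p = ap.PhasePattern("flat0", np.zeros(5), 1, ())
        ds = ap.simulate_dataset(p, 50, rng)
        assert ds.completed.all()

    def test_certain_dropout_at_question_one(self, rng):
        h = np.zeros(5)
        h[0] = 1.0
        p = ap.PhasePattern("sure", h, 2, (2,))
        ds = ap.simulate_dataset(p, 50, rng)
        assert all(e == 1 for _, e in ds.records())

    def test_completion_fraction_matches_survival_product(self, rng):
        p = ap.make_pattern("constant", "mild", "none", K=20,
                            rates={"stable": 0.05})
        ds = ap.simulate_dataset(p, 10_000, rng)
        expected = 0.95**20
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(ds.completed.mean() - expected) < 3 * se

    def test_exit_distribution_matches_closed_form(self, rng):
        hazards = np.array([0.1, 0.3, 0.05, 0.2])
        p = ap.PhasePattern("mix", hazards, 4, (2, 3, 4))
        n = 20_000
        ds = ap.simulate_dataset(p, n, rng)
        surv = np.concatenate(([1.0], np.cumprod(1 - hazards)))
        probs = np.append(hazards * surv[:-1], surv[-1])  # exit at 1..4, completed
        observed = np.bincount(ds.exit_codes, minlength=6)[1:]
        chi2, pval = stats.chisquare(observed, probs * n)
        assert pval > 0.001


class TestSimulateBatch:
    def test_same_master_seed_is_bitwise_reproducible(self):
        p = ap.make_pattern("two_phase", "mild", "middle", K=10)
        cfg = ap.SimulationConfig(n_participants=30, n_replicates=5, master_seed=99)
        runs = [
            [ds.exit_codes.tolist() for ds in ap.simulate_batch(p, cfg)]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_replicates_are_distinct(self):
        p = ap.make_pattern("constant", "severe", "none", K=20)
        cfg = ap.SimulationConfig(n_participants=200, n_replicates=100, master_seed=3)
        seen = {tuple(ds.exit_codes) for ds in ap.simulate_batch(p, cfg)}
        assert len(seen) == 100

    def test_pooled_hazard_recovery_constant(self):
        """Pooled empirical hazards stay within 3 binomial SEs of truth."""
        h = 0.05
        p = ap.make_pattern("constant", "mild", "none", K=20, rates={"stable": h})
        cfg = ap.SimulationConfig(n_participants=200, n_replicates=500, master_seed=8)
        at_risk = np.zeros(20)
        dropped = np.zeros(20)
        for ds in ap.simulate_batch(p, cfg):
            s = ap.summarize(ds)
            at_risk += s.n_at_risk
            dropped += s.n_dropped
        emp = dropped / at_risk
        se = np.sqrt(h * (1 - h) / at_risk)
        assert np.all(np.abs(emp - h) < 3.5 * se)


def test_config_validation():
    with pytest.raises(ValueError):
        ap.SimulationConfig(n_participants=0, n_replicates=1, master_seed=0)
    with pytest.raises(ValueError):
        ap.PhasePattern("bad", np.array([0.5, 1.5]), 2, (2,))
    with pytest.raises(ValueError, match="inconsistent"):
        ap.PhasePattern("bad", np.array([0.1, 0.2]), 1, ())


def test_study_grid_has_22_cells():
    assert len(STUDY_GRID) == 22
    patterns = ap.default_patterns(K=20)
    assert len({p.name for p in patterns}) == 22
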