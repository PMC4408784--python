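"""Generator correctness: modification statistics, the RT-walk termination
law, selection behaviour, and agreement with the analytic stop fractions."""

import numpy as np
import pytest

from shapes_kit.counting import runoff_fraction, termination_counts
from shapes_kit.errors import ConfigurationError
from shapes_kit.simdata import (
    SimulationConfig,
    apply_selection,
    expected_stop_fraction,
    ground_truth,
    simulate_experiment,
    simulate_fragments,
    simulate_modifications,
    size_filter,
    synthetic_structure,
)


def make_config(L=100, **kw):
    paired = kw.pop("paired", np.arange(L) % 2 == 0)
    defaults = dict(n_molecules=1000, min_fragment_len=1, dropoff_rate=0.0)
    defaults.update(kw)
    return SimulationConfig(paired=paired, **defaults)


class TestModifications:
    def test_zero_rates_give_no_modifications(self, rng):
        cfg = make_config(mod_rate_unpaired=0.0, mod_rate_paired=0.0)
        assert not simulate_modifications(cfg, rng).any()

    def test_mean_modifications_match_analytic_expectation(self, rng):
        # 50 unpaired at 0.02 + 50 paired at 0.002 -> 1.1 adducts/molecule
        paired = np.zeros(100, bool)
        paired[50:] = True
        cfg = make_config(
            L=100, paired=paired, n_molecules=10_000,
            mod_rate_unpaired=0.02, mod_rate_paired=0.002,
        )
        per_molecule = simulate_modifications(cfg, rng).sum(axis=1)
        expect = 50 * 0.02 + 50 * 0.002
        se = per_molecule.std(ddof=1) / np.sqrt(len(per_molecule))
        assert abs(per_molecule.mean() - expect) < 3 * se

    def test_fixed_seed_reproduces_modification_sets(self):
        cfg = make_config(mod_rate_unpaired=0.05, mod_rate_paired=0.01)
        a = simulate_modifications(cfg, np.random.default_rng(7))
        b = simulate_modifications(cfg, np.random.default_rng(7))
        assert np.array_equal(a, b)

    @pytest.mark.parametrize(
        "kw",
        [
            {"mod_rate_unpaired": 1.5},
            {"mod_rate_unpaired": 0.001, "mod_rate_paired": 0.01},
            {"dropoff_rate": 1.0},
            {"selection_keep": 0.0},
            {"n_molecules": 0},
            {"min_fragment_len": 0},
        ],
    )
    def test_invalid_configuration_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            make_config(**kw)


class TestFragments:
    def test_no_stop_sources_gives_pure_runoff(self, rng):
        cfg = make_config(mod_rate_unpaired=0.0, mod_rate_paired=0.0)
        mods = simulate_modifications(cfg, rng)
        frags = simulate_fragments(mods, cfg, rng)
        assert all(f.left == 1 and f.cause == "runoff" for f in frags)

    def test_one_fragment_per_molecule_before_size_filter(self, rng):
        cfg = make_config(mod_rate_unpaired=0.1, mod_rate_paired=0.05,
                          dropoff_rate=0.01, n_molecules=777)
        frags = simulate_fragments(simulate_modifications(cfg, rng), cfg, rng)
        assert len(frags) == 777

    def test_geometric_termination_law(self):
        # priming fixed at p, drop-off only: P(left=j) = d(1-d)^(p-j) for
        # 1 < j <= p and P(run-off) = (1-d)^(p-1)
        L, p, d, n = 30, 25, 0.08, 50_000
        w = np.zeros(L)
        w[p - 1] = 1.0
        cfg = make_config(
            L=L, n_molecules=n, mod_rate_unpaired=0.0, mod_rate_paired=0.0,
            dropoff_rate=d, priming_weights=w,
        )
        rng = np.random.default_rng(11)
        frags = simulate_fragments(simulate_modifications(cfg, rng), cfg, rng)
        lefts = np.array([f.left for f in frags])
        assert (np.array([f.right for f in frags]) == p).all()
        for j in range(2, p + 1):
            expect = d * (1 - d) ** (p - j)
            emp = (lefts == j).mean()
            se = np.sqrt(expect * (1 - expect) / n)
            assert abs(emp - expect) < 3.6 * se, f"left={j}"
        expect_ro = (1 - d) ** (p - 1)
        se = np.sqrt(expect_ro * (1 - expect_ro) / n)
        assert abs((lefts == 1).mean() - expect_ro) < 3.6 * se

    def test_forced_stop_at_modified_position(self, rng):
        # blocking adduct at i, no read-through, no drop-off -> left = i + 1
        L, i, p = 50, 20, 45
        w = np.zeros(L)
        w[p - 1] = 1.0
        cfg = make_config(L=L, n_molecules=200, priming_weights=w,
                          mod_rate_unpaired=0.0, mod_rate_paired=0.0)
        mods = np.zeros((200, L), bool)
        mods[:, i - 1] = True
        frags = simulate_fragments(mods, cfg, rng)
        assert all(f.left == i + 1 and f.cause == "modification" for f in frags)

    def test_fixed_seed_gives_identical_fragment_lists(self):
        cfg = make_config(mod_rate_unpaired=0.05, mod_rate_paired=0.005,
                          dropoff_rate=0.01)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            runs.append(simulate_fragments(simulate_modifications(cfg, rng), cfg, rng))
        assert runs[0] == runs[1]

    def test_size_filter_counts_discards(self):
        cfg = make_config(L=100, n_molecules=500, dropoff_rate=0.05)
        rng = np.random.default_rng(5)
        frags = simulate_fragments(simulate_modifications(cfg, rng), cfg, rng)
        kept, n_short = size_filter(frags, 30)
        assert len(kept) + n_short == len(frags)
        assert all(f.length >= 30 for f in kept)


class TestSelection:
    def _labelled_fragments(self, rng, n_mod=1000, n_bg=1000):
        cfg = make_config(L=200, n_molecules=n_mod + n_bg,
                          mod_rate_unpaired=0.5, mod_rate_paired=0.5,
                          dropoff_rate=0.02)
        frags = simulate_fragments(simulate_modifications(cfg, rng), cfg, rng)
        return cfg, frags

    def test_zero_leak_retains_only_modification_stops(self, rng):
        cfg, frags = self._labelled_fragments(rng)
        cfg2 = make_config(L=200, selection_keep=0.9, selection_leak=0.0)
        kept = apply_selection(frags, cfg2, rng)
        assert kept and all(f.cause == "modification" for f in kept)

    def test_keep_one_leak_one_is_identity(self, rng):
        cfg, frags = self._labelled_fragments(rng)
        cfg2 = make_config(L=200, selection_keep=1.0, selection_leak=0.999999999)
        assert apply_selection(frags, cfg2, np.random.default_rng(0)) == frags

    def test_binomial_retention_counts(self):
        # 1000 background + 1000 modification stops, keep 0.8 / leak 0.02
        from shapes_kit.fragments import FragmentRecord

        frags = [FragmentRecord("r", 2, 50, "modification")] * 1000 + [
            FragmentRecord("r", 2, 50, "dropoff")
        ] * 1000
        cfg = make_config(L=100, selection_keep=0.8, selection_leak=0.02)
        kept = apply_selection(frags, cfg, np.random.default_rng(3))
        n_mod = sum(f.cause == "modification" for f in kept)
        n_bg = len(kept) - n_mod
        assert abs(n_mod - 800) < 3 * np.sqrt(1000 * 0.8 * 0.2)
        assert abs(n_bg - 20) < 3 * np.sqrt(1000 * 0.02 * 0.98)

    def test_selection_lowers_runoff_fraction_on_same_molecules(self):
        paired, _ = synthetic_structure(400, 0.45, np.random.default_rng(1))
        cfg = SimulationConfig(paired=paired, n_molecules=20_000, seed=9,
                               min_fragment_len=1)
        res = simulate_experiment(cfg, seed=9)
        ro_probed = runoff_fraction(termination_counts(res.arms["probed"], 400))
        ro_sel = runoff_fraction(termination_counts(res.arms["selected"], 400))
        assert ro_sel <= ro_probed


class TestAnalyticTwin:
    def test_all_rates_zero_is_pure_runoff(self):
        cfg = make_config(mod_rate_unpaired=0.0, mod_rate_paired=0.0)
        stops, runoff = expected_stop_fraction(cfg)
        assert np.allclose(stops, 0.0) and runoff == pytest.approx(1.0)

    def test_geometric_closed_form_single_priming(self):
        L, p, d = 40, 35, 0.05
        w = np.zeros(L)
        w[p - 1] = 1.0
        cfg = make_config(L=L, mod_rate_unpaired=0.0, mod_rate_paired=0.0,
                          dropoff_rate=d, priming_weights=w)
        stops, runoff = expected_stop_fraction(cfg)
        # stop reported at i corresponds to left = i + 1
        for i in range(1, p):
            assert stops[i - 1] == pytest.approx(d * (1 - d) ** (p - 1 - i))
        assert (stops[p - 1 :] == 0).all()
        assert runoff == pytest.approx((1 - d) ** (p - 1))
        assert stops.sum() + runoff == pytest.approx(1.0)

    def test_simulation_matches_closed_form(self):
        paired = np.arange(120) % 3 == 0
        cfg = SimulationConfig(
            paired=paired, n_molecules=50_000, mod_rate_unpaired=0.02,
            mod_rate_paired=0.002, dropoff_rate=0.01, readthrough_prob=0.2,
            min_fragment_len=1,
        )
        stops, runoff = expected_stop_fraction(cfg)
        rng = np.random.default_rng(17)
        frags = simulate_fragments(simulate_modifications(cfg, rng), cfg, rng)
        term = termination_counts(frags, 120)
        emp = term.counts / cfg.n_molecules
        se = np.sqrt(stops * (1 - stops) / cfg.n_molecules)
        z = np.abs(emp - stops) / np.where(se > 0, se, 1.0)
        # pointwise 3-SE agreement, allowing the expected handful of
        # >3-sigma excursions among 120 simultaneous comparisons
        assert (z < 3).mean() > 0.97
        assert z.max() < 5
        ro_se = np.sqrt(runoff * (1 - runoff) / cfg.n_molecules)
        assert abs(term.runoff_count / cfg.n_molecules - runoff) < 3.6 * ro_se

    def test_ground_truth_vectors_are_consistent(self):
        cfg = make_config(L=80, dropoff_rate=0.01)
        gt = ground_truth(cfg)
        assert len(gt.modification_rate) == len(gt.labels) == 80
        assert ((gt.expected_stop_fraction >= 0) & (gt.expected_stop_fraction <= 1)).all()
        assert gt.expected_stop_fraction.sum() + gt.expected_runoff_fraction == pytest.approx(1.0)


class TestSyntheticStructure:
    def test_unpaired_fraction_and_validity(self):
        paired, db = synthetic_structure(1000, 0.45, np.random.default_rng(2))
        assert len(db) == 1000 and len(paired) == 1000
        assert abs((1 - paired.mean()) - 0.45) < 0.05
        assert db.count("(") == db.count(")")
        # dot-bracket agrees with the paired vector
        assert all((c != ".") == p for c, p in zip(db, paired))


class TestExperiment:
    def test_experiment_is_deterministic_given_seed(self):
        paired, _ = synthetic_structure(150, 0.5, np.random.default_rng(0))
        cfg = SimulationConfig(paired=paired, n_molecules=2000, seed=13,
                               min_fragment_len=10)
        a = simulate_experiment(cfg, seed=13)
        b = simulate_experiment(cfg, seed=13)
        assert a.arms == b.arms

    def test_control_arm_carries_no_modification_stops(self):
        paired, _ = synthetic_structure(150, 0.5, np.random.default_rng(0))
        cfg = SimulationConfig(paired=paired, n_molecules=2000, seed=1,
                               min_fragment_len=1)
        res = simulate_experiment(cfg, seed=1)
        assert all(f.cause != "modification" for f in res.arms["control"])
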