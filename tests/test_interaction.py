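"""Grab summaries, first-grab densities, error filtering, RT slopes."""

import numpy as np
import pandas as pd
import pytest

from scenegram import (grab_summary, grab_order_contrast,
                       first_grab_density, filter_error_trials, rt_summary)


def _grabs(rows):
    return pd.DataFrame(rows, columns=[
        "participant_id", "room_id", "condition", "phase", "object_id",
        "object_type", "duration_s", "grab_index"])


class TestGrabSummary:
    def test_mean_of_logs(self):
        g = _grabs([("p1", "r", "consistent", "build", "a", "local",
                     np.e, 1),
                    ("p1", "r", "consistent", "build", "b", "local",
                     np.e ** 3, 2)])
        out = grab_summary(g)
        assert out.mean_log_value.iloc[0] == pytest.approx(2.0)
        assert out.n.iloc[0] == 2

    def test_matches_group_mean_oracle(self):
        rng = np.random.default_rng(3)
        n = 300
        g = _grabs([
            (f"p{rng.integers(3)}", "r",
             rng.choice(["consistent", "inconsistent"]),
             rng.choice(["build", "recall"]), f"o{i}",
             rng.choice(["global", "local"]),
             rng.lognormal(0.5, 0.5), 1 + i % 15)
            for i in range(n)])
        out = grab_summary(g).set_index(
            ["participant_id", "condition", "object_type", "phase"])
        for key, grp in g.groupby(
                ["participant_id", "condition", "object_type", "phase"]):
            assert out.loc[key, "mean_log_value"] == pytest.approx(
                np.log(grp.duration_s).mean())

    def test_nonpositive_duration_rejected(self):
        g = _grabs([("p1", "r", "consistent", "build", "a", "local",
                     0.0, 1)])
        with pytest.raises(ValueError):
            grab_summary(g)

    def test_local_inconsistency_cost_with_global_unaffected(self, exp1_ds):
        out = grab_summary(exp1_ds.grabs)
        cell = (out[out.phase == "build"]
                .groupby(["condition", "object_type"])
                .mean_log_value.mean())
        local_gap = (cell[("inconsistent", "local")]
                     - cell[("consistent", "local")])
        global_gap = abs(cell[("inconsistent", "global")]
                         - cell[("consistent", "global")])
        assert local_gap > 0
        assert global_gap < local_gap / 2


class TestGrabOrder:
    def test_arithmetic_example(self):
        # p1: globals at orders 1-5 -> mean 3, locals 6-15 -> mean 10.5
        # p2: globals at orders 2-6 -> mean 4, locals mean 10
        rows = []
        for i in range(1, 16):
            otype = "global" if i <= 5 else "local"
            rows.append(("p1", "r", "consistent", "build", f"o{i}", otype,
                         1.0, i))
            order2 = i + 1 if i <= 5 else (1 if i == 6 else i)
            rows.append(("p2", "r", "consistent", "build", f"o{i}", otype,
                         1.0, order2))
        res = grab_order_contrast(_grabs(rows))
        assert res.mean_diff == pytest.approx(((3 - 10.5) + (4 - 10)) / 2)

    def test_random_order_gives_null(self):
        rng = np.random.default_rng(11)
        diffs = []
        for seed in range(20):
            rows = []
            for p in range(6):
                order = rng.permutation(15) + 1
                for i in range(15):
                    otype = "global" if i < 5 else "local"
                    rows.append((f"p{p}", "r", "consistent", "build",
                                 f"o{i}", otype, 1.0, order[i]))
            diffs.append(grab_order_contrast(_grabs(rows)).mean_diff)
        assert abs(np.mean(diffs)) < 0.5


class TestFirstGrabDensity:
    def test_all_mass_at_one_puts_mode_there(self):
        g = _grabs([("p1", "r", "consistent", "build", f"o{i}", "local",
                     1.0, 1) for i in range(10)])
        dens = first_grab_density(g)
        peak = dens.loc[dens.density.idxmax(), "grab_index"]
        assert peak == pytest.approx(1.0)

    def test_uniform_indices_give_flat_interior(self):
        g = _grabs([("p1", "r", "consistent", "build", f"o{i}", "local",
                     1.0, 1 + i % 15) for i in range(150)])
        dens = first_grab_density(g, bandwidth=1.0)
        interior = dens[(dens.grab_index > 4) & (dens.grab_index < 12)]
        assert interior.density.std() / interior.density.mean() < 0.05

    def test_unit_mass_on_grid(self, exp1_ds):
        dens = first_grab_density(exp1_ds.grabs)
        for _, grp in dens.groupby("object_type"):
            mass = np.trapezoid(grp.density, grp.grab_index)
            assert mass == pytest.approx(1.0, abs=1e-3)

    def test_globals_peak_before_locals(self, exp1_ds):
        dens = first_grab_density(exp1_ds.grabs)
        modes = dens.loc[dens.groupby("object_type").density.idxmax()]
        modes = modes.set_index("object_type").grab_index
        assert modes["global"] < modes["local"]


class TestErrorFiltering:
    def _searches(self, errors):
        return pd.DataFrame({
            "participant_id": "p1", "room_id": "r", "condition":
            "consistent", "room_type": "own",
            "object_id": [f"o{i}" for i in range(len(errors))],
            "object_type": "local",
            "trial_index": (np.arange(len(errors)) % 15) + 1,
            "rt_s": 1.0, "error": errors})

    def test_no_errors_identity(self):
        s = self._searches([False] * 10)
        out, prop = filter_error_trials(s)
        assert prop == 0.0 and len(out) == 10

    def test_exact_proportion(self):
        s = self._searches([True] * 38 + [False] * 962)
        out, prop = filter_error_trials(s)
        assert prop == pytest.approx(0.038)
        assert len(out) == 962 and not out.error.any()

    def test_generator_rate_within_binomial_error(self, exp2_ds):
        _, prop = filter_error_trials(exp2_ds.searches)
        n = len(exp2_ds.searches)
        se = np.sqrt(0.038 * 0.962 / n)
        assert abs(prop - 0.038) < 4 * se


class TestRTSummary:
    def _searches(self, rows):
        return pd.DataFrame(rows, columns=[
            "participant_id", "room_id", "condition", "room_type",
            "object_id", "object_type", "trial_index", "rt_s", "error"])

    def test_constant_rts_give_zero_slopes(self):
        rows = [("p1", "r", "consistent", "own", f"o{i}", "local", i,
                 2.0, False) for i in range(1, 16)]
        out = rt_summary(self._searches(rows))
        assert out["slopes_by_type"].slope.iloc[0] == pytest.approx(
            0.0, abs=1e-12)

    def test_noise_free_line_recovered_exactly(self):
        rows = [("p1", "r", "consistent", "own", f"o{i}", "local", i,
                 float(np.exp(1.0 - 0.05 * i)), False)
                for i in range(1, 16)]
        out = rt_summary(self._searches(rows))
        assert out["slopes_by_type"].slope.iloc[0] == pytest.approx(
            -0.05, abs=1e-10)

    def test_too_few_trials_reported_missing(self):
        rows = [("p1", "r", "consistent", "own", "o1", "local", 1, 2.0,
                 False),
                ("p1", "r", "consistent", "own", "o2", "local", 2, 2.0,
                 False)]
        out = rt_summary(self._searches(rows))
        assert np.isnan(out["slopes_by_type"].slope.iloc[0])

    def test_generator_truth_recovery(self, exp2_ds):
        filtered, _ = filter_error_trials(exp2_ds.searches)
        out = rt_summary(filtered)
        slopes = out["slopes_by_type"].groupby("object_type").slope.mean()
        assert slopes["local"] < slopes["global"] < 0
        cells = (out["cells"].groupby(
            ["condition", "object_type", "room_type"])
            .mean_log_value.mean())
        assert (cells.xs("consistent", level=0).mean()
                < cells.xs("inconsistent", level=0).mean())
        # room familiarity affects local objects, not globals
        local_gap = (cells.xs(("local", "other"), level=(1, 2)).mean()
                     - cells.xs(("local", "own"), level=(1, 2)).mean())
        global_gap = abs(cells.xs(("global", "other"), level=(1, 2)).mean()
                         - cells.xs(("global", "own"), level=(1, 2)).mean())
        assert local_gap > 0 and global_gap < local_gap / 2
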