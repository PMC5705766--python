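"""Nearest-local-neighbor pairing, repetition counts, Poisson contrast."""

import numpy as np
import pandas as pd
import pytest

from scenegram import (nearest_local_neighbor, extract_pairs,
                       pair_frequency, poisson_rate_contrast)


def _room(objs, participant="p1", room="r1", condition="consistent"):
    """objs: (object_id, object_type, x, y, z)."""
    rows = [(participant, room, condition, o, t, x, y, z)
            for o, t, x, y, z in objs]
    return pd.DataFrame(rows, columns=[
        "participant_id", "room_id", "condition", "object_id",
        "object_type", "x", "y", "z"])


def _oracle_pairs(room):
    """Exhaustive O(n^2) nearest-local-neighbor with lexicographic ties."""
    out = {}
    rows = list(room.itertuples())
    for a in rows:
        best = None
        for b in sorted(rows, key=lambda r: r.object_id):
            if b.object_id == a.object_id or b.object_type != "local":
                continue
            d = ((a.x - b.x) ** 2 + (a.y - b.y) ** 2
                 + (a.z - b.z) ** 2) ** 0.5
            if best is None or d < best[1]:
                best = (b.object_id, d)
        out[a.object_id] = best
    return out


class TestNearestLocalNeighbor:
    def test_three_object_example(self):
        room = _room([("A", "local", 0, 0, 0), ("B", "local", 1, 0, 0),
                      ("G", "global", 0.4, 0, 0)])
        pairs = nearest_local_neighbor(room).set_index("focal_object_id")
        assert pairs.loc["A", "neighbor_object_id"] == "B"
        assert pairs.loc["B", "neighbor_object_id"] == "A"
        assert pairs.loc["G", "neighbor_object_id"] == "A"
        assert pairs.loc["G", "distance"] == pytest.approx(0.4)

    def test_focal_never_its_own_neighbor_at_duplicate_coords(self):
        room = _room([("A", "local", 0, 0, 0), ("B", "local", 0, 0, 0)])
        pairs = nearest_local_neighbor(room)
        assert (pairs.focal_object_id != pairs.neighbor_object_id).all()

    def test_lexicographic_tie_break(self):
        room = _room([("F", "local", 0, 0, 0), ("zed", "local", 1, 0, 0),
                      ("abc", "local", -1, 0, 0)])
        pairs = nearest_local_neighbor(room).set_index("focal_object_id")
        assert pairs.loc["F", "neighbor_object_id"] == "abc"

    def test_no_local_neighbor_raises(self):
        room = _room([("G1", "global", 0, 0, 0), ("G2", "global", 1, 0, 0)])
        with pytest.raises(ValueError):
            nearest_local_neighbor(room)

    def test_matches_exhaustive_oracle_on_random_rooms(self):
        rng = np.random.default_rng(3)
        for i in range(200):
            n = rng.integers(3, 16)
            types = rng.choice(["local", "global"], n,
                               p=[2 / 3, 1 / 3]).tolist()
            # a local focal needs at least one other local as neighbor
            types[0] = types[1] = "local"
            objs = [(f"o{j:02d}", types[j], *rng.uniform(-1.5, 1.5, 3))
                    for j in range(n)]
            room = _room(objs, room=f"r{i}")
            got = nearest_local_neighbor(room).set_index("focal_object_id")
            oracle = _oracle_pairs(room)
            for oid, (n_oid, n_d) in oracle.items():
                assert got.loc[oid, "neighbor_object_id"] == n_oid
                assert got.loc[oid, "distance"] == pytest.approx(n_d)


class TestPairFrequency:
    def test_direct_count(self):
        rooms = [_room([("pot", "local", 0, 0, 0),
                        ("oven", "local", 0.1, 0, 0),
                        ("mug", "local", 2, 2, 0)],
                       participant=p, room="kitchen_1")
                 for p in ("p1", "p2")]
        pairs = pd.concat([nearest_local_neighbor(r) for r in rooms])
        table = pair_frequency(pairs).set_index(
            ["focal_object_id", "neighbor_object_id"])
        assert table.loc[("pot", "oven"), "count"] == 2
        assert table.loc[("mug", "oven"), "count"] == 2

    def test_matches_hash_count_oracle(self):
        rng = np.random.default_rng(6)
        rows = []
        for p in range(8):
            for room in ("a", "b"):
                for focal in "uvwxy":
                    rows.append((f"p{p}", room, "consistent", focal,
                                 "local",
                                 "n" + str(rng.integers(3)), 0.1))
        pairs = pd.DataFrame(rows, columns=[
            "participant_id", "room_id", "condition", "focal_object_id",
            "focal_type", "neighbor_object_id", "distance"])
        table = pair_frequency(pairs)
        oracle: dict = {}
        for r in pairs.itertuples():
            key = (r.room_id, r.condition, r.focal_object_id,
                   r.neighbor_object_id)
            oracle.setdefault(key, set()).add(r.participant_id)
        assert len(table) == len(oracle)
        for r in table.itertuples():
            key = (r.room_id, r.condition, r.focal_object_id,
                   r.neighbor_object_id)
            assert r.count == len(oracle[key])

    def test_token_conservation(self, exp1_ds):
        build = exp1_ds.placements[exp1_ds.placements.phase == "build"]
        pairs = extract_pairs(build)
        table = pair_frequency(pairs)
        totals = table.groupby(["room_id", "condition"])["count"].sum()
        # 5 participants build each room under each condition, 15 objects
        assert (totals == 5 * 15).all()

    def test_unordered_collapse_merges_reciprocal_pairs(self):
        pairs = pd.DataFrame(
            [("p1", "r", "consistent", "a", "local", "b", 0.1),
             ("p2", "r", "consistent", "b", "local", "a", 0.1)],
            columns=["participant_id", "room_id", "condition",
                     "focal_object_id", "focal_type",
                     "neighbor_object_id", "distance"])
        assert len(pair_frequency(pairs, ordered=True)) == 2
        un = pair_frequency(pairs, ordered=False)
        assert len(un) == 1 and un["count"].iloc[0] == 2


class TestPoissonContrast:
    def _table(self, con_counts, incon_counts, room="r1"):
        rows = ([(room, "consistent", f"a{i}", "b", c)
                 for i, c in enumerate(con_counts)]
                + [(room, "inconsistent", f"c{i}", "d", c)
                   for i, c in enumerate(incon_counts)])
        return pd.DataFrame(rows, columns=[
            "room_id", "condition", "focal_object_id",
            "neighbor_object_id", "count"])

    def test_saturated_two_group_closed_form(self):
        # one room, counts {con: all 4, incon: all 2} -> log rate ratio log 2
        table = self._table([4] * 6, [2] * 6)
        res = poisson_rate_contrast(table)
        assert res.log_rate_ratio == pytest.approx(np.log(2), abs=1e-8)

    def test_null_case(self):
        table = self._table([3, 2, 4, 3], [3, 2, 4, 3])
        res = poisson_rate_contrast(table)
        assert res.log_rate_ratio == pytest.approx(0.0, abs=1e-8)
        assert abs(res.z) < 0.1

    def test_closed_form_with_room_effects(self):
        # two rooms with different base rates; the MLE of the condition
        # effect in the room-adjusted model equals the common within-room
        # ratio when the design is balanced and the ratio is shared
        t1 = self._table([6] * 5, [3] * 5, room="r1")
        t2 = self._table([4] * 5, [2] * 5, room="r2")
        res = poisson_rate_contrast(pd.concat([t1, t2], ignore_index=True))
        assert res.log_rate_ratio == pytest.approx(np.log(2), abs=1e-6)

    def test_single_condition_raises(self):
        table = self._table([4, 4], [])
        with pytest.raises(ValueError, match="both conditions"):
            poisson_rate_contrast(table)

    def test_rate_ratio_estimation_is_unbiased(self):
        # counts with true ratio e^0.5: mean estimate near 0.5.  The
        # per-rep estimator is checked against the GLM on a few reps, then
        # the remaining reps use the closed form (identical by MLE).
        rng = np.random.default_rng(9)
        true = 0.5
        estimates = []
        for rep in range(1000):
            con = rng.poisson(2.0 * np.exp(true), 200).clip(min=1)
            incon = rng.poisson(2.0, 200).clip(min=1)
            estimates.append(np.log(con.mean() / incon.mean()))
            if rep < 3:
                res = poisson_rate_contrast(
                    self._table(con.tolist(), incon.tolist()))
                assert res.log_rate_ratio == pytest.approx(
                    estimates[-1], abs=1e-8)
        # clipping at 1 inflates both means a little; the ratio stays close
        assert np.mean(estimates) == pytest.approx(true, abs=0.1)
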