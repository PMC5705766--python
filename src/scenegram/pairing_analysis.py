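"""Nearest-local-neighbor pairings and their cross-participant repetition.

The "grammar" of a self-built scene is probed through object-to-object
relations: for every object in a room (global and local alike) we find its
closest *local* neighbor in 3D, then count how many participants exhibit the
identical (focal -> neighbor) pairing in the same room under the same
condition.  A pairing repeated by many participants (the pot next to the
oven) marks a shared arrangement rule; the count distribution is contrasted
across consistency conditions with a Poisson log-linear model.

Pairs are ordered (focal -> neighbor) by default, which conserves tokens:
each participant contributes exactly one pair per object, so counts within a
(room, condition) cell sum to participants x objects-per-room.  An unordered
collapse is available via ``ordered=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

PAIR_COLUMNS = [
    "participant_id", "room_id", "condition", "focal_object_id",
    "focal_type", "neighbor_object_id", "distance",
]


def nearest_local_neighbor(room: pd.DataFrame) -> pd.DataFrame:
    """Closest local neighbor of every object in one participant-room.

    ``room`` holds the placements of a single (participant, room, phase).
    The focal object itself is excluded; ties are broken lexicographically by
    neighbor ``object_id`` so the result is seed-free and deterministic.
    Raises if the room has no eligible local neighbor for some focal.
    """
    ids = room.object_id.to_numpy()
    types = room.object_type.to_numpy()
    xyz = room[["x", "y", "z"]].to_numpy(dtype=float)
    n = len(ids)
    local_mask = types == "local"
    if local_mask.sum() == 0 or (n == 1 and local_mask.any()):
        raise ValueError("room has no eligible local neighbors")

    # lexicographic tie-break: evaluate candidates in object_id order
    order = np.argsort(ids, kind="stable")
    d2 = ((xyz[:, None, :] - xyz[None, :, :]) ** 2).sum(axis=-1)

    rows = []
    pid = room.participant_id.iloc[0]
    rid = room.room_id.iloc[0]
    cond = room.condition.iloc[0]
    for i in range(n):
        best_j, best_d2 = -1, np.inf
        for j in order:
            if j == i or not local_mask[j]:
                continue
            if d2[i, j] < best_d2:
                best_d2, best_j = d2[i, j], j
        if best_j < 0:
            raise ValueError(f"no local neighbor for focal {ids[i]!r}")
        rows.append((pid, rid, cond, ids[i], types[i], ids[best_j],
                     float(np.sqrt(best_d2))))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def extract_pairs(placements: pd.DataFrame,
                  phase: str = "build") -> pd.DataFrame:
    """Nearest-local-neighbor pairs for every (participant, room) in a table."""
    pl = placements
    if "phase" in pl.columns:
        pl = pl[pl.phase == phase]
    parts = [nearest_local_neighbor(grp)
             for _, grp in pl.groupby(["participant_id", "room_id"],
                                      sort=True)]
    if not parts:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def pair_frequency(pairs: pd.DataFrame, ordered: bool = True) -> pd.DataFrame:
    """Count, per (room, condition, focal, neighbor), the participants
    exhibiting that pairing.

    Each participant contributes at most one token to any given pair.  With
    ``ordered=False`` the (focal, neighbor) identity is collapsed to an
    unordered pair before counting.
    """
    df = pairs.copy()
    if not ordered:
        lo = np.minimum(df.focal_object_id, df.neighbor_object_id)
        hi = np.maximum(df.focal_object_id, df.neighbor_object_id)
        df["focal_object_id"], df["neighbor_object_id"] = lo, hi
    key = ["room_id", "condition", "focal_object_id", "neighbor_object_id"]
    out = (df.drop_duplicates(key + ["participant_id"])
           .groupby(key).size().rename("count").reset_index())
    return out.sort_values(key, ignore_index=True)


@dataclass
class PoissonContrast:
    log_rate_ratio: float   # consistent relative to inconsistent
    se: float
    z: float
    p: float
    converged: bool

    def as_dict(self) -> dict:
        return {"log_rate_ratio": self.log_rate_ratio, "se": self.se,
                "z": self.z, "p": self.p}


def poisson_rate_contrast(table: pd.DataFrame,
                          room_effects: bool = True) -> PoissonContrast:
    """Poisson log-linear contrast of pair counts by consistency condition.

    Fits count ~ condition (+ room fixed effects) by IRLS and returns the
    Wald test of the condition coefficient; the coefficient is the log rate
    ratio of consistent over inconsistent counts.
    """
    conds = set(table.condition.unique())
    if conds != {"consistent", "inconsistent"}:
        raise ValueError(f"need both conditions present, got {sorted(conds)}")
    if (table["count"] < 1).any():
        raise ValueError("pair counts must be >= 1 (observed pairs only)")

    X = pd.DataFrame({
        "const": 1.0,
        "consistent": (table.condition == "consistent").astype(float),
    })
    if room_effects and table.room_id.nunique() > 1:
        dummies = pd.get_dummies(table.room_id, prefix="room",
                                 drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    model = sm.GLM(table["count"].to_numpy(), X.to_numpy(),
                   family=sm.families.Poisson())
    res = model.fit(maxiter=100)
    if not res.converged:
        raise RuntimeError("Poisson IRLS did not converge in 100 iterations")
    beta = float(res.params[1])
    se = float(res.bse[1])
    z = beta / se
    from scipy import stats
    return PoissonContrast(log_rate_ratio=beta, se=se, z=z,
                           p=float(2 * stats.norm.sf(abs(z))),
                           converged=bool(res.converged))


def pairing_report(placements: pd.DataFrame, ordered: bool = True) -> dict:
    """End-to-end pairing analysis of a build-phase placement table."""
    pairs = extract_pairs(placements)
    table = pair_frequency(pairs, ordered=ordered)
    contrast = poisson_rate_contrast(table)
    mean_counts = table.groupby("condition")["count"].mean()
    repeated = table[table["count"] >= 2].groupby("condition").size()
    return {
        "pairs": pairs,
        "table": table,
        "contrast": contrast.as_dict(),
        "mean_count": {c: float(v) for c, v in mean_counts.items()},
        "n_repeated_pairs": {c: int(repeated.get(c, 0))
                             for c in ("consistent", "inconsistent")},
        "max_count": {c: int(g["count"].max())
                      for c, g in table.groupby("condition")},
        "ordered": ordered,
    }
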