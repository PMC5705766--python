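"""Location-memory scoring: displacement, cross-participant baseline, contrasts.

Memory for an object's location is scored as *displacement*: the 3D Euclidean
distance between the object's build-phase center and its recall-phase center
(lower = better memory).  Chance performance is estimated with a
cross-participant resampling baseline: for each (participant, room) the
distances between that participant's build and the build of one randomly
chosen other participant who arranged the same room under the same condition.
Dependent variables are analysed on the natural-log scale and aggregated to
per-participant cell means before paired contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LOG_EPS = 1e-6  # meters added before log; guards exact-zero displacements

DISPLACEMENT_COLUMNS = [
    "participant_id", "room_id", "condition", "object_id", "object_type",
    "displacement", "kind", "partner_id",
]


def displacement(build: pd.DataFrame, recall: pd.DataFrame) -> pd.DataFrame:
    """Per-object displacement records (kind = 'empirical').

    Both inputs are placement tables; every (participant, room, object) key
    present in one phase must be present in the other.
    """
    key = ["participant_id", "room_id", "object_id"]
    b = build[build.phase == "build"] if "phase" in build else build
    r = recall[recall.phase == "recall"] if "phase" in recall else recall
    merged = b.merge(r[key + ["x", "y", "z"]], on=key, how="outer",
                     suffixes=("_b", "_r"), indicator=True)
    missing = merged[merged._merge != "both"]
    if len(missing):
        keys = missing[key].to_records(index=False).tolist()
        raise ValueError(f"unmatched placement keys between phases: "
                         f"{keys[:10]}{' ...' if len(keys) > 10 else ''}")
    diff = (merged[["x_b", "y_b", "z_b"]].to_numpy()
            - merged[["x_r", "y_r", "z_r"]].to_numpy())
    out = merged[key + ["condition", "object_type"]].copy()
    out["displacement"] = np.linalg.norm(diff, axis=1)
    out["kind"] = "empirical"
    out["partner_id"] = ""
    return out[DISPLACEMENT_COLUMNS].reset_index(drop=True)


def cross_participant_baseline(build: pd.DataFrame,
                               seed: int = 0) -> pd.DataFrame:
    """Chance-level displacement records (kind = 'baseline').

    For each (participant, room), one partner is drawn uniformly from the
    other participants who built the same room under the same condition, and
    the per-object distances between the two arrangements are recorded.
    Partners are redrawn independently per room; a participant is never
    paired with themselves.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    b = build[build.phase == "build"] if "phase" in build else build
    by_room_cond: dict[tuple, list[str]] = {
        k: sorted(g.participant_id.unique())
        for k, g in b.groupby(["room_id", "condition"])
    }
    coords = b.set_index(["participant_id", "room_id", "object_id"])[
        ["x", "y", "z"]].sort_index()

    rows = []
    cells = b.groupby(["participant_id", "room_id", "condition"],
                      sort=True)
    for (pid, room, cond), grp in cells:
        eligible = [p for p in by_room_cond[(room, cond)] if p != pid]
        if not eligible:
            raise ValueError(f"no eligible baseline partner for room "
                             f"{room!r} under condition {cond!r} "
                             f"(participant {pid!r})")
        partner = eligible[rng.integers(len(eligible))]
        own = coords.loc[(pid, room)]
        theirs = coords.loc[(partner, room)]
        common = own.index.intersection(theirs.index)
        d = np.linalg.norm(own.loc[common].to_numpy()
                           - theirs.loc[common].to_numpy(), axis=1)
        otype = grp.set_index("object_id").object_type
        for oid, dist in zip(common, d):
            rows.append((pid, room, cond, oid, otype[oid], dist,
                         "baseline", partner))
    return pd.DataFrame(rows, columns=DISPLACEMENT_COLUMNS)


def aggregate_cells(records: pd.DataFrame,
                    factors: list[str] | None = None) -> pd.DataFrame:
    """Per-participant mean log-displacement per design cell.

    The default cells are condition x object_type x kind.  Returns columns
    ``participant_id``, the factors, ``mean_log_displacement`` and ``n``.
    Empty cells are simply absent (missing, never fabricated).
    """
    factors = factors or ["condition", "object_type", "kind"]
    rec = records.copy()
    rec["log_disp"] = np.log(rec["displacement"] + LOG_EPS)
    out = (rec.groupby(["participant_id"] + factors)["log_disp"]
           .agg(mean_log_displacement="mean", n="size")
           .reset_index())
    return out


@dataclass
class PairedContrast:
    t: float
    df: int
    p: float
    cohen_d: float
    mean_diff: float
    n: int

    def as_dict(self) -> dict:
        return {"t": self.t, "df": self.df, "p": self.p,
                "cohen_d": self.cohen_d, "mean_diff": self.mean_diff,
                "n": self.n}


def paired_contrast(a, b) -> PairedContrast:
    """Classical paired t-test of two equal-length per-participant vectors.

    Returns t, df = n - 1, two-sided p, Cohen's d = mean(diff) / sd(diff)
    and the mean difference.  The degenerate all-equal case (zero-variance
    differences with zero mean) reports t = 0, p = 1, d = 0 by convention;
    zero variance with a nonzero mean is an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_contrast expects equal-length 1D vectors")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0:
        if mean_diff == 0.0:
            return PairedContrast(t=0.0, df=n - 1, p=1.0, cohen_d=0.0,
                                  mean_diff=0.0, n=n)
        raise ValueError("zero variance of differences with nonzero mean")
    t = mean_diff / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedContrast(t=float(t), df=n - 1, p=float(p),
                          cohen_d=mean_diff / sd, mean_diff=mean_diff, n=n)


def maxwell_mean(sigma: float) -> float:
    """Expected norm of an isotropic 3D Gaussian: sigma * sqrt(8 / pi).

    The closed-form mean displacement under isotropic memory noise; used for
    parameter-recovery checks.
    """
    return sigma * math.sqrt(8.0 / math.pi)


def memory_report(build: pd.DataFrame, recall: pd.DataFrame,
                  seed: int = 0) -> dict:
    """End-to-end memory analysis: records, cell means, headline contrasts."""
    emp = displacement(build, recall)
    base = cross_participant_baseline(build, seed=seed)
    records = pd.concat([emp, base], ignore_index=True)
    cells = aggregate_cells(records)

    def cell_vector(kind: str, **sel) -> pd.Series:
        sub = cells[cells.kind == kind]
        for k, v in sel.items():
            sub = sub[sub[k] == v]
        return (sub.groupby("participant_id").mean_log_displacement.mean()
                .sort_index())

    contrasts = {}
    emp_all = cell_vector("empirical")
    base_all = cell_vector("baseline")
    contrasts["empirical_vs_baseline"] = paired_contrast(
        emp_all, base_all.loc[emp_all.index]).as_dict()
    contrasts["consistent_vs_inconsistent"] = paired_contrast(
        cell_vector("empirical", condition="consistent"),
        cell_vector("empirical", condition="inconsistent")).as_dict()
    contrasts["global_vs_local"] = paired_contrast(
        cell_vector("empirical", object_type="global"),
        cell_vector("empirical", object_type="local")).as_dict()
    contrasts["baseline_global_con_vs_incon"] = paired_contrast(
        cell_vector("baseline", condition="consistent",
                    object_type="global"),
        cell_vector("baseline", condition="inconsistent",
                    object_type="global")).as_dict()

    means = (records.groupby(["kind", "condition", "object_type"])
             .displacement.mean())
    return {
        "records": records,
        "cells": cells,
        "contrasts": contrasts,
        "mean_displacement_m": {
            "empirical": float(records[records.kind == "empirical"]
                               .displacement.mean()),
            "baseline": float(records[records.kind == "baseline"]
                              .displacement.mean()),
        },
        "cell_mean_displacement_m": {
            f"{k}:{c}:{t}": float(v) for (k, c, t), v in means.items()
        },
        "baseline_seed": seed,
    }
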