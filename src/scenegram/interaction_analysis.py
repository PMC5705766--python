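"""Object-interaction and repeated-search summaries.

Grab durations, grab order, first-grab densities, error-trial filtering and
search-RT learning slopes.  All dependent variables are analysed on the
natural-log scale and aggregated to per-participant cell means; repeated
search is summarised per participant by an OLS slope of log RT on the
centered within-room trial index, separately by object type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .memory_analysis import paired_contrast, PairedContrast

GRID_STEP = 0.1


def grab_summary(grabs: pd.DataFrame,
                 factors: list[str] | None = None) -> pd.DataFrame:
    """Per-participant mean log grab duration per design cell.

    Default cells are condition x object_type x phase.  Raises on
    non-positive durations; empty cells are absent from the output.
    """
    if (grabs.duration_s <= 0).any():
        raise ValueError("grab durations must be positive")
    factors = factors or ["condition", "object_type", "phase"]
    df = grabs.copy()
    df["log_dur"] = np.log(df.duration_s)
    return (df.groupby(["participant_id"] + factors)["log_dur"]
            .agg(mean_log_value="mean", n="size").reset_index())


def grab_order_contrast(grabs: pd.DataFrame) -> PairedContrast:
    """Paired contrast of per-participant mean first-grab index,
    global vs local objects (negative mean_diff = globals grabbed earlier)."""
    means = (grabs.groupby(["participant_id", "object_type"])
             .grab_index.mean().unstack("object_type"))
    return paired_contrast(means["global"], means["local"])


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb KDE bandwidth for 1D data."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if min(sd, iqr) > 0 else max(sd, iqr / 1.34)
    if spread <= 0:
        return 0.5  # degenerate (all-equal) data: fixed fallback
    return 0.9 * spread * n ** (-0.2)


def first_grab_density(grabs: pd.DataFrame,
                       bandwidth: float | None = None,
                       lo: float = 1.0, hi: float = 15.0) -> pd.DataFrame:
    """Gaussian-kernel density of first-grab order per object type.

    Densities are evaluated on the fixed grid lo..hi (step 0.1) and
    renormalised to unit trapezoid mass on the grid, so boundary leakage of
    the kernels does not bias the comparison between object types.
    """
    grid = np.arange(lo, hi + GRID_STEP / 2, GRID_STEP)
    out = []
    for otype, grp in grabs.groupby("object_type"):
        x = grp.grab_index.to_numpy(dtype=float)
        if len(x) == 0:
            raise ValueError(f"no grabs for object_type {otype!r}")
        h = bandwidth if bandwidth is not None else silverman_bandwidth(x)
        dens = norm.pdf((grid[:, None] - x[None, :]) / h).mean(axis=1) / h
        mass = np.trapezoid(dens, grid)
        dens = dens / mass
        out.append(pd.DataFrame({"object_type": otype, "grab_index": grid,
                                 "density": dens, "bandwidth": h}))
    return pd.concat(out, ignore_index=True)


def filter_error_trials(searches: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Drop error trials; return (filtered trials, proportion removed)."""
    if len(searches) == 0:
        return searches, 0.0
    errs = searches.error.astype(bool)
    return (searches[~errs].reset_index(drop=True),
            float(errs.mean()))


def rt_summary(searches: pd.DataFrame) -> dict:
    """Cell means and per-participant learning slopes for search RTs.

    Input should already be error-filtered.  Cell means are per-participant
    mean log RT over condition x object_type x room_type; slopes are OLS
    slopes of log RT on the centered trial index (1..15 -> -7..+7),
    per participant and object type (and additionally by condition).
    Participants with fewer than 3 trials in a slope cell are reported as
    missing.
    """
    df = searches.copy()
    df["log_rt"] = np.log(df.rt_s)
    n_trials = df.trial_index.max()
    df["trial_c"] = df.trial_index - (n_trials + 1) / 2.0

    cells = (df.groupby(["participant_id", "condition", "object_type",
                         "room_type"])["log_rt"]
             .agg(mean_log_value="mean", n="size").reset_index())

    def slopes(group_cols: list[str]) -> pd.DataFrame:
        rows = []
        for key, grp in df.groupby(group_cols):
            if len(grp) < 3:
                rows.append((*key, np.nan, len(grp)))
                continue
            b, _ = np.polyfit(grp.trial_c, grp.log_rt, 1)
            rows.append((*key, float(b), len(grp)))
        return pd.DataFrame(rows, columns=group_cols + ["slope", "n"])

    return {
        "cells": cells,
        "slopes_by_type": slopes(["participant_id", "object_type"]),
        "slopes_by_type_condition": slopes(
            ["participant_id", "object_type", "condition"]),
    }


def interaction_report(grabs: pd.DataFrame, searches: pd.DataFrame | None,
                       bandwidth: float | None = None) -> dict:
    """End-to-end interaction analysis (grabs always; searches if present)."""
    out: dict = {
        "grab_cells": grab_summary(grabs),
        "grab_order": grab_order_contrast(grabs).as_dict(),
        "first_grab_density": first_grab_density(grabs, bandwidth=bandwidth),
    }
    if searches is not None and len(searches):
        filtered, prop = filter_error_trials(searches)
        rt = rt_summary(filtered)
        mean_slopes = (rt["slopes_by_type"].groupby("object_type")
                       .slope.mean())
        out.update({
            "error_proportion": prop,
            "rt_cells": rt["cells"],
            "rt_slopes": rt["slopes_by_type"],
            "rt_slopes_by_condition": rt["slopes_by_type_condition"],
            "mean_slope": {t: float(v) for t, v in mean_slopes.items()},
        })
    return out
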