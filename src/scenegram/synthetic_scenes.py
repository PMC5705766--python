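"""Generative model for virtual-room arrangement datasets.

The study this package analyses has no public raw data, so every analysis is
exercised on synthetic datasets with the same structure: participants arrange
15 objects (10 local, 5 global) in 3 x 3 m rooms of four semantic categories,
half of each participant's rooms under *consistent* instructions (arrange
according to expectations) and half under *inconsistent* ones (against them);
a recall phase re-places every object from memory, and a search phase locates
cued targets in one's own and in other participants' rooms.

The placement model is anchor-based: each room category has five global
objects with canonical floor positions, and each local object has a canonical
anchor (a global object) plus a canonical offset from it.  Consistent
arrangements realise this shared layout with small jitter; inconsistent
arrangements permute the global slots per participant and attach locals to
mostly random anchors.  This is the minimal model that yields the qualitative
effects the downstream analyses test: shared cross-participant pairings and
tight spread in the consistent condition, condition- and object-type-graded
memory noise, globals grabbed earlier, and search-RT effects of consistency,
object type and room familiarity.

All generation is deterministic given the config seed; sub-streams are
derived with ``numpy.random.SeedSequence`` so the phases are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .scene_model import (
    ArrangementDataset, DesignConfig, ObjectSpec,
    PLACEMENT_COLUMNS, GRAB_COLUMNS, SEARCH_COLUMNS, GAZE_COLUMNS,
    ROOM_HALF_WIDTH,
)

# object vocabularies, 5 global + 10 local per experimental room category
_CATALOG: dict[str, tuple[list[str], list[str]]] = {
    "kitchen": (
        ["oven", "fridge", "sink_unit", "counter", "kitchen_table"],
        ["pot", "pan", "kettle", "toaster", "cutting_board",
         "knife", "plate", "mug", "spatula", "colander"],
    ),
    "bathroom": (
        ["bathtub", "shower", "toilet", "washbasin", "bathroom_cabinet"],
        ["toothbrush", "toothpaste", "shampoo", "towel", "comb",
         "soap", "razor", "hairdryer", "toilet_brush", "bath_mat"],
    ),
    "bedroom": (
        ["bed", "wardrobe", "dresser", "desk", "bookshelf"],
        ["pillow", "blanket", "alarm_clock", "lamp", "book",
         "slippers", "handbag", "hand_mirror", "photo_frame",
         "laundry_basket"],
    ),
    "living_room": (
        ["sofa", "tv_stand", "coffee_table", "armchair", "sideboard"],
        ["remote", "cushion", "magazine", "vase", "candle",
         "game_controller", "plant_pot", "coaster", "throw_blanket",
         "picture"],
    ),
}

_Z_MAX = 2.5  # ceiling clip for object centers, meters


@dataclass
class GeneratorConfig:
    """All tunable constants of the generative model.

    Placement sigmas are meters; grab and RT parameters act on the natural-log
    scale of seconds.  Defaults encode the study's design constants (sample
    structure, spawn circle) and the directions of its reported effects; the
    placement/memory noise magnitudes are free calibration constants the
    source study never reports.
    """

    n_participants: int = 10
    room_categories: int = 4
    rooms_per_category: int = 4          # Exp-2 preset: 2 (8 rooms)
    n_local: int = 10
    n_global: int = 5
    room_half_width: float = ROOM_HALF_WIDTH
    spawn_radius: float = 1.5
    spawn_height: float = 1.0

    # build-phase placement noise
    sigma_place_global_consistent: float = 0.15
    sigma_place_global_inconsistent: float = 0.60
    sigma_place_local: float = 0.10
    p_canonical_anchor_consistent: float = 0.9
    p_canonical_anchor_inconsistent: float = 0.1
    anchor_min_spacing: float = 0.8
    anchor_offset_max: float = 0.5

    # recall-phase memory noise, meters, keyed (condition, object_type)
    sigma_memory: dict = field(default_factory=lambda: {
        ("consistent", "global"): 0.25,
        ("inconsistent", "global"): 0.35,
        ("consistent", "local"): 0.35,
        ("inconsistent", "local"): 0.55,
    })

    # summed grab duration, lognormal location by (condition, object_type);
    # the local cells differ by condition, the global cells do not
    grab_mu: dict = field(default_factory=lambda: {
        ("consistent", "global"): 0.9,
        ("inconsistent", "global"): 0.9,
        ("consistent", "local"): 0.7,
        ("inconsistent", "local"): 1.0,
    })
    grab_sigma: float = 0.4
    grab_recall_shift: float = -0.3      # recall grabs are shorter
    global_order_bias: float = 3.0       # grab-priority weight of globals
    gaze_mu: float = 1.5
    gaze_sigma: float = 0.5
    gaze_grab_rho: float = 0.5           # corr(log gaze, log grab)

    # search RT model, natural-log seconds
    rt_base: float = 1.0
    rt_effect_inconsistent: float = 0.12
    rt_effect_local: float = 0.18
    rt_effect_other_local: float = 0.15  # room-familiarity cost, locals only
    rt_slope: dict = field(default_factory=lambda: {
        ("consistent", "global"): -0.010,
        ("inconsistent", "global"): -0.012,
        ("consistent", "local"): -0.028,
        ("inconsistent", "local"): -0.032,
    })
    rt_sigma: float = 0.22
    error_rate: float = 0.038

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_place_global_consistent",
                     "sigma_place_global_inconsistent", "sigma_place_local"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for k, v in self.sigma_memory.items():
            if v < 0:
                raise ValueError(f"sigma_memory[{k}] must be >= 0")
        for p in (self.p_canonical_anchor_consistent,
                  self.p_canonical_anchor_inconsistent, self.error_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def categories(self) -> list[str]:
        return list(_CATALOG)[: self.room_categories]

    def design(self) -> DesignConfig:
        return DesignConfig(
            n_participants=self.n_participants,
            room_categories=self.room_categories,
            rooms_per_category=self.rooms_per_category,
            n_local=self.n_local, n_global=self.n_global,
            spawn_radius=self.spawn_radius, spawn_height=self.spawn_height,
            room_half_width=self.room_half_width,
        )


def exp1_config(**overrides) -> GeneratorConfig:
    """Experiment-1 preset: 16 rooms per participant, build + recall."""
    return GeneratorConfig(**overrides)


def exp2_config(**overrides) -> GeneratorConfig:
    """Experiment-2 preset: 8 rooms per participant, build + search."""
    overrides.setdefault("rooms_per_category", 2)
    return GeneratorConfig(**overrides)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(16)[stream])


def participant_ids(config: GeneratorConfig, prefix: str = "p") -> list[str]:
    return [f"{prefix}{i + 1:02d}" for i in range(config.n_participants)]


def room_ids(config: GeneratorConfig) -> list[str]:
    return [f"{cat}_{i + 1}"
            for cat in config.categories
            for i in range(config.rooms_per_category)]


def assigned_condition(participant_index: int, room_index_in_category: int
                       ) -> str:
    """Counterbalanced condition assignment by participant parity.

    Within each category the room index parity alternates between conditions,
    and the mapping flips with participant parity, so every participant
    builds half of their rooms consistent and every room is built consistent
    by half of the participants.
    """
    if (participant_index + room_index_in_category) % 2 == 0:
        return "consistent"
    return "inconsistent"


def _clip(pos: np.ndarray, half: float) -> np.ndarray:
    out = pos.copy()
    out[..., 0] = np.clip(out[..., 0], -half, half)
    out[..., 1] = np.clip(out[..., 1], -half, half)
    out[..., 2] = np.clip(out[..., 2], 0.0, _Z_MAX)
    return out


# ---------------------------------------------------------------------------
# inventory
# ---------------------------------------------------------------------------

def generate_inventory(config: GeneratorConfig,
                       seed: int | None = None) -> list[ObjectSpec]:
    """Build the object inventory with its canonical layout.

    Per room category: the five global objects receive canonical floor
    positions at least ``anchor_min_spacing`` apart; each local object is
    linked to one canonical anchor (globals are reused round-robin after a
    shuffle) with a canonical offset of magnitude <= ``anchor_offset_max``.
    Deterministic given the seed; raises if anchor spacing cannot be
    satisfied in 200 attempts.
    """
    rng = _rng(config.seed if seed is None else seed, 0)
    half = config.room_half_width
    specs: list[ObjectSpec] = []
    for cat in config.categories:
        glob_names, loc_names = _CATALOG[cat]
        glob_names = glob_names[: config.n_global]
        loc_names = loc_names[: config.n_local]
        if len(glob_names) < config.n_global or len(loc_names) < config.n_local:
            raise ValueError(f"catalog for {cat} has too few object names")

        positions = _place_anchors(rng, config.n_global, half,
                                   config.anchor_min_spacing)
        heights = rng.uniform(0.2, 0.9, size=config.n_global)
        gids = []
        for name, (x, y), z in zip(glob_names, positions, heights):
            oid = f"{cat}.{name}"
            gids.append(oid)
            specs.append(ObjectSpec(
                object_id=oid, name=name, room_category=cat,
                object_type="global",
                canonical_position=(float(x), float(y), float(z))))

        anchor_cycle = list(rng.permutation(gids))
        for j, name in enumerate(loc_names):
            anchor = anchor_cycle[j % len(anchor_cycle)]
            theta = rng.uniform(0, 2 * np.pi)
            r = rng.uniform(0.15, 0.45)
            dz = rng.uniform(-0.1, 0.1)
            offset = (float(r * np.cos(theta)), float(r * np.sin(theta)),
                      float(dz))
            specs.append(ObjectSpec(
                object_id=f"{cat}.{name}", name=name, room_category=cat,
                object_type="local", canonical_anchor=anchor,
                canonical_offset=offset))
    return specs


def _place_anchors(rng: np.random.Generator, n: int, half: float,
                   min_spacing: float) -> np.ndarray:
    margin = 0.2
    for _ in range(200):
        pts = rng.uniform(-(half - margin), half - margin, size=(n, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        if d[np.triu_indices(n, 1)].min() >= min_spacing:
            return pts
    raise RuntimeError(
        f"could not place {n} anchors >= {min_spacing} m apart in 200 "
        f"attempts; config infeasible")


# ---------------------------------------------------------------------------
# build phase
# ---------------------------------------------------------------------------

def generate_build_phase(inventory: Sequence[ObjectSpec],
                         config: GeneratorConfig,
                         seed: int | None = None,
                         participant_prefix: str = "p") -> ArrangementDataset:
    """Generate build-phase placements, grab events and gaze totals."""
    rng = _rng(config.seed if seed is None else seed, 1)
    specs = {s.object_id: s for s in inventory}
    by_cat: dict[str, tuple[list[str], list[str]]] = {}
    for s in inventory:
        g, l = by_cat.setdefault(s.room_category, ([], []))
        (g if s.object_type == "global" else l).append(s.object_id)

    placements, grabs, gaze = [], [], []
    for pidx, pid in enumerate(participant_ids(config, participant_prefix)):
        for cat in config.categories:
            gids, lids = by_cat[cat]
            canon = np.array([specs[g].canonical_position for g in gids])
            for ridx in range(config.rooms_per_category):
                room = f"{cat}_{ridx + 1}"
                cond = assigned_condition(pidx, ridx)
                pos = _arrange_room(rng, config, cond, gids, lids, specs,
                                    canon)
                for oid, p in pos.items():
                    placements.append((pid, room, cat, cond, "build", "",
                                       oid, specs[oid].object_type,
                                       *np.round(p, 9)))
                grabs_r, gaze_r = _interactions(rng, config, cond, "build",
                                                gids, lids)
                for oid, dur, gi in grabs_r:
                    grabs.append((pid, room, cond, "build", oid,
                                  specs[oid].object_type, dur, gi))
                for oid, gz in gaze_r:
                    gaze.append((pid, room, oid, gz))

    ds = ArrangementDataset(
        inventory=list(inventory),
        placements=pd.DataFrame(placements, columns=PLACEMENT_COLUMNS),
        grabs=pd.DataFrame(grabs, columns=GRAB_COLUMNS),
        gaze_totals=pd.DataFrame(gaze, columns=GAZE_COLUMNS),
        design=config.design(),
    )
    return ds


def _arrange_room(rng, config, cond, gids, lids, specs, canon):
    half = config.room_half_width
    n_g = len(gids)
    if cond == "consistent":
        slots = canon
        sigma_g = config.sigma_place_global_consistent
        p_canon = config.p_canonical_anchor_consistent
    else:
        slots = canon[rng.permutation(n_g)]
        sigma_g = config.sigma_place_global_inconsistent
        p_canon = config.p_canonical_anchor_inconsistent

    gpos = _clip(slots + rng.normal(0, sigma_g, size=(n_g, 3)), half)
    pos = {g: gpos[i] for i, g in enumerate(gids)}
    for lid in lids:
        spec = specs[lid]
        if rng.random() < p_canon:
            anchor = spec.canonical_anchor
        else:
            others = [g for g in gids if g != spec.canonical_anchor]
            anchor = others[rng.integers(len(others))]
        p = (pos[anchor] + np.asarray(spec.canonical_offset)
             + rng.normal(0, config.sigma_place_local, size=3))
        pos[lid] = _clip(p, half)
    return pos


def _interactions(rng, config, cond, phase, gids, lids):
    """Grab (summed duration + first-grab order) and gaze totals for a room."""
    oids = gids + lids
    types = ["global"] * len(gids) + ["local"] * len(lids)
    rho = config.gaze_grab_rho
    shift = config.grab_recall_shift if phase == "recall" else 0.0

    z_shared = rng.normal(size=len(oids))
    z_grab = rng.normal(size=len(oids))
    z_gaze = rng.normal(size=len(oids))
    mix_grab = np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * z_grab
    mix_gaze = np.sqrt(rho) * z_shared + np.sqrt(1 - rho) * z_gaze

    mu = np.array([config.grab_mu[(cond, t)] for t in types]) + shift
    durations = np.exp(mu + config.grab_sigma * mix_grab)
    gaze = np.exp(config.gaze_mu + config.gaze_sigma * mix_gaze)

    # first-grab order: exponential race with priority weights (globals first
    # on average); equivalent to sequential weighted sampling w/o replacement
    w = np.where(np.array(types) == "global", config.global_order_bias, 1.0)
    race = rng.exponential(1.0, size=len(oids)) / w
    order = np.empty(len(oids), dtype=int)
    order[np.argsort(race, kind="stable")] = np.arange(1, len(oids) + 1)

    grabs = list(zip(oids, durations, order))
    gaze_rows = list(zip(oids, gaze)) if phase == "build" else []
    return grabs, gaze_rows


# ---------------------------------------------------------------------------
# recall phase
# ---------------------------------------------------------------------------

def generate_recall_phase(build: ArrangementDataset,
                          config: GeneratorConfig,
                          seed: int | None = None) -> ArrangementDataset:
    """Recall placements: build position + memory noise, plus recall grabs.

    Memory noise is isotropic Gaussian with sigma keyed by
    (condition, object_type); positions are clipped to the room bounds.
    """
    rng = _rng(config.seed if seed is None else seed, 2)
    bp = build.placements
    bp = bp[bp.phase == "build"]
    if len(bp) == 0:
        raise ValueError("no build placements to recall from")
    expected = build.design.objects_per_room if build.design else None
    if expected is not None:
        bad = bp.groupby(["participant_id", "room_id"]).size()
        short = bad[bad != expected]
        if len(short):
            raise ValueError(f"missing build placements in rooms: "
                             f"{list(short.index)}")

    sigma = np.array([config.sigma_memory[(c, t)]
                      for c, t in zip(bp.condition, bp.object_type)])
    noise = rng.normal(size=(len(bp), 3)) * sigma[:, None]
    pos = _clip(bp[["x", "y", "z"]].to_numpy() + noise,
                config.room_half_width)

    recall = bp.copy()
    recall["phase"] = "recall"
    recall[["x", "y", "z"]] = np.round(pos, 9)

    specs = build.inventory_by_id()
    by_cat: dict[str, tuple[list[str], list[str]]] = {}
    for s in build.inventory:
        g, l = by_cat.setdefault(s.room_category, ([], []))
        (g if s.object_type == "global" else l).append(s.object_id)

    grabs = []
    for (pid, room, cond), grp in bp.groupby(
            ["participant_id", "room_id", "condition"], sort=False):
        cat = grp.room_category.iloc[0]
        gids, lids = by_cat[cat]
        grabs_r, _ = _interactions(rng, config, cond, "recall", gids, lids)
        for oid, dur, gi in grabs_r:
            grabs.append((pid, room, cond, "recall", oid,
                          specs[oid].object_type, dur, gi))

    return ArrangementDataset(
        inventory=list(build.inventory),
        placements=recall.reset_index(drop=True),
        grabs=pd.DataFrame(grabs, columns=GRAB_COLUMNS),
        design=build.design,
    )


# ---------------------------------------------------------------------------
# search phase
# ---------------------------------------------------------------------------

def generate_search_phase(own_builds: ArrangementDataset,
                          other_builds: ArrangementDataset,
                          config: GeneratorConfig,
                          seed: int | None = None) -> pd.DataFrame:
    """Search trials over own and other participants' rooms.

    Each searcher is matched to the same-position participant of
    ``other_builds``.  Search order within a room is randomised; log-RT is
    baseline + main effects (consistency, object type) + a room-familiarity
    cost for local objects in other rooms + a per-trial learning slope
    (steeper for local objects) + Gaussian noise; errors are Bernoulli.
    """
    rng = _rng(config.seed if seed is None else seed, 3)
    own_ids = sorted(own_builds.placements.participant_id.unique())
    other_ids = sorted(other_builds.placements.participant_id.unique())
    if len(other_ids) < len(own_ids):
        raise ValueError("not enough partner participants in other_builds")

    rows = []
    for pid, partner in zip(own_ids, other_ids):
        for room_type, src, builder in (("own", own_builds, pid),
                                        ("other", other_builds, partner)):
            pl = src.placements
            pl = pl[(pl.participant_id == builder) & (pl.phase == "build")]
            for room, grp in pl.groupby("room_id", sort=True):
                cond = grp.condition.iloc[0]
                objs = grp[["object_id", "object_type"]].to_numpy()
                order = rng.permutation(len(objs))
                n = len(objs)
                center = (n + 1) / 2.0
                for trial, k in enumerate(order, start=1):
                    oid, otype = objs[k]
                    log_rt = config.rt_base
                    if cond == "inconsistent":
                        log_rt += config.rt_effect_inconsistent
                    if otype == "local":
                        log_rt += config.rt_effect_local
                        if room_type == "other":
                            log_rt += config.rt_effect_other_local
                    log_rt += config.rt_slope[(cond, otype)] * (trial - center)
                    log_rt += rng.normal(0, config.rt_sigma)
                    err = bool(rng.random() < config.error_rate)
                    rows.append((pid, room, cond, room_type, oid, otype,
                                 trial, float(np.exp(log_rt)), err))
    return pd.DataFrame(rows, columns=SEARCH_COLUMNS)


# ---------------------------------------------------------------------------
# end-to-end presets
# ---------------------------------------------------------------------------

def generate_exp1(config: GeneratorConfig | None = None) -> ArrangementDataset:
    """Full Experiment-1-style dataset: build + recall phases."""
    config = config or exp1_config()
    inv = generate_inventory(config)
    build = generate_build_phase(inv, config)
    recall = generate_recall_phase(build, config)
    return ArrangementDataset(
        inventory=inv,
        placements=pd.concat([build.placements, recall.placements],
                             ignore_index=True),
        grabs=pd.concat([build.grabs, recall.grabs], ignore_index=True),
        gaze_totals=build.gaze_totals,
        design=config.design(),
    )


def generate_exp2(config: GeneratorConfig | None = None) -> ArrangementDataset:
    """Full Experiment-2-style dataset: build phase + repeated search.

    The "other" rooms are built by a disjoint set of partner participants
    generated from a derived seed with the same room layout, mirroring the
    matched-partner design of the search experiment.
    """
    config = config or exp2_config()
    inv = generate_inventory(config)
    build = generate_build_phase(inv, config)
    partner_cfg = replace(
        config,
        sigma_memory=dict(config.sigma_memory),
        grab_mu=dict(config.grab_mu), rt_slope=dict(config.rt_slope),
        seed=int(np.random.SeedSequence(config.seed).generate_state(1)[0]
                 % (2 ** 31)),
    )
    other = generate_build_phase(inv, partner_cfg, participant_prefix="q")
    searches = generate_search_phase(build, other, config)

    own_pl = build.placements.copy()
    own_pl["room_type"] = "own"
    return ArrangementDataset(
        inventory=inv,
        placements=own_pl,
        grabs=build.grabs,
        gaze_totals=build.gaze_totals,
        searches=searches,
        design=config.design(),
    )


def config_to_dict(config: GeneratorConfig) -> dict:
    """JSON-serialisable dump of a config (tuple keys flattened)."""
    d = asdict(config)
    for key in ("sigma_memory", "grab_mu", "rt_slope"):
        d[key] = {f"{c}:{t}": v for (c, t), v in d[key].items()}
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    for key in ("sigma_memory", "grab_mu", "rt_slope"):
        if key in d:
            d[key] = {tuple(k.split(":")): v for k, v in d[key].items()}
    return GeneratorConfig(**d)
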