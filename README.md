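# scenegram

Analysis pipeline for *self-generated scene arrangements*: what people
remember about 3D environments they built themselves, and the statistical
regularities ("scene grammar") of how they place objects.

In the paradigm this package models, participants arrange 15 objects — 10
small, movable **local** objects (toothbrush, pot) and 5 large, static
**global** objects (bathtub, oven) that act as spatial *anchors* — in 3 × 3 m
virtual rooms, either **consistent** with their expectations or deliberately
**inconsistent**. Memory is probed by exact recall (re-placing every object)
or by repeated search. No raw data from such studies are public, so the
package ships a seeded generative model of the whole design and exercises
every analysis on it.

## What it computes

- **Location memory.** Displacement per object
  `d = ‖x_build − x_recall‖₂` (meters, 3D), compared against a
  **cross-participant baseline**: for each (participant, room), the distances
  to the same objects placed by a randomly drawn *other* participant who
  built the same room under the same condition. Analyses use per-participant
  mean log-displacement cells and classical paired *t* contrasts
  (Cohen's *d* = mean(diff)/sd(diff)).
- **Pairing statistics.** For every object, its nearest *local* neighbor in
  3D; repeated (focal → neighbor) pairings are counted across participants
  per room and condition, and the counts contrasted with a Poisson
  log-linear model `log E[count] = β₀ + β₁·consistent (+ room)`, fitted by
  IRLS.
- **Rank-frequency laws.** Pair counts sorted by rank are fitted by maximum
  likelihood to the Zipf law `p(r) ∝ r^(−α)` and the Zipf–Mandelbrot law
  `p(r) ∝ (r + β)^(−α)` on finite support `r = 1..R`, with a tail-pooled
  Pearson χ² fit index.
- **Interaction and search behavior.** Grab-duration cell means (log scale),
  grab order (globals first), Gaussian-kernel first-grab densities, error
  filtering, and per-participant OLS learning slopes of log RT on the
  centered search-trial index.

## Worked example

```python
import scenegram as sg

ds = sg.generate_exp1(sg.exp1_config(seed=1))      # 10 participants x 16 rooms
build = ds.placements[ds.placements.phase == "build"]
recall = ds.placements[ds.placements.phase == "recall"]

mem = sg.memory_report(build, recall, seed=2)
print("mean displacement (m):",
      {k: round(v, 3) for k, v in mem["mean_displacement_m"].items()})
c = mem["contrasts"]["empirical_vs_baseline"]
print(f"memory vs baseline: t({c['df']}) = {c['t']:.2f}, d = {c['cohen_d']:.2f}")

pairs = sg.pairing_report(build)
print("mean pair count:", {k: round(v, 2) for k, v in pairs["mean_count"].items()})
print(f"Poisson contrast: log rate ratio = {pairs['contrast']['log_rate_ratio']:.3f}, "
      f"z = {pairs['contrast']['z']:.2f}")
```

prints

```
mean displacement (m): {'empirical': 0.58, 'baseline': 1.177}
memory vs baseline: t(9) = -22.62, d = -7.15
mean pair count: {'consistent': 2.14, 'inconsistent': 1.23}
Poisson contrast: log rate ratio = 0.569, z = 13.88
```

Read: recall error (0.58 m) is roughly half the between-person chance level
(1.18 m), so participants hold genuine object-specific location memory; and
the same (focal → nearest-local-neighbor) pairings recur across participants
about e^0.57 ≈ 1.8× more often in consistently built rooms — shared
arrangement rules, not idiosyncratic choices.

The same stages run from the shell:

```sh
scenegram generate --preset exp1 --seed 1 --out data/
scenegram report --preset exp1 --seed 1 --out out/     # all stages + JSON reports
```

## Layout

| module | contents |
| --- | --- |
| `scenegram.scene_model` | domain types, 3D geometry, validation, CSV/JSON I/O |
| `scenegram.synthetic_scenes` | the anchor-based generative model and presets |
| `scenegram.memory_analysis` | displacement, cross-participant baseline, contrasts |
| `scenegram.pairing_analysis` | nearest local neighbors, repetition counts, Poisson GLM |
| `scenegram.zipf_fit` | rank-frequency construction, Zipf/ZM ML fits, GOF |
| `scenegram.interaction_analysis` | grab/gaze/search summaries, densities, slopes |
| `scenegram.pipeline`, `scenegram.cli` | orchestration and the `scenegram` command |

See `docs/methods.md` for the model, its assumptions and numerical choices.
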