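# larvaswim

Swimming-speed measurement for larval fish, developed around the early
life stages of grass carp, bighead carp and silver carp — species whose
dispersal from spawning rivers into nursery habitat depends on how well
their larvae can swim. The package measures the two quantities that
matter for dispersal modelling:

* **Routine swimming speed** — spontaneous speeds of free-swimming
  larvae in still water, extracted from sequences of backlit still
  photographs (2–7 frames/s): each frame is thresholded, dark larval
  bodies are segmented and reduced to mass centroids, centroids are
  linked frame-to-frame into per-fish tracks, and each inter-frame
  displacement becomes a calibrated movement with signed vertical
  (up/down) and horizontal speed components.
* **Maximum swimming speed (U_max)** — from incremental-velocity
  swim-chamber trials in which water velocity rises by a fixed increment
  U_i (default 0.218 cm/s) every t_i seconds (default 2 s) until the
  fish can no longer hold position:

  `U_max = U + (t / t_i) · U_i`,  with `U = U_final − U_i` the
  penultimate speed and `t` the time survived in the failure increment
  (conventionally 0). Relative speed is `U_maxrel = U_max / TL` in total
  lengths per second, using the daily mean total length. Chamber speed
  is set by pump frequency through the affine calibration
  `U = 0.0218·Hz − 0.0731` (cm/s).

Daily means of U_max are regressed (OLS) on age (days post-hatch), mean
total length (mm) and mean developmental stage (ordinal stages 31–48),
per species.

Because raw laboratory photographs of this kind are rarely shareable, a
synthetic-scene generator renders backlit larvae as semi-transparent
dark ellipses moving on programmed trajectories, with exact per-frame
ground-truth centroids and velocities; a companion simulator runs
virtual fish of known U_max through the step protocol. Every pipeline
stage is validated against this programmed truth.

## Worked example

```python
import larvaswim as lw
from larvaswim.pipeline import track_sequence, recover_speeds

# 20 larvae at programmed speeds 0.5-5 cm/s, 60 frames at 6 fps
spec = lw.make_speed_survey_scene(n_larvae=20, n_frames=60, seed=1)
seq, truth = lw.render_sequence(spec)

cal = lw.Calibration(cm_per_px=spec.cm_per_px)
tracks, steps, summaries = track_sequence(seq, cal)
for s in summaries:
    print(f"{s.direction:10s} {s.mean_cm_s:.2f} ± {s.sd_cm_s:.2f} cm/s "
          f"(range {s.min_cm_s:.3f}-{s.max_cm_s:.2f}, n={s.n_movements})")

rec = recover_speeds(truth, tracks, cal, seq.timestamps)
print("recovered within 10%:", (rec.rel_error <= 0.10).mean())
```

prints (seed 1):

```
upward     1.55 ± 1.49 cm/s (range 0.018-4.31, n=336)
downward   1.51 ± 1.26 cm/s (range 0.037-7.63, n=629)
horizontal 1.72 ± 1.23 cm/s (range 0.296-4.40, n=965)
overall    2.62 ± 1.32 cm/s (range 0.527-8.50, n=965)
recovered within 10%: 1.0
```

i.e. 965 individual movements were measured; every one of the 20
programmed larval speeds was recovered within 10 %. The directional
groups count vector components: a diagonal movement contributes its
vertical component to upward *or* downward and its |horizontal|
component to horizontal, so the component means sit below the overall
(vector-magnitude) mean.

The chamber side:

```python
rec = lw.simulate_chamber_trial(5.0, lw.ChamberProtocol(start_speed=4.782))
lw.compute_umax(rec).u_max        # 5.0  (final 5.218 minus one increment)
lw.hz_to_velocity(60.0)           # (1.2349, True)

trials = lw.simulate_chamber_dataset(seed=1)   # 3 species, 10-20 fish/day
daily = lw.daily_means(trials)                 # mean ± SD U_max, TL, stage
```

A `larvaswim` command-line tool exposes the same stages
(`simulate`, `detect`, `track`, `speeds`, `chamber`, `regress`, `all`)
over TOML configs and CSV artifacts; `larvaswim all --seed 7 --out run/`
executes both pipelines end to end and is byte-reproducible per seed.

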