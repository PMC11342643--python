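# prltrain

Headless engine for software-supported visual rehabilitation in age-related
macular degeneration (AMD).  AMD destroys central vision; rehabilitation
trains a functional peripheral retinal area — the preferred retinal locus
(PRL) — to take over fixation (eccentric viewing).  `prltrain` implements
the computation behind such an application, with no GUI, audio, or network:

- **Amsler-grid self-assessment** — seeded 50-stimulus test plans on the
  10 × 10 cm / 0.5 cm-spaced chart viewed at 30 cm (each square ≈ 1° of
  visual angle), shortened scotoma-targeted follow-up tests, and per-cell
  scotoma maps with a recency rule for tracking progression.
- **Eccentric-viewing exercises** — the full initial (15) and revised
  (11 + demonstration) catalogues, seeded stimulus streams projected on the
  practitioner-set treatment area relative to the fixation point, and
  hit/miss/attempt scoring including sequential alternating fixation.
- **Closed-loop adaptation** — per-skill ability scores (EWMA of session
  success), a difficulty index
  `D = 0.5·rank/9 + 0.3/(1+size_cm) + 0.2/(1+interval_s)`,
  a content-based recommender that keeps difficulty slightly above ability
  (target `a + δ`, chosen from above), and a self-adjustment rule that
  steps an exercise easier whenever misses exceed hits — failure never
  escalates difficulty.
- **Role-gated records** — practitioner/patient accounts with unique
  numeric registration codes, audit-logged treatment areas, sync-pending
  flags with atomic export.
- **Synthetic AMD patient** — a seeded responder with a localized scotoma
  (low detection probability inside, high outside), a logistic psychometric
  function for exercise hits, truncated-normal reaction times, and a
  Bernoulli compliance gate, so every pipeline can be tested end to end
  without real patients.

The model details and design rationale are in [docs/methods.md](docs/methods.md).

## Worked example

```python
import prltrain as pt

grid = pt.GridSpec()                     # 10x10 cm, 0.5 cm spacing, 30 cm distance
pt.cm_to_deg(grid.spacing_cm, grid.working_distance_cm)
# 0.955  -> one grid square subtends ~1 degree

# a simulated patient with a 3x3-cell scotoma takes a full 50-stimulus test
patient = pt.make_patient(seed=2)
plan = pt.build_test_plan(grid, "full", seed=1)      # 50 distinct cells, 300 s schedule
result = pt.run_test(plan, pt.amsler_responder(patient, grid))
result.n_seen, result.n_missed
# (46, 4)

sorted(pt.estimate_scotoma(result, grid).missed_cells)
# [(5, 13), (6, 11), (7, 12), (8, 15)]
# three of the four missed cells fall inside the true scotoma block
# (rows 5-7, cols 11-13); (8, 15) is a lapse outside it.  A single test
# samples 50 of 400 cells, so maps sharpen as follow-up tests are pooled.

# 30 closed-loop sessions: recommend -> execute -> score -> update
history = pt.run_selection_loop(
    pt.AbilityModel(), pt.exercises_only(pt.catalogue("revised")),
    pt.ExerciseResponder(pt.make_patient(seed=3)), 30, seed=3,
)
[round(r, 3) for r in pt.rolling_success(history)[-5:]]
# [0.59, 0.63, 0.67, 0.75, 0.71]   -> settled in the [0.6, 0.8] target band
```

The same operations are available from the shell; every command accepts
`--seed` and `--config` and prints JSON:

```sh
$ prltrain --seed 1 recommend
{
  "difficulty": 0.5270707070707071,
  "rationale": "hold",
  "spec_id": 9
}
```

Other subcommands: `plan-test`, `simulate-test`, `estimate-scotoma`,
`list-exercises`, `simulate-exercise`, `simulate-program`, `make-patient`,
`create-patient`, `set-area`, `export`, `report`.

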