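# vesselgame

A headless, scriptable re-implementation of a blood-vessel cutting game
used to quantify the effect of a restricted field of view (FOV) on visual
search and cutting task performance. The package provides:

- **`vesselgame.scene`** — procedural scene generation: wavy vessel bands
  stroked from cubic-spline centerlines, a 7-level structure (1–3 vessels,
  plain or intertwined, full or limited FOV), and two black endpoint
  markers identifying the single target vessel.
- **`vesselgame.engine`** — deterministic game mechanics: pointer-event
  streams (move/press/drag/release), a circular spotlight mask centred on
  the cursor for limited-FOV levels, cut lines clamped to 45 scene units,
  full-transection cut detection, attempt counting, an injected clock, and
  bitwise-reproducible replay. An optional paint mode reveals regions
  permanently.
- **`vesselgame.simulate`** — synthetic cohorts from a transparent
  generative model (lognormal times with additive level/FOV/participant
  effects; 1 + Poisson attempts independent of FOV), plus a mechanistic
  agent that actually plays generated scenes through the engine (a
  boustrophedon spotlight sweep under limited FOV).
- **`vesselgame.stats`** — per-level summaries with t-based 95% CIs, Welch
  two-sample tests with Satterthwaite df, Cohen's d (equal-n pooled form),
  percent increases over matched level pairs, questionnaire arithmetic,
  and exact noncentral-t sample-size planning (`required_n`).
- **`vesselgame.io` / `vesselgame.cli`** — lossless plain-text formats
  (scene JSON, event JSONL, trial CSV, report JSON/text with a config
  fingerprint) and a `vesselgame` command-line interface.

## CLI

```sh
# generate a level-5 scene, have the agent play it, replay the log
vesselgame generate --level 5 --seed 7 --out scene.json
vesselgame agent --scene scene.json --seed 7 --out events.jsonl
vesselgame replay --scene scene.json --events events.jsonl --out trials.csv

# simulate a 25-participant cohort and analyze the FOV level pairs
vesselgame simulate --participants 25 --seed 1 --out trials.csv
vesselgame analyze --trials trials.csv --pairs 4:5,6:7 --metric time
vesselgame report --trials trials.csv --out report.json
```

Everything honours `--seed`; identical inputs give byte-identical
artifacts end to end.

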