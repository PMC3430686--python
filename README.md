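# dyadstate

Analysis pipeline for leadership in foraging dyads that shuttle between a
covered (safe) area and an exposed (risky) area. The joint behaviour of a
pair is modelled as a fully observed 4-state continuous-time Markov chain
(1 = both under cover, 2 = focal out, 3 = partner out, 4 = both out) with
transition intensities only on the eight single-fish-move edges and
log-linear covariate effects (satiation, boldness) on those intensities.

The package provides:

- **`dyadstate.eventlog`** — validated data model and CSV I/O for
  pair-session transition event logs (events + session metadata at two
  grains; zero-event sessions representable; structural zeros enforced).
- **`dyadstate.metrics`** — boldness scores, merging per-fish leave/return
  streams into joint states, sufficient statistics (transition counts and
  sojourn times with right-censored final sojourn), the trip taxonomy
  (attempted initiations / joint-trip initiations / follows), per-fish
  session summaries, and boldness-ratio pair categories (SM/SL/BM/BL).
- **`dyadstate.ctmc`** — exact log-likelihood, maximum-likelihood
  estimation on the working scale (log baseline intensities +
  coefficients) by per-edge Newton iteration with analytic gradients and
  Hessians, 95% confidence intervals from the observed information, Wald
  tests on coefficients and delta-method contrasts of log intensities.
- **`dyadstate.simulate`** — seeded synthetic studies: Beta-distributed
  boldness populations, quota-based pair assembly, boldness-linked
  intensity models, exact (Gillespie) trajectory simulation and full
  two-session study generation with a ground-truth record.
- **`dyadstate.ttests`** — the paired two-tailed t-test battery:
  within-pair initiation asymmetries and pre/post-satiation contrasts.
- **`dyadstate.cli`** — the `dyadstate` command-line pipeline.

## Command-line usage

```sh
# simulate a study (YAML config optional; all fields have defaults)
dyadstate simulate --config config.yaml --seed 1 --out study/

# fit the intensity model per category (or --per-pair)
dyadstate fit study/events.csv study/sessions.csv --out fits/

# per-fish behavioural summaries
dyadstate summarize study/events.csv study/sessions.csv --out summaries/

# the paired t-test battery (optionally --holm)
dyadstate analyze summaries/summaries.csv study/sessions.csv --out tests/
```

Exit codes: 0 ok, 2 usage/config error, 3 input validation error, 4
convergence failure. Every command writes a `manifest.json` (command,
config digest, seed, inputs/outputs, version, timestamp) into its output
directory.

### File formats

- events CSV: `pair_id,session,time_s,from_state,to_state`, one row per
  transition, times in seconds from session start (6 d.p.).
- sessions CSV: `pair_id,session,duration_s,initial_state,focal_boldness,
  partner_boldness,focal_satiated,category`, one row per pair-session.

## Notes on modelling choices

- Sessions are half-open `[0, duration)`; the final sojourn is
  right-censored and always enters the likelihood.
- The generator's boldness link (`log q_leave = a + b*boldness`,
  `log q_return = a' - b'*boldness`) is a documented implementation choice:
  the simulated chain is exactly the model the fitter assumes, so recovery
  studies are well-specified by construction.
- The trip taxonomy is bout-local: every entry into the both-out state is
  one joint trip, crediting the mover a follow and the already-out fish a
  joint-trip initiation, which makes the cross-fish ledger identities exact
  on every trajectory.
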