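# File formats

All artefacts are diff-able text.

## Run configuration (YAML)

Read by `neuritesim.config.load_run_config`; unknown keys are rejected.

```yaml
velocity: 10            # required, um/h
t_end: 5000             # min; record_every must divide it
record_every: 500
rtol: 1.0e-8
atol: 1.0e-10
seed: 1
spec_overrides:         # any SteadyStateSpec field except velocity/free
  cycling_rate: 0.5
free_overrides:         # any FreeChoices field
  tether_rate_gc: 5.0e-4
```

## Response surfaces (JSON)

Written by `ResponseSurfaces.to_json` / the `fit-surfaces` subcommand:
`tu_domain`, `h_domain` (fit rectangle), `coef_mean` and `coef_deg`
(4×4 cubic coefficient matrices in domain-normalised variables),
`mean_length_space` (`"log"` means `coef_mean` fits log length), and
`fit_residuals` (per-grid-point relative errors).

## Parameter set (JSON)

Written by `ParameterSet.to_json` / the `predict` subcommand: the full
`transport` and `mt` parameter blocks (including the embedded surfaces),
the steady-state initial `state0` (areas, 4×3 vesicle counts, 4×4×3
vesicle protein loads, 4×2 organelle proteins, microtubule pools), the
membrane-type `fluxes`, a human-oriented `report` of every derived
quantity, and `provenance` (the generating spec).  Round-trips exactly.

## Trajectory (CSV)

One row per checkpoint (schema version 1).  Columns: `time_min`, the
three membrane areas and `shaft_length_um`; aggregate and per-class
vesicle counts (`n_<CLASS>_<COMPARTMENT>`); moving/fusing fractions
(`antero_moving_frac_nsc`, `antero_moving_frac_nsc_all`,
`retro_moving_frac_nsc`, `gcc_fusing_frac`); membrane fluxes
(`fusion_area_gc`, `retro_fusion_area_tgn`, `endocytosis_area`,
`overflow_area`); microtubule state (`n_dyn`, `l_dyn_total`,
`l_stable_total`, `dynamic_span_um`, `mtb_length_um`); per-species
protein totals (`total_<species>`), the NSC kinesin-receptor load
`kr_per_nsc_antero`, and `total_membrane_area` for conservation checks.

## Constraint report (CSV)

Long form, one row per (checkpoint × postulate): `time_min`, `postulate`,
`observed`, `target`, `rel_deviation`, `tolerance`, `passed`.

## Manifests (JSON)

Every CLI output is accompanied by a manifest: the generating config, its
SHA-256 hash, the seed, and numpy/scipy/pandas versions — enough to
reproduce the file bit-for-bit.

## Acceptance results (JSON)

`scripts/acceptance.py` writes `{"<id>": {"value": <number>, "n": <size>}}`
per measured quantity.
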