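# neuritesim

Growing a neurite is a logistics problem: membrane lipids and proteins are
made at the trans-Golgi network (TGN) in the cell body, packaged into coated
vesicles, carried by kinesin along microtubules through the lengthening
shaft, and fused into the growth-cone plasma membrane (GC-PM) by SNARE
pairing — while the microtubule scaffold itself must elongate at the same
pace by converting dynamic microtubules into stable ones.  `neuritesim` is a
Python library for studying how these subcellular processes (SCPs) must be
*balanced* for a neurite to grow at a steady velocity, and what goes wrong —
stalled growth, vesicle-engorged growth cones resembling dystrophic bulbs —
when the balance is broken.

It is written for computational cell biologists and systems-biology
modellers; everything is driven from Python (a thin `neuritesim` CLI wraps
the same calls).

## The model

Three coupled pieces:

1. **Single dynamic microtubules** (stochastic).  A Gillespie jump process
   over the filament length with a GTP cap: dimer layers add at
   `k_on·Tu`, the cap hydrolyses at `h` per cap dimer, cap exhaustion
   triggers rapid shrinkage, and shrinking below 4 layers is complete
   breakdown followed by re-nucleation.  A grid over effective tubulin
   `Tu ∈ [8, 10] µM` and hydrolysis rate `h ∈ [0.65, 0.75] /s` (26,000 s
   traces) is reduced to two cubic response surfaces: the mean length
   `L̄(Tu, h)` and the complete-breakdown rate `k_deg(Tu, h)`.

2. **Microtubule population** (deterministic).  With `n` dynamic filaments,

       dn/dt = k_nuc − (k_deg + k_stab)·n,
       dL_stable/dt = k_stab · n · L̄,

   and the microtubule-bundle (MTB) length is the total filament length
   divided by the number of filaments per cross-section.

3. **Vesicle transport** (compartmental ODE).  Membrane areas of TGN,
   GC-PM and shaft plus four vesicle classes (coat A/B × origin TGN/GC-PM)
   in three transit compartments (cell-body, neurite-shaft, growth-cone
   cytoplasm), each carrying v-SNAREs U/V and kinesin/dynein receptors.
   A vesicle is microtubule-bound with probability `1 − (1 − f)ⁿ` for `n`
   motor receptors; fusion flux is bilinear in v-SNARE load and t-SNARE
   surface density; the GC-PM is capped at 50 µm² with the excess membrane
   added to the shaft, whose length is `area / (π·d)` at diameter `d = 1 µm`.

The centrepiece is the **analytical steady-state solver**: given a target
velocity `v` and the postulated constraints (cycling membrane 0.5 µm²/min,
~10% of shaft anterograde vesicles moving, 90% of retrograde moving, 20 µm
of dynamic-MT span), it classifies membrane into four destination types
(reservoir / shaft / endocytosed / cycling), solves the fluxes, inverts the
fusion law and coat partition for SNARE amounts and production rates, and
derives `k_nuc`, `k_stab`, `n_dyn` — a complete parameter set whose
simulation holds every postulate from the first checkpoint.

## Worked example

```bash
python examples/03_predict_baseline.py
```

prints (fitted surfaces from seed 1):

```
membrane fluxes (um^2/min):
  type I   (NSC reservoir)   0.0285
  type II  (shaft addition)  0.5236
  type III (endocytosed)     0.0015
  type IV  (cycling)         0.5000
  total budding at the TGN   1.0535
NSC accumulation             0.599 vesicles/min
v-SNARE V: 10.0/vesicle, total 4251
kinesin receptors/vesicle:   2
MT rates: k_nuc 3.594/min, k_stab 0.00833/min, k_deg 0.0620/min, n_dyn 51.1
```

Growing at 10 µm/h through a 1 µm-diameter tube consumes membrane at
`π · 1 µm · 10/60 = 0.5236 µm²/min` (type II); almost as much membrane
merely cycles between TGN and growth cone (type IV = the 0.5 µm²/min
back-transport postulate), and a further ~0.03 µm²/min is swallowed by the
growing shaft-cytoplasm vesicle reservoir — ~0.57 vesicles/min at
0.05 µm² per vesicle.  `examples/04_validate_baseline.py` integrates this
set for 5,000 min and shows every postulate holding at every 500 min
checkpoint; `examples/05_vsnare_knockdown.py` reproduces the prediction
that knocking down the exocytic v-SNARE leaves velocity untouched but
floods the growth cone with vesicles.

Other entry points: `examples/01_single_microtubule.py` (one stochastic
trace), `examples/02_response_surfaces.py` (grid → surfaces), and the CLI
(`neuritesim fit-surfaces / predict / simulate / validate / perturb /
scan`).

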