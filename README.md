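# sspt — light-induced phase transitions in riboswitch crystals

`sspt` is a toolkit for quantifying **solid-to-solid phase transitions
(SSPTs)** in RNA crystals observed by **polarized video microscopy (PVM)**.
When a birefringent crystal of the *add* adenine riboswitch aptamer binds
its ligand, the lattice converts between crystal forms and the transmitted
intensity between crossed polarizers changes; the time course of that
change carries the transition kinetics.  The package is written for
structural biologists and microscopists preparing time-resolved
crystallography experiments who need to ask: *how uniform is the
transition in space and time, and what reaction kinetics explain it?*

It provides four pieces, usable from Python (see `examples/`) or a thin
command line (`sspt simulate|analyze|kinetics|photo`):

* **`sspt.synthetic`** — a generator of PVM-like 8-bit video stacks with a
  known per-pixel ground-truth transition-time field (T1 map), so every
  analysis stage can be validated without real microscopy data.
* **`sspt.pvm`** — the trace analysis: ROI cropping, superpixel binning
  (1–2 px), boxcar smoothing (windows 65/39), first derivatives, and
  extraction of the transition time **T1** (time of the primary
  first-derivative peak) and width **HWHM** (half-width at half-maximum of
  that peak), plus positional and ROI-size study designs and k-means
  classification of transition times.
* **`sspt.kinetics`** — the four-state forward binding model

      apo1 →(k_op) apo2 —ade→(k_on) IB·ade →(k_f) B·ade

  integrated as mass-action ODEs (reverse rates fixed at 0, the in-crystal
  transition being unidirectional).  The inflection point of the B·ade
  accumulation curve (max d[B·ade]/dt) is the model's T1.  Includes
  reproducible fitting of (B0, k_op, k_f) to normalized transition curves
  and an explicit, calibrated treatment of the rate-law conventions.
* **`sspt.photochemistry`** — uncaging arithmetic for the photocaged
  ligand: HPLC standard curves, % released, replicate summaries, beam
  power density, illuminated drop fraction, and nominal uncaged
  concentration.

## Worked example

```bash
python examples/kinetics_transition_times.py
```

prints

```
crystal   B0 (mM)   k_op      k_f    simulated T1 (s)   observed T1 (s)
S2        0.46      2.35e-04  0.50       56.5           55.7
M3        0.42      2.00e-04  1.00       62.2           60.4
L1        0.43      1.60e-04  0.90       71.1           72.1
```

Each row integrates the four-state model with that crystal's fitted
parameters (16 mM of each apo conformer in crystal) and reports the B·ade
inflection time — the model's prediction of the transition time seen by
PVM for a 1×1 µm region of that crystal.  The simulated times track the
measured ones within ~2 s, and the bulk free-ligand concentration B0 falls
in a narrow band (0.42–0.46 mM) across crystals spanning two orders of
magnitude in area — far below the ~2.5 mM nominal uncaged concentration,
reflecting slow, partial uncaging.

`examples/simulate_and_analyze.py` renders a synthetic crystal with a
spatial T1 gradient and shows the recovered mean T1 per concentric ROI
size, with sd(T1) growing from 0.3 s (0.3 µm ROI) to 2.6 s (3 µm ROI) —
the larger the region, the less uniform the transition it contains.
`examples/uncaging_photochemistry.py` reproduces the uncaging yield table
and beam arithmetic.

## Layout

```
src/sspt/          library (synthetic, pvm, kinetics, photochemistry,
                   reference_data, stack, cli)
examples/          narrative scripts, one per capability
tests/             pytest suite incl. acceptance checks
scripts/           acceptance.py
docs/methods.md    models, conventions, parameter choices, limitations
```
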