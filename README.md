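# ncstream

A cellular Potts simulator of cranial neural-crest (NC) / epibranchial
placode "chase-and-run" interactions, for studying how NC migratory streams
emerge without any pre-existing guidance pattern.

During vertebrate head development the neural crest forms as a continuous
band next to the placodal ectoderm and then splits into discrete ventral
migratory streams. `ncstream` implements a two-tissue model of this process
for computational developmental biologists: NC cells chase the placodes up
a chemokine (Sdf1) gradient, both tissues repolarize away from each other
on contact (contact inhibition of locomotion, CIL), NC cells co-attract via
a secreted factor, and placodes deposit a short-range inhibitor. Streams,
when they form, are an emergent property of these rules — there is no
pre-pattern in the model.

## Model in brief

Cells are site domains on a 2D lattice evolving by biased copy attempts
accepted with probability `min{1, exp[(W − ΔH)/T]}` where

    H  =  Σ_i λ_V (V_i − V_T)²  +  Σ_<x,y> J(τ_x, τ_y)

(volume constraint + contact energies) and the work bias `W` adds
extension-only chemotaxis `Σ_s λ_s Δc_s`, persistent-adhesion springs
(`λ_M`, rest length `d0 = 2√(V_T/π)`), and polarized motility
`λ_P (Δr·p̂)`. Per MCS, every cell updates its polarity
`p ← (1 − δ_P) p + Δr`, CIL switches on new NC contacts (biasing polarity
away from contacts with strength `λ_CIL`), adhesion links form and break,
three reaction–diffusion fields advance (`∂c/∂t = D∇²c − δc + S`), and new
NC cells enter at the dorsal edge (EMT). Streams are quantified by the NC
density-probability function ρ(r) — the probability of finding two NC cells
at relative offset r — whose axis profiles define the stream width W and
length L at the 0.5 level. Calibration: 1 site = 3.5 µm, 1 MCS = 10 s.

All published constants are defaults of `ncstream.ParameterSet`; the
constants the publication leaves open (temperature, concentration scales,
CIL probabilities) are documented in [docs/methods.md](docs/methods.md)
together with how they were fixed.

## Worked example

Run a small control ensemble from the shell and measure it:

```bash
ncstream run --preset control --seed 7 --replicates 2 --out out/demo
```

which prints

```
W=29.6 L=39.2 streams=2.5 no_stream_fraction=0.00
```

— the ensemble-pooled stream width and length in lattice sites (multiply by
3.5 for µm) and the mean number of streams crossing mid-placode depth.
`out/demo/` then holds per-replicate snapshots (`snapshot_seed*.npz`), a
tidy per-MCS metrics CSV, a `summary.json`, and a checksummed
`manifest.json` sufficient to re-run the scenario bit-identically. Other
presets: `no_sdf1_chemotaxis`, `no_placode_cil`, `low_adhesion`,
`high_adhesion`, `width_0.5/1.5/2`; `ncstream sweep` and `ncstream map`
produce the 1D sweeps and 2D morphology maps, `ncstream render` draws
NC-orange / placode-red configuration PNGs and field heatmaps.

The same from Python:

```python
from ncstream import ParameterSet, Simulation
from ncstream.metrics import density_probability, width_length

sim = Simulation(ParameterSet(), seed=7).run()
W, L = width_length(density_probability(sim.state.nc_mask()))
```

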