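# Model and methods

`ncstream` simulates the emergence of cranial neural-crest (NC) migratory
streams from the interaction of two tissues — NC and epibranchial placodes —
on a 2D cellular Potts lattice coupled to three diffusible fields. No
pre-pattern of guidance cues is imposed: streams, when they form, are an
emergent property of chase-and-run cell interactions.

## The cellular Potts engine

Cells are domains of lattice sites carrying an integer label; label 0 is
cell-free medium. One Monte Carlo step (MCS) performs N copy attempts, N
being the number of lattice sites (17 100 for the default 180 x 95 domain).
An attempt picks a random target site and proposes to overwrite it with the
label of a random Moore neighbor, or with medium in 10% of attempts
(membrane retraction). The proposal is accepted with probability

    p = min{ 1, exp[ (W - dH) / T ] }.

`dH` is the change of the Hamiltonian

    H = sum_i lambda_V (V_i - V_T)^2  +  sum_<x,y> J(tau_x, tau_y),

a volume constraint (lambda_V = 5, V_T = 25 sites ~ one cell of diameter
d0 = 2 sqrt(V_T/pi) = 5.64 sites) plus contact energies over unordered
Moore-neighbor site pairs belonging to different cells (J values per the
published table: NC-NC 3, NC-medium 5, placode-medium 5, placode-placode
10, NC-placode 20 — the two tissues de-wet from each other). Neighbors
outside the closed lattice contribute no bond. Attempts that would remove a
cell's last site are rejected; there is no division or death, and cells may
transiently fragment (no connectivity constraint is imposed).

`W` is the work bias with three terms:

* **Extension-only chemotaxis** — applied only when a cell extends into a
  medium site: `sum_s lambda_s [c_s(target) - c_s(source)]` with the NC
  weights lambda_A = 1 (co-attraction), lambda_S* = 150 (Sdf1) and
  lambda_I = -100 (inhibitor repulsion). Placodes do not chemotax. No
  chemotaxis acts at cell-cell contacts or on retractions.
* **Persistent-adhesion springs** — cells in contact link with probability
  0.1 per MCS; a link breaks when lattice contact is lost, and otherwise
  with probability (|r_ij| - d0)/100 (clamped to [0, 1]). A linked pair
  contributes a Hookean restoring force of strength lambda_M (pair-type
  resolved, default 5; the NC-NC entry is the adhesion-perturbation axis,
  0 and 2 being the published low/high endpoints).
* **Polarized motility** — `lambda_P (dr . p-hat)` with lambda_P = 6 (NC)
  and 12 (placodes) and p-hat the unit polarity vector.

The displacement `dr` entering the spring and polarity terms is the copy
displacement vector (source site to target site) for both cells affected by
the copy; for a retraction the losing cell recoils along the unit vector
from the removed site toward its centroid. This lattice-scale convention is
a deliberate model choice: with `dr` read instead as the attempt-induced
centroid displacement (magnitude 1/V ~ 0.04), the motility and spring
weights would be two orders of magnitude below every other term of W - dH
and neither the placodal "run" nor any adhesion dependence of stream shape
could occur.

**Temperature.** The acceptance rule carries a Boltzmann temperature
T = 2.5. With the published contact energies (3-20 per Moore bond) and
volume stiffness, typical interface moves cost dH ~ 10-40, so at T = 1 the
tissue is frozen (measured acceptance ~1%, no placode motion, no invasion
over a full run). T is one of the engine constants the model definition
leaves open; it was calibrated once against the control-scenario phenotype
(ventral invasion within 3600 MCS and per-MCS cell speeds of order 0.1-0.2
sites/MCS) and then frozen.

## Polarity, CIL, EMT

Every cell carries a polarity vector updated once per MCS:

    p(t+1) = (1 - dP) p(t) + dr(t),

where `dr(t)` is the centroid displacement over the last MCS and the decay
dP depends on type and contact status (NC: 0.3 free / 0.08 in contact;
placodes: 0.5 / 0.1) — NC are the more persistent migrators.

Contact inhibition of locomotion (CIL): when two cells come into (new)
8-neighborhood contact and at least one is NC, each participant
independently enters CIL state with its type's probability p(CIL)
(placode-placode contacts never trigger). While in CIL state the polarity
update subtracts `lambda_CIL = 0.5` times the normalized sum of vectors
toward all current contact partners, repolarizing the cell away from its
contacts; the state clears when no triggering contact remains. The
probability is drawn once per new contact event, not re-drawn during
sustained contact, and the densely packed initial tissue does not count its
pre-existing adjacency as new contacts (otherwise a synchronized CIL burst
at MCS 1 recoils both tissues at once and the inhibitor seals the gap
permanently). p(CIL) is not published; the defaults are 1.0 for placodes
(the placodal-CIL sweep lowers this axis, so the control must sit high) and
0.3 for NC (calibrated: at 1.0 the sustained mutual repulsion inside the
packed NC population outweighs co-attraction and disperses it).

EMT: the dorsal edge continuously produces new NC cells. Whenever an
all-medium rectangle of 5 x 3 sites (one cell wide, half a cell high) is
found in the top strip, a new NC cell is inserted there with a fresh label,
zero polarity and no links; it relaxes toward V_T under the volume
constraint. Insertion is deterministic, scanning left to right.

Per-MCS update order (fixed for reproducibility): copy attempts ->
contacts -> links -> CIL -> polarity -> fields -> EMT -> clock.

## Reaction-diffusion fields

Three substances live on the cell lattice extended by a 100-site halo on
every side (open space around the tissue; cells never enter it):

| field | secreted by | D [su^2/MCS] | decay [1/MCS] | range sqrt(D/delta) |
|---|---|---|---|---|
| A, co-attractant (C3a-like) | NC, rate 5 | 8 | 0.006 | 36.5 su |
| S, Sdf1 | placodes, rate 20 | 8 | 0.006 | 36.5 su |
| I, inhibitor | placodes, rate 0.7 | 0.005 | 0.0006 | 2.9 su (half a cell) |

S is additionally taken up by NC sites (rate U_S = 20, proportional to the
local concentration so it can never overdraw; the uptake rate is not
published and matching the secretion scale makes NC strong local sinks,
which is what sharpens the Sdf1 gradient at the invasion front).

Secretion is logistic toward a per-substance carrying capacity K:
`S_i (1 - c/K_i)` at secreting sites. The published description uses plain
rates with no concentration scale (fields are in arbitrary units); with
unbounded accumulation the steady concentrations are of order S/delta ~ 1e3
and the chemotaxis weights (150, -100) then dwarf every other term of the
acceptance rule by two to three orders of magnitude — verified to abolish
invasion entirely (the inhibitor deposited at the initial interface forms a
permanent wall). The capacities are therefore part of the model: K_S = 1
and K_I = 1 set the Sdf1 attraction and the inhibitor wall to the scale of
the contact energies, and K_A = 400 sets co-attraction strong enough to
hold the NC population together against CIL repolarization. K_A is the
most delicate of the three: much below ~400 the NC population disperses
into fragments; much above ~600 co-attraction both collapses the streams
into a single mass and lets NC invade open space even with Sdf1 chemotaxis
removed (they climb their own co-attractant halo), destroying the
chemotaxis-knockout phenotype. The capacities were calibrated once against
the control and knockout phenotypes and frozen; the chemokine saturation
they introduce also reproduces the observed leveling-off of mean Sdf1
toward the end of the run.

Numerics: explicit forward-Euler substeps with a 5-point Laplacian on unit
spacing and zero-flux outer boundary. `field_substeps_per_MCS` (default 40)
applies to the stiffest substance (D = 8 -> D dt = 0.2 < 0.25); substances
with smaller D take proportionally fewer substeps under the same bound (the
inhibitor takes 1). The secretion/uptake terms are integrated
semi-implicitly because their rates (20/MCS) exceed the explicit reaction
stability bound at dt = 1/40 — treated explicitly they produce a
checkerboard instability that drives concentrations above the carrying
capacity. Decay stays explicit (so a uniform field decays by exactly
(1 - delta/n)^n per MCS). Solutions converge first-order under substep
refinement; concentrations are clamped at zero as a numerical guard and are
bounded by K by construction.

## Initial condition and units

Cells start as 5 x 5 patches spanning the lattice width (a partial
rightmost column is truncated): two patch rows of NC at the dorsal edge
(72 cells at default width), thirteen rows of placodes beneath (468 cells),
and a 20-site ventral strip of medium. All fields start at zero, polarities
zero, no links, no CIL. One RNG stream per simulation drives every
stochastic draw in a fixed, documented order, so runs are bit-reproducible
per seed. Width sweeps scale the lattice width only; the number of cell
rows — hence the linear cell density along the AP axis — is fixed.

Calibration: 1 lattice site = 3.5 um, 1 MCS = 10 s. Hence d0 ~ 17 um
(cell diameter), 3600 MCS = 10 h, and 0.1 sites/MCS = 2.1 um/min.

## Quantification

Streams are measured with the NC density probability function rho(r): for
every offset r, the occupancy at R + r averaged over all NC-occupied
reference sites R (offsets leaving the lattice are excluded from numerator
and count). rho is computed exactly by FFT cross-correlation and verified
against a brute-force double loop in the tests. Stream width W and length L
are the distances between the first 0.5-crossings (linearly interpolated)
of the axis profiles of rho through the origin along the AP and DV axes; a
profile that never falls below 0.5 yields a NaN sentinel (the no-stream /
full-band outcome), which sweeps tally as a no-stream fraction rather than
average. Ensembles pool numerators and counts (count-weighted) across
replicates. Note that the estimator is exactly symmetric in its pair counts
but not in rho itself near the lattice boundary, where the reference set is
truncated; the dorsal NC band sits at the boundary, so profiles toward the
dorsal edge are conditioned on an interior subset.

Stream counting automates the published by-eye procedure: connected runs of
NC occupancy along the horizontal line at half placodal-region depth below
the initial interface, merging runs separated by fewer than 2 medium sites.

Cell speed is the mean per-MCS centroid displacement magnitude. This
includes the diffusive boundary-churn of the Potts dynamics on top of
directed migration; over 30-MCS windows (the scale of in-vivo tracking
intervals) the measured NC speed is roughly 0.05 sites/MCS while per MCS it
is ~0.19.

## Scale of the shipped checks

The test suite and the acceptance script run control ensembles of 3
replicates at full spatial and temporal scale (180 x 95, 3600 MCS), versus
20 replicates in the published study; perturbation scenarios (chemotaxis
knockout, placodal CIL knockout, adhesion endpoints, half-width) run as
single runs or pairs at 2400 MCS, by which time invasion and stream
segmentation are developed. Replicate-to-replicate spread of W at this
ensemble size is ~5-10 sites, so three-seed means carry SEMs of ~3-6
sites. The full width sweep (>= 4 widths x >= 10 replicates) and the
placodal-CIL sweep reproduce the published relationships only at overnight
scale; desk-scale smoke versions (two widths; p(CIL) 0.3 vs 1.0) stand in
for them in the suite.

## What the simulations do and do not show

The simulator reproduces the qualitative core of the published model:
ventral invasion of the placodal region requires Sdf1 chemotaxis; removing
placodal CIL yields a uniform broad-front invasion; NC-NC adhesion widens
streams; the chemokine saturates while the inhibitor keeps rising; and the
invading NC organize into a small number of streams whose width is of the
published order. Quantitatively, the frozen calibration gives ensemble
stream widths of ~25-36 sites (published: 36 +- 3) but stream lengths of
only ~20-45 sites (published: 79 +- 5) — in this implementation the
dorsal-to-ventral flux of NC through the stream roots is too low to keep
streams dense over their full depth, and the length correlation decays
after ~2400 MCS instead of plateauing. The per-MCS speed measure (~0.19
sites/MCS) sits above the published 0.1, and the late-time rise of the
mean inhibitor level is marginal rather than clearly positive. Several constants of the published
model are unrecoverable from its description (temperature, concentration
scales, p(CIL), the dr convention in W); the calibration choices above are
the package's best single reading, and all of them are exposed as ordinary
parameters so other readings can be explored directly.

These are simulations of an idealized 2D tissue: no mesoderm or epidermis,
no cell division or death, a single combined inhibitor with purely
pericellular range, and a closed AP boundary. Passing tests demonstrate
internal correctness (energies, fields, measures, reproducibility) and the
emergent behaviors above at the stated scales — not quantitative agreement
with embryonic measurements beyond the published calibration.
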