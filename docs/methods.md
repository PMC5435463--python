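# Methods

## Lattice geometry and conventions

Retinotopic medulla columns are addressed by integer axial coordinates
`(q, r)` with the Home column at the origin. The Cartesian embedding is
pointy-top with `(1,0) → (1,0)` and `(0,1) → (1/2, √3/2)`, so every pair of
adjacent columns is exactly 1.0 apart: one *ommatidial unit*, the unit of
all subfield centres and offsets. The six Home neighbours carry the
cosmetic labels A–F counter-clockwise from `(1,0)`; algorithms only ever
use coordinates. The orientation of the lattice relative to the animal's
body axes (which lattice direction is "front-to-back") is not a measurable
of these analyses; it is a configuration. The package convention is:

* subtype **a** dendritic arbour extends along +x, **b** along −x,
  **c** along +y, **d** along −y;
* T4 dendrites extend **opposite** to the preferred direction (PD points
  from the dendritic tips toward the base), so the PD of subtype a is −x,
  of b +x, of c −y, of d +y.

The tips-opposite-PD geometry is forced by two facts the package keeps
consistent: presynaptic T4s contact same-subtype T4s at their dendritic
tips and sit retinotopically opposite the postsynaptic PD, and a
Barlow-Levick detector prefers motion from its excitatory (shaft) toward
its delayed inhibitory (base) field centre.

## Counting convention

One synaptic input = one postsynaptic density (PSD) = one synapse-table
row. Fly synapses are polyadic: one presynaptic T-bar contacts several
PSDs, so a `tbar_id` may repeat across rows; T-bar counts are a derived
quantity. Connection strength is the PSD count of an ordered (pre, post)
cell pair. Strength bins are <10 (weak), 10–20 inclusive (medium), >20
(strong): the printed ranges "<10" and ">20" force both boundary counts
into the middle bin. `exclude_weak` (default threshold 2) removes
single-synapse pairs before per-column and subfield analyses; input
fractions can be computed before or after that exclusion (both orders are
supported because the original tabulations do not fix one).

CT1, a single wide-field cell with strikingly columnar terminal arbours, is
modelled as per-column terminal units, each a record with its own home
column and a shared parent id — the unit at which its inputs behave like a
unicolumnar cell's.

## Subfield centres and the completeness adjustment

The anatomical subfield centre of input type T for one T4 is the synapse-
count-weighted centre of mass of the presynaptic cells' home columns on
the ideal lattice, `c = Σ wᵢxᵢ / Σ wᵢ`; offsets are reported relative to
the Mi1 centre of the same T4. Degenerate inputs (no synapses, all-zero
weights) raise, never silently return the origin.

Multicolumnar Tm3 (and TmY15) cells have no home column. A per-cell field
centre is instead derived from the cell's L1 inputs — L1 is strictly one
cell per column on the regular grid — weighted by L1 synapse counts. The
T4-level Tm3 centre is then the Tm3→T4-count-weighted mean of those
per-cell centres, and likewise for Mi1 when the two are compared on equal
footing.

Partial reconstruction biases this estimate: a cell extending beyond the
imaged volume loses synapse count, hence weight. The *adjusted* estimator
divides each cell's weight by its completeness (retained / true PSD
fraction). This inverse-completeness reweighting is the simplest
correction consistent with the available information, and it is exactly
unbiased under uniform synapse loss (see below); the output metadata flags
which mode produced each offset. Completeness itself is ground truth for
synthetic cells and a user-supplied column for real data — no estimation
procedure for it is implemented.

No statistics across T4s are computed for these offsets: with one fully
contained T4 per subtype per column there is nothing to average.

## Dendrite maps and segregation

Synapses are snapped to the nearest skeleton node (KD-tree, Euclidean);
anything farther than the snap radius (default 2 µm) is flagged unmapped
and reported, never dropped. A synapse's dendritic position is the path
distance from the trunk — the SWC root; synthetic skeletons are rooted
there by construction and real inputs must be pre-rooted — normalized by
the arbour's maximum path distance. Path distance (not Euclidean proximity
to the trunk) is the criterion; this is a documented choice, not a given.
Regions partition [0,1] into base [0,⅓), shaft [⅓,⅔), tip [⅔,1]; the
thresholds are configurable because the underlying tip/shaft/base language
is qualitative.

Segregation of two input types is the difference of mean normalized
positions (type B minus type A, in [−1,1]) with a two-sided label-
permutation p-value (≥1000 permutations, seeded, add-one corrected — hence
slightly conservative). A permutation test was chosen because the
positional clustering it quantifies was originally reported visually,
without a statistic.

T4 subtype is classified from the arbour orientation (mean displacement
from trunk to nodes) into ±45° sectors around the four cardinal axes
(a=+x, b=−x, c=+y, d=−y); an angle exactly on a boundary breaks the tie
toward the earlier subtype letter. The selectivity audit counts reciprocal
T4-T4 contacts independently in each direction.

## Motion detector models

Both models take two channels with offset fields of view, channel 1
carrying a first-order exponential low-pass `LP` (unit DC gain, time
constant τ):

* HR: `R = ⟨LP(s₁)·s₂ − s₁·LP(s₂)⟩` — exactly antisymmetric under channel
  swap, zero for static scenes.
* BL: `R = ⟨max(s₂ − g·LP(s₁), 0)⟩` with inhibitory gain g (default 1) —
  half-wave-rectified subtraction; no equation is canonical, this is the
  minimal one.

Responses are time-averaged after discarding one filter time constant of
transient. Stimuli are ON edges or drifting sinusoids in lattice
coordinates; the edge lead-in and duration are sized so the stimulus fully
crosses both channels at every speed and direction.

τ defaults to 150 ms and is config-exposed, not fitted: the measured
latency difference between the candidate excitatory channels (~15 ms) is
too small to explain the ~1 Hz temporal-frequency optimum, so no
biophysical delay is asserted. Reproducing that optimum quantitatively is
out of scope; only qualitative direction preference and DSI are evaluated.

`circuit_from_anatomy` builds the BL candidate: non-delayed excitation at
the mean of the '+' subfield centres (Mi1/Tm3, shaft), delayed inhibition
at the mean of the '−' centres (Mi4/C3/CT1, base). Predicted PD is the
direction from the excitatory toward the inhibitory centre. Mi9
(glutamatergic) has a deliberately undetermined sign: `transmitter_signs()`
omits it unless a sign is passed, both signs are runnable, and the default
detector does not include it.

## The synthetic generator

`make_circuit` emulates the features the analyses rest on, with every
planted quantity recorded exactly as ground truth:

* **Lattice**: hex disc, radius 1 (7 columns) by default.
* **Input composition**: per-type fractions roughly matching the measured
  composition (Mi1 0.35, Tm3 0.16, Mi9 0.13, Mi4 0.06, C3 0.04, CT1 0.08,
  TmY15 0.07, T4 0.06, Mi10 0.006, unidentified 0.044), 300 inputs per T4.
  Generator defaults, never assertions about real data.
* **Column weight maps**: symmetric ring mass plus a directed mass
  realizing an exact planted centroid shift along the arbour axis (Mi1
  +0.35, Mi9 +0.70, base types 0). ±x shifts use the axis column; ±y
  shifts split mass over the two flanking 60° neighbours.
* **Tm3 pool**: two multicolumnar cells per column at mirrored lateral
  offsets; each cell's field centre is defined by Gaussian-kernel L1
  weights over nearby columns (120 L1 inputs realized per cell). A T4
  draws its Tm3 inputs from the 8 nearest pool cells with kernel weights
  *re-centred by constrained least squares* so the planted T4-level Tm3
  centre equals its target exactly (default: the Mi1 centre, i.e. zero
  planted Tm3−Mi1 offset) — without this the discrete pool would make the
  planted value only approximate.
* **Dendritic placement**: per-type Beta profiles over normalized path
  position — Mi9 Beta(5, 1.5) tip-biased, Mi4/C3/CT1 Beta(1.5, 5)
  base-biased, Mi1/Tm3 Beta(2, 2) shaft, T4→T4 Beta(5, 1.5) tips. The
  qualitative pattern is given; the distributions are free parameters
  exposed in the template.
* **Skeletons**: four branches fanning ±15° around the arbour axis,
  ~2.1–2.6 column spacings long, 1.2 µm node spacing, column spacing
  8 µm; trunk (root) at the column centre.
* **Polyadic grouping**: per presynaptic cell, T-bar sizes are
  1 + Poisson(5) PSDs (mean 6, the global PSD:T-bar ratio of the
  reconstruction this emulates).
* **T4→T4 partners**: same-subtype T4s in the tip-side column(s) —
  retinotopically opposite the postsynaptic PD.
* **Randomness**: one global seed; per-cell streams derived by stable
  hashing of (seed, cell id), so datasets are byte-identical across runs
  and insensitive to iteration order.
* **Truncation**: `truncate` clips synapses and skeleton subtrees to a
  box; `thin_cells` retains each PSD of a listed cell independently with
  that cell's probability (the *uniform-truncation model*, under which the
  per-cell centre estimate stays unbiased and only the weight is lost —
  exactly the regime where inverse-completeness reweighting is unbiased).
  `completeness_ladder` assigns the graded retention fractions
  (1.0, 1.0, 0.94, 0.85, 0.72, 0.61, 0.49, 0.42) across a set of cells
  ordered by field-centre x, emulating incompleteness graded toward a
  volume edge. Realized completeness (retained/original) is recorded, not
  the nominal fraction.

What the generator does **not** emulate: imaging noise, segmentation or
proofreading errors, realistic 3-D neurite geometry beyond a fanned tree,
eye-map distortions, and any correlation between a synapse's dendritic
position and its column of origin. Passing tests therefore show that the
estimators recover what was planted under the stated statistical
structure — not that real EM data satisfy that structure.

## Simulation study sizes

The acceptance studies (`t4circuit.experiments`, also run by
`scripts/acceptance.py`) use these sizes, chosen so Monte-Carlo error is
small against each effect while a full run stays well under a minute:

* centroid oracle: 100 random integer-count instances on columns within
  ring 3, compared to the unit-mass mean at 1e-9;
* offset recovery: planted Mi9−Mi1 offsets of 0.5 and 1.0 ommatidia
  (split symmetrically about the home column), 500 synapses per type,
  50 replicates per offset;
* completeness adjustment: 100 replicates; 1200 inputs per T4 and a
  selection σ of 1.0 so both estimators' count noise (which they share)
  sits well below the raw estimator's truncation bias;
* segregation: 100 seeds at 50 synapses per type (detection), 500 draws
  of identical Beta(2,2) samples at n=50 (null calibration at the
  statistic level), 1000 permutations throughout;
* detectors: one default dataset per check; DSI across speeds 0.5, 1, 2,
  5 columns/s (a decade), τ = 150 ms, dt = 1 ms.

## Known limitations

* The completeness adjustment corrects weights only; under *geometric*
  truncation the per-cell centres themselves are biased toward the
  retained region, and no correction for that is attempted (the box
  `truncate` exists to produce exactly this harder regime).
* Real SWC inputs must already be rooted at the trunk; no trunk-detection
  heuristic is provided.
* Tm3/TmY15 field centres require L1 connectivity in the dataset; without
  it the multicolumnar analyses are unavailable by design.
* The detector simulations are means over deterministic stimuli — no
  physiological noise, adaptation, or receptor dynamics.
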