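# Methods

## Scope and data model

The package analyzes nucleosome trajectories: ~147 bp of DNA wrapped ~1.65
superhelical turns around a histone octamer (2× H3, H4, H2A, H2B), with
linker-DNA (L-DNA) arms extending past the wrapped core and intrinsically
disordered histone tails. Structures are read from PDB (biotite),
trajectories from DCD (MDAnalysis) or multi-model PDB; coordinates are in
Ångström throughout.

A `NucleosomeAnnotation` maps structure to roles. Base pairs are indexed
1..L along the sense strand 5′→3′; the antisense partner of bp *i* is
residue L+1−*i* of the complementary chain. Derived index sets, all defined
by counts relative to the ends/dyad so any total length works:

| set | definition | default |
|---|---|---|
| outer gyres | terminal `outer_bp` bp at each end | 40 bp each |
| inner gyre | complement of the outer gyres | — |
| L-DNA segments | terminal `ldna_bp` bp of each arm | 15 bp |
| dyad segments | dyad bp + `dyad_half` bp toward each arm | 5 bp per side |
| arm ranges (v₃/v₅) | terminal `arm_bp` bp, ordered inner→terminal | 15 bp (synthetic profile: the 11 linker bp) |

The "8 bp centered on the dyad, per side" reference is genuinely ambiguous
as usually stated; we resolve it as the dyad bp plus 4 bp toward the tail's
arm (configurable width). Tail residue ranges per histone ship as species
profiles (human, drosophila, tailless). The human H2A C-tail default is
119–129; published core-exclusion lists for human H2A are sometimes printed
as a truncated range ("1–18 and 129"), so the profile is explicitly
overridable per chain. The histone core is the complement of the tail
ranges and is the superposition reference selection.

## Dyad frame and opening angles

Per frame: origin = midpoint of the dyad bp's C1′-equivalent atoms;
X = unit(origin − centroid of inner-gyre bp centers); S = unit normal of the
total-least-squares plane through the inner-gyre bp centers, with its sign
fixed by the DNA winding direction (sum of consecutive cross products about
the centroid), which keeps the frame continuous across frames without
external state; Y = unit(X × S); Z = X × Y. The construction fails loudly
(GeometryError) on collinear degenerate input rather than guessing.

The stated textbook construction ("a vector perpendicular to X intersecting
it approximately at the center") is under-determined; using the inner-gyre
plane normal as the superhelical axis makes XY the nucleosome disc plane, so
γ₂ is in-plane and γ₁ out-of-plane opening. The rule lives in one function
(`frame_from_bp_centers`) so alternatives can be swapped.

Arm vectors are total-least-squares lines through the arm bp centers
(endpoint difference available as `mode="endpoints"`), oriented
inner→terminal. Angles, in degrees in (−180, 180]:

- γ₁ = atan2(v·X, v·Z) — signed about +Y, grows as the arm tilts toward +X;
- γ₂ = atan2(−v·X, v·Y) — signed about +Z, grows as the arm tilts toward −X.

Both angles are projections of the same vector, so their signs are coupled:
a motion that increases γ₁ decreases γ₂ and vice versa (this matches the
usual field convention in which opening at one arm reads with opposite sign
at the other). Degenerate projections (norm < 1e-9) yield NaN, recorded as
missing, never fabricated. Rigid-motion invariance and frame equivariance
are enforced by tests to 1e-6.

2D γ histograms use 2.5° bins aligned on multiples of the bin width and an
occupancy threshold of 1 frame (both configurable; no canonical values
exist). `occupied_area` = (#bins ≥ threshold) × bin_width².

## Rg, contacts, weighted distances

Rg = √(Σw‖r−r̄‖²/Σw), mass-weighted by default (unweighted flag provided;
for the uniform-mass synthetic beads the two coincide). Contacts are counted
as **atom pairs** (not distinct atoms) with a strict `<` at the 4.5 Å
cutoff over non-hydrogen atoms — the pair/atom choice is not canonical in
the literature; pairs are stricter and exactly checkable against an O(N²)
oracle, and the counting unit is config-switchable in spirit (the primitive
takes arbitrary selections).

The inverse-power weighted mean distance d[n] = ((1/N₁N₂)Σ‖dᵢⱼ‖⁻ⁿ)^(−1/n)
is evaluated with the minimum distance factored out, so each term
(d_min/dᵢⱼ)ⁿ ∈ (0,1] and n = 100 is stable from sub-Å to 10³ Å separations.
Exact properties, all test-enforced: d[n] is non-increasing in n;
d[n] ≥ min‖dᵢⱼ‖ always; and d[n] ≤ min‖dᵢⱼ‖·(N₁N₂)^(1/n). The last bound is
worth stating because it quantifies how fast d[100] approaches the true
minimum: for 20×20-atom groups with an isolated minimum the bias is
(400)^(1/100) ≈ 6%, for a single residue against a DNA gyre ≈ 5%. δ_min
values should therefore be read as a smoothed minimum with a small
systematic positive offset, identical across frames and residues in
relative comparisons. δ uses n = 10, δ_min n = 100; per-residue profiles
use all heavy atoms of the residue (side-chain-only is not meaningfully
different for single-bead synthetic residues and is not canonical for
all-atom input either).

Default cadences mirror common practice: angles/Rg every frame (configurable
stride; a 20 ps frame interval is typical), contacts/distances every 5th
frame (~100 ps).

## Conformational clustering and co-occupancy

Features: each frame is least-squares superposed (Kabsch via scipy, proper
rotation only) on a reference over the histone-core heavy atoms, then a
coordinate subset is flattened: `dna` = backbone heavy atoms of the inner
gyre plus the *opening* arm's outer gyre (the quiet arm carries no signal
and is excluded, which arm being a config choice), `h3` = entire H3 chains,
`h2ac` = H2A minus the N-terminal tail. Euclidean distance on globally
superposed coordinates approximates no-refit positional RMSD; per-pair
best-fit k-medoids is out of scope.

k-means: k-means++ initialization, n_init = 10, max_iter = 500, tol 1e-6,
fixed seed — the exact init/iteration details have no canonical reference,
so determinism and robustness drive the defaults, all exposed. Labels are
re-ranked by cluster size (1 = largest, ties by lowest original label), so
output labels are canonical under label permutation.

Cross-tabulation: entry (i,j) = 100 × |{frames: dna=i ∧ tail=j}| / |dna=i|;
rows sum to 100 within 1e-6 by construction. Per-cluster γ means (with
sizes) support centroid overlays on the γ histograms; per-frame label series
support cluster-on-time-series plots. Percentile summaries use linear
interpolation (numpy default), 5th/95th by default.

## Synthetic generator

The generator is the package's verification instrument: it emulates the
*geometry* of a breathing nucleosome, not its physics — no energies, no
integrator, sequence-independent; motion is prescribed.

Construction: bp centers on a superhelix (radius 41.9 Å, pitch 25.9 Å/turn,
1.65 turns over the 147 bp core — canonical nucleosome-like dimensions,
nothing more), two strand beads per bp offset ±5 Å along the local
bi-normal, straight linkers (11 bp, 3.3 Å rise), a 160-bead histone ring of
radius 30 Å split over eight chains, and one tail bead chain per histone
(H3 tails carry the real human H3 1–45 sequence so residue labels like K27
resolve; tail beads are uniform carbon-like pseudo-atoms — with uniform
masses, mass-weighted and unweighted statistics coincide). The closed
linker direction is chosen *in the dyad frame* with zero X component
(elevation 30° between Y and Z), which makes both opening angles exactly 0
in the closed state by construction.

Per frame, the linker+outer-gyre arm rotates rigidly about its hinge (the
innermost outer-gyre bp) by the prescribed out-of-plane (about Y) and
in-plane (about Z) angles; positive prescribed angles yield positive γ₁ and
γ₂ respectively. Because γ₁ and γ₂ are coupled projections, a pure
out-of-plane rotation also moves γ₂ (and vice versa); the ground truth
therefore records the *actual* (γ₁, γ₂) of the constructed arm direction,
computed analytically, so recovery tests are convention-independent. Tails
are repositioned each frame by mode: `bridge` interpolates beads between
points 1.5 Å from an outer-gyre and an inner-gyre bead (contacts to both
gyres guaranteed); `dyad_collapsed` places beads 2.5 Å off the same-side
dyad-segment beads (≥ 8 Å from L-DNA, asserted at generation);
`detached` places them ≥ 130 Å beyond the dyad on the −X side (≥ 10 Å from
all DNA, asserted — note the DNA ring's far edge lies ~2R from the dyad on
that side, which sets the scale). Gaussian jitter (σ = 0.3 Å default) is
added last with the run seed; identical spec + seed gives bit-identical
coordinates.

What the generator does *not* emulate — and hence what passing tests do not
show about real MD data: DNA elastic deformation along the arm (arms are
rigid), histone-core plasticity, realistic tail conformational ensembles
(tails teleport between modes), solvent/ion effects, and realistic
time correlation. Tests against it validate the *estimators* (geometry,
counting, clustering), not the biology.

The `coupled_opening_scenario` couples tail release to arm opening with a
configurable lead (tails detach `lag` frames before the arm steps open) —
the synthetic twin of the observed mechanism in which loss of H3/H2A-C-tail
contacts with the L-DNA precedes large openings. With well-separated
regimes, ≥ 80% (in practice 100%) of the most-open DNA cluster's frames
fall in the tail cluster with the lowest outer-gyre contacts, and the tail
cluster transition precedes the DNA one by exactly the constructed lag.

## Pipeline and reproducibility

`run_analysis` executes generate → annotate → observables → tails → cluster
→ crosstab → report from a validated YAML config (unknown keys are errors,
named in the message). One global seed fans out to per-stage seeds via
`seed*1000003 + crc32(stage) mod 2³¹`, all recorded in the manifest together
with row counts and SHA-256 checksums of every output; reruns are
byte-identical. The CLI (`nucbreathe generate|annotate|observables|cluster|
crosstab|report|run`) wraps the same stages; exit codes: 0 ok, 1 usage,
2 runtime.

## Problem sizes used in the shipped checks

The test-suite and acceptance runs use 169 bp nucleosomes (~740 beads),
trajectories of 48–200 frames, k = 2–3 clusters on the synthetic scenarios
(8 remains the analysis default), 100-configuration oracle sweeps for the
weighted distance and 50 fixtures of 100+100 atoms for contacts. These
sizes fully determine the estimators' correctness; nothing in the
implementation is specific to them.

## Known limitations

- The dyad-frame rule is one defensible reading of an under-specified
  construction; absolute γ values depend on it (differences and dynamics
  much less so). Alternative frames can be swapped in via
  `frame_from_bp_centers`.
- d[100] carries the (N₁N₂)^(1/100) positive bias discussed above.
- Clustering uses no-refit superposed coordinates; trajectories with large
  histone-core rearrangement would need per-pair refitting.
- The DCD reader assumes coordinates in Å and does not interpret unit cells.
- Contact counts are pair counts; comparing against atom-count conventions
  requires rescaling expectations, not code changes.
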