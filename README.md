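# nucbreathe

Analysis of **nucleosome breathing** — the spontaneous, transient detachment
of the DNA ends (linker DNA, "L-DNA") from the histone core — in molecular
dynamics trajectories, together with the histone-tail/DNA interactions that
gate it. The package is aimed at people running atomistic or coarse-grained
nucleosome simulations who want reproducible, scriptable versions of the
standard breathing observables and of the clustering analysis that links DNA
opening to histone-tail release.

## What it computes

Given a trajectory (DCD or multi-model PDB with a PDB topology) and a
nucleosome annotation (which chains are DNA, which histone residues are
disordered tails, where the dyad is):

- **Dyad coordinate frame.** Origin on the central base pair; *X* along the
  dyad axis (inner-gyre DNA centroid → dyad), the superhelical axis from the
  best-fit plane of the inner-gyre base-pair centers, *Y* = X̂ × Ŝ,
  *Z* = X̂ × Ŷ. The *XY* plane is the nucleosome disc plane.
- **Opening angles.** For each L-DNA arm vector *v* (total-least-squares line
  through the arm base-pair centers), γ₁ = ∠(proj_XZ v, Z) measures
  out-of-plane opening and γ₂ = ∠(proj_XY v, Y) in-plane opening, as signed
  angles. 2D (γ₁, γ₂) histograms report the occupied area (deg²) and the most
  populated bin.
- **Radius of gyration** of the DNA (mass-weighted by default): larger Rg =
  less compact, more open nucleosome.
- **Contacts** N_C: pairs of non-hydrogen atoms closer than 4.5 Å, split by
  DNA gyre (outer = terminal 40 bp at each end, inner = the rest).
- **Weighted mean distances** d[n] = ((1/N₁N₂) Σᵢⱼ ‖dᵢⱼ‖⁻ⁿ)^(−1/n): with
  n = 10 a mean-like tail-to-DNA distance (δ), with n = 100 a smooth
  minimal distance (δ_min), evaluated with the minimum factored out so n=100
  never overflows. Per-residue δ_min profiles cover the epigenetically
  modified H3-tail residues (tip R2/K4 … anchor K36/K37/R40/R42).
- **Conformational clustering.** Frames are superposed on the histone core,
  then k-means (k = 8 by default, size-ranked labels) partitions the DNA,
  H3, and H2A-C-tail coordinate subsets separately; cross-tabulation gives,
  for each DNA cluster, the percentage of its frames in each tail cluster —
  the co-occupancy matrix connecting DNA opening to tail configuration.
- **5–95 percentile summaries** of every observable series.

A **synthetic nucleosome generator** builds an idealized 147 bp superhelix
with two 11 bp straight linker arms, a histone-core bead ring, and
per-histone tail bead chains whose modes (bridging both gyres / collapsed on
the dyad / detached / absent) and per-frame arm opening angles are
prescribed, with the exact ground truth returned. Every analysis stage is
validated against it.

## Worked example

Prescribe a 30° out-of-plane step on the 3′ arm at frame 100 and recover it:

```python
import numpy as np, nucbreathe as nb

n = 200
step = np.zeros((n, 2)); step[100:, 0] = 30.0      # (out-of-plane, in-plane)
spec = nb.SyntheticSpec(seed=1)
traj, truth = nb.make_breathing_trajectory(spec, {"3p": step}, seed=1)
nuc = nb.annotate_synthetic(traj.topology, spec)
obs = nb.breathing_series(traj, nuc)
print(obs.loc[[0, 99, 100, 199], ["frame", "gamma1_3p", "gamma2_3p", "rg"]].round(2))
```

```
 frame  gamma1_3p  gamma2_3p    rg
     0      -0.33       0.56 44.93
    99       0.73      -1.25 44.93
   100      30.26     -41.03 47.61
   199      30.27     -41.07 47.56
```

γ₁ jumps from ≈0° to ≈30° exactly at frame 100 (the residual ±1° scatter is
the prescribed 0.3 Å coordinate jitter), and the DNA Rg rises from 44.9 Å to
47.6 Å as the arm leaves the wrapped conformation. γ₂ moves too because the
two angles are coupled projections of the same arm vector — out-of-plane
opening reads as in-plane closing, matching their opposite sign conventions.
Summaries in the Table-1 style of the field:

```python
row = nb.percentile_summary(obs["rg"], "rg")     # -> 44.92 - 47.59 A (5-95)
hist = nb.gamma_histogram2d(obs, "3p")           # occupied_area = 37.5 deg^2
```

The same stages run from the shell:

```bash
nucbreathe run --config demo.yml --out out/
```

with a YAML config selecting either a synthetic scenario or `input:
{topology, trajectory, profile}` files; outputs are deterministic CSV/JSON
plus a manifest with seeds and checksums.

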