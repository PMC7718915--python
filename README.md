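# laminmesh

Scale-free models of the nuclear lamin meshwork and the mechanics of single
lamin filaments under transverse point loads.

The nuclear lamina — the meshwork of lamin intermediate filaments lining
the inner nuclear membrane — protects the genome mechanically. Cryo-electron
tomograms show it is a *scale-free* network: the junction degree
distribution follows a power law P(k) ~ k^−λ with λ ≈ 5.6, a mean degree
⟨k⟩ ≈ 3.3, and a minor population of hubs of degree 5–17. AFM pushing on
single filaments in situ shows a characteristic force–extension (FE)
morphology: a low-force plateau (coiled-coil unfolding, F ≈ 0.3 nN),
strain stiffening (α-helix → β-sheet transition, κ ≈ 0.3 nN nm⁻¹), and
failure near 2–5 nN after engineering strains of ≈ 250%.

`laminmesh` implements the computational side of this picture for
structural biophysicists and network-mechanics researchers:

- **meshgen** — scale-free meshwork generation: preferential-attachment
  seed, Monte-Carlo degree rewiring toward P(k) ~ k^−λ on [3, 17],
  coordinate Monte Carlo to filament lengths of 12 ± 3 nm, and bead-spring
  discretization at 1 nm spacing.
- **forcefield** — the mesoscopic energy terms: a piecewise nonlinear bond
  tension law with Fermi–Dirac rupture smoothing (breaking distance
  3.6 nm), harmonic bending, cosine non-bonded repulsion, and a 9-3
  membrane-adhesion wall (20 mJ m⁻² at 1.5 nm).
- **simulator** — overdamped Langevin dynamics at 300 K: substrate
  relaxation, displacement-clamped pushing of a central filament normal to
  the plane, FE recording, permanent bond rupture, strain distributions,
  and a constant-force clamp mode.
- **mechanics** — AFM-style analysis: plateau force/stiffness/extent,
  high stiffness with an R² ≥ 0.93 gate, failure force, step units,
  hysteresis energy, toughness density, chord engineering strain,
  force-clamp step/lifetime segmentation.
- **topology** — skeleton polylines → junction graph (1.3 nm crossover
  criterion), degree statistics, truncated discrete-MLE power-law exponent,
  hub census, small-world path-length scaling.
- **workbench** — the topology sweep (strength/toughness vs λ with a Welch
  t-test on the λ = 0.5 vs 5.6 contrast) and all synthetic fixtures.

## Worked example

```python
import laminmesh as lm

# 1. generate a cryo-ET-matched meshwork model
cfg  = lm.MeshConfig()                    # 500 nodes, 1e6 / 6e5 MC proposals
geom = lm.generate_mesh(5.6, cfg, seed=1)
print(geom.graph.n_edges, round(geom.edge_lengths().mean(), 2))

# 2. its topology
stats = lm.degree_stats(geom.graph)
fit   = lm.fit_power_law(geom.graph.degrees(), k_min=3, k_max=17)
print(round(stats.mean_degree, 3), stats.hub_count, round(fit.exponent, 2))

# 3. analyze a (noisy) force-extension curve
curve = lm.make_synthetic_fecurve(noise_sd=0.05, seed=0)
f = lm.extract_features(curve)
print(f.plateau_force, f.high_stiffness, f.failure_force)
```

prints (seed 1 meshwork, seed 0 curve):

```
844 12.0
3.376 38 5.54
0.298 0.299 2.46
```

i.e. the generated meshwork has 844 filaments of mean length 12.0 nm, mean
junction degree 3.376 with 38 hubs (k ≥ 5) and a fitted exponent of 5.54;
the extractor recovers the plateau at 0.298 nN, the stiffening slope at
0.299 nN nm⁻¹ and the failure force at 2.46 nN from a curve constructed
with 0.30 / 0.30 / 2.4 plus 0.05 nN noise. Derived quantities follow the
same conventions: `toughness_density(1e-16, 2, 54)` → 147.4 MJ m⁻³ and
`engineering_strain(54, 91)` → 251.6%.

The same pipeline is scriptable from the shell:

```sh
laminmesh generate --nodes 500 --lambda 5.6 --seed 1 -o mesh.json
laminmesh simulate --mesh mesh.json --max-d 100 --seed 7 -o run1/
laminmesh analyze-curve run1/fe.csv --report features.json
laminmesh sweep --lambdas 0.5,5.6 --profile desk -o sweep.json
```

The desk-profile sweep (20 replicates of 48-node meshworks per exponent)
reproduces the central mechanical result: filaments in the well-connected
λ = 5.6 meshwork are tougher and stronger than in the hub-dominated
λ = 0.5 meshwork, with the toughness contrast strongly significant.

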