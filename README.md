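# canopyconn

**2D vs 3D urban greenspace connectivity.** Flat optical maps of urban
vegetation (NDVI from red/near-infrared reflectance) merge grass, shrubs
and tree canopy into one green footprint. Organisms do not move through
that footprint — they move through the stratum they actually use, and a
hedgehog confined to ground vegetation experiences a very different
landscape than the NDVI map suggests. `canopyconn` quantifies this bias:
it stratifies a scene into grass / shrub / tree layers using a voxelized
canopy-cover grid (the kind derived from waveform lidar), computes
landscape-connectivity metrics per layer, and models functional
connectivity as a function of dispersal distance, including the
systematic overestimate a 2D-only analysis produces.

It is aimed at landscape ecologists and remote-sensing analysts working
with raster greenspace data. Because airborne lidar/hyperspectral
surveys are rarely shareable, the package ships a seeded synthetic-scene
generator with three urban-form archetypes so every stage is exercisable
and testable without external data.

## The model

**Stratification.** A pixel is vegetated when NDVI = (NIR − red)/(NIR +
red) ≥ 0.2. A voxel (1.5 m × 1.5 m × 0.5 m by default) is occupied when
its fractional vegetation cover is ≥ 1%. Each occupied voxel belongs to
one height band by its center height *h*: grass (*h* < 0.5 m), shrub
(0.5 ≤ *h* ≤ 4 m), tree (*h* > 4 m). Projecting each band to the ground
and intersecting with the NDVI mask yields per-stratum masks; a column
can carry several strata (grass understorey beneath a crown).

**Structural metrics.** With patch areas *aᵢⱼ* (connected components,
8-neighborhood by default) and total landscape area *A*:

- landscape proportion  Σ*aᵢⱼ*/*A*;
- small patch density — patches < 30 m² per hectare;
- largest patch index  100·max(*aᵢⱼ*)/*A* (%);
- **connectivity index (CI)**, the landscape division index

  CI = 1 − Σ (*aᵢⱼ*/*A*)²,

  the probability that two pixels drawn uniformly from the landscape do
  not lie in the same patch. Higher CI = lower connectivity.

**Functional connectivity.** Buffer each layer outward in 1 m
increments (Euclidean, between pixel centers) and recompute CI after
each step until the buffered layer covers the landscape. The resulting
CI-vs-distance curve reads as connectivity experienced by an organism
with that dispersal capacity; the distance where CI first drops below
0.15 marks "high connectivity" (> 85% chance two random pixels
connect). Since every stratum mask is a subset of the 2D footprint,
CI_stratum(d) ≥ CI_2D(d) at every distance — the 2D bias — and the
difference curve Δ CI(d) peaks at short dispersal distances.

## Worked example

```
python examples/structural_metrics.py
```

```
layer      cover  small/ha   LPI %      CI
green2d    0.251      4.34    1.97  0.9975
grass      0.160      0.00    1.16  0.9989
shrub      0.040      6.51    0.17  1.0000
tree       0.070      0.00    1.21  0.9995
```

On this terraced-town scene the flat 2D view covers 25% of the
landscape while no single stratum exceeds 16%; shrubs are the sparsest
and most fragmented layer (highest CI). The bias this induces at the
functional level:

```
python examples/two_d_bias.py
```

```
stratum   peak distance m  peak delta CI
grass                10.0          0.599
shrub                11.0          0.827
tree                 16.0          0.945
```

At a 16 m dispersal capacity the 2D map suggests a nearly connected
landscape while the tree stratum is still almost completely
disconnected (Δ CI ≈ 0.95). The other examples
(`generate_scene.py`, `functional_curves.py`) print realized stratum
covers and threshold dispersal distances.

A thin CLI wraps the same pipeline:

```
canopyconn run --archetype terraced --seed 3 --outdir out/
```

writing per-layer masks, metric and curve CSVs, plots and a JSON
summary.

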