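# Methods

## Scope and model

`canopyconn` analyses a vegetated raster scene along two routes that
must agree in the horizontal plane: an optical route (red/NIR
reflectance → NDVI → flat green-cover mask) and a volumetric route (a
3D fractional-cover voxel grid → occupied voxels → height bands →
per-stratum ground masks). All downstream analysis is binary raster
morphology and connected-component statistics; there is no vector
geometry, no CRS handling, and no organism-specific movement model
beyond an isotropic dispersal radius.

Coordinate convention, used everywhere: row-major grids, origin at the
top-left, the center of pixel (row, col) at ((col + 0.5), (row + 0.5))
· pixel_size. Voxel level k spans heights [k·dz, (k+1)·dz) above
ground; heights are above-ground (terrain normalization of real canopy
height data is out of scope).

## Thresholds and bands

| parameter | default | units | meaning |
|---|---|---|---|
| `ndvi_min` | 0.2 | – | pixel vegetated iff NDVI ≥ 0.2 (inclusive) |
| `cover_min` | 0.01 | fraction | voxel occupied iff cover ≥ 1% (inclusive) |
| `grass_max_h` | 0.5 | m | grass band: center height < 0.5 |
| `shrub_max_h` | 4.0 | m | shrub band: 0.5 ≤ center ≤ 4.0 (closed) |
| `neighborhood` | 8 | – | patch adjacency (queen's case); 4 available |
| `step_m` | 1.0 | m | buffer increment |
| `ci_threshold` | 0.15 | – | "high connectivity" CI cut-off (strict <) |
| small-patch cut | 30 | m² | strict <; density reported per hectare |

Band membership uses the voxel-**center** height. The literature
convention "between 0.5 and 4 m" does not fix the endpoints; the closed
shrub interval on center heights is unambiguous and assigns every voxel
to exactly one band. With 0.5 m voxels starting at ground level the
centers are 0.25, 0.75, …, so level 0 is grass, levels 1–7 shrub,
levels ≥ 8 tree.

Where NDVI and voxel grids differ in resolution, NDVI should be
resampled to the voxel grid by nearest-neighbour (preserving the binary
threshold semantics); the synthetic generator emits matched grids so
the package's tests never depend on resampling artifacts, and no
resampler is shipped.

A degenerate reflectance pixel with red = NIR = 0 gets NDVI 0.0 (below
threshold, i.e. non-vegetated) rather than NaN.

## Structural metrics

Patches are maximal connected components; labels are renumbered to
row-major first-pixel order so labelings are deterministic regardless
of the labeling algorithm. The landscape area A is the **full raster
extent** (vegetated + non-vegetated): the division index samples pixel
pairs "in the landscape", not in the vegetated subset. Consequences:

- CI = 1 − Σ(aᵢⱼ/A)² is exactly the probability that two pixels drawn
  uniformly with replacement from the whole raster do not share a
  patch (background pixels never share one). Empty landscape → CI = 1
  (the no-pair limit); a single all-covering patch → CI = 0.
- CI is monotone under mask growth: vegetating any background pixel
  grows or merges patches and (a₁+a₂)² ≥ a₁² + a₂², so CI can only
  drop. Hence M₁ ⊆ M₂ ⇒ CI(M₂) ≤ CI(M₁), which is the formal content
  of the 2D bias: the flat footprint is a superset of every stratum.

Small-patch density uses a strict < 30 m² cut and is reported per
hectare (the natural unit at garden scale; the source convention
leaves the denominator unit open).

## Functional connectivity

Buffering is an exact Euclidean dilation between pixel centers,
threshold inclusive (≤ d). It is computed once per layer via the
feature transform (`scipy.ndimage.distance_transform_edt` with index
output): nearest-source pixel offsets give *integer* squared pixel
distances, so the buffered mask at any distance is an exact threshold
of one precomputed distance field, with a 1 nm epsilon absorbing
floating-point noise at exact radii. Buffers expand isotropically over
all land cover — built barriers are intentionally ignored (a
barrier-aware mode is a non-goal), and buffered pixels count as patch
area in CI, which is what makes "fully vegetated" the natural
termination point.

The curve samples d = 0, 1, 2, … m regardless of pixel size (sub-pixel
steps may repeat identical masks; duplicates are retained so the
distance axis stays regular) and stops at the first d where the
buffered mask covers the landscape (CI exactly 0), or at a safeguard
maximum equal to the grid diagonal, in which case the curve is flagged
as not fully connected and a warning is emitted. CI at d = 0 equals
the structural CI. The threshold distance is the smallest *sampled*
distance with CI strictly below the cut-off, so it is quantized to the
step; an organism-level reading should treat it as an upper bound at
1 m granularity.

Bias curves subtract the 2D curve from a stratum curve pointwise; the
shorter (already fully connected) curve is zero-extended, which is
exact since post-full-cover CI is identically 0. Peak bias ties break
toward the smallest distance.

## Synthetic scenes

The generator emulates the two survey inputs for a town-like scene.
Vegetation is laid down as seeded random discs per stratum until the
target cover fraction is met ("blob dropping"); the `fragmentation`
knob (0–1) maps to the mean disc radius, from a few large blobs to
many small ones, and per-stratum radius factors make tree stands broad
(×1.5) and shrubs garden-scale (×0.6). Shrub and tree columns are
horizontally exclusive (a crown column is not simultaneously a shrub
column); grass overlaps freely, and one grass understorey patch is
always seeded beneath a tree stand when both layers are requested, so
the multi-stratum projection path is always exercised. Targets with
shrub + tree > 1 are rejected as impossible.

Realized covers stop at the first disc that reaches the target, with
late discs shrunk toward the remaining deficit; realized cover
overshoots by at most about one small-disc area and sits within 0.03
of the target on 512-px grids (tested). Voxel columns then realize the
strata: grass fills level 0 with cover ~U(0.2, 0.9); shrubs draw a top
height ~U(1, 4) m and fill shrub levels below it; trees draw a crown
top ~U(4.25, grid top) and fill tree-band levels below it, so crowns
never leak into the shrub band. Vegetated pixels draw NDVI ~U(0.4,
0.9) and others ~U(−0.2, 0.1); the red band is back-solved with NIR
pinned at 0.5, so the 0.2 threshold separates the populations with
margin while the NDVI arithmetic is still exercised end to end.
Buildings and roads exist only implicitly as NDVI < 0.2, zero-cover
columns — the connectivity analysis only consumes vegetation layers.

Three archetypes sketch contrasting urban forms (illustrative, not
calibrated to any real town — no quantitative urban-form data exists
to calibrate against):

| archetype | grass | shrub | tree | fragmentation |
|---|---|---|---|---|
| planned_green | 0.30 | 0.06 | 0.18 | 0.20 |
| medieval_clustered | 0.22 | 0.05 | 0.12 | 0.45 |
| terraced | 0.16 | 0.04 | 0.07 | 0.70 |

One `numpy.random.default_rng(seed)` stream per scene makes output
bit-reproducible.

**What the generator does not emulate:** radiometric realism, sensor
noise, waveform artifacts, terrain, building footprints as geometry,
road networks with spatial autocorrelation, or seasonal phenology.
Passing tests therefore demonstrate the *mathematical* properties of
the metrics and the generic 2D-vs-3D bias mechanism, not the absolute
connectivity values of any real town; real-survey numbers additionally
depend on the survey's resolution, resampling and adjacency choices.

## Verification strategy

- CI is cross-checked against a Monte-Carlo oracle that literally
  samples ≥ 10⁵ random pixel pairs and counts shared patches
  (agreement within 3 standard errors on random masks).
- Buffering is cross-checked against brute-force all-pairs
  center-distance dilation on small grids.
- Monotonicity (curve non-increase, buffer nesting, CI under mask
  growth) is property-tested with hypothesis on randomized masks.
- The 2D-bias ordering (stratum ⊆ 2D ⇒ CI dominance and ordered
  threshold distances) is asserted across 20 seeded scenes per
  archetype at 64 × 64 px; qualitative patterns (shrubs most
  disconnected, bias peaking at short distances) are asserted as means
  over seeds, never per scene. These problem sizes keep the default
  suite under a few seconds while the properties themselves are
  size-independent.

## Known limitations

- Threshold distances are quantized to the buffer step and depend on
  raster-vs-vector buffer geometry; absolute values are comparable
  only between runs with identical grids and steps.
- The adjacency convention (4 vs 8) changes patch counts and hence all
  metrics; 8 is the default and the flag exists precisely because
  published raster analyses often leave it unstated.
- Buffers ignore barriers, so functional distances are optimistic for
  organisms blocked by buildings or roads.
- The generator's disc-based morphology has no spatial anisotropy
  (no street grids, hedgerow lines or riparian corridors).
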