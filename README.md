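# volstorm

Volumetric scanning 3D-dSTORM processing: from per-movie localization
tables of repeated axial scans to drift-corrected volumetric point
clouds, segmented presynaptic protein clusters with size, volume and
density metrics, truncation and localization-reduction robustness
analyses, and assignment of clusters to membrane-labeled boutons — with
a synthetic acquisition simulator so every stage is testable without
raw data.

## The problem

Single-molecule localization microscopy (dSTORM) resolves presynaptic
scaffold clusters — Bassoon-marked active zones — at nanometre scale,
but a single focal plane truncates structures that extend axially, and
2D projections superimpose neighbours.  Scanning the focal plane
continuously through a thick tissue block while recording many short
movies captures entire structures: with an astigmatic (cylindrical-lens)
detection path the fitted PSF widths `(wx, wy)` encode the axial offset
of each emitter from the focal plane, and the piezo trajectory gives the
focal plane's position in every frame, so each localization's true axial
coordinate is

```
z = z_stage(frame, scan) + argmin_z [(wx(z) − Wx)² + (wy(z) − Wy)²]
```

with `wx(z), wy(z)` cubic-smoothing-spline calibration curves measured
on a bead sample.  Coverslip fiducials imaged before and after each
measurement provide a rigid drift estimate, interpolated linearly in
acquisition time, and align sequential staining rounds into one frame.
Clusters are segmented by thresholding a Gaussian localization-density
map and taking 26-connected components; each cluster is quantified by
its localization count (a relative protein-content proxy), 3D Feret
length, width, isosurface volume and count density.  Boutons
reconstructed from a membrane channel receive every cluster whose
centroid falls inside their filled surface.

The package is aimed at microscopists and analysts working with
rapidSTORM-style localization tables from scanned 3D acquisitions, and
at anyone who needs a transparent, scriptable replacement for
closed-source isosurface pipelines.

## Worked example

Simulate a small acquisition (25 clusters in an 8 × 8 × 4 µm block, ten
alternating scans, drift on), then run the full pipeline:

```python
import numpy as np
import volstorm as vs

spec = vs.SceneSpec(field_of_view=(8.0, 8.0), z_extent=4.0,
                    n_clusters=25, seed=7)
movies, beads_pre, beads_post, truth = vs.simulate_scene(spec)

calib = vs.fit_calibration(
    vs.simulate_calibration_stack(width_noise=0.0, seed=1))
scan = spec.scan_spec()
volume = vs.assemble_volume(movies, scan, calib)

tf = vs.estimate_transform(
    vs.summarize_beads(beads_pre),
    vs.summarize_beads(beads_post, timestamp="post"))
corrected = vs.correct_drift(volume, tf, scan)

denoised = vs.denoise(corrected)
result = vs.segment_clusters(denoised, vs.ClusterParams())

lengths = [c.length for c in result.clusters]
s = vs.summarize(lengths, "length")
print(f"{len(result.clusters)} clusters; length median "
      f"{s.median:.0f} [{s.q25:.0f}-{s.q75:.0f}] nm")
```

This prints (annotated):

```
calibrated range -795..795 nm, focal plane at -0.0 nm
assembled 3741 localizations, 0 rejected by the width lookup
drift (30.1, -19.9, 14.7) nm over the acquisition, residual 1.1 nm
25 clusters (threshold 87 /um^3, 0 unassigned)
cluster length median 372 [348-427] nm; median count 143
```

The estimated drift matches the injected (30, −20, 15) nm to within the
bead precision; all 25 simulated clusters are recovered; the median
count reproduces the simulated blinking budget (negative-binomial mean
139); and the median member length sits below the 450 nm envelope median
exactly as expected — the extreme poles of an ellipsoid carry almost no
emitter mass (see `docs/methods.md`).

The same pipeline is scriptable from the shell:

```
volstorm simulate --spec scene.toml -o sim/
volstorm calibrate stack.csv -o calib.csv
volstorm assemble sim/movie_*.csv --calib calib.csv -o volume.csv
volstorm drift volume.csv --pre sim/beads_pre.csv --post sim/beads_post.csv -o corrected.csv
volstorm cluster corrected.csv -o clusters.csv
volstorm report clusters.csv
```

sklearn-style estimators (`ZCalibration`, `DriftCorrector`,
`DensitySegmenter`) expose the core stages with
`fit`/`predict`/`transform` and `get_params`/`set_params` for use in
pipelines and parameter searches.

## Layout

```
src/volstorm/
  io.py           localization-table dialects (rapidSTORM text, canonical CSV)
  table.py        canonical container, intensity filter, 2D rendering
  calibration.py  astigmatic width-vs-z calibration and lookup
  scan.py         piezo trajectory model and volumetric assembly
  drift.py        fiducial summarization, drift correction, round alignment
  density.py      Gaussian density maps, dense + sparse isosurface labeling
  clusters.py     denoising, segmentation, metrics, truncation, reduction
  boutons.py      bouton surface reconstruction and cluster assignment
  simulate.py     synthetic acquisitions with full ground truth
  stats.py        median/quartile summaries, rank tests, Spearman
  cli.py          the `volstorm` command
```

`docs/methods.md` documents the models, defaults, numerical conventions
and limitations in detail.
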