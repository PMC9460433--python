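# uavfvc

Fractional vegetation cover (FVC) estimation for mine-tailings sites from
visible-band UAV products: an RGB orthomosaic and an RGB-attributed dense
point cloud. The package is aimed at remote-sensing and ecological-monitoring
practitioners who need to quantify vegetation recovery on tailings dams and
similar disturbed terrain where only a consumer RGB camera (no near-infrared
band) is available.

## What it computes

The workflow classifies *image objects* rather than pixels and counts cover in
the 3-D point cloud:

1. **Visible-band vegetation indices.** Nine indices computable from R, G, B
   alone (NGRDI, NGBDI, MRBVI, MGRVI, RGBVI, ExG, CIVE, VDVI, EGRBDI), e.g.
   the visible-band difference vegetation index

   VDVI = (2G − R − B) / (2G + R + B) ∈ [−1, 1].

   A selection procedure picks the classification index: discard indices with
   out-of-range pixels, discard indices whose scene histogram is not clearly
   bimodal (vegetation vs background), then rank the survivors by ascending
   mean per-class standard deviation.

2. **Multiresolution segmentation.** Bottom-up region merging under the
   weighted color/shape heterogeneity criterion
   C = w_color·Δh_color + w_shape·Δh_shape, with
   Δh_color = Σ_c w_c·[n·σ_c(merge) − (n₁σ_c(1) + n₂σ_c(2))] and shape terms
   built from perimeter l, bounding-box short side b and area n (smoothness
   l/b, compactness l/√n). A merge happens only between mutually-best
   neighbors with C < scale². The working scale is chosen from the LV-ROC
   curve — the rate of change of mean per-segment variance across candidate
   scales — optionally with elevation and slope added as extra layers.

3. **Random-forest object classification.** A bagged ensemble of CART trees
   (Gini impurity splits, majority vote H(x) = argmax_Y Σ I(h_i(x) = Y)) on
   per-segment features (band means/stds, mean index, mean elevation/slope,
   area), with the full accuracy suite: producer's and user's accuracy,
   overall accuracy, and the kappa coefficient from the confusion matrix.

4. **Surface-to-point mapping and FVC.** Vegetation polygons are projected
   onto the point cloud (a point is vegetation iff its (x, y) falls inside a
   vegetation polygon, boundary included). With M vegetation polygons and N of
   them receiving points, the mapping error is Q = N/M × 100. Residual
   bare-soil points can be purged by a per-point VDVI rule, and
   FVC = vegetation points / total points × 100.

Because UAV campaigns of this kind rarely deposit their rasters, the package
ships a synthetic-scene generator (`uavfvc.scene`) that reproduces the
statistical structure such a site presents — four blob-shaped cover classes,
a terraced ~140 m elevation ramp, ~0.08 m pixels, a ~214 points/m² RGB cloud
colored from the raster — so every stage is testable end to end.

## Worked example

```python
import uavfvc as uv

report = uv.run(uv.PipelineConfig(seed=7), "out")
print(report["chosen_index"], report["optimal_scale"], report["n_segments"])
print(report["accuracy"]["OA"], round(report["accuracy"]["kappa"], 4))
print(report["mapping"])
print(report["truth_fvc_percent"])
```

prints (abridged):

```
VDVI 20.0 333
0.9924812030075187 0.9854
{'M': 217, 'N': 217, 'Q_percent': 100.0, 'vegetation_points': 32667,
 'points_purged': 0, 'total_points': 90266, 'fvc_percent': 36.19}
36.00006103515625
```

Reading: the selection diagnostics picked VDVI; the LV-ROC curve put the
optimal scale at 20, giving 333 image objects; the held-out object accuracy
is OA ≈ 0.99 (kappa 0.985); all 217 vegetation polygons received cloud points
(Q = 100%); and the recovered cover, 36.19% of the 90,266 points, sits within
0.2 points of the scene's true 36.00% vegetation fraction.

The same chain is available from the shell, stage by stage or at once:

```bash
uavfvc simulate --rows 256 --cols 256 --seed 7 --out out/scene
uavfvc run --out out            # or: indices, select-index, select-scale,
                                # segment, classify, evaluate, map3d, fvc
```

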