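# ivpharm

Single-cell pharmacokinetic analysis of intravital fluorescence microscopy
movies.

Intravital time-lapse imaging of a fluorophore-labeled drug — together with
a nuclear marker such as an H2B fluorescent fusion — makes it possible to
watch drug uptake cell by cell inside living tissue. Turning those movies
into numbers requires segmenting hundreds of nuclei across conditions that
defeat simple global thresholds (multiple brightness levels, dense cell
fields, uneven illumination), then reading the drug channel inside each
nuclear border and converting fluorescence to concentration. `ivpharm`
implements that workflow end to end for researchers doing quantitative
intravital pharmacology:

* **Thresholding** — Otsu (between-class variance), Huang (fuzzy
  index-of-fuzziness), and an iterative locally-adaptive method with three
  inputs (iteration cap, selectivity `power`, termination `epsilon`) that
  handles multi-brightness and uneven-background images a single global
  threshold cannot.
* **Segmentation** — gamma adjust → threshold → speckle-removal opening →
  8-connected labeling (centroids, borders, per-channel means) → minimum-
  area filter; per-slice Z-stack support with an outline projection.
* **Quality metrics** — misclassification error
  `ME = 1 − (|B_o∩B_T| + |F_o∩F_T|)/(|B_o|+|F_o|)`, region-count
  nonuniformity `TRNU = |R_T−R_o|/R_o`, and foreground-variance
  nonuniformity `VNU = |σ²_T−σ²_M|/σ²_M` against manual reference masks,
  with Friedman rank-sums and pairwise Wilcoxon rank-sum testing
  (p < 0.05 gate).
* **Pharmacokinetics** — OLS calibration line from a dilution series;
  per-cell nuclear concentrations (µM) over time with mean ± sd, vessel-ROI
  curve, subtherapeutic cell fraction (default 1.5 µM), nuclear-vs-cytosol
  drug partitioning, and one-compartment uptake refits
  (`dC/dt = k_in C_v − k_out C`, `C_v(t) = peak·e^(−k_decay t)`).
* **Tracking** — optimal-assignment centroid linking with a 10 px default
  search radius, plus CSV export for external LAP trackers.
* **Synthetic data** — a ground-truthed generator for two-channel movies
  and the canonical hard fixtures (multi-brightness, dense fields, both,
  high magnification), so every stage is validated quantitatively without
  external data.

## Worked example

Simulate a 20-frame (25 min at 75 s/frame) movie of 30 nuclei with a
vessel bolus and heterogeneous per-cell uptake, then run the full analysis:

```bash
cat > scene.yaml <<EOF
n_cells: 30
field_size: 224
n_frames: 20
noise_sigma: 0.01
seed: 11
EOF
ivpharm simulate movie.tif --spec scene.yaml --truth truth.json

cat > run.yaml <<EOF
input_path: movie.tif
calibration_path: cal.csv     # CSV: concentration_uM, fluorescence
vessel_roi: [0, 224, 0, 8]
EOF
ivpharm run --config run.yaml out
```

```
wrote movie.tif: 20 frames x 2 channels
wrote 6 outputs to out
```

`out/pk_frames.csv` then holds the assay curves:

```
frame,time_s,n_cells,mean_uM,sd_uM,vessel_uM,frac_subtherapeutic
0,0.0,30,-0.0028096997615043363,0.03051530169165872,5.993664270182779,1.0
...
19,1425.0,30,2.341240810855332,0.9736096439731499,3.4065856644214074,0.26666666666666666
```

Read: the vessel starts at ~6.0 µM and decays to 3.4 µM by 24 min while
the mean nuclear concentration rises from 0 to 2.34 ± 0.97 µM; the
fraction of cells still below the 1.5 µM therapeutic level falls from 100 %
to 27 %. `out/manifest.json` records every parameter plus summary values
(here `n_tracks: 30` — every cell tracked through all frames — and
`nuclear_fraction_final: 0.867`, the share of drug signal in the nuclear
compartment at the last frame). `out/regions.csv`, `out/pk_cells.csv`,
`out/detections.csv` and `out/tracks.csv` carry the per-cell detail;
re-running with the same config reproduces every CSV byte for byte.

Other subcommands: `ivpharm preview` (overlay PNG for parameter tuning),
`ivpharm threshold`, `ivpharm segment`, `ivpharm evaluate` (ME/TRNU/VNU
against manual masks), `ivpharm pk`, `ivpharm track`. All are thin wrappers
over the library API (`import ivpharm`).

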