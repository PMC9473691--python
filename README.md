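# nmquant

Quantification pipeline for zebrafish lateral-line hair-cell physiology.

Hair cells of the larval zebrafish lateral line are an accessible model for
inner-ear mechanosensation, synaptic transmission and ototoxicity. A typical
study of these cells combines several quantitative readouts: evoked
fluorescence transients from genetically encoded calcium/exocytosis
indicators (GCaMP, SypHy), vital-dye uptake and clearance (e.g. fluorescent
aminoglycosides), ratiometric oxidation reporters, hair-cell survival after
ototoxin exposure, spontaneous afferent spike rates from loose-patch
recordings, developmental-age classification by kinocilial height, and CRISPR
indel genotyping. `nmquant` implements that entire workflow as a tested,
scriptable Python library with a thin `nmq` command line — together with a
ground-truthed synthetic-data generator that emulates the acquisitions, so
every stage is verifiable without any microscope.

## The core quantities

For an ROI-mean fluorescence trace F(t) with pre-stimulus baseline F₀, the
evoked response is ΔF/F₀ = (F − F₀)/F₀ and the per-cell metrics are

- peak ΔF/F₀ (maximum from stimulus onset onward),
- duration (onset → peak) and slope (peak/duration),
- decay half-life from a one-phase exponential fit
  y(t) = A·e^(−kt) + C, t½ = ln 2 / k,
- resting intensity (mean over the 2 s prestim interval),
- an activity flag (peak above k·σ of the prestim ΔF/F₀ noise, k = 3).

Preprocessing follows the standard chain — trim the first 10 volumes
(photobleaching), rigid x-y registration, z projection, F₀ subtraction,
0.5 s temporal binning for display. Dye assays quantify the masked mean of a
background-subtracted channel (rolling ball, radius 50 px) under a
mean-threshold mask from a reference channel. Survival is
100·(surviving)/(pre-treatment) cells per neuromast (paired) or
100·treated/mean(untreated) (group-normalized). Spikes are counted by a
median/MAD threshold detector and reported per minute. Group comparisons
follow the normality-gated decision tree (t / Mann-Whitney / ANOVA+Tukey or
Dunnett / Kruskal-Wallis+Dunn / two-way ANOVA+Sidak) with mean ± SEM
summaries. Details, defaults and design rationale: `docs/methods.md`.

## Worked example

Simulate a small functional movie (4 cells, 2 responding, 5% noise), run the
full pipeline, and quantify every cell:

```python
from nmquant import ROISpec
from nmquant.kinetics import (classify_activity, compute_kinetics,
                              estimate_baseline_noise, extract_trace)
from nmquant.movie_prep import prep_pipeline
from nmquant.synthetic import make_movie_truth, simulate_functional_movie

truth = make_movie_truth(n_cells=4, n_active=2, n_volumes=100,
                         seed=42, noise=(10.0, 0.0))
movie, truth = simulate_functional_movie(truth)
series, projected, shifts = prep_pipeline(movie, truth.stimulus)
print(f"movie: {movie.n_volumes} volumes at {movie.meta.volume_rate_hz:.0f} Hz, "
      f"stimulus at {truth.stimulus.onset_s} s")

for i, cell in enumerate(truth.cells):
    roi = ROISpec(cell.center, 3.3)                # 3.3 µm ≙ 12 px ROI
    trace = extract_trace(projected, roi)
    trace.stimulus = truth.stimulus
    f0 = float(series.F0[roi.mask(series.F0.shape)].mean())
    res = compute_kinetics(trace, truth.stimulus, f0)
    noise = estimate_baseline_noise(trace, f0, truth.stimulus)
    dff = (trace.values - f0) / f0
    post = dff[trace.times_s >= truth.stimulus.onset_s]
    active = classify_activity(res, noise, dff_post_onset=post, min_sustained=3)
    hl = f"{res.halflife_s:.3f}" if res.halflife_s else "--"
    print(f"cell {i}: peak dF/F0={res.peak_dff:6.3f}  duration={res.duration_s:.2f} s  "
          f"slope={res.slope_per_s:6.3f}/s  t1/2={hl} s  active={active}")
```

Output:

```
movie: 100 volumes at 10 Hz, stimulus at 3.0 s
cell 0: peak dF/F0= 1.000  duration=0.50 s  slope= 1.999/s  t1/2=1.002 s  active=True
cell 1: peak dF/F0= 0.996  duration=0.50 s  slope= 1.992/s  t1/2=1.006 s  active=True
cell 2: peak dF/F0= 0.005  duration=6.90 s  slope= 0.001/s  t1/2=-- s  active=False
cell 3: peak dF/F0= 0.004  duration=5.30 s  slope= 0.001/s  t1/2=-- s  active=False
```

The two responding cells were generated with peak ΔF/F₀ = 1.0, a 0.5 s rise
and a 1.0 s decay half-life: the pipeline recovers all three to within the
noise, and the activity classifier separates responders from silent cells.
The same circle of ideas runs the other assays, e.g.:

```python
from nmquant.assays import indel_length
indel_length("CAAACTACTTCAAACGTGGGGA", "CAAACTACACGTGGGGA")   # -> 5 (bp)
```

The command line mirrors the library:

```bash
nmq simulate movie --seed 1 --out movie.tif       # + ground-truth sidecar
nmq kinetics movie.tif rois.csv --stim-onset-s 3.0 --stim-duration-s 0.5 --out cells.csv
nmq assay genotype CAAACTACTTCAAACGTGGGGA CAAACTACACGTGGGGA
nmq stats long.csv --design two_group_unpaired --out comparison.csv
```

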