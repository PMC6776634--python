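# retinamech

Combined mechano-electrophysiology analysis of explanted retina: dynamic
micro-indentation rheology of the tissue, and detection of mechanically
evoked firing-rate modulation of retinal ganglion cells (RGCs) recorded on
a high-density 64×64 multi-electrode array (42 µm pitch).

The package is for experimenters who indent soft neural tissue with a
ferrule-top (spherical-tip cantilever) probe while recording spiking, and
who want a tested, reproducible version of the full analysis chain:

1. **Mechanics** — from depth-controlled traces (piezo position, cantilever
   deflection, load) extract per-frequency oscillation amplitudes and the
   load–indentation phase lag Φ, and compute the apparent moduli over the
   Hertzian contact area `A = π R h`:

   ```
   K′ = (F₀/h₀) · cos Φ · √π / (2√A)      (storage)
   K″ = (F₀/h₀) · sin Φ · √π / (2√A)      (loss)
   tan Φ = K″ / K′                         (loss tangent)
   ```

   plus Shapiro–Wilk normality and Kruskal–Wallis comparison across the
   0.1 / 1 / 10 Hz frequency sweep.
2. **Probe localization** — the probe shadow under far-red light is the
   largest 4-connected non-saturating component of the electrode grid; its
   centroid is the stimulation site.
3. **Spike pipeline** — 2 s / 10 ms sliding-window firing rates, z-scoring,
   basal vs indentation-phase Pearson correlation matrices, hierarchical
   clustering on `1 − |ρ|` with silhouette-selected k ∈ [4, 60], basal-matrix
   reordering, and responsive-cluster detection via basal-referenced z-rates.
4. **Cell types** — ON / OFF / ON-OFF / NC classification from white/black
   full-field flash responses via the Bias Index
   `BI = (A_w − A_b)/(A_w + A_b)` with ±0.3 thresholds, and cell-type
   composition of responsive vs unresponsive clusters.
5. **Trial predictors** — per-trial features (contact area, strain `√(h/R)`,
   pressure, depth, local unit density d5, local basal rate r5) ranked by
   normalized Gini importance of a decision tree averaged over 1000
   stratified 80/20-split refits.

A synthetic-data module generates both streams from known ground truth
(a standard-linear-solid tissue model; inhomogeneous-Poisson spike trains
with planted flash responses and mechanically evoked clusters), so every
stage is testable end to end without laboratory data.

## Worked example

The numbered drivers under `analysis/` run the whole study on the bundled
synthetic conditions (raw data go to `scratch/`, tables to `results/`):

```bash
python analysis/01_simulate_dataset.py
python analysis/02_mechanics_map.py
python analysis/03_probe_localization.py
python analysis/04_spike_clustering.py
python analysis/05_rgc_classification.py
python analysis/06_trial_predictors.py
```

`02_mechanics_map.py` prints, for 10 scan locations at 5 nm deflection
noise:

```
mean moduli per frequency:
         k_storage_pa  k_loss_pa  tan_phi
freq_hz
0.1             699.7      101.1      0.1
1.0            1198.9      510.4      0.4
10.0           1698.3      100.1      0.1
k_storage: Kruskal-Wallis H=25.8 p=2.49e-06 (significant at 0.0005: True)
```

i.e. the planted stiffening from 0.7 kPa at 0.1 Hz to 1.7 kPa at 10 Hz is
recovered and the frequency dependence is highly significant.
`04_spike_clustering.py` and `05_rgc_classification.py` then report:

```
silhouette-selected k = 58
responsive clusters: [8, 21, 26, 58]
within-cluster mean |rho|: indentation 0.50 vs basal 0.09
ON enrichment in responsive clusters: +19.0 percentage points
```

— the four planted mechanically evoked assemblies are flagged responsive,
their correlations are present only during stimulation, and the responsive
population is ON-cell enriched, mirroring the planted composition.

The same stages are available as a CLI (`retinamech simulate|analyze|
classify|locate|predict|run`) and as one deterministic end-to-end call,
`retinamech.io.run_full_pipeline(RunConfig(...))`.

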