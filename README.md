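# caudconn

Aging is associated with *dedifferentiation* of cortico-striatal function:
the centrolateral caudate's preferential coupling with the fronto-parietal
network (FPN) weakens across the adult lifespan while its coupling with
the default-mode network (DMN) strengthens, and this loss of specificity
relates to dopamine D1 receptor availability and to memory performance.
`caudconn` implements the full analysis chain used to study this
phenomenon — for methodologists who want to validate, extend, or stress
the procedures without access to human imaging data:

- **synthgen** — a first-class synthetic cohort generator: lifespan
  subject tables with planted mediation paths, resting-state and blocked
  n-back BOLD runs with planted network coupling, motion traces with
  spikes, reference-tissue PET time-activity curves, and a six-task memory
  battery, all with ground truth emitted alongside.
- **preprocess** — framewise displacement (Power / Jenkinson), the
  24-parameter motion expansion, nuisance regression with spike scrubbing
  (FD > 0.2 mm), 0.009–0.09 Hz zero-phase bandpass, 6 mm FWHM Gaussian
  smoothing, and strict QC exclusion rules (mean FD > 0.30 mm, accuracy
  ≤ 50%, outliers > 3.29 SD).
- **parcellation** — voxel-wise winner-take-all assignment of striatal
  voxels to cortical networks: each voxel takes the modal network among
  its top-25 most correlated cortical voxels (group-mean Fisher z),
  with allocation fractions and cross-group overlap tables.
- **connectivity** — bilateral 6 mm sphere ROIs (the standard caudate seed
  at ±12, 10, 8 and six cortical targets ship as the default table),
  seed-to-network Fisher-z connectivity, per-load task connectivity with a
  4 s hemodynamic-lag shift, and the differentiation score
  `D = z_FPN − z_DMN`.
- **pet_srtm** — the simplified reference tissue model,

      C_T(t) = R1·C_R(t) + (k2 − R1·k2/(1+BP_ND)) · [C_R ⊗ e^(−k2 t/(1+BP_ND))](t),

  as both forward simulator and bounded weighted-least-squares fitter of
  (R1, k2, BP_ND) from frame-averaged TACs.
- **stats** — mixed-effects and covariate-adjusted linear models with
  likelihood-ratio model selection, bias-corrected accelerated (BCa)
  bootstrap mediation (5,000 resamples), the first-principal-component
  memory composite, Holm–Bonferroni correction, and a driver that runs the
  whole model battery.
- **cli** — `caudconn simulate | preprocess | parcellate | connect | srtm
  | stats | run-all`, a JSON config carrying every threshold, and a
  checksummed artifact manifest (two runs with the same config and seed
  are bit-identical).

## Worked example

Generate a 60-subject lifespan cohort, clean every run, parcellate the
striatum per age group, and measure how well the analysis recovers the
planted structure:

```python
from caudconn import studies

res = studies.run_rest_cohort(seed=7, n_subjects=60)
print(round(res.accuracy_pct, 2))
print(res.fractions.round(2))
print(f"slope {res.slope:.5f}  planted {res.planted_slope:.5f}  se {res.slope_se:.5f}")
```

prints

```
99.83
            1      2     3    4    5    6    7
young   33.33  41.67  25.0  0.0  0.0  0.0  0.0
middle  25.52  49.48  25.0  0.0  0.0  0.0  0.0
old     16.67  58.33  25.0  0.0  0.0  0.0  0.0
slope -0.00386  planted -0.00427  se 0.00145
```

Reading this: 99.83% of striatal voxels were assigned the network planted
for their age group; the allocation table (columns = network labels,
1 = FPN, 2 = DMN, 3 = limbic-like) shows the FPN territory shrinking from
33% to 17% and the DMN territory growing from 42% to 58% from young to
old — the dedifferentiation pattern — while the limbic band stays put; and
the regression of measured rest differentiation on age recovers the
planted slope (−0.0039 vs −0.0043 Fisher-z units per year) well within
one standard error.

The same module exposes the other studies: `run_lag_gain_study` (the
4 s-delay task analysis and load-gain ordering), `srtm_grid_recovery` and
`srtm_noise_recovery` (kinetic parameter recovery), `lrt_null_calibration`
and `mediation_null_coverage` (calibration of the inferential layer), and
`run_battery_cohort` (the full model battery — mixed models, D1-binding
regressions, mediation, memory composite — on a measured cohort).

The disk pipeline does the same end-to-end from a shell:

```sh
caudconn run-all --seed 5 --n-subjects 14 --outdir out/
```

writing NIfTI volumes, TSV tables, a JSON results bundle, and
`manifest.json` with a SHA-256 checksum per artifact.  (At the default
cohort size of 180 subjects the simulate stage writes several GB of
NIfTI; pass `--n-subjects` for demo-scale runs.)

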