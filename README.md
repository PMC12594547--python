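# dermoct

Multifunctional OCT analysis of skin for longitudinal preclinical
studies — the kind used to track drug response in a murine dermal
fibrosis model.  One package covers the four layers such a study needs:

* **structure** — skin thickness from repeated structural volumes:
  average the repeats, trim edge frames/A-lines, track the top and
  bottom surfaces by intensity thresholding, exclude pigmented regions,
  and convert pixel separations with
  $t = (z_\mathrm{bottom} - z_\mathrm{top})\,\Delta z / n$, $n = 1.376$;
* **elastography** — elastic-wave group velocity from phase-sensitive
  M–B-mode records: $u = \Delta\varphi\,\lambda / (4\pi n)$,
  time-of-flight delays by normalized cross-correlation, and
  $c_g$ as the slope of the distance–delay regression, averaged over the
  left/right propagation sides and the two scan orientations;
* **angiography** — correlation-mapping OCTA
  ($\mathrm{flow} = 1 - \overline{\mathrm{ZNCC}}_{5\times5}$ over
  consecutive repeated B-scans), multiscale Hessian vessel enhancement,
  and automated lumen-width measurement from perpendicular flow
  profiles;
* **stats** — the study's nonparametric layer: Wilcoxon signed-rank and
  Mann–Whitney U tests with exact small-sample p-values, Bonferroni
  correction, Hodges–Lehmann shift estimates with rank-inverted CIs,
  Hedges' g, and the sample-size / minimum-detectable-difference
  arithmetic of a two-sample power analysis.

No imaging data ship with the package.  Instead a **phantom** module
generates speckle-faithful synthetic volumes, wave records, angiography
stacks and longitudinal cohorts with known ground truth, so every stage
is verified end to end; **workbench** adds TIFF/HDF5 I/O, TOML-configured
pipelines and JSON run records with per-file checksums.

## Worked example

```python
from dermoct import stats as st

g = st.hedges_g(1.6, 0.3, 6, 1.2, 0.2, 6)       # pilot day-28 summaries
n = st.sample_size_two_sample(g)                  # alpha 0.05, power 0.80
sd = st.pooled_sd(0.3, 6, 0.2, 6)
mdd = st.minimum_detectable_difference(15, sd)

from dermoct.phantom import PhantomSpec, ScanGeometry, WaveSpec, generate_oce_dataset
from dermoct.elastography import estimate_group_velocity

geometry = ScanGeometry(n_alines=500, n_bscans=128, n_repeats=1, n_depth=64)
spec = PhantomSpec(geometry=geometry, top_surface_um=40.0, bottom_surface_um=200.0,
                   wave=WaveSpec(frequency_hz=5000.0, n_pushes=1,
                                 group_velocity_m_s=2.5),
                   seed=1)
mb, truth = generate_oce_dataset(spec)
est = estimate_group_velocity(mb, top_idx=truth.top_surface_idx)
```

prints, with the values above:

```
Hedges' g            : 1.45
animals per group    : 8
MDD at n = 15        : 0.26 m/s (16% of 1.6 m/s)
recovered velocity   : 2.501 m/s (truth 2.5 m/s)
```

A pilot effect of 1.6 ± 0.3 vs 1.2 ± 0.2 m/s at n = 6 per group is a
large standardized effect (g = 1.45), detectable with 8 animals per
group; enrolling 15 leaves power for a difference as small as
0.26 m/s — about 16% of the stiffer group's mean.  The phantom run shows
the elastography chain (phase → displacement → space–time map →
time-of-flight regression) recovering a known 2.5 m/s wave to 0.1%
with near-unity fit quality on both sides of the excitation.

The same pipelines run from the shell:

```sh
dermoct simulate structural --seed 1 --out runs/structural
dermoct oce --frequency 5000 --pushes 1 --seed 1 --out runs/oce
dermoct octa --kernel 5 --seed 2 --out runs/octa
dermoct stats --seed 1 --out runs/cohort
```

Each command writes CSV/TIFF/HDF5 outputs plus `run_record.json` with a
SHA-256 checksum per file; identical config and seed reproduce every
byte.

## Layout

```
src/dermoct/
  phantom.py       synthetic volumes, wave records, OCTA stacks, cohorts
  structure.py     thickness pipeline
  elastography.py  displacement, space-time maps, group velocity
  angiography.py   correlation mapping, vesselness, lumen widths
  stats.py         rank tests, HL estimates, effect size and power
  workbench.py     I/O, run configs, end-to-end pipeline
  cli.py           `dermoct` command group
docs/methods.md    models, defaults, design choices, limitations
```
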