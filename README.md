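# gliosim

Scenario ensembles of glioblastoma (GBM) growth on patient-specific brain
voxel grids.

Recurrent glioblastoma responds unpredictably to treatment, and clinicians
counseling patients need a realistic *range* of likely outcomes over the
next surveillance interval (typically 2–3 months) rather than a single
prediction.  `gliosim` implements a deliberately simple mechanistic model
for this purpose — in the spirit of a financial planner's portfolio
projections — for researchers in mathematical oncology and quantitative
imaging: the same fixed set of 18 parameter scenarios is simulated for
every tumor, and the spread of simulated outcomes brackets the plausible
clinical courses.

## Model

Tumor cells are split into proliferating *p*(x,t) and quiescent *q*(x,t)
densities (fractions of a carrying capacity K = 1) on the labeled brain
domain extracted from MRI:

    ∂p/∂t = ∇·(D(x) ∇p) + ρ(x) p [1 − δ(p+q)] − k(x) p δ(p+q)
    ∂q/∂t =                                     k(x) p δ(p+q)

- **D(x)** — motility: D_w in white matter and tumorous tissue, D_w/2 in
  gray matter, 0 in CSF and outside the brain (no-flux at skull and
  ventricles).
- **ρ(x), k(x)** — maximum growth and quiescence rates, piecewise constant:
  one pair of values inside the contrast-enhancing region, another in
  edema and the rest of the brain.  They are specified as doubling/halving
  times T̂ in days, with rate = ln 2 / T̂, and absorb the net effect of
  treatment response and resistance.
- **δ(u)** — a monotone density gate, the Beta(3,1) CDF of total density
  u = p + q, i.e. min(u,1)³: small populations grow almost exponentially;
  at carrying capacity growth stops and proliferating cells transfer into
  the quiescent pool (hypercellular but non-growing tissue, e.g. the
  necrotic core).

Initial conditions are imputed from imaging: cell density varies linearly
with T1-post-contrast intensity in the enhancing segmentation (onto the
density window I_c) and inversely with T2/FLAIR intensity in the edema
segmentation (onto I_e).  After simulating the inter-scan interval, the
final field is re-segmented virtually — voxels with p+q ∈ I_c count as
enhancing — and compared against the observed follow-up through the
relative volume change Δ = (V₁−V₀)/V₀, the closest-scenario error
R_best = (V*−V_obs)/V_obs, and the spatial overlap scores
containment C = |S∩R|/|R| and agreement A = |S∩R|/|S∪R|.

The 18 scenarios form a Taguchi (L18 orthogonal-array) design over seven
3-level parameters (k̂₀, ρ̂₀, D_w, I_e, I_c, k̂₁, ρ̂₁): every level of every
parameter appears 6 times, and each of the 9 level pairs of the two most
sensitive parameters (k̂₀, ρ̂₀) appears exactly twice.

The package also ships a synthetic brain phantom generator (layered
ellipsoidal brain, spherical tumor with necrotic core / enhancing rim /
edema halo, intensities consistent with the linear intensity–density maps)
so the entire pipeline runs and is tested without any patient data.

## Worked example

```python
import gliosim as g

grid = g.make_brain_grid((32, 32, 8))                 # 0.9x0.9x7 mm voxels
spec = g.PhantomSpec(dims=(32, 32, 8), noise_sd=0.0)
scenarios = g.default_scenarios()
baseline = g.make_baseline_study(grid, spec, scenarios[1])
followup = g.make_followup_by_simulation(baseline, scenarios[1], 60)

model = g.TumorGrowthModel(baseline, followup)
res = model.fit()
print(res.summary())
```

```
Tumor growth scenario ensemble
================================================================
scenarios:        18
interval:         60 days
V_0 (enhancing):  40 voxels
V_obs:            108 voxels
delta_obs:        +1.7000
best scenario:    1  (R_best = +0.0000)
----------------------------------------------------------------
       V_sim  delta_sim  agreement  containment
index
1        108     1.7000     1.0000       1.0000
2         38    -0.0500     0.3519       0.3519
3         56     0.4000     0.4138       0.4444
...
18         0    -1.0000     0.0000       0.0000
================================================================
```

The follow-up here was manufactured by simulating scenario 1 for 60 days,
so the ensemble recovers it exactly: the baseline's 40 enhancing voxels
grow to an observed 108 (Δobs = +1.70, a 170 % increase), scenario 1
reproduces that count with zero relative error (R_best = 0) and perfect
overlap (A = C = 1), while the other 17 scenarios span outcomes from
complete disappearance of enhancement (Δsim = −1) to more than a
four-fold increase — the kind of outcome range the ensemble is designed
to present.

The same pipeline runs from the shell:

```sh
gliosim phantom --out study/ --followup-days 60 --scenario-row 1 --noise-sd 0
gliosim ensemble --baseline study/baseline_manifest.txt \
                 --followup study/followup_manifest.txt --out results/
gliosim validate-design
```

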