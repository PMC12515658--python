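# Methods

## Model

The simulator evolves two cell densities on a labeled brain voxel grid:
proliferating cells p(x,t), which diffuse and grow, and quiescent cells
q(x,t), which only accumulate.  Densities are dimensionless fractions of a
carrying capacity normalized to 1; lengths are in mm and times in days
throughout.

    ∂p/∂t = ∇·(D ∇p) + ρ p [1 − δ(p+q)] − k p δ(p+q)
    ∂q/∂t =                               k p δ(p+q)

The gate δ(u) = min(u,1)³ (the Beta(3,1) cumulative distribution of total
density) switches the proliferating pool from near-exponential growth at
low density (δ ≈ 0, net rate ≈ ρ) to pure transfer into quiescence at
carrying capacity (δ = 1, net rate −k).  Quiescence here lumps together
cell death, hypoxia and treatment effect: the model makes no attempt to
represent individual therapies, only their net effect on growth and
attrition over a surveillance interval.  Two consequences worth keeping in
mind: q is monotonically non-decreasing at every voxel, and a tumor
initialized below carrying capacity can never shed total cell mass — rapid
clinical shrinkage of enhancement can only be mimicked by densities
growing *through* and out of the enhancing window, which is a known
structural limitation.

### Coefficients

| Parameter | Units | Meaning | Where |
|---|---|---|---|
| D_w | mm²/day | motility | white matter and any tumor-masked voxel |
| D_w/2 | mm²/day | motility | gray matter outside tumor masks |
| 0 | — | motility | CSF, background, resection cavity |
| ρ̂₁, k̂₁ | days | doubling/halving times | enhancing segmentation |
| ρ̂₀, k̂₀ | days | doubling/halving times | edema and all other tissue |

Rates used in the equations are ln 2 / T̂.  Tumor masks override gray
matter for D (an infiltrated cortex is treated as freely navigable).  The
published parameterization only covers enhancing and edematous tissue, yet
cells diffuse beyond both; we apply the edema-region values to all
non-enhancing tissue, since those parameters are meant to govern
low-density populations, which is exactly what diffuses into normal brain.
The scenario table spans doubling times of 21–97 days, halving times of
14–58 days and D_w of 0.015–0.06 mm²/day, consistent with the (wide)
ranges reported for gliomas.

### Initialization

Within the enhancing mask, T1-post-contrast intensities are min–max
normalized over the mask and mapped linearly (increasing) onto I_c; within
the edema mask, T2/FLAIR intensities are mapped linearly *decreasing* onto
I_e.  Min–max normalization is our choice — the linear intensity–density
relationship needs an anchoring, and per-mask normalization makes the
initialization invariant to scanner gain.  A constant-intensity mask maps
to the window midpoint (the 0/0 guard of the normalization).  All imputed
density starts in p; the necrotic core, when segmented, is seeded as pure
quiescent tissue at q = 0.9 — above every scenario's enhancing window, so
the core never re-classifies as enhancing, and hypercellular-but-inert,
matching its T1-hypointense appearance.  The 0.9 value is a documented
assumption; no published value exists.  An empty enhancing mask is an
error: without baseline enhancement there is no relative change to
compute, and such scans are excluded upstream.

## Discretization and integration

Space: conservative finite volumes on the anisotropic voxel grid.  Face
diffusivity is the *harmonic* mean of the adjacent voxel diffusivities —
zero whenever either side is CSF/background — so the no-flux condition at
the skull, the ventricles and the resection cavity falls out of the
scheme; an arithmetic mean would leak mass into zero-D voxels.  The
divergence telescopes, so total mass is conserved to rounding error under
pure diffusion (verified at ≤1e−8 relative over 60 days).

Time: an adaptive explicit Runge–Kutta (Dormand–Prince) integration with
rel_tol = 1e−4, abs_tol = 1e−7 and a 1-day step cap.  At clinical voxel
sizes this problem is not stiff: the explicit diffusion stability limit is
h²-limited at roughly 3 days for the largest D_w, above the step cap, and
reaction rates are of order ln 2/14 per day.  Correctness is defined
behaviorally, not by solver internals: halving rel_tol changes the final
enhancing-voxel count by far less than 0.5 % on the test phantoms, and
uniform-field runs match an independently integrated two-variable
well-mixed reduction to ≤1e−3 relative at 60 days.

Numerical guards: δ is evaluated on total density clipped to [0,1], so a
transient local overshoot of p+q above 1 (possible from diffusion influx)
saturates the gate rather than failing; the reaction then only transfers
p→q.  Final densities are checked against a −1e−9 positivity floor —
undershoot within the floor is snapped to zero, anything beyond raises an
error rather than being clipped silently.  CSF/background voxels have
identically zero right-hand side, so they remain exactly zero, not
approximately.  The q-monotonicity invariant is asserted across saved
checkpoints with the same 1e−9 slack.

## Scenario design

The ensemble is the standard L18 orthogonal array over seven 3-level
parameters, ordered (k̂₀, ρ̂₀, D_w, I_e, I_c, k̂₁, ρ̂₁) by decreasing
sensitivity.  Balance properties — all 9 (k̂₀, ρ̂₀) level pairs twice
each, every parameter's 3 levels six times each, I_e strictly below I_c in
every row — are enforced at runtime by `validate_design`, which guards the
shipped CSV against transcription errors.  Custom tables with the same
schema are accepted; for non-3-level designs (e.g. a 12-level variant) the
balance checks report "not applicable" and only the window check applies.

Scenarios are independent: ensemble output is deterministic and invariant
to execution order and worker count.  There are no stochastic components
anywhere in the model; the only random number generator in the package is
the phantom's intensity noise, which is seeded.

## Virtual imaging and metrics

A simulated state is re-segmented by thresholding p+q with the scenario's
own windows; both intervals are closed at both ends.  Voxel counts (not
mm³) are the primary volume measure.  `best_scenario` breaks ties toward
the lowest index, making reports order-stable.  Overlap scores compare
simulated masks against the follow-up's observed mask on the baseline
grid; no re-registration is attempted, so on real data the scores fold in
co-registration error (gray/white agreement between successive clinical
scans is typically only ~0.6).

One analytic point about the two scores: A = C·|R|/|S∪R|, so A < C
whenever S has any voxel outside R, and A = C below 1 *requires* S ⊂ R,
where both equal |S|/|R|.  The package's reference "coinciding scores"
configuration is therefore a simulated mask contained in the observed one
and covering half of it (A = C = 0.5); for equal-size masks overlapping in
half of each, the scores necessarily split into C = 1/2, A = 1/3.

## Phantoms and what the tests show

The phantom brain is a set of concentric ellipsoids — gray cortical shell,
white interior, two ventricles — with a spherical tumor (necrotic core
1.2 mm, enhancing rim 3.5 mm, edema halo 6.5 mm by default) whose target
density decreases radially, spanning I_c across the rim and I_e across the
halo.  Intensities apply the exact inverse of the imputation maps (plus
optional seeded Gaussian noise, default SD 1.0 on a 0–250 intensity
scale), so noise-free imputation recovers the target field to ≤1e−9 and
follow-ups generated by actually running the model are exact ground truth
for recovery experiments.

Test problem sizes are 32×32×8 and 48×48×10 grids at 0.9×0.9×7 mm — the
same voxel anisotropy as clinical surveillance scans at about one-tenth
the in-plane extent; a full 18-scenario, 60-day ensemble takes seconds at
32³-scale and ~10 s at 48-scale on one core.  On these phantoms the suite
verifies conservation, positivity, q-monotonicity, zero fluid-voxel
density for all 18 scenarios, the well-mixed oracle match, the
small-density exponential limit (within 2 % of e^{ρt}), scenario
recovery (the generating scenario's volume within 1 % of the observed
follow-up, |R_best| ≤ 5 %, best agreement ≥ 0.9), pairwise
non-redundancy of all 18 scenarios across two phantoms, and end-to-end
determinism.  None of this certifies clinical accuracy: phantoms have
clean geometry, perfect co-registration, no imaging physics, and their
follow-ups are generated by the model itself — they validate the
machinery, not the biology.

## Known limitations

- No mass effect or domain deformation; the brain geometry is frozen at
  baseline.
- Isotropic scalar diffusion only (no tensor-valued motility from DTI).
- Monotone q means enhancement cannot shrink rapidly unless densities
  grow out of the window from above; intervals with >66 % observed
  shrinkage are poorly served by construction.
- Treatment is not modeled explicitly; its net effect is folded into the
  scenario rate ranges.
- Voxels imputed exactly onto a window endpoint (an artifact of min–max
  normalization hitting the closed interval bounds) can leave the window
  in arbitrarily short simulations; zero-time identities therefore hold up
  to boundary voxels.
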