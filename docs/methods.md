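# Methods

## Model and assumptions

The core object is a deterministic mass-action ODE model of the
CheA3/CheA4/CheY6 split-kinase module, treated in isolation from the rest
of the chemotaxis pathway. Species are well mixed (concentrations in µM,
time in seconds); ATP is clamped at 1000 µM and ADP/Pi are not tracked,
so the ATP-binding step enters as a pseudo-first-order flux
k3·[A3A4]·[ATP]. Autophosphorylation releases CheA3-P and CheA4 as
separate species in the basic model; the alternative in which the
complex survives phosphorylation is a variant architecture (below).
Reverse phosphotransfer (k7) is modeled as an elementary bimolecular
step, consistent with its per-µM-per-s units. Incoming signal is the
autophosphorylation catalytic rate k5; everything upstream (receptor
state, cluster activation) is abstracted into that one number.

The stoichiometry fixes three conserved moieties — total CheA3, CheA4
and CheY6 — which the integrator must preserve; conservation to 1e-8
relative along trajectories is asserted in the tests and monitored at run
time (drift beyond 1e-6 relative attaches a warning to the trajectory).

Default rate constants and totals are the literature-derived base values
(see `ParameterSet`); k1 = 100 /µM/s is the effective in-vivo association
rate, ~500-fold above the in vitro measurement (0.208 /µM/s), reflecting
co-confinement of CheA3/CheA4 in the cytoplasmic chemoreceptor cluster —
a subregion whose ~5% share of the cell cross-section implies ~1% of its
volume and hence up to ~100-fold concentration enrichment.

## Numerics

* Integration: LSODA with rtol 1e-8, atol 1e-10 µM and an analytic
  Jacobian (rates span five orders of magnitude, so the system is stiff).
  Piecewise-constant signal schedules are integrated segment by segment
  so the solver never steps across a discontinuity.
* Steady states: integrate in growing chunks until ‖rhs‖ <
  1e-10·(1+‖y‖), then polish by bounded least-squares on the
  conservation-augmented system `[rhs(y); L·y − totals] = 0`, followed by
  a few Gauss–Newton steps (the trust-region solver stagnates above
  round-off near folds). Roots are accepted below residual 1e-8·(1+‖y‖).
* Stability: eigenvalues of the finite-difference Jacobian (relative
  step 1e-6) projected onto the stoichiometric subspace, which removes
  the structural zero modes of the conserved moieties.
* Signal-response curves: bidirectional warm-started sweeps (ascending
  from the unphosphorylated state, descending from the fully
  phosphorylated one). Where a sweep's root refinement fails or lands on
  an unstable root, the point is re-settled by integration from the warm
  start, which follows the basin through a fold. Sweep disagreement
  beyond 1% of total CheY6 flags bistability; the two saddle-node folds
  are refined by bisection to 1e-4 relative in k5 (tighter on demand —
  the critical eigenvalue shrinks as the square root of the distance to
  the fold), and the unstable branch is traced by root-finding from the
  midpoint of the stable branches. A 10× denser sub-grid is inserted
  around the maximum-slope region; sub-grid points that numerically
  coincide with existing grid points are dropped, since near-zero spacing
  corrupts finite-difference slopes.
* Sigmoidality: RS = k5s·s_max with the slope taken by central
  differences on the (possibly non-uniform) grid and the maximum refined
  by an exact parabola through the three bracketing points. RS is
  reported on the normalized response (Y6p/Y6_tot) so values are
  comparable across parameter sets; the µM-scale value is stored
  alongside (RS_µM = RS·Y6_tot). On bistable curves the slope is taken
  along the ascending sweep and the bistable flag, not the RS value, is
  the headline: the fold makes the true slope unbounded.
* Hysteresis protocol: the signal steps 2→6→2 /s in unit steps with a
  2000 s dwell (settling is verified via the ‖rhs‖ criterion at each
  segment end; an unsettled dwell marks the thresholds unreliable). The
  switching threshold on each leg is the signal at which the settled
  normalized response crosses 0.5 — the half-saturation convention is a
  package definition — located by linear interpolation between
  bracketing signal levels. On a monostable system both legs retrace one
  single-valued curve and the thresholds coincide by construction.

## Variant architectures

Variants are built by appending reactions to the basic network and nest
it exactly: zeroing the extra rates reproduces the basic curves to
numerical precision (tested). Supplementary-table values for the extra
rates are not available, so defaults are package choices, echoed into
every provenance record:

* Complex-phosphatase off-rates k13, k16, k19 default to k10 (0.04 /s) —
  the same complex-dissociation kinetics as the CheA3 phosphatase
  complex. The `tie_complex_rates` option ties k12=k15 and k14=k17 so both
  complex species are swept as one activity.
* The retained-complex variant replaces the release step with
  A3A4T → A3pA4, adds release A3pA4 → A3p + A4 (k5′, default 0.1 /s) and
  direct phosphotransfer A3pA4 + Y6 → A3A4 + Y6p at k6. Signal can be
  applied to k5 alone (k5′ fixed) or to both simultaneously.
* The extra-kinase variant adds A2 → A2p (k5\*) and A2p + Y6 → A2 + Y6p
  at k6, with A2_tot = 20 µM. At that level the maximal background flux
  k6·A2_tot·[Y6] can exceed the phosphatase capacity k11·A3_tot, so the
  variant exhibits the full documented range of behavior: RS unchanged
  (within 5%) at low background and bistability lost at high background.
  At substantially lower A2_tot the background saturates below
  phosphatase capacity and bistability only narrows.

Comparison architectures are minimal reconstructions (the exact reaction
lists used in the original structural analyses are not distributed):
a non-split bifunctional HK (unphosphorylated H is its own RR
phosphatase), a monofunctional HK with dedicated phosphatase Z, and a
monofunctional split kinase (the basic network with the free-CheA3
phosphatase reactions removed — the structural equivalent of k9=k11=0).
Their generic rates mirror the split-system magnitudes.

## Reaction-network analysis

Deficiency is computed as δ = n − l − s (distinct complexes, linkage
classes, stoichiometric rank), with clamped species removed before
complex formation (keeping them is a flag). Weak reversibility is strong
connectivity of each linkage class. A deficiency-zero weakly reversible
network is reported as structurally excluded from multistationarity. For
all other networks the package runs an explicit numerical screen: per
random draw of rate constants and totals (log-uniform, 1e-3–1e3 and
1–300 µM), steady states are solved from the two phosphorylation
extremes plus hit-and-run samples inside one stoichiometric compatibility
class; two distinct stable validated states (residual < 1e-10, stable
reduced Jacobian, totals matching to 1e-8) constitute a witness. The
full higher-deficiency machinery is deliberately not implemented: the
verdict enum distinguishes "multiple states found" from "none found in
this search", and the package never claims impossibility.

## In vitro assay model

The dephosphorylation assay mixes 100 µM CheY6 with 30 µM phosphorylated
CheA3-P1 (sole phosphodonor), 2.5 µM CheA3 when present, and 0–60 µM
CheA4. There are no kinase reactions (ATP removed during purification),
free CheA4 is inert toward CheY6-P, and phosphatase activity is
restricted to free CheA3. The P1 domain reuses the full-length
phosphotransfer rates k6/k7 (the P1 domain carries the transfer
chemistry), and association uses the in vitro value k1_iv = 0.208 /µM/s
with k2 = 10 /s. The observable is total phospho-CheY6 (free plus
complexed), which is what a denaturing gel quantifies.

At these rates phosphotransfer completes within a fraction of a second
(checked and recorded per condition) and CheY6-P decays over seconds:
a saturated, near-zero-order phase (Vmax = k11·[A3] with Km ≈
(k10+k11)/k9 ≈ 0.45 µM) followed by a fast first-order tail. k_obs is
the pseudo-first-order constant of a free (y0, k) single-exponential
least-squares fit with the window starting at 0.5 s — past the transfer
phase, which is the purpose of the window. The default simulation grid
is 0–30 s at 0.25 s spacing, more than five half-lives of the slowest
(CheA3-absent, k8-driven) condition.

Parameter estimation for (k9, k10, k11) is a seeded differential
evolution over log10 parameters (bounds a factor 100 around the base
values) followed by bounded least-squares refinement of the residual
vector. The fit objective shares the assay's integration path, so a
noise-free synthetic panel has an exactly attainable zero-residual
optimum. Identifiability caveat: after the transfer phase the decay is
governed by Vmax and Km only, so k11 (and through Km, k9) are well
determined while k10 — a 1.6% contributor to Km at base values — is
close to structurally unidentifiable; the fit reports a two-fold profile
perturbation per parameter and flags flat directions. In the k11 = 0
limit, binding does not change total phospho-CheY6, so k9 is flagged
likewise.

## Synthetic data

The generator emulates phosphorimaging decay panels: the simulated assay
perturbed by multiplicative log-normal noise (band intensities are
positive with roughly proportional error), sigma 0.05 by default, fully
seeded. Ground-truth rates ride along in the metadata for recovery
tests. It does not emulate gel artifacts (background, saturation),
radioactive decay correction, or inter-gel calibration drift, so passing
recovery tests demonstrate estimator correctness under the stated error
model, not robustness to real gel pathology. Analytic reference curves
(Hill, linear, smoothed step) provide exact oracles for the RS metric
(e.g. RS = 3/8 for Hill n = 2).

## Problem sizes

Chosen so the full analysis suite runs comfortably on one CPU: default
scans use 120–150 grid points on k5 ∈ [0, 10] /s with slope refinement
(500 points via the CLI default for production curves); the
multistationarity screen uses 1000 draws per alternative architecture in
the test suite and 300 in the acceptance script, 10–12 multistarts each;
recovery fits use a 3-condition panel (A4 = 0, 20, 60 µM) on a 25-point,
12 s grid, with 20 noise replicates for the k11 error study.

## Known limitations

No spatial or cluster-localization effects (the in-vivo enrichment enters
only through the effective k1); no stochastic kinetics; no Hopf/
oscillation detection (none expected in this network); the numerical
multistationarity screen cannot prove impossibility; variant and
architecture rate defaults stand in for unavailable supplementary tables
and are flagged in provenance records rather than asserted as measured
values.
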