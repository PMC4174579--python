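# Methods

## The cis-inactivation model

A Notch receptor N and a DSL ligand D co-expressed in the same cell bind
reversibly into a cis complex that is irreversibly inactivated:

    N + D  <=>[kC+][kC-]  [ND]  ->[kI]  inactive

With production rates βN, βD and first-order removal γN, γD, the dynamics
of one cell are

    dN/dt = βN − γN·N − (kC+·N·D − kC−·C)
    dD/dt = βD − γD·D − (kC+·N·D − kC−·C)
    dC/dt = kC+·N·D − kC−·C − kI·C

Assuming the complex is at quasi-steady state (QSS), the cis flux becomes
N·D/kc with the single lumped constant

    kc = (kC− + kI) / (kC+ · kI),

and free receptor at steady state obeys the closed form

    N_ss = (βN/γN) / (1 + D_ss/(kc·γN)).

Two facts follow and anchor the test suite: N_ss(0) = βN/γN, and
N_ss(kc·γN) = N_ss(0)/2 — kc·γN is the half-depletion ligand level.
Because the cis flux at a fixed point satisfies dC/dt = 0 identically,
the reduced algebra describes the *exact* steady state of the full
three-variable system; the QSS assumption only matters for transients.
The solver/ODE-agreement checks therefore demand sub-percent agreement.

**Multi-ligand extension.** Several cis-ligands competing for one Notch
pool are modelled as independent cis reactions sharing N:

    βN   = N·(γN + Σℓ Dℓ/kcℓ),      βDℓ = Dℓ·(γDℓ + N/kcℓ).

Eliminating each Dℓ leaves a strictly increasing scalar function of N on
[0, βN/γN]; the solver uses the exact quadratic root for one ligand and
bracketed root finding (Brent) for more. No damping or iteration-budget
heuristics are needed because the bracket is guaranteed.

**Trans-activation.** A receptor on one cell and a ligand on a neighbour
form a fast complex (kD±) that produces signal at rate kS; at quasi-steady
state the signal flux is kS·kD+·N·D/(kD− + kS). Sender ligand is not
depleted by this flux — whether trans-bound ligand is recycled or consumed
is left open by the biology, and the non-depleting form is the simpler
committed choice.

**Fringe modulation.** Fringe glycosyltransferases act on the receptor and
re-weight its ligand interactions. We model them as multiplicative factors
on the *association* rates only (kC+, kD+), which makes modulation exactly
multiplicative and composable. Preset factors (direction fixed by the
biology, magnitudes a design choice, all config-overridable):

| preset | Dll1 cis | Dll1 trans | Jag1 cis | Jag1 trans | detection gain |
|--------|---------:|-----------:|---------:|-----------:|---------------:|
| none   | 1.0      | 1.0        | 1.0      | 1.0        | 1.0 |
| Lfng / Mfng | 2.0 | 2.0        | 0.2      | 0.2        | 1.5 |
| Rfng   | 1.5      | 1.5        | 1.5      | 1.5        | 1.5 |

The Drosophila preset `fng` uses Delta cis 2.0 / trans 5.0 and Serrate
cis 0.2 / trans 0.1: fly Delta signals poorly to Fringe-negative
receivers, which requires a stronger trans asymmetry than the mammalian
presets (see the boundary model below). `detection_gain` scales the
receptor-availability readout only — the soluble ligand-Fc reagent binds
the Fringe-modified receptor, so Fringe changes that channel's gain but
not the receptor-Fc readout of surface ligand.

All model units are dimensionless; conversion to fluorescence happens
only in the synthetic-data layer.

## The synthetic availability experiment

The generator emulates a tet-inducible ligand / constitutive receptor
cell line measured by the surface-availability assay:

1. The 4-epiTc dose d sets the *median* total-ligand fluorescence through
   a Hill curve T(d) = basal + T_max·d²/(d² + EC50²) with EC50 = 25 ng/ml,
   T_max = 3000, basal = 20 (defaults; induction levels 0/10/30/100 ng/ml,
   500 cells per level).
2. Cells spread log-normally around the median with σ = 0.5 natural-log
   units, reproducing the order-of-magnitude per-level spread seen in
   single-cell scatters.
3. Surface ligand in model units is efficiency·T (Dll1 0.010, Jag1 0.020
   per fluorescence unit — Jag1 reaches the surface more efficiently),
   imposed as the cell's unopposed ligand level βD/γD.
4. Free N and free L come from the cis steady state; the recorded
   availability is gain·(detection_gain·)N_free (or gain·L_free) times
   multiplicative log-normal noise of CV 0.10, plus Gaussian background
   (mean 50, sd 10), clipped at zero.

The generator kinetics put ligand in excess of receptor (βN/γN = 1 model
unit, kc·γN = 10 units), so free ligand tracks total ligand and the
forward availability curve is close to the hyperbolic fitting form
bg + A/(1 + L/L50). The ground-truth half-inhibition point is computed
from the same forward model by root finding, never assumed equal to
kc·γN/efficiency. What the generator does *not* emulate: receptor
trafficking, cell-cycle gating, spectral bleed-through, or the spatial
correlations of real imaging data — recovery tests therefore validate the
estimator under the stated noise model, not under every failure mode of
real data.

The dilution assay starts cells at 1000 model units of cis-ligand
(100× the half-depletion point) on plate-bound ligand at unit density;
after washout, ligand decays at ln2/18 h (division) + γD, frames every
20 min for 60 h. Reporter accumulation integrates the trans signal rate
at the instantaneous cis steady state (trapezoid rule).

## Image quantification

Segmentation: Gaussian smoothing (σ = 2 px) of the cytoplasm channel,
Otsu threshold (Li and mean available), connected components, area filter.
No watershed splitting — doublets are removed downstream by the area gate
and an isolation gate (minimum mask-to-mask gap, default 5 px), which
replaces the original protocol's irreproducible by-eye screening and is a
declared surrogate, not an inference of its criteria. Per-cell background
is the median of unsegmented pixels within a 20 px dilation annulus
(global unsegmented median as a flagged fallback); the per-cell mean is
the mean of background-subtracted pixels, negatives kept. Synthetic
fields render cells with exact in-mask intensity and a one-pixel soft rim
outside the mask, so measurement accuracy can be asserted to
floating-point on noise-free fields and to 5% under gradient background
and read noise.

## Statistics

* **Binned profiles** use log-spaced bins (default 12), per-bin medians
  and percentile-bootstrap 95% CIs (default 1000 resamples, seeded; bins
  with n < 10 flagged). Bin/boot counts are defaults of this package;
  only the 95% level is inherited from the protocol being emulated.
* **Effective total ligand**: ligand-only availability is regressed
  through the origin on total-ligand fluorescence; slope ratios rescale
  each ligand's axis so surface-expression efficiency differences cancel.
* **Cis-inhibition fits** run on single-cell points with equal weights
  (binning is presentation, not estimation) and by default on
  log-availability residuals, which stabilises the multiplicative
  measurement noise; plain least squares is a flag away.
* **Condition comparisons** use the two-sided Wilcoxon rank-sum test per
  bin with no multiple-testing correction by default (matching per-bin
  starring); Benjamini–Hochberg is available.
* **t_on** is the first time the smoothed reporter slope strictly exceeds
  10% of the final slope (final = mean slope over the last 20% of
  frames). Smoothing is a 3-frame moving average with centred
  differences: a wider window systematically fires earlier than the kink
  on a sharp onset (the symmetric support spreads the transition), and 3
  frames keeps the detector within one frame of a piecewise-linear onset
  while remaining robust at CV 0.1 reporter noise.

## Signaling states

A cell's capabilities derive from its multi-ligand cis steady state under
Fringe-modified parameters:

* receive from ℓ ⇔ N_free ≥ 0.1·(βN/γN) and the Fringe trans factor for
  ℓ is ≥ 0.5 (Lfng/Mfng block Jag1 trans-activation);
* send with ℓ ⇔ L_free,ℓ ≥ 0.2·(βDℓ/γD).

Sending demands a larger surviving fraction than receiving. This
asymmetry is forced by the model's structure: under the QSS algebra the
depleted fraction of the subordinate partner is identical in the
"receptor-dominant" and "ligand-dominant" endpoint configurations
(exactly dual under N↔L exchange), so with equal thresholds a weakened
cis interaction either lets a low-expressed ligand count as sending or
prevents a cis-weakened receptor from counting as receiving — never
neither. Setting the receive threshold below the send threshold encodes
that a receptor event is amplified by downstream transduction while
sending requires substantial surface-ligand density, and places the
Lfng-weakened depletion fraction (~0.15 with the default kinetics,
kc·γN = 2/3 model units, endpoint levels 20 and 0.5) between the two.
Both fractions are relative to the cell's own unopposed levels, making
classification invariant under joint rescaling of production rates and
kc.

The canonical endpoint set (2 ligands × {no Fringe, Lfng} × 2 dominance
directions = 8 configurations) yields a signaling graph with no
self-edges and no directed cycles. This is a *consequence* of strong
mutual cis-inhibition, not of the construction: with kc → ∞ a
co-expressing cell acquires a reported self-edge. The no-cycle property
is asserted only for the enumerated canonical set; arbitrary level
choices can violate it and violations are reported, never suppressed.

## Dorsal-ventral boundary model

A rectangular lattice (default 6×4, 4-neighbour coupling, no cell
movement) with dorsal rows expressing Notch (level 30), Delta (0.5),
Serrate (20) and Fringe, and ventral rows expressing Notch (20) and
Delta (0.5). Per step, each cell's free levels are re-solved from its
cis steady state; accumulated signal S integrates neighbour trans fluxes
(receiver-side Fringe factors) by forward Euler (dt = 0.02). Ventral
Delta production is up-regulated by 1 + 30·S²/(S² + 25²); the target-gene
threshold is S = 40.

These defaults were calibrated by forward simulation to sit in the
intended two-phase regime and give comfortable margins: dorsal free
Serrate (~4 units, cis-weakened by Fringe) activates the first ventral
row (crossing at t ≈ 3.2), whose Delta upregulation (free Delta rising
>10-fold) back-activates the first dorsal row (t ≈ 4.1) through the
Fringe-enhanced Delta response; flanking rows peak below 62% of
threshold. The feedback fold (30) is deliberately moderate so activated
ventral cells keep part of their free Notch and continue integrating
phase-1 signal; a much larger fold switches them to pure senders before
they reach the target-gene threshold. Dorsal-to-dorsal Delta signaling
is naturally negligible (free dorsal Delta ~0.02 units because Fringe
strengthens Delta cis-inhibition) rather than being forced to zero.
Removing dorsal Serrate abolishes all activation; removing dorsal Fringe
lowers dorsal free Notch (Serrate cis strengthens) and destroys the
interface stripe. Wingless/Cut feedbacks and later refinement stages are
out of scope; only the initial two signaling phases are modelled.

## Numerical choices and degenerate inputs

* Steady-state solves: closed-form quadratic (1 ligand) or Brent
  bracketed on [0, βN/γN]; residuals checked against 1e-10·scale.
* ODE cross-checks: LSODA, rtol 1e-10, atol 1e-12, integrated to
  ≥300/min(γ).
* kc is undefined (raised) when kC+ = 0 or kI = 0: no inactivation
  pathway exists.
* Fits flag non-identifiability (K or L50 outside the sampled range,
  flat data, all-zero signal) instead of failing.
* Empty bins carry n = 0 and NaN statistics; comparisons skip bins below
  n_min on either side.
* Traces with non-positive final slope return a flagged no-onset result.

## Problem sizes

Round-trip and calibration checks use 2000 cells per table (20 seeds),
100 random parameter sets for solver/ODE agreement, 1000 null replicates
for the rank-sum type-I rate, 200 replicates for bootstrap coverage, and
50-cell 512×512 synthetic fields — sizes at which every estimate above is
stable to well within its stated tolerance.
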