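# Methods

`sqt3sim` is a multiscale simulator of human ventricular electrophysiology
in short-QT syndrome variant 3 (SQT3, the Kir2.1/KCNJ2 D172N
gain-of-function channelopathy) and of the tonic action of amiodarone on
it.  This note records the models, the numerical choices, the calibration
that produced the committed constants, and the known limitations.

## Cell model

The single-cell model is the 2006 ten Tusscher–Panfilov human ventricular
formulation with its endocardial (ENDO), mid-myocardial (MIDDLE) and
epicardial (EPI) parameter sets, extended in two ways:

* **Late sodium current.** The O'Hara–Rudy I_NaL gating scheme
  (activation `mL`, inactivation `hL`, non-phosphorylated channels only,
  `tau_hL` = 200 ms) is grafted on, its Na⁺ flux added to the
  intracellular Na⁺ balance.  Its conductance is the donor model's
  endocardial value, G_NaL = 0.0075 mS/µF, for all three cell types:
  calibration showed no rescaling was needed — with this value the paced
  wild-type APD90 triple (see below) falls within 2% of the reference
  values.

* **Variant inward rectifier.** I_K1 keeps the baseline form
  `I_K1 = G_K1 sqrt(K_o/5.4) x_K1∞ (V − E_K)`.  A genotype is expressed
  through three constants acting on the rectification factor x_K1∞:
  a multiplicative scale `s`, and a rightward shift `ΔV` and steepness `k`
  of the rectification-cutoff exponential
  (`exp(k (u − 10 − ΔV))`, `u = V − E_K`; baseline k = 0.1 /mV).
  Shifting the *cutoff* (rather than the whole x_K1∞ curve) moves the peak
  of the outward limb to more positive voltages without inflating the
  current just above E_K, and leaves the reversal potential untouched —
  the experimental D172N phenotype.  See "Calibration" below.

Integration is forward Euler for voltage and concentrations and
Rush–Larsen exponential updates for all Hodgkin–Huxley gates, at
dt = 0.02 ms.  Gates stay in [0, 1] by construction and are never clipped;
numerical divergence (|V| > 300 mV) raises an error naming the time (and
node) rather than being masked.

## Calibration of the variant I_K1

The exact variant x_K1∞ coefficients used by the original SQT3 studies are
not public, so the package re-derives them from the constraints the
experimental literature fixes:

1. Under the simulated voltage clamp (holding −60 mV, 400 ms steps from
   −120 to +20 mV in 5 mV increments, K_o = 5.4 mM, K_i = 138.3 mM — the
   committed resting intracellular K⁺), the peak outward current must be
   2.2-fold (heterozygous WT-D172N) and 4.6-fold (homozygous D172N) the
   wild-type peak.  Given (ΔV, k), the scale `s` satisfying this is a
   closed-form ratio of grid maxima, so `calibrate_variants` is exact,
   deterministic and idempotent.
2. The mutant peak-current voltage must not sit left of the WT peak
   (rightward shift of the peak repolarizing current).
3. The paced APD90 of all nine genotype × cell-type combinations must
   land within 2% of the reference values (BCL 800 ms, 10 conditioning
   beats from the committed resting state):
   WT 302/406/304 ms, WT-D172N 273/357/274 ms, D172N 261/341/262 ms
   (ENDO/MIDDLE/EPI).

Constraints 1–2 fix one of three degrees of freedom; (ΔV, k) were chosen
once, per variant, to satisfy constraint 3 and committed to
`data/ik1_variants.yaml`:

| variant  | scale s  | ΔV (mV) | k (mV⁻¹) |
|----------|----------|---------|----------|
| WT       | 1.0      | 0       | 0.100    |
| WT-D172N | 1.601636 | 5.0     | 0.080    |
| D172N    | 3.171656 | 7.5     | 0.088    |

A pure scale+shift parameterization (k fixed at 0.1) cannot satisfy
constraint 3 for the heterozygote: with the peak fold pinned at 2.2 the
plateau-range current is too small to shorten the AP sufficiently,
whatever the shift.  Widening the cutoff (smaller k) supplies the missing
plateau-range current while the peak fold stays exact.

## Drug model

Amiodarone acts by tonic pore block: each affected conductance retains the
fraction `1 − θ = 1/(1 + ([D]/IC50)^nH)`.  The packaged registry
(`data/drugs.csv`) carries the literature IC50/nH pairs for I_Kr, I_Na,
I_NaK, I_CaL, I_NaCa and I_Ks; the published percentage table at the two
therapeutic doses (1 and 3 µM) is shipped verbatim
(`data/amiodarone_verbatim.csv`) and is the default for reproduction runs,
because the rows with non-unity Hill coefficients cannot be regenerated
exactly from the rounded printed constants (the differences are < 0.7
percentage points and presumably stem from unrounded nH values).  The
block factor for I_Na is applied to the fast sodium conductance only;
I_NaL is left unblocked, matching the published conductance table.

No pharmacokinetics, no state-dependent (use-dependent) block, no
temperature or pH dependence.

## Single-cell protocols

* Pacing: −52 pA/pF, 1 ms pulses at BCL 800 ms (1.25 Hz), 10 conditioning
  beats from the committed resting state (10 s of quiescent settling).
* APD90: from the instant of maximum dV/dt to 90% repolarization;
  amplitude = peak V − V immediately before stimulus onset; crossings
  linearly interpolated.
* ERP: smallest S1–S2 interval whose S2 response reaches peak V > 0 mV,
  found by a 5 ms coarse scan plus bisection to 0.5 ms.  S2 trials restart
  from cached full-state snapshots on a 0.5 ms grid, so the conditioning
  beats are simulated once.
* Restitution: APD-R varies the S2 coupling after 10 conditioning beats
  (reported against DI = coupling − APD90 of the conditioning beat);
  ERP-R re-measures ERP across BCLs (protocol: 50 conditioning beats per
  BCL, 300–1000 ms range).  Maximal slope = maximal forward finite
  difference, no smoothing.
* δV: pointwise difference of two aligned traces; its reported maximum is
  restricted to the repolarization window (later peak → later APD95).

## Tissue models

1D fiber: 15 mm, 100 nodes (dx = 0.15 mm), ENDO:MIDDLE:EPI = 25:35:40%,
monodomain with D = 8 × 10⁻⁴ cm²/ms, per-face coupling coefficients, and
the single MIDDLE–EPI junction face reduced fivefold (the sharp
gap-junctional resistance transition of the wall).  Explicit scheme
(D·dt/dx² ≈ 0.071, stable); no-flux ends; S1 on the three ENDO-end nodes.
Conduction velocity is the regression slope of interpolated −20 mV
upstroke crossings over nodes 10–54 (clear of the stimulus and the
junction); the default configuration yields ≈ 52 cm/s.

Pseudo-ECG: φ_e = (α²/4) ∫ (−∂V/∂x) ∂(1/r)/∂x dx with the electrode
2.0 cm from the ENDO end on the ENDO side, giving a negative QRS and a
positive T wave.  Spatial derivatives are central differences
(`np.gradient`), the integral a node sum × dx.  QT runs from stimulus
onset (beat 3 of BCL-800 pacing) to the last downward crossing of the
0.01 mV threshold after the T peak.  The strand radius only scales φ_e,
but through that absolute threshold it affects QT; α = 2.4 mm places the
threshold at ≈ 5% of the T-peak amplitude, where the absolute criterion
and the scale-free fallback (threshold = 5% of T peak,
`relative_threshold=0.05`) agree to within a few milliseconds — the
fallback is asserted in the tests to bound this sensitivity.

Vulnerability: one conditioning S1 wave, then a premature stimulus at the
ENDO or EPI segment at a scanned delay; sentinel re-activation of the two
fiber ends classifies bidirectional block / unidirectional block /
bidirectional conduction; the vulnerable window is the contiguous
unidirectional range (0.5 ms resolution; the bisection search is verified
against the exhaustive scan).  The premature segment is 15 nodes
(2.25 mm): with the S1-strength pulse, narrower segments cannot charge the
partially recovered tissue past threshold until ≈ 80 ms after local
repolarization (the slow j-gate recovery of the baseline Na⁺ current
combined with the electrotonic load), which would leave no unidirectional
window at all.  The 2.25 mm segment restores capture shortly after local
recovery and yields the block → unidirectional → conduction progression.

2D sheet: the fiber extended laterally to 75 mm (500 nodes), isotropic D.
Cross-field protocol: planar S1 from the ENDO edge; premature S2 strip at
the MIDDLE–EPI junction (3 nodes wide in x by default, configurable —
the re-entry demonstrations in the test suite use a 15-node strip for the
capture reason above), length growing from the y = 0 edge.  Outcomes:
*sustained* (any node above −40 mV at the 1500 ms horizon),
*self-terminated* (re-entry formed — some node re-excited after S2 — but
activity ceased earlier), *no re-entry*.  `min_s2_length` resolves the
smallest re-entry-forming strip length to 0.15 mm by bisection, with the
linear-decrement scan as the reference procedure (equivalent under the
monotone length effect).

## Problem sizes in the test suite

The unit/property suite runs single cells and the 100-node fiber at full
resolution.  The 2D checks use the laterally reduced sheet
(15 × 30 mm, 800 ms horizon) — the package's scaled-down configuration —
and small sheets for the dimensional-reduction and bookkeeping tests; the
full-size sheet (15 × 75 mm, 1500 ms) is reproducible through the shipped
`reentry-*` scenarios.

## Known limitations

* The re-derived variant I_K1 is calibrated to peak folds, shift direction
  and APD90 values; it is not a fit to the original Kir2.1 recordings
  (unavailable), so biomarkers that depend on fine I_K1 kinetics (exact
  vulnerable-window edges, re-entry induction delays) shift by ≈ 5–10 ms
  relative to the reference study.
* With the 2006 baseline model the amiodarone dose ordering of APD/QT
  prolongation is monotone (high dose prolongs more than low dose),
  because the slow, large epicardial I_Ks of this model revision makes the
  I_Ks block dominant; the reference study reports a slightly *smaller*
  high-dose prolongation (291 vs 289 ms APD90), consistent with a weaker
  I_Ks contribution in the model revision its code link hosts.  The
  affected reproduction checks are asserted, and fail, in the acceptance
  suite; all drug-effect *directions* (APD/ERP/QT prolongation, T-wave and
  dispersion reduction, vulnerability reduction) reproduce.
* At the published S2 delays and the 0.45 mm premature-strip width, the
  junction strip cannot capture in this model (Na⁺ recovery, above), so
  the printed 2D induction timings do not transfer; re-entry behaviour is
  demonstrated at this model's own vulnerable delays with the wider strip.
* Idealized isotropic 1D/2D geometry: no anatomical ventricle, no Purkinje
  system, no mechano-electric feedback, no fiber anisotropy.
* The synthetic I–V generator adds i.i.d. Gaussian noise to the model
  curve; real voltage-clamp recordings have correlated drift, seal leak
  and series-resistance artifacts, so the parameter-recovery tests bound
  estimator behaviour only under the idealized noise model.
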