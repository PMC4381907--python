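# Methods

## The gating model

The channel is a pore (closed C / open O) coupled to four identical,
non-cooperative voltage-sensing domains (VSDs), each in a resting (R),
intermediate (I), or activated (A) conformation.  Counting VSDs rather
than labelling them gives 15 VSD-count combinations and, with the pore
factor, 30 channel states.

Two parameter families define the kinetics:

* **Intrinsic rates k.**  Each VSD undergoes two sequential transitions
  (R↔I, I↔A) with voltage-dependent rates
  `k(V) = k0 · exp(z F V / R T)` (k0 in s⁻¹ at 0 mV, z the equivalent
  valence in elementary charges, V in volts internally, mV at every
  interface).  The pore opens and closes with voltage-independent rates
  `k_co`, `k_oc`.  These are the rates the domains would show if they were
  completely decoupled — the model's reference state.
* **Coupling strengths θ.**  One dimensionless factor per
  (VSD conformation, pore conformation) pair: θ_RC, θ_IC, θ_AC, θ_RO,
  θ_IO, θ_AO.  θ_XP > 1 stabilizes the X–P pair, and every transition that
  *leaves* a stabilized pair is slowed by it:
  * a VSD step X→Y under pore state P runs at `n(X) · k_XY(V) / θ_XP`
    (the multiplicity n(X) counts eligible VSDs);
  * pore opening runs at `k_co / (θ_RC^nR · θ_IC^nI · θ_AC^nA)` and
    closing at `k_oc / (θ_RO^nR · θ_IO^nI · θ_AO^nA)`.

Dividing departure rates by the θ of the pair being left makes the chain
reversible by construction.  The stationary distribution has closed-form
Gibbs weights

    w(P, n) ∝ multinomial(4; nR, nI, nA) · K_RI(V)^(nI+nA) · K_IA(V)^nA
              · [K_CO if open] · θ_RP^nR · θ_IP^nI · θ_AP^nA

with K_xy = k_xy/k_yx and K_CO = k_co/k_oc, evaluated in log space so
extreme voltages cannot overflow.  The tests verify edgewise detailed
balance against these weights, the Kolmogorov product criterion on a cycle
basis of the state graph (the log-product over any simple cycle is an
integer combination of basis-cycle log-products, so the basis check covers
every cycle), agreement of the closed form with the rate-matrix nullspace,
and agreement of the whole aggregated model with an independently coded
162-microstate labelled-VSD implementation.

A gauge freedom exists: scaling all closed-state θ by a constant is
equivalent to rescaling `k_co` (likewise open-state θ and `k_oc`).  The
defaults fix θ_RC = θ_RO = 1, making the resting VSD the coupling
reference.

Deliberately out of scope, as in the biology the model idealizes:
inactivated states, subconductance levels, lipid-binding (PIP₂) occupancy
states, VSD–VSD cooperativity, and accessory-subunit stoichiometry.  All
open states share one conductance.

## Simulation

Protocols are piecewise-constant command-voltage segments from a −80 mV
holding potential.  Within a segment the occupancy follows
`p(t) = p(t0) · expm(Q(V) Δt)`, computed by eigendecomposition of the
30×30 rate matrix (exact in time, no step error) with an iterated
scaling-and-squaring fallback when the eigenvector matrix is
ill-conditioned (condition number > 1e10).  Macroscopic observables:

* current `I = N · g_ion · P_open · (V − E_rev,ion)` (ohmic driving
  force; per-ion conductance and reversal potential configurable; the
  K⁺/Rb⁺/Na⁺ conditions differ only in g and E_rev);
* fluorescence `F = Σ_states p(state) · (n_I f_I + n_A f_A)/4` with
  default weights f_I = 0.8, f_A = 1.0, so the first VSD step carries
  most of the optical signal and the second step adds the remainder.

GV curves are instantaneous tail currents (open probability at the end of
a 4 s test pulse times the tail driving force) normalized to the
highest-voltage pulse; FV curves are end-of-pulse fluorescence referenced
to the holding-potential equilibrium fluorescence — the model counterpart
of a baseline-corrected ΔF/F — normalized the same way.  Each GV/FV point
carries an equilibration flag (relative change of P_open over the final
5% of the pulse below 1e-4); 4 s pulses equilibrate the default baseline
but not every perturbed set, which is reported rather than hidden.

## Default parameter values

No published table of rate constants informs these defaults; they are the
package's own choice, tuned once to reproduce the qualitative phenotype of
homomeric KCNQ1 and then frozen:

| parameter | value | meaning |
|---|---|---|
| k_RI | 35 s⁻¹, z = +0.8 | fast first VSD step, half-point ≈ −50 mV with the reverse rate |
| k_IR | 1.5 s⁻¹, z = −0.8 | |
| k_IA | 2.0 s⁻¹, z = +0.7 | slow second VSD step, half-point ≈ +25 mV |
| k_AI | 7.8 s⁻¹, z = −0.7 | |
| k_CO / k_OC | 6 / 300 s⁻¹ | intrinsic pore equilibrium biased closed (P_open = 0.02 decoupled) |
| θ_IC, θ_AC, θ_RC, θ_RO | 1 | closed-state interactions neutral; resting is the gauge reference |
| θ_IO | 2.3 | the intermediate state already promotes opening |
| θ_AO | 2.7 | the activated state promotes it slightly more |
| N, g_K, E_rev | 1000, 1.0, −80 mV | current scale only |
| T, F, R | 298.15 K, 96485.332 C/mol, 8.31446 J/(mol·K) | thermal voltage RT/F ≈ 25.7 mV |

This yields: GV V½ ≈ −27 mV overlapping the low-voltage FV component
(V½ ≈ −52 mV) rather than the high one (≈ +23 mV); a biphasic current
onset (τ ≈ 64 and 177 ms at +40 mV, bi-exponential strongly preferred
over mono); resting open probability ≈ 0.04 at −80 mV; maximal open
probability ≈ 0.5.

## The KCNE1 experiment

The accessory subunit is modelled purely as a perturbation of two coupling
strengths — θ_IC ×20 (the intermediate-closed pair is stabilized, so the
pore stays shut while VSDs are intermediate) and θ_AO ×5 (the
activated-open pair is stabilized) — with every intrinsic rate untouched.
Five directional signatures are quantified against the baseline, each
flagged true only beyond a 2 mV (or equivalent) slack:

1. GV right shift (here +109 mV);
2. reassignment of the GV from the low- to the high-voltage FV component
   (nearest-fitted-V½ rule, ties within 2 mV flagged ambiguous);
3. current-onset delay, measured fit-free as the time for the current to
   reach 10% of its end-of-pulse value at +40 mV (5 → 770 ms);
4. maximal steady-state current fold change over the voltage family
   (×1.76);
5. left shift of the low-voltage FV component (−47 mV, close to the
   per-VSD prediction −(RT/q₁F)·ln 20 ≈ −48 mV for a first-step charge of
   q₁ = 1.6 e₀).

The counterfactual replaces the θ_IC strengthening with a θ_IO weakening
of the same size (÷20), keeping the θ_AO change: opening decouples from
the first VSD step just the same (the open/closed bias of an
intermediate-state VSD is θ_IO/θ_IC, so dividing one mirrors multiplying
the other), and signatures 1–4 still trigger, but signature 5 does not
(+1.3 mV): weakening an open-state interaction leaves closed-state
stabilities — which set the low-voltage VSD equilibrium while the pore is
shut — untouched.  A pure θ_IO weakening without the θ_AO change produces
signatures 1–3 but cannot raise the maximal current; the θ_AO term is kept
in both arms so the contrast isolates the θ_IC-vs-θ_IO question.

Signature FV fits constrain the two-component amplitude split to the
structural fluorophore ratio f_I : (f_A − f_I) (with one free overall
scale and a free baseline, since ΔF/F referenced to −80 mV can be negative
at hyperpolarized steps).  Free-amplitude two-component fits misattribute
components on these smooth curves: a model-free reading of the FV foot
confirms the constrained fits and contradicts the free ones.

## Synthetic recordings

The generator emulates two-electrode voltage clamp with simultaneous
fluorometry: 1 kHz sampling, fluorescence low-pass filtered at 200 Hz
(implemented zero-phase, 2nd-order Butterworth, to avoid phase lag that
would bias kinetic fits — a documented deviation from a true analog
filter), additive Gaussian noise per channel (defaults 1% of max |I| and
2% of max ΔF; the paper-scale noise magnitudes are not published, these
are calibration choices), a 2 s holding-potential pre-pulse for the
baseline window, and a linearly bleaching fluorescence baseline
(−0.5%/s) multiplying (1 + 0.05·F_model), which is what a photodiode
reports.  XE991 block is phenomenological: the drug-condition current is
the control current times `1 − f(c)·(1 − exp(−t/τ_block))` with
f(c) = f_max·c/(c + IC50), Hill coefficient 1, τ_block = 500 ms,
mimicking slowly developing block without claiming a mechanism.  Rb⁺/Na⁺
conditions change only per-ion conductance (default g_Rb/g_K = 0.7) and
reversal potential.  Every output is a pure function of (parameters,
protocol, acquisition spec, seed); each experiment ships a manifest of
all generating values.

Not emulated, hence untested by passing round trips: capacitive and leak
currents, series-resistance error, endogenous oocyte conductances,
labelling efficiency, open-state-dependent permeation differences, and
real photon-shot noise statistics.

## Analysis estimators

* **ΔF/F**: line fit to the 2 s pre-pulse fluorescence at holding,
  extrapolated; ΔF/F = (F − baseline)/baseline.  Exact for any
  multiplicative signal on a linear baseline.
* **Instantaneous tail amplitude**: two-component exponential fit over
  0–100 ms after the tail step, extrapolated to the step time (the two
  components absorb the fast pore and slower VSD relaxations; deterministic
  multi-starts over τ, best residual wins, flagged first-sample fallback).
  A mono-exponential over a late window (20–300 ms) was measured ~2%
  biased on normalized GV against simulator truth and is available but not
  default.  FV end-of-pulse values are averaged over a 40 ms window ending
  10 ms before the tail step, outside the zero-phase filter's backward
  smear.
* **Boltzmann fits**: sums of `a/(1+exp(−zF(V−V½)/RT))`, 1 or 2
  components, deterministic multi-starts over a coarse (z, V½) grid, ties
  broken toward the lower main-component V½; optional fixed amplitude
  ratio and baseline.  The lower-V½ component of a double fit is "main",
  the other "high".
* **Exponential kinetics**: onset `y0 + Σ aᵢ(1−exp(−t/τᵢ))` or decay
  form, fast component first, degenerate (zero-amplitude) and
  τ-exceeds-segment flags; mono-vs-bi selection by extra-sum-of-squares
  F-test at α = 0.01.
* **Permeability ratio**: ratio of instantaneous tail amplitudes
  (Rb⁺ over K⁺) on a shared protocol — an operational tail-amplitude
  ratio, not a GHK permeability.
* **Hill fit**: `f = f_max · c/(c + IC50)` with coefficient fixed at 1.

## θ-factor recovery and its identifiability

`recover_perturbation` fits multiplicative factors on chosen θ parameters
(log-space, positivity structural) to GV/FV tables with every k fixed,
via bounded least squares; standard errors from the residual curvature,
and a flat Jacobian direction is reported as non-identifiable.  When the
GV table carries raw tail amplitudes the fit uses them (N and g are known
in the simulation world): the absolute current scale is the principal
observable for θ_AO, which pure normalization discards.

Noiseless tables return the generating factors to machine precision.  At
2% noise the θ_AO likelihood flattens above the voltage range's
open-probability saturation point — increasing θ_AO further changes no
observable — so its estimate has a heavy upper tail; θ_IC stays sharp
(±3% per replicate set).  Averaging extracted tables over 10 seeded
replicate experiments (the standard multi-cell averaging of this field)
on a 10 mV grid recovers θ_IC to ~0.1% and θ_AO to ~10–15% for typical
seed sets, but occasional noise realizations still prefer arbitrarily
large θ_AO; the reported standard error and identifiability flag convey
this.  This is a property of the observables, not of the optimizer: the
fluorescence high component cannot rescue it because, in the perturbed
channel, the I→A step is taken almost entirely while the pore is closed,
where θ_AO plays no role.

## Numerical choices

* Rate-law exponents clamped at |zFV/RT| = 700 with a warning.
* Occupancies clipped at 0 and renormalized after propagation (round-off
  only; conservation is checked to 1e-9 in tests).
* Stationary solves warn above condition number 1e12.
* Simulated curve problem sizes: 12-voltage families (−120…+100 mV,
  20 mV steps) for signatures, 23-voltage (10 mV) for recovery; 4 s
  pulses at 1 kHz for recordings, 80-sample internal grids for
  steady-state tables, where only the pulse-end values matter because
  propagation is exact.

## Known limitations

* The default parameter set is a qualitative stand-in, not a fit to any
  published recordings; quantitative agreement with experimental IKs
  curves is not claimed anywhere.
* The ohmic current model cannot express the open-state-dependent
  permeation and pharmacology that motivate the Rb⁺/K⁺ and inhibitor
  experiments biologically; the analysis chain treats those as given
  conductance ratios and block fractions.
* θ_AO recovery above saturation is weakly identified (above).
* The F-test model selection assumes independent Gaussian residuals; on
  low-pass-filtered fluorescence its p-values are optimistic and it is
  used only as a labelled convenience rule.
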