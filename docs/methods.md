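# Methods

## Scope and model

The package analyses a two-state, fast-exchange interaction between an
isotopically labelled disordered receptor peptide (observed by ¹⁵N-HSQC)
and an unlabelled folded ligand titrated into it. Three independent
readouts are implemented: weighted chemical-shift perturbations with a
depletion-model affinity fit, ¹⁵N relaxation (R1/R2) with ΔR2 segment
mapping, and chemical-shift-index secondary structure. All residue
numbering is the parent protein's own (murine 18.5 kDa MBP; the bundled
construct spans S38–S107) and is never renumbered internally.

## Chemical-shift perturbation

The per-residue observable is Δδ = sqrt(Δδ_H² + w·Δδ_N²) with w = 1/4
by default. The ¼ nitrogen weighting is the common amide convention;
because other weightings circulate (e.g. (Δδ_N/5)²), `w` is an explicit
parameter everywhere, including the peak-tracking metric.

Peak tracking runs only between adjacent titration points (fast
exchange moves peaks continuously, so adjacent displacements are small
even when apo-to-endpoint displacements are not), greedily in order of
increasing weighted distance, with a 0.15 ppm default cutoff; assigned
labels, when a spectrum carries them, override geometry. Trajectories
broken by an unmatched step are truncated with a warning and excluded
from profiles at later points.

## Binding isotherm and fitting

With receptor at P = 0.8 mM and micromolar K_D the ligand is
substantially depleted, so the fraction of sites bound is the physical
root of (F − C)(nP − C) = K_D·C, i.e.

f = [F + nP + K_D − sqrt((F + nP + K_D)² − 4·F·nP)] / (2·nP),

evaluated in the numerically stable form 2F/(b + sqrt(b² − 4FnP)) with
the exact limit f = min(F, nP)/nP at K_D = 0.

Fits are done in CSP space (csp_i = Δδ_max·f_i) rather than on
pre-normalised saturation values: dividing by a noisy endpoint would
distort the error structure, while the fractional-saturation view
remains available as a post-fit transformation (normalising either by
the fitted amplitude, default, or by the final point). Parameters are
bounded — K_D ∈ (0, 1 M], n ∈ (0, 4], Δδ_max ∈ (0, 10 ppm] — and the
optimiser restarts from K_D ∈ {0.1, 1, 10, 100 μM}, keeping the lowest
cost. The multistart-plus-bounds design is deliberate: in the
tight-binding regime (K_D ≪ P) the cost surface develops a flat valley
toward K_D → 0 and a degenerate large-K_D/large-amplitude ridge, and an
unconstrained optimum occasionally lives on that ridge. Fits with
K_D < P/50 carry a tight-binding warning; affinities from such data are
order-of-magnitude estimates by the nature of the experiment, not of
the optimiser. Reported uncertainties are asymptotic standard errors
from the Jacobian at the optimum. Stoichiometry can be fitted or fixed
(both modes are first-class, since saturation experiments at P ≫ K_D
constrain n far better than K_D).

The global fit shares (K_D, n) across residues with free per-residue
amplitudes and exposes the reduced χ²; on residues simulated with
genuinely different affinities the residual floor rises by an order of
magnitude, which is the intended diagnostic against over-pooling.

## Relaxation and NOE

Rates come from 2-parameter fits of I(t) = A·exp(−R·t) — no baseline
term by default (an offset variant exists but is off, matching plain
exponential fitting of peak heights). Delay schedules are shipped as
constants: R1 at 1.6–1200 ms (9 points) and CPMG total relaxation
delays 64–250 ms (6 points), interpreted as single effective R2 values
(no dispersion analysis). The initial rate guess
ln(I_first/I_last)/Δt is clipped to [10⁻³, 10³] s⁻¹; optimiser
tolerances are set to 10⁻¹⁴ so that noiseless round trips are exact to
machine precision and a constant series fits R = 0 exactly. Ensemble
summaries (min/max/mean) cover converged fits only.

NOE = I_sat/I_unsat with first-order error propagation from
user-supplied per-spectrum noise levels; the propagated error matches
Monte-Carlo within 5% for relative intensity errors up to 5%, which is
the regime the linearisation is valid for.

## Segment calling

Binding segments are maximal runs of residues whose statistic (CSP, or
ΔR2 with errors combined in quadrature) exceeds a threshold; the
default rule is mean + 1 SD of the profile (population SD), with
`mean` and `absolute` as alternatives and min_run = 3 exceeding
residues. Two bridging rules differ on purpose: residues entirely
absent from a profile (prolines have no amide; unassigned residues
carry no evidence) are bridged regardless of how many occur in a row —
a Pro-Pro-Pro stretch must not split a binding region — whereas
*measured* sub-threshold residues are bridged only one at a time, and
the ΔR2 caller additionally caps such interior exceptions at two per
run (single residues inside a binding region can stay fast without
disqualifying the region). Intervals are reported closed, 1-based, in
sequence numbering.

## Chemical-shift index

Secondary shifts are δ_obs − δ_coil per nucleus (Cα, Cβ, C′, Hα)
against a bundled random-coil table compiled from the classical
CSI-era ¹H/¹³C random-coil literature (Wishart and co-workers); the
table is plain data and swappable. Ternary indices use cutoffs 0.7 ppm
(carbons) and 0.1 ppm (Hα); downfield Cα/C′ votes helix, downfield
Cβ/Hα votes sheet, sub-cutoff votes coil, consensus is a strict
majority with ties to coil, and only residues with ≥ 2 available nuclei
are classified. Two limitations are stated plainly: classical CSI has
no poly-proline-II class, so the strongest statement it supports for a
disordered ligand is "no helix/sheet signal"; and its coil percentages
are not comparable with trained propensity predictors, which solve a
different problem.

## Peptide properties

Average mass is the sum of IUPAC average residue masses plus one water
(18.01528 Da) — the quantity MALDI-TOF reports — making mass exactly
additive over concatenation. Net charge is a Henderson–Hasselbalch sum
over D/E/C/Y/H/K/R and both termini; the default pKa set is
Bjellqvist's (with residue-specific terminal corrections), EMBOSS
selectable; pI is found by root bracketing on [0, 14] to 10⁻³ pH.
An integer formal charge (K+R − D−E) is reported alongside the
titration value, since printed "net charge" figures are often the
former. For the bundled construct the two give +7.8 and +8 at pH 7.

## Synthetic data: what it emulates and what it does not

The generator produces exactly the observables the estimators consume:
per-point assigned peak lists at apo + f·Δδ_max with Gaussian shift
noise (σ_H, σ_N), exponential decays with Gaussian intensity noise, and
NOE intensity pairs. Fraction bound is computed by bisection on the
mass-action equilibrium — a deliberately different route from the
closed-form quadratic used in fitting — so round-trip agreement to
1e-4 is a genuine two-implementation cross-check, not an identity.

The default titration scenario encodes the study design: the 70-residue
construct at 0.8 mM, ratios (0, 0.1, 0.2, 0.4, 0.5, 0.6, 0.7, 0.8, 1.0,
1.1, 1.2), K_D 5 μM, n = 1, and a two-tier amplitude profile — weighted
Δδ_max 0.12 ppm over residues 62–68 and 0.15 ppm over 83–99, zero
elsewhere — chosen so the default mean+1SD threshold separates both
tiers from baseline (for the two-tier profile, mean + SD ≈ 0.11 ppm
after scaling by the endpoint saturation of ~0.97). Apo shifts are
drawn once, with a fixed internal seed, from the poorly dispersed
windows of a disordered peptide (¹H 7.7–8.6 ppm, ¹⁵N 105–130 ppm); the
user seed controls only measurement noise. The relaxation scenario
draws free-state R1 in 0.87–2.2 s⁻¹ and R2 in 1.1–5.0 s⁻¹ and elevates
bound-state R2 by 3 s⁻¹ over the same two regions except residues 85
and 92, which stay fast — exercising the exception tolerance of the
ΔR2 caller.

Not emulated: linewidths, exchange broadening and intermediate/slow
exchange behaviour, peak overlap and mis-tracking from spectral
crowding, baseline and phasing artefacts, receptor dilution over the
titration. Passing round trips therefore validate the estimators under
the stated fast-exchange, two-state model — they do not certify
performance on pathological spectra.

## Numerical and statistical choices

* Optimiser tolerances 10⁻¹⁴ (both fitters) so noiseless round trips
  are limited by arithmetic, not stopping rules; the equilibrium
  bisection runs at machine precision, and the closed form agrees with
  it to < 10⁻¹⁰ over nine orders of magnitude of K_D.
* The stochastic K_D-recovery suite fits with n fixed at 1 (the
  saturation design determines n robustly; freeing it under noise tests
  a different, worse-conditioned problem). The recovered-K_D
  distribution at the experimental noise level (σ = 0.005 ppm on
  amplitudes of ~0.12 ppm, K_D 40–200× below the receptor
  concentration) is heavy-tailed in both directions, so the suite
  checks the *median* of recovered/true ratios and estimates it from
  1500 replicates per truth value — enough that the Monte-Carlo error
  of the median is small against the 25% acceptance band.
* Rate-recovery checks pair each truth with the schedule a
  spectroscopist would use for that timescale: the R1 schedule for
  1–2 s⁻¹, the CPMG schedule for 5–10 s⁻¹.
* Degenerate inputs fail loudly and early: flat trajectories, profiles
  with no residues, decay series that are mostly non-positive, zero
  unsaturated NOE intensity, non-monotone ratio schedules.
* Duplicate NMR-STAR shift rows keep the first occurrence (warned);
  sequence gaps in sparse shift tables are filled with 'X' and treated
  as unknown rather than inconsistent.

## Known limitations

Single-site two-state model only (no cooperativity or multi-site
binding); no line-shape or relaxation-dispersion analysis; no
model-free dynamics interpretation of R1/R2/NOE; no neighbour-corrected
random-coil model for CSI (hook available by swapping the reference
table); receptor concentration assumed constant over the titration.
Whether CSP profiles are taken at the 1:1 point or the final point is
configurable (default: final point).
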