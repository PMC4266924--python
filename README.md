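# nmrbind

Analysis pipeline for solution-NMR titration studies of an intrinsically
disordered peptide binding a folded domain, built around the interaction
of the myelin basic protein (MBP) xα2 peptide (murine 18.5 kDa MBP
residues S38–S107) with an SH3 domain. It is written for NMR
spectroscopists and structural biologists who have per-titration-point
²D ¹H–¹⁵N peak lists, relaxation decay tables and assigned backbone
shifts, and want per-residue binding parameters and binding-site maps
out the other end.

## What it computes

**Weighted chemical-shift perturbation (CSP).** For each backbone amide
followed across a titration,

    Δδ = sqrt( Δδ(¹H)² + ¼·Δδ(¹⁵N)² )

relative to the apo spectrum (nitrogen weight configurable). Peaks are
tracked between *adjacent* titration points by greedy nearest-neighbour
matching in this metric, so continuously moving fast-exchange peaks are
followed even when total displacements are large.

**Ligand-depletion binding isotherm.** The receptor is at 0.8 mM —
orders of magnitude above a micromolar K_D — so the free-ligand
approximation fails and saturation follows the binding quadratic

    f = [F + nP + K_D − sqrt((F + nP + K_D)² − 4·F·nP)] / (2·nP)

with F the total ligand, P the total receptor and n the stoichiometry.
Per-residue curves csp = Δδ_max·f are fit by bounded multistart
least squares for (K_D, n, Δδ_max); a global variant shares K_D and n
across residues.

**¹⁵N relaxation and NOE.** R1/R2 from mono-exponential fits of
intensity decays I(t) = A·exp(−R·t) at the standard delay schedules,
steady-state heteronuclear NOE ratios I_sat/I_unsat with first-order
error propagation, and binding-segment calls from ΔR2 = R2_bound −
R2_free profiles (tolerating isolated fast residues inside a segment).

**Chemical-shift-index (CSI) secondary structure.** Classical ternary
indices of Cα/Cβ/C′/Hα secondary shifts against a bundled random-coil
table, majority-vote consensus per residue, class fractions — the check
that a disordered peptide stays disordered (no helix/sheet signal) upon
binding.

**Peptide properties.** Average mass, Bjellqvist/EMBOSS isoelectric
point, Henderson–Hasselbalch net charge, and sample molarity.

A seeded synthetic-data generator (`nmrbind.synthetic`) produces
ground-truth-known inputs for every stage — fast-exchange peak lists
(fraction bound obtained by an independent mass-action bisection solver,
not the fitting formula), exponential decays and NOE pairs — so the
entire pipeline is testable end to end without any spectrometer data.

## Worked example

```bash
python analysis/01_simulate_titration.py      # write synthetic titration
python analysis/02_csp_profile_and_segments.py
python analysis/03_binding_fits.py
python analysis/04_relaxation_and_noe.py
python analysis/05_csi_and_properties.py
```

prints, for the default scenario (K_D 5 μM, 1:1, 0.8 mM receptor,
ratios 1:0 → 1:1.2):

```
binding segments (mean+1SD, min run 3): [[62, 68], [83, 99]]
Y65: K_D = 5.00 uM, n = 1.00, ddmax = 0.120 ppm
T95: K_D = 5.00 uM, n = 1.00, ddmax = 0.150 ppm
global fit: K_D = 5.00 uM (n = 1.00)
dR2 segments: [[62, 68], [83, 99]]
CSI class fractions: {'helix': 0.0, 'sheet': 0.0, 'coil': 1.0}
construct: 7642.4 Da, pI 11.34, charge(pH 7) +7.81 (integer +8)
3 mg in 500 ul -> 0.785 mM
```

Two binding segments are recovered from both the CSP and the ΔR2
channel: the dominant proline-rich region (83–99, prolines bridged) and
a moderate upstream segment (62–68); the per-residue fits return the
simulated affinity and stoichiometry exactly on noiseless input; the
disordered control classifies as pure coil; and the construct's
sequence-derived mass, pI and charge match its printed
characterization. The same pipeline is available as a CLI
(`nmrbind simulate|csp|fit|relax|noe|csi|props|run-all`); real peak
lists in SPARKY or CSV form drop in via the same YAML config.

## Layout

- `src/nmrbind/` — library: `io` (peak lists, NMR-STAR, FASTA, YAML),
  `csp`, `binding`, `relaxation`, `csi`, `peptide`, `synthetic`,
  `pipeline`, `cli`
- `analysis/` — numbered drivers reproducing the study's analyses
- `tests/` — unit, property and acceptance suites
- `docs/methods.md` — models, parameter choices and limitations
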