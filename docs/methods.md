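# Methods

## Scope and model

`sasbead` evaluates small-angle X-ray and neutron scattering intensities of
biomolecular conformations at two resolutions that share the Debye equation
I(q) = ΣᵢΣⱼ Fᵢ(q)Fⱼ(q) sinc(q rᵢⱼ):

* **Atomistic** (the reference): per-atom contrast amplitudes
  f′ᵢ(q) = φᵢ(q) − ρ·gᵢ(q), where φᵢ is the Cromer–Mann amplitude (X-rays,
  argument convention s = q/4π) or the flat coherent neutron length bᵢ, and
  gᵢ(q) = ν·exp(−ν^{2/3}q²/4π) is the displaced-solvent Gaussian
  (Fraser–MacRae–Suzuki form, the convention CRYSOL and FoXS use) with
  displaced volume ν.
* **Coarse-grained**: one bead per amino acid, three per nucleotide
  (phosphate / pentose sugar / base, with dedicated 5′-OH and 3′-OH terminal
  sugar types and three histidine protonation types HISD/HISE/HISP). Bead
  form factors come from the single-bead approximation — the orientationally
  averaged intra-bead Debye sum — decomposed into three solvent-density-free
  terms, F²(q;ρ) = A(q) − ρ·Mx(q) + ρ²·S(q). The decomposition is an exact
  algebraic identity (verified to machine precision in the tests), so term
  tables computed once serve any solvent density, any per-bead
  solvation-layer decrement, and both H- and D-substituted neutron variants.

F(q;ρ) = √max(F²,0); clipping is logged if it ever activates (it does not on
the bundled fixtures at aqueous densities). Note the square root discards
the sign of the bead amplitude; beads with strongly negative net neutron
contrast (hydrogen-rich beads in H₂O) are therefore the least accurate part
of the SANS path — the same limitation the underlying approximation has in
all bead-based scattering models.

## Parametrization

Term curves are averaged over every bead instance of a type pooled across
ensemble frames (instance-weighted; for balanced ensembles this equals the
frame-mean of means). Each of A, Mx, S is fitted with an ordinary
least-squares sixth-order polynomial in q over the parametrization grid —
201 points from 1e-10 to 0.5 Å⁻¹ in steps of 0.0025 (the first point stands
in for q = 0, where sinc is series-guarded). 3 × 7 = 21 coefficients per
bead type and mode (SAXS, SANS-H, SANS-D) are stored in a versioned JSON
parameter file with bit-exact round-tripping. Evaluation outside the fitted
q range raises instead of extrapolating. The averaging of F² (not F) across
frames is forced by the decomposition: only the squared form admits
ρ-independent precomputation.

Bead types averaged from fewer than 10 instances get a provenance warning
(the synthetic test fixtures legitimately run with `min_instances=1`).

## Bead centers

Mapping computes mass-weighted bead centers (geometric optional). For
intensity evaluation, however, the engine defaults to the **zero-angle
contrast-weighted center**: each atom weighted by φ(0) − ρ·ν (mode- and
ρ-aware, falling back to the mass center if a bead's net contrast vanishes).
At that point the dipole term of the bead's multipole expansion is zero. The
difference matters: carbon is nearly contrast-matched in water, so mass and
scattering centers differ by ~1 Å, and on the 20-residue helix fixture the
choice moves the worst residual against the atomistic reference at
q = 0.3 Å⁻¹ from ≈13 % (mass centers) to ≈1.5 % (contrast centers).
`center="mapped"` restores the mapped centers (used e.g. by the
finite-difference gradient tests).

## Hydrogens

Structures with and without explicit hydrogens are both legal. When any H is
present, every atom scatters individually (explicit-H mode). Otherwise heavy
atoms become united-atom groups: Cromer–Mann Gaussians concatenate
(f_CH2 = f_C + 2f_H exactly), volumes and neutron lengths add, with implicit
H counts taken from embedded residue topology tables (terminal hydroxyls and
the N-terminal ammonium are position-aware). For SANS parametrization the
SANS-H/SANS-D term sets substitute every bead hydrogen — explicit or
implicit — with b_H or b_D; at evaluation time solvent-exposed beads use the
D set with probability equal to the buffer D₂O fraction (one seeded draw per
bead per evaluation), or the two F² sets are mixed linearly in d in
`deterministic_hd` mode for reproducible pipelines. Atomistic SANS honours
per-atom isotope tags; solvent-exchange of labile hydrogens at the atomistic
level is left to the caller.

## Solvation-layer correction and SASA

The hydration shell is denser than bulk water; the model mimics the extra
scattering by letting solvent-exposed beads see a decremented density
ρ = ρ₀ − SLC. Exposure is decided per bead: per-atom LCPO
(linear-combination-of-pairwise-overlaps) areas, summed over the bead and
compared against the cutoff SC in nm² (1 nm² = 100 Ų; all internal areas are
Ų). Presets SLC = 0.08 e Å⁻³ / SC = 0.7 nm² (protein) and 0.12 / 0.8 nm²
(nucleic) reflect common practice; the correction is always opt-in. For SANS
the same decrement is applied to the neutron solvent density in that mode's
units (fm Å⁻³) — a pragmatic choice, flagged here, since the two densities
are not unit-compatible and no rescaling rule is established.

LCPO parameters are the published four-parameter fit per atom class; classes
resolve from element + bonded heavy-neighbor count (distance bonding, 1.9 Å
cutoff, 2.2 Å when S/P involved) with name-based sp2/carboxylate overrides
for standard residues. Hydrogens carry zero area. Atoms with no bonded
neighbors use the exact isolated sphere minus first-order pairwise overlap
(exact for isolated atoms and non-bonded pairs). The independent numerical
oracle is an in-repo Shrake–Rupley implementation on a deterministic
Fibonacci point set (default 960 points/atom). On the bundled fixtures LCPO
totals agree with the oracle to better than 10 % with per-atom correlation
> 0.95, the published accuracy class of the method. SASA flags are frozen
within a single intensity + gradient evaluation; forces from SASA changes
are neglected.

## Gradients

∂I(q)/∂R_bead is analytic from the Debye kernel derivative
(sinc′ series-guarded below x = 1e-4), with SASA flags and H/D draws frozen.
Central-difference agreement is ≤ 1e-5 relative; gradients sum to zero per q
by translation invariance.

## Comparison metrics

* Percent residuals: 100·(I_test − I_ref)/I_ref on a shared grid.
* log₁₀ RMSE after fitting a single multiplicative scale (closed-form offset
  in log space); the raw value is also available. Disclosed because profiles
  from different programs carry arbitrary normalizations.
* Reduced χ² against experimental (q, I, σ) data: calculated curve
  interpolated onto the experimental grid, scale + constant background fitted
  by weighted least squares, sum reduced by N−1. On data simulated as
  c·I + N(0,σ) the statistic calibrates to 1 within 3/√N.
* Guinier Rg: iterative ln I vs q² fit restricted to q·Rg < 1.3.

## Synthetic fixtures

The generator builds idealized, fully deterministic structures so that every
test runs without downloads: peptides on ideal backbone geometry (helix
φ,ψ = −57°,−47°; extended −120°,120°; standard bond lengths/angles) with
side chains grown as internal-coordinate trees using a deterministic
steric-clearance search; single-stranded RNA with free 5′-OH/3′-OH termini;
uniform sphere clusters for Debye/Guinier oracles; jittered Gaussian
ensembles (frame 1 is the unperturbed base). Fixture geometry is chemically
plausible but not force-field minimized, and aromatic ring closures are left
open — none of the consumers (mapping, SBA sums, SASA, Debye) depend on ring
closure. What passing tests show is therefore the internal consistency and
accuracy class of the forward model on realistic compositions and length
scales, not agreement with experimental scattering of real folded proteins;
the parametrization pipeline applied to real MD ensembles is the intended
production path.

Problem sizes used throughout the suite and the acceptance script — a
20-residue peptide (one of each amino acid), a 12-mer RNA, 10–20 frame
ensembles, ≤ 400-atom sphere clusters — were chosen as the smallest systems
that exercise every bead type and keep the full pipeline comfortably
interactive.

## Numerical choices

* q = 0 is represented as 1e-10 Å⁻¹; sinc and sinc′ are series-guarded.
* Polynomial fits run on q scaled to [0,1] for conditioning; coefficients
  are stored in plain powers of q.
* A(q) ≥ 0 and S(q) ≥ 0 are asserted on every term table (sums of squared
  amplitudes over a compact bead stay positive at small-angle q); violation
  is a hard error, not a warning.
* Alternate locations keep the highest-occupancy conformer; waters and
  heteroatoms are excluded on read unless requested; chain-break residues
  missing a mid-chain phosphate are treated as internal with a warning.
* Histidine without hydrogens defaults to the ε-tautomer with a warning.

## Known limitations

* No explicit-solvent scattering, no CRYSOL-style border-layer envelope
  term (the SLC density decrement replaces it), no anomalous X-ray terms,
  no incoherent neutron background.
* Bead form factors lose the amplitude sign (√F²); near-zero-contrast SANS
  conditions are the least accurate regime.
* LCPO is heavy-atom only and approximate by construction; exact analytic
  SASA is out of scope.
* The bundled tables cover H/D, C, N, O, P, S — the standard biopolymer
  inventory; ligands, ions and modified residues are not parametrized.
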