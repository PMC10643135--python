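# Methods

This note records the models implemented in redoxmap, the defaults and
why they were chosen, what the synthetic fixtures do and do not emulate,
and the numerical choices that affect results.

## Structures and cofactor edges

Coordinate files (PDB, mmCIF) are read through gemmi; only the first
model is used, alternate locations collapse to the `A` (else
highest-occupancy) conformer, and hydrogens are dropped — deposited
models of large membrane complexes are heavy-atom models, and every
distance in this package is defined on heavy atoms. Author residue
numbering is the canonical addressing scheme, because the residues
discussed in the structural literature (e.g. the NqrB gate
phenylalanines) are author-numbered.

Cofactor recognition is registry-driven. The default edge-atom sets
follow the tunneling-edge convention of counting conjugated atoms only:

| kind          | residue codes | edge atoms                               |
|---------------|---------------|-------------------------------------------|
| FAD/FMN/RBF   | FAD, FMN, RBF | isoalloxazine ring (14 atoms) + O2, O4; name variants C4A/C4X etc. listed so both flavin nomenclatures resolve |
| [2Fe-2S]      | FES, FS2      | FE1, FE2, S1, S2 (cysteine Sγ excluded)   |
| ubiquinone    | UQ1, UQ2      | head-group ring C + carbonyl/methoxy O; isoprenoid tail excluded |
| NAD(H)        | NAD, NAI      | nicotinamide ring                         |

An instance is kept when at least half of its listed edge names resolve,
so a partially modeled cofactor still reports (with its missing atoms
listed). The registry is overridable per call. Which atoms constitute a
cofactor "edge" is a convention; reported distances therefore carry the
registry identity, and the ±0.5 Å tolerance used in edge-distance checks
absorbs the convention's spread.

## Tunneling ruler

`log₁₀ k = A − B·R − C·(ΔG + λ)²/λ` with A = 15 log₁₀(s⁻¹), B = 0.6 Å⁻¹,
C = 3.1 eV⁻¹ — the standard exergonic parameterization for protein
electron transfer. Endergonic steps are handled by supplying ΔG > 0 in
the same expression. R below van der Waals contact (3.6 Å) is clamped
with a warning. Rate ratios between two distances computed under shared
(ΔG, λ) are exactly 10^(B·|ΔR|): the Franck–Condon term cancels, which
is why conformational gating factors are parameter-free. The per-step
(ΔG, λ) are user inputs, never hardcoded; `driving_force_for_rate`
inverts the ruler for the endergonic-branch ΔG that reproduces an
observed rate at a known distance and an assumed λ (default 1.0 eV, a
typical protein value) — useful for calibrating against published
per-state rates, which are only self-consistent to their printed
precision. Pairs at ≤14 Å are classified `fast`, beyond `obstructed`;
the threshold is the distance at which the activationless ruler falls to
the 10⁶–10⁷ s⁻¹ band and is configurable.

## Domain motions, helix tilts, crosslinks

Superposition is least-squares Kabsch with the determinant correction
(proper rotations only; a handedness flip cannot be hidden by an
improper solution). Atom pairing is strict identity on (chain, residue
number, insertion code, atom name) — the two states are the same
protein, so no alignment fallback exists and unmatched residues warn.

Domain motion: after core superposition the domain's own rigid fit gives
the rotation angle (from the trace), axis (unit eigenvector of the
rotation), and screw translation (translation component along the axis).
"Maximum translational movement" is defined here as the largest per-atom
Cα displacement of the domain after core superposition — the swing of
the distal tip — since that is the quantity a maximum-motion statement
about a rotating domain describes; the centroid shift is also reported.

Helix tilt: the helix axis per state is the principal component of the
Cα coordinates, disambiguated N→C; the tilt is the angle between the two
axes after core superposition. The axis-fit quality metric is the
scatter of Cα radial distances about their mean (zero for any ideal
helix, large for bent or non-helical selections); above 1 Å a warning
flags the selection. Principal-component axes are adequate for straight
segments of ≥2 turns; kinked helices should be split at the kink.

Crosslink validation is a Cα–Cα distance check against the crosslinker
span, default 30 Å for DSS (two lysine side chains plus the 11.4 Å
spacer, with conformational slack). Unresolvable residues yield flagged
records rather than disappearing, so report length always equals input
length.

## Ion sites

The first coordination shell collects all non-hydrogen, non-carbon atoms
within a cutoff (default 3.0 Å; the supported window is 2.0–3.5 Å —
shorter truncates genuine Na–O contacts, longer admits second-shell
atoms). Ligands are classed as backbone carbonyl O, side-chain O, water
O, N, S, or other. The decision table:

- **Na⁺**: CN 4–6, mean distance 2.2–2.6 Å (half-open at 2.6), ≥80% O ligands.
- **K⁺**: CN 5–8, mean distance 2.6–3.1 Å.
- **water**: CN ≤ 2, or CN ≤ 4 with mean distance in the hydrogen-bond
  band 2.6–3.2 Å.
- otherwise **ambiguous** (score < 0.5).

The Na⁺ and K⁺ distance bands deliberately partition at 2.6 Å so the
calls are mutually exclusive; the bands are standard alkali–oxygen
coordination windows and are config-exposed. Map density is never used:
the point of the geometric classifier is precisely that density cannot
distinguish water from Na⁺. `scan_candidate_ions` evaluates every
modeled water and monatomic ion and ranks by score, ions before waters
on ties.

## Pore profiling

At each station along a user-supplied line (start + direction), the
largest probe sphere not overlapping any atom's van der Waals sphere is
found by maximizing `min_i(|c − xᵢ| − vdwᵢ)` over the plane normal to
the pathway: seeded uniform restarts (default 16) in a disc of the bulk
cap radius, each refined by Nelder–Mead (the objective is piecewise
smooth, so a derivative-free simplex is appropriate), with each station
additionally seeded from the previous optimum so the profile tracks a
continuous channel. The march stops once the radius exceeds the bulk cap
(default 10 Å — the probe has left the protein) on each side. Radii:
Bondi-style table (C 1.70, N 1.55, O 1.52, S 1.80, Fe 1.40 Å),
replaceable. Negative clearances (start buried in an atom) clamp to 0
with a warning. The profile is deterministic given its seed, and on
convex ring fixtures the stochastic optimum matches the closed-form
radius to better than 0.05 Å. The pathway line is user-anchored (e.g. at
known entry/exit residues) rather than discovered; full 3-D path
wandering is out of scope.

## Spectra

**Mössbauer.** A zero-field quadrupole doublet is two Lorentzians of
FWHM Γ at δ ± ΔE_Q/2; spectra are stored transmission-style (dips below
a zero baseline), so the absorption minima sit at the line centers. The
default Γ = 0.24 mm/s is a typical experimental minimum linewidth. The
asymmetry parameter is the low/high-velocity area ratio (1 = symmetric).
Fits are Levenberg–Marquardt least squares (lmfit) with bounds
(ΔE_Q ≥ 0, Γ > 0) and per-parameter uncertainties; non-convergence is
returned as a flagged result with the residual norm, never an exception.
At zero noise the fit recovers the generating parameters to ~1e-6.

**EPR.** For an axial g tensor, g(θ)² = g∥²cos²θ + g⊥²sin²θ and the
resonance field is B = 71.4477·ν[GHz]/g(θ) mT. The powder envelope is
accumulated on a sin θ-weighted grid of 1800 orientations (doubling the
grid changes the spectrum by <0.5%), convolved with a Gaussian in the
field domain (linewidths quoted in gauss; 1 G = 0.1 mT), and
differentiated to the first-derivative form. Component weights are
double-integral (spin-count) fractions; amplitude-fraction weighting
would differ for components of unequal linewidth, and the double
integral is the physically meaningful (spin-counting) convention.
Weight re-fitting holds g values and linewidths fixed and solves a
non-negative least-squares problem, normalizing to Σw = 1; identical
components are rejected as a degenerate design. The microwave frequency
is a required input ("X-band" is not a number); fixtures use 9.40 GHz.
Not modeled: hyperfine structure, zero-field splitting, relaxation and
power saturation (so the power dependence of fast-relaxing cluster
signals is outside scope), magnetic Mössbauer sextets.

## Synthetic fixtures

Fixture defaults mirror the study conditions the package is built to
analyze: a 5.7 Å flavin–flavin gap, CN-5 oxygen shells at 2.4 Å, a 26°
hinge, Fe–Fe 2.70 Å / Fe–S 2.28 Å clusters, δ = 0.3 / ΔE_Q = 0.51 /
Γ = 0.24 mm/s doublets with 1% Gaussian noise, and a 96:4 axial+radical
EPR mixture at 9.40 GHz. Helices are Cα-only ideal helices (100°/residue,
1.5 Å rise, 2.3 Å radius); flavin rings are chemically idealized planar
hexagonal-lattice ring systems with correct atom names; channels are
stacked atom rings whose analytic pore radius is exact by construction;
the flavin-pair gap is solved by bisection on the brute-force minimum
distance (monotone in the translation), accurate to <1e-6 Å.

What fixtures do **not** emulate: side chains and packing around
cofactors, solvent beyond explicit shell waters, B-factors/disorder,
experimental coordinate error, baselines and instrumental artifacts in
spectra. Passing the fixture matrix therefore demonstrates that the
measurement operators are correct on exactly known geometry, not that
selections or cutoffs are optimal for any particular deposited model;
on real structures the dominant uncertainties are the edge-set
convention (distances), the choice of superposition core (motions), and
the shell cutoff (ion calls), each of which is an explicit, documented
parameter.

One seed governs each recipe; there is no global random state.

## Problem sizes

Test-suite simulations are sized for exactness rather than bulk: the
Monte-Carlo checks use 100 seeded replicates (fit-bias and noise-s.d.
checks), the hinge-recovery property uses 100 random axis/angle draws,
pore fixtures profile 2–62 stations with 4–16 restarts, and spectra use
801-point velocity and 1401-point field grids. The acceptance script
evaluates one ruler inversion (closed form) and one 801-point doublet
fit.

## Known limitations

- mmCIF files lacking author numbering fall back to label numbering.
- The pore optimizer assumes the channel is a single connected void
  around the given line; disconnected voids in the same normal plane can
  capture the probe if they are wider.
- The EPR model is g-only; spectra with resolved hyperfine will fit with
  inflated linewidths.
- Crosslink checking validates distances only; it does not identify
  peptides or quantify abundances.
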