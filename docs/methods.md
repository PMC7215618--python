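# Methods

## Scope and model

The package post-processes computed chemical shielding tensors (CSTs)
of peptide backbones. The physical chain is: a periodic-DFT code
produces a 3×3 shielding tensor σ per nucleus; its symmetric part has
three principal components and axes; an affine calibration maps
computed shieldings onto the experimental chemical-shift scale; and the
principal axes, expressed in a local peptide-plane frame, give the
orientation angles that oriented-sample SSNMR experiments (e.g.
PISA-wheel analyses of helical peptaibols) consume. The DFT step itself
is out of scope — its outputs (magres files, or CSV tensors) are the
pipeline's inputs.

## Conventions and their rationale

**Eigenvalue order.** Eigenvalues are ordered ascending for both
shieldings and shifts. The "most/least shielded" vocabulary is
ambiguous across the two scales (a slope ≈ −1 maps the smallest σ to
the largest δ), and published tables are not internally consistent
about it, so all cross-scale correspondence is explicit: component
pairing for calibration is σ-ascending ↔ δ-descending by default
(configurable to direct pairing).

**ξ₁ selection.** The orientation angles bind ξ₁ to the eigenvector of
the *numerically smallest* shielding eigenvalue — the largest-shift
component, which physically lies near the N–H bond. Only this binding
yields β in the 11–21° range observed for helical amides; the opposite
literal reading is available via `convention="largest"` for users who
want it. A degenerate selecting eigenvalue (gap < 1e-8 ppm) raises an
error rather than returning an arbitrary direction.

**Angle folding.** Eigenvectors have no intrinsic sign, so {α, β, γ}
are folded to [0°, 90°]. α is the out-of-plane tilt of ξ₁ (angle to its
own in-plane projection), computed via arcsin of the normal component,
which is numerically exact near 0 where arccos loses precision; if ξ₁
is exactly normal to the plane, α = 90° by continuity. The in-plane
azimuth (satisfying cos β = cos α · cos azimuth) is exposed as a
separate diagnostic, not as α.

**Dihedrals.** IUPAC sign convention, range (−180°, 180°], trans =
180°. φ(i) = C(i−1)–N(i)–Cα(i)–C(i), ψ(i) = N(i)–Cα(i)–C(i)–N(i+1);
both undefined at the corresponding chain terminus. Coordinates are
Å internally; r_NH is reported in pm (×100) to match tabulation
practice.

**Ramachandran regions.** Circles of radius 60° (configurable) around
β-sheet (−150°, 150°), PP II (−75°, 145°) and right-handed α-helix
(−90°, −30°), classified by wrap-around Euclidean distance with
nearest-center tie-breaking so overlapping circles stay deterministic.
The α_R center follows the right-handed helical quadrant consistent
with φ ≈ −55° helical data; a left-handed variant (+90°, −30°) is
provided as `CAPTION_ALPHA_REGION` for users who need that quadrant.

**Calibration fit.** Ordinary least squares of σ on δ (the literal
form of the affine law), via `scipy.stats.linregress`. Diagnostics are
standard single-predictor OLS: adj R² = 1 − (1−R²)(n−1)/(n−2) and
residual SD with n−2 degrees of freedom. The same (a, b) are then
applied directly as ε = a·σ + b; with a ≈ −1 this is an excellent
approximate inverse and reproduces the reference validation table at
print precision. Both fitted and user-supplied (a, b) paths exist.

**Group statistics and rounding.** Report rounding is half-up: ppm and
angles to 1 decimal, group component differences to integer ppm,
matching print precision of the reference tables. Component group
differences are reported under both ascending and descending labels
because parts of the literature index components largest-first. The
default group memberships (Aib = residues 2, 3, 4, 8, 9, 14; canonical
= 1, 5, 6, 7, 11 of samarosporin I) are configuration inputs, adopted
because they reproduce all five published summary statistics exactly;
the C-terminal alcohol, isovaline and hydroxyprolines belong to
neither.

## Synthetic data: what it emulates, what it does not

`make_backbone` builds chains from internal coordinates (NeRF
placement) with textbook backbone geometry (N–Cα 1.458 Å, Cα–C
1.525 Å, C–N 1.329 Å, N–H 1.02 Å; ω = 180°), the amide H placed on the
external bisector in the C(i−1)–N–Cα plane. `make_tensor` constructs
tensors from prescribed eigenvalues and an eigenframe given either
explicitly or as target {α, β, γ} relative to a peptide-plane frame
(feasible iff β ≥ α and γ ≥ α; infeasible triples are rejected).
`make_calibration_pairs` draws σ = a·δ + b + N(0, sd²) over a 3×3-
component benchmark emulating the reference fit's size (9 pairs,
default a = −0.93574, b = 209.54, noise 6 ppm in the noisy setting).
`make_cohort` draws class-conditional Gaussian shift parameters whose
means encode the three secondary-structure trends at glycyl-realistic
values (¹³Cα iso ≈ 41–45 ppm, spans 36–52 ppm, ¹⁵N dev 21–40 ppm,
within-class SDs 0.5–2 ppm).

All generators are deterministic under an explicit seed (one private
`numpy` generator per call). They do **not** model the physics linking
geometry to shielding: a passing pipeline shows the analysis chain is
self-consistent (every prescribed quantity is recovered by the
corresponding measurement at stated tolerance — dihedrals 0.01°,
orientation angles 1e-6°, r_NH 1e-6 pm, calibration 1e-9 at zero
noise), not that DFT tensors for a real peptide would be accurate.

## Numerical choices

- Degenerate geometry (coincident/collinear dihedral points, parallel
  N–H and N–Cα vectors) raises `GeometryError`; frame orthonormality
  holds to 1e-10.
- Eigen-decomposition uses `numpy.linalg.eigh` on the symmetrized
  matrix; reconstruction agrees with the symmetric part to 1e-8 ppm.
- PDB parsing is gemmi-backed with a strict fixed-column pre-scan that
  reports line numbers; altLoc other than blank/'A' is dropped; amide H
  is resolved by name preference (H, HN, H01), then nearest hydrogen
  within 1.2 Å of N. PDB output carries 3-decimal coordinates, so
  angle round-trips through PDB text are limited to ~0.03° (in-memory
  round-trips hit the tolerances above).
- Unknown residue codes map to kind "other" with a warning rather than
  an error; the kind table is user-extensible.

## Problem sizes

The test suite and the acceptance script use deliberately small
problems: 1000-sample dihedral and eigenvalue oracle comparisons,
500-frame orientation oracles, 200 seeded 9-pair calibration
replicates, 30-site trend cohorts and 15-residue synthetic peptides.
These sizes give stable statistics for the recovery checks while the
whole suite runs in seconds.

## Known limitations

- No mmCIF input, space-group symmetry expansion, or periodic-image
  handling; frames and dihedrals are intra-molecular.
- Calibration is single-nucleus, unweighted OLS; no robust regression.
- The secondary-structure classifier is purely {φ, ψ}-based (no
  hydrogen-bond criteria), adequate for the regular motifs it targets.
- Quadrupolar/EFG blocks of magres files are ignored; no Haeberlen
  asymmetry or skew parameters beyond iso/span/dev.
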