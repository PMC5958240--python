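# Methods

This note documents the models implemented in `myotail`, the parameter
choices behind them, what the synthetic-data generators emulate, and the
numerical conventions that matter when interpreting results.

## Coiled-coil parameterization

A two-strand coiled coil is generated along a straight supercoil axis (z).
Writing ω₀ for the supercoil twist and ω₁ for the helix phase rate in the
frame co-rotating with the supercoil (both per residue), the model fixes the
intrinsic helix rotation ω_int = 360°/residues-per-turn and assigns ω₁ per
motif as 360·N/L (N helical turns over L residues), absorbing the
difference as supercoil twist: ω₀ = ω_int − ω₁.  Defaults (residues per
turn 3.617, rise 1.495 Å, major radius 4.9 Å, strand phase 210°, blend
fraction b = 0.03) describe the β-MHC rod.  Consequences worth spelling
out:

- canonical heptads (N = 2, L = 7): ω₀ ≈ −3.33°/res, a left-handed
  supercoil with ~108-residue pitch;
- the 29-residue skip motif (N = 8): ω₀ ≈ +0.22°/res — the supercoil is
  locally unwound to almost straight, which is the structural signature of
  a skip residue;
- the 27-residue deletion motif (N = 8): ω₀ ≈ −7.1°/res — locally
  overwound, the deletion analogue of a double stammer.

Non-canonical motifs span two heptads upstream of the defect-containing
heptad and one downstream (four heptads merged ± the defect residue), so
the skip at E1582 produces the 29-residue motif starting at the F1565 `a`
anchor and the K1617 deletion the 27-residue motif starting at L1601, with
canonical register restored at V1594 and L1629 respectively.  Edge segments
shorter than a heptad are tiled as fillers carrying the canonical phase
rate (fractional turn counts); they exist only at the chain termini.

**Strand placement.**  The 210° parameter is interpreted as the helix
self-rotation phase, applied identically to both strands, with the strand
axes antipodal (180° apart) about the supercoil axis.  This makes the dimer
exactly C2-symmetric, which we treat as a modelling requirement for a
parallel homodimer.  The phase origin is anchored so heptad `a` residues
sit at 210° from the outward radial; with the canonical rate of 102.857°
per residue this buries `a` (210°) and `d` (158.6°) into the inter-helix
seam, flanked by `e`/`g`, with `b`/`c`/`f` solvent-facing — the standard
knobs-into-holes arrangement.  The alternative reading of 210° as the
azimuthal strand separation would break C2 symmetry and was rejected.

**Phase-rate smoothing.**  Transitions between motif rates are blended with
logistic ramps of width b × (mean adjacent motif length); b = 0.03 makes
the ramp sub-residue-wide, i.e. near-sharp transitions, while keeping the
rate function smooth for the analytic tangent.

**Backbone completion.**  The Crick construction places Cα only (minor
radius 2.26 Å, chosen as the Cα radius of an ideal α-helix; not a measured
quantity).  N, C and O are added by rigidly fitting an ideal α-helix
template (φ = −57°, ψ = −47°, Engh–Huber-style internal coordinates, built
by natural-extension-reference-frame chaining) onto each residue's local
Cα triad.  The result passes the backbone-dihedral helicity filter at
every residue.  No side chains are built; analyses that need them
(salt bridges, full RSA) accept externally packed all-atom ensembles.

**Deletion bookkeeping.**  All sequences, profiles and schedules index by
wild-type numbering.  K1617del retains a gap at 1617 — nothing is ever
renumbered — and moving windows run over physical neighbours with
gap-crossing windows flagged in the output.

## Wild-type chain

No accession is distributed with the package; the built-in 164-residue
chain (1526–1689) is a synthetic stand-in generated from the heptad
register with heptad-appropriate filler residues, and every residue the
analyses name (F1565, E1582, V1594, L1601, A1603, E1604, S1607, R1608,
V1614, K1615, K1616, K1617, E1619, D1621, L1629) pinned at its published
position.  Register propagation from the single anchor L1601 = `a`
(pausing at the E1582 skip) reproduces all published assignments, e.g.
E1604 = `d`, R1608 = K1615 = `a`.  Geometry-level results (distances,
angles, twists, RSA patterns by heptad position) do not depend on filler
identities; composition-level results would, and users with the real
sequence can substitute it anywhere.

## Trajectory metrics

- **D_com**: per residue, the distance between the 7-Cα window centroids of
  the two chains; undefined at the three terminal residues.  On an ideal
  model it equals twice the major radius away from the termini.
- **Heptad length**: default is the windowed-positions convention (distance
  between the mean Cα of windows i−3…i+3 and i+4…i+10), which cancels the
  minor helix almost exactly; a windowed-distances alternative (mean of the
  seven i→i+7 distances) is provided because the source description is
  ambiguous between the two.
- **Inter-heptad angle**: interior angle at residue i between segments to
  Cα(i∓7); 180° when straight, decreasing with bends.  The interior angle
  (not its deviation from 180°) is reported so that bends *decrease* the
  metric.
- **Helicity**: fraction of (residue, frame) pairs with φ ∈ [−100°, −30°]
  and ψ ∈ [−80°, −5°]; the windows are configurable since dihedral-window
  conventions differ between analysis packages.
- **RSA**: Shrake–Rupley areas (960 sphere points by default, 1.4 Å probe,
  NACCESS-style element radii: C 1.87, N 1.65, O 1.40, S 1.85 Å) of each
  residue's side-chain atoms, Cα included.  The per-residue-type maximum is
  computed with the same engine from an extended (φ = −120°, ψ = 140°)
  Gly-X-Gly tripeptide assembled from ideal backbone geometry plus CCD
  side-chain templates, restricted to the atom-name subset present in the
  query — backbone-only models are therefore normalized against a
  backbone-only reference and remain self-consistent (RSA of the reference
  itself is exactly 1).  Frames are subsampled at a 10 ps equivalent.
- **Salt bridges**: charge centers are Lys NZ, Arg NH1/NH2 midpoint
  (preferred over CZ as closer to the formal charge locus; configurable),
  Asp OD1/OD2 and Glu OE1/OE2 midpoints; a pair is bridged below 4 Å and
  occupancies are bridged-frame fractions.  A vectorized all-pairs
  distance computation is used; tests pin it to a per-frame brute-force
  enumeration.
- **RMSF** superposes frames iteratively onto their running mean (Kabsch,
  mass-unweighted) until the mean structure moves < 10⁻⁴ Å.
- **Clustering** uses the deterministic leader algorithm (a frame joins the
  first cluster whose *founding* frame is within the 8 Å Cα-RMSD cutoff).
  The algorithm behind the original cutoff is not specified in the source
  methods; leader clustering was chosen for determinism and streaming, and
  the result type is algorithm-agnostic so a gromos-style average-linkage
  scheme can be swapped in.

## CD quantification

Helical content is |MRE₂₂₂|/36 000 (the fully-helical reference magnitude;
no chain-length correction is applied, as none is stated for the reference
value), clipped at 120 % with a warning above 100 %.  The 222/208 ratio is
read at the nearest sampled wavelength with linear interpolation off-grid.
Melts are normalized affinely to 100 % folded at 10 °C and 0 % at 80 °C and
fitted with a two-state logistic with zero post-normalization baseline
slopes — the data motivating the model are described only as "sigmoidal",
so the simplest two-parameter form was chosen; the fit is invariant to any
affine transform of the raw signal.

## Morphometry and imaging

Group tests are two-tailed Welch (unequal-variance) t tests against wild
type — the unequal-variance form was chosen because group sizes and spreads
differ strongly (n from 4 to 72).  EM-morphometry stars follow
**/***/**** at p < 0.01/0.001/10⁻⁴; cell-imaging stars follow */**/*** at
p < 0.05/0.001/10⁻⁴.  Bundling is summarized per image field with Wilson
binomial intervals.  Solubility fractions are supernatant/total clipped to
[0, 1] with an optional logistic half-solubility fit.  Integration scoring
takes per-cell categories (integrated / partial / aggregated), reports
per-experiment percentages and Welch tests across experiment means.

Sarcomere line scans are segmented at M-line minima.  Peaks alternate
short (intra-sarcomere, across the bare zone) and long (across the Z-line)
gaps; minima inside short gaps are classified as M.  Pure depth ordering is
not robust here because the mutant M-line accumulation term *raises* the M
minimum; the gap-alternation rule is, and a depth-based fallback handles
scans without detectable alternation.  Peak detection uses a prominence
floor of 0.25 × signal span (above noise, below the shallowest genuine
peak) and no pre-smoothing — noise is handled by averaging.  Windows span
one estimated period centered on each M minimum; alignment re-centers each
window on the minimum within its central quarter (the Z-line shoulders near
the window edges can be darker than the M-line and must not capture the
alignment), then two-level averaging proceeds per myofibril first and
across myofibrils second.  A pooled-sarcomere average is available but
never the default.  Peak metrics take the largest local maximum on each
side of offset 0 with parabolic sub-sample refinement; the peak/minimum
ratio is intentionally not offset-invariant (adding c maps it to
(p + c)/(m + c)), which is documented behaviour, not a defect.

## Synthetic-data generators

All generators use numpy's PCG64 (`default_rng`) under a single root seed
and emit their ground-truth parameters alongside the data.  What they
emulate — and what they deliberately do not:

- **Ensembles** are rigid hinge-bend perturbations of the built model (a
  random perpendicular bend axis at the hinge Cα midpoint) plus 0.08 Å
  isotropic jitter, the jitter magnitude chosen so backbone helicity stays
  ≈ 99 %, i.e. the near-fully-helical regime of an equilibrated coiled
  coil.  In end-to-end-target mode the per-frame target length is drawn
  from the requested Normal truncated to the achievable range (no bend can
  exceed the straight length), with the location parameter solved so the
  truncated mean equals the requested mean; the bend angle is then found by
  bisection.  A requested mean at or beyond the straight length errors.
  These ensembles have no local unfolding, no side chains and no solvent;
  passing closed-loop tests demonstrates correct measurement, not
  force-field realism.
- **CD spectra** are Gaussian-band composites: a helix basis constrained to
  MRE₂₂₂ = −36 000 exactly with a 222/208 ratio of ≈ 1.24, and a coil basis
  with its minimum at 198 nm.  Only the 208/222 anchor behaviour matters
  downstream; the band shapes are not measured basis sets.
- **Melts** are exact two-state logistics plus Gaussian noise on the
  percent scale.
- **Filament populations** draw lengths/widths from Normal(mean, SEM·√n)
  truncated positive and per-field bundling flags from Bernoulli(p).
  Published preset values: WT length 431 ± 34 (SEM) nm n = 34, width
  18.4 ± 0.4 nm n = 72; A1603P length 208 ± 16 nm n = 24, width 25 ± 1 nm
  n = 31; WT:A1603P mixture length 390 nm, width 22 nm, n = 11; bundling
  70 % (K1617del) and 19 % (WT).  Values not published and therefore chosen
  here as plausible study conditions: K1617del length 250 ± 40 nm and width
  24 ± 1.5 nm (n = 4; described only as shorter/wider), A1603P bundling
  30 %, WT:K1617del mixture 410 nm / 21 nm / 40 % bundling (described as
  intermediate with reduced bundling).  Mixtures draw from a single
  intermediate Normal rather than a bimodal mixture, matching the reported
  intermediate phenotype.
- **Line scans** are baseline + two Gaussian peaks per sarcomere at
  M ± separation/2 (σ 0.13 µm) + a broad central M-line Gaussian (σ 0.20 µm,
  broad so that mutant-level amplitudes raise the M minimum without
  creating a spurious central maximum) + noise, sampled at 0.065 µm/pixel
  with a random phase per myofibril.  Presets: sarcomere length 1.85 µm;
  WT peak separation 0.70 µm, M-line amplitude 0.15, 24 myofibrils;
  A1603P 0.70 µm / 0.55 / 12; K1617del 0.60 µm / 0.35 with reduced peak
  amplitude (0.75) / 13.  With a strong overlapping M-line term the *true*
  intensity maxima genuinely move inward, so the peak-separation parameter
  is only recovered exactly in the weak-M-line regime; recovery tests use
  that regime.
- **Solubility** uses increasing logistic curves over the five assay salt
  concentrations (100–300 mM NaCl); midpoints WT 190 mM, K1617del 195 mM
  (similar to WT), A1603P 140 mM (more soluble at low salt).  **Integration**
  draws per-cell categories from per-genotype multinomials (WT
  85/10/5 %, A1603P 45/30/25 %, K1617del 40/30/30 %), 30 cells × 3
  experiments.
- **End-to-end presets**: WT 23.9 ± 0.5 nm, K1617del 23.4 ± 0.5 nm,
  K1617del-c 23.7 ± 0.4 nm (published); A1603P 23.7 ± 0.5 nm (not
  published; chosen slightly below WT to reflect the local bend).
- **Melt presets**: WT Tm 48 °C, both mutants 50 °C, width 2.5 °C.

## Problem sizes and numerical choices

The pipeline defaults to 60-frame ensembles at 0.5 ns/frame with the first
10 ns discarded, RSA on 3 subsampled frames at 240 sphere points, and
200-frame ensembles for end-to-end summaries — sizes at which every
statistic is stable at the tolerances tested while a full multi-scenario
run stays interactive.  Melt fits start from the 50 % crossing;
the logistic solubility fit starts at the median salt.  Cα–Cα virtual bonds
are validated to 3.80 ± 0.10 Å at build time.  PDB round trips preserve
coordinates at the format's 10⁻³ Å precision.

## Known limitations

- The stand-in sequence makes composition-dependent analyses (salt-bridge
  inventories, residue-specific RSA on all-atom input) illustrative rather
  than biological until a real sequence is supplied.
- Builder output is backbone-only; the pipeline skips the salt-bridge stage
  for such ensembles (the analysis itself is fully exercised on all-atom
  toy inputs in the tests).
- Hinge-bend ensembles explore a single rigid degree of freedom plus
  jitter; RMSF/cluster structure is correspondingly simple.
- Leader clustering is order-dependent by design (deterministic streaming);
  reordered frames can cluster differently near the cutoff.
- The two-state melt model has no baseline slopes; strongly sloped raw
  baselines should be corrected before fitting.
- The LMM construct boundary is reported inconsistently in the source
  literature (1280–1935 vs 1280–1936); the builder takes explicit
  boundaries and does not adjudicate.
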