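# Methods

## Elastic-network model and normal modes

The potential energy of an N-site system near equilibrium is approximated
by the quadratic form V(q) = ½ Δqᵀ H Δq. Instead of differentiating a
force field, `enmcoop` builds H geometrically from an elastic network: all
node pairs (i, j) with equilibrium distance d⁰_ij ≤ γ_c are joined by a
spring of constant γ, giving

V_ANM = (γ/2) Σ_{i<j, d⁰_ij ≤ γ_c} (d_ij − d⁰_ij)².

The 3×3 off-diagonal super-block of the ANM Hessian for a connected pair
is −γ·r̂r̂ᵀ (r̂ the unit equilibrium bond vector); diagonal super-blocks are
minus the row sums, so translation invariance holds exactly, not only to
rounding. The GNM variant is the Kirchhoff matrix γ(D − A) on the same
graph. Optional mass weighting replaces H by M^{-1/2} H M^{-1/2} with the
per-coordinate diagonal mass matrix; the default is off (uniform masses),
since the downstream Pearson statistics are invariant to overall scale and
only weakly sensitive to the weighting.

Defaults: cutoff γ_c = 10 Å, γ = 1 (energy is used only relatively, so the
unit is immaterial), all-atom granularity; under `c-alpha` granularity one
node per residue (its CA), with every atom of the residue inheriting the
node's displacement.

Modes are numbered 1-based over the ascending full spectrum. Eigenvalues
below 1e-8 × λ_max count as trivial — dimensionless, hence robust across
network sizes. A connected, non-collinear ANM network has exactly six
trivial modes (rigid translations and rotations); more than six raises a
disconnected-network error naming the components. The essential modes are
the ten following the trivial block, i.e. modes 7–16. Below 9000
coordinates a full dense symmetric eigendecomposition is used; above, a
shift-invert Lanczos solver (σ = −1e-3, which is safely below the spectrum
and keeps the shifted matrix invertible despite the six-fold zero
eigenvalue) returns the low end only. Within a degenerate eigenvalue block
the eigenvector basis is solver-dependent; results are therefore reported
per eigenvalue, and no test asserts on individual vectors inside such a
block.

## Curves

**Motion magnitude.** For residue i with atoms j = 1..N_i and displacement
vectors d_ij, the curve value is (1/N_i) Σ_j ‖d_ij‖ — the average over the
residue's *own* atoms. Magnitude curves feed Pearson correlation, which is
scale-invariant, so the eigenvector amplitude is irrelevant there.

**Rotation angles.** Each residue is reduced to a representative point —
the all-atom centroid by default (consistent with the all-atom magnitude
average), or its CA. Link k runs from residue k to k+1 in file order
within one protein subset; the curve value is the angle between the
equilibrium and deformed link k, computed as atan2(‖u×v‖, u·v). This
equals arccos of the clamped normalised dot product but remains accurate
for nearly parallel links, where arccos amplifies rounding to ~1e-8.
Angles are amplitude-dependent (the map is nonlinear), so the displacement
field is rescaled to a fixed physical scale — maximum per-atom
displacement 1 Å by default, recorded on the curve — to make runs
comparable. Zero-length links (coincident representatives) yield angle 0
with a warning.

## Segment search and correlation tables

For curves F1, F2 of a protein pair and window length λ, the search is
exhaustive over *all* start pairs (i, j) — the two subscripts are
independent, not a single relative shift; a restricted diagonal-shift
variant is available behind `search="shift"` for comparison. The segment
pair maximising |corr| wins; ties in |c| within 1e-12 are broken by the
smallest i, then the smallest j. The tolerance exists because
mathematically tied windows (e.g. every window at λ = 2) otherwise get
reordered by floating-point noise. A zero-variance window has undefined
correlation; it is defined as 0 (never significant) and flagged
degenerate, which biases nothing upward.

λ is parameterised as p = λ/x with x the shorter protein's length, over
p = 1.0 … 0.5 in steps of 0.1; λ = round(p·x) (half away from zero),
clamped to [2, x]. Smaller p values are excluded because very short
segments correlate highly by chance. Signed values are kept in the table;
absolute values are taken only by the filters.

**PCA condensation** stacks a protein's ten angle curves as columns
(positions are observations), centres the columns, and returns the
length-L score series on the first principal axis, with the sign chosen so
the condensed curve correlates non-negatively with the per-position mean
curve. **Fourier magnitude** is the unnormalised DFT magnitude of the full
curve, DC bin included; spectra are non-negative, which empirically drives
all subtype counts positive in that analysis branch.

## Filters and cooperativity counting

Per table row m the threshold is computed on |c_mn|: the median (mean of
the two central order statistics for the even count of 10), the arithmetic
mean, or the quantile inf{v : F(v) ≥ p} with F the empirical CDF and
p = 1/3 (tertile) or 1/4 (quartile) — i.e. the smallest order statistic
whose rank/10 reaches p. Significance is *strictly* greater than the
threshold. For a row of ten distinct absolute values this yields exactly
5 / 6 / 7 significant entries (median / tertile / quartile), and hence the
exact totals s_i + d = 6·6·5 = 180, 216, 252 over the 360 triples; the
mean filter gives between 1 and 9 per row. These identities are the
package's main internal consistency check, and the lower/inf quantile
convention together with strict comparison is the only combination that
produces them.

The sign matrix Z records c_mn ≥ 0; zero counts as positive (a tie-break
that in practice never fires on continuous data). Counting is a direct
loop over the 360 triples; an equivalent row-replication matrix
formulation (tile row m1 of pair 1's matrices to full shape, combine
elementwise with pair 2's) is kept in the test suite as an independent
oracle.

## Synthetic data

`gen_complex` produces three perturbed helical bead chains (radius 2.3 Å,
rise 1.5 Å, 100° twist → ~3.83 Å consecutive spacing, jitter sd 0.15 Å)
laid side by side ~7 Å apart so a 10 Å cutoff connects everything into one
component (checked; regenerated with a warning on failure, at most five
attempts). Chain A carries the POUS/POUHD annotation with a two-residue
linker whose links are stretched ~1.2 Å each. Default sizes 60/40/30
residues mirror the rough proportions of a POU protein, an HMG domain and
an enhancer fragment. What it does **not** emulate: real secondary
structure, side-chain chemistry, sequence, or protein–DNA contact
geometry — passing tests therefore demonstrate the correctness of the
machinery, not biological conclusions about any particular complex.

`gen_curve_pair` plants a shared smooth latent signal (a standardised
sine with random phase) in one window of each curve: within the windows
the curves are positive affine maps of the latent plus independent noise
of sd σ = noise_sd·√((1−ρ)/ρ), which makes the expected within-window
correlation ρ at the default noise_sd = 1 (corr(g+e₁, g+e₂) = 1/(1+σ²)
for unit-variance g); noise_sd = 0 gives an exactly affine pair. Outside
the windows the curves are independent gamma(3, 1) noise — positive, as
befits magnitude curves. `gen_corr_table` draws |c| ~ U(0.02, 0.98) with
row-wise pairwise distinctness (rejection at gap 1e-4) and applies a given
or random ±1 sign pattern.

## Problem sizes and numerical choices

The reference end-to-end configuration is the 60/40/30-residue complex at
3 atoms per residue (390 atoms, 1170 coordinates) — large enough for a
clean six-mode rigid-body block and non-trivial curves, small enough that
a full run (dense eigendecomposition included) takes a few seconds.
Acceptance-style property checks use 100 random compact clusters of 10–60
nodes for the spectral suite, 200 random curve pairs (lengths ≤ 40) for
the search oracle, and 50 seeded pairs for planted-window recovery.
Tolerances: Hessian vs finite differences 1e-5 (step 1e-4); rigid-body
annihilation 1e-8 (translations) and 1e-6 (rotations) relative;
dense-vs-partial essential eigenvalues 1e-6 relative.

## Known limitations

* Published correlation tables for the two crystal structures the method
  was originally applied to are not reproduced: they depend on the exact
  (unpublished) server-side ENM parameters; this package fixes and
  documents its own.
* The per-row count identities assume distinct |c| values within a row;
  exact ties reduce the significant count, which the report surfaces via
  `significant_per_row`.
* The rotation-angle branch depends on the chosen residue representative
  and amplitude; both are configuration, and no canonical values exist.
* ANM networks with nearly collinear regions can possess soft non-rigid
  modes close to the zero threshold; the trivial-mode count is guaranteed
  only for reasonably compact, connected geometries.
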