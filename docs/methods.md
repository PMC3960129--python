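# Methods

This note documents the model, the numerical choices, the synthetic
study conditions, and the limits of what the test suite demonstrates.

## Statistical potentials

A statistical potential converts the frequency of a (sequence motif c,
structure motif s) co-occurrence in a dataset into an effective energy by
Boltzmann inversion. `tmpot` derives four potentials per dataset:

| kind  | sequence motif c              | structure motif s            |
|-------|-------------------------------|------------------------------|
| tor1  | amino acid + signed offset k, |k| ≤ window | torsion domain of residue i+k |
| tor2  | ordered amino-acid pair (a_i, a_j), 1 ≤ j−i ≤ window | torsion domain of residue i |
| dist1 | single amino acid             | distance bin (pair partner arbitrary) |
| dist2 | unordered amino-acid pair, j−i ≥ min_sep | distance bin |

The energy is

    ΔW(c, s) = −ln[ f̃(s|c) / f(s) ],   f̃(s|c) = (σ·f(s) + m_c·f(s|c)) / (σ + m_c)

in units of kT (kT ≡ 1: the dataset temperature enters only through
*which* proteins are counted; no absolute-temperature factor is
identifiable from the construction). The shrinkage parameter σ ≥ 0
interpolates between the plain inversion −ln[f(c,s)/(f(c)f(s))]
(abundant data, σ → 0) and zero energy (m_c → 0 or σ → ∞): a motif seen
too rarely carries no energy. Cells with f(s) = 0 or m_c = 0 are zero by
convention; with σ = 0 an unobserved (c,s) for a present motif is capped
at ln(2·n_total) — as if half an occurrence had been seen — to keep the
table finite.

Distance counts are first smoothed per motif row: core-bin counts are
replaced by Σ_k λ^|k|·n(b+k) (all core bins in reach, out-of-range terms
dropped), then rescaled so each row's core mass is unchanged. The
underflow and overflow bins are not smoothed. λ = 0 is the identity.

**Defaults and units.** window = 8 residues; min_sep = 2 (excludes
covalent neighbours); distance bins 25 × 0.2 Å on [3.0, 8.0) Å plus
underflow/overflow (27 bins, half-open intervals); σ ∈ {10, 50}
(occurrence counts); λ = 0.5. All are config-exposed. The σ and λ
defaults are package choices satisfying the construction's stated
limits; the two-σ averaging keeps both a mild and a strong shrinkage in
play.

**Torsion domains.** Seven half-open (φ,ψ) regions: A (helical,
φ∈[−120,0), ψ∈[−90,30)), C (φ∈[−120,0), ψ∈[30,90)), B (extended,
φ∈[−180,−120), ψ∈[60,180)∪[−180,−150)), P (polyproline-like,
φ∈[−120,−30), ψ∈[90,180)), G (left-handed, φ∈[0,120), ψ∈[−30,90)),
E (φ∈[0,180), ψ∈[90,180)∪[−180,−150)), and O (everything else). The
partition is a config artifact (`TorsionDomainTable`); all downstream
code only requires a consistent disjoint 7-way cover of the plane, and
tests verify coverage and disjointness on a dense grid. Dihedrals follow
the IUPAC sign convention, degrees in [−180, 180); φ is undefined at the
N-terminus, ψ at the C-terminus, and both wherever a backbone atom is
missing (such residues are kept for distance statistics but skipped in
torsion counts). Whether tor2 conditions on the domain of the first or
second residue of the pair is not decidable a priori; the first is the
default and the choice is a config flag (`tor2_domain_of`).

**Structure input.** PDB chains via Biopython; HETATM groups, waters and
non-standard residues are skipped and counted; only the first model is
used; altlocs resolve to the highest-occupancy conformer. The
residue-residue distance is between geometric centers of the heavy
side-chain atoms; glycine uses CA (standard centroid convention);
partial side chains are averaged over the atoms present.

## Datasets, Tm estimation and culling

Measured melting temperatures are scarce, so datasets are enlarged with
proteins whose host environmental temperature Tenv is known. Three rules
estimate Tm from context — none pretends to be accurate; they only
decide on which side of the meso/thermo split a protein falls:

1. **global regression**: an OLS line Tm = a·Tenv + b over all measured
   proteins;
2. **family regression**: the same line fitted within the protein's
   family (requires ≥ 2 measured members);
3. **identity transfer**: the Tm of the measured family member with the
   highest pairwise sequence identity (ties: higher identity, then
   lexicographic id).

Each family-enlarged dataset is split at the median Tm (equal-size
split; with an odd count the median protein goes to the thermostable
half) into a mesostable set (Tm < Tm0) and thermostable set (Tm ≥ Tm0);
the unsplit set is the "average" set. Each subset is culled so that no
pair exceeds 25% identity: the currently most-similar pair is resolved
first (ties by lexicographic id pair), a measured Tm always survives
over an estimated one, and otherwise the higher-Tm protein survives in
the thermostable set, the lower-Tm in the mesostable set, and the
closest-to-the-pre-culling-mean in the average set. The greedy order is
a package choice (the reference culling procedure is an external server
whose order is unspecified); it makes results reproducible.

Identity is computed from a global pairwise alignment (BLOSUM62, affine
gaps: open 11, extend 1, end gaps penalized) as identical positions over
alignment length, gap columns included. Tests verify the aligner against
exhaustive alignment enumeration on short sequences.

## Energies and prediction

Scoring a protein against a potential set sums the table entries over
the protein's motif occurrences (same window/min_sep as counting) and
divides by the residue count N, giving four per-residue terms in kT.
Scoring against the meso-, thermo- and average-derived sets yields
ΔG_M, ΔG_T, ΔG_A; the difference features ΔΔG = ΔG_M − ΔG_T isolate the
temperature dependence. Any per-family normalization factor multiplies a
linear model and is absorbed into the fitted coefficients (it is not
separately identifiable); per-family scaling is available as a flag.

The predictor is a linear model (`TmRegression`) with intercept, fitted
by closed-form least squares: the objective — σ, the RMS deviation
between predicted and experimental Tm — is a convex quadratic in the
coefficients, so the OLS solution is the exact minimizer (a generic
numerical minimizer would find the same point). σ is the RMS residual
(not the n−1 sample SD). Per-family σ values are RMS residuals within
each family under the single global fit, so the n-weighted mean of
squared per-family σ equals the overall σ² identically.

Zero-variance feature columns are absorbed into the intercept with
coefficient 0 (all-zero features give the intercept-only fit, prediction
= mean Tm); genuine collinearity among varying columns raises an error
naming the columns involved.

Cross-validation is leave-one-out. By default only the coefficients are
re-identified per fold (features fixed); strict mode re-derives the
potentials and all features without the held-out protein (the protein
then also drops out of every counting set — leave-out hygiene). The
iterative worst-k exclusion removes, k times, the protein with the
largest absolute jack-knife residual (ties by id) and refits; k = 0 is a
no-op.

## Synthetic study conditions

The generator (`tmpot.synthetic`) emulates the data situation —
homologous families, scarce measured Tm, Tenv-only members — with known
ground truth. Default conditions, chosen once:

* 3 families × 8 proteins × 80 residues; 75% of proteins have a
  "measured" Tm (true Tm + 2 °C noise), the rest only Tenv.
* True Tm drawn uniformly from a 5 °C grid on [40, 90] °C (the grid
  keeps planted contact counts exactly integral: slope × grid = 1).
* Tenv = (Tm − 25)/1.0 + N(0, 4 °C): proteins melt ~25 °C above the
  host growth temperature, with realistic scatter.
* Planted contacts: (D,R) side-chain pairs at 4.1 Å with count
  5 + 0.2·(Tm − 65), and at 6.9 Å with count 5 − 0.2·(Tm − 65). The two
  windows are complementary, so the total (D,R) contact count is
  Tm-independent: the thermal signal lives entirely in *which bin* the
  contacts occupy — readable by the meso-vs-thermo potential difference
  but invisible to the average-potential energy. This is the planted
  analogue of thermal stabilization without thermodynamic stabilization
  (e.g. the salt-bridge effect).
* Background contacts: 2–5 (A,R) pairs at 5.1 Å, count independent of
  Tm. Sharing R with the planted pair keeps the dist1 and dist2 feature
  directions linearly independent.
* Torsion plant: helix propensity 0.45 + 0.004·(Tm − 65) (extended
  propensity complementary), realized by sampling per-residue domains
  and building the backbone by exact forward kinematics (ideal bond
  lengths/angles, trans ω).
* Sequences: per family, a random ancestor mutated along the ladder
  (0, 0.05, 0.15, 0.3, 0.5, 0.7, 0.9), which produces within-family
  identities on both sides of the 25% culling cutoff. Amino acids used
  by planted/background contacts (D, R, A) and glycine are excluded from
  the free alphabet, so planted cells contain exactly the prescribed
  counts (verified by re-binning).
* Geometry: each contact pair occupies a dedicated, isolated island, its
  distance realized exactly; the remaining residues lie on a "ruler"
  line whose successive spacings cycle through the core bins, filling
  every distance column with Tm-independent mass from many amino-acid
  pairs — as in real datasets, where no single pair type dominates a
  bin. Side chains are decoupled from the backbone; only binned
  distances and torsion domains are guaranteed, not physical realism
  (no sterics, no packing).

`GeneratorConfig.noise_free()` defines the exact-recovery variant: one
family of 14 proteins, no mutations, no Tm noise, all proteins measured,
a two-level background count, a deterministic contact layout, and (in
the workflow) no identity culling. Under these conditions every energy
feature is an exact affine function of the two planted latent variables,
so the jack-knife σ of the ΔΔG-mode predictor is numerically zero
(~1e-12 °C). Culling must be off here because identical sequences would
collapse each subset to a single protein, where the background latent
can cancel exactly from both distance features.

## What the tests show — and what they do not

The acceptance suite verifies, on these synthetic conditions: exact
counting against brute-force recounts; the analytic limits of the
inversion and smoothing; culling correctness including every tie-break
rule; planted-signal detection (thermo-vs-meso potential difference with
the planted sign in the planted cells) in ≥95% of 50 replicates, with a
zero-slope control inside a permutation null; OLS parameter recovery
within 3 standard errors and σ_CV calibration on a feature-level linear
benchmark (n = 60); the ΔΔG-vs-ΔG_A mode contrast in ≥90% of 50
pipeline replicates; complete removal of 6 planted +40 °C outliers in
≥95% of 100 runs; and the per-family σ aggregation identity.

Problem sizes (24-protein pipelines, 50–100 replicates) were chosen so
the full suite and the acceptance script each run in minutes on a single
core while keeping the statistical assertions comfortably powered.

Passing these tests shows the machinery is correct and that the
temperature-dependent construction recovers planted thermal signals it
was designed for. It does not show predictive accuracy on real proteins:
synthetic structures have no sterics, no ligands, no solvent, no
experimental heterogeneity in Tm measurements, and their planted signal
is far cleaner than real temperature-dependent propensities. On real
data the method additionally inherits the limitations of its inputs —
potentials ignore ligands (heme-containing families are predicted
poorly), Tm estimates from Tenv are rough, and family regressions can be
unreliable for families of warm-blooded hosts with near-identical Tenv
but spread-out Tm.

## Degenerate inputs and tie-breaks

* Chains with zero standard residues, missing chains, unreadable files:
  explicit errors at parse time.
* Non-glycine residues with no side-chain heavy atoms are flagged
  incomplete; their distance pairs are skipped (CA fallback available as
  an opt-in).
* Distance exactly at a bin edge goes to the upper bin (half-open
  intervals); d = 8.0 Å is overflow, d = 3.0 Å is core bin 0.
* Estimation rules fail loudly, naming the missing ingredient; the
  pipeline skips (and logs) proteins that no rule can estimate.
* Culling ties (equal identity, equal Tm) resolve lexicographically by
  protein id; worst-k residual ties likewise.
* Jack-knife folds inherit the fit's collinearity check; a fold-level
  degeneracy raises rather than silently regularizing.
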