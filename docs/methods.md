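# Methods

This package implements the quantitative spine of a structure-based
agonist-discovery campaign: the post-docking triage of a score-ranked
library, geometric validation of docked poses, in vitro pharmacology
statistics, and in vivo summary metrics. This note records the models,
the defaults and why they were chosen, what the synthetic data does and
does not emulate, and the numerical decisions a maintainer would want
written down.

## Library triage

**Fingerprints and similarity.** Molecules are compared by hashed circular
fingerprints of radius 2 folded to 2048 bits (the conventional ECFP4
equivalent, computed with RDKit's Morgan generator) and the Tanimoto
coefficient Tc = |A∩B| / |A∪B|. Two empty fingerprints are defined to have
Tc = 0 (with a warning): scoring featureless molecules as identical would
let them collapse every cluster they touch. All thresholds in the cascade
are applied with this package's own fingerprinter; bit-exact agreement
with other toolkits is not promised, and thresholds ported from elsewhere
should be re-validated.

**Property windows.** The lead-like window defaults to 350–500 amu and
cLogP 3–5, read as closed intervals, so boundary molecules are kept. Both
bounds are parameters.

**Leader clustering.** The ranked list is clustered in a single greedy
pass in score order: each molecule joins the first existing cluster whose
leader it matches at Tc ≥ 0.5, otherwise it founds a new cluster. Because
the pass runs best-score-first, every representative is by construction
the best-scoring member of its cluster. This is deliberately not
complete-linkage clustering: the cascade's purpose is picking one
well-scoring exemplar per chemotype, and the greedy leader pass is the
algorithm that guarantees representative-by-best-score. Whether the
threshold is inclusive is consequential only for ties; ≥ is used and
score ties are broken by ascending id.

**Novelty and analog thresholds.** Candidates with maximum Tc ≥ 0.38 to
any reference ("known ligand") are rejected — the threshold is inclusive
on the rejection side — and an empty reference set keeps everything with
max Tc = 0. Analog search keeps pool members at Tc ≥ 0.5 to a named hit,
sorted by descending similarity with id as tie-break. Keeping both
thresholds on the same fingerprinter makes the kept/rejected sets
self-consistent even if absolute Tc values differ between toolkits.

**Bookkeeping.** Campaign summaries multiply mean orientations by mean
conformations per orientation (poses per molecule, reported to 3
significant figures in millions) and by the number of molecules fit
(total complexes). The hit-rate counts displacements *strictly* above the
threshold (default 50%), clips over-displacement to 100%, and reports
both the exact and integer-rounded rate. All guarantees are stated at
desk scale (hundreds of molecules); the code is not engineered for
300,000-molecule inputs.

## Pose geometry

**Symmetry-corrected RMSD.** Chemically equivalent atoms make the naive
index-matched RMSD ill-defined: swapping the labels of two equivalent
oxygens changes the number without changing the structure. Within each
element class, the atom correspondence is chosen by solving the optimal
assignment problem on the squared-distance cost matrix
(`scipy.optimize.linear_sum_assignment`, the Hungarian algorithm), and

    RMSD = sqrt( Σ_classes min_assignment Σ d² / n_atoms ).

The assignment is restricted to element classes only — no bond-topology
or automorphism check — which can be permissive for large ligands whose
same-element atoms are not chemically equivalent; for graph-aware
matching, use an automorphism-based tool. No re-superposition is
performed by default, because docked and experimental poses of the same
ligand already share the receptor frame; an optional `align=True` flag
applies an index-matched least-squares (Kabsch) superposition first for
poses that do not. Note the superposition uses the index correspondence,
so it is meaningful only when the input ordering is trustworthy. Brute-force enumeration
over same-element permutations (feasible to ~8 atoms per class) is kept
in the test suite as the independent oracle.

**Polar contacts.** Polar ligand atoms default to N and O heavy atoms
(S excluded: thioethers are poor hydrogen-bond partners at heavy-atom
cutoffs); explicit per-atom flags override the default. The filter
records, for each named receptor probe atom, the minimum heavy-atom
distance to any polar ligand atom, and passes when the required
combination of probes ("any" by default) is within the cutoff. The
cutoff defaults to 3.5 Å — the conventional heavy-atom hydrogen-bond
limit — inclusive, and is exposed as a parameter; no hydrogen placement
or angle criterion is applied, so the filter is distance-only and
slightly permissive.

## In vitro pharmacology

**4PL model.** Concentration-response data are fit on x = log10([L]/M):

    y(x) = bottom + (top − bottom) / (1 + 10^((log10 EC50 − x)·hill)),

parameterized by pEC50 = −log10 EC50 so that unit rescaling of
concentrations shifts pEC50 by exactly the log of the scale factor.
Rising agonist curves have hill > 0. Fitting is unweighted least squares
on replicate-level points (no stated weighting scheme justifies more);
initialization takes bottom/top from the response extremes, pEC50 from
the concentration nearest the half-maximal response, and hill = 1.
Standard errors are asymptotic (Wald) from the Jacobian; 95% CIs use the
t distribution on the residual degrees of freedom. A curve whose span is
below 1e-6 of its absolute scale, or whose covariance is singular, is
reported `converged=False` with a diagnostic instead of raising — flat
curves are data, not errors.

**Recovery simulations.** The fitter-recovery grid (pEC50 ∈ {6,7,8,9},
hill ∈ {0.7,1,1.5}, noise 5% of span, triplicates) uses 8-point designs
spanning ±3.5 log units around each true EC50. Bracketing the EC50 is the
standard recovery-study design; a fixed window that truncates the top
plateau (e.g. a micromolar EC50 against a 10 µM ceiling) measures range
censoring, not fitter bias. Under bracketed designs the absolute pEC50
bias is below 0.015 log units in every cell; CI coverage for pEC50 is
~95%.

**Normalization and derived quantities.** Raw signals are mapped to
percent of a reference agonist's fitted span (bottom → 0%, top → 100%).
If the reference fit is flat or unconverged, data pass through unchanged
with a flag rather than an exception, mirroring the convention of leaving
data unnormalized when the reference shows no response. Cheng–Prusoff
converts competition IC50 to Ki = IC50/(1 + [L]/Kd); the radioligand
concentration and Kd are required caller inputs, never assumed. Percent
activity is 100·(test − vehicle)/(reference max − reference baseline);
the denominator is the *reference span*, the reading under which the
reference compound itself scores 100%. Fold-changes report the exact
ratio alongside the integer-rounded value used in prose, and the caller
must name the parent compound — the package does not guess reference
compounds.

## Signaling signatures

BRET ratios are standardized as uBRET = (ratio − A)/(B − A)·10,000 with A
and B the negative- and positive-control ratios. Per pathway, activity is
summarized as log R = log10(Emax/EC50); Emax is conventionally in percent
of reference and EC50 in molar, and while the absolute log R depends on
that convention, the reported quantity Δlog R = log R(compound) −
log R(reference) does not. SEMs are σ/√n over independent experiments
and propagate as SEM_Δ = √(SEM₁² + SEM₂²); relative efficacy is
RE = 10^Δ, tabulated compound × pathway with the reference as a row of
exactly 1.0 for radar plotting. Pairwise comparisons use the two-tailed
unpaired Student t-test on the per-experiment log R summaries (Welch
optional); with fewer than two experiments the p-value is reported as
undefined while point estimates are still returned. No multiple-testing
correction is applied across pathways by default, matching per-pathway
pairwise reporting; `holm_adjust` provides the step-down family-wise
correction when wanted. A flat (no-response) pathway yields a missing RE,
not zero. Simulations at the panel's stated conditions (n = 4, σ = 0.1) show
the planted Δ = 0.30 recovered within 0.05, >80% power, and type-I error
within 2 points of the nominal 5%.

## In vivo metrics

**NCA.** Cmax/Tmax are the maximum observed quantifiable concentration
and its time. The terminal slope λz is fit by log-linear regression over
candidate windows of the last k ≥ 3 quantifiable points strictly after
Tmax, selecting the window with the best adjusted R² (the conventional
automatic rule; overridable by fixing k). T½ = ln 2/λz. AUC_last is the
linear trapezoid over the quantifiable span — linear-up/linear-down,
chosen as the simplest defensible default — and AUC_inf = AUC_last +
C_last/λz, with the extrapolated fraction reported. LLOQ handling is
asymmetric by design: below-limit values before the first quantifiable
point enter the trapezoid as zero, while below-limit values later are
treated as missing and excluded from the λz fit, so an unreliable tail
cannot corrupt the half-life. A non-positive terminal slope yields an
undefined T½ with a diagnostic, not an exception.

**Windows and scores.** The therapeutic window is (minimum significant
side-effect dose)/(minimum significant analgesic dose); when no
side-effect dose reached significance the highest tested dose is used
and the window is flagged `lower_bound_only`. Significance flags are
inputs from the caller's own statistics — the underlying ANOVAs are out
of scope — so the module never recomputes them. CPP scores are per-
chamber test-minus-pretest times in seconds; their sum equals the
difference in total session times. Affinity fold-changes convert to
binding free energy as ΔΔG = −RT ln(fold) with R = 1.987×10⁻³
kcal·mol⁻¹·K⁻¹ at 298.15 K; gains in affinity are negative.

## Synthetic data

All generators draw from one explicitly seeded
`numpy.random.default_rng` per call — no global state — and identical
seeds reproduce outputs exactly.

**Libraries.** A library of n molecules in k families is built from a
curated pool of 24 diverse drug-like scaffolds, each written so the
SMILES string ends at an aliphatic attachment point; members of a family
append one of 12 small substituents there. This yields intra-family Tc
typically ≥ 0.6 and inter-family Tc ≤ ~0.31 — cleanly separated around
the 0.5 clustering and 0.38 novelty thresholds. MW and cLogP are sampled
uniformly inside the configured closed ranges (they are labels, not
computed from the structures); scores are family base scores
(Normal(−38, 4), docking-energy-like) plus Normal(0, 2) member noise.
Ids encode the planted family for recovery scoring. What this does *not*
emulate: real chemotype families are not equally sized, their similarity
to references is not bimodal, and property labels correlate with
structure — so clustering-recovery results here bound the algorithm's
correctness, not its performance on a real screening deck.

**Pose pairs.** The first pose scatters atoms (cycled C/O/N pattern) with
≥ 3 Å minimum separation; the second applies a random permutation within
the requested element classes plus isotropic Gaussian displacement scaled
by fixed-point iteration until the optimal-assignment RMSD equals the
requested target within 1e-9 (the map s → RMSD(s) is essentially linear
while the optimal assignment is stable, so convergence takes a few
steps). These are point clouds, not conformers: no bonds, no chemistry —
sufficient for exercising assignment-based RMSD, nothing more.

**Curves and PK.** Dose-response generators add Gaussian noise (a stated
fraction of span) to exact 4PL values, recording the true parameters.
PK profiles follow the one-compartment extravascular model
C(t) = (F·D·ka)/(V(ka−ke))·(e^(−ke·t) − e^(−ka·t)); defaults (0.2 mg/kg
in a 30 g mouse, ka 0.05 min⁻¹, T½ 114 min, V/F 300 mL, LLOQ 2 ng/mL)
put Cmax in the mid-teens ng/mL so the standard nine-point schedule
(5–1440 min) retains a quantifiable terminal phase while the 24 h point
is genuinely censored — the regime the LLOQ rules exist for. ka = ke is
rejected as degenerate rather than special-cased to the limiting form.

**Pathway panels.** Per-experiment log R values are drawn
Normal(μ, σ) with the compound mean shifted by a planted Δ; Emax is
pinned at 100% so EC50 carries the shift. This matches the t-test's
normality assumption exactly, so the type-I-error simulation checks the
test's calibration, not its robustness to non-normal data.

## Problem sizes

Simulation-based checks run at sizes chosen to keep the full suite
interactive on a laptop while leaving Monte-Carlo error well inside each
tolerance: 10 × 500-molecule libraries for clustering recovery, 100
six-atom pose pairs against the brute-force oracle, 40 replicate fits per
cell of the 12-cell 4PL grid, 500 simulations for Δ-recovery/power and
2,000 for type-I error.

## Known limitations

- Fingerprint bits are toolkit-specific; thresholds are calibrated
  within this package only.
- Assignment-based RMSD ignores bond topology; it can under-report the
  deviation for ligands with same-element atoms in inequivalent
  environments.
- NCA supports linear trapezoids only (no log-linear option yet) and
  one terminal-window selection rule (best adjusted R²).
- The 4PL fitter reports asymptotic uncertainties; profile-likelihood
  or bootstrap CIs are out of scope.
- Behavioral significance flags are consumed, never computed; the
  package deliberately contains no ANOVA machinery.
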