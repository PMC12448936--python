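# Methods

This note documents the models implemented in `olfevo`, the study
conditions the synthetic generators encode, and the numerical choices
made where the underlying procedures are conventionally
under-specified.

## Spike quantification and sensilla classification

A single-sensillum recording trial is a list of spike timestamps with a
1-s stimulus at onset `t₀ ≥ 0.5 s`.  The net response is
`2 × (N[t₀+0.2, t₀+0.7) − N[t₀−0.5, t₀))` spikes/s: a 0.5-s response
window starting 0.2 s after onset (accounting for odor-delivery delay),
a 0.5-s pre-stimulus baseline, doubled to a per-second rate.  Windows
are closed-open, so a spike exactly on a boundary belongs to the later
window; both window constants are module-level and in seconds.
Responses may be negative and are never clipped — the downstream
BITC/(BITC + γ-hexalactone) spike ratio depends on this, and is
returned as NaN (undefined, not an error) when the denominator is ≤ 0,
as happens when the γ-hexalactone response falls below the solvent
control.

Control subtraction removes the mean solvent-trial net response per
sensillum.  Each sensillum must have at least one solvent trial;
missing controls are an error naming the sensillum rather than a silent
NaN.

Sensilla are classified from their response-profile vectors by
agglomerative clustering (Ward linkage on Euclidean distance, cut at
`n_classes`, default 3).  No clustering algorithm is canonical for this
task; Ward on response vectors was chosen because it is deterministic,
needs no tuning beyond the class count, and is invariant to uniform
scaling of all responses and to row order (labels are canonicalized by
sorted sensillum id).  The two-OSN ("a"/"b") identity within a
sensillum is taken from the input labels; spike-sorting is out of
scope.

## EC50 estimation

Both logistic forms are fitted in log10-concentration space for
conditioning, with `scipy.optimize.curve_fit` (tolerances 1e-14), a
restart grid over initial Hill slopes {0.5, 1, 2}, and the initial
log-EC50 at the tested concentration whose response is nearest
half-range.  Input points are canonically sorted before fitting so the
result is exactly independent of point order.  Estimates are reported
on the linear vol/vol scale.

**Failure criteria.**  "Failed to fit" is operationalized as: optimizer
non-convergence; fitted EC50 outside
[min tested concentration / 100, max tested concentration × 100]; Hill
slope ≤ 0; or (4P only) a collapsed dynamic range
(|top − bottom| below a machine-scale threshold), without which a
constant series would "converge" to an arbitrary EC50 and the
minimum-value fallback branch would be unreachable.

**Policy.**  The estimator first normalizes responses within the
chemical–species pair (negatives floored at 0, maximum scaled to 100)
and applies the 2P fit; chemicals on a configured forced-4P list skip
straight to the raw 4P fit, which is also the fallback when the 2P fit
fails.  If both fail, the minimum observed response value is reported
under the `min_value_fallback` method tag.  Note that this fallback
value is a response (spikes/s), not a concentration — the method tag
exists precisely so the two are never conflated.

**A bias worth knowing about.**  Normalizing to the observed maximum
makes the 2P fit exact only when the top tested concentration reaches
the plateau.  When it does not, the rescaling inflates every response
by the factor `1 + (EC50/x_max)^h` and biases the 2P estimate downward
— the very situation in which the free-ceiling 4P fit is the
appropriate branch.  The noise-free inversion checks therefore use the
4P fit on raw series (exact by construction) and the 2P fit on an
exactly normalized logistic.

**Recovery scenario.**  The parameter-recovery study uses 7
concentrations log-spaced over 10⁻⁵–10⁻² vol/vol, Gaussian response
noise of sd 5 spikes/s on a 0–100 spikes/s curve, Hill slope 1, and the
true EC50 at the geometric center of the tested range (10⁻³·⁵) — the
natural design for a recovery experiment, with the midpoint bracketed
on both sides.  Under these conditions the median relative EC50 error
of the full policy is ~12% over 100 seeded replicates.

## Behavioral indices

*Immobility*: % mobile per vial on the {10, …, 60}-min grid.  For the
log-rank comparison, a fly's event time is the first grid time at which
it is scored immobile (immobility is treated as absorbing) and flies
mobile at 60 min are right-censored; the interval-censored nature of
the grid observation is collapsed to the grid times.

*Positional choice*: % made choice = (odor + control)/released × 100;
% odor side = odor/(odor + control) × 100, undefined (NaN, excluded
from downstream signed-rank samples) when no fly chose.  An assay is
discarded only if participation is strictly below 40% at **every** time
point; exactly 40% anywhere keeps it.

*Consumption*: feeding score
`(0·n₀ + 0.25·n₀.₂₅ + 0.5·n₀.₅ + 1·n₁ + 2·n₂)/N` per vial, normalized
by the mean control score of the same (day, genotype); the normalized
null value is 1.  Comparisons across genotypes default to two-sided
Mann–Whitney; one-sided alternatives are available per configuration.

## Nonparametric tests

All four tests are implemented self-contained so the exact small-sample
null distributions are available, with `scipy`/`lifelines` used only as
independent cross-checks in the test suite.

* Signed-rank: zero differences dropped (Wilcoxon convention); exact
  p-values by a rank-sum-count dynamic program (equivalent to full
  2ⁿ enumeration) for n ≤ 25 without ties; otherwise tie-corrected
  normal approximation with continuity correction.  At the boundary the
  two paths agree to |Δp| ≤ 0.01.
* Mann–Whitney U: exact distribution via the Gaussian-binomial
  recurrence for n + m ≤ 20 without ties; tie-corrected normal
  approximation otherwise.
* Kruskal–Wallis H with tie correction; Dunn pairwise z-tests use the
  pooled tie-corrected rank variance and a Bonferroni adjustment over
  the tested pairs by default (the adjustment is configurable; no
  particular one is canonical).
* Log-rank (Mantel–Cox): observed-minus-expected event sums with
  hypergeometric variance across distinct event times, χ² with 1 df.

Under simulated continuous nulls the empirical size of every test is
within the binomial band of α = 0.05 (500 replicates).  Note that at
very small n the exact tests are conservative purely through
discreteness of the null distribution — e.g. the two-sided exact
Mann–Whitney at n = m = 10 has attainable size 0.043; size simulations
use sample sizes at which the nominal level is attainable.

## Expression summaries

RPM uses the column (library) sum over **all genes present in the
table** as denominator, not the Or subset — whether the original
denominator was all mapped reads or all counted genes is ambiguous, and
the counted-genes convention is reproducible from the input table
alone.  The low-expression filter excludes a gene when its median
log2(RPM + 1) across replicates is strictly below 1; with multiple
sample groups a gene is retained if it passes in at least one group
(per-group display convention), with an `require_all_groups` flag for
the stricter alternative.  Cell-count ratios are per-animal
receptor-positive / Orco-positive counts (Orco-positive cells proxy the
total OSN population), compared across species by two-sided
Mann–Whitney.

## Structure screen

Models are Cα-only with per-residue pLDDT (stored in the PDB B-factor
column, as structure predictors emit).  Residues with pLDDT > 70
(strict) are considered reliable; disordered termini fall below this.

**Superposition frame.**  The two models are superposed once, by a
least-squares Kabsch fit (SVD with proper-rotation correction) over
*all* mutually confident residues, and regional RMSDs are then measured
under that fixed global transform.  Re-fitting per region would absorb
exactly the local divergence the screen is trying to measure.  Cα-only
RMSD is used throughout; all-atom selection is out of scope.

**Greedy selection.**  Candidates are all sequence differences between
the paralogs (donor residue substituted into the background sequence).
Each round evaluates every remaining candidate through the prediction
backend (a pure, deterministic function of sequence, cached by
sequence), fixes the best S5–S6-RMSD reducer (ties broken toward the
lowest residue position), and repeats until the target-region RMSD
falls to `max(0.15 Å, median RMSD of the non-target regions)` — i.e.
"comparable to the other helices" — or no candidate reduces it
further.  Greedy forward selection was chosen for the otherwise
under-specified "repeat until resolved" loop; with distinct reduction
values the accepted set is independent of candidate order.

## Synthetic study conditions

The generators define the conditions under which the pipeline is
exercised; passing tests demonstrate correct computation under these
conditions, not performance on real recordings or real predicted
structures.

* **Spike trains** are homogeneous Poisson (baseline rate everywhere,
  baseline + response rate inside the response window, step rate at the
  window edges).  Real spike trains have refractoriness, adaptation and
  response latency jitter; none of these affect the counting formulas
  under test.
* **Dose-response series** are 2P logistic plus i.i.d. Gaussian noise
  truncated at −max_response.  Replicate structure and
  heteroscedasticity of real SSR dose series are not modeled.
* **Structure pairs** are an idealized 7-helix Cα bundle (helices on an
  11 Å circle, 1.5 Å rise and 100° turn per residue, interpolated
  loops; default 400 residues with S5 = 170–200, S6 = 290–320).  The
  divergent paralog adds, at each planted causal position, a Gaussian
  displacement field (sd 3 residues) confined to S5–S6.  The default
  peak amplitude of 4.2 Å was calibrated once so the S5–S6 regional
  RMSD of the default two-site pair is ≈1.7 Å, the divergence scale the
  screen is designed to resolve; 30 decoy substitutions are
  structurally silent, modeling sequence differences with no local
  structural consequence.  The mock prediction backend returns the
  background bundle plus the field of every causal site whose donor
  residue is present — a perfectly informative predictor.  Optional
  per-coordinate Gaussian jitter (default scenarios use 0.04 Å,
  deterministic per sequence) emulates predictor reproducibility error
  and yields ≈0.1 Å inter-model RMSD in unperturbed regions, so the
  converged screen ends at the ~0.1 Å floor rather than 0.  Real
  predictors are nondeterministic across versions, can move distant
  regions in response to a substitution, and have confidence-correlated
  error; the mock backend has none of these properties.
* **Behavior tables**: tube choices are Bernoulli per fly with an
  exponential time-to-commitment (half-life 10 min) observed on the
  5–35/65-min grid; immobilization times are exponential per-arm
  hazards, censored at 60 min and discretized to the 10-min grid;
  feeding categories are multinomial per vial.  Choice-side switching
  and non-absorbing recovery from immobility are not modeled.

All generators draw from a single `numpy` Generator seeded by a
required `seed` argument; identical spec + seed reproduces outputs
bit-for-bit, and no global random state is touched.

## Known limitations

* The screen assumes equal-length paralog sequences (pre-aligned
  input); indel handling is the caller's responsibility.
* Only a mock prediction backend ships; a real ColabFold adapter must
  satisfy the same pure-function contract (rank-1 model, deterministic
  for a fixed sequence) and is deliberately not bundled.
* mmCIF input, all-atom RMSD, ligand docking, and spike sorting from
  raw voltage traces are out of scope.
* Confidence intervals for EC50 are not provided beyond the residual
  diagnostics; a bootstrap would be the natural extension.
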