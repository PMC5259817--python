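# Methods

This note documents the models and procedures implemented in `pginflate`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the simulation can show about real
data.

## Database construction

**Digestion.** Trypsin cleaves C-terminal to K or R but not before P.
`digest` enumerates fully-tryptic peptides as runs between cleavage points
(protein termini count as tryptic) spanning at most `max_missed_cleavages`
internal cleavage points (default 2), with a minimum length of 8 residues.
Semi-tryptic mode additionally enumerates peptides with exactly one tryptic
terminus, under the same missed-cleavage budget. Peptides containing `X`
(indeterminate residues) are kept in sequences but excluded from peptide
statistics, since they cannot be matched.

**Decoy transforms.** Pseudo-reversal and pseudo-shuffling act per tryptic
segment with the C-terminal residue fixed in place, so decoy proteins remain
tryptic and preserve the length and residue multiset of their targets. For
whole-protein decoys the protein is segmented at every cleavage point (the
mc = 0 segmentation) and each segment transformed independently; only this
segmentation re-assembles unambiguously into a same-length protein, whereas
overlapping missed-cleavage peptides do not. The shuffles are uniform over
permutations fixing the last residue; at database scale they are computed by
a single sort of (segment id, 32-bit random key) pairs over the flattened
residue array, which makes a 6 × 36 M AA decoy build take well under a
minute.

**Simulated proteogenomic databases.** `1TnD` = reference ++ one
pseudo-reversed copy ++ (n − 1) pseudo-shuffled copies (the simulated-novel
block); the matched decoy is (n + 1) pseudo-shuffled copies. Total lengths
are exactly (n + 1) × the reference length on both sides. Random streams are
derived from one master seed with (role, copy-index) spawn keys, so target
and decoy copies are reproducible and disjoint.

**Six-frame translation.** ORFs start at an exact ATG and end at the first
in-frame stop (TAA/TAG/TGA, excluded); codons containing N translate to X;
default minimum ORF length is 8 aa, matching the minimum peptide length.
Frames with no in-frame stop before the contig end are emitted and flagged
`partial` rather than silently dropped. Coordinates in identifiers are
1-based, inclusive, on the forward strand. Alternative start codons
(GTG/TTG) are not considered; these rules are declared defaults, not
inferences about any particular external tool.

## The search-score model

Each spectrum reports one best match against the concatenated database,
partitioned into known targets (reference), novel targets (the inflation
block) and decoys.

* With probability `p_correct` the spectrum's true peptide is in the
  database and its match scores `Normal(gaussian_mu, gaussian_sigma)`.
  Truth lies in the novel partition for a fraction `p_novel_true` of true
  peptides (assigned at the peptide level, so a peptide is consistently
  known or novel).
* Every non-empty partition of `m` candidates contributes its best random
  score, `Gumbel(gumbel_mu0 + gumbel_beta · ln m, gumbel_beta)` — the exact
  distribution of the maximum of `m` i.i.d. Gumbel scores. This is the
  extreme-value mechanism by which database growth inflates random-hit
  scores by `β · ln(growth)`.
* The reported PSM is the argmax over the correct candidate (if any) and
  the partition maxima, carrying the winner's provenance and correctness.
  Feature columns: `delta_next` (winner minus runner-up) and
  `mass_error_like` (tight zero-centred normal, σ = 0.005, for correct
  matches; uniform on ±0.5 otherwise; the `informative_features=False`
  switch makes it uninformative for both classes).

The decoy partition is split between the known and novel groups in
proportion to the target partitions — with `m_novel = n·m_known` and
`m_decoy = (n+1)·m_known` this pairs one reference-sized decoy block with
the known group and `n` blocks with the novel group, mirroring how the
decoy database is constructed from shuffled reference copies.

### Default parameters and why

| parameter | default | rationale |
|---|---|---|
| `m_known` | 688,452 | unique fully-tryptic peptide count of a yeast reference proteome |
| `n_spectra` | 20,000 per stratum | a realistic LC-MS/MS run; large enough for stable counts, small enough for minutes-scale sweeps |
| `p_correct` | 0.35 | typical fraction of identifiable spectra in lysate data; yields ~3,300 accepted peptides per stratum at 1% FDR, the scale reported for yeast 2+ searches |
| `p_novel_true` | 0.01 | novel identifications are ~1% of the total in published proteogenomic searches |
| `n_true_peptides` | 4,000 | distinct true peptides per run, giving a realistic PSM-per-peptide multiplicity |
| `gumbel_mu0`, `gumbel_beta` | 0, 1 | scale convention for per-candidate random scores |
| `gaussian_mu`, `gaussian_sigma` | 23, 2 | places the correct-score population relative to the random maxima so that five-fold inflation costs pooled TD filtering ≈ 9% of accepted peptides — the sensitivity loss reported for real yeast searches — while separate filtering stays nearly flat |
| `charge_strata` | 2+, 3+ (3+ shifted −2) | strata are simulated and filtered independently; the lower 3+ location reflects the weaker identifiability of 3+ spectra |

These defaults are the simulation's study conditions; experiments vary
`m_novel`, `m_decoy` and the seed, not the score model.

## Validation procedures

**Target-decoy filtering.** At every observed threshold `t` (accept iff
value ≥ t) the FDR estimate is `N_D / N_T`; estimates are monotonized into
q-values by a running minimum from the most permissive threshold upward, and
the largest acceptance set with q ≤ α is returned. Records tied on the
ranking value are accepted or rejected together. The estimator is the plain
ratio, without the "+1" decoy correction: at a *selected* threshold this is
known to be slightly anti-conservative (the selection favours thresholds
where the decoy count dips low), and with ~3,300 accepted peptides we
measure the realized FDR at α = 1% to be ≈ 1.1% — a property of the
estimator itself, reproduced deliberately.

**Mixture model (MB).** A two-component mixture
`π0 · Gumbel(μ_g, β_g) + π1 · Normal(μ_n, σ_n)` is fitted by EM to the
target PSM scores (decoys excluded by default; a pooled fit is available via
`include_decoys`). The M-step updates the Gaussian in closed form and the
Gumbel by weighted maximum likelihood, solving the scale equation with
Brent's method (bracket grown geometrically; the β → 0 limit handled
analytically). Initialization is moment-based: Gumbel moments on the lower
60% of scores, Gaussian moments on the top 20%, π0 = 0.8. The
log-likelihood is non-decreasing every iteration; a collapsing component
(σ or β below 1e-6, or a vanishing mixing weight) stops the fit with
`converged=False`. PEPs are `π0 f0 / (π0 f0 + π1 f1)` computed in log-space
(scores where both densities underflow are treated as certainly incorrect).
The MB threshold is the most permissive score with mean PEP ≤ α. A
parametric EM stands in for semi-parametric kernel fitting; when the
incorrect-component shape deviates from Gumbel (as it mildly does for
argmax-selected winners), MB's PEPs can be optimistic and its realized FDR
exceeds the nominal level — visible in the experiment tables because the
simulator knows the truth.

**Self-boosted rescoring (BP).** A deliberately small Percolator-style
rescorer: features (score, delta_next, |mass_error_like|) are standardized;
per boosting round (default 5), positives are target PSMs accepted at 1%
FDR under the current ranking (raw score initially, the running average of
recalibrated scores afterwards; rounds after the first subsample 80% of the
positives under a round-specific sub-seed), negatives are decoys, and a
logistic regression is trained per cross-validation fold (default 3),
scoring only held-out PSMs. The final score is the round average. With no
decoys or no positives the raw score is returned with a warning. The full
engine feature set and SVM machinery of production rescorers are
intentionally out of scope.

**Separate filtering.** Learning steps (rescoring, mixture fitting) run
once on the pooled PSMs — the novel group alone is too small to train on —
then records are partitioned by group and thresholded independently with
`N_D / N_T` on the method's ranking field (raw score, recalibrated score, or
1 − PEP). Decoy PSMs carry the group of the decoy sub-partition they were
drawn from (reference-paired decoys → known, inflation-paired → novel); a
proportional-allocation alternative would change only the group-wise decoy
counts, and the simulated construction makes the paired assignment the
natural one.

**Two-stage FDR.** Stage 1 filters the reference-only search at α (peptide
level); spectra whose PSM was not accepted are re-searched against the full
proteogenomic database and stage 2 is filtered at α independently. In
simulation, a spectrum's latent correct score is a property of the spectrum
and is shared between stages, while random-hit competition is redrawn per
stage.

**Peptide level.** All methods collapse to the best PSM per peptide before
thresholding, ranking by the method's own field; ties break on spectrum id.

## The inflation experiment

For each inflation factor `n`, partition sizes are `m_known`,
`n · m_known`, `(n+1) · m_known`; each replicate derives a sub-seed from the
master seed, simulates the search, and runs all seven methods. Replicates
are aggregated as mean ± SD. The experiment reproduces the *qualitative*
findings — pooled TD/MB counts decrease in `n`; separate filtering keeps
known-peptide counts nearly constant and strips most novel acceptances; the
empirical FDR of pooled-accepted novel peptides far exceeds the nominal
level when the novel partition is spurious — not the absolute counts of any
real data set, which depend on the actual spectra and engines.

## What the simulator does and does not emulate

It emulates the statistical structure that FDR procedures react to:
size-dependent extreme-value competition between database partitions,
a correct-score population insensitive to database size, class-informative
auxiliary features, charge strata, and peptide-level multiplicity. It does
not model spectra, fragmentation, precursor masses, retention time,
engine-specific score formulas, correlated spectra of the same analyte, or
homology between database partitions. Passing tests therefore certify the
*procedures* (estimators, thresholds, orderings) under the declared score
model — not engine behaviour on any particular sample.

## Numerical choices and problem sizes

Thresholding uses exact tie-group boundaries; q-value monotonization is a
reverse cumulative minimum; EM stops at log-likelihood change < 1e-8 or 500
iterations; the Gumbel scale root is bracketed in [1e-8, 2^k · max(β̂, 1e-3)]
and solved to xtol 1e-10. The test suite runs the sweep at 20 replicates ×
20,000 spectra on one stratum and the calibration check over 50 seeds; the
database-arithmetic checks build synthetic proteomes of 3,062,279 AA
(yeast-sized) and 35,856,033 AA (human-sized) and transform them at full
scale. All randomness flows from named sub-seeds of a single master seed.

## Known limitations

* `N_D/N_T` without the +1 correction is anti-conservative at the selected
  threshold (≈ 10% relative at these problem sizes), so realized FDR sits
  slightly above α even in the calibrated n = 0 setting.
* MB calibration inherits the parametric model's misfit; its accepted sets
  run larger and less reliable than TD's at the same nominal level.
* The synthetic `mass_error_like` feature separates classes more cleanly
  than real mass errors do, so BP's gains (and its robustness to inflation)
  are upper bounds on what rescoring achieves in practice.
* Separate filtering of a small novel group rests on very few decoys; its
  novel-group FDR estimates are noisy at realistic novel fractions, which
  is faithful to the underlying difficulty rather than an artefact.
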