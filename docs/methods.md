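# Methods

## Data model

Genotypes are recombinant-inbred (RI): each strain is homozygous at every
marker, so a genotype is a single bit (1 = *B* allele, 0 = *D* allele).
Heterozygous or unknown calls are imputed at load time with the per-marker
mode (ties resolved to 1); the count of imputed calls is reported, because the
choice is a convention, not a fact about the data. Coordinates are 1-based
inclusive internally; BED input is converted at ingest. All distance cutoffs
(cis windows, the gene→marker rule) are physical base pairs.

## Mapping methods

**Single-marker LOD (HK).** For RI strains scored at the markers themselves,
interval-mapping regression reduces to one-marker least squares:
LOD_m = (n/2)·log₁₀(RSS₀/RSS₁), with RSS₀ the intercept-only residual sum of
squares. RSS₁ is floored at 10⁻¹⁰·RSS₀, capping a perfect fit at (n/2)·10
instead of infinity; the floor is recorded in output metadata.

**Composite mapping (CIM).** A deliberately simplified marker-based variant of
composite interval mapping: cofactors are chosen by greedy forward selection
(default 3; each step adds the marker with the largest RSS reduction,
implemented by Gram–Schmidt residualization; collinear candidates are
skipped with a warning). Scoring marker m drops cofactors on m's chromosome
within 10 Mb (which silently handles the self-exclusion case) and compares
the cofactor model with and without m on the LOD scale. When the cofactor
background already fits the trait to numerical precision, the test LOD is 0 —
there is no evidence left to apportion. With zero cofactors the scorer is
bit-for-bit the single-marker LOD. The window is in base pairs because the
synthetic fixtures carry no genetic map.

**Penalized regression (LASSO / ENET).** The naive elastic net
min ‖y−Xβ‖² + λ₂‖β‖² + λ₁‖β‖₁ is solved exactly along the L1 path by LARS on
ridge-augmented data (λ₂ = 0 is the lasso; the elastic net uses λ₂ = 1).
Predictors are standardized internally and coefficients reported on the
standardized scale. The path is parameterized by the fraction
s = ‖β‖₁ / max‖β‖₁; s is selected on the grid {0.5, 0.55, …, 1.0} by 10-fold
cross-validated MSE (folds: round-robin after a seeded shuffle; each fold
re-standardizes and refits its own path and reads s as a fraction of its own
maximal norm). The 0.5 floor prevents models too sparse to score several
loci. Coefficients between path knots are linear in the L1 norm, so grid
values are interpolated exactly. When near-duplicate marker columns break the
LARS active-set update, a coordinate-descent path over a dense penalty grid
stands in.

**Regression forest.** A bagged CART forest over the binary markers:
bootstrap of n strains per tree; at each node a random mtry-subset of markers
(default ⌊p/3⌋) is scanned and the best variance-reducing split taken; a node
is split only if the split strictly reduces RSS and the node holds more than
`nodesize` bootstrap samples (default 5) — except the root, which is always
eligible. The root exemption means nodesize = n yields stump forests that
stop after the first split, the shallow end of the depth ladder. The grower
is numba-compiled and records, per tree, every split (marker, RSS decrease)
and the in-bag multiplicities, which the importance measures need:

* **RFPI** — for each tree and each marker the tree split on, the marker's
  out-of-bag values are permuted once (seeded) and the increase in OOB MSE
  recorded; the average over all trees, unscaled. Trees not using a marker
  contribute zero.
* **RFRSS** — summed RSS decreases of a marker's splits, divided by the tree
  count.
* **RFSF (raw)** — a marker's split count divided by the tree count. The
  per-tree normalization is a choice (any positive scale preserves ranking);
  it makes the 5,000-tree study forest and the pooled 5,000-tree null
  commensurate, which the subtraction below requires.

**Selection-frequency bias correction.** 500 forests of 10 trees each are fit
to independent standard-Gaussian traits on the actual genotypes (5,000 trees
in total, matching the study forests). Pooled null selection frequencies are
not flat: markers in strong LD are under-selected because the block shares
its splits. The correction vector is the per-marker deviation from the mean
null frequency; subtracting it from observed selection frequencies removes
the bias (corrected scores may be negative). The null forests reuse the
study forests' mtry and nodesize, recorded in the model's provenance.

## Simulation study

Traits start at baseline 9; additive terms add coefficient × genotype;
epistatic terms add a coefficient times the logical AND of the binary
genotypes. Models: single locus (coefficient 1); two-locus epistatic
(0.25 + 0.25 additive, AND coefficient 1); three-locus additive (0.25 each);
three-locus epistatic (0.25 each plus a three-way AND at 1 — the three-locus
recipes mirror the two-locus one, and are configurable); eight-locus
(2 strong at 1.0, 6 weak at 0.25, all additive — coefficients are a package
choice, so comparisons built on this model are directional, not numeric).
Gaussian noise has standard deviation equal to a percentage (the "noise
level", ladder 2.5–20%) of the noiseless trait mean — the mean is read before
noising, since the noise scale must be defined first.

Per replicate, causal loci are redrawn uniformly (without replacement, no two
within 10 marker indices — tightly overlapping models are unidentifiable;
the spacing rule is recorded in output metadata). Every method scores the
same noisy data. A method/noise cell is summarized by the median over
replicates of the worst (maximum, ties get the group's worst) rank among
causal markers, and "succeeds" when that median fits the top-1% set size
k = ⌈0.01·p⌉.

## Knowledge-driven benchmarks

**cis proportion.** A trait is cis-recovered when a top-1% marker lies within
the window (500 kb mouse / 50 kb yeast defaults) of its gene's midpoint.
Unannotated genes are excluded and counted.

**Pathway enrichment.** Genes map to their nearest same-chromosome marker;
genes farther than 5 Mb from any marker are omitted (ties toward the lower
coordinate). For each trait, each pathway containing the trait's gene is
tested by the hypergeometric upper tail of |top-set ∩ pathway markers| with
the population being all markers in the map (the top set is drawn from the
full map; the alternative universe is recorded in output). The trait's own
gene is excluded from the pathway's marker set — otherwise a cis hit would
masquerade as a pathway hit (a flag restores inclusion). The minimum P over
pathways represents the trait. Because min-over-pathways on a fixed-size
marker set is biased even for random scores, raw Ps are corrected against an
empirical null: random Gaussian score profiles pushed through the identical
test (each trait's own pathway context, the min rule included; 1 null
replicate per trait by default, configurable upward), pooled, and
corrected_i = (1 + #{null ≤ raw_i}) / (1 + M) — add-one smoothing keeps
corrected P > 0. The corrected distribution is summarized by the one-sided
KS statistic D = sup(ECDF(x) − x) against uniform with the asymptotic tail
p = exp(−2nD²); only D and orderings drive the comparisons, so exact small-n
KS distributions are unnecessary. The TF-centric variant tests the union of
pathways containing any known transcription factor of the trait's gene.

**Mutant enrichment.** Each mutated regulator maps to its nearest marker
(5 Mb rule). Per trait, over top-set markers that are mapped markers of
mutated regulators, the maximum |log₂ ratio| of the regulator's deletion
effect on that trait's gene is collected; the null repeats this with the
trait's scores permuted across markers. One-sided two-sample KS, alternative
"observed accumulates slower" (tends to larger changes):
D = sup(F_null − F_obs), p = exp(−2D²·n₁n₂/(n₁+n₂)).

**Method overlap.** Per trait, overlap(A,B) = |S_A ∩ S_B| / ((|S_A|+|S_B|)/2),
averaged over traits, ×100. The mean-size denominator is a declared choice:
with fixed-size top sets it is monotonically related to Jaccard.

**Tree-depth and subsample studies.** The depth study refits forests over the
nodesize ladder 5, 15, 29, 57, 114 (or any list), re-estimates the
selection-frequency bias with a matching-nodesize null per rung, and re-runs
a chosen benchmark; improvements are read against the stump forest
(nodesize = n). The subsample study re-runs mapping + benchmarks on nested,
seeded strain subsets in decreasing size; the full-size subset preserves the
original strain order, so it reproduces the full-data result exactly.

## Synthetic fixtures

`generate_fixture(FixtureSpec)` builds a complete study: an RI panel
(two-state Markov chains along randomly placed marker positions — irregular
maps are realistic and create the heterogeneous local LD the bias correction
targets; switch probability min(0.5, 2(1−e^(−c·d))), the doubled
recombination fraction mimicking RI map expansion); one trait per gene,
planted cis (own nearest marker, coefficient 1.0) or trans (a planted
regulator's nearest marker, 0.8, optionally with an AND-epistatic partner,
plus a weak local term 0.25 and optionally weak extra same-pathway
regulators); pathways built so each regulator co-occurs with its targets
(plus fillers so every gene is in one); a TF→target map of the planted
regulation; and a mutant table with large planted |log₂| ratios (3.0×
jitter) against a 0.1 background for all other regulator–gene pairs. Ground
truth (causal markers per trait, regulators and their markers) is emitted as
JSON. Defaults: 100 strains, 5×100 markers at ~1 Mb spacing, 60 genes, 50%
cis, 6 regulators, 5% noise.

What the fixture does **not** emulate: measurement batch structure,
non-Gaussian expression noise, polygenic backgrounds beyond the planted
terms, allele-frequency skew, or annotation errors — so green benchmarks here
demonstrate correctness of the machinery and the expected orderings under
the planted model, not performance on any real tissue.

## Desk-scale study conditions

The bundled end-to-end checks and `scripts/acceptance.py` run on fixed
synthetic panels chosen to expose each phenomenon at ~500–600 markers, where
the top-1% set holds only k = 5–6 markers (full-size studies had k ≈ 29–38,
which changes what is observable):

* a **dense** panel (90 strains, 500 markers, ~1 Mb spacing, adjacent-marker
  r ≈ 0.95) where LD blocks span many markers — used for the bias-flattening
  study and the two-locus epistatic comparison, whose mechanism is broad LOD
  peaks crowding the small top set;
* a **sparser** panel (~2 Mb spacing, r ≈ 0.6) — used for locus-recovery
  studies; at k = 5 a dense map would make sparse regression methods drop
  the causal marker in favour of a near-duplicate neighbour, a scale
  artefact rather than a method property;
* a **120-strain × 600-marker** dense panel for the flattening ratio;
* the **weak-effect fixture** for the depth study: trans traits driven by a
  strong *unannotated hub* locus plus weak same-pathway regulators (0.25)
  and a weak local term — shallow forests see only the hub, so the benefit
  of depth is measurable in both the cis and pathway benchmarks. If the
  strong driver carried pathway signal itself, the min-P correction would
  floor and the KS D would saturate regardless of depth.

Problem sizes in the checks (20–250 replicates, 500–1,000-tree forests for
replicated studies, 5,000 trees in single-fit examples and nulls) are the
package's standing choices for these conditions. Weak-locus recovery events
at k = 5 are rare, so that comparison pools 250 replicates.

## Numerical choices and degenerate inputs

* Ties in top-percentile sets and ranks break deterministically by genome
  order; all-tied profiles yield well-defined sets (flagged by a warning).
* Zero-variance traits map to all-zero profiles with a warning everywhere.
* Split gains must exceed 10⁻¹² to count; binary markers make thresholds
  trivially 0.5.
* The hypergeometric tail uses the survival function in log space; KS
  p-values are the asymptotic one-sided forms, clipped to [0, 1].
* One master seed derives per-stage, per-trait streams by stable hashing of
  stage labels, so adding a trait never reshuffles other results; pipeline
  reruns with the same configuration are byte-identical, and outputs carry
  the master seed, a configuration hash and a marker-map hash.

## Known limitations

* CIM here is a simplified marker-based re-implementation (no interval EM,
  no genetic map); it serves as a legacy-method comparator, not a reference
  implementation, and with few cofactors its top sets resemble the
  single-marker LOD's far more than a full CIM's would.
* Sparse partial least squares is not implemented; external score tables can
  be imported as method `EXTERNAL` for benchmarking.
* No significance thresholds are produced: the benchmarks compare whole
  score distributions and fixed-size top sets, not per-trait significance
  calls, and no multiple-testing control across traits is attempted.
* Interval (pseudomarker) mapping between markers is out of scope; all
  scores live at marker locations.
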