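# Methods

This note documents the models and conventions behind `clipfoot`, the
parameters that matter, what the synthetic data do and do not emulate, and
the design choices made where more than one defensible option existed.

## Footprint construction

All coordinates are 0-based half-open (BED convention) throughout; the
interval kernel (`clipfoot.intervals`) is written from scratch so its
semantics are fully specified here rather than inherited from an external
tool.

- **Background depletion** (`subtract`): every base of a peak covered by
  any background interval (size-matched input or pooled IgG peaks) is
  removed; peaks wholly covered vanish, split peaks yield fragments that
  inherit the source peak's score and name. Comparison is strand-agnostic
  by default, matching the default behaviour of the standard interval
  tools; strand-aware variants sit behind a flag.
- **Merging** (`merge`): overlapping and book-ended intervals (end ==
  start) are unioned at `gap=0`; a `gap > 0` bridges nearby intervals.
- **Consensus footprints**: candidate regions are the merge of the union
  of all replicate footprints (not a reference replicate — a documented
  choice, since no replicate is privileged). A replicate supports a
  candidate iff one of its intervals overlaps it by at least
  `min_overlap` nt; the default of 2 nt is the strict reading of a
  "more than 1 nt" overlap requirement, and the default `min_support=2`
  encodes the 2-of-3 / 2-of-4 majority rule for the 3- and 4-replicate
  groups this analysis uses. The reported region is the merged union
  (the broader, safer representation for gene-level downstream use).
- **Closest feature**: distance between nearest span edges, 0 on overlap;
  exact ties return all tied genes in lexicographic order. Intervals on
  chromosomes absent from the annotation are flagged unassigned rather
  than raising.
- **Genic-region proportions**: each interval overlapping annotation gets
  one class by majority of overlapped bases; exact ties break by the
  precedence CDS > 5′UTR > 3′UTR > intron (a package convention — coding
  impact first; the choice only matters on exact ties). Intergenic
  intervals are excluded from the denominator, so proportions are over
  intervals mapping to annotated regions.

## The copula-mixture IDR model

Peak scores from two replicates are matched one-to-one (greedy, by
descending combined score among pairs overlapping ≥ 1 nt; greedy was
chosen over optimal matching for determinism and speed, and a test
quantifies its agreement with the exhaustive maximum-weight oracle).
Matched scores are reduced to midranks per replicate and mapped to
uniforms with the n/(n+1) ECDF correction, so the fit is invariant to any
strictly monotone transform of either replicate's scores. Pseudo-data
z = G⁻¹(u) are obtained by inverting the current mixture marginal CDF
G(z) = π₁Φ((z−μ₁)/σ₁) + (1−π₁)Φ(z) on a 4096-point grid (monotone, so
linear interpolation inverts it to well below the EM tolerance).

The mixture has a fixed null component (standard bivariate normal,
correlation 0) and a signal component N((μ₁, μ₁), σ₁², ρ₁). EM runs on
fixed pseudo-data (up to 50 inner steps) with the pseudo-data refreshed
each outer iteration, up to `max_iter=100` outer iterations; convergence
is declared when no parameter moves more than `tol=1e-4` across a
refresh. Initialization is fixed at (π₁, μ₁, σ₁, ρ₁) = (0.5, 1, 1, 0.5)
for reproducibility — there are no random restarts. The self-consistent
refresh scheme can crawl near its fixed point; in that case the capped
result is returned with `converged=False`, which at these defaults is
common and benign (parameter movement per iteration is far below the
scientific tolerances). Estimates are clipped to constraint boxes
(π₁ ∈ [1e-4, 1−1e-4], μ₁ ≥ 1e-3, σ₁ ≥ 1e-3, ρ₁ ∈ [0, 0.999]); duplicated
replicates legitimately drive ρ₁ to the upper bound.

**Identifiability guard.** After rank transformation the marginal carries
no information (the pseudo-data marginal is the current mixture by
construction), so the two components are distinguished *only* through the
signal correlation. When the fitted ρ₁ is at or below 0.05 — at the
fitted sample sizes, indistinguishable from zero — the "reproducible"
component is declared vacuous: every pair gets local idr 1 and the result
is flagged. Without this guard, pure-noise inputs can drift to a
degenerate high-π₁ fixed point that would pass everything.

Local idr is the posterior probability of the null component; global IDR
is the running mean of local idr in ascending order, assigned back to
each pair; `count_passing` counts pairs with global IDR ≤ threshold
(default 0.05, exposed because the upstream convention does not pin it).

Fits are refused below 50 matched pairs: the four-parameter mixture is
unstable there, and a refusal is more informative than a noisy estimate.

## Reproducibility ratios and outlier flagging

Pseudo-replicates are built by binomial thinning of integer peak support
counts (each count split Bin(c, ½); zero halves drop the peak) — the
peak-level analogue of ENCODE's read splitting, preserving the intent
(halved evidence) without read-level data. Four IDR analyses per pair
give N_t (true pair), N_p (pooled peaks, pseudo-split), N₁ and N₂ (each
replicate split against itself). rescue = max(N_p, N_t)/min(N_p, N_t);
self-consistency = max(N₁, N₂)/min(N₁, N₂). A pair is acceptable iff both
ratios could be computed and either is *strictly* below 2 (exactly 2
fails); a pair whose sub-analyses failed (e.g. a replicate so discordant
that fewer than 50 peaks match) is conservatively unacceptable, which is
what makes a pure-noise replicate detectable at all — its self-split can
look internally consistent because thinned halves of the same counts are
correlated by construction. Within a group, all C(n,2) pairs are
evaluated and a sample is flagged "of concern" when more than half of its
pairs are unacceptable.

## Profile comparison

Venn partitions are exact exclusive-region counts with percentages of the
union. Footprint deltas are interval subtractions in both directions
(lost = a∖b, gained = b∖a), summarized per gene using the closest-feature
assignment of the consensus region (not of each fragment — fragment-level
reassignment is unstable at region edges). Motif enrichment counts exact,
overlap-allowed occurrences and compares against per-sequence
dinucleotide-preserving shuffles (Altschul–Erickson arborescence
construction), the standard null for RNA motifs since it preserves local
composition; a mononucleotide option is retained. The empirical p uses
the add-one rule, p = (1 + #{null ≥ observed})/(n_shuffles + 1), and is
never zero. Motifs given in the RNA alphabet are matched after U→T.

## Assay quantification

- ψ = (I/l_I)/(I/l_I + S/l_S) with effective lengths; Δψ = mean ψ(control)
  − mean ψ(case), so positive Δψ means higher inclusion in controls.
- Three-primer PCR inclusion = A/(A+B); digest isoform fraction =
  (cut₁+cut₂)/(uncut+cut₁+cut₂). Band intensities are taken as numbers —
  image densitometry is out of scope.
- ΔΔCt: ΔCt = Ct_target − Ct_reference per sample, baselined to the
  *arithmetic* mean ΔCt of the calibrator group (a documented,
  configurable convention; it makes the calibrator's fold changes have
  geometric mean exactly 1), fold = 2^(−ΔΔCt).
- Neurite summaries: per-image length/nuclei (zero-nuclei images excluded
  and counted), per-replicate means, mutants as percent of the matched
  wild-type replicate.
- The exact Mann–Whitney U test enumerates all C(n₁+n₂, n₁) assignments of
  pooled midranks (restricted to combined n ≤ 20) and reports the
  two-sided probability of a U at least as far from n₁n₂/2 as observed;
  with ties the enumeration is conditional on the observed midrank
  pattern. At the assay sample sizes (3–7 per group) this is instant and
  avoids the normal approximation entirely. One- and two-tailed t tests
  (Welch by default, pooled variance optional — the equal-variance
  assumption of the original analyses is not recorded) are dispatched
  through the same interface.

## Synthetic data: what it emulates, and what it does not

The generator produces a toy genome (2 chromosomes × 1 Mb, 60
non-overlapping single-transcript genes with 5′UTR / ≥2 CDS exons /
introns / 3′UTR), 300 true binding sites of 20–60 nt placed inside
sampled region classes with an intron-heavy bias
(intron 0.6, CDS 0.2, 3′UTR 0.1, 5′UTR 0.1 — mirroring the
intron-dominant binding reported for this protein), replicate peaks whose
latent scores follow exactly the copula mixture the IDR model assumes
(defaults π₁ = 0.65, μ₁ = 2.5, σ₁ = 1.0, ρ₁ = 0.8 — a moderately strong,
realistic reproducible fraction; the source analysis does not print its
fitted values), 100 unmatched noise peaks per replicate, Poisson
background at 0.05 peaks/kb, and a condition series
(naive 0 / mild 0.25 / severe 0.5 fraction of sites lost) emulating the
progressive loss of binding with disease severity. Scores are emitted
both as positive reals (exp of the latent) and as integer counts
(Poisson with mean exp(latent)) so binomial pseudo-replicate thinning is
well defined. Sequences are uniform-composition DNA with extra motif
copies planted at Poisson((enrichment−1) × background-expected rate).
Assay tables encode group PSI through the length-reversed read-level
inclusion probability, Ct shifts per group, and lognormal band noise at
10% CV.

Deliberately *not* emulated: read-level data (no FASTQ, alignment or
deduplication), realistic transcriptome sequence composition, overlapping
or multi-isoform gene models, chromatin-scale peak density, and
condition-dependent score distributions beyond site loss. Passing tests
therefore demonstrate correctness of the computations and calibration of
the estimators under the stated generative assumptions — not robustness
to every artefact of real CLIP-seq libraries.

Every generator is a pure function of (scenario, seed); per-stage
substreams are derived from the root seed (stage tag + CRC of condition
labels), so any stage can be re-run in isolation without disturbing the
randomness of the others.

## Numerical and scale choices

Test and acceptance problem sizes were chosen so the full suite runs in
about two minutes on one CPU while keeping estimator checks
well-powered: 200 random instances for the interval oracle, n = 10,000
pairs × 20 seeds for parameter recovery, n = 5,000 for null calibration,
100 seeds × 60 shuffles × 100 sequences for motif null calibration, and
20 pipeline seeds for the condition trend. The matching-oracle test uses
footprint-scale widths (≤ 40 nt) on a 10 kb chromosome so that overlap
structure is sparse, as it is in real peak sets; at artificially dense
overlap the greedy and globally optimal matchings legitimately diverge.

## Known limitations

- The IDR convergence flag is conservative: at the default 100 outer
  iterations, hard mixtures report `converged=False` while the estimates
  are already stable to well below the scientific tolerances.
- The acceptability rule (either ratio < 2) is the lenient published
  convention; with pseudo-replicates built by thinning, self-consistency
  is optimistic, so cross-replicate failures surface mainly through the
  rescue ratio and through fit refusals.
- The exact Mann–Whitney path is O(C(n₁+n₂, n₁)) and restricted to
  combined n ≤ 20 by design.
- `simulate_sequences` requires every footprint to be at least as long as
  the motif and raises otherwise.
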