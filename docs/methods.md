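# Methods

This note records the models, numerical conventions and open design
choices behind each module, and what the synthetic benchmarks do and do
not demonstrate.

## Differential expression (`cernet.diffexp`)

**Model.** Counts `K_gj ~ NB(s_j q_gρ(j), α_g)` with per-sample size
factor `s_j`, per-group mean `q_gρ` and dispersion `α_g` (variance
`μ + α μ²`). Size factors are median-of-ratios: the median over genes
with all-positive counts of `k_gj / geomean_g`. A single sample yields
`s = 1` by construction; data in which no gene is positive everywhere
raise an error rather than silently switching reference (a
pseudo-reference is a caller decision).

**Dispersion.** Per gene, a method-of-moments estimate on normalized
counts: `α̂_g = (w_g − μ_g·mean(1/s_j)) / μ_g²`, with `w_g` the pooled
within-group variance (the subtraction removes the Poisson sampling
component; values below 0 are floored). A trend `α(μ) = a₀ + a₁/μ` is
fitted by non-negative least squares over genes with `α̂ > 0`, and the
final value is `max(α̂_g, trend(μ_g))`. The maximum rule is the
conservative sharing mode: with 3–4 replicates per group the gene-wise
estimator is noisy, and taking the maximum guards against underestimated
dispersion inflating significance. The measured cost is mild
conservatism — the null simulation below shows type-I error around
0.03–0.05 at nominal 0.05.

**Exact test.** Conditional on the total `K = ΣK_A + ΣK_B`, each split
`(a, K−a)` is weighted by the product of the two group pmfs; each group
sum is approximated by one NB matching its mean `q·S_X` and variance
`q·S_X + α q² Σ s_j²` (exact Poisson when `α = 0`). The p-value is the
normalized weight of splits no more probable than the observed one; a
relative tolerance of 1e-7 protects probability ties from floating-point
rounding, and sums are computed by log-sum-exp. At `α = 0` with unit
size factors this collapses exactly to binomial enumeration, which the
tests verify to 12 decimals for all `K ≤ 50`.

**Screen.** `Up ⇔ log₂FC > 1 ∧ p ≤ 0.05`, mirrored for Down. The raw p
drives the screen; the BH q-value is reported alongside. Fold change is
oriented case/reference (group B over group A), matching the convention
of published tables in which up-regulated case transcripts have FC > 1.
Genes with zero counts in every sample are dropped (FC undefined) and
counted in the log.

## Transcript catalog (`cernet.catalog`)

Coordinates are 1-based closed intervals; overlap means an intersection
of at least one base on the same chromosome. The candidate filter keeps
transcripts longer than 200 nt and, for unannotated candidates only,
with at least two exons — annotated known lncRNAs keep single-exon
entries, which is the only reading that reconciles a strict exon rule
with a catalog containing a few percent of single-exon lncRNAs.
Orientation calls resolve multiple overlaps by largest overlap, then
antisense over sense, then lowest coding id; these tie-breaks are
package conventions (field practice varies and no single standard
exists). PCA is a gene-centered SVD with the component sign fixed by the
largest-magnitude loading; variance fractions are normalized squared
singular values.

## MRE prediction (`cernet.targets`)

A seed-and-extend scanner. Candidates are transcript windows whose bases
facing miRNA positions 2–8 all pair, Watson–Crick or G:U, with at most
one wobble; classes follow the canonical taxonomy (8mer ⊃ 7mer-m8 ⊃
7mer-A1 ⊃ 6mer, assigned on Watson–Crick terms; a candidate whose only
non-WC pairing is a wobble inside positions 2–7 is reported as 6mer).
Each candidate is extended by a local affine-gap alignment of the full
miRNA (threaded antiparallel) over a window covering the expected
pairing footprint plus 5 nt per side. Scoring: +5 WC, +1 G:U, −3
mismatch, −9 first gap residue, −4 per further residue, substitution
scores ×4 at miRNA positions 2–8, no gaps touching the seed region, and
an emission threshold of 140 — the published defaults of the classic
weighted-complementarity target scanner this module re-implements.
Thermodynamic (free-energy) filtering is deliberately omitted; the score
threshold is the only gate, and all parameters are exposed in
`AlignmentParams`. A perfect 22-nt duplex scores `7·5·4 + 15·5 = 215`.
Overlapping hits of one (miRNA, transcript) pair are merged keeping the
maximum score (ties: leftmost). Internally coordinates are 0-based
half-open.

The DP is cross-checked in the tests against an exhaustive
path-enumeration oracle on tiny instances (with weighting and gap bans)
and against Biopython's `PairwiseAligner` in the position-independent
special case.

## ceRNA network (`cernet.network`)

Correlations are Pearson on `log₂(normalized + 1)` (pseudo-count fixed
at 1), with p from the t transform on `n − 2` df. The default screen —
|r| ≥ 0.7, p ≤ 0.05 — is a common vendor-pipeline convention; the
source workflows state only the sign constraints, so both thresholds are
configurable. Zero-variance features are skipped and counted.

The ceRNA score for a candidate pair (A = lncRNA, B = mRNA) with shared
miRNA set M uses hit starts `p₁ ≤ … ≤ p_n` and a nominal 7-nt site
footprint:

* `S1 = |M|² / (|M_A|·|M_B|)` — shared fraction of targeting miRNAs;
* `S2` — mean site density `n/(p_n − p₁ + 7)` (single site: `1/len`);
* `S3` — mean spacing evenness `min(gap)/mean(gap)` (single gap: 1);
* `S4` — shared-miRNA hits over all hits on the pair;
* `raw = Σ ln Sᵢ` with each component floored at 1e-12, then min–max
  scaled to [0, 100] across all evaluated pairs (a single pair scores
  100).

Candidate pairs are all lncRNA × mRNA pairs with at least one shared
predicted miRNA — not only coexpressed pairs — so the min–max
normalization sees the full background of chance-shared pairs and the
score separates real shared-site architecture from it. `score_min = 50`
is the default reliability gate, with an optional hypergeometric
co-targeting test (population = DE miRNAs, successes = miRNAs hitting
the lncRNA, draws = miRNAs hitting the mRNA).

Triplets require all three sign-constrained edges, shared-miRNA
membership and the score gate simultaneously (the strictest consistent
reading of "intersection"); the sign pattern (−, −, +) is re-asserted on
every emitted triplet. Top-N axes sort by (score desc, |r(L,G)| desc,
lexicographic) — the ranking key is a package convention. Export writes
SIF plus node/edge attribute TSVs, deterministically sorted so re-export
is byte-identical.

## Enrichment (`cernet.enrichment`)

Upper-tail hypergeometric per set (`P(overlap ≥ k)`), exact against
combinatorial enumeration for all universes ≤ 15 in the tests; BH FDR
via the standard step-up; rows sorted by p (ties: larger overlap, then
term id). The universe defaults to the caller's tested genes, not the
whole annotation — the conventional background. Depletion testing and
ontology-topology-aware methods are out of scope.

## Validation statistics (`cernet.validation`)

2^−ΔΔCt averages technical replicates on the Ct scale, subtracts the
reference gene per sample and the calibrator group's mean ΔCt, and is
invariant to global Ct shifts. AUC is the midrank rank-sum statistic,
exactly equal to pair counting. The CI defaults to the DeLong
structural-components variance (the standard for a single marker) with a
normal interval truncated to [0, 1]; perfect separation degenerates the
variance and falls back to a seeded 2000-resample bootstrap, which is
also available directly. Coverage of the 95% interval at true AUC 0.5
with 20 + 20 samples measures ≈ 94–95% in the acceptance run.

## Synthetic data (`cernet.simulate`)

**What it emulates.** A small two-group clinical design (default 4 vs 4
samples, the typical tissue-study size), three feature layers at
desk-scale censuses (150/60/300), NB counts with log-uniform baselines
in [100, 3000], log-uniform size factors in [0.5, 2], dispersion trend
`0.05 + 2/μ`, and a planted fraction of DE features (default 0.15) with
|log₂FC| ~ |N(2, 0.5)| and random sign. Planted ceRNA triplets couple
their three members through a latent standard-normal per-sample factor
with log₂ amplitude `2·coupling`, positive on the lncRNA and mRNA and
negative on the miRNA — inducing the assumed sign pattern without
committing to a kinetic sponge model. Transcripts are uniform-random
RNA (lengths 300–800 nt); each planted (miRNA, transcript) pair receives
3 exact reverse complements of miRNA positions 1–8 as a cluster with
10–50 nt inter-site gaps at a random offset — sponge MREs cluster, and
the density/evenness components of the ceRNA score presuppose exactly
that architecture. Generated miRNAs are 22 nt and start with U (the
dominant 5′ residue of mature miRNAs), which makes every planted perfect
site an 8mer. One RNG substream per stage, derived from the dataset seed
by fixed offsets, keeps earlier layers byte-identical when later stages
change.

**What it does not emulate.** Read-level noise (no FASTQ or error
model), GC/length bias, shared miRNA regulation across many targets,
isoform structure, batch effects, or clinical covariates. Passing the
planted-truth benchmarks therefore demonstrates the statistical
machinery is correct and calibrated under its own assumptions — not that
the defaults match any particular tissue's effect sizes.

## Benchmark problem sizes

The reference planted-truth benchmark uses 20 samples per group, 50
triplets at coupling 0.8 among 120/60/200 features — large enough for
the |r| ≥ 0.7 screen to have power while the full run (generation, site
prediction over 19,200 miRNA × transcript pairs, three correlation
screens, ~5,000 scored pairs, assembly) completes in seconds. The null
type-I simulation uses 2,000 genes at 4 vs 4; exact-test enumeration
covers all totals ≤ 50; DeLong coverage uses 1,000 replicates of
20 + 20. Measured on these: triplet precision 1.0 and recall 0.96–1.0
across seeds, planted-site pair recall 100%, strict-seed decoy
false-positive pair rate ≈ 3%, null type-I error 0.03–0.05, CI coverage
≈ 94–95% — each recomputed, never hard-coded, by
`scripts/acceptance.py` and the test suite.

## Known limitations

* The exact test enumerates all `K + 1` splits; genes with totals in the
  millions would be slow (a saddlepoint or windowed enumeration would be
  the next step).
* The aligner is plain Python per candidate; genome-scale scans would
  want a compiled kernel.
* ceRNA scores are min–max normalized within a run, so scores are
  comparable only within one evaluated pair set.
* Orientation classification is pairwise-overlap only; it does not
  implement intronic/bidirectional/enhancer subclasses.
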