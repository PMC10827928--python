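# Methods

This note documents the models and procedures implemented in
`proteoconcord`, the parameters that matter, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
establish about behaviour on real data.

## Identifier harmonisation and matching

Differential-protein tables identify proteins inconsistently across
sources: isoform-level UniProt accessions, mixed-case gene symbols, or only
one of the two. Keys are normalised (accession stripped of the `-<digits>`
isoform suffix, gene symbol upper-cased and trimmed) and two records match
when *either* normalised identifier agrees exactly. Design choices:

- **Equality only, no synonym expansion.** External ID-mapping services
  change over time and would make overlap counts irreproducible from the
  inputs. The cost is that records renamed between sources do not match.
- **Accession priority.** When a record's accession and gene symbol each
  match *different* records in the other table, the accession match wins.
  Matching is pairwise between the two tables and never chained through
  intermediates (the match relation is not transitive and we do not close
  it).
- **Duplicate collapse** keeps the record with the smallest significance
  value, ties broken by largest |log2 fold-change|, then first occurrence —
  deterministic and favouring the strongest evidence.

## Directional-consistency scoring

Multi-study evidence per protein is a vector of signed reports (±1). Let
*M* and *m* be the majority and minority counts. The call is the majority
direction with score ±*M* when *m* = 0, or when *m* = 1 and *M* > 5; in
every other case (ties included) the protein is *inconsistent* and carries
no score. Two readings were open:

- whether the score counts all reports or only majority-direction reports —
  we use *M* (majority only), which keeps the sign logic trivial;
- whether the ">5" forgiveness threshold is applied before or after the
  exception — we apply it to the majority count itself.

Both choices only affect proteins with exactly one dissenting report, and
neither changes the inconsistent/consistent boundary for vectors shorter
than seven reports.

## Concordance categories

Anchor-table proteins are classified into `same_up`, `same_down`,
`opposite`, `inconsistent_b` (matched, but the other disease's evidence is
directionally inconsistent, so no comparison is possible), and `a_only`
(unmatched). Matched proteins with inconsistent partner evidence form their
own category rather than being dropped, so category counts always partition
the anchor table and reported fractions reconcile. Reported percentages are
rounded half-up to integer percent. Several anchor records may match the
same partner record; each inherits that call (set semantics — the anchor
table is the denominator of every reported fraction).

## Enrichment statistics

The one-sided Fisher's exact test of a 2×2 set-overlap table equals the
hypergeometric upper tail, computed via `scipy.stats.hypergeom.sf` (verified
against exact rational enumeration to better than 1e-10 relative error for
all table sizes up to N = 200). The odds ratio uses the Haldane 0.5
correction only when a margin cell is zero. Over-representation analysis
tests each annotation term the same way; terms with zero query hits are
excluded before Benjamini–Hochberg adjustment (this changes the number of
tests m, and is the standard ORA practice); results are filtered at
q < 0.05 and sorted by q then descending fold enrichment. BH rather than
Storey's q-value because it is parameter-free and reproducible.

There is deliberately **no default background universe** for overlap tests:
published overlap p-values frequently omit the universe, and the choice
dominates the result. `setstats.scan_universe` inverts the problem — given
the observed counts and a published p-value, it ranks candidate universe
sizes by how closely they reproduce it (closeness on the log10 scale).

## Co-expression analysis

Standard WGCNA sequence with two documented simplifications.

- **Correlation**: Pearson on protein rows; proteins with more than 30%
  missing samples are dropped, the remainder mean-imputed (the original
  study does not state its missing-data handling).
- **Soft threshold**: for each candidate power β, connectivity
  k_i = Σ_j |cor(i,j)|^β. The scale-free fit bins k into 10 equal-width
  bins and regresses log10 bin frequency on log10 mean bin connectivity;
  the signed fit index is −sign(slope)·R², positive for the decreasing
  degree distributions a scale-free network produces. Chosen β is the
  smallest reaching the target (default 0.8), else the best-fitting β with
  a warning. Defaults: unsigned network, β = 4, minimum module size 20,
  merge cut height 0.15.
- **Module detection** simplifies the dynamic hybrid tree cut: average
  linkage on TOM dissimilarity, a fixed cut at 0.995 of the tree height,
  clusters below the minimum size assigned to module 0 (unassigned),
  iterative merging of modules whose eigenproteins correlate above
  1 − merge-cut-height, and renumbering by descending size. Exact
  replication of the published dynamic hybrid algorithm (and of any
  particular published module decomposition) is a non-goal; the supported
  contract is recovery of planted structure, which the tests check by
  adjusted Rand index. The whole matrix is treated as one block.
- **Eigenproteins** are the unit-norm first right singular vectors of the
  row-standardised member submatrices, sign-anchored to correlate
  positively with the module mean profile.
- **Trait correlation** is Pearson r with the two-sided Student-t p from
  t = r·√((n−2)/(1−r²)).

## IHC positive-pixel counting

The HSI variant is fixed here because vendor documentation names the
algorithm but not the formulas: intensity = (R+G+B)/3 on 0–255, saturation
= 1 − 3·min(R,G,B)/(R+G+B), hue from the arccos chromaticity formula on the
[0,1) circle. A pixel is candidate-positive when its circular hue distance
to the configured stain hue is within the hue width and its saturation
clears the floor; candidates are binned by intensity into strong, medium
and weak positivity (darker = stronger staining), and everything else —
including candidates brighter than the weak-band ceiling — is negative.
Conventions for degenerate pixels: achromatic pixels (R=G=B) have undefined
hue and are treated as passing the hue gate (the intensity gate still
excludes bright background); pure black has undefined saturation and is
negative.

The shipped default configuration fixes saturation floor 0 and weak-band
ceiling 80 (the two standardised modifications) and uses example values for
the remaining thresholds, calibrated for a DAB-brown stain in the unit
tests; they carry no canonical status and should be recalibrated per stain.
Per-case values are unweighted means of ROI percentages. Group comparison
defaults to Welch's t-test (Mann–Whitney available); the fold change is the
ratio of group means and is reported as missing when the control mean is
zero.

## Synthetic data: what it emulates and what it does not

Each generator is a pure function of (parameters, seed) and emits an answer
key sufficient to check its downstream stage exactly (counts) or within a
stated tolerance (correlations).

- **Differential-table pairs** plant the overlap size and the fraction of
  direction-concordant shared proteins; log2 fold-changes are ±Uniform(0.3,
  2.0) dressing whose sign carries the planted direction. A second
  scenario generator plants per-category counts directly (including
  inconsistent-in-B proteins) for twin reconstructions of published count
  tables.
- **Study-report vectors** are unanimous for consistent proteins and
  balanced for planted-inconsistent ones (a balanced split can never be
  rescued by the single-dissent forgiveness rule, so the planted class is
  forced).
- **Expression matrices** draw a latent N(0,1) profile per module; members
  are √w·latent + √(1−w)·ε with ε ~ N(0, noise_sd²), so with the default
  noise_sd = 1 the expected within-module correlation is exactly w. The
  trait is r·latent + √(1−r²)·noise for the chosen module. Defaults (two
  modules of 30, 50 samples, w = 0.8, r = 0.9, 200 proteins with the
  remainder background noise) are the desk-scale study conditions; the
  recovery loop in the acceptance checks uses exactly the two planted
  modules with no background so that the adjusted Rand index scores module
  separation rather than background rejection, which is exercised
  separately by the pure-noise test.
- **Stain images** are flat-colour with an exactly planted count of
  positive-coloured ROI pixels (optional Gaussian RGB jitter bounded at ±10
  so the default colours never cross a class boundary).

Passing tests on these fixtures establishes that the *machinery* is correct
— identifier matching, classification bookkeeping, exact tail
probabilities, module recovery at realistic signal strength, exact pixel
accounting. They do not establish robustness to the features real data add:
identifier drift between databases, correlated missingness, non-Gaussian
abundance distributions, batch structure, stain texture and counterstain
gradients. Those require the user's own data and judgement.

## Problem sizes and numerical choices

Simulation sizes used by the test suite and the acceptance script — 500
replicates for the null-FDR and fold-change Monte-Carlos, 20 seeds for the
module-recovery loop, 100 random configurations for the concordance
invariants, exhaustive report-vector enumeration to length 10, exact-tail
verification to N = 200 — were chosen as the smallest sizes at which the
checked properties are stable from run to run. Correlations are clipped to
[−1, 1] before powering; TOM entries are clipped to [0, 1] against rounding
drift; hierarchical clustering uses scipy's average linkage on the
condensed TOM dissimilarity; SVD sign indeterminacy is resolved by the
module-mean anchor. All RNG flows through `numpy.random.default_rng` with
explicit seeds; no global RNG state is used anywhere.
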