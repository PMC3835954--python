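# Methods

## The specificity screen

An ingested dsRNA trigger silences a transcript through ~21-nt small
interfering RNAs, so cross-species activity requires the trigger and the
non-target ortholog to share at least one contiguous stretch of 21
identical nucleotides. The package operationalizes that rule over a gapped
pairwise alignment of the trigger (a 240-nt region by default) against each
ortholog:

- **SNPs** — columns where both rows are non-gap and differ. A column
  containing N counts as a difference: an ambiguous base can never be
  claimed identical, which is the conservative choice for a risk screen.
- **Percent identity** — `100 · (identical non-gap columns) / L_aln`; gap
  columns stay in the denominator and count as non-identical, so for
  gap-free pairs identity is exactly `100·(L − s)/L` for `s` SNPs. Reported
  values are rounded half-up to one decimal (98.75 → 98.8); distance
  matrices use the unrounded value.
- **Shared k-windows** — `m` counts every start column `t` (1-based,
  windows `[t, t+k−1]`) whose k columns are all identical non-gap matches;
  overlapping windows all count. `ℓ` is the longest run of consecutive
  matching columns, and `m ≥ 1 ⇔ ℓ ≥ k`. Gap and N columns break runs.
- **Activity call** — predicted active iff `m ≥ 1` at `k = 21`. The 21-nt
  threshold is the empirically supported minimum: single 19-nt matches show
  no activity in sensitive species even at high doses, while as few as
  three shared 21-nt windows can be lethal. When bioassay data are present
  the report shows both; a sequence prediction never overrides an observed
  bioassay outcome, because downstream barriers (uptake, dicing efficiency)
  make sequence matching necessary but not sufficient.

For `s ≥ 1` SNPs in a gap-free pair of length `L` there are `W = L − k + 1`
windows and the sharp bounds `max(0, W − s·k) ≤ m ≤ W − min(s, W)` hold:
clustering SNPs at one end attains the maximum, spacing them `k` apart the
minimum. The location-dependence is why two orthologs with identical SNP
counts can have very different `m` (e.g. 18 vs 3 at 22 SNPs).

A position-free substring mode is also provided for unaligned screening:
`m` counts trigger k-mers occurring verbatim anywhere in the target, sense
strand only by default (a dsRNA trigger already carries both strands); a
flag adds the reverse complement.

### Alignment

`global_align` is an affine-gap Needleman–Wunsch global alignment
(Bio.Align.PairwiseAligner underneath). Defaults: match +1, mismatch −1,
gap open −5, gap extend −2, where a gap of length `g` costs
`open + (g−1)·extend`. Orthologs of the same coding region at this length
are effectively gap-free, so gaps are strongly discouraged; the scores are
exposed in `AlignmentParams` for other regimes. N scores as a mismatch
against every base including N. Ties among optimal alignments are resolved
deterministically by taking the first traceback. Pre-aligned gapped FASTA
is accepted with its columns taken as given, since all reported statistics
are pairwise and do not require reconstructing a multiple alignment.

### Identity-distance tree

`d(i,j) = 100 − PID(i,j)` in percentage points (unrounded PID), clustered
with classical size-weighted UPGMA: merge the closest pair, place the new
node at height `d/2`, update distances as member-count-weighted means.
Equidistant merge candidates are broken toward the lowest label-index pair,
and children are ordered by lowest original leaf index, so the tree and its
Newick serialization are deterministic. The tree is ultrametric by
construction; only distances computed from actual input sequences are used —
the pipeline never fabricates a missing pairwise distance.

## Bioassay statistics

Dose-response mortality is modelled as binomial with

    P(dead | dose) = c + (1 − c) · Φ(a + b · log10 dose),

where `b` is the probit slope per tenfold concentration and `c ∈ [0, 0.99]`
is the natural (control) mortality — the same correction SAS PROC PROBIT's
OPTC option applies. Doses of 0 are excluded from the regression; control
rows enter the likelihood through `P = c`. `LC50 = 10^(−a/b)`;
`LCp = 10^((Φ⁻¹(p) − a)/b)`.

Numerical choices: starting values for `(a, b)` come from least squares on
empirical probits of Abbott-corrected proportions, with 0/1 proportions
shrunk by `(r + 0.5)/(n + 1)`; `c` starts at the observed control mortality
(0 without a control group). The full likelihood is then maximized with
L-BFGS-B (`c` box-bounded to [0, 0.99]). The 95% interval for the LC50 is a
delta-method interval on `log10(LC50)` from the numerically differentiated
observed information, back-transformed; when `ĉ` sits on its bound the `c`
row is dropped from the information matrix (curvature there is one-sided).
SAS reports fiducial limits instead; at these sample sizes the two differ
modestly and the package documents its interval as Wald-type. Fits are
dose-unit equivariant: rescaling all doses by `f` rescales the LC50 and its
interval by exactly `f` and leaves the slope unchanged. Degenerate series
(all dead or all alive at every positive dose) are reported as
non-converged with NaN estimates — never fabricated numbers — and series
with fewer than three distinct positive doses are rejected outright.

Binary endpoints use Fisher's exact test (two-sided, summing hypergeometric
probabilities ≤ the observed table's, the convention of common
implementations); an empty margin returns p = 1 with a warning. Continuous
endpoints use the pooled-variance Student's *t* (homogeneity having been
checked with classical Levene on absolute deviations from group means;
Shapiro–Wilk normality testing is deliberately not reimplemented — a
`normality_hook` slot accepts any external `(values) → (stat, p)`
implementation). Zero-variance degeneracies return `t = 0, p = 1` for equal
means and a signed infinite `t` with `p = 0` otherwise.

`margin_of_exposure(tested, max_expression)` is the plain fold ratio
between a tested diet concentration and the maximum measured tissue
expression, reported to one decimal (e.g. 500 / 1.76 ng/g = 284.1-fold).

## Synthetic data

The generator emulates the statistical structure of the study inputs, since
the original ortholog sequences and raw mortality counts are unpublished:

- uniform random 240-nt triggers; SNPs planted at explicit positions with a
  uniform choice among the three alternative bases (no transition bias —
  irrelevant to every computed statistic; indels are not simulated);
- `place_snps_for_window_count` solves for SNP positions realizing an exact
  window count `m`: one clean run of `m + k − 1` columns is protected at
  the left end, the tail starts with a SNP and is broken by SNPs spaced `k`
  apart so no clean 21-mer survives, and spare SNPs fill remaining tail
  positions (shuffled under the seed). This construction is exact for every
  feasible `(s, m)` — feasibility is precisely the sharp bounds above — so
  the randomized-restart fallback a search-based design would need never
  arises; every placement is still verified against the brute-force window
  scan before being returned, and infeasible targets raise an error stating
  the attainable range.
- bioassays are binomial draws from the probit model. Defaults mirror the
  conspecific dose-response design for a sensitive beetle: 8 twofold doses
  from 1.6 ng/mL diet, 16 insects per dose, a 16-insect control, slope 1.6,
  LC50 19 ng/mL, natural mortality 0.05. Mortality is independent binomial
  per dose — no overdispersion, cage effects, or time structure — so
  passing recovery tests demonstrates correctness of the estimator under
  its own model, not robustness to real-world heterogeneity.

All generators take explicit seeds and use no global random state.

## Problem sizes

The test suite and the acceptance script use 500 replicate bioassay
simulations for LC50 recovery and interval coverage, ~1000 random pairs for
the window-count oracle checks, and 4–12 taxa for tree-recovery properties;
these sizes give Monte-Carlo error comfortably inside the stated tolerances
(median LC50 across seeds varies by well under the ±10% band) while keeping
a full run in the low minutes.

## Known limitations and discrepancies

- The published self-comparison of the 240-nt trigger lists 221 21-nt
  windows, but a 240-nt sequence has exactly `240 − 21 + 1 = 220`; the
  package computes `L − k + 1` and does not imitate the off-by-one.
- Published window counts for specific species (186, 69, 18, 3) depend on
  unpublished SNP positions; they are bounds-checked against the sharp
  inequalities rather than reproduced, and the generator can construct
  families realizing them exactly.
- The probit interval is Wald-type on the log scale, not fiducial; point
  estimates are unaffected.
- Aligned-mode and substring-mode window counts coincide for gap-free
  equal-length orthologs (the tested regime) but can differ when repeats
  let a trigger k-mer match elsewhere in the target.
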