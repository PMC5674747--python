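# Methods

This note documents the models, algorithms, defaults and design choices
behind `cnahet`, and what the synthetic cohort does and does not emulate.

## Input model and QC

Probe tables are TSVs modeled on two-color Feature Extraction exports: one
row per oligo with `ProbeName`, `Chromosome`, `Start`, `End` (1-based
inclusive on disk; 0-based half-open in memory), a `LogRatio`, and 0/1 QC
flag columns. A `# ratio_base=<b>` header records the logarithm base
(default 10, the upstream convention); `to_log2` rescales by
$1/\log_b 2$. A column-mapping config block adapts real exports whose
columns are named differently.

QC removes probes with any saturation flag (`gIsSaturated`, `rIsSaturated`)
or feature-non-uniformity flag (`gIsFeatNonUnifOL`, `rIsFeatNonUnifOL`) set,
and probes whose log ratio is exactly 0. The zero rule is deliberately
literal: extraction software writes 0 when local background exceeds the
signal, so an exact zero is a sentinel, not a measurement. The one situation
where this assumption breaks is a noise-free simulation, where genuinely
diploid probes are exactly 0; the corresponding recovery test therefore runs
with `QCPolicy(drop_zero_ratio=False)`. Real (noisy) data is unaffected —
exact zeros have probability zero under any continuous noise.

Median centering subtracts the median log2 ratio over **all retained
probes** (autosome-only centering would be an alternative; with the toy
genome there is no distinction). Centering assumes aberrant probes are a
minority; a genome more than half aberrant would shift the baseline, a known
limitation of median normalization in highly rearranged genomes.

## Segmentation

The piecewise-constant fit uses penalized recursive binary splitting. Within
a segment, the candidate breakpoint maximizing the residual-sum-of-squares
reduction

$$\Delta\mathrm{RSS}(k) = \frac{n_1 n_2}{n}(\bar y_1 - \bar y_2)^2$$

is accepted when $\Delta\mathrm{RSS} > \lambda\,\hat\sigma^2 \log n$, with
$\lambda = 2$ (BIC-like) and $\hat\sigma$ a robust per-chromosome noise
estimate: median absolute successive difference divided by
$\sqrt{2}\cdot 0.6745$. Scaling the penalty by $\hat\sigma^2$ makes the
criterion the standard Gaussian BIC (equivalently, penalizing
$\mathrm{RSS}/\sigma^2$ by $2\log n$ per breakpoint); an unscaled penalty
would be dimensionally arbitrary and either over- or under-segment depending
on the data's noise level. At zero noise $\hat\sigma = 0$ and any strict RSS
reduction (above a $10^{-12}$ float guard) splits, which recovers noise-free
piecewise-constant signals exactly.

After top-down splitting, a bottom-up pass repeatedly merges the adjacent
pair whose merge cost is smallest while that cost stays within the penalty.
This removes redundant breakpoints the greedy splitter can leave behind, so
noise-free inputs attain zero residual with the minimal breakpoint count.
Ties in $\Delta\mathrm{RSS}$ break to the leftmost split; the procedure is
fully deterministic. Minimum segment length is 1 probe — the three-oligo
rule belongs to calling, where it is stated. A `max_breakpoints` cap
(default 2000/chromosome) bounds pathological inputs.

This detector replaces the adaptive-weights smoothing engine commonly used
for this stage; that algorithm is prior art and the downstream analysis is
segmentation-agnostic. `import_segments` accepts externally produced SEG
files (validated against probe data when available) so users can substitute
any segmentation they prefer.

## Calling and sample inclusion

A segment yields a call iff it spans ≥ 3 oligos, $|\bar y| \ge 0.2$, and
$2^{\bar y} > 1.2$ (gain) or $< 0.8$ (loss). The amplitude prefilter is
redundant given the ratio cutoffs ($|\log_2 1.2| \approx 0.263$,
$|\log_2 0.8| \approx 0.322$) but both rules are applied literally as
stated by the upstream protocol; whether 0.2 was meant to be the operative
threshold is ambiguous, so `CallingParams(amplitude_only=True)` exposes that
alternative reading. High-level amplifications and homozygous losses map to
the same two states. Sex chromosomes are called like autosomes
(`include_sex_chromosomes=False` to drop them).

A sample with aberrant-amplitude segments but *no* segment passing the
three-oligo rule is excluded from all downstream analysis (its signal is
untrustworthy); a sample with no aberrant segment at all stays in with zero
CNAs. Group medians use the midpoint convention for even sizes.

## Harmonization and distance

Calls from all samples are cut at the union of their boundaries; each
resulting region gets a per-sample state in {gain, loss, neutral}. Each
original call is exactly tiled by its harmonized regions (reconstruction
property, enforced by tests). An aberrant (region, direction) element
carried by ≥ 2 samples of the evaluated set is *shared*; by exactly one,
*private*.

The pairwise distance counts elements over the **pair's** regions: adjacent
harmonized regions with identical joint state are merged first, so a third
sample's breakpoints cannot inflate the counts. With direction-aware
semantics (default), an interval gained in one sample and lost in the other
contributes two private elements — opposite dosage changes are different
events; `direction_aware=False` reproduces plain presence/absence counting.
A length-weighted mode (`length_weighted=True`) weights elements by bp span
for sensitivity analysis. Pairs where neither sample has any aberration have
an undefined (NaN) distance and are excluded from subset means.

Subsets: `pt_vs_matched_lnm` (each patient's PT against their own LNMs),
`inter_case_lnm` (LNM pairs from **different** patients only),
`matched_lnm_vs_om` (within-patient LNM/OM pairs). The Mann–Whitney U test
compares subsets: exact (full enumeration, via `scipy.stats.mannwhitneyu`)
when $n_1+n_2 \le 20$ with no ties, otherwise normal approximation with
continuity and tie correction; the method used is recorded in the result.
Two groups of identical values return p = 1 directly. Distance pairs within
a subset are treated as exchangeable observations; within-patient pairs
are in fact correlated, so subset p-values are descriptive rather than
strictly valid — the same caveat applies to the published analyses this
package systematizes.

## Penetrance and enrichment

Penetrance is the fraction of a group's samples carrying a given direction
at a region. For enrichment, each region's 3×2 gain/loss/neutral × group
table gets an exact p-value by enumerating both free cells of the
margin-conditioned multivariate hypergeometric distribution and summing
probabilities ≤ that of the observed table, with $10^{-7}$ relative slack
against float ties (computed in log space with cached log-factorials;
exhaustively verified against an integer-arithmetic oracle for all tables
with total ≤ 24).

A region is reported when $p \le 0.05$ and the driving direction (larger
between-group frequency difference) has prevalence strictly > 0.25 in the
group where it is more frequent (`prevalence_mode="both"` requires both
groups). Raw p-values are the default, matching the convention of reporting
each region's unadjusted test; `multiple_testing="BH"` applies
Benjamini–Hochberg. Adjacent reported regions with identical direction and
carrier set merge into one band for reporting. Gene lists are produced by
≥ 1 bp overlap with a user-supplied BED annotation; ontology analysis itself
is out of scope (external services).

## Synthetic cohort

The generator emulates the sampling design of a matched pancreatic cohort:
default 18 patients, each with 1 PT, 1–5 LNM and 0–2 OM. Per patient, 2–6
trunk events are shared by all samples; each sample adds private events with
a site gradient (PT 0–3, LNM 1–5, OM 2–7) reflecting the higher alteration
load observed in metastases. Event footprints are log-uniform between 2 and
40 Mb (dozens to hundreds of probes on the default grid), placed by
rejection sampling to be disjoint within a sample (trunk ∪ own private), so
the per-probe ground truth is single-valued; should placement ever fall back
to overlapping events, the later event wins per probe. Gains draw CN from
{3, 4, 5} (probabilities 0.7/0.2/0.1), losses from {1, 0} (0.85/0.15).

Signals follow the two-color mixture model
$\log_2((\rho\,\mathrm{CN} + 2(1-\rho))/2)$ with per-sample purity
$\rho \sim U(0.6, 1)$ and i.i.d. Gaussian noise (default sd 0.1 log2 units);
1% of probes get a random QC flag and 0.5% a zero-ratio sentinel so the QC
stage has work to do. No published amplitude or noise figures exist for the
motivating data, so these are conventional values for FFPE-derived 60K
arrays, chosen once. The default genome is a toy 4 × 2,500-probe grid
(40 kb spacing, the density of a 60K whole-genome design) so simulations run
in seconds; `GenomeModel.full_human()` provides an hg19-sized grid.

What the generator does **not** emulate: GC/wave artifacts, FFPE-specific
noise structure, dye bias, replicate/dye-swap designs, allele-specific
signal, subclonal (non-integer) events, and correlated breakpoints between
patients. Passing recovery tests therefore demonstrate correctness of the
pipeline's logic under a clean noise model, not robustness to every real
aCGH artifact — externally segmented input is the escape hatch for data
needing heavier preprocessing.

## Determinism and problem sizes

All randomness flows from a single integer seed through
`numpy.random.default_rng`; the pipeline itself is deterministic, and the
run manifest records a config hash plus a SHA-256 checksum of every output,
so identical config and inputs reproduce byte-identical runs.

Test and acceptance problem sizes are chosen to exercise each property at
the smallest scale where it is informative: exhaustive Fisher verification
over all 3×2 tables with total ≤ 24 plus 500 random tables with margins
≤ 12; Mann–Whitney enumeration for all splits with $n_1, n_2 \le 6$; noisy
recovery on 20 samples × 10,000 probes at noise sd 0.15 with event
amplitudes ≥ 0.585 (95% probe-state accuracy, 90% of breakpoints within ±3
probes); trunk-fraction recovery on 10 replicate cohorts per fraction; and
enrichment power/size on 100/50 simulated cohorts of 39 + 18 samples. The
acceptance script runs the full default cohort (≈ 90 samples × 10,000
probes) end to end.

## Known limitations

- Greedy binary splitting is not globally optimal; very short, low-amplitude
  events flanked by long segments can be missed where exhaustive dynamic
  programming would find them. The merge pass mitigates over-segmentation
  but not misses.
- Region-counting distances weight a 50 kb and a 30 Mb element equally; the
  length-weighted mode exists precisely because this choice is debatable.
- The enrichment unit is the harmonized region, whose boundaries depend on
  the cohort's call set; band merging reduces but does not remove this
  dependence.
- Purity is neither estimated nor corrected for; calls on low-purity samples
  lose sensitivity exactly as they do in real bulk aCGH.
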