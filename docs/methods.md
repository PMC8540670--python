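# Methods

## Reference library

The RT library covers the 22 catalogued HMW-GS of hexaploid bread wheat:
two 1Ax, seven 1Bx, seven 1By, four 1Dx and two 1Dy subunits, each with a
mean apex retention time (minutes) and the relative standard deviation of
that RT across the standard cultivars carrying it. Means are stored at
millisecond-scale (3-decimal) precision; the earliest-eluting subunit is
1Dy12 at 2.970 min and the latest 1Ax1 at 5.373 min. The canonical family
elution order is 1Dy < 1By < 1Dx < 1Bx < 1Ax with a single known
exception, 1Bx13, which elutes inside the 1Dx range;
`elution_order_violations` finds such exceptions by iteratively removing
the subunit with the most cross-family order inversions.

Two 20-subunits are stored under distinct names `1Bx20x`/`1By20y`
(their catalogued rows are "20x"/"20y"); displays join them as "20 + 20".

Curated ambiguity groups are configuration, not derivation: the defaults
are {1Bx7, 1Bx7OE, 1Bx14} (gel-resolved), {1By8\*, 1By9, 1By15}
(gel-resolved), {1Bx7, 1Bx7OE} (PCR-resolved) and
{1By8\*, 1By9, 1By15, 1By18} (linkage-resolved via the 1Bx17 anchor).
`derive_ambiguity_groups(k)` computes the connected components of the
k·SD window-overlap graph as a diagnostic; at k = 2 the curated groups
appear as subsets of its components (the graph also joins close
non-curated neighbours such as 1Dy10/1Dy12, which the caller separates by
RT proximity).

The allele catalog maps 27 (locus, subunit-set) pairs to symbols,
including single-subunit alleles with a null partner (e.g. {1By15} →
*Glu-B1-2e*), the locus null *Glu-A1c*, and the catalogued sentinel
"unknown" for 7^OE^ + 9. Combinations outside the catalog return the same
sentinel with `in_catalog=False` and are flagged by the caller.

## Synthetic chromatograms

Each expressed subunit contributes a Gaussian peak

    y(t) = A / (σ_p √(2π)) · exp(−(t − c)² / 2σ_p²)

with width σ_p = 0.012 min, apex c drawn per injection from
N(μ, μ·CV_rt/100) and area A = base_area · scale · N(1, CV_area/100);
the trace adds a linear baseline (0.2 units/min) and white detector noise
(SD 0.5) on a 0.002-min grid over 0–12 min. 1Bx7^OE^ peaks are scaled 2×
(duplicated gene; simulation-only — the caller does not use area by
default). Heterozygous second-allele subunits render at half area.
Defaults keep the adjacent references 1Dy12/1Dy10 (2.970/3.000 min)
separable, consistent with the separation the optimized gradient
achieves. The draw order per injection (RT jitters in library order, then
area factors, then the noise vector) is fixed, so a (genotype, config,
seed) triple reproduces a trace bit-for-bit.

**Noise calibration.** The instrument study reports 10-injection
reproducibility bounds: RT RSD < 0.21% and peak-area RSD < 1.18% (maxima
over the four Chinese Spring subunits). With n = 10 the sample RSD has a
relative sampling SD of 1/√(2·9) ≈ 24%, so a generator whose true CV sat
at the bound would *observe* a max-of-four RSD above it in roughly half
of all runs. The generating CVs are therefore set to ≈ 0.64× the printed
bounds — CV_rt = 0.13%, CV_area = 0.75% — which keeps the observed
10-replicate maximum below the published bound with ≥ 95% probability
while staying the same order of magnitude. Between-cultivar RT spread is
modelled, when requested, as a uniform per-line shift of up to ±0.25% of
each mean applied to all subunits of the line (a correlated run-level
retention shift); it is off by default because the catalogued per-subunit
RSDs (0.07–0.42%) pool between-cultivar variation that would otherwise
double-count in replicate studies.

Cohorts are materialized from per-locus allele counts; per-locus allele
lists are independently permuted under a seed-derived permutation and
zipped, so truth marginals equal the requested counts exactly while locus
combinations pair pseudo-randomly (real germplasm has linkage
disequilibrium across loci; the simulator deliberately does not).
Auxiliary evidence derives from the truth: SDS-PAGE confirms carried
subunits belonging to gel-resolved groups, and the 7^OE^ junction PCR is
positive/negative/untested according to 1Bx7^OE^/1Bx7/neither.

What passing tests on this generator do **not** show about real data:
robustness to peak tailing, co-eluting non-glutenin background, gradient
drift between instruments, or miscalibrated reference RTs — real traces
would need RT re-alignment against external standards first.

## Peak detection

The baseline is a straight line fitted to the first and last 0.5 min of
the trace (peak-free by construction here; configurable) and subtracted,
clipping at zero. Candidate maxima must clear a height threshold
(default 2.5 = 5× the default noise SD) **and** a topographic prominence
threshold (default equal to the height threshold). The prominence guard
exists because pure height thresholding admits phantom peaks: on the
flank of a tall peak, ~4.2–4.6 peak-sigmas from the apex, the trace sits
on a pedestal of a few intensity units where noise wiggles create local
maxima that pass the height test but have only noise-sized prominence.
Maxima closer together than 0.02 min collapse into one reported peak
flagged `merged` (the paper's practice is to resolve co-elution by
orthogonal evidence, not curve fitting, so no deconvolution is
attempted). Apexes are refined by 3-point parabolic interpolation (error
≪ half the 0.002-min sampling step on Gaussian shapes); integration runs
between the flanking minima or apex ± 4σ_p (0.048 min), whichever is
nearer, which covers 99.99% of a Gaussian's area.

A half-dose peak 2.5σ_p from a full-dose neighbour (the heterozygous
1Dy10 + 1Dy12 mixture) produces a *unimodal* sum and is genuinely
absorbed — matching the observation that such mixtures are not separable
by this method; the caller never invents the hidden partner.

## Allele calling

Matching windows are μ ± k·σ with k = 3 and σ floored at an RSD of 0.21%
(the replicate reproducibility bound): subunits catalogued from one or
two cultivars (1By20y at 0.07%, 1Dx2.2 at 0.11%) would otherwise get
windows narrower than ordinary injection jitter. A peak hitting several
windows resolves to the nearest reference by absolute RT distance unless
that reference belongs to a curated ambiguity component, in which case
the whole component becomes the candidate set (absolute distance rather
than library-SD z-scores because injection jitter is proportional to RT,
while the per-subunit library SDs reflect uneven between-cultivar
sampling and would systematically pull calls toward wide-RSD subunits
such as 1Dx5). Merged peaks keep every window hit. Two peaks claiming
the same singleton reference: the nearer apex (normalized by the window
SD) wins; the loser becomes unknown.

Evidence applies in a fixed order — linkage, gel, PCR — because linkage
is intrinsic to the chromatogram-level call while the assays are
external. Gel evidence intersects candidate sets at gel *mobility class*
resolution (1Bx7 ≡ 1Bx7^OE^ on gel), so a 7-family candidate narrows to
{7, 7OE} and only the junction PCR finalizes it; an untested PCR leaves
the pair unresolved and flagged `unresolved_7_7OE`. Gel bands matching no
candidate peak are surfaced as conflicts, never used to create calls.
An area-ratio fallback for 7^OE^ (peak area ≥ 1.5× the median peak) is
implemented but off by default. The 13↔16, 14↔15 and 20x↔20y pairings
are consistency expectations only and never create calls.

Assembly partitions calls by locus: no 1Ax ⇒ *Glu-A1c* (+ `a1_null`),
a missing x or y partner at *Glu-B1*/*Glu-D1* ⇒ the corresponding null
flag and single-subunit symbol, two complete catalogued allele sets at
one locus ⇒ `heterozygous` with both symbols joined "A/B", total subunit
counts outside 3–5 ⇒ `subunit_count_atypical`, and uncatalogued
combinations ⇒ the "unknown" sentinel plus `unknown_combination`. Every
mis-assembled locus therefore carries at least one flag, which the
population statistics treat conservatively (heterozygotes excluded from
frequency denominators with a reported count; unresolved lines excluded
from the quality screen).

On the simulated 1787-line reference cohort at default noise the
end-to-end pipeline recovers ≥ 99.5% of locus-level calls, with every
mismatch flagged; the residual errors are the geometric collisions the
method itself acknowledges (1Dx2.2/1Dx5 are 0.03 min apart, and the
narrow 1By20y window abuts the 1By cluster).

## Population statistics

Frequencies are 100·count/N rounded half-up to two decimals (the printed
convention; e.g. 418/1787 → 23.39). Replicate RSD tables use the sample
standard deviation (ddof = 1). The good-quality screen requires 1Ax1 or
1Ax2\* at *Glu-A1*; 7 + 8, 17 + 18, 7^OE^ + 8\* or 7^OE^ + 9 at
*Glu-B1*; and 5 + 10 at *Glu-D1*. The null inventory tabulates x/y-null
lines by their surviving partner.

## Problem sizes

The acceptance script simulates and calls the full 1787-line cohort
(≈ 3 s on one CPU), ten replicate injections of Chinese Spring, and ten
replicates of each of the 16 standard cultivars; the test suite runs the
same cohort once plus a 200-replicate parameter-recovery check.

## Known limitations

- No multi-Gaussian deconvolution, RT alignment or instrument-format
  ingestion; input chromatograms are assumed baseline-recoverable,
  uniformly sampled CSV traces on the calibrated RT scale.
- Areas are arbitrary units throughout; absolute quantitation is out of
  scope, and the 7^OE^ area heuristic is advisory only.
- The cohort generator pairs locus alleles independently, so
  cross-locus combination statistics (e.g. counts of distinct allelic
  combinations) are not comparable to a real collection's.
- Numeric *Glu-1* quality scores are not computed.
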