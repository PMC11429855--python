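# Methods

`mcdhic` analyses binned Hi-C contact maps for fine-scale microcompartments:
small (25–125 kb) domains of active cis-regulatory chromatin that interact
focally with one another across the genome, in cis and in trans, most
prominently in post-mitotic cells that lack cohesin-mediated loop extrusion.
Every analysis stage is driven by a synthetic contact-map generator with
planted ground truth, so the whole pipeline can be validated by parameter
recovery at desk scale. This note records the models, the defaults and why
they were chosen, and what the synthetic benchmarks do and do not show.

## Contact-matrix model

A `ContactMatrix` stores one dense count block per chromosome pair over a
fixed `BinTable` (0-based, half-open coordinates; cis blocks symmetric).

**Balancing.** Iterative correction finds one positive weight per bin such
that weighted marginals of unmasked bins are equal (normalised to 1);
convergence is declared when the marginal coefficient of variation drops
below `tol` (default 1e-5; failure raises with the last CV). Balancing is
genome-wide (cis + trans jointly) because trans observed/expected values are
used throughout; a cis-only flag exists. Masking: bins with zero raw
marginal, plus the lowest 2% of nonzero marginals (`marginal_filter = 0.02`,
configurable; the appropriate filter is data-dependent and there is no
universal value).

**Expected models.** The cis expectation is the per-diagonal mean of balanced
values per chromosome. Beyond 40 bins the diagonals are pooled in log-spaced
windows (ratio 2^(1/8)) to control variance where per-diagonal pixel counts
thin out; short distances stay exact so the domain caller's background is
unbiased at the scales it tests. The trans expectation is a single scalar
mean per chromosome pair. O/E is the elementwise ratio, undefined on masked
bins or zero expectation; with the unsmoothed expectation every cis diagonal
of O/E has mean exactly 1 (asserted to 1e-12 in tests).

## Synthetic Hi-C generator

Cis pixel intensity at bin distance `s`:

    N_c · b_i b_j · B(s) · C_ij · M_ij · L_ij,   counts ~ Poisson

with

* `b_i`: log-normal per-bin biases (log-SD 0.25 by default; this is the
  multiplicative bias magnitude typical of mappability/GC structure after
  filtering);
* `B(s)`: distance decay. Its log-log slope is
  `-alpha + w · exp(-(ln s - ln L)^2 / (2 sigma^2))` with `alpha = 1`,
  integrated in closed form (an erf term), so the slope carries a Gaussian
  bump of amplitude `w` (`bump_weight`, default 0.6; 0 = off) centred
  *exactly* at the mean loop size `L`. This makes the extrusion "bump"
  estimable without calibration: the derivative-peak estimator should find
  `L` up to log-binning resolution. `sigma = 0.35` in log units gives a bump
  width comparable to real P(s) shoulders.
* `C_ij`: compartment checkerboard, `kappa` for same-label pairs and
  `1/kappa` otherwise (default 1.6). Labels are alternating A/B blocks with
  exponentially distributed lengths (mean 1.5 Mb); optionally the A blocks
  cycle through subcompartment labels A1/A2/V-VI.
* `M_ij`: the microcompartment grid, `mu` (default 4) whenever the two bins
  fall in two *distinct* planted MCDs — any two, at any distance, cis or
  trans. MCDs are placed without overlap, uniformly at random inside
  A-labelled runs, with a 50 kb exclusion margin so that planted domains
  remain individually resolvable at 10 kb.
* `L_ij`: convergent-CTCF loop pixels, factor `loop_factor` (default 5) at
  the anchor-pair pixel, half-height on the surrounding 3x3 ring. 75% of
  MCDs are placed to contain a loop anchor by default, mirroring the
  anchor-overlap fraction reported for real domains.

Trans intensity omits `B(s)` and `L_ij` (checkerboard and MCD grid only).
Normalisation constants match the configured cis/trans read budgets in
expectation. A pruning knob (`prune_distance`, `prune_factor`,
`prune_requires_anchor`) attenuates `M_ij` for long-range cis pairs touching
a loop anchor — the generative stand-in for extrusion-dependent pruning; it
is deliberately cis-only because pruning is an extrusion phenomenon.

All randomness flows through one `numpy.random.default_rng` (PCG64) stream
seeded from the config; outputs are bit-identical across runs and platforms.

**What the generator does not emulate:** read-level artifacts, fragment
ligation structure, realistic sequence, TAD insulation/stripes/flames beyond
loop pixels, distance-dependent trans structure, copy-number variation, and
overdispersion beyond Poisson (a gamma-mixing knob exists but is off, since
the caller's test statistic assumes Poisson counts). Passing benchmarks
therefore demonstrate correctness of the estimators under the stated model,
not performance on real libraries.

## Microcompartment-domain caller

Candidate cis pixels in a 50 kb – 2 Mb separation band are scored against
four local-background footprints — donut ring, lower-left quadrant,
horizontal stripe, vertical stripe — each excluding the central peak zone.
Per kernel, the expectation is `lambda_k = E(s) · mean(O/E over footprint)`,
rescaled to raw-count units via the bin weights, and the observed count gets
the exact Poisson upper-tail p-value. P-values are BH-adjusted within
geometric lambda-chunks (ratio 2^(1/3)): the lambda distribution is heavy
tailed, and pooled BH across a 10^3-fold lambda range would be dominated by
the short-range mass. A pixel is significant iff all four q-values are
<= 0.1 and observed/max-lambda >= 2.

**Kernel geometry.** Peak half-width `p = 1`; background half-width
`w = 12` bins. The background window of a *domain*-scale feature must
extend beyond the domain: with the 125 kb size cap, a 25-bin window is the
smallest for which the donut of a central pixel is guaranteed to sample
outside the enriched block. (A loop-scale `w` of ~5 bins places most of the
footprint inside larger domains, inflating lambda and collapsing
sensitivity.) Windows clipped by the matrix edge are evaluated on the valid
part of each footprint, requiring at least half the cells; heavily clipped
corner pixels are skipped.

**Clustering and domain extents.** Significant pixels are linked into 2D
components (Chebyshev radius 2 bins), each component projects two 1D anchor
intervals, and each interval is *seed-and-extended*: flanking bins join
while their mean O/E toward the component's partner window stays >= 2.5, at
most 5 bins per side. At ~5e6 cis reads only the strongest pixels of a true
domain cross the per-pixel FDR, so the raw significant footprint understates
the domain; the extension reports the extent the data actually supports,
while the 2.5 threshold (below the planted 4-fold, far above background)
keeps isolated false-positive pixels from growing into domains. Extended
anchor intervals are pooled genome-wide, merged with a one-bin gap
tolerance, and kept when 25–125 kb — the definitional size range. Summit:
bin with the largest summed focal enrichment over member pixels (lowest
coordinate on ties); strength: mean focal enrichment over member pixels.

**Stage classification** labels a G1-call as "cytokinesis-detected" when it
has >= 50% reciprocal overlap with a call from the earlier time point, else
"G1-specific"; the output partitions the late call set.

## Pairwise projection and pile-ups

All unordered MCD pairs are projected (cis pairs under 100 kb separation
dropped for pile-ups; counts conserve C(N,2) and are logged). Snippets are
centred on summit pairs — summits carry the signal while interval lengths
vary 4-fold — with half-width 10 bins; cis snippets crossing the diagonal
and snippets with > 50% undefined pixels are dropped. Cis snippets are O/E
against the distance expectation and trans snippets against the
chromosome-pair mean, so 1 means background in both panels. The focal score
of a pair is the mean O/E of the central 3x3 zone over the mean of the
square ring between 3 and 5 bins; it is invariant to global rescaling.

## Extrusion features and pruning classes

Loop strength is the mean O/E over the central 3x3 of a 200 kb motif-centred
window. Extrusion domains (TADs) are the outermost loops of
containment-nested groups: loop a contains b iff b's span lies within a's;
non-nested overlapping loops yield separate domains (any chaining rule would
be invented structure); duplicate spans resolve to the canonically first
loop. Cis MCD pairs are classified exhaustively: "loop-exact" when one
loop's two anchors hit the two MCDs; otherwise the anchor axis (>= 1 anchor
overlap vs 0, pad 0 at 10 kb granularity) crosses the TAD axis (both summits
in one common domain = intra-TAD; summit-based membership avoids straddling
ambiguity — straddling MCDs count as inter-TAD). Trans pairs short-circuit
to "trans". The pruning report tabulates mean focal scores per class x
distance stratum x condition with bootstrap CIs and condition ratios;
default stratum boundary 500 kb, the distance beyond which extruded loops
are rare.

## Compartment profiles

EV1 is the leading eigenvector (by |eigenvalue|) of the centred cis O/E
block per chromosome, scaled by sqrt(|eigenvalue|) and sign-phased so its
correlation with gene density is positive (A > 0); masked bins are excluded
and chromosomes under 50 unmasked bins left undefined. The eigendecomposition
acts on the centred O/E (not a correlation matrix), matching
current-generation compartment callers and keeping trans contacts out of the
track. Saddle analysis ranks bins by EV1 (or a borrowed reference EV) into
50 equal-count quantiles; corner strengths average the extreme 20% x 20%
blocks ("top 20% strongest A and B loci"). Subcompartment aggregation
reports mean O/E per label pair, optionally splitting each label into MCD /
non-MCD subsets.

P(s) is the mean balanced contact per log-spaced separation bin (ratio
2^(1/8); each bin's abscissa is the mean separation of its pixels, so
single-integer bins at short range sit exactly on their distance). The
log-log derivative uses central differences, smoothed with a 3-bin moving
average; the average loop size is the most prominent local maximum
(prominence >= 0.1 in derivative units), or none.

## cCRE and ATAC set logic

Union peaks merge overlapping intervals across the three condition sets
(prometaphase, G1-control, G1-depleted; merge gap 0 — a peak with shifted
boundaries in two conditions is one union peak); the membership vector
yields seven categories, "bookmarked" = present in all three. Fold
enrichment compares per-class element densities (elements per Mb) in target
vs background interval sets; the A-compartment background uses EV1 > 0
(threshold configurable). Bookmark coverage is the fraction of MCDs with at
least one bookmarked promoter/enhancer element; valency counts the
significant pairwise interactions per MCD (focal score >= 2 by default) and
conserves: the valencies sum to twice the number of qualifying pairs.

## Benchmark experiments and problem sizes

The frozen experiments in `mcdhic.experiments` define the reported numbers:

* **Recovery**: 2 x 20 Mb at 10 kb, ~5e6 cis / 2.5e6 trans reads, 40 planted
  MCDs (30–100 kb, mu = 4), no loop enrichment or bump — the
  transport-depleted condition domains are called in has no cohesin. Recovery
  is averaged over 3 replicate genomes because single-genome recovery varies
  with placement luck: a planted domain whose nearest partner lies beyond the
  2 Mb calling scan is undetectable by design. The null control plants
  nothing.
* **Focal recovery**: 20 MCDs of 30–60 kb (~2% genome occupancy), kappa = 1,
  mu swept over {2, 4, 8}, weights taken from the planted biases. This
  isolates the projection/pile-up machinery. With ICE-estimated weights the
  central value is attenuated by roughly `(1 + (mu-1)·f)^-1` per anchor
  (f = MCD genome fraction): about 20–25% at mu = 8 at desk scale, a real
  property of balanced Hi-C that also caps what focal enrichments real maps
  can display. The flat control runs the pile-up over an exactly flat O/E
  container.
* **Loop sizes**: single 20 Mb chromosome, bump at 50/100/250 kb and a
  no-bump control.
* **Pruning**: one truth observed under two conditions differing only in the
  planted long-range attenuation (factor 0.5 beyond 500 kb for
  anchor-touching pairs); anchor fraction 0.5 here so both anchor classes
  have enough pairs for a ratio; cells with n >= 20 are assessed.
* **Compartments**: kappa swept over {1.2, 1.5, 2.0} with no MCDs.
* **Determinism**: the full pipeline run twice from one seed on a 2 x 10 Mb
  genome, outputs compared byte-for-byte.

These sizes keep every experiment within a few minutes on one CPU while
leaving each measured effect many standard errors from its threshold.

## Known limitations

* Detection is cis-only and band-limited (50 kb – 2 Mb); domains whose only
  partners are farther away rely on the 10% unmatched/recovery slack.
* The caller's Poisson model ignores overdispersion; on real libraries the
  q-values would be anticonservative and the thresholds would need
  recalibration.
* Balancing attenuates planted focal enrichment in proportion to the
  features' share of contact mass (see above); at real-genome scale the
  effect is a few percent, at desk scale up to ~25% at mu = 8.
* Nested-loop domain construction uses containment only; reticulate overlap
  patterns produce separate domains rather than merged superdomains.
* The exact thresholds of the published domain caller are not public; the
  kernel constants here are this package's own, validated by planted
  recovery, and are all config keys.
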