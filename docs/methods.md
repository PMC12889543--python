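# Methods

## Data model and assumptions

Each sample is a pair per chromosome: a symmetric nonnegative contact
matrix `A ∈ R^{N×N}` at a fixed bin size, and a nonnegative enrichment
vector `b ∈ R^N` at the same resolution. Bins are 0-indexed, half-open
`[k·bin, (k+1)·bin)`; BED-family inputs are 0-based half-open. Contact
anchors are assigned to the bin containing the anchor **midpoint**
(deterministic, matches common loop-file practice; fractional overlap
splitting was considered and rejected). Coverage intervals contribute
`value × overlapping base pairs` to every bin they overlap. Inter-
chromosomal contacts are discarded (the method is intra-chromosomal by
construction); their count is logged.

The minimum-value thresholds (`min_hic_value`, `min_bedgraph_value`) apply
to **binned** values, after accumulation and after the `ba_mult`
multiplier: the parameters describe a valid interaction/signal at the
working resolution, not a per-row filter. `ba_mult` is applied at binning
time, before any graph construction.

## Sliding windows

Windows of `M = window_size / bin_size` bins slide along the main diagonal
with step `M // stride`. When the regular sequence would overrun, the final
window is `[N−M, N)` — snapped to the chromosome end so all windows on a
chromosome with `N ≥ M` have identical size (many similarity measures are
dimension-dependent). Duplicate end windows are collapsed. A chromosome
shorter than the window yields a single full-chromosome window, scored with
its smaller size recorded in the output. Windows are enumerated in
chromosome-file order with a single global index; the genome-wide score is
the flat mean over all windows, not a per-chromosome mean of means.

## Signal-graph information exchange

Per window, with contact block `A` and signal `b`:

1. `Ã_ij = A_ij + b_i + b_j` for **all** `i, j` (default). The additive
   form prioritizes interactions where both anchors carry signal over
   one-sided support, without a peak caller. A `coverage_weight_mode =
   "support"` variant weights only cells with `A_ij > 0`, for users who
   want weighting restricted to observed loops.
2. 3-bin 2D mean filter on `Ã`. Edges use the in-bounds neighborhood mean
   (zero padding would darken window borders and break the
   constant-matrix-is-fixed-point property); symmetry is preserved.
3. `K(μ) = (Ã D⁻¹)^μ`, `D = diag(1ᵀÃ)`. Columns of `Ã D⁻¹` sum to 1, so
   `K` is a μ-step Markov transition matrix. `μ = 0` is the identity.
4. `π = b / Σb`; the walk is applied as the push-forward `π* = K(μ) π`
   (column-stochastic kernel acting on a column vector), which keeps `π*`
   on the simplex — mass at node *j* moves to node *i* with probability
   `Ã_ij / d_j`. As μ grows, `π*` approaches the walk's limiting
   distribution and depends increasingly on structure rather than on the
   initial signal.

Numerical conventions: simplex sums are checked to 1e-9 absolute. A window
whose raw signal sums to zero is degenerate: it is enumerated, flagged, and
excluded from the genome mean (an undefined comparison must not poison the
average); counts of skipped windows are reported. Isolated nodes
(zero-degree columns) get zero kernel columns and drop walk mass — the
result is then flagged degenerate. Under the default dense coverage
weighting with any positive signal this cannot occur, since every column
degree includes `Σb`. For scoring, the μ-step product is computed as μ
iterated one-step matrix–vector products rather than a dense matrix power
(identical to 1e-9, cheaper; equivalence is asserted in the tests).

## Comparison

Spearman uses average ranks for ties; a constant processed vector makes the
correlation undefined and the window degenerate. The JSD route requires
both inputs on the simplex, uses base-2 logarithms with `0·log 0 = 0`, and
returns `2(1 − JSD) − 1 ∈ [−1, 1]`: 1 for identical distributions, −1 for
disjoint supports. Both comparisons are symmetric in the sample order.

## Depth adjustment

Round one equalizes totals: the deeper input's entries are replaced by
`Binomial(count, T_low / T_high)` draws; the shallower input is untouched.
Round two thins both by `Binomial(·, p)`. Non-integer entries are rounded
with a warning. Matrices are sampled on the upper triangle (diagonal once)
and mirrored — entrywise sampling of both triangles would break symmetry.
Signals are treated identically in 1-D. All draws come from a seeded
generator; the same (seed, input) reproduces the same output. This is an
evaluation utility for depth-robustness studies, not a normalization.

## Synthetic data generator

`SyntheticSpec` emulates one chromosome of an enrichment-based library:

- contacts: `λ_ij = background_rate · (|i−j| + 1)^{−decay_exponent}` plus
  `loop_strength` at `n_loops` random anchor pairs; observed counts are
  independent Poisson draws, symmetrized.
- coverage: `anchor_peak_height` at loop-anchor bins over a baseline
  `signal_baseline × exp(field)`, where the field is a smoothed log-normal
  background (log-sd `baseline_cv`, correlation length
  `baseline_corr_bins`) shared by both libraries of a pair — real coverage
  tracks share nonspecific-binding structure between libraries from the
  same protocol, and that shared background is what makes replicate ranks
  correlate. Counts are Poisson with optional Gaussian jitter (`noise_sd`).
- replicate pairs share λ and anchors and differ by counting noise and
  jitter; non-replicate pairs relocate `structural_fraction` of the loops
  and their anchor peaks before drawing.

Defaults (n_bins 300 at 10 kb = 3 Mb; background_rate 100, decay 1.0,
12 loops of strength 400, peaks 1000 over baseline 50, jitter sd 50,
structural_fraction 0.5) describe a deep library: tens-to-hundreds of
counts near the diagonal and peaks ~20× background. Integer Poisson counts
feed the binomial depth utilities directly. Test runs score 1 Mb windows
(μ = 5, Spearman), i.e. five windows per simulated chromosome — sizes
chosen so the whole suite runs on a laptop in seconds.

What the generator does *not* emulate: random-ligation noise, IP-efficiency
variation, distance-dependent replicate noise, TADs/stripes/compartments,
mappability gaps, and genome-scale depth. Consequently synthetic replicate
scores sit around 0.6–0.75 rather than the >0.9 typical of real deep
replicates — desk-scale Poisson noise is proportionally larger — so passing
tests demonstrate ordering (replicates > non-replicates, stability under
subsampling), not absolute score levels on real data. Published genome-wide
scores on public ENCODE/4DN libraries (e.g. CTCF cross-cell-line
comparisons) require those downloads and serve only as optional integration
checks; nothing in the test suite depends on them.

## Embeddings

Chromatin-graph plots invert coverage-weighted contacts into local
discrepancies `Y_ij = 1/(A_ij + 0.1)` (the offset keeps every edge finite,
so the graph is complete), take Floyd–Warshall shortest paths, and run
non-metric MDS (SMACOF) into 2-D. Score matrices `P ∈ [0,1]` are embedded
after `D_ij = (1 − P_ij)²`, a monotone transform that emphasizes large
distances while preserving proximity rank order. Because a non-metric
solution is defined only up to scale, coordinates are rescaled by the
least-squares factor matching embedded distances to `D`; MDS uses a seeded
random initialization, 4 restarts, and relative-stress convergence 1e-6.

## Design choices that were genuinely open

- Coverage weighting density: the additive formula is applied to every
  cell by default; the sparse "support" variant is a config flag.
- Walk application: the kernel is applied as a push-forward on the column
  vector (see above) — the only reading under which the walked signal
  remains a probability distribution, which the comparison step requires.
- min-value thresholds on binned values (documented config convention).
- Degenerate windows excluded from the mean rather than scored 0 or −1.
- Short chromosomes produce one smaller window rather than being skipped.

## Limitations

- No statistical significance is attached to window-score differences.
- Scores depend on bin size and μ; cross-study comparisons should fix both.
- The flat genome mean can average out locally meaningful differences; use
  the per-window table to find them.
- `.hic` input requires the optional `hicstraw` package; `.bigWig` requires
  pyBigWig. BEDPE/bedGraph paths have no optional dependencies.
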