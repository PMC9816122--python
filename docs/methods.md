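# Methods

## The statistic

A raster is a binary occupancy grid r(n, t) with D_s ≥ 1 spatial
dimensions (channels, electrode coordinates) and one temporal dimension
of integer bins. Its triple correlation over a lag window λ is

    c3(n1, t1, n2, t2) = Σ_{n,t} r(n, t) r(n + n1, t + t1) r(n + n2, t + t2),

a function of two spatiotemporal lag vectors; each lag pair describes a
*triplet motif* — three events at A, A + (n1, t1), A + (n2, t2). We use
the count form (no division by NT): it makes c3 an exact integer, makes
M_0 equal the raster's spike count, and matches the null expectation
formula below without extra factors. The averaged form c3/NT is
available for the correlation surface itself.

Two reductions make c3 interpretable. First, lag pairs are classified
into **fourteen motif classes**: the anchor-plus-two-lags form is turned
into its three-event multiset; the class is determined by the number of
distinct events (1, 2 or 3), the time ordering, and the
position-equality pattern (a spatial lag counts as "same neuron" only
when the full coordinate vector matches). Classes 0 (rate), I
(autocorrelation), III (synchrony) and V (propagation) have fewer than
three distinct events; the ten third-order classes are II, IV, VI–XIII.
The fourteen-class partition is forced by the invariances (node
permutation, spatial reflection, zero/non-zero spatial collapse); the
assignment of numerals within three ambiguous sub-pairs is a
convention, centralized in one table: VI = lone event earlier / VII =
later (co-located synchrony classes); VIII = co-located pair at the two
earliest temporal ranks / X = at the two latest; XI = divergence (lone
event earlier) / XII = convergence. For one spatial dimension the
intermediate taxonomy of **169 lag-sign motifs** — the realizable
combinations of sign triples (sgn(l1), sgn(l2), sgn(l2−l1)) per
dimension, 13 per dimension — is enumerated by brute-force witness
search over lags in −2..2 (sufficient: sign constraints are
scale-free), and maps onto the 14 classes via witnesses.

Second, each class contribution M_i = Σ c3 over its lag pairs is
compared to a null. Under an i.i.d. Bernoulli (Poisson-per-bin) model
at the observed rate p = spikes/NT,

    E[M_i | p, λ] = NT · #(M_i | λ) · p^{n_i},

where #(M_i | λ) counts the class's lag pairs in the window and n_i is
the class order. The reported statistic is **M_i / E_c[M_i] − 1**, with
ratio_0 ≡ 0 (the rate is controlled for by construction).

## Constituent control

E_c[M_i] conditions a third-order class on the contributions of its
second-order constituents through an adjacent-pair chain rule: writing
q_c = M_c / (NT · #(M_c | λ)) for the empirical pair rate of
constituent class c ∈ {I, III, V} and (c12, c23) for the classes of the
two temporally adjacent event pairs of the canonical triplet,

    E_c[M_i] = NT · #(M_i | λ) · q_c12 · q_c23 / p .

For classes 0, I, III, V, E_c = E. Substituting q_c = p² (the Bernoulli
value) recovers E exactly, so E_c is a consistent generalization of E.
The adjacency convention for ties places the co-located member of a
synchronous pair next to the lone event, giving pair classes
II:(I,I), IV:(III,III), VI:(I,III), VII:(III,I), VIII:(I,V), IX:(V,V),
X:(V,I), XI:(V,III), XII:(III,V), XIII:(V,V).

The ratio's default anchoring evaluates E_c at the *null* pair rates
(q_c = p²), where the chain rule reduces to E. This is deliberate: it
is the statistic whose surrogate distribution centers on zero and which
flags second- and third-order structure alike — a fully synchronous
raster scores high on both III and IV. The alternative
(`control="observed"`) plugs in the analyzed raster's own pair rates
and therefore *discounts* third-order structure that pairwise structure
already explains (the same synchronous raster then scores ratio_IV ≈ 0,
because q_III ≈ p makes triple synchrony the expected consequence of
pairwise synchrony). Both are exposed; which is appropriate depends on
whether the question is "is there structure at all?" (poisson) or "is
there *irreducibly* third-order structure?" (observed).

## Boundaries and the c3 kernel

Three boundary modes: `zero_pad` (partners outside the raster count as
empty; the default for generic finite recordings), `periodic` (all
dimensions wrap), and `periodic_spatial` (spatial dimensions wrap, time
does not — the natural convention for closed electrode arrays such as a
4×4 MEA analyzed with asymmetric −1:2 spatial lags, where time has a
genuine start and end). Zero padding biases M_i downward relative to E
by the fraction of anchor/partner combinations lost at the edges
(≈ 2λ/T per temporal lag; measured ≈ −0.10 on the ratio scale for
λ = 14, T = 150), so quantitative null comparisons in the test battery
use periodic boundaries, where E is exact.

The kernel is event-driven: for each spike, one pass over the window's
offsets collects which lags hold spikes, then every ordered pair of
present lags increments one c3 cell. Cost is O(S·W + Σ |L_s|²) for S
spikes and window volume W — far below the dense O(NT·W²) — and the
accumulation is exact integer arithmetic (numba-compiled; an
independent pure-Python triple-loop oracle backs it in the tests). A
150×150 raster at λ = 20 takes ~1 s on one core.

## Simulators

*Thresholded sine* (synchronous periodic firing): s(t) = sin(2πft)
shared by all channels; a bin spikes when s(t) + u ≥ θ with u ~
Uniform(−a, a) i.i.d. per channel *and* bin (shared noise would not
degrade synchrony). Defaults: 150×150, f = 0.08 cycles/bin, θ = 0.9
(narrow bursts, ~16% duty cycle; the threshold is a free parameter of
the construction and is exposed). The SNR is the pre-threshold power
ratio mean(s²)/mean(u²) in dB, so a = sqrt(3·mean(s²)/10^(SNR/10));
SNR = ∞ gives a = 0 and channel-identical rows.

*Single-triplet tiling*: one exemplar triplet (canonical lag pair per
class) stamped at anchors on a regular grid. The spacing default is 50
bins on a 150×150 raster (9 tiles): tiles must be separated by more
than the analysis lag so windows never straddle two copies, and the
tiling must be sparse enough that the stamped triples dominate chance
combinatorics — at dense tilings the O(λ⁴) motif count of classes like
XIII swamps the linear-in-tiles signal and detection genuinely fails.
With spacing 50 and λ = 14 every exemplar class and exactly its
constituents come out positive, with the expected magnitude ordering
(rare-by-chance classes I and III score far higher than V). An optional
`max_analysis_lag` guard errors out on spacings that would create
cross-tile motifs.

*Bernoulli raster*: i.i.d. Bernoulli(p) bins — the null itself.

All generators are deterministic given their seed.

## Surrogates

`shuffle_all` permutes every bin (preserves total spike count exactly;
the default), `shuffle_within_channel` permutes each channel's bins
(preserves per-channel counts; preferable when rates are
heterogeneous), `bernoulli_matched` redraws i.i.d. bins at the observed
rate. Ensembles are bit-reproducible given (method, n, seed). Each
surrogate is scored with its own ratio spectrum, and the ensemble
summary reports per-class min/quartiles/median/max — on structureless
surrogates these distributions center on zero, which is the calibration
the test battery checks (per-class |mean| < 0.05 over 100 shuffles of
the synchronous raster).

## Pipeline conventions

Spike-time tables are binned into half-open bins [k/rate, (k+1)/rate);
multiple spikes in one channel-bin collapse to a single 1 (rasters are
binary throughout; matrix-text readers clip entries > 0 to 1 with a
warning). Lag windows are inclusive per-dimension ranges containing
zero, applied identically to both lag vectors; millisecond lags are
converted through the bin rate (50 ms at 500 Hz → 25 bins). Spectrum
and comparison documents are JSON with a full config echo, seed and
version; treatment/baseline comparisons require matching window and
boundary configs, report per-class quotients of the two ratio spectra,
and flag classes with a zero or undefined baseline as absent instead of
raising. Batch comparisons summarize quotients across matched pairs as
five-number summaries.

## Problem sizes in the test battery

Oracle equivalence uses 100 random rasters up to 5×8 with window radius
≤ 2 (both boundary modes) — small enough for the naive
loop-over-everything oracle to stay independent and exact. Poisson-null
recovery uses 500 Bernoulli(0.1) rasters of 30×200 at window radius 3
(mean M_i within 3 SE of E for all classes). The figure-level
reproductions run at the original 150×150 scale: λ = 20 for the
synchronous raster and its 100-surrogate calibration, λ = 14 for the
six triplet tilings and the SNR sweep {∞, 0, −9, −17, −40} dB (3 seeds
per level; the seed-averaged synchrony-class mean ratio decreases
strictly and lands below 0.05 in magnitude at −40 dB).

## Known limitations

- The classifier and window machinery are D_s-agnostic, but lag-sign
  motifs (the 169) are defined only for one spatial dimension, and the
  triplet tiler generates 1-D rasters.
- E[M_i] assumes homogeneous rates; with strongly heterogeneous
  channels, use within-channel shuffles and the surrogate band rather
  than the analytic E.
- The constituent-controlled E_c uses only the two temporally adjacent
  pairs of the canonical triplet; a class like IX (feedback) whose
  third constituent (I) enters via the non-adjacent pair is controlled
  only through p and the adjacent V pairs. The factorization is
  isolated in one function so an alternative can be swapped in.
- No analytic variance of M_i and no multiple-testing control across
  the 14 classes: inference beyond "above/below the surrogate band" is
  out of scope.
- The simulators emulate idealized structure (shared sinusoidal drive,
  exact tilings, i.i.d. noise); they do not reproduce bursting
  statistics, refractoriness, or rate nonstationarity of real cultures,
  so passing tests validate the estimator and its calibration, not any
  claim about biological recordings.
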