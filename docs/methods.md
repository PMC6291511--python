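# Methods

`plimst` implements a resting-state source-space connectivity pipeline for
MEG/EEG: phase lag index (PLI) functional connectivity, minimum spanning tree
(MST) topology, and two-group permutation inference, together with a
synthetic-cohort generator that provides ground truth for every stage.

## Signal model and preprocessing

The pipeline's input is an ROI × time matrix of source-reconstructed signals
with a known sampling rate (how the ROI time series were obtained — sensor
cleaning, beamforming, atlas parcellation — is upstream of this package).
The working configuration is 512 Hz, with the record segmented into the
first 10 contiguous, non-overlapping epochs of 8 s. Band decomposition uses
the five canonical bands — delta (0.5–4 Hz), theta (4–8), alpha (8–13),
beta (13–30), gamma (30–48) — implemented as 4th-order Butterworth band-pass
filters applied forward–backward (`sosfiltfilt`). The zero net phase of the
forward–backward pass is essential: every downstream quantity is a function
of instantaneous phase, and a filter with group delay would bias it. Band
edges are −3 dB corner frequencies. Filtering is applied to the continuous
record before epoching, avoiding per-epoch edge transients. Downsampling
(integer factors only) applies scipy's zero-phase anti-alias decimator and
requires the target rate to exceed twice the highest band edge (96 Hz).

## Phase lag index

For two band-limited signals with instantaneous phases φᵢ, φⱼ from the
analytic (Hilbert) representation,

    PLI = | ⟨ sign( sin(φᵢ(t_k) − φⱼ(t_k)) ) ⟩ |,

the absolute time-average of the sign of the phase-difference sine. PLI is 1
when one signal consistently leads the other, and 0 when the lag has no
consistent sign — including exactly zero (or π) lag, which makes the metric
blind to volume conduction / field spread at the cost of discarding true
zero-lag coupling. Implementation choices:

- `sign(0)` is the mathematical signum (0), and |sin ΔΦ| < 1e−12 is treated
  as exact zero, so rounding noise cannot inject spurious signs.
- The Hilbert transform is taken per epoch (one PLI matrix per 8-s epoch);
  the subject-level matrix is the elementwise arithmetic mean over epochs.
- The pairwise computation uses the angle-difference identity
  sin(φᵢ−φⱼ) = sinφᵢ cosφⱼ − cosφᵢ sinφⱼ in a compiled kernel; a vectorized
  numpy fallback implements the identical arithmetic.

Finite epochs give PLI a positive bias for *any* pair of independent
band-limited signals: the sign of ΔΦ decorrelates on the time scale of the
band's inverse bandwidth, so an 8-s theta epoch carries only a few dozen
effective samples and the per-epoch |mean sign| floor is ≈ 0.1–0.15.
Averaging per-epoch PLIs across epochs does not reduce this floor (the
absolute value is taken per epoch). All group comparisons are therefore
relative; the floor cancels between groups.

## Minimum spanning tree and its metrics

The PLI matrix is read as a weighted graph (ROIs = nodes) with distances
1/PLI, and reduced to its MST with Kruskal's algorithm: sort links by
ascending distance, add one at a time, discard any that closes a loop, stop
at N−1 accepted links. Ties are broken by (distance, smaller index, larger
index), making the tree deterministic; with all-distinct weights it is
unique and equals the maximum spanning tree on the raw PLI weights.
Zero-PLI entries get infinite distance; if the strictly-positive graph is
disconnected the run fails rather than fabricating a meaningless backbone
edge. The tree is treated as binary (unweighted) for all metrics.

Global metrics (L = leaf count, M = N−1 links):

- **leaf fraction** L/M (a `nodes` convention L/N is available by flag; the
  two differ by the constant N/(N−1) and cannot change a permutation-test
  conclusion);
- **tree hierarchy** Th = L / (2 · M · BC_max), the trade-off between hub
  overload and communication efficiency;
- **degree divergence** κ = ⟨k²⟩/⟨k⟩ of the degree sequence.

Nodal metrics: **degree**; **betweenness centrality** — the fraction of the
(N−1)(N−2)/2 unordered node pairs whose unique tree path passes through the
node (endpoints excluded), computed in O(N) from rooted subtree sizes; and
**eccentricity** — hop distance to the farthest node.

## Group inference

The primary test is a two-sided label permutation test on the difference of
group means. When the number of distinct label assignments C(n_a+n_b, n_a)
is ≤ 20,000 the null distribution is enumerated exhaustively (p = b/total);
otherwise n_perm Monte-Carlo reshuffles are drawn and p = (b+1)/(n_perm+1),
the standard conservative estimator that cannot return zero. The default is
10,000 permutations at α = 0.05. The permutation null depends only on the
pooled multiset of values, so rows are sorted before reshuffling — this
makes Monte-Carlo p-values invariant to subject ordering (and to swapping
equal-sized groups) at fixed seed. Multiple comparisons are corrected with
the Benjamini–Hochberg step-up procedure: one family per band across the
3 global metrics, and one family per band per metric across all ROIs for
the nodal metrics; bands are not pooled.

Follow-ups for a node found significant: a permutation test on the mean PLI
of each of its N−1 incident links (FDR across links), and a Pearson
chi-square test (1 df, no continuity correction by default) on how many
subjects of each group carry each incident link in their MST (FDR across
links; degenerate 2×2 margins give p = 1 by convention). Clinical
correlations are sample Pearson r with the two-sided t-distribution p,
computed within one designated group only and deliberately uncorrected —
they are exploratory. Clinical group comparisons use Welch's
unequal-variance t-test.

## Synthetic cohorts

The generator produces two groups of subjects with a known coupling
structure so that every downstream stage can be validated against ground
truth. For each coupled ROI pair a *shared* narrow-band stochastic carrier
is drawn (white noise band-passed with an order-8 zero-phase Butterworth,
unit variance). The first ROI receives the carrier scaled by the coupling
strength; the second receives the carrier's analytic signal rotated by the
requested phase lag — a frequency-flat rotation, so the imposed lag is
constant across the carrier band. Lags of exactly 0 or π are legal and, by
construction of the PLI, invisible. Independent noise of standard deviation
`noise_sd` (default 0.3) is added to every ROI. Every draw is a pure
function of (spec, seed); subject seeds are the master seed offset by group
and subject index.

Three design choices depart from the most naive additive scheme, all driven
by how band-limited analysis filters interact with narrow-band carriers:

1. **Carrier placement.** The default carrier band is the theta *interior*
   (5–7 Hz), not edge-to-edge 4–8 Hz. The analysis filters place their −3 dB
   corners exactly at the band edges, so an edge-to-edge carrier leaks
   substantial coherent energy through the delta and alpha filter shoulders
   and the planted effect stops being band-specific.
2. **Hub normalization.** Each ROI's summed coupled component is rescaled to
   the strongest incident coupling strength. Without this, a 6-edge hub is
   ~6× louder than its partners; even at −25 dB the adjacent-band filter
   shoulders then pass enough hub energy to shift the PLI's finite-sample
   bias and flag the hub in bands that carry no coupling. Normalization also
   keeps the per-link signal-to-noise ratio of a hub comparable to that of a
   singly-coupled pair, which is the regime of interest.
3. **Noise spectrum.** The independent noise carries equal power in each of
   the five canonical bands, so every analysis band has an independent phase
   floor of its own. (A full 1/f background model is deliberately out of
   scope; equal-power-per-band is the minimal spectrum with that property.)

A planted effect adds strong (default 0.9, lag π/4) edges from one target
ROI to its next `n_edges` (default 6) neighbours in group B only, raising
that ROI's expected MST degree and betweenness. Synthetic clinical scores
with a prescribed population correlation r to any metric are built as
r·z + √(1−r²)·ε with z the standardized metric and ε standard normal.

**What the generator does not emulate:** sensor physics and field spread,
head geometry, physiological artifacts, 1/f spectral background, amplitude
dynamics, or any spatial correlation structure beyond the planted edges.
Passing tests therefore demonstrate that the *pipeline* recovers known
coupling topology from phase-lagged signals under realistic epoch lengths
and sample sizes — not that any particular clinical finding would replicate.

## Problem sizes and tolerances

Validation runs use cohorts of 16 + 16 subjects with 30 ROIs (the package's
chosen desk-scale cohort; all pipeline code is size-agnostic and the 90-ROI
default is exercised in structural tests), 10 × 8 s epochs at 512 Hz, and
2,000 permutations per test in replicate studies (10,000 in single runs).
Exact identities (PLI fixed points, tree metrics on stars and paths,
exhaustive permutation p-values) are asserted to machine precision; oracle
equivalences (naive PLI loop, brute-force spanning-tree enumeration,
pairwise-path betweenness, reference step-up FDR) to 1e−12; calibration
rates (type-I error at α = 0.05) to the binomial error of the replicate
count. Degenerate inputs follow explicit conventions: constant pooled data
give p = 1; degenerate 2×2 margins give χ² = 0, p = 1; correlations on
constant input are errors, not NaNs.

## Known limitations

- Per-epoch MST mode and per-epoch filtering exist as flags but the
  validated default is one tree per subject from the epoch-averaged matrix.
- The PLI bias floor means absolute PLI values are not comparable across
  epoch lengths or spectral contents; only within-study contrasts are
  meaningful.
- The inclusion-frequency chi-square uses the asymptotic distribution; with
  16 subjects per group expected cell counts can be small and the test is
  approximate (a continuity-correction flag is provided).
- Monte-Carlo p-values have resolution 1/(n_perm+1); borderline FDR
  decisions near α should be read with that granularity in mind.
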