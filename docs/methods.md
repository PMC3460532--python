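# Methods

`slnets` reconstructs time-varying functional networks from multichannel
neural recordings with the synchronization likelihood (SL), screens edges
against phase-randomized surrogates, and segments the resulting network
time series into recurring network states. This note documents the models,
the parameter choices and their rationale, the synthetic benchmark, and the
numerical decisions a user should know before trusting (or extending) the
results.

## Synchronization likelihood

For channel series `x^k` the state at sample `i` is the time-delay
embedding `X_i = <x_i, x_{i+l}, ..., x_{i+(m-1)l}>` with lag `l` and
dimension `m`. The recurrences of `X_i` are the `n_rec` candidates with
smallest Euclidean distance among all `j` with `w1 < |i-j| < w2` (strict,
two-sided); the inner edge excludes autocorrelated neighbours, the outer
edge bounds the search horizon. SL between channels `k1, k2` at sample `i`
is `|J^{k1} ∩ J^{k2}| / n_rec`, the fraction of simultaneous recurrences;
values lie on the grid `{0, 1/n_rec, ..., 1}`. For independent channels the
expected SL is the chance level `n_rec / (2 (w2 - w1 - 1))`.

Parameters derive from the band's frequency content:

| parameter | rule | broadband (4–30 Hz) @ 500 Hz |
|---|---|---|
| lag `l` | `floor(fs / 3 f_high)` (≈3 samples per fastest cycle) | 5 samples |
| dimension `m` | `round(3 f_high / f_low + 1)` | 24 |
| inner edge `w1` | `2 l (m-1)` (two embedding spans) | 230 samples = 460 ms |
| outer edge `w2` | `w1 + n_rec/p_ref - 1` | 429 samples = 858 ms |
| recurrences `n_rec` | fixed | 10 |

with `p_ref = 0.05` the reference recurrence density. A sample is *valid*
when its own embedding and the embeddings of every window candidate fit
inside the epoch, i.e. (0-based) `i ∈ [w2-1, N - (m-1)l - w2]`; a
2500-sample epoch at these values has exactly 1529 valid samples (3.058 s
at 2 ms per sample). This two-sided strict-inequality convention is the
unique one reproducing that count. Distance ties are broken by temporal
proximity, then by index, so the estimator is fully deterministic.

Note the broadband embedding span (230 ms) is slightly shorter than one
full cycle of the slowest component (250 ms at 4 Hz); the formula above is
the canonical parameter set and is used as-is.

## Preprocessing

Continuous recordings are cut into 5 s epochs and decimated to 500 Hz with
an anti-alias filter (`scipy.signal.decimate`, zero-phase); an online
acquisition filter alone does not prevent aliasing, hence the explicit
anti-alias step. Artifact screening operates on the raw microvolt signal:
(1) any sample beyond ±200 µV, (2) a fitted linear trend exceeding 75 µV
over the epoch, (3) a channel's per-epoch mean absolute amplitude more than
3 SD from that channel's across-epoch mean, or (4) an amplitude-kurtosis
z-score above 5. Rule 3 deliberately uses a per-epoch statistic — a
per-sample 3-SD rule would reject essentially every epoch of Gaussian
data; the kurtosis threshold of 5 is this package's choice. Band-pass
filtering uses a zero-phase Hamming windowed-sinc FIR with transition
widths of 25% of each band edge (linear phase avoids group-delay
distortion of the recurrence structure). Epochs are then re-referenced to the instantaneous channel
average and each channel standardized to zero mean, unit variance.

`average_reference=False` skips re-referencing. This matters for synthetic
montages with few channels: subtracting the channel mean injects every
channel — including planted nonlinear couplings — into all others at
`O(1/K)`, contaminating deliberately uncoupled edges. The simulation preset
therefore disables it; real recordings (29 channels) keep the default.

## Surrogate screening of edges

The null hypothesis per edge is a stationary linear Gaussian process with
the observed power spectra and cross-spectra. Surrogates realize it by
rank-remapping each channel onto Gaussian deviates, rotating all channels'
Fourier phases by one shared random phase vector (preserving every
cross-spectrum, hence all *linear* coupling), inverse-transforming, and
undoing the Gaussian remap — each channel's amplitude multiset is preserved
exactly. SL is computed on `n_surr` surrogates (default 200; the
full-scale analysis uses 10,000), giving per-edge, per-sample null samples.

Each (edge, sample) cell is tested with a one-tailed Wilcoxon signed-rank
test on (observed − surrogate) differences, H1: median > 0 (Pratt zero
handling; exact tie-free null for small n, normal approximation with tie
correction otherwise), followed by Benjamini–Hochberg step-up at
`q = 1e-4` *within each sample point* across its edges. Non-retained edge
weights are zeroed.

**Known limitation — anticonservative p-values.** Testing a single observed
value against its own null *sample* with a one-sample signed-rank test is
not a calibrated procedure: under the exchangeable null the p-value is a
monotone transform of the observation's percentile within the null sample,
so any cell above roughly the 65th null percentile receives an
astronomically small p. On fully uncoupled band-limited epochs about 17% of
edge-samples survive the q=1e-4 mask, for any `n_surr`. The calibrated
alternative — the empirical percentile p = (1+#{surr ≥ obs})/(n_surr+1) —
has a p-value floor of 1/(n_surr+1) and can never clear q=1e-4 at
desk-scale surrogate counts. The signed-rank form is retained as the
method's defined behaviour; its consequence is benign for the downstream
stages because falsely retained edges carry small weights (≈ the chance
level) that do not dominate cosine similarity against genuinely coupled
edges (~10× larger). Screens intended as calibrated hypothesis tests should
use the percentile form with a correspondingly large surrogate ensemble.

## Graph metrics

Per-sample networks are the FDR-masked symmetric weight matrices. Density
is the mean upper-triangle weight (equal to mean node strength over n−1).
Clustering is the Onnela geometric-mean weighted coefficient normalized by
the mean over `n_null = 20` degree-preserving rewired networks (double edge
swaps, weights carried with edges); the Onnela variant is this package's
choice among the standard weighted-clustering formulations. Modularity is weighted
Newman–Girvan Q maximized by greedy multilevel (Louvain) optimization, best
of `n_restarts = 10`; the returned Q is never below the trivial one-module
partition's 0. Metrics are computed on the FDR-masked networks — a pipeline
choice (computing them on unmasked tensors is equally defensible and only
requires skipping the masking stage).

## Similarity and edge communities

The T×T cosine-similarity matrix between per-sample SL vectors uses plain
cosine similarity — SL vectors are nonnegative, so values already lie in
[0, 1] and need no further normalization. Edge communities are Louvain communities of the
zero-lag Pearson correlation matrix between edge time series, negative
entries floored at 0 (single-layer modularity assumes nonnegative weights);
zero-variance edges form a designated silent community.

## Evolutionary clustering into network states

Per-sample network descriptions are partitioned by a genetic algorithm
maximizing a Dunn-index variant: minimum between-cluster centroid distance
divided by the maximum over clusters of the mean member-to-centroid
distance. All-point-mass partitions are degenerate and score 0. The
all-pairs minimum in the numerator doubles as a natural guard: a cluster
obtained by excising a few noisy samples sits close to its parent's
centroid and drags the score down, so the optimizer cannot game the ratio
by dumping outliers into micro-clusters. (An optional `min_cluster_size`
exempts sub-minimum clusters from the separation term for heavy-noise
data; it is off by default precisely because the exemption re-enables that
gaming.)

The population (default 30; full scale 50) is seeded from hierarchical
clusterings: 25 cluster numbers drawn without replacement from 2..100
(capped at T−1), each cut with single, average and complete linkage; each
member repeatedly adopts a random cluster from this pool until all samples
are assigned (members with k<2 are repaired by splitting at the temporal
midpoint). Generations (default 200; full scale 1500) apply binary
tournament selection, elitism (5), and four variation operators:

- **crossover** (rate 0.3): copy the donor's raw labels on a random
  contiguous time window; coinciding label ids merge clusters across the
  window boundary;
- **mutation** (0.3): reassign one random sample to a random existing or
  fresh cluster (cluster-count ceiling 100, mirroring the seeding range);
- **jitter** (0.3): expand, contract, or shift a random contiguous run by
  one sample — the temporal move that refines state boundaries;
- **merge** (0.3): agglomerate nearest-centroid cluster pairs down to a
  uniformly drawn target count.

The merge operator is this implementation's addition. The other moves alter
at most a few samples per application, so a fragmented partition (seeded
members typically start with k≈50–190) can only coarsen by neutral drift
across a fitness plateau — empirically hopeless within desk-scale budgets.
One merge application can reach any coarseness, and nearest-centroid order
preferentially rejoins fragments of the same underlying state. A fraction
(0.1) of each generation is replaced by freshly seeded immigrants. The
best-ever partition by fitness is returned; all randomness flows from one
seed, so results are reproducible. Selection scheme, operator rates and the
immigrant fraction were chosen for robustness and live in `EvoConfig`.

The pipeline clusters each sample's **cosine-similarity profile** (its row
of the T×T similarity matrix, subsampled by `profile_stride`, default 4)
rather than the raw SL vector (`cluster_features="sl"` restores the
latter). Each similarity entry already averages over all edges, so profile
space suppresses the per-sample recurrence-counting noise (SD ∝ 1/√n_rec
per edge) that otherwise rivals between-state separation; planted-state
recovery is markedly more reliable there, and the similarity matrix is
the representation in which quasi-stable blocks are defined in the first
place.

Two deterministic post-processing steps polish the returned partition.
`absorb_short_runs` folds label runs shorter than `min_state_samples`
(default 5) into the temporally adjacent run with the nearer feature
centroid: the SL estimator smears any coupling change over roughly the
embedding span, so shorter flicker lies below the measure's temporal
resolution and its near-single-sample representatives are too noisy to
classify downstream. `refine_boundaries` then scans each junction between
adjacent states over ±60 positions and keeps the placement maximizing the
fitness — the stochastic search settles cluster identities long before
exact junction positions, and this greedy finisher never decreases fitness
and never shrinks a run below the minimum.

Maximal runs of constant cluster label are the network states: boundaries,
durations (run length × sample period), and mean-SL representative vectors.
Because states recur, their number generally exceeds the cluster count.

## Network state repertoire

To balance unequal state counts across subjects, 100 ensembles are drawn:
the target time is the smallest per-subject total state duration divided by
4; per ensemble and subject, states are sampled uniformly without
replacement until the subject's sampled duration exceeds the target. Within
an ensemble, each state pair's cosine similarity is compared with a null of
`n_perm = 1000` edge permutations of each representative vector; a
one-sample one-tailed t-test of the null sample against the empirical value
(H1: empirical greater) marks pairs significant at `p < 1e-6`. Louvain communities of the
binary graph are the state families. Family-average topographies from all
ensembles are aggregated (unweighted) into a family-by-family cosine
matrix whose Louvain
communities are the consensus meta-families, reported with the fraction of
states (by count, and by duration in the pipeline output) per meta-family.

## Synthetic benchmark

`gen_coupled_henon` chains Hénon maps (`x ← 1.4 − u² + 0.3y`, `y ← x`) with
the drive `u = (1−c_tot)x + Σ c_jk x_j`; the symmetric coupling matrix
encodes undirected strength while the lower-index channel of each pair
drives the higher one. A literally mutual drive exchanges rather than
shares state and cannot synchronize identically at full coupling; under
this convention coupling 1 reproduces the driver's quadratic term exactly
and the pair synchronizes identically after a ≥1000-iterate transient.
Identical synchronization sets in near c≈0.4; the regime informative for
surrogate contrasts (nonlinear but not affine dependence) is partial
coupling, c≈0.2–0.3.

`gen_switching_epoch` band-passes independent Gaussian noise per channel,
then, per schedule segment, mixes into each response channel a static
nonlinear distortion of its filtered driver
(`s_k = (1−c_tot) z_k + Σ c_jk g(z_j)`, default `g(u) = u|u|/√3`), then
adds broadband measurement noise. The distortion is applied *after*
filtering because a purely linear mixture would be preserved exactly by the
common-phase surrogates and every planted edge would (correctly) fail the
nonlinearity screen — higher-order dependence is the property the generator
must plant. The simulation preset plants three coupling topographies on 9
channels built from the parallel triple classes of the affine plane over
GF(3): per state, three driver→(response, response) triples at strengths
(1.0, 0.9), giving nine strong edges per state with pairwise disjoint edge
sets across states.

The preset overrides the band-derived SL parameters with a short-span
embedding (`l=2, m=6, w1=20, w2=119, n_rec=10` at 250 Hz). SL smears a
coupling switch over the embedding span, so the band-derived 24-dimension
embedding (span 46 samples) caps boundary localization at roughly ±half a
span; a 10-sample span localizes planted switches to within a few samples.
Nothing is lost: the stochastic band-limited sources have no
low-dimensional attractor for a large embedding to reconstruct. The
band-derived parameters remain the library defaults for real recordings.

What the generator does *not* emulate: volume conduction and reference
effects, 1/f background spectra, nonstationary amplitude dynamics within a
state, ocular/muscle artifacts, and inter-subject topographic variability.
Passing tests therefore demonstrate that the pipeline recovers planted
nonlinear coupling structure under its own stated assumptions, not that it
would resolve states in arbitrary real recordings.

## Problem sizes and reproducibility

Library defaults reproduce the full-scale analysis conventions (500 Hz,
n_rec=10, p_ref=0.05, q=1e-4, 100 ensembles, 1000 permutations; the
full-scale evolutionary configuration is `EvoConfig.full_scale()`). The
simulation preset and the test suite run the identical code paths at
reduced sizes chosen as this package's benchmark conditions: 9 channels at
250 Hz, 5 s epochs, the short-span embedding above (1004 valid samples per
epoch), 60 surrogates, desk evolutionary configuration (30×200), 50
ensembles.

Every stochastic component takes an explicit seed; rerunning a pipeline
configuration reproduces outputs bit-for-bit, and the run directory's
`manifest.json` records the configuration hash, seeds and versions.

## Known limitations

- The signed-rank edge screen is anticonservative under the null (above);
  retained-edge fractions are not an FDR in the calibrated sense.
- SL smears state transitions over roughly the embedding span, bounding
  boundary localization at ±(span/2) samples regardless of the optimizer.
- The Dunn-variant objective has no preferred cluster count; on data whose
  within-state variability approaches between-state separation it favours
  refinements, so segmentations should be read as over- rather than
  under-segmented (state *families* absorb the refinement downstream).
- Consensus meta-family counts depend on the modularity resolution of the
  family-similarity graph; very similar topographies may merge.
- EDF input requires the optional `mne` dependency; EDF export is not
  supported (recordings round-trip as TSV).
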