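# Methods

## The observation model

The unit of observation is a paired OTU table: non-negative integer
read counts indexed by OTU, with one column per (sample, fraction)
where the fraction is DNA (community membership) or RNA/cDNA
(metabolically active membership), produced from co-extracted nucleic
acids of the same sample. A rooted phylogeny with branch lengths over
the OTUs is a second input; all distances are used in the tree's native
units, since every statistic downstream is either scale-free by
construction (K, Kse) or standardized against a null computed on the
same tree (SES).

## Replicate-consensus filtering and rarefaction

Technical PCR replicates guard against amplification artefacts: a read
(an exact sequence string; in the simulator, a read token labelled by
its OTU) is retained only if it occurs in **every** replicate of a
library, with retained multiplicity equal to the summed count across
replicates. The filter is exposed on sequence multisets and is
order-invariant.

Rarefaction draws each (sample, fraction) column down to a common depth
without replacement (multivariate hypergeometric), in a single seeded
draw — no averaging over repeated draws. Columns below the target depth
are reported and excluded by the pipeline rather than silently padded.
Alpha- and beta-diversity stages run on the rarefied table; the core
microbiome and the expression ratio use the full table (the core is a
presence pattern that subsampling would destroy, and the ratio is built
from relative abundances, which cancel depth).

## Diversity

Hill numbers use the positive proportions only, with the q = 1 Shannon
limit computed as `exp(−Σ p ln p)` and `0·log 0 ≡ 0`. Chao 1 uses the
bias-corrected form `S_obs + F1(F1−1)/(2(F2+1))` throughout so that
zero doubletons never divide by zero (scikit-bio's implementation
backs it). The Bray–Curtis `wisconsin_sqrt` transform is square root first, then
Wisconsin double standardization in the conventional order: each OTU
row divided by its maximum across samples, then each sample column by
its total. Paired DNA-vs-RNA comparisons use Student's paired t, or the
Wilcoxon **signed-rank** test when normality is doubtful — the paired
design dictates signed-rank rather than rank-sum; zero differences are
dropped and the exact null is used for n ≤ 25 (tie-corrected normal
approximation above). Degenerate input (all differences zero) is
reported as p = 1 with a flag rather than an error.

## Core microbiome

The mode-m core over a sample set is the set of OTUs with count ≥ 1 in
fraction m (or in both fractions, mode `both`) of every listed sample;
it is antitone in the sample set. The sampling-effort curve draws, for
each k from 1 to the number of samples, uniform k-subsets without
replacement (1,000 by default) and records the mean and sd of the core
size; at k = n the value is deterministic and sd is 0.

## Mean expression ratio

With RA the within-column relative abundance, the trait is
`mean RA_RNA / (mean RA_RNA + mean RA_DNA)`, both means taken over
exactly the n samples in which the OTU is present in DNA and/or RNA —
a zero in the other fraction of a supporting sample counts; samples
where the OTU is absent from both contribute nothing, including to n.
The default standard error is the SEM of the per-sample ratios
`r_i = RA_RNA,i/(RA_RNA,i + RA_DNA,i)` over the n supporting samples
(sample sd, n − 1 denominator); a delta-method alternative propagated
from the SEs of the two means is available (`se_method="delta"`). The
two constructions were both implemented because the SE definition is
genuinely open; the per-sample SEM is the default as the most direct
reading of a per-OTU SE "over the samples". OTUs supported by a single
sample have no defined SE; they receive the median SE of the n ≥ 2
OTUs (configurable to NaN), are flagged `se_substituted`, and counted
in the run manifest — Kse requires a finite SE for every tip, and the
median is a conservative, scale-appropriate fill.

## Community phylogenetic structure

MPD is the mean patristic distance over unordered pairs of co-occurring
OTUs, MNTD the mean nearest-co-occurring-neighbour distance; both are
unweighted by default (abundance-weighted variants exist) because the
null holds abundance patterns fixed and shuffles only phylogenetic
position. The null shuffles tip labels across the phylogeny with the
community matrix fixed; for a fixed membership this is exactly a
uniform random draw of an equal-sized tip subset, which is how the null
is sampled (a permutation of the distance-matrix index). SES is
`(obs − mean_null)/sd_null`; p is lower-tailed by default (clustering
is the hypothesis of interest; two-sided available) with the add-one
rule `p = (#{null ≤ obs} + 1)/(B + 1)`, B = 999 by default. A null
whose sd is at floating-point noise (e.g. the community equals the
pool) is flagged degenerate instead of yielding a meaningless SES. The
local OTU pool is the union over all samples and both fractions by
default; a per-fraction pool is available as the robustness variant.
Before the SES stage the pipeline computes Blomberg's K on per-OTU
total abundance and warns if it is significant, since the
fixed-abundance null is only calibrated when abundance itself carries
no phylogenetic signal.

## Phylogenetic signal

K is computed in its GLS form: with C the phylogenetic
variance–covariance matrix, `â = (1'C⁻¹x)/(1'C⁻¹1)`,
`MSE0 = (x−â)'(x−â)/(n−1)`, `MSE = (x−â)'C⁻¹(x−â)/(n−1)`, and
`K = (MSE0/MSE) / [(tr C − n/(1'C⁻¹1))/(n−1)]`. K is invariant to
affine transforms of the trait and to uniform branch scaling; on a star
tree it is identically 1. Solves use Cholesky factorization with a
logged jitter of `1e-10·tr(C)/n` added only on failure.

Kse treats the trait as measured with known per-tip error: `x ~ N(a·1,
σ²C + diag(se²))`. σ² is estimated by bounded scalar ML on log σ² and K
is evaluated with C replaced by `C* = σ̂²C + diag(se²)`; because K is
scale-invariant in its covariance argument, all-zero SEs reduce Kse to
K exactly. When the fitted phylogenetic share of variance
`σ̂²·tr(C) / (σ̂²·tr(C) + Σse²)` falls below 1e-6 the signal is
unidentifiable (error dominates every tip) and the result is flagged
degenerate rather than trusted.

Significance does not permute K itself: the statistic is the mean
squared standardized independent contrast, computed via Felsenstein
pruning (contrast `(x_L − x_R)/√(v_L + v_R)` at each internal node,
parent branch augmented by `v_L v_R/(v_L + v_R)`), with the null from
shuffling trait values across tips and a lower tail (true signal
shrinks contrasts). The pruning recursion is linear in the tip values,
so the contrasts are precomputed once as an (n−1) × n operator and the
whole permutation null is a single matrix product. Zero-length branches
are raised to `1e-8 ×` tree depth before pruning and polytomies are
resolved arbitrarily with zero-length internal edges first — an
edge-case policy only, since input trees are expected to be bifurcating
ML trees.

## Synthetic data

The generator emulates the design the statistics assume: 19 hosts × 2
fractions, a regional pool of 300 OTUs (defaults; ~100–650 supported),
per-sample richness 140, sequencing depth 2,000 reads per library with
2 technical replicates, and a pure-birth (Yule) phylogeny. Yule trees
are grown by exponential waiting times with uniform lineage splits and
a final epoch extension, so they are exactly ultrametric with strictly
positive branch lengths; birth–death generalisations add parameters
without changing any tested property. Latent within-sample abundances
are log-normal (meanlog 0, sdlog 1.5), reproducing the dominance of a
few OTUs typical of such surveys. A per-OTU latent activity `a ∈ [0,1]`
— the logistic transform of a Brownian, white-noise or constant trait —
splits reads between fractions: DNA read weights are proportional to
`latent·(1−a)` and RNA weights to `latent·a`, i.e. the RNA composition
is the DNA composition reweighted by `a/(1−a)`. This makes the boundary
semantics exact (a = 0 ⇒ no RNA reads anywhere; a = 1 ⇒ no DNA reads)
and the estimated expression ratio a monotone, consistent estimator of
a (rank correlation > 0.99 at depth 10⁴). Technical replicates are
independent multinomial draws from the same latent composition, so the
consensus filter removes only singleton noise, mirroring its procedural
role.

Community assembly offers three regimes: `random` (uniform subsets —
the null the SES calibration needs), `filtered` (membership drawn from
within one randomly chosen clade large enough to hold the requested
richness, the signature of host filtering; absence of such a clade is a
loud error), and `overdispersed` (greedy max–min patristic distance
selection — deterministic given the seeded start, simpler than
annealing, and sufficient to produce positive SES).

What the generator does **not** emulate: nucleotide sequences, PCR and
chimera artefacts, taxonomy, occupancy–abundance coupling (membership
is drawn independently of latent abundance, so ubiquitous "core" OTUs
are much rarer than in real surveys), and compositional correlations
between hosts beyond shared clade membership. Passing tests therefore
demonstrate the correctness and calibration of the statistics under
these controlled conditions, not the ecological conclusions one would
draw from any real dataset.

## Problem sizes and determinism

Every stochastic routine takes an explicit integer seed and is
bit-reproducible under it; the pipeline derives per-stage seeds from
one master seed via a seed sequence and logs them in the run manifest.
The validation suite uses the scales at which the checked properties
are statistically decidable yet quick: type-I calibrations use 1,000
simulations of 199 permutations each; K calibration uses 200 Brownian
traits on a fixed 100-tip tree; power checks use 100 simulations;
end-to-end recovery uses 50 replicates of a 60-OTU pool at depth 10⁴.

## Known limitations

- Kse assumes the reported SEs are the true observation standard
  deviations; underestimated SEs leave K attenuated.
- The n = 1 median-SE substitution is a pragmatic fill, not an
  estimate; runs with many singleton OTUs should treat Kse cautiously
  (the count is in the manifest).
- The tip-shuffle null conditions on the observed richness per
  community only; it does not preserve per-OTU occupancy across
  communities (the abundance-signal precondition is the guard rail).
- MNTD's SES is computed against the same subset-resampling null as
  MPD; nearest-neighbour statistics are more sensitive to pool
  delimitation, which is why both pool variants are exposed.
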