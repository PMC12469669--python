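# Methods

`msatpop` implements the statistical workflow of a classical microsatellite
survey of livestock diversity: seven rabbit breeds (Black Baladi, White
Baladi, Red Baladi, Jabali, New Zealand White, American Rex, Chinchilla;
sample sizes 127/40/40/112/87/60/60) typed at a 14-marker panel on
polyacrylamide gels. The raw genotypes of that survey were never deposited,
so the package pairs every analysis stage with a synthetic generator that
emulates the study design, and checks the published derived columns for
internal consistency instead of recomputing them from data.

## Gel sizing and allele binning

Fragment sizes are calibrated against a molecular ladder with the standard
log-linear model, log10(bp) = a·migration + b, fitted by least squares over
the rungs; r² is reported and a warning is emitted below 0.99 (typical
quality bar for a usable calibration). Sizing is exact on ladders that lie
exactly on a line and strictly monotone decreasing in migration.

Raw band sizes are binned into integer allele classes by sorted
single-linkage chaining: a gap strictly smaller than the tolerance
(default 2 bp, typical PAGE resolution) joins, and any chain whose running
span would exceed the tolerance is split greedily where the span first
overflows. Each class is labelled by its rounded mean, with labels forced
strictly increasing so adjacent narrow classes never collide. One band is
called a homozygote; two bands a heterozygote; two bands falling in the same
class collapse to a homozygote with a warning (faint double bands resolved
manually in the lab workflow this mirrors).

**Resolution limit.** This binning rule has an intrinsic error floor under
per-band Gaussian size noise. A class observed m times is mislabelled by
±1 bp with probability 2·Φ(−√m) (≈32% for singletons, 4.6% at m = 4)
because the label is the rounded mean of the noisy observations, and a class
whose sample range exceeds the tolerance is fragmented by the span cap
(at noise sd 0.5 bp the expected range already reaches 2.2 bp at m = 30).
In round-trip simulations at 0.5 bp noise the exact-recovery rate is
therefore 90–96% depending on batch size, with essentially all miscalls
within ±1 bp of the truth; noiseless tables are recovered exactly. Users
who need higher fidelity at that noise level should widen the tolerance or
bin against known allele ladders.

## Diversity statistics

Per population × locus cell: observed allele count No; effective allele
count Ne = 1/Σp²; observed heterozygosity Ho (fraction of typed individuals
with two distinct alleles; missing calls excluded from the denominator);
expected heterozygosity He = 1 − Σp², by default with Nei's small-sample
correction n/(n−1) since breeds as small as n = 40 are in scope (the biased
form is available); Botstein's polymorphic information content
PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j² with the conventional bands (>0.50 high,
0.25–0.50 moderate); and the inbreeding coefficient F = 1 − Ho/He, undefined
at monomorphic cells. Breed summaries are means ± SE over loci with the
SE convention sd(n−1)/√L. Breed-level F defaults to the across-loci mean of
per-locus 1 − Ho/He over polymorphic loci; a ratio-of-means alternative
(1 − mean Ho / mean He) is provided because the averaging rule behind
published tables of this kind is often unstated.

## F-statistics and gene flow

Per locus, Wright's indices come from Nei's gene-diversity decomposition:
HI = weighted mean observed heterozygosity across populations, HS = weighted
mean within-population gene diversity (biased form), HT = gene diversity of
the pooled (weighted mean) allele frequencies; then FIS = 1 − HI/HS,
FST = 1 − HS/HT, FIT = 1 − HI/HT. This construction satisfies Wright's
identity (1−FIS)(1−FST) = (1−FIT) exactly, which the published per-locus
rows of the survey obey within ±0.002 (rounding) — the reason this estimator
family was chosen over variance-components estimators, one of which
(Weir–Cockerham θ) is still available behind a flag for sensitivity.
Weighting is by per-locus typed sample size by default (breed sizes range
40–127); equal weighting is available. Degenerate cells are reported, not
silently dropped: HT = 0 leaves all indices undefined; HS = 0 with HT > 0
gives FST = 1 with FIS undefined.

Island-model gene flow is Nm = (1−FST)/(4·FST), suppressed (rendered "-")
below an FST floor of 0.005 where the transform is numerically meaningless;
the published table's dash at FST = 0.002 motivates that floor.

Note that with r sampled populations the pooled-frequency HT deflates the
realized differentiation by roughly 1 − Σw² relative to the generative
(ancestral-reference) FST — with the study's sample-size weights Σw² ≈ 0.17,
so simulations at a generative FST of 0.22 estimate ≈ 0.18. The parameter-
recovery band in the tests brackets this expected shrinkage.

## Ewens–Watterson neutrality test

The observed sample homozygosity F = Σp̂² is compared with its null under
the Ewens sampling formula conditioned on (n genes, k alleles) — the
classical homozygosity test of neutrality; conditioned on k the null is
free of θ and equals the cycle-type distribution of a uniform random
permutation of n elements with exactly k cycles:
P(λ|n,k) = [n!/Π_j j^{a_j} a_j!] / |s(n,k)|, with |s(n,k)| the unsigned
Stirling number of the first kind. The deviate is
D = (E_null[F] − F_obs)/sd_null[F], positive for allele-rich, evenly
distributed samples under the default sign convention (a flag flips it);
D is undefined for monomorphic cells, rendered "-".

Null moments are computed three ways, which the tests verify agree:

1. **Exact closed form** (default): E[Σλ²] and E[(Σλ²)²] from expected
   cycle counts — E[a_j] = C(n,j)(j−1)!|s(n−j,k−1)|/|s(n,k)| and the
   analogous ordered-pair formula with |s(n−j−l,k−2)| — evaluated in exact
   big-integer/rational arithmetic before the final float conversion. This
   is exact for any (n,k) and fast (≈0.1 s at n = 254), so the exact method
   never needs a stochastic fallback.
2. **Full partition enumeration**, budget-checked, which also yields the
   whole null distribution for small (n,k).
3. **Seeded Monte Carlo**: Chinese-restaurant-process proposals with θ
   solved from E[K|θ,n] = k, rejecting configurations with K ≠ k
   (reps ≥ 1000, seed mandatory).

Per-breed tables report D per locus with Mean and SE rows over the loci
where D is defined.

## Distances and dendrograms

Breed-level trees use Nei's standard genetic distance
D = −ln(Σpq/√(Σp²·Σq²)) on per-locus allele-frequency spectra, capped
(default 10) when no alleles are shared; individual-level trees use the
Dice band-sharing distance 1 − 2|A∩B|/(|A|+|B|). Clustering is UPGMA
(cluster-size-weighted average linkage) — chosen because published figures
of this kind are ultrametric dendrograms — with deterministic lexicographic
tie-breaking, serialized to Newick with branch lengths. Exact topologies of
the original survey's figures cannot be reproduced without the raw gels;
the trees here are the two defensible reconstructions from genotype data.

## Synthetic data generator

Population allele frequencies follow the Balding–Nichols model: per locus,
ancestral frequencies p from a flat Dirichlet over 2–10 alleles, breed
frequencies from Dirichlet(p·(1−FST)/FST) at FST = 0.22 (the survey's
between-breed differentiation), FIS = 0 genotype sampling with
P(hom i) = p_i² + FIS·p_i(1−p_i) and P(het ij) = 2p_ip_j(1−FIS), 2% missing
calls, and the survey's seven breed sizes. No mutation model is simulated
because no downstream statistic uses one. Allele identities map to bp sizes
on a 4-bp (tetranucleotide-style) grid: class spacing must exceed the
binning tolerance plus the band-noise spread for the gel stage to resolve
its own output, and 2-bp spacing would put adjacent classes inside the
2-bp tolerance at any realistic noise. Band tables are generated by
inverting the log-linear sizing model, with optional per-band Gaussian size
noise and an exactly on-curve 50-bp ladder.

What the generator does *not* emulate: null alleles and allelic dropout,
stutter bands, linkage between loci, departures from the
Dirichlet-equilibrium frequency model, and per-gel systematic sizing
offsets. Tests passing on synthetic data therefore validate the estimators
and their plumbing, not robustness to those artefacts.

## Problem sizes and determinism

The test suite and the reproduction script run the full seven-breed design
(526 individuals × 14 loci) for parameter recovery (10 seeds), and
gel-scale batches (2 × 30 individuals, 6 loci) for the sizing round trip;
Monte-Carlo checks use 20 000 replicates. All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; a fixed
configuration reproduces byte-identical outputs, and every output table
carries a commented provenance header with version, seed and thresholds.

## Known limitations

- The published survey's breed-level F values and four of its seven
  neutrality-mean columns are not arithmetically recoverable from its own
  printed per-locus values; the package documents its conventions and checks
  itself only against the internally consistent columns.
- Exact-bp genotype recovery through the gel stage is bounded away from
  100% under Gaussian band noise (see the resolution-limit analysis above).
- No rarefaction of allelic richness, null-allele detection, pairwise-FST
  matrices, AMOVA, or bootstrap support values.
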