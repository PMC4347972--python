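# Methods

## Data model and preprocessing

The unit of analysis is a fixed-width genomic bin (default 1000 bp).  Reads
are reduced to their leftmost aligned coordinate — strand is ignored by
default because broad marks have no meaningful strand asymmetry at 1 kb
resolution; a `strand_aware_5prime` option shifts reverse-strand reads to
their stored 3' coordinate for users who want 5'-end counting.  Reads with
mapping quality below 1 are skipped when MAPQ is available (uniquely mapping
reads); PCR-duplicate removal is assumed to have happened upstream, with an
optional `(chrom, start, strand)` de-duplication filter as a convenience.

Counts are capped at the sample's genome-wide empirical quantile at 0.999,
using the nearest-rank (type 1) definition so the cap is always an observed
integer.  The cap protects the emission densities from mapping artifacts
(collapsed repeats, blacklisted-region pile-ups) whose probabilities would
otherwise underflow.  Truncation is applied per sample, pooled across
chromosomes: per-chromosome quantiles would give each chromosome a
different cap and create artificial inter-chromosome differences.

## Univariate model

Bin counts follow a two-component mixture of zero-inflated negative
binomials; the ZINB is parameterised by dispersion `r > 0`, success
probability `p ∈ (0,1)` (NB mean `r(1−p)/p`) and inflation weight
`β ∈ [0,1)`, giving component mean `μ = (1−β)r(1−p)/p`.  Component 0 is
constrained to the lower mean after fitting.

**EM.**  Starting responsibilities come from a median split (≤ median →
0.9 responsibility for component 0; ties at the median go to the lower
group, which makes the start deterministic), followed by a standard M-step.
Two implementation points matter:

- *Three-way split at zero.*  A zero count can come from the inflation
  point mass or from the NB itself; the E-step therefore splits each
  component's zero responsibility by `β / (β + (1−β)·NB(0))`.  Without this
  inner split the β update is inconsistent and EM can decrease the
  likelihood.
- *M-step for (r, p).*  No closed form exists for the NB dispersion.  `p`
  is profiled out at its conditional MLE `r/(r + weighted mean)` and the
  1-D profile log-likelihood is maximised in `log r` over `[1e−3, 1e4]`
  (bounded Brent).  The E-step operates on unique count values with
  multiplicities, so cost is independent of genome size.

Defaults: `tol = 1e−6` relative log-likelihood change, `max_iter = 500`.
The fit uses a single training chromosome (the largest present unless
configured otherwise) — six parameters need only a fraction of a genome,
and this mirrors how the method is used in practice.

**Identifiability convention.**  The mixture likelihood depends on the two
inflation weights only through the total zero point mass
`π₀ = αβ₀ + (1−α)β₁`: moving point mass between the components' inflation
terms, with the compensating change of α, leaves the likelihood *exactly*
unchanged (verified numerically — different EM starts converge to identical
log-likelihood at different `(α, β₀, β₁)`).  Fitted mixtures are therefore
canonicalised to the ridge representative with `β₁ = 0`: all excess zeros
are attributed to the low-mean background component, where they belong
scientifically (zero inflation in a high-occupancy modified state has no
biological reading).  The NB shape parameters are ridge-invariant and
untouched.  Reported α and β values are only meaningful under this
convention.

**Degenerate inputs.**  All-identical counts (including all-zero tracks)
cannot support a two-component fit and raise an error rather than returning
an arbitrary mixture.

## HMM machinery

The 2-state (and 4-state) HMMs keep their emission densities fixed from the
mixture fit; Baum–Welch re-estimates only the transition matrix and the
initial distribution.  Implementation notes:

- Forward–backward uses per-position scaling plus a per-position max-shift
  of the log emissions, so even extremely unlikely observations (floored
  pmf values of 1e−300) stay in range.
- Chromosomes are independent sequences: the recursion restarts from the
  initial distribution at each chromosome start, expected transition counts
  are pooled into one shared matrix, and the log-likelihood is summed.
- The initial distribution starts uniform and is re-estimated from expected
  chromosome-start occupancies; with genome-scale sequences it has no
  practical influence, but re-estimating it keeps the EM interpretation
  exact.
- Transitions start diagonal-heavy (0.9 self-transition) reflecting the
  multi-kilobase persistence of broad domains; on all data tested the fixed
  point is unchanged, convergence is just faster.
- A state with zero expected occupancy keeps its previous transition row
  (with a warning) instead of producing a 0/0 row.
- Decoding is by posterior threshold (`λ = 0.5` by default on the modified
  state, equivalent to the maximal-probability rule for two states) or by
  argmax for the 4-state model.  Argmax ties break to the lower state
  index; the 4-state order (both-unmodified, both-modified, A-only, B-only)
  makes this conservative — a tie never becomes a differential call.
  Viterbi decoding is deliberately absent: region calls are defined by
  per-bin posteriors.

## Bivariate copula emissions

For modification pattern `(a, b)`, the counts `(x, y)` are transformed by
the probability integral transform `z = Φ⁻¹(F(x))` using the matching
marginals `θ_{A,a}, θ_{B,b}`, and the transformed pair is modelled as
bivariate normal.  The discrete joint pmf is the normal measure of the
rectangle between consecutive transformed CDF values, evaluated from the
bivariate normal CDF at the four corners (scipy's Genz-algorithm CDF, which
is exact to machine precision in two dimensions); differences are floored
at 0 before the log, and `F(−1) = 0` maps to an exactly −∞ bound (zero CDF
column/row) rather than a clipped finite score.

- *Correlation rescaling.*  PIT margins are standard normal by
  construction, so the estimated covariance is rescaled to its correlation
  before evaluation; the diagonal carries only estimation noise.  The
  general `(ρ, σx, σy)` covariance is retained in storage and in the
  parameter files.
- *Caching.*  Counts are small integers repeated genome-wide, so each
  component caches one dense rectangle-probability table keyed by the
  maximum counts seen; the 4-state genome-wide emission evaluation costs
  four table builds.
- *Covariance estimation.*  Σ_{a,b} is the sample covariance of the PIT
  scores over bins with univariate posterior > 0.9 for state `a` in A *and*
  state `b` in B.  Patterns with fewer than 50 supporting bins fall back to
  the identity covariance (warning logged); a near-singular estimate (as
  arises when a track is compared against itself, where the PIT scores are
  identical) is shrunk slightly toward a scaled identity so the component
  stays positive definite.
- At `ρ = 0` the CDF factorises analytically and the implementation uses
  the exact product form, making independence factorisation exact rather
  than approximate.

The mixing weights γ_{a,b} (high-confidence bin fractions) are recorded as
a diagnostic only — in the HMM the transition structure replaces them.

## Pipelines

`call_single`: mixture fit on the training chromosome → 2-state HMM →
Baum–Welch transitions → genome-wide forward–backward → threshold at λ →
maximal same-label runs become regions (never merged across chromosomes;
regions partition the binned genome).  `call_differential`: univariate runs
for both samples → copula component estimation → 4-state HMM → argmax
classification → regions; differential calls are the A-only / B-only
states.  No minimum region length is imposed by default (a `min_bins`
config filter exists); reported per-state megabases are exactly
`Σ(end−start)/1e6`.

## Synthetic data

The generators sample the model's own data-generating process: sticky
Markov chains (self-transition 0.95) started from the stationary
distribution, ZINB counts per state, and — bivariately — a bivariate normal
draw with the state's ρ pushed through `Φ` and the ZINB quantile function,
which guarantees the marginals exactly.  The default world (2 chromosomes ×
5000 bins, background mean ≈ 2.7 with 10% zero inflation, modified mean 25,
ρ = 0.5 in concordant states, 0 in discordant ones) reflects a realistic
low-coverage broad-mark experiment where domains are well separated from
background; a full differential run finishes in seconds.

What the generators do **not** emulate: mappability and GC bias, copy-number
variation, fragment-length autocorrelation between neighbouring bins beyond
the Markov state structure, unequal library sizes, and replicate structure.
A green end-to-end test therefore establishes correctness of the inference
machinery under the model's assumptions, not robustness to real-data
artifacts.

## Numerical choices

- pmf values are floored at 1e−300 before logs; rectangle probabilities at
  the same floor after the signed corner sum.
- PIT CDF values are clipped to `[1e−12, 1 − 1e−12]` so transformed scores
  stay finite (|z| ≲ 7); interior rectangle bounds use the same clip, while
  the `x = −1` bound stays exactly −∞.
- EM and Baum–Welch stop on relative log-likelihood change (`1e−6`) or the
  iteration cap (500 / 100).  For parameter-recovery studies EM should be
  run much tighter (`1e−12`): near the zero-mass ridge the default
  tolerance stops while parameters are still drifting along directions the
  likelihood barely constrains.
- The ZINB quantile function inverts the inflation-adjusted NB CDF through
  `nbinom.ppf`, which is exact for the discrete inverse.

## Limitations

- Exactly two components per sample and two samples per comparison; no
  input/IgG normalisation (the model absorbs background into θ₀).
- The copula correlation is estimated from high-confidence subsets, which
  slightly underestimates |ρ| when posteriors are noisy.
- α, β₀, β₁ are reported under the zero-mass canonicalisation described
  above and are not comparable to fits using a different convention.
- Replicates are handled by summing counts before analysis.
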