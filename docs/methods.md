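# Methods

## The continuous optimizer

The slime mould algorithm (SMA) maintains `N` agents with positions
`X_i ∈ [LB, UB]^D` on a minimization objective. Each iteration `t = 1..T`:

1. **Weights.** Agents are sorted by fitness (ascending). With `bF`/`wF` the
   current best/worst fitness, each agent's weight element is
   `W = 1 ± r·log10((bF − S_i)/(bF − wF) + 1)` with a fresh uniform
   `r ∈ [0,1)` per element — `+` for the better half of the ranking, `−` for
   the worse half. The log argument's ratio is defined as 0 when
   `bF = wF`, so a fitness-degenerate population gets all-ones weights;
   every weight lies in `[1 − log10 2, 1 + log10 2]`.
2. **Schedules.** `a = arctanh(1 − t/T)` and `b = 1 − t/T`. The iteration
   counter starts at 1 so `a` is finite; at `t = T` both vanish and the
   update degenerates (the attraction branch returns the incumbent, the
   contraction branch the origin).
3. **Position update.** Per agent: with probability `z` (default 0.03) the
   whole vector is re-seeded uniformly in the box. Otherwise, with
   `p = tanh|S_i − DF|` (`DF` the best fitness ever seen), a uniform draw
   `r < p` selects the attraction move
   `X ← X_b + vb ∘ (W_i ∘ X_A − X_B)` (random agents `A`, `B`,
   `vb ~ U[−a, a]^D`), else the contraction move `X ← vc ∘ X` with
   `vc ~ U[−b, b]^D`. Positions are clamped to the box (reflection
   available) and re-evaluated; the incumbent `(X_b, DF)` is elite and
   updated after the sweep.

The hybrid (ISMA) adds two greedy refinements of the incumbent per
iteration, each costing one evaluation and accepted only on strict
improvement:

- **Cauchy mutation** `x' = X_b ∘ (1 + c)`, `c_d` i.i.d. Cauchy(0, `t0`)
  drawn by inverse-CDF `t0·tan(π(u − ½))`. The heavy tail gives occasional
  basin-escaping jumps while the multiplicative form preserves sign
  structure (the zero vector is a fixed point).
- **DE crossover/mutation**: a mutant `x_a + F·(x_b − x_c)` from three
  distinct random agents (excluding the current best agent's index) is
  binomially crossed with `X_b` (`rand ≤ Pc` or the forced coordinate
  `j0`), guaranteeing at least one mutant component.

Ablations `SMA`, `CSMA` (Cauchy only), `MCSMA` (crossover only) run the
identical code path with refinements gated off, so the plain-SMA trajectory
is bit-for-bit reproducible from the hybrid loop under the same seed.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `z` | 0.03 | uniform re-seeding probability |
| `N` | 20 | population size (≥ 4; the DE step needs 3 partners) |
| `T` | 50 | iterations; a function-evaluation budget `B` maps to `T = ⌊B/(N+2)⌋`, charging the two refinement evaluations uniformly across variants |
| `t0` | 1 | Cauchy scale (standard Cauchy) |
| `F` | fresh `U[0,1)` per mutation | DE scale; a fixed float pins it |
| `Pc` | 0.5 | crossover rate |

The per-iteration randomness order (weights block, then per-agent draws,
then refinement draws) is part of the documented contract; a pinned stream
makes one iteration hand-traceable, and the test suite checks a literal
transcription of the update equations against the implementation to
12 decimals.

Design choices where the formulation was open: the branch-decision
probability uses a single `tanh` (the canonical form); the attraction move
weights only the first random agent (`W∘X_A − X_B`), with the
`W∘(X_A − X_B)` reading available as a switch for sensitivity checks;
`rand`, `r`, `A`, `B` are drawn once per agent while `vb`, `vc` are
per-dimension vectors; refinements act on the best individual only (a
population-wide variant of the prose description is intentionally not
implemented); out-of-bounds proposals clamp to the nearest bound.

## Benchmarks

The classical 23-function suite (7 unimodal, 6 multimodal, 10
fixed-dimension multimodal) with conventional boxes and `D = 30` for the
scalable functions. Fixed-dimension optimum locations were refined
numerically to machine precision and frozen, so every registry entry's
`f*` is self-consistent to 1e-12. The noisy quartic draws its additive
uniform noise from an explicitly passed generator; its registered optimum
refers to the deterministic part.

## Binarization

Subset problems keep a continuous "shadow" position per agent in a fixed
box ([0, 1] by default; the choice is empirically indifferent — see below)
updated by the full hybrid machinery, plus a bit vector scored by the
user's subset fitness. Bits derive from shadows through one of eight
standard transfer functions: S-shaped sigmoids (`S1..S4`, the bit is
redrawn as Bernoulli(S(x)) each update) and V-shaped folded sigmoids
(`V1..V4`, the current bit is complemented with probability V(x); V(0)=0,
so a shadow at the origin freezes its bits). `V4 = |(2/π)·arctan((π/2)x)|`
is the default. Initial bits are drawn by a 0.5 threshold. No evaluated
bit vector is ever all-zero: the default repair sets one uniformly chosen
bit (assigning worst fitness instead is available). The Cauchy/DE
refinements mutate the best shadow, re-derive its bits and accept
greedily.

## Wrapper gene selection

A gene subset is scored by `fit = α·err + β·DR/D` with `α = 0.95`,
`β = 0.05`, where `err` is the leave-one-out error of a 1-nearest-neighbour
classifier restricted to the selected genes (Euclidean distance; ties to
the smallest sample index, making every fitness bitwise reproducible; the
non-metric "literal" distance variant exists only for audit). Evaluations
are memoized by packed mask. No feature scaling is applied by default;
per-gene z-scoring is available. Standard run protocol: 20 agents,
50 iterations, 10 independent repeats with consecutive seeds.

## Synthetic data

The generator emulates the microarray regime (samples in the tens, genes
in the hundreds-to-thousands, a small planted informative set): i.i.d.
Gaussian noise genes (Student-t optionally, rescaled to the target SD);
informative genes shifted by `c·δ` noise-SDs in class `c`; optional
correlated redundant copies; round-robin balanced labels; fully
deterministic by seed. It does not model probe effects, batch effects or
gene-gene correlation beyond the redundancy construction, so passing tests
demonstrate algorithmic correctness, not robustness to platform artifacts.
Datasets round-trip losslessly through CSV (`%.17g` formatting, correctly
rounded parsing).

## Behavior on planted data, and a structural caveat

Because the wrapper fitness lives in [0, 1], fitness differences between
agents are of order 0.01, so `p = tanh|S_i − DF| ≈ 0.01` and the attraction
branch essentially never fires in the binary setting: shadows contract to
the origin, where V-family bits freeze near their initialized ~50% density
and S-family bits keep resampling at density ½. The only force shrinking
the subset is the pair of greedy best-only refinements (~2 evaluations per
iteration), which removes genes at roughly one per accepted trial. Under
the standard 50-iteration protocol on a 40 × 500 planted dataset the
method therefore reaches mean LOOCV error 0 but retains roughly 40% of the
genes; longer budgets shrink the subset monotonically (≈32% at 400
iterations) without ever losing the zero error. This is a property of the
update equations themselves, not of the implementation — the hand-trace
and oracle tests pin the mechanics independently.

Relatedly, at large class shift (δ = 6) *any* half-density mask classifies
perfectly, so the fitness surface carries no gradient toward the planted
genes and subset membership is uninformative about them. Wrapper selection
pressure is identifiable in a weak-signal regime instead (e.g. n = 60,
D = 100, 10 informative genes at δ = 2, 100 iterations), where selected
subsets are strongly enriched for planted genes (pooled hypergeometric
p ≈ 1e-8) and the best run recovers most of the planted set; the
enrichment tests run in that regime.

## Statistics

Multi-seed comparisons use the two-sided Wilcoxon signed-rank test at
α = 0.05 (zero differences dropped; exact distribution by full sign
enumeration for n ≤ 12 — valid under ties, which the tie-free closed form
is not — scipy's exact method for tie-free n ≤ 25, tie-corrected normal
approximation otherwise), Friedman mean ranks (average ranks on ties;
lower score = better), and "+/=/−" superiority counts with direction taken
from the median paired difference. Every grid cell's seed derives
deterministically from the base seed and cell coordinates.

## Problem sizes used in the test and acceptance runs

Convergence checks use 30-D sphere/Rastrigin at a 10,000-evaluation budget
over 10 seeds; the binary oracle check enumerates all 255 nonempty 8-bit
subsets; planted-data runs use 40 × 500 (protocol check) and 60 × 100
(enrichment) matrices. These sizes were chosen to exercise every code path
at full statistical strength while keeping a complete run of the suite in
well under half an hour on one core.
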