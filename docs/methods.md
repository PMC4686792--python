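# Methods

## Model

A chromosome is a permutation `π` of `1..n`, signed (elements carry strand
signs) or unsigned. Although bacterial chromosomes are circular, the origin
of replication fixes a reference point: `π_1` is the first gene after it,
indices are linear `1..n`, and no rotation or reflection normalisation is
performed. An inversion `ρ(i, j)`, `1 ≤ i ≤ j ≤ n`, reverses the segment
`i..j` and flips its signs in the signed case; for unsigned permutations
`i < j` is required, since an unsigned unitary inversion is the identity
operation and is rejected rather than silently ignored.

With `slice(k) = min(k, n − k + 1)` — positions paired by their distance to
the nearer end, range `1..⌈n/2⌉` — the cost of `ρ(i, j)` is
`|slice(i) − slice(j)| + 1`. Endpoints on the same side of the middle give
`|i − j| + 1` (length-weighted); endpoints straddling the middle pay for
asymmetry, down to cost 1 for perfectly symmetric inversions
(`j = n − i + 1`). Sorting means reaching the identity at minimum total
cost. Note the codomain of `slice` is stated as `⌈n/2⌉`: for odd `n` the
middle position has slice `(n+1)/2`.

Two progress metrics drive the greedy sorters:

- `NB(π)`: breakpoints of the extended permutation (`π_0 = 0`,
  `π_{n+1} = n + 1`; both sentinels positive). A signed adjacency is a
  breakpoint when `π_{i+1} − π_i ≠ 1`, an unsigned one when
  `|π_{i+1} − π_i| ≠ 1`. Only the identity has `NB = 0`, and one inversion
  changes `NB` by at most 2 (only the two boundary adjacencies change —
  exploited for an O(1) delta, cross-checked in tests against a full
  recount).
- `SMP(π)`: slice-misplaced pairs — unordered element pairs whose slice
  order in `π` strictly contradicts their slice order in the identity.
  Signs are irrelevant (slices are sign-blind), and `SMP` is invariant
  under perfectly symmetric inversions, which map every position to its
  mirror and hence change no slice.

The *benefit* of an inversion under metric `f` is
`(f(π) − f(π·ρ)) / cost(ρ)`, compared in exact rational arithmetic
(`fractions.Fraction`) so that tie behaviour is platform-independent.
Tie-breaking everywhere: highest benefit, then lowest cost, then smallest
`i`, then smallest `j`. All sorters are therefore deterministic: same input,
same scenario, byte for byte.

## The sorters

**LR (Left or Right).** Slice `s` is *sorted* when magnitude `s` sits at
position `s` and magnitude `n − s + 1` at position `n − s + 1` (signed:
both positive) and all smaller slices are sorted. Each step takes the
smallest unsorted slice and considers its two candidates: the element of
magnitude `s` destined for position `s` ("left") and the element of
magnitude `n − s + 1` destined for position `n − s + 1` ("right").
Placement cost is the single inversion between the candidate's current and
final positions, plus 1 if (signed) the placement leaves it negative and a
unitary fix will be needed. The cheaper candidate moves; ties move the
right one. If only one candidate is out of place it is placed directly;
if both are in place but a sign is negative, a unitary inversion fixes it.
The description of which side is "left" versus "right" is ambiguous in
places; the convention above (candidates identified by target magnitude,
single-inversion placement) is self-consistent and makes the tie rule well
defined. Because both candidates live inside the unsorted window
`[s, n − s + 1]` and placements pin them to its edges, sorted slices are
never disturbed; each slice needs at most four steps, so termination is
structural.

**SMP.** Greedy on `SMP` while some inversion has positive benefit. Two
fallbacks cover the rest:

- *Symmetric endgame* (`SMP = 0` but `π ≠ ι`): every element then sits in
  its identity slice, i.e. at its final position or that position's mirror.
  Scanning `i = 1..⌊n/2⌋` and applying the mirror reversal
  `ρ(i, n − i + 1)` whenever `|π_i| = n − i + 1` sorts all magnitudes in at
  most `⌊n/2⌋` cost-1 steps (each mirror reversal fixes its own pair for
  good and merely toggles inner pairs, which later scan steps fix); signed
  permutations finish with cost-1 unitary sign fixes.
- *Two-inversion detour* (`SMP > 0` but no single improving inversion):
  such permutations have slices non-decreasing to the middle and
  non-increasing after it, so some adjacent positions hold two elements
  sharing a below-maximum identity slice. Mirroring the member with the
  larger position slice via a perfectly symmetric inversion (cost 1,
  `SMP`-neutral) re-pairs the slices so that an `SMP`-decreasing inversion
  exists; the detour applies that pair of inversions. Candidate pairs are
  tried from the largest position slice down (smallest start position on
  ties), and — as a robustness net that exhaustive runs never needed — all
  remaining perfectly symmetric inversions are tried afterwards.

Along any `smp_sort` scenario the `SMP` count is non-increasing step by
step (greedy steps decrease it, detour first-halves and endgame steps leave
it fixed), which the tests assert exhaustively at small `n`.

**NB.** Greedy on `NB` while some inversion has positive benefit —
guaranteed whenever a decreasing strip exists (strips are the maximal
breakpoint-free intervals; singletons count as decreasing). When every
strip is increasing, a contingency move creates decreasing strips:

1. `lr` — one LR placement step;
2. `strip-lr` — the whole-strip variant: push the strip holding the right
   candidate to the right edge of the unsorted window or the strip holding
   the left candidate to the left edge, whichever is cheaper (right on
   ties);
3. `revert` — one inversion reversing the entire unsorted window (a
   perfectly symmetric, cost-1 move);
4. `best-strip` (default, used in all evaluations) — among inversions whose
   endpoints coincide with strip boundaries, reversing one or more whole
   strips and splitting none, apply the cheapest (smallest `(i, j)` on
   ties).

A best-strip contingency step changes no breakpoint (`Δ_NB = 0`: both
affected adjacencies are already breakpoints) and, for unsigned
permutations, creates a decreasing strip so the next step is greedy again;
`NB` is non-increasing along the whole scenario. For signed permutations
the decreasing-strip guarantee has no published counterpart, so contingency
moves carry a deterministic anti-cycling guard: a move that would revisit
an earlier state is skipped for the next candidate, and if none remains the
permutation is finished with LR placements. Exhaustive runs (unsigned
`n ≤ 7`, signed `n ≤ 5`) never triggered the LR completion for
`best-strip`; it exists so that termination is unconditional for every
strategy.

**NB+SMP.** The combined metric change is
`Δ_NB + Δ_SMP / (C(n,2) + 1)`. The divisor makes `|Δ_SMP| / (C(n,2)+1) < 1`
always, so the breakpoint term strictly dominates and the pair term only
refines ties — the intended priority of the combination. (A divisor as
small as `⌈n/2⌉` would let the pair term override breakpoints, which
contradicts that priority; hence the conservative normaliser.) Comparisons
are exact rationals. When no inversion has positive benefit the best-strip
contingency applies, with the same guard. Signed permutations are driven by
their unsigned copy: each inversion chosen for the unsigned copy is applied
to the signed permutation too (costs depend only on endpoints, so the two
scenarios cost the same), and remaining negatives are flipped by unitary
inversions at the end.

**All.** Runs LR, SMP, NB (best-strip) and NB+SMP and keeps the cheapest
scenario; ties resolve in that fixed order.

## Exact solver

Vertices are all `n!` (unsigned) or `2^n·n!` (signed) permutations, edges
are single inversions weighted by cost; inversions are involutions, so the
graph is undirected and one Dijkstra run from the identity yields every
optimal sorting cost plus predecessor links for scenario recovery. A binary
heap suffices at the solvable sizes (edge weights are small integers, so a
Dial-style bucket queue would also do; correctness, not queue choice, is
what the tests pin — against an independent fixpoint-relaxation oracle over
the whole state space). States are ranked densely: factorial-number-system
rank of the magnitude order, times a `2^n` sign-mask factor when signed —
O(n) per conversion, mutually inverse (verified exhaustively). Edges are
enumerated in increasing `(i, j)` order with first-improvement predecessor
updates, so recovered scenarios are deterministic; which optimal scenario
is reported is otherwise arbitrary, and only costs feed the evaluations.

Default refusal bounds — unsigned `n ≤ 9`, signed `n ≤ 7` — keep the state
space within desk memory and patience (3.6 M and 10.3 M states at the next
sizes up); both are explicit parameters for callers with bigger machines.

## Evaluation harness and synthetic data

Exhaustive mode enumerates every permutation of each size in state-space
rank order, asserts the count against the closed form, and reports per
size and method: fraction sorted optimally, mean and maximum ratio
(heuristic/optimal; identity rows, where both costs are 0, count as ratio
1), and best-answer frequency among the methods run, with ties credited to
every tying method (so the fractions can sum past 1). Random mode draws
uniform permutations — `numpy` Generator shuffle, i.i.d. fair-coin signs —
and reports mean cost instead of ratios, the optimum being out of reach.
All summaries are recomputable from the emitted per-instance records, and
processing order does not affect them.

Default evaluation sizes are exhaustive unsigned `n ∈ 2..7` and signed
`n ∈ 2..5`, and random sizes a few tens with ~100 replicates: large enough
that the method ranking (NB+SMP ≤ NB ≤ SMP on mean ratio, All best overall,
LR ahead of SMP on worst-case ratio) is stable across sizes, small enough
to run in minutes in pure Python. Larger sizes and replicate counts are
plain configuration.

Uniform random permutations model maximal scrambling, not real gene
orders: real pairs of genomes differ by bounded, length- and
symmetry-biased scenarios, carry duplications and content differences this
model excludes, and are far from uniform. Passing tests therefore certify
the algorithms and the cost model's combinatorics, not biological fidelity
of any inferred scenario.

## Degenerate inputs and edge cases

`n = 1`: the unsigned space is a single sorted state with no legal
inversions; the signed space is `{(+1), (−1)}` with the unitary inversion.
Unsigned unitary inversions raise; invalid endpoint pairs raise; the
scenario validator re-derives every step cost and replays the scenario
before any scenario is written out. Permutation text files infer
signedness per line (any explicit sign marks the line signed) and refuse
mixed files, since the two variants have different legal inversion sets.

## Known limitations

- No approximation guarantees: all four sorters are heuristics; their
  quality is measured empirically against the exact solver at small sizes.
- The exact solver is exponential by nature; it is an oracle for
  benchmarking, not a tool for realistic genome sizes.
- SMP and NB+SMP recompute the pair count per candidate inversion
  (O(n²) each, O(n⁴) per step), fine at evaluation sizes but the binding
  cost for permutations with hundreds of elements.
- Single chromosome, equal gene content, inversions only; no duplications,
  transpositions, translocations, or rotation canonicalisation.
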