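# Methods

## Model

The simulator plays seasons of pairwise agonistic contests between *n*
competitors, each holding an integer token stock that encodes its
resource holding power (RHP). A contest is a two-token urn draw: writing
*q* for the focal competitor's share of the combined effective RHP, the
outcome probabilities are *q²* (win), *(1−q)²* (loss) and *2q(1−q)*
(draw). The two tokens are drawn independently — with-replacement
semantics — which is what makes the equal-RHP odds exactly ¼/¼/½; a
without-replacement urn of finite token counts cannot produce those
odds. A decisive contest moves exactly one token from loser to winner;
draws move nothing; a competitor reaching zero tokens becomes inactive
and is skipped by all future pairings (it remains a node of the network,
with whatever edges it last held). Token accounting is identical in all
variants, so the total token count is invariant over a game.

The four variants differ only in the *effective* RHP entering the urn:

| variant      | effective RHP                                    |
|--------------|--------------------------------------------------|
| null         | starting stock *T₀*, always                      |
| memory5      | max(1, *T₀* + net of last `memory_length` marks) |
| winner_loser | current token count                              |
| keystone     | current token count; competitor 0 starts with *T₀* + bonus |

Memory marks are +1/−1/0 for win/loss/draw; a draw consumes a memory
slot (the memory records *contests*, not wins). The floor at 1 keeps the
urn well-defined for small *T₀* configurations; at the defaults it never
binds.

## Scheduling

All-pairs mode contests every unordered pair exactly once per season, in
a fresh uniform shuffle each season (order matters for memory variants,
so it is randomized and seed-controlled). Spatial mode places the
competitors on a rows × cols lattice with unit spacing and one-time
per-coordinate jitter uniform on ±ε/2 (default ε = 0.1, so adjacent
spacing is 1.0 ± 0.1); each season every pair is included independently
with probability given by the Gompertz kernel

    p(x) = 1 − exp(−b · exp(−c · x))

of its Euclidean distance *x*. *b* (default 15) translates the kernel:
the half-probability distance is ln(b/ln 2)/c ≈ 3.07 standard distances
at b = 15, c = 1. *c* (default 1.0) sets the steepness. There is no cap
on contests per node; inclusion is a plain Bernoulli draw. The per-node
sum of kernel probabilities ("expected neighbours") quantifies each
competitor's pool of potential opponents: ≈ 31 on a 20×20 lattice at
c = 1.0, ≈ 14 at c = 1.5, lower at corners and edges (boundary effect).

## Dominance graph and metrics

The directed dominance relation keeps, per pair, only the most recent
outcome: a decisive contest (re)orients the winner→loser edge, a draw
clears it. This "last contest wins" reading keeps the null variant's
per-pair edge probability at exactly ½ and is the only reading
consistent with the observed path-length behaviour — accumulating any
historical decisive outcome drives edge density to 1 and all geodesics
to 1.

Average shortest path is computed on the undirected view, over connected
pairs only (disconnected pairs are excluded from the mean, the common
convention). Global reaching centrality uses the directed view: with
C_R(i) the fraction of nodes reachable from *i*, the index is
Σ(C_Rmax − C_R(i))/(N−1) — 1 for a perfect out-star, 0 for a cycle or an
empty relation. Both are delegated to networkx.

The triad census classifies every node triple into double-dominant (dd),
double-subordinate (ds), pass-along (pa), transitive (tr) or cyclic (cy);
triples with fewer than two edges are tallied as uncounted so the six
classes always sum to C(n,3). The implementation is closed-form — cycle
and transitive counts from adjacency-matrix traces, the two-edge motifs
from out/in-degree pair counts with triangle corrections — which is exact
and fast enough for 400-node graphs (10.6 M triples). Tests verify it
against brute-force triple enumeration and networkx's 16-class triadic
census. Variant contrasts use a two-sided Wilcoxon–Mann–Whitney test on
replicate motif counts (exact null when tie-free), reported unadjusted
with Holm-adjusted values alongside; the headline claims use the
unadjusted values at α = 0.05.

## Parameters and defaults

- *T₀* = 10 starting tokens. Not dictated by the model; chosen so that
  the wealth categories of the token histogram (0–1, 2, 3–9, 10–20, >20)
  put the starting stock in the middle band, and configurable.
- keystone bonus = 10 (keystone starts at 2·T₀), competitor 0 by
  convention; configurable.
- memory_length = 5 for the bounded-memory variant.
- Scenario presets: `small12_allpairs` (n = 12, 66 contests/season),
  `grid4x4_spatial` (n = 16, b = 15, c = 1.0), `grid20x20_spatial_c10`
  and `grid20x20_spatial_c15` (n = 400). All default to 30 seasons.
- Reference analyses use 10 replicates; replicate seeds are consecutive
  32-bit words of the NumPy seed-sequence stream keyed by the master
  seed (shifted below 2³¹), so one integer reproduces an entire summary
  bit-exactly.

## Numerical and design notes

- Determinism: a single `numpy.random.Generator` seeded by the config
  drives landscape jitter, schedules and contest draws, in a fixed
  order; identical seeds give byte-identical histories.
- The Gompertz kernel saturates in floating point (p = 1 within 1e−16
  below roughly x = ln(b/36)/c); strict monotonicity is only asserted
  away from saturation.
- Contest histories record only contests actually played; skipped
  pairings of eliminated competitors leave no record.
- The token histogram's default bins mirror the wealth categories used
  for network colouring, with the gap value 2 given an explicit bin so
  the bins partition the non-negative integers.

## What the simulations do and do not show

The generator *is* the study system: all reference numbers are
properties of the game itself, so the tests characterize the model, not
any empirical dataset. Real dominance data differ in ways the model
deliberately ignores: observation is partial (not every dyad is seen),
group membership changes, contests are not scheduled independently of
state, and RHP has biological components beyond contest history. The
standalone census mode can be applied to empirical edge lists, but the
simulated reference patterns should be compared qualitatively, not
numerically.

Known behaviours worth noting:

- Under the null variant the mean path is not perfectly stationary:
  eliminated competitors freeze with a decisive last contest (a loss),
  which biases edge density slightly above ½ and drifts the 10-replicate
  mean path from ≈ 1.55 (season 1) to ≈ 1.47 (season 30) — a small but
  statistically detectable trend. The package therefore reports the
  season-invariant path length as the replicate mean over the evaluated
  seasons {1, 5, 10, 30}.
- The memory5 variant's centralization (dd, tr counts) sits between null
  and winner_loser *in expectation*, but the gap is a few triads against
  a replicate SD near ten, so the ordering is only reliably resolved
  with ~100 replicates; at 10 replicates it can invert by chance.
- At 30 seasons the winner-loser variant typically concentrates nearly
  all tokens in 2–4 competitors; most nodes are inactive and the
  dominance structure is effectively frozen apart from contests among
  the survivors.

## Problem sizes

The test suite and the acceptance script run the published scenario
sizes throughout — 10 (occasionally 100, where statistical power demands
it) replicates of 12-competitor games over 30 seasons, single 400-node
spatial games, and 20×20 landscape constructions averaged over 5 jitter
realizations. The full suite completes in well under a minute on one
core.
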