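# Methods

## Model

A user's day is an ordered list of activity types drawn from a closed set of
seven (Residence, Community, Entertainment, Food, Outdoors, Shopping,
Travel). Consecutive repeats are merged, so a day of length L defines L−1
typed transitions in temporal order. A *typed temporal pattern* is a
temporally ordered list of 1–4 transitions over at most 4 distinct types;
node identity is the type itself, so pattern equality is plain edge-list
equality and no subgraph isomorphism search is ever needed.

A day *contains* a pattern when the pattern's edge list is an
order-preserving subsequence of the day's transition list. This single rule
implements both relaxations the model needs: temporally discontinuous edges
(skip intermediate activities) and topologically discontinuous edges (two
detached processes co-occurring in one day). Occurrence is per-day
containment — a day contributes at most 1 to each pattern — so a pattern's
count is the number of distinct daily sequences containing it. Durations
and spatial information are deliberately out of the pattern definition; the
only temporal constraint is the day boundary itself.

### Shape classes

Relabeling a pattern's types by first appearance yields a canonical label
word that indexes the topology catalog:

- **Sequential** shapes are temporal walks: 1 one-edge (Line), 2 two-edge
  (Ring = ABA, Chain = ABC), 5 three-edge (Triple_line, Star_pre, Triad,
  Star_pos, Triple_chain), 14 four-edge with ≤ 4 labels (Four_times_line
  plus 13 systematically named walks) — 19 high-order shapes in all,
  generated by exhaustive enumeration of adjacent-distinct canonical words.
- **Non-sequential** shapes are not walks but are weakly connected; they
  decompose into two or more maximal walks ("processes") sharing at least
  one type. All four connected two-edge shapes exist and are cataloged
  (Ring_n repeated transition; Chain_n1 shared source; Chain_n2 shared
  target; Chain_n3 later target = earlier source). Five three-edge shapes
  are cataloged: Triple_line_n1/n2 (the only two canonical orderings of the
  two-type, three-edge multiset that split into two walks), Star_pos_n1/n2
  (a branch edge entering/leaving the shared type, followed by a two-type
  cycle — branch first, cycle after, the Star_pos temporal arrangement), and
  Triad_n (the directed triangle; its three non-cyclic orderings all
  canonicalize to one shape of three single-edge processes). A directed
  triangle cannot split into exactly two maximal walks, which is why Triad_n
  is the one shape with three processes. The non-sequential catalog lives in
  `data/topology_catalog.yaml` so a corrected transcription of the shape
  schematics needs no code change.

Patterns whose processes share no type (e.g. R→C with F→E) are contained by
days and recognized by `contains`, but are excluded from the motif candidate
space; three-edge non-walk patterns outside the five cataloged shapes are
likewise not candidates. Reflexive self-loops (persisting in one type) are
out of scope.

## Preprocessing choices

Filter order is: POI support filter (≥ 10 check-ins, counted once on the
raw input, no re-iteration), then the interval filter (per user, greedy
keep-first: a check-in survives iff it is ≥ 10 min after the last *kept*
check-in of that user), then type assignment, 5 AM segmentation, and run
merging. Timestamps are local wall-clock; no timezone conversion (the day
boundary is a wall-clock rule and the intended data is single-metro). The
day window is half-open [05:00, 05:00 + 24 h). A merged run is stamped with
its first check-in's time, so transition times reflect the earliest
evidence of the type change. Ties within a minute keep input order (stable
sort). Duplicate rows are kept — deduplication is a data-quality decision
left to the caller. Days with fewer than two merged items are excluded;
sequences are never split by long within-day gaps.

## Counting

The brute-force path enumerates all index combinations of 1–4 transitions
per day and keeps the admissible distinct patterns; it is the semantics
anchor and test oracle. The production path sweeps each day once,
maintaining the set of distinct prefix patterns seen so far (each new
transition extends every shorter prefix and opens a new one, with pruning at
4 edges / 4 distinct types). Because containment needs only a boolean per
(day, pattern), sets of prefixes are exactly the reachability flags needed,
and the cost is O(L × prefix states) per day rather than O(C(L−1, 4)).
Equality of the two paths is asserted exactly on randomized corpora in the
test suite.

## Selection and metrics

Thresholds are ⌊f · N⌋ clamped to ≥ 1, with (f_high, f_low) = (0.1%, 0.5%)
by default and sensitivity settings (0.08%, 0.4%) and (0.12%, 0.6%)
available through configuration. "Reaching the threshold" is implemented as
count ≥ threshold; with floor rounding this reproduces the published
threshold semantics (80/400 at N = 80,118). Low-order sequential patterns
(≤ 2 edges) face the larger f_low threshold; sequential patterns with ≥ 3
edges and all non-sequential patterns face f_high, because only the minority
of long days can realize them.

MCR uses the group's minimum edge count k for its denominator: N_a = days
with ≥ k transitions, N_c = days containing ≥ 1 group motif (deduplicated).
A zero denominator yields an explicitly undefined result, not an error. COR
selectors by node position use the catalog's display labels (A is the
central node of Star_pre, Star_pos and Triad), aligned positionally to a
concrete pattern's edges. COR over a partition of a scope sums to 1 exactly
up to float addition (tested at 1e-12).

## Synthetic corpus

The generator is a first-order Markov chain per user-day — the simplest
model that exercises every pipeline stage and both threshold classes.
Defaults (chosen once as the package's study conditions):

| parameter | default | why |
|---|---|---|
| type marginals (R,C,E,F,O,S,T) | .10,.20,.15,.20,.15,.08,.12 | check-in-like: Community/Food heavy, Residence/Shopping light |
| kernel | 0.15 self + marginal-proportional off-diagonal | self-transitions create mergeable runs; destination pull follows popularity |
| active-day probability | 0.65 | most user-days silent, as in sparse check-in data |
| daily check-in count | geometric(0.45), support ≥ 1 | heavy-tailed: most days 1–2 check-ins, ≈ 17 % have ≥ 4 |
| sparse POI fraction | 0.04 | produces sub-threshold POIs so the support filter has work |
| timestamps | distinct uniform minutes in the 5 AM-anchored day | occasional < 10 min gaps exercise the interval filter |

Planted patterns multiply the kernel entries of their edges by a boost
factor (rows renormalized); a 20× boost on F→S and S→F pushes the
Food–Shopping ring far above the low-order threshold while the unboosted
ring stays well below it, which is how threshold selection is validated
end-to-end. One seeded `numpy` generator drives every draw, so equal seeds
give byte-identical corpora.

What the simulator does **not** emulate: spatial structure beyond uniform
metro-box coordinates, weekday/weekend or diurnal non-uniformity, social
network effects, user heterogeneity in kernels (all users share one chain),
and category noise. Passing tests therefore demonstrate the pipeline's
correctness and the selection mechanics, not that real check-in corpora
have any particular motif content.

## Problem sizes

Tests and the acceptance script run on simulated corpora of 100–300 users
over 8–30 days (hundreds to a few thousand daily sequences), sizes at which
the brute-force oracle remains exactly computable alongside the sweep path.
The full published-scale corpus (80,118 sequences) enters only through
threshold arithmetic, which is scale-exact by construction.

## Known limitations

- The packaged category→type map is a documented approximation; published
  analyses refined a proprietary multi-level taxonomy by hand, so per-deposit
  maps should be supplied.
- The three-edge non-sequential shape transcriptions are structural
  derivations (see the catalog notes above); alternates can be dropped into
  the YAML catalog.
- Occurrence is containment (0/1 per day); embedding multiplicity within a
  day is not counted.
- The interval filter's keep-first convention and the filter order are one
  of several defensible readings of the cleaning procedure; totals on real
  data are mildly sensitive to them.
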