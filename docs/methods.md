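# Methods

## Scope and model

`g4switch` treats the folding of a G/C-rich DNA sequence as a competition
between two intramolecular structures: a three-quartet parallel
G-quadruplex built from four G-tracts, and a Watson–Crick hairpin whose
stem zips the sequence's C-runs onto its G-tracts. The G4 is strongly
stabilised by K⁺ and only weakly by Na⁺; the hairpin is indifferent to
which monovalent cation is present. Everything the package computes —
scores, motif calls, cytosine statistics, pairing capacities, regime
calls — feeds that one picture. The package makes equilibrium,
low-temperature predictions only: no melting temperatures, no free
energies, and no kinetics (see Limitations).

## G4Hunter scoring

Per-base scores: each G in a maximal G-run of length *L* scores
+min(*L*, 4); each C in a maximal C-run scores −min(*L*, 4); A, T and N
score 0, and N breaks runs. The G4Hunter score is the arithmetic mean
over all bases, kept at full precision internally and rounded half away
from zero to 2 decimals only for presentation (this convention is what
reproduces published values such as 39/26 → 1.50 and 29/26 → 1.12).

The *soft* scheme replaces the penalty of every C inside a C-run of
length ≥ 3 with a flat, configurable magnitude (2 or 1.5 are the
recommended values); C-runs of length 1–2 keep their classic −1/−2. The
rationale is that the C-penalty encodes the *risk of an alternative
fold*, not an intrinsic cost to quartet formation — sequences with one or
two CCC runs still fold into G4s given enough potassium, so −3 per C is
too severe. We apply the soft penalty to all runs of length ≥ 3, not just
exact triplets: the penalty models stem-forming potential, which does not
stop growing at three cytosines. A soft penalty of 3 on a sequence whose
C-runs are all exactly length 3 reduces to the classic rule (a useful
self-check).

Window mode computes window means from a cumulative sum (default window
25 nt, step 1, |mean| ≥ 1.2 flags a hit — conventional genome-scan
practice); negative windows are reverse-strand candidates by the
antisymmetry of the rule under reverse complement. Whole-sequence mode is
the default for oligo input.

## PQS motif grammar

Four classes, all requiring four G-tracts:

| class      | tracts                              | loops                |
|------------|-------------------------------------|----------------------|
| classical  | 4 × (≥ 3 G)                         | all 1–7 nt           |
| long_loop  | 4 × (≥ 3 G)                         | exactly one 8–15 nt  |
| bulged     | one tract = G-triplet split 1+2 or 2+1 by a 1–7 nt non-G bulge | all 1–7 nt |
| vacancy    | one tract = GG (terminal or internal), rest ≥ 3 G | all 1–7 nt |

Two-tetrad motifs (all tracts GG) are deliberately out of scope — they
are generally of low thermal stability.

Detection is run-based rather than regex-based: maximal G-runs are
enumerated, candidate tract units assembled from them (a whole run of
≥ 3 G; a GG run for the vacancy class; an adjacent 1+2/2+1 run pair for
the bulged class), and hits built by a left-to-right walk. Design
choices, each configurable or bypassable with `report_all`:

* **Greedy shortest match per anchor** — at each anchor tract the walk
  takes the nearest compatible next tract, yielding minimal loops and the
  shortest hit. Genome PQS databases differ in these conventions and
  rarely publish them; shortest-match is the common default.
* **Leftmost merging** — overlapping same-class, same-strand hits
  collapse to the leftmost representative.
* **Class precedence** classical > long_loop > bulged > vacancy resolves
  loci that satisfy several grammars (a bulged locus usually also parses
  as vacancy, for instance) deterministically.
* **Strands** — a minus-strand hit is a C-motif on the forward strand
  whose reverse complement satisfies the grammar; coordinates are
  reported on the forward strand, 0-based half-open (BED convention);
  human-readable reports are 1-based closed.

Every emitted hit re-validates against its own grammar (`PqsHit.validate`),
which the property suite exercises on random sequences.

## Cytosine statistics

Two statistics are deliberately kept distinct:

* `n_stat` = total C ÷ 3 — fractional; the "how many CCC-equivalents"
  measure used for the oligo series (4 C → 1.33). Invariant under any
  composition-preserving shuffle.
* `ccc_runs` — the count of discrete maximal C-runs of length ≥ 3; the
  genome-census filter ("PQS containing at least one CCC run"). Not
  shuffle-invariant.

Census filters can key on either (`filter_on=`); the census default is
`ccc_runs`, matching how catalogue counts are phrased. Whether a census
threshold of "N ≥ 2" means two discrete runs or n_stat ≥ 2 is ambiguous
in common usage, which is exactly why both filters are exposed.

## Hairpin pairing capacity

A Nussinov-style maximum-cardinality dynamic program over nested
(non-crossing) pairings, restricted to Watson–Crick G-C pairs (A-T
optionally included), with a minimum hairpin-loop length and an O(n³)
interval recurrence. Traceback is deterministic: at each interval the
left end is paired if some pairing of it attains the optimum, and with
its outermost compatible partner first. Ties elsewhere cannot arise.

Two `min_loop` settings matter:

* `min_loop=1` gives the *pairing capacity* — the combinatorial upper
  bound on stem content. This is the statistic quoted against observed
  hairpin behaviour (CEBm5: 9 G-C pairs, which equals its cytosine
  count); it is a capacity, not a realistic fold.
* `min_loop=3` (default for fold reports) is the sterically realistic
  setting; on CEBm5 the optimum is smaller than 9.

No pseudoknots, no G-T wobble pairs, no nearest-neighbour
thermodynamics: the model counts pairs only. The test suite checks the
DP against an independent exhaustive enumeration of all nested pairings
on sequences up to length 18, plus monotonicity (non-increasing in
`min_loop`, non-decreasing under appending) and the min(#G, #C) bound.

## Phase-regime classification

The rule table maps cytosine features to one of three regimes:

* `n_stat ≤ 1` (and G-C pairing capacity < 6) → **g4_locked**,
  threshold 0 mM K⁺;
* `ccc_runs ≥ 3` → **hairpin_locked**, threshold ∞;
* otherwise → **switchable**, with the predominance threshold [K⁺]
  interpolated linearly on `n_stat` from the calibration ladder
  (4/3 → 15 mM, 5/3 → 25 mM, 2 → 40 mM), clamped outside it.

The ladder is calibrated to the observed behaviour of the CEB series:
N = 1 keeps the G4 even in potassium-free sodium buffer; N = 1.33 shows
G4 signatures from 15 mM K⁺ (this point is marked low-confidence — the
melting profile at that condition is ambiguous and the call rests on
difference spectra); N = 1.67 from 25 mM; N = 2 from 40 mM; three or
more discrete CCC runs lock the hairpin at every tested condition. The
capacity guard on the G4-locked rule is belt-and-braces: with n_stat ≤ 1
a sequence has at most 3 cytosines and cannot reach 6 G-C pairs, but the
guard keeps the rule safe under user-modified tables. All thresholds
live in a JSON rule table (`RuleTable.to_file`/`from_file`) and are
user-tunable.

`predict_fold` is a step function: G4 iff buffer K⁺ ≥ threshold, which
makes K⁺-monotonicity (hairpin → G4 only) structural. The B1–B9 buffer
ladder (140 mM total monovalent cation, sodium traded for potassium) is
shipped as named constants; B1 approximates extracellular and B9
intracellular conditions.

A switchable call carries a caveat string: these are equilibrium calls,
and a pre-formed hairpin is a kinetic trap — conversion to the G4 after
a K⁺ rise can take hours to days, so the prediction says where the
equilibrium lies, not how fast it is reached.

## Synthetic data

The fixture generator serves two purposes:

* `build_ceb_family()` constructs the ten-member CEB series
  programmatically from the wild-type scaffold (prefix + 8-nt
  central-loop segment + suffix, plus 3′ extensions for the C-rich
  members) with self-checks on loop-edit length and tract integrity.
* `synth_genome(FixtureSpec)` plants motifs of chosen classes into an
  i.i.d. background (default 40% GC, a genome-like composition) whose
  G/C runs are capped at length 2, so the background alone can contain
  no tract and hence no PQS of any class. Planted motifs use A/T-only
  loops and are surrounded by 16-nt A/T guard zones — one base longer
  than the longest permitted loop — so no composite hit can bridge a
  plant and the background or two plants. Recall and false-positive
  audits on these genomes are therefore exact by construction, and a
  single integer seed determines every byte.

What this does *not* emulate: real genomes are not i.i.d. (repeats, CpG
suppression, isochores), real PQS overlap and nest heavily, and real
C-runs co-occur with G-tracts rather than being excluded from loops.
Passing the fixture tests shows the scanner's grammar and bookkeeping
are correct, not that any genome-wide count produced elsewhere is
reproduced; genome-scale catalogue numbers depend on the cataloguer's
exact grammar and are out of scope here.

## Numerical and edge-case choices

* Presentation rounding: half away from zero, 2 decimals, via `decimal`.
* Scores and capacities are exact integers over small denominators; all
  equality tests in the suite are exact or at float tolerance.
* Empty sequences are rejected at record construction; sequences shorter
  than `min_loop + 2` fold with 0 pairs; a window longer than its
  sequence is an error, not a clamp.
* U (RNA) is rejected — this is a DNA tool; lowercase is accepted and
  upper-cased; N scores 0, breaks runs, and never pairs.
* Problem sizes in the test suite: oracle equivalence on random
  sequences up to length 18; planted-genome audits on 30–100 kb genomes
  with up to 48 plants; invariant sweeps on 1000 random sequences.

## Known limitations

* The switchable threshold ladder is calibrated on a single sequence
  family (one scaffold, one loop position); applying it to arbitrary
  genomic PQS is an extrapolation, and the rule table exists precisely
  so users can re-calibrate.
* Temperature is outside the quantitative scope: the classifier predicts
  the low-temperature predominant species only.
* Molecularity is assumed intramolecular; at high strand concentration
  C-rich extensions can instead form intermolecular duplexes, which the
  pair-counting model does not distinguish.
* i-motif (C-quadruplex) formation on the C-rich strand is not modelled.
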