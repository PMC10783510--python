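# g4switch

Hairpin/G-quadruplex competition analysis for G/C-rich DNA.

Many putative quadruplex sequences (PQS) carry runs of cytosines in or
around their G-tracts. Such mixed G/C-rich sequences can fold into either
an intramolecular G-quadruplex (G4) — stabilised by K⁺ much more than by
Na⁺ — or a competing Watson–Crick hairpin whose stability is
cation-indifferent. Which structure predominates therefore depends on the
Na⁺/K⁺ balance of the environment: such "shape-shifting" sequences are
expected to fold differently inside cells (K⁺-rich) and outside them
(Na⁺-rich). `g4switch` is a toolkit for scoring, detecting and
classifying these sequences. It is aimed at people studying G4 biology,
aptamer designers working in extracellular (sodium-rich) media, and
anyone curating genome-scale PQS catalogues.

## What it computes

* **G4Hunter scoring** — the mean per-base score where each G in a maximal
  G-run of length *L* contributes +min(*L*, 4), each C in a C-run
  contributes −min(*L*, 4), and A/T/N contribute 0. Besides the classic
  rule a *softened* scheme scores every C inside a CCC run at a flat −2 or
  −1.5, reflecting that the C-penalty models hairpin competition rather
  than any intrinsic harm to quartet formation. Whole-sequence and
  sliding-window modes.
* **PQS motif detection** — four motif classes built on four G-tracts:
  classical (tracts ≥ 3 G, loops 1–7 nt), long-loop (one loop 8–15 nt),
  bulged (one tract is a G-triplet split by a 1–7 nt bulge) and
  G-vacancy (one tract of only GG). Both strands, BED6 output, census
  summaries with cytosine-run filters.
* **Cytosine-run statistics** — the N statistic (total C ÷ 3) and the
  count of discrete CCC runs, the two quantities that gauge how much
  competing stem a sequence can build.
* **Hairpin capacity** — the maximum number of G-C base pairs attainable
  in a nested (pseudoknot-free) intramolecular pairing, by a
  Nussinov-style maximum-cardinality dynamic program with traceback to
  dot-bracket.
* **Phase-regime classification** — each sequence is placed in one of
  three regimes: *G4-locked* (G4 predominates at any Na⁺/K⁺ ratio),
  *switchable* (hairpin at low K⁺, G4 above a sequence-dependent
  potassium threshold) or *hairpin-locked* (hairpin at every ionic
  condition), with fold predictions for the B1–B9 buffer ladder
  (140 mM Na⁺/0 mM K⁺ … 0 mM Na⁺/140 mM K⁺).

## Worked example

The package ships a programmatic generator for the CEB oligonucleotide
family: the human minisatellite CEB25 quadruplex (CEBwt, a parallel G4
with a 9-nt central loop) and nine mutants in which loop bases are
progressively replaced by cytosines.

```sh
g4switch fixtures --ceb --out ceb.fa
g4switch classify ceb.fa --buffers --quiet
```

prints (columns trimmed to the first buffers):

```
id      regime          k_threshold_mM  ccc_runs  n_stat  max_gc_pairs  g4hunter  B1       B2       B3  B4  B5 ...
CEBwt   g4_locked       0               0         0       0             1.5       G4       G4       G4  G4  G4
CEBm1   g4_locked       0               1         1       3             1.12      G4       G4       G4  G4  G4
CEBm2   switchable      15              1         1.33    4             1.04      Hairpin  Hairpin  G4  G4  G4
CEBm3   switchable      25              1         1.67    5             0.92      Hairpin  Hairpin  Hairpin  G4  G4
CEBm4   switchable      40              2         2       6             0.69      Hairpin  Hairpin  Hairpin  Hairpin  G4
CEBm7   hairpin_locked  inf             4         4       12            0         Hairpin  Hairpin  Hairpin  Hairpin  Hairpin
```

Reading CEBm4's row: two CCC runs (N = 2) in the central loop give the
sequence a 6-pair G-C hairpin stem to fall back on; the classifier calls
it switchable with a 40 mM K⁺ threshold, so it is predicted to fold as a
hairpin in sodium-dominated buffers B1–B4 and as a G4 from B5
(40 mM K⁺) on. CEBwt has no cytosines and is G4-locked everywhere;
CEBm7 (four CCC runs, 12 G-C pairs of stem capacity) never leaves the
hairpin regime. Note the calls are equilibrium predictions: conversion
of a pre-formed hairpin to the G4 can take hours to days.

Scoring the same file with the softened penalty:

```sh
g4switch score ceb.fa --scheme soft:2 --quiet | grep CEBm4
# CEBm4  26  soft:2  0.92  6  2.0  2
```

i.e. CEBm4's G4Hunter score rises from 0.69 (classic) to 0.92, in line
with its observed ability to fold into a G4 at intracellular potassium.

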