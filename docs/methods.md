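# Methods

`centrohor` annotates the internal structure of centromeric satellite
arrays: it infers the monomer alphabet of an array, rewrites the array as
a monomer-ID sequence, and mines that sequence for higher-order repeats
(HORs), including locally nested HORs in which a sub-span of consecutive
monomers is itself tandemly amplified inside a unit. This note records the
model, the parameters that matter, the numerical choices, and what the
simulation-based validation does and does not show.

## Pipeline model

**Block decomposition.** The array is segmented into consecutive,
non-overlapping blocks, one per monomer instance, by a dynamic program
over (template position, array position). Starting a new template copy at
any array position inherits the best score of the already-segmented
prefix, so all block boundaries are chosen jointly to maximise the summed
semi-global alignment score of the template against every block. Scoring
is match +1, mismatch −1, indel −1; soft-masked bases are uppercased and
`N` mismatches every base. Only the forward strand is aligned: an inverted
segment of an array surfaces as a second HOR with a reversed monomer
pattern rather than being folded onto the forward one. Terminal blocks
shorter than 60% of the template are trimmed as alignment fragments.
Complexity is O(|array| × |template|) time (numba-compiled) and
O(|template|) memory per column.

**Block similarity.** Similarity of blocks *i*, *j* is
`S_ij = 1 − ed(i, j) / max(len_i, len_j)` with `ed` the unit-cost
Levenshtein distance (edlib). The literal unit-cost form is used rather
than alignment identity. Blocks with identical sequences are collapsed
before the quadratic pairwise step; representatives keep first-occurrence
order so results are order-stable. The merge is exactly lossless: the full
matrix is recoverable by indexing the merged one.

**Monomer inference.** For each threshold `t` in an ascending schedule
(default 0.94 to just below 1.0 in steps of 0.005), blocks with
`S_ij > t` (strictly) are linked, and Louvain communities of that graph
(resolution 1.0, seeded) are the monomers. The graph is built over merged
representatives with multiplicities folded into edge weights
(`m_i·m_j`, self-loops `m(m−1)/2`), which makes modularity identical to
the unmerged block graph — equivalent to duplicating nodes but much
cheaper. Monomer IDs are 1..k in order of first block occurrence.

**Hierarchical tandem repeat mining (HTRM).** On the monomer-ID sequence,
tandem runs of unit length 1, 2, … are detected; accepted runs are stored
in a non-overlapping *top layer* (original coordinates) and compressed in
the working sequence to **one copy of their unit**, after which detection
restarts at unit length 1. Compression-to-one-copy is the key design
choice: a locally nested unit such as `1-2-(3-4)×3-5` collapses to
`1-2-3-4-5`, so canonical and nested units line up into a single long run
whose unit is the canonical HOR unit; the amplification survives as a
child repeat with its own span and copy number. Region checking follows a
four-way rule — disjoint runs are saved; runs covered by an old repeat are
discarded (ties on identical spans count as covered); runs covering old
repeats replace them and adopt them as children; partial overlaps are
trimmed to whole units, dropping the run if fewer than two units remain.
Overlapping same-length new runs keep the leftmost (a run is anchored at
the leftmost phase of its maximal periodic region). The loop terminates
because each compression strictly shortens the working sequence and the
unit length is bounded (default 40, an efficiency bound: HORs with longer
units are not searched for).

A nested repeat can sit out of phase with a later, larger repeat, in which
case its span straddles an instance boundary of the outer repeat. The
expand-once reduction of an instance to the unit is then undefined for
that instance; rendering falls back to the literal monomer symbols. This
cannot happen when amplifications are confined within HOR units (the
simulated regime) and is rare in practice.

**HOR assembly and scoring.** Top-layer repeats whose units are rotations
of one another are merged as one HOR under the lexicographically smallest
rotation. Because nesting was compressed to one unit copy, pattern
variants differing only in nested copy number — including the literal
n = 1 unit — share the same canonical unit and merge automatically. Each
HOR is scored `HORscore = cr × pr`, `cr = HOR.len / m.len` (covered
fraction of the monomer sequence, measured in original, uncompressed
symbols so that cr reflects true sequence coverage) and
`pr = HOR.rn / (HOR.len / HORunit.len)` (actual over nominal repeat
count; < 1 flags local nesting / over-compression). Ranking ties break by
covered length (desc), unit length (asc), then first occurrence; names
are `R{rank}L{unit_len}`. The similarity threshold is chosen by
annotating at every threshold of the schedule and keeping the largest
total HOR coverage, ties to the lowest threshold; the sweep stops early
once a threshold reaches coverage 1.0, which provably cannot change the
selection. Instances project to genomic coordinates through their block
spans (BED, 0-based half-open).

## Synthetic data

The generator emulates a homogenised satellite array: one HOR of five
distinct monomers repeated 40 times. A random raw template (monomer size
100/200/300/400 bp, the observed satellite range) yields five diverged
monomer templates by substituting exactly `round(d × size)` distinct
positions (monomer divergence d = 10/20/30%); every monomer instance then
receives its own `round(h × size)` substitutions (HOR divergence
h = 0.5/1.5/2.5%), emulating the 95–100% unit-to-unit identity of real
HOR arrays. In locally nested mode, 20 of the 40 units are modified by
amplifying a uniformly chosen span of 1–4 consecutive monomers (confined
within the unit) to a uniform total of 2–5 copies. The annotator receives
the *raw* template, so monomer recovery is genuinely inferred. The full
design is the 4 × 3 × 3 grid × 10 replicates per mode (360 datasets per
mode); each (cell, replicate) uses an independent RNG stream derived from
(seed, cell index, replicate), so cells are individually re-runnable.

Deliberate simplifications: mutations are substitutions only (no indels),
at distinct positions; arrays contain a single HOR family, no strand
inversions, no hybrid monomers, and no higher-order array-level structure.
Passing the simulation suite therefore shows that monomer inference,
nested-repeat mining and unit accounting are correct under substitution
divergence in the published parameter range; it does not exercise
indel-rich divergence, template mismatch, or multi-family arrays.

Evaluation counts the instances of the top-ranked HOR whose unit length
is 5: `bias = |AN − 40|`; instances split into canonical (no nested
child) and locally nested. An annotation matches the ground truth exactly
when the predicted monomer sequence is a bijective relabeling of the true
one, every annotated unit span equals the true unit boundary, and every
amplification is recovered with its exact span and copy number.

Observed failures concentrate in the hardest cells (large monomers with
30% monomer and 2.5% HOR divergence), where a community occasionally
splits and the inferred monomer alphabet exceeds five — the same regime
in which the reference results report their losses.

## Enrichment test

HOR instances are binned by midpoint into equal-width bins (default 25)
of the array region. Per pattern class, the observed per-bin counts are
compared with `n_random = 100` uniform re-placements of the same number
of instances (uniform midpoint is equivalent to a uniform bin draw for
equal-width bins): `z = (N_obv − μ)/σ`, one-sided upper-tail normal
p-value, enriched at p < 0.05. Bins with σ = 0 are reported untestable
(NA) rather than as infinite z. No multiple-testing correction is
applied; the p-values are per-bin descriptors, and under the null the
p < 0.05 rate calibrates to ~5%.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `min_similarity` | 0.94 | lowest block-similarity threshold of the sweep (fraction; CLI takes percent) |
| `step` | 0.005 | threshold increment of the sweep |
| `max_unit_len` | 40 | largest repeat-unit length searched (monomer symbols) |
| `seed` | 0 | Louvain RNG seed, recorded in run metadata |
| terminal trim | 0.6 × template | minimum length of a kept terminal block |
| alignment scores | +1/−1/−1 | match / mismatch / indel in the decomposition DP |

## Numerical and degenerate-input choices

- Edge rule is strictly `S > t`; a similarity exactly at the threshold
  does not link.
- Threshold ties select the lowest threshold; score ties are broken
  deterministically (above), so ranks and names are reproducible.
- `round()` (banker's rounding) fixes mutation counts in the generator;
  divergence 2.5% of 100 bp is 2 substitutions.
- Empty sequences and arrays shorter than half the template are input
  errors; a repeat-free sequence returns an empty HOR list with
  coverage 0 rather than an error.
- All randomness (Louvain, generator, enrichment background) flows from
  explicit seeds; a fixed seed makes every output byte-identical.

## Limitations

- One monomer template, forward strand only; no hybrid-monomer splitting
  or dehybridization, no raw-read input.
- Tandem detection is exact over monomer symbols; a unit mutated into a
  different monomer ID breaks a run rather than being absorbed as an
  approximate match (the threshold sweep, not the miner, absorbs sequence
  divergence).
- The unit-length bound (40) caps detectable HOR units.
- Simulation grids at desk scale use the published design (360 datasets
  per mode); accuracy statistics carry the corresponding binomial noise.
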