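# Model and methods

`ecoevosim` is a bottom-up eco-evolutionary simulator: macroevolutionary
patterns (diversification trajectories, speciation–extinction coupling,
species lifetimes, niche occupancy) are not scripted but emerge from
population-level mechanisms applied every iteration.  This note documents
the model as implemented, the parameters that matter, the design choices
made where the design was genuinely open, and what the packaged scaled-down
experiments do and do not show.

## Units of evolution

Populations are the units of evolution.  Each population carries a single
*featured genotype* — the dominant genotype under a strong-selection,
weak-mutation abstraction — as a variable-length bit string in three
segments:

* **phenotypic genes** (default 36 × 8 bits) feed the genotype→phenotype
  mapping;
* **reproductive genes** (default 2 × 8 bits) determine interbreeding
  compatibility;
* **niche genes** (one 8-bit gene per role *n*, *c*, *r*) encode position,
  optimum and tolerance on an abstract niche gradient (0–255 per 8-bit
  gene; duplicated role genes concatenate big-endian).

Species are sets of reproductively compatible populations; speciation and
extinction are irreversible bookkeeping events derived from the population
dynamics.

## Genotype→phenotype mapping (grammatical evolution)

Traits are mathematical expressions derived from a context-free grammar.
The phenotypic segment is read as a circular stream of 2-bit codons; a
left-most derivation picks, at every nonterminal with k > 1 options, option
`codon mod k` (single-option rules consume nothing).  Trait *t* starts
reading at bit offset `t × size_gene × stagger` (stagger = 4 genes), so the
eight default traits consume shifted, overlapping codon windows.  Wrapping
is allowed up to 8 circuits; past a depth cap the remaining nonterminals
expand through their fastest-terminating options (first among ties), which
forces termination deterministically.  The depth cap defaults to 16: it
bounds expression bloat — under selection, unbounded derivations grow very
large trees whose evaluation cost and numeric range grow with them — while
still allowing richly nested expressions.

Only the codons a derivation actually consumed make genes *expressed*; the
three gene classes (fitness-influencing / expressed non-fitness /
non-expressed) follow from which traits the population's fitness function
reads.  Mutations confined to non-expressed genes provably cannot change
any trait, which is what lets genetic drift emerge on them.

Fitness functions are derived from a second grammar with uniformly random
choices at population initialization (the derivation path is recorded and
inherited unchanged by daughter populations).  The packaged fitness grammar
scores trait–environment compatibility with three kernels — a sharp
Gaussian match `exp(-8(a-b)²)`, a linear match `1-|a-b|` and a tolerant
rational match `1/(1+(a-b)²)` — combined by averages, products and minima
(limiting factors).  The sharp kernel matters: with only tolerant kernels,
fitness can never fall below the extinction threshold for bounded inputs
and environmental change loses all selective force.  All primitives are
protected (safe division, clamped exp, log of |x|), and the final fitness
is clamped to [0, 1] with NaN mapped to 0.  The packaged grammars are
representative fixtures, not reproductions of any particular reference
grammar.

Trait expressions take the region's normalized environmental properties
(value / (2^bits − 1) ∈ [0, 1]) as inputs; the fitness expression reads
both trait values and the properties.  This is one consistent reading of
"compatibility between phenotype and environment"; a plausible alternative
(traits as genotype-only constants) is noted but not implemented.

## Environment

A d1 × d2 toroidal grid of cells is partitioned into connected regions
(initially one cell each), each carrying 24 properties of 8 bits.  Per
iteration each region, with its own rate drawn once from U(0.005, 0.025),
flips one uniformly chosen bit of one uniformly chosen property — the
mildest reading of "temporal variability at the bit level" that keeps the
rate interpretable as an event rate.  Region merging/splitting (macro-
regions) is implemented (merge inherits a per-property random combination;
split cuts a random spanning-tree edge of the cell graph) but disabled by
default, matching the proof-of-concept setup.  Environmental shocks replace
every region's drift rate for a scheduled window and restore the original
rates afterwards.

## Ecology

Realized niches are intervals [n−r, n+r]; overlap is interval Jaccard
(degenerate points: 1 if identical, else 0).  Cohabiting overlapping pairs
compete automatically through bidirectional negative links of weight
−overlap.  Non-overlapping ordered pairs form stochastic non-competitive
links (probability 0.01 per iteration, removed at 0.01, magnitude 0.5):
facilitative from higher-*n* to lower-*n* populations, inhibitory the other
way (the allometric rule).  The net ecological impact of population A is

    NEI_A = Σ_{i≠A} [ L_Ai · (1 − F_Ai) + W_Ai ]

with L the (negative) competitive weight, F = clamp(fit_A − fit_i, −1, 1)
— the fitter party suffers less — and W the incoming signed non-competitive
weights.  The signed-link reading of L is the central interpretive choice:
with positive L, competition would raise NEI and the stated semantics
("positive NEI = favourable conditions") would invert.

When NEI falls below the shift threshold (−0.5), the population evaluates
all ±1 moves of n and/or r (8 candidates, negatives excluded), scores each
by prospective NEI (incoming non-competitive weights count only while the
pair stays disjoint) and adopts the best strictly-improving candidate, ties
uniform.  This is the only process that ever changes n; c and r are
re-decoded from the genotype whenever niche genes mutate or flow.

## Demography

Mutation flips each bit independently (rates per population drawn from
U(0, 5e-4)/U(0, 1e-4)/U(0, 1e-5) for the three segments; n-role niche bits
never mutate).  Gene flow copies whole genes, position by position, from
one uniformly chosen coexisting conspecific per iteration; duplication
(tandem, adjacent insertion) expands segments at 5e-7 / 1e-7 / 0 per
iteration.  Splitting creates a daughter with a deep-copied genotype, the
parent's fitness function, and parameters drawn as: uniform-range rates
re-drawn; Normal-family parameters (gene flow, splitting, migration) drawn
around the *lineage mean inherited unchanged from the parent*.  Keeping
lineage means fixed is deliberate: if instead each child's mean were its
parent's realized value, the parameters follow a random walk on which
fecundity selection is unopposed — splitting probabilities escalate to
~0.4 per iteration within ten thousand iterations, population turnover
reaches ~30% per iteration, coalescence becomes so shallow that
reproductive divergence can never accumulate, and no speciation occurs at
any affordable scale.  With stable means the dynamics are calm enough for
lineages to persist and diverge.

Founder lineage means are not fixed by the proof-of-concept table and were
chosen once, from establishment pilots, as study conditions: gene flow
0.001 per gene, splitting 0.005 per iteration, and migration-after-split
0.9.  The high dispersal value is load-bearing: a non-migrating split
leaves parent and child fully overlapping with equal fitness, NEI = −1,
which is at or below every collapse threshold in U(−1, −0.25) — local
splits are lethal, and lineages that do not disperse die out.  With high
dispersal roughly one replicate in five to seven establishes a persistent,
growing community while the rest lose all life early — the same two
regimes the full-scale scenario exhibits, though desk-scale establishment
is rarer than the roughly one-in-two reported at full scale (a single
founder in a 64-region world has far fewer escape routes).

### Extinction

Three independent routes, evaluated in the fixed order fitness → NEI →
niche mismatch (the order affects only event labels): fitness below 0.10;
NEI below the species' collapse threshold (U(−1.0, −0.25)); realized niche
position outside the fundamental interval [c−r, c+r].  A species is extinct
when its last population is removed; species ids are never reused.

### Speciation

Reproductive distance is the differing-bit count between reproductive
segments: aligned-prefix mismatches plus the full surplus length of the
longer segment (so genome expansion counts toward divergence), optionally
normalized by the longer bit length; an absolute big-endian numeric
distance is also available.  The species threshold is drawn at species
emergence as `ngenr × size_gene × U(0.5, 0.9)` bits; each *new* species
draws fresh species-scope parameters (threshold and collapse threshold),
per the rule that entity-scope parameters are assigned when the entity
emerges.

The partition rule is the one place where this package deliberately departs
from a transitive compatibility reading.  Under single linkage (species =
connected components of the pairwise-compatibility graph), speciation
essentially never completes: populations form dense chains of close
relatives by construction, so the threshold graph stays connected even when
pairs diverge far beyond the threshold (observed: maximum pairwise
divergence 12–14 bits against a threshold of 8.2 with the species still
whole after 50,000 iterations).  The default rule is therefore *pairwise
diameter splitting*: while any member pair exceeds the threshold, the
members are bipartitioned around the two most divergent poles (each member
joins the nearer pole; ties join the lower-id pole), recursively.  This
matches the primitive definition — two populations whose divergence
exceeds the threshold are different species — and produces ongoing
speciation.  The single-linkage rule remains available
(`speciation_rule="connected_components"`) for sensitivity analysis.  The
group containing the oldest member keeps the ancestral species id (a
convention giving stable lineage identity for the phylogeny); speciation is
irreversible.

## Engine

Canonical per-iteration order: environment → mutation → gene flow →
expansion → phenotype/fitness refresh → network/NEI → adaptive shifts →
extinctions → splits/migration → speciation → sampling.  Variation precedes
selection; newborns are first evaluated the next iteration.  All randomness
flows through one seeded generator in documented order, so runs are pure
functions of (config, seed); an empty world short-circuits with a terminal
event.  The per-population Bernoulli screens are vectorized over a
slot-indexed structure of arrays, phenotypes are re-derived only for traits
whose consumed codons overlap changed bits, and each species maintains an
incremental pairwise-distance index — all pure optimizations that leave
event semantics untouched.

## Statistics

Per-iteration speciation/extinction rates divide event counts by the number
of extant species at the previous iteration (configurable: current-richness
or raw-count denominators), undefined at zero richness; the richness
recurrence richness(t) = richness(t−1) + originations(t) − extinctions(t)
holds exactly against every log.  Correlations are Pearson with pairwise
deletion; constant series report NaN, never 0.  A 200-iteration moving
average of the rates is available for comparability with smoothed full-
scale analyses.  Species lifetimes exclude extant (censored) species from
closed histograms but keep them, flagged, in the table.  Niche occupancy
counts positions 0..2^bits−1 per region.  Allele-frequency tracks sample,
per gene class, the modal 8-bit allele's share across a species'
populations at a configurable cadence.  The species ancestry serializes to
Newick with branch lengths in iterations and `_x` flags on extinct tips.

## The packaged study (problem sizes)

The proof-of-concept scale (1000×1000 regions, 5×10⁶ iterations, 1000
surviving replicates) is out of reach for this implementation on one CPU;
the packaged replicate study runs the same process on an 8×8 torus for
60,000 iterations, launching seeds spawned from one master seed until 12
replicates survive to the end.  At this scale communities hold tens to a
few hundred populations and a handful of species; speciation begins once
reproductive divergence saturates (typically after ~10⁴ iterations), so
event counts per replicate are small and the pooled statistics are far
noisier than the full-scale ones.  The speciation–extinction balance is
therefore measured as the full-scale analysis states it — the correlation
*across simulations* between each replicate's mean speciation and mean
extinction rate — rather than over single-iteration points, which at this
event density carry almost no signal (speciation and species loss rarely
share an iteration; the per-iteration pooled correlation is also computed
and exposed by the study API).  What the passing checks show is that the
mechanisms produce the right *couplings* (origination and loss balancing
each other across replicates, right-skewed lifetimes, a nonzero
early-extinction fraction, growing niche occupancy, shock-driven extinction
pulses) — not that the desk-scale magnitudes equal the full-scale ones.  Species-level
mass-extinction percentages and near-complete niche saturation require the
full scale and are probed only qualitatively here.

## Known limitations

* Within-population genetic variance, abundances and age structure are
  abstracted away (featured genotypes).
* The interaction-strength magnitude (0.5) and the thresholds governing
  shifts and links are stated assumptions exposed in the configuration, not
  values from the source scenario table.
* Desk-scale communities are small; statistics that need thousands of
  coexisting species (rate magnitudes in the tens of percent, 74%/98%
  occupancy figures, 60–85% shock collapses) are out of reach and only
  their qualitative signatures are tested.
* With the tolerant match kernels alone, fitness-driven extinction would be
  unreachable; the sharp kernel in the fitness grammar is what gives
  environmental change selective teeth.
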