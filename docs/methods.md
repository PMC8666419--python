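# Methods

This note documents the model, the conventions the implementation
commits to where the method leaves room, the synthetic-data generator's
scope, and the problem sizes used by the test and acceptance suites.

## Error model and consensus calling

The unit of observation is the molecule: one synthetic single-stranded
template copied exactly once by the polymerase, identified by its 20-nt
UMI. Sequencing yields a stack of reads for each strand of the resulting
duplex. Per (bin, locus, strand) the consensus is the strict-majority
symbol over {A, C, G, T, DEL} among reads covering the locus; ties give
no call and the bin-locus is skipped. An error call compares the two
strand consensuses in reference orientation: differing bases are a
substitution X→Y (X the template base), a DEL consensus on the
polymerized strand is a deletion of X, and a strict majority of
polymerized reads carrying an inserted base after a locus is an
insertion anchored to that locus.

**False-consensus probability.** Read `j` is individually correct with
probability `c_j = (1 - b_j)(1 - q_j)`: `q_j = 10^(-Q_j/10)` from its
Phred score at the locus, `b_j` the probability its UMI was misread
(`1 - prod(1 - 10^(-Q_i/10))` over the 20 UMI bases), which accounts for
reads falsely added to the bin. Given the observed agreement pattern
`e_j` (read agrees/disagrees with the consensus), the consensus is wrong
exactly when incorrectly-called reads form a strict majority, so

    P_E = P( sum_j X_j > m/2 ),   X_j ~ Bernoulli(p_j),
    p_j = 1 - c_j if e_j = 0,  p_j = c_j if e_j = 1.

This is a Poisson-binomial tail, computed exactly by dynamic programming
in O(m²) and verified against exhaustive 2^m enumeration to 1e-12. The
printed scenario-sum formulation of this quantity is ambiguous about
whether scenario membership encodes correct or incorrect calls; the
literal membership-equals-correct reading evaluates to ~1 for clean
unanimous stacks, which contradicts both its name and its use as a
*retention* threshold, so the majority-incorrect reading above is the
implemented one. The literal variant is kept behind
`false_consensus_prob(..., literal=True)` for comparison.

**Conventions committed to here.**

- Stacks deeper than 12 reads are uniformly subsampled to 12 for the
  P_E computation only (consensus and the depth rule use the full
  stack); the subsample is driven by the run-level seed.
- The two strands are combined assuming independence:
  `P_E = 1 - (1 - P_E,template)(1 - P_E,polymerized)`; the threshold
  (default 1e-5, configurable) applies to the combined value.
- `e` in the expected error `|e - P_E|` is the per-locus binary call,
  the only reading that yields one expected error per base comparison.
  Retained `e = 0` comparisons carry their `P_E` as mass of type "none";
  it counts toward coverage but toward no error type.
- A deleted read position has no base quality of its own; it borrows
  the quality of the preceding read base (the following one at a read
  edge).
- Insertion calls reuse the same machinery on present/absent
  observations; a call is emitted only when present reads form a strict
  majority on the polymerized strand and the template strand calls
  absent. The inserted base is the majority base among present reads.
- Template-read validation (exact match to the reference) applies to
  the analysis window only — bases outside the window are never
  compared, and in this assay products are truncated.

## Filters and their order

1. UMI binning (prefix tree, exact lookup), bin ids in first-seen order.
2. Singleton rescue: a one-pair bin moves into its unique
   Hamming-distance-1 neighbour if that destination held > 5 mate-pairs,
   evaluated against the pre-move state in a single pass (no cascades —
   the iteration scheme is unspecified in the method, and a one-pass
   rule is order-stable).
3. Bin filters: ≥ 6 mate-pairs, both strand classes present,
   template:polymerized ratio within [1/3, 3] inclusive (a range "from
   1:3 to 3:1" most naturally includes its endpoints).
4. Template-read validation, then per-locus: ≥ 6 reads per strand,
   strict consensus both strands, combined P_E ≤ threshold.
5. Oxidation filter on the rate tables: a locus is dropped for a
   condition when its pooled C→A rate (expected-error sum over coverage,
   pooled across the condition's replicates — the pooling level is a
   choice made here) is ≥ 5e-4. The artifact is oxidative guanine
   damage on the polymerized strand, which reads as C→A in reference
   orientation.

Every exclusion is counted; a run's manifest reconciles each input SAM
record into used-pair or exactly one exclusion category, and the
pipeline aborts if the accounting does not balance.

## Rates, contexts, statistics

Rates are expected-error sums divided by qualifying bin-locus coverage,
per replicate and condition, over the 175 analysis-window loci
(coordinates 0-based within the window). Context tables assign each
k-mer occurrence starting at locus ℓ the sum of the k per-locus total
substitution rates — the anchor is the k-mer *beginning* at the locus,
matching grouping by the identity of the first template base; k = 1
reproduces the per-locus table. Indel tables group by event, the
deleted/inserted base, and its 5′ neighbour (deletions at window locus 0
are skipped: their neighbour is the molecule-specific UMI base), with
purine/pyrimidine roll-ups. The moving-average profile is a step-1
sliding mean (default window 25 nt — the method's figure legend states
both 10 and 25; the window is a config parameter) with the Pearson
correlation between window means and window GC, NaN under zero variance.

The statistics layer takes per-locus medians of (by default) triplicate
rates after mean imputation: cells with no coverage, and cells whose
rate is exactly zero, are replaced by the mean of the non-zero
replicates at the same locus and condition — never across conditions, to
avoid leaking the contrast; loci with no non-zero replicate stay zero.
Paired contrasts use the two-tailed Wilcoxon signed-rank test (zeros
dropped, classic Wilcoxon; the Pratt variant is available by flag; exact
null up to 25 untied non-zero differences, otherwise normal
approximation with continuity correction; fewer than 5 non-zero
differences is refused with a diagnostic). Unpaired contrasts use the
two-tailed Mann–Whitney U test (exact when the smaller sample has ≤ 10
untied observations, otherwise the tie-corrected normal approximation).
Both are computed by scipy beneath this interface and are cross-checked
in the tests against explicit enumeration of sign patterns / label
assignments. Fold changes are reported both as the mean of per-locus
ratios (zero denominators skipped and counted) and as the ratio of
overall medians, since the two summaries answer different questions and
the method's printed fold values do not identify which was used. The PCR
extrapolation assumes one replication of every base per cycle with
independent errors, `F(c) = 1 - (1 - e)^(L·c)`; it is parameterized, not
tied to any particular enzyme's rate.

## The synthetic-data generator

Each molecule gets a uniform random 20-nt UMI (collisions at 4^20 are
negligible and handled by binning regardless), a product length drawn
from a clipped normal (defaults 200 ± 10 nt, emulating the observed
~200-bp products), and per-strand read depths uniform on 6–14. The
polymerized strand starts as the reference segment with the UMI
substituted in, then acquires substitutions (scalar rate split uniformly
over the three alternatives, or a full 4×4 matrix), deletions and
insertions at per-base rates over the synthesized region (everything
downstream of the primer, so the copied UMI can itself acquire errors —
such molecules lose their polymerized pairs to a satellite bin and drop
out at the both-strands filter, as in the real assay). Oxidative damage
is a per-molecule, per-hotspot Bernoulli conversion applied after
polymerization to the polymerized strand (G→T in its own orientation,
C→A in reference orientation), recorded separately from the polymerase
truth table. Reads cover the product from both fragment ends at read
length 150 in FR orientation; template-strand pairs align first-in-pair
forward, polymerized-strand pairs first-in-pair reverse; mates merge
with first-in-pair priority where they overlap. Sequencer noise draws a
Phred score per base from a clipped rounded normal (default 30 ± 3) and
miscalls with probability 10^(-Q/10), uniformly over the three
alternative bases — the simplest model consistent with Phred semantics.
Molecule-level randomness is drawn once; read-level noise comes from a
derived stream inside the writers, so SAM and FASTQ outputs are
byte-identical across repeated calls and runs.

What the generator does **not** emulate: the multi-round PCR library
preparation (one UMI per molecule, many independent reads per strand is
the abstraction), exonuclease trimming, adapter content, optical
duplicates, quality-by-cycle structure, context-dependent sequencer
error, or GC-dependent polymerase error. Passing recovery tests
therefore demonstrates correctness of the pipeline's inference given the
assay's error structure, not robustness to every artifact of real
libraries.

## Problem sizes and study conditions in the test suites

- The bundled default template is a 1-kb, 50%-GC sequence generated by
  this package's own screen (seeded, regenerable; see
  `umierr/_template.py`).
- Recovery and false-positive runs use 7,500 molecules (≈ 1.1–1.5
  million qualifying bin-locus comparisons) with product length
  240 ± 8 nt so the full 175-nt window is covered, and flat Q30
  sequencer noise (error 1e-3); tolerances are 3 Poisson standard
  deviations of the injected rate.
- Fold-change recovery simulates condition pairs with rate ratios 2.4
  and 1.1. The absolute rates (3e-3 base) are set so that per-locus,
  per-replicate expected error counts are ≳ 12 — the level at which a
  mean of per-locus median ratios is identifiable at desk scale; only
  the ratio, not the absolute rate, is the quantity under test. At
  these rates the C→A oxidation cutoff removes essentially all C loci
  in both conditions, which leaves the recovered ratio unaffected
  (rates are uniform across loci) and the paired test with ~130 loci.
- Type-I calibration uses 500 paired tests on independent identically
  distributed per-locus medians of triplicate Poisson(10) counts at
  n = 175 loci.
- The self-test (`umierr selftest`) runs the four bundled condition
  presets — earth-gravity medians with the observed microgravity fold
  changes applied — at 20,000 molecules per replicate by default and
  checks 3-SD recovery; the pytest suite runs a miniature version.

## Known limitations

- Insertion calls are emitted only when called present; the expected
  "no-insertion" mass is not tabulated (its contribution is ≪ the
  insertion rates of interest).
- The indel-context denominator pools the coverage of all loci whose
  deletion would fall in a (base, neighbour) class; with uneven
  coverage this is a convention, not the only possible one.
- Contexts and profiles are not normalized for the template's uneven
  k-mer composition; normalization against composition is template
  design's job, not the rate layer's.
- The false-consensus model treats reads as independent given the
  molecule; PCR-sibling correlation within a strand's read stack is not
  modelled (the generator does not create it either).
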