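# umierr

UMI-consensus estimation of DNA polymerase error rates from paired
template/polymerized-strand sequencing.

## The problem

Measuring the fidelity of a DNA polymerase by sequencing is confounded by
the sequencer itself: Illumina-class instruments miscall bases orders of
magnitude more often than a polymerase misincorporates them. The assay
this package implements separates the two error sources with unique
molecular identifiers (UMIs): every synthetic single-stranded template
molecule carries a random 20-nt barcode downstream of the polymerization
primer site, the polymerase copies each template exactly once, and the
resulting duplexes are sequenced deeply. All reads descending from one
molecule share its UMI, so sequencer errors can be removed by majority
consensus within each UMI bin, strand by strand, and a polymerase error
appears as a disagreement between the template-strand consensus and the
polymerized-strand consensus at a locus. The design supports condition
contrasts (for example polymerization under parabolic-flight microgravity
versus level-flight gravity, with and without proofreading exonuclease
activity) through a nonparametric statistics layer.

`umierr` is aimed at anyone running or reanalysing such an assay: it
consumes aligned reads (SAM), calls per-molecule errors, tabulates
substitution/deletion/insertion rates and their sequence contexts, and
tests condition contrasts. A synthetic-data generator with a full truth
table makes every stage testable without any external data.

## The method

For each retained UMI bin and each locus of the 175-nt analysis window,
template and polymerized read stacks are collapsed to strict-majority
consensus symbols (deletions are first-class symbols; ties yield no
call). A comparison produces `e = 1` if the consensuses differ, else 0.
Each read `j` of a stack is individually correct with probability

```
c_j = (1 - b_j)(1 - q_j)
```

where `q_j = 10^(-Q_j/10)` is its base-call error probability and
`b_j = 1 - prod_i (1 - 10^(-Q_i/10))` is the probability its 20-nt UMI
was misread (hence the read mis-binned). The false-consensus probability
`P_E` is the probability that incorrectly-called reads form a strict
majority of the stack — a Poisson-binomial tail in which a read agreeing
with the consensus is wrong with probability `1 - c_j` and a disagreeing
read with probability `c_j`; stacks deeper than 12 reads are subsampled
to 12 for this computation. A comparison is retained when the combined
two-strand probability `1 - (1 - P_E,t)(1 - P_E,p)` is at most `1e-5`,
and contributes the expected error `|e - P_E|`. Rates are expected-error
sums divided by the number of qualifying comparisons (molecules, not
reads).

Upstream, reads are binned by UMI through a prefix tree; single-pair bins
are rescued into a unique Hamming-distance-1 neighbour holding more than
5 mate-pairs; bins need at least 6 mate-pairs, both strands, and a
template:polymerized ratio within 1:3–3:1; template reads must match the
reference exactly inside the window; each strand needs at least 6 reads
at a locus. Loci whose pooled C→A rate reaches `5e-4` are excluded as
oxidative (8-oxoguanine) damage artifacts. Downstream, per-locus
replicate medians (after per-locus mean imputation of missing/zero
cells) feed two-tailed Wilcoxon signed-rank and Mann–Whitney U tests at
α = 0.05, fold changes, and a PCR error-propagation extrapolation
`F(c) = 1 - (1 - e)^(L·c)`.

## Worked example

Simulate a proofreading-deficient-like library (substitution rate
4×10⁻⁴ per base, deletions 5×10⁻⁵, insertions 2×10⁻⁵), then call errors:

```python
from umierr import (SimConfig, simulate_library, TemplateSpec, read_pairs,
                    build_bins, rebin_singletons, filter_bins,
                    call_bin_errors, CallConfig)
from umierr._template import DEFAULT_TEMPLATE

cfg = SimConfig(
    template=DEFAULT_TEMPLATE, n_molecules=2000,
    substitution_rate=4e-4, deletion_rate=5e-5, insertion_rate=2e-5,
    product_length_mean=240, product_length_sd=8,
    phred_mean=30, phred_sd=0, seed=7,
)
lib = simulate_library(cfg)
lib.write_sam("library.sam")

spec = TemplateSpec.from_layout(DEFAULT_TEMPLATE)  # primer 24 nt, UMI 20 nt, window 175 nt
obs = read_pairs("library.sam", spec)
bins, _ = rebin_singletons(obs, build_bins(obs))
bins, _ = filter_bins(bins)
calls, stats = call_bin_errors(obs, bins, CallConfig(), seed=1)

n = int((~calls["is_insertion"]).sum())
subs = calls[calls["type"].astype(str).str.contains(">")]
dels = calls[calls["type"].astype(str).str.startswith("del")]
print(f"qualifying bin-locus comparisons: {n}")
print(f"substitution rate: {subs['expected_error'].sum() / n:.3g}  (injected 4e-04)")
print(f"deletion rate:     {dels['expected_error'].sum() / n:.3g}  (injected 5e-05)")
```

prints

```
qualifying bin-locus comparisons: 289205
substitution rate: 0.000405  (injected 4e-04)
deletion rate:     4.15e-05  (injected 5e-05)
```

The 2000 molecules yield ~289k qualifying per-molecule, per-locus
comparisons; the recovered substitution rate (4.05×10⁻⁴) sits within
sampling error of the injected 4×10⁻⁴, and the deletion estimate is
built from 12 consensus-confirmed deletion calls (15 deletions were
injected inside the window; not every molecule passes the depth and
validation filters).

The same flow is available from the shell:

```bash
umierr simulate --n-molecules 2000 --condition 1G- --out-dir sim/
umierr call --sam sim/library.sam --reference sim/reference.fasta --out calls.tsv
umierr rates --calls calls.tsv --reference sim/reference.fasta --out-dir tables/
umierr selftest --n-molecules 5000   # 4-condition end-to-end recovery check
```

A full multi-condition run (`umierr run-all --config run.yaml`) writes
locus/context/indel rate tables, moving-average window profiles with
their GC correlation, condition comparisons, and a manifest with every
threshold and per-stage exclusion count.

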