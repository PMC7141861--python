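# Methods

## Scope

`strpop` genotypes microsatellites (short tandem repeats, motif length
1–6 bp) from aligned short reads, jointly across a population; screens a
panel of known pathogenic repeat expansions; estimates sample-specific
slippage rates against a kernel of reliable markers; and bins
multi-allelic genotypes for association analysis.  A synthetic-data
module generates diploid cohorts, trios and expansion carriers with
ground truth, and defines the study conditions for all simulation-based
checks.

## Genotyping model

An STR allele is a whole number of motif copies.  Library preparation
and sequencing introduce *slippage* (stutter): a read may report the
template allele shifted by whole motif copies.  For a read `r` with
reported copy number `x` and a candidate template allele `a`, the
read likelihood is a two-component mixture

    P(x | a) = p_r · Q(x | a) + (1 − p_r) / |S|

where `S` is the finite candidate support (the distinct whole-unit read
values at the locus plus a ±1-unit neighbourhood), `p_r` is the read's
reliability, and `Q` is the stutter kernel:

* `Q(a | a) = 1 − s`;
* `Q(a ± k | a) ∝ s · dir · γ(1 − γ)^{k−1}` for whole-motif offsets
  `k ≥ 1`, with `dir = p_u` for gains and `p_d = 1 − p_u` for losses;
* the kernel is truncated to `S` and renormalized so it sums to one;
* values outside `S` or with fractional offsets receive only the uniform
  component.

`s` is the sum of a marker-specific rate `s_i` and a sample-specific
rate `s_j`, clamped to `[0.001, 0.95]`.  A diploid genotype `(A, B)`
draws reads from its haplotypes with equal probability, so the genotype
likelihood is `Σ_r log(½P(x_r|A) + ½P(x_r|B))`, maximized exhaustively
over all unordered candidate pairs.  The reported posterior is the
normalized likelihood of the best pair under a flat pair prior; a call
is high-confidence when it exceeds 0.90.  Ties break to the smaller
allele sum, then lexicographically.  Reads whose repeat tract touches a
read end only bound the allele from below; they are excluded from the
likelihood (unless no bounded read exists) and flow to the expansion
screen instead.

The semantics of `p_r` matter: it is the probability that the read
reports a value from the stutter kernel around its template — stutter
itself lives in `Q`.  Folding the stutter rate into `p_r` would count it
twice and, empirically, biases the kernel-based sample-slippage estimate
down by about 0.01.  The packaged default model therefore scores a
clean, well-anchored read ≈0.99.

## Read selection and attributes

Informative reads for a marker come from three sources: reads aligned
across the marker; unaligned reads placed at a mate that maps within
1000 bp of the marker; and reads aligned inside another catalog marker
of the same canonical motif whose mate maps within 1000 bp of the
target.  Motifs are canonicalized to the lexicographic minimum over all
cyclic rotations of the motif and of its reverse complement, so both
strands and all repeat phases form one motif class.  Duplicates and
secondary/supplementary alignments are dropped; mapping quality 0 is
accepted only for the latter two sources (such reads are informative
precisely because alignment failed).

The repeat tract of a read is the longest window whose per-base identity
to the periodic extension of the motif (best phase, best strand) is at
least 0.85; ties break to higher purity, then leftmost.  Because a long
pure core can drag ~15% mismatching flank bases into the window, the
terminal mismatching bases of the winning window are trimmed, so tracts
start and end on matching bases.  Reported copy number is window length
divided by motif length.

Each read gets six attributes, in frozen order: tract purity; matched
left- and right-flank lengths (bp, capped at 32); mean tract base
quality rescaled to [0, 1]; a mate-consistency indicator; and a capped
indel-in-flank count.  A logistic regression on these six attributes
yields `p_r`.  Population genotyping alternates: call all genotypes with
current `p_r` and marker parameters; label each read by whether its
rounded value matches a called allele; refit the regression (L2,
C = 1.0; skipped if labels are nearly single-class); re-estimate marker
parameters; stop when under 0.1% of calls change (max 10 iterations —
2–3 in practice).

## Marker parameter estimation

With at least 20 contributing samples (below that, packaged defaults
`s_i = 0.02`, `p_u = 0.15`, `γ = 0.85` are used — estimation from fewer
samples is unreliable):

* `s_i` — reliability-weighted fraction of reads deviating from their
  sample's called genotype by whole units, deviations measured against
  the nearer called allele;
* `p_u` — weighted fraction of slippage reads that gained repeats,
  `p_d = 1 − p_u`; with zero slippage reads the legacy constants
  (0.15 gain / 0.85 loss) apply.  A read equidistant from both alleles
  of a het has unambiguous slip magnitude but unknowable direction: it
  counts toward `s_i` but not the direction tally (attributing it to the
  nearer-by-convention allele inflated `p_u` substantially in het-rich
  cohorts);
* `γ` — matched to the weighted mean slip magnitude via `γ = 1/mean|k|`
  (geometric mean), defaulting when fewer than 5 slippage reads exist.

Known estimator limitations: slips that land exactly on the partner
allele of a het are censored (they look like ordinary reads), so `s_i`
is biased down by a few tenths of a percent, and the direction tally
inherits a small asymmetric censoring bias (~+0.005 on `p_u` at
`s = 0.05`).  Both are properties of count-based classification without
an EM step and are documented rather than corrected.

## Sample slippage and the kernel

A kernel marker is one whose population results show call rate ≥ 0.95,
`s_i ≤ 0.05`, at least two alleles at frequency ≥ 0.05, and mean
posterior ≥ 0.95.  A new sample's `s_j` maximizes, over the kernel, the
marginal read log-likelihood with genotypes integrated out under
Hardy–Weinberg weights from the kernel allele frequencies; 1-D bounded
optimization on [0.001, 0.5] (Brent), which a dense-grid check
reproduces to 1e-3.  By default 50 kernel markers with reads are
required.  The shipped `data/synthetic_kernel.tsv` is generated by the
package's own simulator and is for demonstrations and tests.

## Expansion screen

The screen never genotypes: an expanded allele is often longer than the
read length, so reads are drawn very unevenly from the two haplotypes
and an equal-draw genotyping model is unreliable there.  Instead, for
each of the 31 panel loci the screen recruits informative reads (all
three sources), and flags the locus if any read tract reaches the
pathogenicity threshold, or if the threshold exceeds what one read could
span (`threshold · motif > read length − 2·6 bp`) and at least one fully
repetitive read (tract within 3 bp of both read ends) is present.  A
single fully repetitive read suffices: the downstream action is manual
inspection, and sensitivity is the screen's purpose.  The threshold
comparison is inclusive (≥) for the same reason.  Lower-bound tracts
count at their observed value; no expansion-length extrapolation is
attempted.  The packaged panel is a literature-derived set of 31
repeat-expansion disorder loci (approximate GRCh38 coordinates, treated
as opaque); thresholds are in repeat copies, e.g. 50 for the DMPK CTG
repeat of myotonic dystrophy type 1.

## Allele binning

Bin schemes list explicit allele indices into the marker's
ascending-sorted allele list; groups must be disjoint and cover all
indices (no implicit remainder).  Binarization splits at a length
threshold (`short` < t ≤ `long`).  Posteriors and read counts pass
through unchanged — group-level posteriors are not recomputed.  The VCF
export encodes groups as symbolic alleles so biallelic association
tools can consume binned genotypes.

## Synthetic data

The generator mirrors the model exactly: reads per sample-marker ~
Poisson(coverage); haplotype Bernoulli(½); slippage with probability
`s_i + s_j`, magnitude Geometric(γ), direction Bernoulli(`p_u`);
substitution errors at 0.001/bp.  Defaults: 150 bp reads, 30× coverage,
`s_i = 0.02`, `s_j = 0`, `p_u = 0.15`, `γ = 0.8`, insert ~ N(400, 50).
Two granularities share the slippage draw:

* **sequence level** — full reads with flanks and mates on a toy
  reference (one contig per marker, 600 bp flanks), written as sorted
  indexed BAM.  Reads with fewer than 6 anchoring flank bases on both
  sides are emitted unmapped and placed at their mate, as an aligner
  would leave them — this is how expanded alleles produce the
  fully-repetitive unaligned reads the screen looks for.  The 24 flank
  bases adjacent to each tract are generated to break the motif's
  periodicity (a catalog marker delimits a maximal repeat, so reference
  sequence continuing it would belong to the marker), which makes tract
  detection exact in the noiseless limit.
* **allele level** — the read table (reported units + attributes)
  generated directly and fully vectorized, for large cohorts.

What the simulation does **not** model: mapping ambiguity beyond the
unmapped-in-repeat rule, GC and coverage bias, quality-score miscalibration,
indel sequencing errors, flanking indel polymorphism, and somatic
mosaicism.  Passing simulation checks therefore demonstrates internal
consistency of model and inference under the stated noise structure, not
performance on real sequencing data.

## Numerical and design notes

* Coordinates: marker files are 1-based inclusive; all internal
  arithmetic is half-open 0-based; conversion happens only at the file
  boundary.
* Likelihoods are floored at 1e-300 before logs; `p_r` is clipped to
  (1e-12, 1−1e-12).
* Determinism: a single `numpy` Generator seeds every stochastic step;
  identical seeds give byte-identical truth files and call tables.
* Degenerate inputs: an empty read list is a no-call, not an error; a
  cohort with zero deviating reads returns the slippage floor with the
  legacy direction pair; a panel locus on a chromosome missing from the
  BAM header yields an empty, unflagged report with a warning.
* Problem sizes: the trio-consistency experiment in
  `scripts/acceptance.py` runs 200 trios × 500 markers at the default
  conditions using the allele-level generator (~3 min, single CPU);
  test-suite simulations use 25–200 samples and 3–200 markers.
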