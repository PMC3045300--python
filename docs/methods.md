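# Methods

`ampdenoise` reconstructs the true sequences and abundances in a pool of
pyrosequenced PCR amplicons by modelling each noise source separately:
flow-intensity noise from the sequencer, single-base substitutions from the
polymerase, and chimeric splices from incomplete PCR extension.  This note
records the models, the parameters that matter, and the choices made where
the design was genuinely open.

## Flow-intensity model and filtering

A 454-style read is a flowgram: one light intensity per nucleotide flow
(order `TACG`), with a homopolymer of length *n* emitting an intensity
spread around *n*.  The package models this with a binned lookup
`d(f|n) = -log P(f|n)` at 0.01-intensity resolution for run lengths 0–9;
cells never observed during calibration take a finite cap (100 nats) so
arithmetic stays finite.  Runs longer than 9 reuse the length-9 column — an
approximation that matters only for extreme homopolymers the upstream
filter rarely passes.  The distance between a read and a candidate sequence
is the mean per-flow `d` over the common truncated length:
`d'(f, U) = sum_i d(f_i|u_i) / M`.

The model can be calibrated from any reads of known origin
(`calibrate_intensity_model`), serialised as a plain-text table, or taken
from the package's parametric default: per run length a discretised normal
centred on *n* with standard deviation `0.04 + 0.03 n` (background signal
`N(0.04, 0.03)` truncated at zero for n = 0), mixed with a 10^-3 uniform
outlier component on `[n-1, n+1]` that produces the occasional gross
miscall.  The growing spread and the mode sitting on the integer mirror
what calibration on real mock-community runs produces; the default is
regenerated on demand rather than shipped as a file.

Reads are filtered before clustering: exact IUPAC-aware tag+primer match;
truncation at the first intensity in [0.5, 0.7) (the half-open reading of
the published 0.5–0.7 noise band) or at the first frame of four flows with
no signal ≥ 0.5; rejection if that happens before flow 360; end-truncation
at flow 360 (GS FLX) or 720 (Titanium) to drop the noisy last 10% of
flows.  Truncation is to whole frames, which keeps the one-signal-per-frame
invariant testable and makes filtering idempotent.  The noise-band check is
applied to the full flowgram (whether it should run before or after primer
trimming is not specified anywhere we know of; the difference is a few
flows at the read start).

## Stage one: flowgram mixture EM

Filtered flowgrams are modelled as a mixture over L true sequences with
exponential kernels `exp(-d'/sigma_p)`, `sigma_p = 1/60`.  Component
centres are restricted to perfect flowgrams observed in the data (the
roundings of the reads), so the E and M steps reduce to indexing a single
precomputed read x candidate distance matrix; the M step's argmin scan over
all candidates is therefore exact and needs no pruning.  Initialisation is
complete-linkage clustering cut at `c_p = 0.01`.

Because `d'` is a literal mean of `-log P` values, every read carries its
per-flow entropy (~2–3 nats/flow) as an additive constant.  That constant
cancels exactly in the responsibility normalisation, so the EM is
unaffected, but a raw symmetrised `d'` would place every read pair far
above `c_p`.  The initialisation distance is therefore centred on each
read's distance to its own rounding:
`d_init(a,b) = [(d'(a,U_b) - d'(a,U_a)) + (d'(b,U_a) - d'(b,U_b))] / 2`,
clipped at zero — identically-rounding reads sit at 0 and `c_p` operates on
the scale of per-flow distance differences, which is where the information
about miscalls lives.

Convergence is `max |dz| < 1e-6` or 1000 iterations (no criterion is
standard; the likelihood trace is asserted non-decreasing to 1e-8 in the
tests).  Ties in the argmin/argmax break to the lowest candidate index
after ordering candidates by abundance descending then sequence
lexicographic, making runs deterministic.  Components no read maps to are
dropped; the exponential kernel's 1/sigma normaliser is identical across
components and iterations and is omitted from reported log-likelihoods.

## Stage two: sequence mixture EM under a PCR error model

Stage-one sequences, truncated to 220 bp (GS FLX; 400 bp Titanium) and
weighted by their read counts, are clustered again with the distance

`e(r, S) = [sum_l -log P(r_l|s_l) + gap penalties] / A`

over a global alignment of A columns.  `P(m|n)` defaults to substitution
frequencies measured on mock communities (transitions ~50x transversions,
the Taq signature); rows are renormalised at load to absorb printed
rounding.  The identity cost `-log P(x|x)` (~5e-4) is kept — the distance
is the literal negative log probability of the read given the template.
Alignment is Needleman–Wunsch with gap 15.0, reduced to 4.0 when the
inserted/deleted base equals either base flanking the gap point in the
ungapped sequence (a homopolymer extension/contraction, the footprint of
residual flow noise).  All alignment columns count toward A, terminal gaps
included.  Kernel scale `sigma_s = 0.033` and initial cut `c_s = 0.08`
(GS FLX defaults; 0.1/0.04 are the usual Titanium presets).  Weights enter
both the mixture proportions and the effective multiplicities, so output
frequencies sum to the input weight exactly.

## Chimera classification

Each sequence, in decreasing abundance, is tested against the pool of
sequences with equal or greater abundance (its possible parents, since a
chimera undergoes at least one fewer PCR cycle than either parent).  For
every parent the package computes forward and reverse DP row minima: the
optimal cost of aligning each query prefix (suffix) against *any* parent
prefix (suffix).  A spliced reconstruction with breakpoint *i* then costs
`fwd_P[i] + rev_S[i]` exactly, and the best pair and breakpoint fall out of
per-side minima without pair enumeration.  (Cumulative costs along the
single global traceback were tried first and rejected: the optimal global
path bleeds cost across the splice boundary, scoring exact bimeras ~0.13
instead of ~0.)  The reconstruction distance is normalised by query length;
parent overhangs are free, which for the homologous, equal-truncation
sequences involved differs from column-count normalisation by well under a
percent.

A candidate must reconstruct to within 0.15 (one standard gap per 100
columns) and at least as well as its closest single parent.  The three-way
alignment for parsimony is built by projecting both pairwise alignments
onto query coordinates (parent insertions dropped) rather than calling an
external multiple aligner; change counts on fixtures match hand counts.
Columns with three distinct states attribute no change (the ancestor is
ambiguous under Fitch parsimony).  The chimera index is
`I = -ln(p_B * p_A)` where `p_B` is the binomial tail probability that the
changes on the distant-parent branch are at least as concentrated in the
close parent's part as observed (part sizes in ungapped query positions),
and symmetrically `p_A`.  Classification is logistic in I with defaults
`alpha = -7.5`, `beta = 0.5` (the cross-dataset recommendation; training
with `logistic_train` supports dataset-specific fits).  Training uses a
binomial GLM (IRLS); a residual deviance of ~0 signals perfectly separated
classes, reported as non-convergence together with the still-finite
separating decision point.

## Evaluation machinery

* Per-base error rate: each read matched to its closest reference; summed
  differences over summed alignment lengths, x100.  Denoised data is scored
  as the sequence a read maps to, against the closest reference of the
  *original* read, so misassignment counts as error.
* Reference-based chimera labels: best 0-, 1-, 2-, 3-breakpoint spliced
  reconstructions from the references via dynamic programming over
  per-reference prefix-difference arrays; each extra breakpoint must
  improve the match by ≥ 3 nucleotides to promote the label
  (Good → Bimera → Trimera → Quadramera), and any label requires
  reconstruction distance < 0.15, else Unclassified.
* OTUs: percent differences from unit-cost global alignment
  ((mismatches + gap columns)/columns — the exact weighting used for OTU
  distances is a package choice), complete or average linkage, partitions
  at 0.1% increments.  Joint clustering of references and denoised output
  labels each OTU Good/Missed/Noise.

## Synthetic data generator

The generator emulates mock-community experiments: known templates at known
proportions, PCR, then flow simulation.  Substitutions: a molecule sampled
after c ideal-doubling cycles was newly synthesised in Binomial(c, 1/2) of
them, each synthesis substituting each base at the measured per-cycle rates
— so whole-run frequencies come out at ~p*c/2, consistent with the measured
totals.  Chimeras: a configurable fraction of reads, grouped into distinct
spliced species whose counts never exceed either parent's (the ordering the
classifier exploits), with breakpoints uniform on positions 30–190 so the
splice stays observable inside the analysed 220 bp prefix.  Flowgrams: each
flow drawn independently from the intensity model's column for its true run
length, padded with background draws past the template end and cut at the
platform's raw flow count.  Molecules are tracked by counts, not lineages;
primer bias, CAFIE/phasing, and quality scores are not modelled — passing
tests show the algorithms handle the modelled noise structure, not every
artefact of real plates.

Reference templates are rejection-sampled 300-mers: homopolymers ≤ 6 and at
least 230 bases inside the first 360 flows, so every template survives
truncation with its full analysed prefix.

## Benchmark and problem sizes

`ampdenoise.benchmark.run_benchmark` is the package's end-to-end check: 20
templates, 2000 reads, 30 cycles at the default per-cycle rates, 5%
chimeras, one CPU, a few minutes.  It reports exact reference recovery, 3%
OTU counts after removing reference-classified chimeras (the OTU-accuracy
procedure; de novo calls are reported separately), per-species chimera
sensitivity and parent false positives, and raw vs denoised per-base error
rates computed on non-chimeric reads only — including chimeric reads adds
the same large splice-mismatch term to both rates and obscures the
substitution/indel signal being compared.

## Known limitations

* The intensity default is parametric, not a table fitted to real runs;
  calibrate on real data where available.
* Candidate centres are restricted to observed sequences (by design, for
  traceability): a true sequence observed only in corrupted copies cannot
  be reconstructed.
* Sequences shorter than the truncation length are padded implicitly by
  terminal gaps in comparisons; amplicons much shorter than the read length
  are out of scope.
* The chimera index covers two-parent splices; higher-order chimeras are
  still usually caught (their best two-parent reconstruction is already
  biased) but are not modelled explicitly.
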