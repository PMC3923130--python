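# Methods

## Overview

`mirevol` links three properties of a microRNA repertoire measured between
two focal *Drosophila*-like species (a "reference", playing the role of
*D. virilis*, and a "partner", playing *D. melanogaster*):

1. **evolutionary age** — the rank (1..7) of the tree node at which the
   family originated, dated by parsimony;
2. **sequence divergence** — substitutions per site between orthologous
   hairpins, partitioned into seed, mature, and loop/stem-extension
   regions, as raw p-distances and Kimura two-parameter (K2P) distances;
3. **developmental expression** — small-RNA counts across an ordered series
   of 11 libraries (e0…e16 embryonic stages, larva, adult), normalized to
   reads per million (RPM).

The headline statistics are per-stage Spearman correlations of divergence
with expression, the expression share of divergence tertiles per stage, and
the transcriptome age/divergence indices

    TAI_s = Σ_i a_i e_is / Σ_i e_is        TDI_s = Σ_i n_i e_is / Σ_i e_is

with `a_i` the age rank, `n_i` substitutions per site, and `e_is` the
expression of microRNA `i` at stage `s`. Bootstrap standard deviations
resample microRNAs with replacement (B = 1000 by default).

## Parsimony dating

The species tree is rooted and ranked: each internal node carries an
integer age rank (1 = the youngest labelled clade, 7 = the root of the
sampled Bilateria). The tree is an input (Newick with `name|rank=K` node
labels); no automatic rank inference is attempted, since rank classes are a
curation decision. A family's origin is the MRCA of all species with a
homolog; its age is that node's rank. Unlabelled leaves inherit the parent
rank, so a family found only in the reference species dates to the terminal
branch's class. Families with several members (paralogs) inherit the age of
the oldest member, and younger members are flagged `duplication_inflated`.

Age assignment is monotone by construction: adding a species to the
presence set can only move the MRCA rootward.

## Ortholog pairing

Orthologs are mutual best hits under deterministic global alignment
(match +2, mismatch −3, gap open −5, extend −2; a gap of length L costs
−5 −2(L−1)). The match/mismatch scheme mirrors the classic short-sequence
BLASTN reward/penalty (+2/−3); hairpins are short enough that exact global
alignment is preferable to a heuristic search. Gap penalties are a design
choice (the sources of this scheme give none): stiff enough to discourage
spurious gapped hits between unrelated ~90-nt hairpins. A tie for the top
score on either side rejects the pair — accepted orthologs are unambiguous
1-to-1 calls. Optional synteny support requires a shared flanking gene id
on both the upstream and downstream side.

## Divergence estimation

Regions are defined on the reference sequence's ungapped coordinates:
mature arms from the annotation (GFF3, miRBase dialect, 1-based inclusive),
seed = positions 2–7 of each arm, outside-mature = hairpin minus the arms.
Rates are substitutions / non-gap sites; columns containing a gap or an N
are excluded from numerator and denominator, which keeps

    substitutions(hairpin) = substitutions(mature) + substitutions(outside)

exact on gap-free alignments. K2P corrects observed transition (P) and
transversion (Q) fractions for multiple hits,
`d = −½ ln(1−2P−Q) − ¼ ln(1−2Q)`; saturated inputs (non-positive log
arguments) raise a saturation error and are flagged rather than silently
clipped. Mature arms are additionally summarized by integer substitution
counts, classed 0 / 1–2 / ≥3, each arm separately (mature sequences are of
approximately equal length, so counts are comparable across microRNAs).
Downstream analyses default to hairpin-level substitutions per site as the
divergence weight; a mature-level switch is available.

## Expression processing

Reads are matched directly against hairpin sequences by windowed
substitution-only comparison (exact first, then best placement with ≤1
mismatch) — a deliberate desk-scale replacement for a genome aligner that
is deterministic and sufficient for hairpin-level counting of synthetic or
miRBase-style inputs. Filtering keeps reads of 19–24 nt mapping to at most
4 loci with at most 1 mismatch; contaminant classes (rRNA/tRNA fragments)
can be removed via a sequence blocklist. Reads shared by paralogous loci
with identical mature sequences are divided equally among the loci, which
conserves the true read total. RPM normalization divides by either the
microRNA-mapped or the genome-mapped library total; Spearman statistics are
invariant to this choice because within-library ranks are unchanged.

Detection ("expressed at stage s") means raw count ≥ 1 by default; the
threshold is configurable because no principled floor exists without spike-
ins. A microRNA whose count is ≥10× the next-highest in any library is
flagged as a single-library dominator and excluded from composition and
correlation analyses (but kept in raw outputs).

## Synthetic-data generator

The generator emulates every input of the study design with known ground
truth, so the pipeline's recovery can be measured end to end.

* **Families** are born on tree branches with configurable probabilities
  (default: mass concentrated on the youngest and oldest branches, the
  usual shape of deep microRNA phylostratigraphies) and inherited by all
  descendant species — presence tables are noise-free, so parsimony dating
  should recover every origin exactly, and does (tested at 500/500).
* **Sequences**: hairpins are uniform-random 90-mers with two annotated
  22-nt arms (positions 10–31 and 60–81). Orthologs evolve by a closed-form
  K2P site process with region rates seed 0.06 / mature 0.12 / outside 0.35
  expected substitutions per site (at family rate factor 1) and ts:tv 2:1.
  A family's rate factor declines linearly with age rank from 1.0 (rank 1)
  to 0.2 (rank 7), with lognormal scatter (σ = 0.4): old families evolve
  slower, reproducing the age–divergence gradient. Indels are off by
  default (divergence metrics are substitution-based); hairpin secondary
  structure is not modelled.
* **Counts**: stage `s` earliness falls linearly from 1 (e0) to 0 (adult).
  The log mean of microRNA `i` is
  `b_i − c·q_i + a·q_i·earliness_s`, with `q_i` the divergence quantile in
  [0, 1], `b_i ~ N(0, 0.8)`, conservation bias `c = 6.5`, and association
  strength `a = 6.0`. The quantile (rather than the raw rate) spreads the
  coupling evenly across the divergence spectrum and bounds the weight
  heterogeneity inside each tertile. Means are scaled so each library's
  expected total equals the depth (10^6 reads); counts are negative
  binomial with dispersion 0.3. Genome-mapped totals add a 150% non-microRNA
  background. With these values the early-embryo excess of fast-evolving
  microRNAs is large relative to counting noise — as it is in real data,
  where the decline is plainly visible — and the five headline ordering
  conditions (tertile share and TDI maximal at e0, minimal in adult; ρ
  least negative at e0, most negative in adult) hold for ≈95% of random
  seeds at n = 300 families. The adult-vs-larva contrasts are the tightest
  races, since those stages differ by only 0.1 in earliness.
* **Reads**: each microRNA emits its mature sequence, repeated its count
  times, so counts → reads → counts is the identity; contaminants (18-nt,
  30-nt, and a 22-mer implanted in five decoy loci) can be injected at
  stated fractions to exercise the filters.

What the generator does **not** emulate: genomic background for mapping,
cluster rearrangements, arm switching, hairpin folding, sequencing error,
adaptor remnants, or library-depth variation beyond counting noise.
Passing tests therefore demonstrate correct bookkeeping and estimator
behaviour under the stated model, not robustness to alignment artefacts or
annotation errors in real data.

## Numerical choices

* Weighted means (TAI/TDI, bootstrap replicates) are computed with centered
  weights, so the constant-weight case is exact in floating point.
* Alignment ties are broken by the aligner's canonical enumeration order;
  outputs are deterministic for fixed inputs.
* Tertile splits sort ascending with a stable identifier tie-break;
  remainders go to the lower (conserved) bins.
* The outlier rule uses ≥ (fold × next-highest), so an exactly 10× ratio is
  flagged.
* All randomness flows from one integer seed; derived stage seeds are
  offsets of it. Identical config + seed reproduces byte-identical tables.

## Problem sizes

Default runs use 300 families × 11 libraries at 10^6 reads per library,
B = 1000 bootstrap replicates; estimator-recovery checks use 200 replicate
pairs of length 1000. A full pipeline run (including the 300×300
reciprocal-best-hit search) takes ~10 s on one CPU.

## Known limitations

* Reciprocal-best-hit search is all-vs-all global alignment, O(n²) in locus
  count — appropriate for microRNA repertoires (hundreds), not genomes.
* K2P saturation is reported, not imputed; deeply diverged outside-mature
  regions of young families occasionally saturate.
* The expression model couples divergence to expression through a single
  monotone score; it cannot represent non-monotone stage profiles
  (e.g. purely zygotic pulses) except through noise.
* With deep libraries and a detection floor of one read, nearly every
  microRNA is "expressed at all stages", so the breadth contrast can be
  degenerate on synthetic data; the pipeline then records it as
  unavailable.
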