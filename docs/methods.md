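# Methods

## Screen model

A saturation-mutagenesis screen replaces one codon of a single-copy
essential gene with all 64 possibilities and follows variant abundance by
amplicon sequencing at days 0.5 (12 h), 2, 4 and 6 after template delivery.
The simulator and the scoring model share one growth law: each codon *c* has
a relative growth rate *w<sub>c</sub>* per day (dimensionless, 1 = neutral,
0 = lethal), abundances evolve deterministically as

  a_c(t) = a_c(t₀) · w_c^(t − t₀),  renormalized to sum to 1,

and sequencing draws a multinomial sample of the configured depth at each
timepoint. There is no drift term and no sequencing error by default: the
counting stage is an exact-match classifier, so error-free reads keep the
regex brute-force oracle exact and make every discrepancy between pipeline
and oracle a genuine defect. Consequences for interpretation: passing tests
demonstrate correctness of the arithmetic and the recovery logic under
multinomial sampling noise only — they say nothing about PCR bias, indel
repair outcomes, chimeric reads or base-call errors, which real screens
contain and which the exact-match counter silently routes to the
unclassified bin.

Key screen parameters, defaults and rationale:

| parameter | default | rationale |
|---|---|---|
| timepoints_days | 0.5, 2, 4, 6 | the screen's sampling days; day 0.5 is the baseline |
| depth | 50 000 pairs/sample | deep enough that lethal-class depletion is resolvable above the pseudo-count floor |
| replicates | 2 | duplicate libraries per edited residue |
| editing_fraction | 0.5 | the bulk edited fraction at 12 h is not measurable in advance; clone screens span roughly 8–95 % depending on the site, so a mid-range value is used |
| read_length | 100 | short-amplicon paired-end geometry; the randomized codon must fall inside one mate |

## Scoring chain

1. **Depth normalization.** factor_s = total_s / mean(totals); counts are
   divided by factor_s. The "total" is the sum of the 64 classified codon
   counts — the counter's own output — not the raw pair count, so unedited
   molecules do not distort the correction. The mean normalized total
   equals the mean raw total by construction.
2. **Replicate averaging.** Arithmetic mean per codon at each timepoint;
   missing replicates are averaged over what is present, with a warning.
3. **Baseline ratio.** score = (n(t)+ε)/(n(t₀)+ε) with ε = 0.5. At finite
   depth, lethal codons reach zero counts; a symmetric half-count
   pseudo-count keeps scores finite and leaves well-populated entries
   essentially untouched. The fixed ε means the full chain is only
   asymptotically scale-invariant; the normalization step itself is exactly
   scale-equivariant.
4. **Amino-acid aggregation.** Mean over synonymous codons; TAA/TAG/TGA
   pool into the stop class `X`. Mean (not median) matches the replicate
   treatment and keeps the six-codon classes comparable to the
   single-codon ones.
5. **Tolerance calls.** logo weight = log2(score_aa / score_K) at the final
   day, K being the wild-type residue at every targeted position here.
   Defaults θ_hi = −1 (tolerated at or above), θ_lo = −3 (not tolerated at
   or below). These are explicit, configurable renderings of what is
   otherwise a qualitative reading of a day-6 logo; with lethal classes
   sitting 8+ log2 units below lysine and neutral classes within ~0.2, the
   calls are insensitive to the exact thresholds over a wide range.
6. **Library pooling.** Duplicate libraries are pooled by summing raw
   counts before normalization (default); score-averaging is available as
   an alternative mode, since published descriptions of pooling are
   ambiguous between the two. A pairwise log-count correlation is reported
   as the replica-concordance diagnostic.

## Template design

Recoding chooses, per codon, a synonymous codon with G or C in the third
position (every amino acid and the stop class has at least one in the
standard code), minimizing Hamming distance to the original with
alphabetical tie-breaks so the output and its change count are
deterministic. Codons overlapping a Cas9 guide site are solved jointly by
exhaustive search over their synonymous G/C-third options (a 23-bp site
spans at most 9 codons with at most 3 options each): the minimal-change
assignment that both destroys the NGG PAM and mismatches ≥ 2 protospacer
bases is taken, falling back to either condition alone when both are
unachievable. Guide matching is strand-aware and the edited sequence is
re-searched for an exact protospacer+PAM hit as a final invariant.

ssODN design places the edited core (target codon plus guide span, extended
to codon boundaries) between exact homology arms of 25 nt. Tag codons
inside the guide site take the synonymous option with the *most* base
changes — the opposite preference from recoding, because tags exist to
maximize divergence from the unedited locus: they must destroy the PAM on
their own (the randomized codon cannot be relied on, since NNN can
regenerate any base) and must yield a 20-mer absent from the reference on
both strands, which becomes the edited-allele-specific primer site. The
novel-k-mer search window may extend into the arms, where novelty still
derives from the covered tag bases. A codon deletion is rejected if the
collapsed sequence recreates the guide site.

## Amplicon counting

A pair is assigned to codon *c* iff either mate, forward or
reverse-complemented, contains flank_left + c + flank_right exactly, with
12-nt flanks by default (shorter than 8 is rejected). Mate 1 takes
precedence when the mates disagree; disagreements are tallied for QC.
Codons containing N are unclassified. The edited fraction is the share of
pairs containing any diagnostic tag k-mer on either strand; tag k-mers are
extracted from windows shifted off the randomized codon so they are
invariant to the codon a molecule carries.

## Polycistronic genome model

Units are built by pairing each TSS with the next TTS in its transcription
direction per chromosome and strand; interleaved or unpaired sites and
overlapping units are rejected. Junctions between genomically adjacent
units are classified from the two facing ends: TSS/TSS divergent, TTS/TTS
convergent, otherwise tandem, irrespective of gap size. Gene distances are
measured along transcription from the unit TSS to the gene's 5′ end and
from the gene's 3′ end to the TTS, so d_TSS + span + d_TTS equals the unit
length; "within 10 kbp" is a strict inequality on d. Genes are assigned to
the unit containing their midpoint (boundary-spanning genes draw a
warning); genes outside every unit are flagged and excluded from cohorts.
A gene near the sites of two short units is counted only for its own unit.

The simulator draws unit strands as a chain that keeps the previous strand
with probability equal to the configured tandem proportion; because
divergent and convergent junctions necessarily alternate along a
chromosome, their achievable shares are equal and the generator splits the
non-tandem mass evenly between them. Genes are laid out with a first-gene
offset ~ Exp(2.7 kbp), intergenic spacing ~ Exp(1 kbp) and gamma-distributed
lengths (mean 1.5 kbp), giving ~50 genes per unit over ~125 kbp — the scale
of a trypanosomatid Pol II polycistrome. The expression defect is
log2FC = −β·max(0, 1 − d_TSS/w) + N(0, σ) with w = 10 kbp; per-condition
replicate log2 abundances (default 3 per condition, SD 0.3) feed a per-gene
Welch t-test and Benjamini–Hochberg correction to produce the FDR column,
standing in for the count-model fit that real data would receive upstream.

## Cohort statistics

t-tests are Welch (unequal variance), two-sided, cohort versus complement;
the complement includes all in-unit genes not in the cohort, which slightly
shifts the null when another cohort carries a true effect — the power
analyses account for this. The χ² test is a goodness-of-fit of (n_up,
n_down) at FDR < 0.01 against 50:50 within the cohort, 1 df, no continuity
correction, so the statistic is exactly (n_up − n_down)²/(n_up + n_down); a
2×2 cohort-versus-background variant is available behind a flag because the
within-cohort construction is a modelling choice, not a forced one. Ratios
between comparisons are reported to 1 decimal and decreased fractions as
integer percentages. No cross-cohort multiplicity adjustment is applied.
β is recovered by ordinary least squares of measured log2FC on the
proximity ramp (with intercept), negating the slope.

## Problem sizes and numerical choices

Simulation-backed checks use depth 10⁵ for rank recovery (Spearman across
all 64 codons), depth 2×10⁴ over 20 seeds for tolerance-call stability, and
45-unit (~2 250-gene) polycistromes over repeated seeds for cohort power,
with a single 300-unit (~15 000-gene) genome for β recovery, where the
regression standard error (~0.017) comfortably resolves a 10 % band around
β = 0.5. Coordinates are 0-based half-open throughout; strands are "+"/"−";
all generators take explicit integer seeds and are byte-identical across
runs for a fixed seed.

## Known limitations

- No error model in reads, no PCR or GC bias, no UMI handling; the counter
  is exact-match by design.
- The replicate-measurement model behind the FDR column is Gaussian on
  log2 abundances, not a count GLM; FDR calibration on real count data
  will differ.
- Logo output is a signed weight matrix (TSV) plus a simple matplotlib
  rendering rather than a stacked-letter logo.
- Tolerance thresholds are screen-calibration-dependent; the defaults suit
  screens where lethal classes collapse to the pseudo-count floor.
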