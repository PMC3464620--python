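# Methods

## The discovery model

`mirscout` implements the classical cluster-then-fold strategy for plant
miRNA discovery.  Its premise: a genuine miRNA locus produces a small
number of distinct, highly abundant read species that map compactly to the
genome, inside a region that folds back into a thermodynamically unusual
stem-loop, with the mature read sitting on one helix arm opposite its star
strand.  Each stage encodes one aspect of that premise, and each stage's
thresholds are the values standard in the plant small-RNA literature:

| parameter | default | meaning |
|---|---|---|
| `min_abundance` | 5 reads | minimum total tag count to consider mapping |
| `max_hits` | 16 | tags with more genomic occurrences are treated as repeats and dropped |
| cluster gap | 200 nt | maximum distance between neighboring hits in one cluster |
| cluster size | ≤4 non-overlapping sRNAs | more implies a siRNA-like locus |
| strand purity | ≥90% | clusters must be transcribed from one strand |
| `window_ladder` | 75 / 150 / 250 nt | flank sizes folded around the candidate |
| hairpin checks | ≤3 consecutive mismatches; ≥17/25 centered pairing; ≥75 nt; ≥50% paired | structural definition of a pre-miRNA |
| `randfold_cutoff` | p ≤ 0.1 | folding stability vs. dinucleotide shuffles (99 by default) |
| `mfei_threshold` | 0.7 | MFEI above this marks a likely miRNA precursor (reported, not filtered on) |
| `e_threshold` | 10⁻³ | reference hit at or below this e-value ⇒ "known" |
| duplex rules | ≤4 total, ≤2-runs, no adjacent non-WC in 2–12, WC at 10–11, ≤2.5 in 1–12, energy ratio ≥0.74 | target-site acceptance |

MFEI uses AMFE = |MFE|/length×100 and MFEI = AMFE/GC%; both are reported as
positive magnitudes.  Candidates are *not* filtered on MFEI — the quantity
is the field's descriptive statistic for separating miRNA precursors from
tRNA/rRNA/mRNA folds, and the pipeline reports it per candidate.

### Window ladder

The window size around a candidate is genuinely ambiguous: published
precursors in related monocots range from 75 to >300 nt, so a single
75 nt flank cannot capture them all.  We fold a ladder of windows (75, 150,
250 nt flanks), trim each to the smallest stem-loop enclosing the mature's
pairing region, and keep the most stable trimmed hairpin that passes every
check.  Trimming walks the enclosing helix outward through bulges and
internal loops and stops at a multiloop branch, so a long window cannot
drag unrelated structure into the precursor.

### Folding backend

The default folder is an in-package energy-minimisation DP over non-crossing
structures: Watson–Crick and G:U pairs, energy contributed only by stacks of
adjacent pairs (a Turner-magnitude stack table, kcal/mol), hairpin loops of
at least 3 nt, and a helix-initiation penalty of +4.0 kcal/mol charged when
a pair closes any loop.  The penalty is the scale of measured loop
initiation terms and is load-bearing: without it an energy model built from
negative stack terms alone over-pairs random sequence, and the hairpin
checks lose their specificity.  MFE is ≤0 by construction and exactly 0
when pairing is not worthwhile (e.g. homopolymers).  ViennaRNA (python
bindings or the `RNAfold` binary) is wired as an optional backend; the
structural checks are defined on the fold contract (structure string + pair
table), and the test suite verifies that validation verdicts on canonical
and defective fixtures agree between backends.

G:U counts as *paired* for all structural checks (folding treats the wobble
as a pair); "mismatch" in the mature-region check means a position with no
partner on the opposite arm.  A mature-region base paired *within* the
mature (local self-structure) does not count as duplex pairing.

### randfold

p = (k+1)/(n+1) over n dinucleotide-preserving shuffles (Altschul–Erikson
Euler-path construction; mononucleotide mode available), where k counts
shuffles folding at least as stably as the original.  Under the null
(uniform random sequence) p is uniform on {1/(n+1), …, 1}; the test suite
KS-tests this at n = 500 sequences.  Note a selection effect that any
implementation of this workflow shares: *conditioned on passing the hairpin
checks*, randfold p is far from uniform, because the checks themselves
select stable folds.  Specificity against random genomes therefore rests on
the structural checks, and the decoy false-positive count is compared
against the 10% null expectation of the number of window folds attempted —
the spec-level quantity a practitioner can actually predict.

### Star inference and confidence classes

The star span is inferred from the mature's pairing partners under
antiparallel duplex geometry with 2 nt 3' overhangs; each paired mature
position votes for where the duplex ends fall and the median is taken,
which is exact for substitution bulges and robust to 1–2 nt helix slippage
at the mature ends.  A candidate is class I iff the inferred star sequence
is itself present, exactly, among the filtered tags of any library — the
community criterion for a high-confidence annotation.  Mature-only
evidence, however abundant, stays class II.

### Known/novel and conservation

Candidates are aligned to reference mature sets with a local aligner
(match +1, mismatch −3, gap −5) and a Karlin–Altschul e-value over the
total reference length (λ solved for the scoring scheme, K = 0.711,
uniform composition).  "No hit at e ≤ 10⁻³ ⇒ novel" is the one sensible
reading of the classification rule; the threshold is configurable.
Conservation in another genome re-runs the structural half of discovery
(exact mapping, window ladder, trim, validate) with no abundance
requirement — a mature mapping into non-hairpin context is "absent".

### Expression and targets

TPM uses the library's filtered read total as denominator — the only
per-library total the workflow retains after trimming and contaminant
removal; users with mapped-read totals can pass those instead.  Detection
is TPM > 0 (configurable).  The duplex model for targets is ungapped: the
rules speak only of mismatches and wobbles, so bulged target sites are out
of scope and documented as such.  The R6 energy rule is a *ratio* to the
perfect-complement duplex, making it robust to the choice of stack table.
G:U at cleavage positions 10–11 is disallowed by default
(`allow_gu_cleavage_site` flips this), and G:U counts 0.5 toward every
mismatch tally.

GO enrichment is the standard singular enrichment analysis: upper-tail
hypergeometric p per term with Benjamini–Hochberg correction across terms.

## The synthetic-data generator

The generator emulates the ten-library stress design of the motivating
study: two pathogen-infection libraries (control/inoculated), four drought
libraries (tolerant/sensitive × 0 h/24 h), four salt libraries (0/1/6/24 h).
Reads are 36 nt: a 20–30 nt insert followed by the 3' adapter, emitted as
FASTQ with constant quality — base-quality filtering is treated as already
applied upstream, and no sequencing-error model is simulated.  Planted
precursors are perfect stems with 1–2 isolated substitution bulges opposite
the mature, spaced ≥8 nt apart (real precursors have isolated bulges; a
perfect stem is avoided because the mature read would map antisense to its
own star arm and distort cluster strand purity).  Star reads default to 10%
of mature reads, reflecting how rarely the passenger strand is sequenced;
star-negative loci get none, giving class assignment a known answer.  Noise
reads are uniform random 20–30-mers, a configurable slice low-complexity or
N-containing to exercise the filters; contaminants are random 20–24-mers
listed in the contaminant FASTA and spiked into every library.

What the generator does **not** emulate — genome repeat structure,
sequencing errors, expression dispersion across biological replicates,
family-level sequence similarity between loci — bounds what the tests show:
recovery and specificity results demonstrate the pipeline's logic is
correct and calibrated on clean signal, not its performance on a real
polyploid transcriptome.

Validation problem sizes (chosen to exercise every code path at desk
scale): 30 planted loci on 3×60 kb chromosomes for recovery; a 100 kb
single-chromosome decoy with 50 genome-derived tags for specificity; 500
random 80-mers for randfold calibration; 10⁴ random duplexes for the rule
engine vs. brute-force oracle.

## Printed-table fixtures

The class-I electronic-northern matrix (37 miRNAs × 10 libraries), the
class-I target catalog (sugarcane target lists and sorghum conservation
flags), and the whole-catalog totals (1 975 targets/483 miRNAs in
sugarcane; 895/373 in sorghum) ship as TSV fixtures under
`src/mirscout/data/`, so their summary logic — assay-specific count,
high-abundance count, distinct matures, conserved-target count, average
targets per miRNA — can be recomputed offline.  The absolute TPM values in
the matrix are not recomputable (their per-library denominators were never
published); only the threshold/partition logic over the printed values is.

## Known limitations

- The internal energy model is deliberately reduced (stacks + a single
  initiation penalty); its MFEs differ from full Turner-model values by
  roughly a scale factor, which MFEI and randfold absorb but absolute MFE
  comparisons would not.
- Exact-match mapping only (mismatch tolerance is a config knob default 0);
  cross-species mapping misses diverged loci.
- Multi-branched precursors and bulged (gapped) target duplexes are out of
  scope.
- The built-in aligner sidesteps BLAST's word-size behavior on 21-mers;
  e-values agree with BLAST for near-identical hits but are not
  bit-for-bit BLAST e-values.
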