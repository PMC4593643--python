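# Methods

## Problem and model

`lncscan` frames lncRNA identification as balanced binary classification of
transcripts: protein-coding (PCT, positive) vs long non-coding (LNCT,
negative). The classifier is an RBF-kernel SVM over six per-transcript
features spanning three signal families — transcript sequence (stop-codon
frame asymmetry), predicted coding segment (ORF score), gene structure
(transcript length, exon count, average exon length) and evolutionary
conservation (mean exonic PhastCons-like score). The feature-extraction
layer additionally computes a wider candidate set (14 tri-nucleotide
frequencies, GC content, CDS length and CDS percentage) used for
single-feature AUC ranking and for experimentation with other subsets.

Assumptions worth making explicit:

* The transcript models in the input GTF are trusted; no transcript
  assembly or boundary refinement is attempted.
* The spliced sequence (5'→3' mRNA orientation) is the unit of analysis;
  introns contribute nothing except through gene structure counts.
* Conservation is positional and unstranded; the `consv` feature is the
  base-weighted mean over exonic positions (not a mean of per-exon means —
  the two differ for unequal exon lengths, and base-weighting treats the
  transcript as the sampling unit).
* Classes are roughly balanced at training time; no class weighting is
  applied.

## Feature definitions and conventions

* **Stop-codon standard deviation.** Codons are read non-overlapping at
  frame offsets 0/1/2 of the spliced sequence (translation semantics); the
  statistic is the population standard deviation (divisor 3) of the three
  counts. A long ORF keeps one frame nearly stop-free while the other two
  accumulate stops at the background rate (~3/64 per codon for uniform
  composition), so coding transcripts show a characteristically uneven
  frame split.
* **Tri-nucleotide frequencies** use overlapping windows normalized by
  window count (L−2); windows containing N count in the denominator only.
* **GC content** counts G+C over the full length, N again in the
  denominator only.
* **Coding-segment prediction** enumerates every maximal ATG→stop ORF in
  the three forward frames (nested ATGs do not open new ORFs; codons
  containing N match neither ATG nor a stop) and scores each as
  `length(nt) + 25·[favorable start context] + 25·[in-frame stop]`.
  The start-context bonus requires both context positions (−3 and +4
  relative to the ATG) to exist and match A/G and G respectively; an ORF at
  the very start of a transcript gets no context bonus. Ties in score break
  toward the longer ORF, then the smaller start offset, making the
  prediction fully deterministic. The scorer is intentionally transparent
  rather than a reimplementation of any external CDS predictor: because the
  classifier is retrained on features produced by this scorer, only the
  ordering information it carries matters, not its absolute scale.
* **Scaling** maps each feature linearly so the training minimum → −1 and
  maximum → +1 (svm-scale convention). Features constant in training map
  to 0 for all inputs; values outside the training range extrapolate beyond
  ±1 by design — clamping would discard ranking information at predict
  time.

## Classifier

`sklearn.svm.SVC` with RBF kernel. Grid search over C ∈ {2⁻¹…2⁷},
γ ∈ {2⁻⁷…2¹} (9×9) with stratified 5-fold cross-validation selecting
highest accuracy; fold shuffling is seeded and the seed is stored in the
model metadata. The decision rule is `score > 0 → PCT` (a score of exactly
0 is conservatively called LNCT, i.e. the tie favors the non-coding class).
The persisted model is a single joblib archive containing the SVM, the
scaling parameters, the ordered feature-name list, the label map and
training metadata, so prediction needs no side files; a format-version
field guards against loading foreign or stale archives. Scoring refuses
feature matrices whose column names or order differ from training.

Known numerical caveat: label-swap antisymmetry of the decision scores
holds only to the SMO solver's convergence tolerance (~1e−3 with sklearn
defaults), not to machine precision.

## Evaluation

SES, SPC, ACC and MCC follow the standard confusion-count identities with
PCT positive; any 0/0 ratio is reported as 0 with a logged warning (the MCC
denominator vanishes whenever a margin is empty, and 0 — "no information" —
is the common convention). The ROC is built by threshold sweep with ties
grouped, AUC by the trapezoid rule; this equals the Mann–Whitney
concordance probability with ties counted ½, which the tests verify against
direct pair counting. Single-feature ranking uses the raw feature value as
a score with orientation correction max(AUC, 1−AUC): the ranking measures
discriminative power regardless of the direction of the class contrast, so
anti-correlated features (e.g. stop-codon SD, higher in non-coding
transcripts) rank by their true signal rather than spuriously low. Ranking
ties break alphabetically for determinism.

Balanced dataset partitioning samples the requested per-class counts
without replacement from seeded permutations; train/test/remaining are
pairwise disjoint by construction. Redundancy filtering of test sets
against training sequences (CD-HIT-style) is out of scope; callers can
apply a precomputed keep-list of transcript ids before splitting.

## Synthetic data: what it emulates, what it does not

The generator writes a complete dataset (genome FASTA, pos/neg GTFs,
bedGraph conservation, truth table, JSON manifest) from one seeded RNG, so
output is byte-identical per (config, seed). Defaults encode the intended
class contrast:

| parameter | PCT-like | LNCT-like |
|---|---|---|
| transcript length (nt) | 1000–5000 | 300–2000 |
| exon count | 4–12 | 1–3 |
| embedded ORF | 100–400 codons | none; ORFs capped at 30 codons |
| mean conservation | 0.7 (sd 0.1, clipped to [0,1]) | 0.2 (sd 0.1) |

Background composition is uniform A/C/G/T. The embedded ORF is written into
the spliced sequence (ATG, a G-initial second codon and an A/G at −3 giving
it the start-context bonus, non-stop body codons, terminal stop) and then
propagated back into the genome across exon boundaries, so the spliced-ORF
path — not just single-exon transcripts — is exercised; with the context
bonus the embedded ORF can only be outscored by a strictly longer ORF,
guaranteeing a predicted CDS of ≥ 300 nt for every PCT. LNCT sequences are
cleaned by bounded iterative repair: any ORF longer than the cap has its
cap'th codon overwritten with a random stop, and the sequence is re-scanned
until clean (whole-sequence rejection sampling is hopeless here — a 2 kb
uniform sequence contains ~20 over-cap ORFs in expectation, so the
acceptance probability of a fresh draw is essentially zero). Conservation
is drawn once per transcript and held constant across its exons, which
makes the expected `consv` value exactly checkable. Gene loci never
overlap; strands are random; ~50 transcripts share one chromosome.

A null configuration (`null_config()`) gives both classes literally the
same generative parameters; a classifier trained on it should perform at
chance, and the test suite requires held-out AUC ∈ [0.4, 0.6] there.

What the generator does **not** emulate: realistic codon usage and hexamer
statistics, isoform structure sharing between transcripts of one gene,
GC/conservation covariation, repeat content, or sequencing/annotation
noise. Passing the end-to-end tests therefore demonstrates that the
pipeline is wired correctly and can recover a designed contrast of
textbook size — not that the shipped defaults reach any particular
accuracy on real annotations, which depends on retraining with real data.

## Problem sizes and numerical choices

The end-to-end checks use 200+200 generated transcripts split 100+100 per
class for training and held-out evaluation, sizes at which the full
pipeline (generation, feature extraction, 9×9×5-fold grid search) completes
in seconds while leaving the grid search non-trivial. Oracle comparisons
run 10,000 random sequences (length 3–3000) for the stop-codon statistic
and 1,000 random score/label instances (n ≤ 200) for AUC, both at 1e−12
tolerance. Degenerate inputs are pinned down explicitly: empty sequence →
no ORFs; sequence < 3 nt → zero stop counts and trimer frequencies; empty
conservation track → default score everywhere; constant features → scaled
to 0 and AUC 0.5; empty prediction input → empty output.

## Known limitations

* GTF parsing is deliberately narrow: 9-column lines with
  `transcript_id`/`gene_id` attributes; GFF3 and UTR/CDS feature
  interpretation are out of scope. Duplicate exon records are rejected
  rather than silently deduplicated.
* The conservation track is held in memory as a per-position map — fine
  for targeted regions and fixtures, wasteful for a whole-genome track.
* No probability calibration; the decision score is a ranking statistic,
  not a probability.
* A model trained with the conservation feature refuses to predict without
  a track (imputing zeros would silently shift every transcript toward the
  unconserved class).
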