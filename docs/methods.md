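# Methods

## CDR3 junction model

A TCRβ rearrangement is summarised by the clonotype key
(V gene, J gene, CDR3 amino-acid string). The CDR3 interval is defined at
the protein level: all residues strictly between the conserved `Y[YFLI]C`
motif at the 3′ end of the V segment and the `[FW]GXGT` motif within the J
segment. Both anchors are excluded, so clonotypes are reported without the
canonical leading cysteine of AIRR-style junctions (`ASSLAGELF`, not
`CASSLAGELFF`). On ingest of AIRR tables carrying only `junction_aa`, the
first and last residue are stripped to recover this convention.

Within a translated read, the V motif is the *rightmost* occurrence inside
the window of residues overlapping the assigned V span (plus two residues
of slack), and the J motif is the *leftmost* occurrence after it. The
conserved anchors are the innermost motif hits flanking the junction;
choosing rightmost/leftmost minimises spuriously long CDR3s when motif-like
strings occur by chance elsewhere in the segments. Failure reasons
(`no_v_motif`, `no_j_motif`, `empty_cdr3`) are reported per read rather
than raised, and tallied in the per-sample QC counters.

A junction is *productive* when the translated span from the V motif
through the end of the J motif contains no stop codon. Because both motifs
are searched in the single reading frame propagated from the V segment
(frame offset carried by the germline record and shifted by the alignment
position), frame consistency between the anchors holds by construction;
out-of-frame junctions surface as motif-search failures.

## Segment assignment

V and J calls use ungapped sliding identity: the V segment's 3′-terminal
window (default 60 nt) and the J segment's 5′ window (default 40 nt) are
slid along the read and scored by exact-match fraction. The best-scoring
placement per segment is kept (rightmost among ties for V, leftmost for J),
the best-scoring segment wins, and ties across genes resolve to the
lexicographically smallest name for determinism. Calls below the identity
threshold (`min_identity`, default 0.9) yield an `unassigned` outcome; a V
match ending after the J match begins yields `incoherent`. Indel-tolerant
alignment is deliberately out of scope: the amplicon reads the pipeline
targets are built from intact V/J ends, and substitution noise is the
error mode the identity threshold must absorb.

Frequencies use the productive-assigned denominator: `total_reads` of a
clonotype table is the number of reads that produced a productive junction,
not the raw read count. The QC side counts preserve the full accounting
(`productive + nonproductive + unassigned + incoherent = reads in`).

## Public-clonotype criteria

A clonotype is flagged public when it is present at ≥ `min_case_freq`
(default 1 %) in at least `min_case_fraction` (default all) of the case
samples and its maximum control frequency is strictly below
`max_control_freq` (default 1e-5, i.e. 0.001 %). Presence in a control
means at least one read; absence contributes frequency 0, not missing
data. The defaults mirror the observed regime: the weakest per-case
frequency of the index clonotype is 1.08 % and controls print as
"< 0.001 %". Detection is monotone in both thresholds, which the property
suite checks. Keys default to (V, J, CDR3) with a CDR3-only mode for
donor-level comparisons that are reported at CDR3 resolution.

CDR3 clusters collect clonotypes of the *same length* within Hamming
distance 1 of a seed (one amino-acid substitution; no indels), seed
included when present — so a cluster frequency is never below the seed
clonotype's own frequency.

Group contrasts report per-group n, mean and standard error of a
clonotype's frequency and Welch (unequal-variance) unpaired two-sided
t-tests for each group pair. Welch is preferred over the pooled-variance
variant because case and control frequency variances differ by orders of
magnitude in this setting. Groups of size 1 carry no standard error and
their pairs are skipped; two exactly constant groups with equal values
report t = 0, p = 1 (the statistic is undefined there and equality is the
only defensible call).

## Other statistics

- **Fold change**: per-gene sample frequency over the control-cohort mean,
  with a pseudocount defaulting to 1/(2 · max total reads) — below
  one-read resolution, it only prevents division by zero for genes unseen
  in controls. Log10 output is available; for display exports a clip to
  [−2, 2] covers the 10–100-fold dynamic range of interest.
- **PCA**: singular value decomposition of the column-centred usage
  matrix, computed on frequencies without unit-variance scaling (usage
  vectors are already compositional fractions on a common scale).
  Explained variance is reported as squared-singular-value fractions; a
  zero-variance matrix reports zeros rather than NaN.
- **qPCR ratio**: `2^(Ct_reference − Ct_target)` with no efficiency
  correction, floored at the assay detection limit 1e-4; "not detected"
  maps to the floor with a flag.
- Reported percentages round half-up to two decimals, matching the printed
  precision of the source tables (e.g. 3.995 % → 4.00 %).

## Synthetic data

The generator is the package's stand-in for the deposited raw sequencing
data and defines the conditions under which the pipeline is validated.

- **Germline**: random sense-codon V segments ending exactly at `Y[YFLI]C`
  codons and J segments beginning exactly at `[FW]GXGT` codons, all in
  frame 0. The J motif's X is drawn from the 19 residues other than T;
  with X = T a junction ending in `FG`/`WG` could complete a premature
  J-motif across the junction/J boundary and truncate extraction.
- **Reads**: V sequence + junction + J sequence, junction nucleotides from
  a fixed one-codon-per-residue table, optional per-base substitution
  errors. At error rate 0 every clonotype maps to a single read sequence,
  making extraction exactly lossless — the round-trip tests assert equality
  with the recorded truth, not approximation.
- **Abundances**: background clonotype weights are lognormal (default) or
  power-law; spike-in counts are *fixed* at round-half-up(frequency ×
  depth) rather than sampled, so planted frequencies are exact and
  table-level acceptance checks are deterministic. The remaining depth is
  multinomial over the background.
- **Background CDR3s**: random peptides of length 8–17, rejected if within
  Hamming distance 1 of any spike (keeps cluster tests unambiguous) or if
  they contain a `[FW]GXGT` match (which would truncate extraction and
  break the lossless guarantee).
- **Study-like cohort preset**: 7 blister cases, 12 tolerant and 44
  healthy PBMC samples. The public clonotype is planted at the seven
  reported per-case frequencies (1.08–42.85 %) and at 0 in controls; case
  V/J usage is skewed so the expected cohort-mean TRBV12-4 (31.62 %) and
  TRBJ2-2 (22.15 %) usage matches the reported blister means. The
  single-sample blister preset additionally plants two secondary TRBV12-4
  expansions — in real blister repertoires the V-usage skew is largely
  carried by clonal expansions, and anchoring most of the V mass in fixed
  spikes keeps the recovered usage within binomial noise of the target.
- **Single cells**: 30 cells sharing the public β clonotype with α
  partners split 25/4/1; panel expression is negative-binomial (shape 2)
  with baseline mean 4 and the cytotoxicity genes GNLY/GZMB elevated to
  mean 45, reflecting the CTL phenotype of the sorted cells.

What the simulator does **not** emulate: VDJ recombination realism
(nucleotide trimming and N-insertions), sequencing-quality profiles,
PCR amplification bias, shared background clonotypes between individuals,
and allele-level germline variation. Passing tests therefore demonstrate
the correctness of the pipeline's arithmetic and detection logic under the
stated generative model, not robustness to every artefact of real
repertoire data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 63-sample cohort at
depth 10⁵ at the clonotype-count level (the read layer is the identity at
error rate 0, which the read-level round-trip tests verify independently at
depth 10³–10⁴), and read-level extraction on a 10,000-read sample with
2,000 background clonotypes. Calibration of the Welch contrast uses 1,000
null replicates of two groups of 8. Frequency invariants are enforced to
1e-9; pairing-marginal consistency is exact up to float summation order
(asserted at 1e-12). All randomness flows through numpy `SeedSequence`
from a single user seed; equal seeds give byte-identical outputs.

## Known limitations

- The ungapped aligner does not handle indels or chimeric reads; such
  reads fall into `unassigned`/`incoherent` QC bins.
- Germline segments whose J motif deviates from `[FW]GXGT` need a
  corrected motif in the germline record to extract at all; the reference
  human J set is expected to be supplied by the user.
- The count-level cohort path assumes error-free reads; with positive
  error rates only the read-level path reflects extraction noise.
- CDR3-only publicity can merge convergent rearrangements with different
  V/J genes; the default key avoids this at the cost of splitting
  allele-level variants that gene-name normalisation does not unify.
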