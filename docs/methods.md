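# Methods

## The model

`rsnpscan` predicts promoter regulatory SNPs (rSNPs): common variants
(minor allele frequency > 1%) in proximal promoters that are expected to
alter transcription-factor (TF) binding and hence expression. The pipeline
has four stages.

**1. Pseudo-promoters.** For each gene, the 2000 bases immediately upstream
of the transcription start site (TSS) are extracted and every embedded
common SNP is set to its *major* allele. "2 kb from the TSS" is read as
upstream-only and TSS-exclusive: for a plus-strand gene with 1-based TSS
`t`, the interval is `[t-1-L, t-1)` (0-based half-open, `L` = 2000 by
default); for a minus-strand gene it is `[t, t+L)` reverse-complemented so
the TSS-proximal end is always rightmost. Whether any downstream sequence
belongs in the window is genuinely open; upstream-only is the standard
proximal-promoter convention and is a config default (`PromoterSpec.length`
and strand handling), not a claim of fact. Variants are evaluated one SNP
at a time with all other SNPs held at major allele — effects are reported
per SNP, and haplotype combinations are out of scope. If the reference base
matches neither allele the major allele is substituted with a warning: the
pseudo-promoter is defined by the SNP catalogue, not by the reference
assembly.

**2. Accessibility gate.** A SNP is only scored in cell lines whose
DNase-I open-chromatin track covers it. Intervals are 0-based half-open
after sort-and-merge; a 1-based position `p` is accessible iff `p-1` lies
in some `[start, end)`.

**3. Motif scoring.** JASPAR-style count matrices (PFMs) are converted to
log2-odds weight matrices with a background-proportional pseudocount:

    w[b,j] = log2( (n[b,j] + pc * q[b]) / (N_j + pc) / q[b] )

with pseudocount `pc = 0.8` (the JASPAR convention) and background `q`
uniform by default; both are configurable. A window's **relative binding
score** (RBS) is its log-odds score min-max normalized by the lowest and
highest scores the matrix can attain, so RBS ∈ [0, 1] with 1 at the
consensus. The original tool never published its scoring formula; the
min-max normalized log-odds is the standard "relative score" convention and
is consistent with the published score range (all reported values lie in
[0.61, 0.96] with an apparent 0.80 reporting floor). The floor therefore
remains a documented config default (`ScanConfig.rbs_floor = 0.80`), not a
recovered constant.

For a SNP, every window/strand combination covering its offset is a
candidate; minus-strand candidates score the reverse complement of the
window. Both alleles are scored at the **same** site — the (offset, strand)
maximizing `max(RBS_M, RBSm)` — so the affinity comparison is like-for-like
while site-creating alleles are still caught (the window is chosen by the
maximum over both alleles). Ties resolve to the smaller offset, then '+'
before '−'. Windows containing N are skipped.

**4. The scoring chain.** With `RBS_M`/`RBSm` the major/minor scores:

    affinity impact (%) = 100 · (RBSm − RBS_M) / RBS_M
    HR  = homotypic redundancy: non-overlapping same-TF sites with
          RBS ≥ floor on either strand of the major-allele promoter,
          counted greedily best-score-first (non-maximum suppression),
          floored at 1 for any SNP that passed the reporting gate
    HWF = 1 / HR
    FIF = affinity impact × HWF

Negative FIF predicts loss of TF affinity for the minor allele; the HWF
discounts the loss of one site among redundant copies. Calls require
`max(RBS_M, RBSm) ≥ rbs_floor` and `|FIF| > fif_threshold` (default 10).
The published threshold is stated only for positive FIF, but every
published |FIF| is ≥ 10.04, so the gate is applied symmetrically by
default; it is configurable. Whether HR should count sites promoter-wide or
only near the SNP is unstated in the source material; promoter-wide is the
default here. Positive FIF above the gate with `RBSm > RBS_M` is labelled
`new_tfbs_suggested`, following the published footnote ("positive FIF > 10
suggests the creation of a new TFBS"); an alternative reading — reserving
the creation label for sites the major allele does not already bind at
reporting strength, labelling the rest `increased_affinity` — is available
via `categorize(..., creation_requires_weak_major=True)`.

**5. Evidence aggregation.** Externally produced annotations (GWAVA and
FunSeq2 deleteriousness labels, DeepSEA eQTL probability, Ensembl effect
sizes, GTEx m-values, Expression Atlas TPM/FPKM) are ingested as data and
never recomputed. A variant is confirmed when ANY enabled clause holds:
either tool labels it deleterious; DeepSEA probability ≥ 0.5; m-value
> 0.9 (m < 0.1 predicts no eQTL effect, between is indeterminate); an
Ensembl effect size is present; or the host gene is expressed at least at
the "low" level (TPM/FPKM ≥ 0.5) in a relevant cell line. The published
expression bins leave a gap between 10 and 11; the low/medium boundary is
closed at 10. The DeepSEA cutoff 0.5 was chosen because every confirmed
probability in the packaged table is ≥ 0.55 and the sole missing value is
unconfirmed; GWAVA's own score cutoff is not published, so its labels are
ingested, never re-derived. The whole rule set is configurable
(`ConfirmRules`) because the source material never defines its confirmation
criterion operationally.

## Synthetic study conditions

The generator (`rsnpscan.synthdata`) emulates the shape of the real inputs
— 2 kb promoters, common biallelic SNPs, JASPAR-text matrices, per-cell-line
BED peaks — with full ground truth. Defaults, chosen once as the study
conditions:

| parameter | default | rationale |
|---|---|---|
| promoter length | 2000 bp | proximal-promoter window |
| GC content | 0.41 | human-like; shared between sequence background and PWM background so the planted-truth oracle stays simple |
| SNPs per gene | 8 | the real panel averages 110/14 ≈ 7.9 |
| effect mix | 0.3 / 0.3 / 0.4 | destroyer / creator / neutral, realized exactly by largest-remainder rounding |
| accessible fraction | 0.7 | majority of promoter SNPs fall in open chromatin in at least one of five cell lines |
| TFs | 8 | at most one planted site per TF per gene, so HR = 1 by construction |
| motif width | 16 | one maximally informative anchor column (counts 100/0/0/0) + 15 medium columns (73/9/9/9) |
| MAF | uniform(0.05, 0.5) | all planted SNPs are common |

The motif design makes the anchor column carry ~15–17% of the score range:
a destroyer (consensus → worst base at the anchor) loses ~15–17% RBS and
clears the |FIF| > 10 gate at HR = 1, while the ~80%-of-range threshold on
a 16-column matrix makes chance background matches rare. Planted slots are
spaced ≥ 48 bp apart so sites never overlap, SNP scan neighbourhoods never
touch a neighbouring site, and 25-bp accessibility peaks never cover a
neighbouring SNP. Truth labels are guaranteed, not merely probable: neutral
SNPs are rejection-sampled below the RBS floor for both alleles under every
matrix, and a gene whose random background happens to contain a spurious
same-TF site (which would inflate HR) or a motif match near a neutral SNP
is redrawn from the seeded stream (bounded attempts). Identical arguments
give byte-identical output files.

What the generator does **not** emulate: linkage disequilibrium, realistic
allele-frequency spectra, dinucleotide background structure, overlapping or
clustered real motifs, cell-line-specific peak breadth, or matrices with
JASPAR-like information-content profiles. Passing the recovery experiment
therefore shows the pipeline's plumbing and arithmetic are correct under
controlled conditions; it does not certify sensitivity or specificity on
real genomes, where motif similarity and background structure dominate the
error budget.

## Numerical choices

- All internal scores are full double precision; rounding to 2 decimals
  happens only in the report writer. `RSNPCall.hwf` is derived (`1/hr`
  exact), and the stored FIF is validated against `impact/hr` within print
  rounding so reports round-trip.
- Scan ties (equal best windows) resolve deterministically: smaller offset,
  then '+' strand. Homotypic-site suppression orders by (score desc,
  offset, strand) and suppresses any overlap regardless of strand.
- An all-uniform matrix builds a valid PWM (all weights 0) but has no score
  range; scoring it raises rather than returning 0/0.
- Multi-allelic VCF lines reduce to the most frequent ALT (logged,
  reversible by re-reading the source); an ALT frequency > 0.5 swaps the
  major/minor roles so MAF ∈ (0, 0.5] always holds.
- Output ordering is lexicographic (gene, rsid, cell line, TF) everywhere,
  so repeated runs are diff-identical.

## Problem sizes

The packaged experiments run at desk scale: the table validations are pure
arithmetic over 27 rows; the synthetic recovery experiment uses 20 genes ×
8 SNPs × 8 TFs × 5 cell lines (160 SNPs, ~230 calls), which completes in a
few seconds. Larger fixtures scale linearly in genes × TFs.

## Known limitations

- Single-nucleotide substitutions only; no indels, no phased haplotypes.
- One TSS per gene; alternative promoters and enhancers are out of scope.
- Motif scores are not calibrated to p-values; the RBS floor is a rank
  threshold, not a significance level.
- The confirmation rules reproduce an editorial pattern in the packaged
  evidence table and should be re-tuned for other evidence sources.
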