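# Methods

`hapedit` models the computational side of designing and measuring
allele-specific *haplotype excision* therapies: CRISPR guide pairs placed
on common heterozygous SNPs flanking a dominant disease gene, so that the
intervening segment — and the disease allele with it — can be excised from
whichever haplotype carries the mutation. The package covers three layers:
population-level therapy design over phased panels, digital-PCR
quantification of excision/inversion outcomes, and amplicon-sequencing
classification of repair junctions. Synthetic-data generators with
ground-truth sidecars stand in for raw experimental data throughout.

## Population coverage model

**Panel.** A cohort of `n` diploid individuals is represented as a
`(2n, s)` 0/1 matrix of phased haplotypes over biallelic SNPs
(`panel_io.PhasedPanel`). Alt-allele frequencies are always recomputed
from the matrix rather than trusted from VCF INFO fields, so every subset
of a panel is self-consistent. Internally all coordinates are 0-based
half-open; VCF positions are converted on read and write.

**Candidate therapies.** Common SNPs (default: alt frequency strictly
between 0.1 and 0.9) are collected from 50-kb windows on either side of
the gene body. Three strategies are compared:

- *mutation-specific*: one reagent per causative mutation, coverage
  accumulating by prevalence weight (uniform by default);
- *SNP pair*: two allele-specific guides; an individual is covered iff
  heterozygous at **both** SNPs. Phase is deliberately ignored — a double
  heterozygote is treatable on either haplotype because guides exist for
  both alleles of each SNP;
- *single SNP + bi-allelic*: one allele-specific guide plus one invariant
  guide cutting inside the gene (default: an intron-1-like coordinate);
  covered iff heterozygous at the single SNP.

Candidates whose excision interval overlaps an exclusion interval (e.g. a
neighboring co-regulated gene) are removed before selection. By default a
SNP pair must span the whole gene body.

**Greedy selection.** Therapy sets are built by greedy maximum coverage:
at each step pick the candidate heterozygous in the most not-yet-covered
individuals, remove those individuals permanently, repeat until a target
coverage or a therapy budget is reached or no candidate adds coverage.
Ties are broken toward the smaller excision span (smaller deletions are
preferable on safety grounds), then the lexicographically smaller label,
making selection fully deterministic. One two-guide pair counts as one
therapy unit by default; `count_per_guide=True` (CLI `--count-per-guide`)
doubles pair costs for the alternative accounting.

**Phasing.** For a genotype heterozygous at `h` sites, all `2^(h-1)`
phasings are enumerated and scored by the product of panel frequencies of
the two implied haplotypes, with a pseudocount of `1/(2N+1)` for
haplotypes absent from the panel (N individuals; proper likelihoods
without zeros). The call reports the log-likelihood ratio over the
runner-up; a single het site has a unique phasing (ratio = inf). The
enumeration is capped at 16 het sites. Recovery is bounded by the
population prevalence of the minor phase among double heterozygotes: the
frequency-product call cannot identify the rare individual who genuinely
carries the unlikely phase, so near-perfect (>= 99%) recovery is expected
only where the minor-phase prevalence is below 1%.

## Digital-PCR quantification

Partition positivity per fluorophore channel is summarised by the
standard Poisson inversion `lambda = -ln(1 - k/n)` (mean copies per
partition), with delta-method standard errors `sqrt(p / ((1-p) n))`
propagated through every derived ratio. All reported quantities are pure
ratios, so partition volume never enters.

- *Gain-of-signal excision / inversion frequency*:
  `100 * (lambda_edit / lambda_ref) * (ref_copies_per_genome /
  alleles_per_genome)`, with an RPP30-style two-copy reference; 50% is
  the ceiling for perfectly allele-specific editing.
- *Loss-of-signal excision*: `100 * (1 - lambda_internal / lambda_ref)`;
  negative point estimates are clamped to zero with a warning.
- *Fractional abundance*: `lambda_A / (lambda_A + lambda_B)`; symmetric
  counts give exactly 0.5 (the unedited-heterozygote null).
- *Expression ratio*: positive-partition count ratio (`raw_ratio`, the
  droplet-count convention) or Poisson-corrected ratio.
- *Multiplexed 4-color assay*: excision frequency as the ROX+/CY5+
  partition-count ratio; specificity as
  `(ROX+ FAM+ VIC-) / (ROX+ FAM+ VIC- + ROX+ VIC+ FAM-)`. Partitions
  positive for the excision probe and **both** allele probes are
  ambiguous (co-loading of an excised molecule with an opposite-allele
  template), always excluded, and reported as a fraction of all
  edit-positive partitions with a warning at >= 10%.

Both estimation modes (`raw` partition-count ratios and `poisson`
corrected occupancies) are available everywhere. The lambda-based
quantifiers default to `poisson`; the multiplex assay defaults to `raw`,
the convention its instrument software reports. At the low occupancies of
a typical reaction the two nearly coincide; at high loading `poisson` is
the statistically sound choice.

**What the partition simulator does and does not model.** Each template
molecule independently picks one of `n` partitions uniformly (multinomial
loading), so molecule counts are conserved exactly and per-partition
occupancy is asymptotically Poisson. Channel linkage is emergent: a
molecule carrying two probes (an excision junction physically linked to a
haplotype SNP) renders both channels positive in its partition. Optional
per-channel false-positive/negative rates model threshold misclassification
("rain"); amplitude clustering itself is out of scope — inputs arrive
binarized. Conditional on a fixed molecule count, occupancy counts are
*less* variable than binomial, so CI-calibration experiments additionally
resample each species' copy number Poisson around its expectation
(`sample_aliquot`) — the molecule-sampling randomness of drawing an
aliquot from bulk DNA, and exactly the generative model under which the
delta-method CI is nominal. Without it the intervals are conservative.

Default simulated assay conditions, chosen once: 20,000 partitions and
5,000 genome equivalents for two-channel reactions (reference occupancy
~0.5); for the 4-color assay, 8,500 partitions per well, 3 merged wells,
700 genome equivalents per well, 25% of alleles excised, 92% of excisions
on the target allele. The per-allele SNP occupancy of ~0.08 keeps the
ambiguous triple-positive fraction near 7–8%, under the 10% warning
threshold, while ~1,000 informative edit-positive partitions put the
specificity standard error near one percentage point.

## Amplicon read analysis

**Alignment.** Reads are aligned to their reference with affine-gap
scoring — match +2, mismatch -1, gap open -6, extend -1, free end gaps at
the read ends — so contiguous indels are preferred over runs of scattered
mismatches. Orientation is auto-detected by best-strand score.
Equal-length reads within the identity threshold take a hamming fast
path, which is exact under the substitution-only error model of the read
simulator. Indel positions are normalised by their alignment-equivalence
range (an indel inside a repeat can sit anywhere along it), so
window-overlap decisions do not depend on the aligner's arbitrary gap
placement.

**Allele deconvolution.** The read base aligned to the heterozygous SNP
assigns the read; a gap or foreign base there, or overall identity below
`1 - max_mismatch_rate` (default 0.1), leaves it unassigned. With
per-base error `e`, misassignment requires the error process to hit the
single SNP base *and* convert it to the opposite allele: rate `e/3` under
uniform substitution; the other two-thirds of SNP-position errors go to
unassigned.

**Indel quantification.** A read counts as edited iff its alignment
contains an insertion or deletion overlapping the inter-base window
`[cut - w, cut + w]` (default half-width w = 1; configurable since
published pipelines differ). Substitutions never count. The result is an
edited fraction plus a net-indel-size spectrum, typically computed per
allele after deconvolution. Cut sites are stored as 0-based inter-base
coordinates, the blunt SpCas9 cut 3 nt 5' of the PAM.

**Junction classification.** For a two-cut excision, the expected repair
junction is the concatenation of the sequence ending at the left cut and
the sequence starting at the right cut. Microhomology annotation finds
exact repeats (length >= 2, by default up to 10, with up to 4 nt of
offset from either cut) such that annealing the two copies deletes
`left_offset + right_offset + length` nt relative to the precise
junction — the characteristic "larger than expected" MMEJ deletions.
Classification matches each read against a candidate library in priority
order: precise junction, each microhomology-collapse junction, then all
±k small-indel junctions for k <= 3; a deletion explainable by a repeat
of length >= 2 is attributed to microhomology, while 1-nt repeats fall
through to the plain small-indel class. A strict substitution cap
(`tolerance`) is tried first; reads over the cap still closest to one
candidate at <= 10% mismatches take that candidate's class, so ordinary
sequencing errors do not leak reads into the imprecise class. Remaining
reads are aligned to the expected junction and reported as
`other_imprecise` with their net indel size; reads shorter than 30 nt are
unassigned. Fractions are reported per class over assigned reads, plus a
pooled imprecise total.

**Read simulator.** Junction reads realise a programmed mixture over
`precise`, `mh_del(k)` (requires the repeat to be embedded in the flanks;
`embed_microhomology` constructs it), `ins(k)` and `del(k)` classes;
allele-amplicon reads draw an allele (default 1:1), apply a per-allele
edit probability and signed-size spectrum at the cut, then substitution
errors. Reads are merged single sequences at constant Q40; no quality
modelling, PCR bias, chimeras or paired ends — so passing recovery tests
demonstrates estimator correctness under clean error statistics, not
robustness to library artefacts.

## Synthetic locus

The default panel generator draws 2 x 2,548 haplotypes i.i.d. from a
fixed distribution over 12 flanking SNPs (6 per side of a 40-kb gene):
two major fully coupled haplotypes (frequencies 0.34 and 0.26) giving the
strong cross-locus LD typical of a real disease gene, plus seven
recombinant minors (total 0.40) that decouple the flanks so different SNP
pairs cover different individuals. All alt frequencies land in (0.1,
0.9); pairwise double-heterozygosity spans ~26–37%, the scale observed
for real flanking-SNP pairs (32–41%). An upstream "neighbor gene"
exclusion interval removes the two most distal upstream SNPs from pair
and single+BA candidacy. At 2,548 individuals the greedy pair strategy
exceeds 50% coverage with 5 therapies (4 on the real reference panel,
which carries more recombinant diversity than 9 haplotypes can) and the
single-SNP+bi-allelic strategy exceeds 75% with 3–4; the mutation-uniform
curve needs 26 of 51 therapies for a majority, an exact desk computation.
What i.i.d. haplotype draws do not model: population structure, kinship,
and fine-scale recombination gradients — so coverage numbers on synthetic
panels are demonstrations of the algorithm, not population estimates.

## Numerical and interface choices

- Greedy ties: `(coverage gain, excision span, label)` — deterministic
  and reproducible across platforms.
- AF bounds strict (`0.1 < f < 0.9`): the boundary frequency is excluded;
  bounds configurable.
- Unphased or missing genotypes: default drops the site (the panel must
  be fully phased for haplotype counting); `drop_individuals` drops the
  affected samples instead. Both are logged with counts.
- Saturated channels (`k = n`) raise an error instructing dilution rather
  than returning an unbounded occupancy; `k = 0` returns exactly 0.
- Every generator is a pure function of (parameters, seed); CLI runs
  write `run_config.json` and `hapedit rerun` replays them
  byte-identically for deterministic stages.
- Test problem sizes: 100 reactions of 20,000 partitions for estimator
  calibration, 10,000 reads for junction-mixture recovery, 5,000
  individuals for Hardy-Weinberg-scale checks — sizes at which binomial
  3-SE bands separate real bias from sampling noise while the full suite
  stays fast.

## Known limitations

- Coverage treats every heterozygote as treatable; it does not model
  guide efficacy differences, PAM availability at a given SNP, or
  off-target constraints.
- dPCR inputs must be pre-binarized; amplitude thresholding and rain
  correction are out of scope.
- The loss-of-signal and gain-of-signal estimators agree on clean
  simulations by construction; on real data, deletions larger than the
  gain amplicon bias the two apart — that discrepancy is a property of
  the assays, not reproducible from these simulations.
- Junction classification assumes merged reads fully spanning the
  junction; partial overlaps beyond the minimum-length cutoff are not
  rescued.
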