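# Methods

## Transcript models and coordinates

A transcript is an ordered list of genomic exon intervals (1-based,
closed) in transcription direction — genomically decreasing for
minus-strand genes, which are first-class throughout — plus CDS bounds in
spliced-transcript (tx) coordinates.  Coding (c.) positions follow HGVS:
`c.1` is the A of the start codon; `c.N+k` / `c.N−k` are intronic offsets
anchored at the donor after coding base N or the acceptor before it.
Design choices:

* **UTRs.** Models may omit UTR content; c. numbering is anchored at the
  CDS start and 5′UTR (negative) positions are rejected.  The synthetic
  transcripts are fully coding (CDS = whole spliced mRNA) — nothing in
  the splice arithmetic depends on UTR presence.
* **Exon numbering.** Exon 1 is the first transcribed exon of the model
  as given.  Where a gene has an alternative first exon, the numbering of
  a model is the numbering of its exon table; fixtures pin one table.
* **Intronic genomic→c. mapping.** The first half of an intron anchors to
  the donor (+), the second half to the acceptor (−); the midpoint goes
  to the donor.  Round-trips are exact for c.→genomic→c.; for
  genomic→c.→genomic they are exact by construction.
* **HGVS dialect.** Exactly {substitution, deletion, duplication,
  insertion, delins} with optional intron offsets — the closed set seen
  in small-panel variant tables.  Anything else (inversions, alleles,
  uncertainty) raises an explicit "unsupported" error rather than
  misparse.

## Splice consequences

Aberrant splicing outcomes are **declared inputs** (exon skip, 3′/5′
partial intron retention via a cryptic site, exonic truncation via an
ectopic acceptor), as established experimentally by RT-PCR and Sanger
sequencing of the products.  No splice-site strength model is used or
implied; `find_ag_dinucleotides` is an exploration helper only.  The
engine:

1. edits the spliced mRNA exactly (retained intronic sequence is taken in
   transcription orientation; a 3′ retention of r nt is the intron's last
   r bases, ending in the canonical AG);
2. classifies the frame (`in_frame` iff Δnt ≡ 0 mod 3; aa_delta = Δ/3);
3. translates from the original start codon to the first stop (standard
   code, stops TAA/TAG/TGA) and compares with the wild-type protein.
   Frameshifts report the count of novel residues before the premature
   stop and `p.Xaa###Yaafs*N` with **N counting the stop**
   (novel_aa_count = N − 1); direct stop gains report `p.Xaa###*`; loss
   of the start codon yields an explicit `no_ORF` result, and a shifted
   frame that never meets a stop yields `no_stop`.
4. predicts NMD by the last-junction rule: the premature stop must start
   more than 55 nt (configurable; the literature uses 50–55) upstream of
   the last exon–exon junction **of the altered transcript**; single-exon
   transcripts never trigger NMD.  The underlying studies assert NMD
   qualitatively; this rule is the field's standard operationalization.
5. predicts RT-PCR band sizes: WT = reverse − forward + 1 in tx
   coordinates, each surviving mutant allele adds its Δnt, and an allele
   whose primer footprint is removed is reported `primer_lost`.  Sizes
   are exact; `gel_match` provides a ±10% comparator for reconciling
   approximate gel estimates (a 242-nt prediction matches a "~250 bp"
   band).

## Pairwise IBD and the founder scan

**Estimator.** The method-of-moments IBD estimator on biallelic SNPs with
allele frequency p (q = 1 − p): conditional IBS probabilities as in the
README (each row sums to 1; all are symmetric in p ↔ q, so allele
labelling is immaterial), solved in cascade for ẑ₀, ẑ₁, ẑ₂, truncated at
0 and renormalized to the simplex; PI_HAT = ẑ₂ + ẑ₁/2 ∈ [0, 1] follows.
Identical vectors give PI_HAT = 1 *exactly* (no IBS0/IBS1 observations).
Frequencies are estimated from the panel (Σ dosage / 2·non-missing) or
supplied; monomorphic and all-missing SNPs are excluded; missing
genotypes are handled pairwise-complete.  Small-sample bias-correction
factors used by some reference implementations are **not** applied:
frequencies here come from the full cohort (or from the generator's truth
at panel scale), where the corrections are negligible, and the acceptance
checks confirm the uncorrected estimator hits the 0 / 0.5 / 1
expectations.  Pairs with fewer than 20 informative SNPs (configurable)
are flagged low-confidence.  Note the estimator is truncated at zero, so
small-window estimates for unrelated pairs are biased slightly upward
(visible as the control curves' mild lift at small h) — this affects scan
and controls identically and cancels in the comparison.

**Scan.** For half-widths h ∈ {step, 2·step, …, max_flank} (defaults
50 and 500 SNPs — window units are SNP counts, not bp), mean pairwise
PI_HAT among the carrier samples is computed over the index SNP ± h,
truncated at chromosome ends with the effective SNP count recorded.  The
default aggregation is the mean over all carrier pairs, with per-pair
curves retained and an optional cohort-baseline curve over random cohort
pairs.  Prefix sums over per-SNP moment components make all windows for
a pair a single O(n) pass.

**Controls.** The same scan at n (default 200) randomly chosen index
SNPs, pairwise non-overlapping within 2·max_flank SNPs on the same
chromosome (different chromosomes never conflict), seeded rejection
sampling, reported in deterministic genomic order.  If the panel cannot
host the requested count, the achievable maximum is used with a warning.
The per-half-width mean and SD across intervals form the null band.  The
"high-confidence array variant" lists used with real chip data are not
reconstructible; a MAF ≥ 0.05 / missingness ≤ 0.05 filter stands in
(configurable, and labelled as a stand-in in the scan metadata).

**Segment call.**  Two deliberately separate questions:

* *Is there locus-specific sharing?*  Half-widths where the scan mean
  exceeds the control mean by 3 control SDs (configurable) are
  significant; the largest such h is the **detection range**.
* *How big is the shared segment?*  The detection range overestimates the
  segment badly, because residual sharing from a finite segment stays
  significant in much wider windows (a 275-SNP segment diluted into a
  ±500-SNP window still lifts mean PI_HAT to ≈0.14, far above the
  control band).  The **extent** is instead estimated by inverting the
  dilution: under a contiguous shared block of s SNPs centred on the
  index, the expected curve is baseline(h) + π_seg · min(s, n_h)/n_h —
  flat inside the block, ∝ 1/n_h beyond it.  A 1-D grid search over s
  (with the closed-form least-squares π_seg given s) over the whole h
  grid recovers s.  Segments at or below the smallest window are not
  resolvable (all such s fit identically) and are reported at that
  resolution floor; a curve with no observable erosion and near-total
  sharing (mean ≥ 0.9, erosion ≤ 0.05 — genome-identical carriers such
  as twins) is flagged `unbounded` with the extent set to the widest
  window.

The decision is "founder-compatible" iff sharing is significant somewhere
and the extent reaches the configured minimum (default 100 SNPs).  The
genomic span converts the extent to Mb from the SNP positions around the
index.  Whether published carrier curves aggregate carrier pairs only or
include carrier-vs-cohort pairs is ambiguous in the sources; carrier
pairs only is the default, with the cohort baseline available separately.

## Variant shortlist filter and trios

All clauses are strict inequalities; absent gnomAD/CADD annotations pass
their clause by default — a novel variant has no frequency record and
must survive — with a strict mode to fail them.  ClinVar "Conflicting"
and absent classifications are retained (only Benign/Likely benign
fail).  The consequence clause accepts any protein-altering or
splice-altering term, or a supplied splice score above a configurable
cutoff (default 0.5, the usual operating point for precomputed splice
deltas).  ACMG classification is a pass-through column, never computed.
Trio phasing is purely combinatorial: in trans iff the two variants trace
exclusively to different parents; missing parents, double-carrier
parents and apparent de novos are ambiguous, never guessed.

## Synthetic data: what it does and does not establish

* **Transcripts.** Exon lengths uniform in a configurable range (default
  90–210 nt, forced where an event prescribes a size), CDS a multiple of
  3 ending in TAA, introns 80–200 nt with canonical GT…AG ends.  Planted
  consequences are engineered: downstream codons are drawn stop-free,
  then a TAA is patched into the shifted frame so a frameshift meets its
  stop after exactly k novel residues, with rejection sampling verifying
  both frames via an independent hand-written codon table (the same
  naive path that produces every truth record; the engine under test
  uses Biopython's translator).  What the fixtures do **not** model:
  realistic codon usage, splice-site strength, UTRs, alternative
  isoforms — so a green suite establishes coordinate/frame/stop
  arithmetic, not biological site prediction (which is out of scope by
  design).
* **Cohorts.** Allele frequencies Beta(2, 2) clipped to [0.05, 0.95]
  (bell-shaped MAF spectrum; clipping avoids monomorphic SNPs the
  estimator would drop), Hardy–Weinberg genotypes, SNP spacing jittered
  ±50% around 22,727 bp so that 275 SNPs span ≈ 6.25 Mb (array-scale
  density).  The founder segment gives each carrier one copy of a single
  founder haplotype over a contiguous SNP interval (two copies available
  for homozygous-founder scenarios); parent–offspring and identical
  pairs are planted by direct haplotype transmission/copy.  There is
  **no recombination, LD, or genotyping-error model** (beyond an optional
  uniform missingness rate): the scan is validated against a clean
  contiguous block, which is exactly the signal model the segment-size
  fit assumes.  Real data erode carrier segments unevenly; the fit's
  tolerance to that is exercised only indirectly (noise), not by an
  ancestry simulation.
* **Variant tables.** A one-hot plan emits one record failing each of
  the seven clauses alone (SNV and indel depth thresholds separately)
  plus an all-pass record; labels come from a direct restatement of the
  rule, independent of the filter engine.

All generators are bit-reproducible under a fixed seed.

## Numerical notes

* ẑ truncation/renormalization guarantees the simplex and PI_HAT ∈ [0, 1]
  for every input; windows with zero usable SNPs propagate NaN rather
  than fabricate estimates.
* The scan's per-pair window sums use float prefix sums; window counts
  are ≤ ~10³, far below any precision concern, and the vectorized
  estimator matches a per-SNP python loop to 10⁻⁹ in the test suite.
* Control-interval placement breaks ties by genomic coordinate so output
  order is deterministic under a fixed seed regardless of sampling order.
* Amplicon sizes are exact integers; all "gel" comparisons go through the
  explicit ±10% comparator.

## Known limitations

* The segment-extent fit assumes one contiguous shared block centred on
  the index variant; multiple nearby blocks or strongly asymmetric
  sharing will be summarized by an effective single-block size.
* PI_HAT inflation from truncation at small windows means absolute
  PI_HAT values at h ≤ ~100 SNPs should be read against the control
  band, not against 0.
* The HGVS layer covers the c. dialect needed for panel variant tables,
  not the full nomenclature; protein-level strings are emitted, never
  parsed.
* NMD prediction is the 55-nt heuristic; it ignores known escape routes
  (last-exon-proximal PTCs in long 3′ exons, re-initiation).
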