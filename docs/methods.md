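# Methods

This note documents the statistical model, the frame-prediction algorithm,
the synthetic-data generator, and the numerical and design choices behind
`spliceframe`, in enough detail to judge what its tests do and do not show.

## Event model and nomenclature

An alternative-splicing event is a local pair of exon–intron structures
(two "isoforms") of one gene, one of six types: exon skip, alternative
3′/5′ splice site, intron retention, mutually exclusive exons, multiple
exon skip. Consistent isoform labels matter because PSI is always reported
for isoform 2. The normalization rules are:

* skip-type events (exon skip, multiple exon skip): isoform 2 is the
  exon-richer form;
* intron retention: isoform 2 is the nucleotide-longer (retained) form —
  the spliced form has more exons but fewer bases, and calling the retained
  form isoform 2 keeps "PSI → 1" meaning "more retention";
* alternative 3′/5′ splice sites: both isoforms have the same exon count,
  so isoform 2 is the nucleotide-longer variant (ties keep input order);
* mutually exclusive exons: either exclusive exon can be longer, so
  isoform 1 is defined as the isoform whose exclusive exon has the smaller
  genomic start.

When the reader swaps labels to normalize an event, the per-sample read
counts are swapped with them, so `reads_iso2` always refers to the
canonical isoform 2. Coordinates are 1-based inclusive throughout
(Ensembl convention); the only 0-based conversion happens inside FASTA
extraction.

## PSI and pre-test filters

PSI = y/n with y = reads supporting isoform 2 and n = total event reads;
PSI is missing when n < `min_coverage` (default 10), avoiding unstable
ratios at low support. Three filters run before testing:

1. **coding** — events in genes not annotated `protein_coding` are dropped
   (genes absent from the annotation count as non-coding, with a warning,
   so partial annotations remain usable);
2. **missingness** — ≥ `min_valid_per_group` (default 10) samples with
   valid PSI required in *every* group;
3. **variability** — the sample standard deviation (n−1 denominator) of
   all valid PSI values pooled across groups must reach `min_psi_sd`
   (default 0.05). Pooling across groups lets variability arise within or
   between groups. Events with fewer than two valid values have no SD and
   are dropped.

Set membership is order-independent (each filter is a pure predicate); the
logged funnel uses the fixed order coding → missingness → variability.

## The beta-binomial test

Per event, y_i ~ BetaBinomial(n_i, p_i, φ_g) with
logit(p_i) = β₀ + β₁·I[case_i], and a separate overdispersion φ ∈ [0, 1)
per group — equivalently, two beta distributions for the two groups'
sample-level inclusion probabilities. The beta-binomial mass is evaluated
through log-gamma functions with shapes a = p(1−φ)/φ, b = (1−p)(1−φ)/φ; as
φ → 0 it reduces to the binomial mass (handled explicitly below φ = 1e−9).
Modelling PSI rather than raw junction counts makes the test invariant to
gene-level expression shifts: doubling both isoform counts moves nothing.

**Fitting.** The four parameters (β₀, β₁, logit φ_case, logit φ_control)
are maximized with L-BFGS-B; φ is optimized on a logit scale to keep it
inside [0, 1), with bounds that cap it near machine precision at the lower
end. The first start uses the empirical logit of pooled PSI, β₁ = 0 and
φ = 0.05; if the optimizer fails, up to four jittered restarts are tried
and the best likelihood kept. Non-converged events are excluded from the
multiple-testing family (so m counts tested events only) and carry missing
p-values.

**Inference.** The default p-value is the signed likelihood root
r = sign(β₁)·√(2(ℓ₁ − ℓ₀)) referred to a t distribution with N − 4 degrees
of freedom (N = samples entering the fit; 4 fitted parameters). The more
conventional Wald z = β₁/se(β₁), with the standard error from the inverse
observed Hessian, is available via `test="wald"` (also on a t(N−4)
reference). Rationale: at the cohort sizes this test is designed for
(~10–14 samples per group) each group's φ is estimated from very few
samples, and both the normal-reference Wald (empirically ~8–9% rejections
at nominal 5% on simulated nulls) and the χ²-reference LRT (~7.5%) are
visibly anti-conservative; the signed root with a t(N−4) reference lands
at ~5–6% across simulation seeds while keeping power ≥ 0.95 for a PSI
shift of 0.3 vs 0.7 at coverage ≥ 100. The t correction is the standard
small-sample device from quasi-likelihood regression; nothing about it is
tuned to any particular dataset.

p-values are Benjamini–Hochberg adjusted (in-package step-up
implementation; tests cross-check it against `statsmodels`), significance
is called at adjusted p < α (default 0.01, strict inequality), and the
effect size is delta average PSI = mean PSI(case) − mean PSI(control),
stored signed; screens like "|ΔPSI| ≥ 0.1" use its absolute value.

## Reading-frame prediction

The frame is predicted from the event's first 5′ exon, shared by both
isoforms. The shared segment is the first exon when both isoforms start
with the same exon; when the first exons share their 5′ boundary but not
their length (intron retention, where the spliced form's first exon is a
prefix of the merged exon; alternative 5′ sites, where the donor moves),
the shared prefix is used. Events sharing no 5′ segment are unresolvable
(frame X).

* **ORF method**: translate the shared exon in frames 1/2/3 (offsets
  0/1/2 on the transcript-oriented sequence). A frame is "open" iff its
  translation is non-empty and stop-free — no start codon is required,
  since event exons are usually internal. Call the frame iff exactly one
  is open.
* **Peptide-match method**: per frame, truncate the translation at its
  first stop and count the gene's known proteins containing it as an exact
  substring; queries shorter than `min_match_len` (default 7 residues)
  are skipped to avoid spurious matches. Call the frame iff it alone has
  matches. Raising `min_match_len` can only remove calls, never create
  them.
* **Combination**: agreement or a single-sided call resolves the frame;
  both ambiguous → fallback; contradictory non-X calls (never observed on
  well-formed inputs) resolve to X with a loud warning rather than
  trusting either method.
* **Fallback**: count internal stop codons of the full assembled
  isoform 2 in all frames (a single terminal stop does not count); call
  the unique clean frame if one exists. A config flag additionally
  requires isoform 1 to be clean.

N-containing codons translate to `X` and count as neither stop nor match —
conservative for both methods.

## Protein diff

Both isoforms are translated in the predicted frame with internal stops
retained as `*` (the first stop's residue index and genomic position are
reported separately, so consumers can truncate if they wish). The peptide
pair is decomposed as: longest common prefix; then longest common suffix
of the two *remainders* (so segments never overlap and ties favor the
prefix); the leftover middles are the isoform-specific peptides. The
four-segment partition reassembles each input exactly.

A frameshift is flagged when the two isoforms' total nucleotide lengths
differ by a non-multiple of 3 — since the flanking segments are shared,
this equals the middle-segment difference. Residue-to-genome mapping walks
the codon's first base through the isoform's exon list (strand-aware), so
a junction-spanning codon maps to its upstream exon.

## Visualizations

All figures are driven by intermediate coordinate tables that tests can
assert on; pixel layout is not part of the contract. The zoomed-in view
colors an exon light blue iff every residue its bases contribute to lies
in the shared prefix/suffix, light green otherwise, marks first stop
codons in red, and pairs the event with a per-sample PSI jitter panel. The
zoomed-out view matches the event's flanking exons to the gene's best
transcript (both flanks exact > one exact > overlap > none; ties to the
longer transcript, then the smaller ID). The domain view collapses the
transcript's exons (introns removed) and aligns protein domains converted
from amino-acid to transcript-nucleotide coordinates via
nt = 5′UTR offset + 3·(aa − 1) + 1; records sharing an accession are
merged by interval union because member databases predict slightly
different boundaries for the same domain. Domains overrunning the
transcript are clipped with a warning.

## Synthetic data

The generator emits every input the pipeline consumes plus a `truth.tsv`
of planted facts, and is the basis of the end-to-end tests. Genes are
built from designed codon blocks, not uniform random DNA:

* SAFE codons carry T only at codon position 1; any concatenation of them
  is provably stop-free in *all three* frames, because a stop codon would
  have to begin at a designed codon boundary, and stops are excluded.
* The POISON block `TTAAATGAC` reads L-N-D in frame but plants TAA at
  shift +1 and TGA at shift +2, making the containing exon's frame
  uniquely open. Placing it near the start of the shared exon also keeps
  the off-frame peptides under the 7-residue matching threshold.
* Novel segments (retained introns, splice-site extensions, the mutually
  exclusive intronic exon) use a T-free {C, G} alphabet and thus cannot
  introduce stops; a truncating TAA is planted explicitly at a known
  in-frame position where a truncation is intended. The first base of a
  novel segment that completes a shared exon's partial codon is forced to
  C, which closes the only remaining stop-forming junction (TA + G).

Each planted event is assigned a resolution mode — both methods, ORF only
(gene omitted from the protein FASTA), peptide only (no poison, all frames
open), or fallback (poison in a downstream exon of isoform 2 only) — and
the generator re-verifies every construction with plain string operations
(Biopython translation and substring search), independent of the analysis
code. About a third of genes are on the minus strand, exercising the
strand logic everywhere. Default study conditions: 14 case and 13 control
samples, coverage uniform in 100–300 reads, planted differential events at
PSI 0.3 vs 0.7, overdispersion φ = 0.05, alternating differential/null
events, plus one event each planted to fail the coding, missingness and
variability filters. Per-sample counts are drawn from the same two-group
beta-binomial the test assumes.

What this does **not** show: the generator draws counts from the model
being fitted, so the calibration results say nothing about robustness to
model misspecification (e.g. within-group PSI multimodality); exon and
intron sizes are toy-scale; the genome has no repeats, paralogs or
sequencing error, so peptide matching is cleaner than against a real
proteome; and novel-segment composition ({C, G}) is unrealistic by design.
The planted truths validate the machinery, not biological discovery.

## Problem sizes and numerics

The test suite and the acceptance script run simulations at these sizes:
2000 null events for type-I calibration, 200 events for power/recovery,
500 + 200 random sequences for the frame-method oracles, and a 60-event
planted dataset (10 per type) for the end-to-end run — sizes at which the
measured quantities are stable to a few parts per thousand while the whole
suite stays fast. Optimizer tolerances are ftol 1e−12 / gtol 1e−8 with at
most 5 starts; the observed Hessian uses central differences with step
1e−4; beta-binomial masses are validated to sum to 1 within 1e−10 for
n ≤ 30. Degenerate inputs (all-zero counts, empty groups, single-sample
events) are handled by the boundary parameterization and reported as
non-converged rather than crashing.

## Known limitations

* The test assumes exactly two groups; covariates and paired designs are
  out of scope.
* Frame prediction trusts the supplied protein FASTA; an incomplete set
  weakens the peptide method (it degrades to X, never to a wrong call).
* The fallback inspects isoform 2 by default; for events whose isoform 1
  contains novel sequence this can under-use evidence (flag available).
* Translation uses the standard genetic code only; selenocysteine and
  non-standard codes are not handled.
* The four-segment protein diff is positional, not an alignment; a single
  substitution inside a long identical stretch splits the diff at that
  point rather than reporting a minimal edit.
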