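# Methods

## The triage model

`cardiotriage` formalises a two-stage triage of annotated gene-panel variant
calls, followed by cohort-level analytics. The unit of analysis is the
*observation*: one variant seen in one phenotype-labelled carrier
(DCM, HCM or ARVC). Annotations — per-database minor allele frequencies,
in-silico predictor verdicts (SIFT, PROVEAN, PolyPhen-2, MutationTaster),
conservation scores (PhyloP, PhastCons, Grantham) and ClinVar/HGMD
assertions — are trusted inputs; the package never re-annotates, never
validates HGVS tokens against reference sequences, and never lifts
coordinates between builds.

### Rarity filter

An observation is retained as a *rare variant* iff all three hold:

- consequence ∈ {missense, nonsense, stop-loss, canonical splice
  (±1–2 of an exon boundary), frameshift indel, in-frame indel} — i.e. the
  call is predicted to alter the protein; synonymous, deep-intronic and UTR
  calls map to `other` and are dropped;
- read depth ≥ `min_depth` (default 10);
- aggregated MAF ≤ the carrier phenotype's ceiling (defaults
  DCM 0.004, HCM 0.002, ARVC 0.0005, chosen from disease prevalence; the
  prevalence→threshold derivation is configuration, not computation).

MAF aggregation defaults to the maximum across databases — a variant is
rare only if rare in *every* database that reports it; absence from all
databases counts as frequency 0 and retains the variant. A
`min_across_sources` mode implements the permissive reading. Thresholds,
depth and aggregation live in a YAML policy; percent and decimal-comma
spellings ("0,4%") are normalised to fractions at load.

### Pathogenicity rule engine

Exactly one branch fires per rare variant, in this order:

1. **TTN missense exemption** — negative regardless of predictors or
   database evidence. This is checked first so that no combination of
   evidence can ever rescue a TTN missense variant; the exemption reflects
   the observation that TTN missense frequencies do not differ between
   cases and controls.
2. **ClinVar demotion** — a ClinVar class of VUS / Likely benign / Benign
   demotes the variant, *unless* HGMD-same-phenotype or published data
   independently assert pathogenicity, in which case the override wins. A
   pathogenic ClinVar assertion cannot rescue here because it is mutually
   exclusive with a demoting class. The demotion-vs-override precedence is
   a genuine design choice (the source rules are unordered); the trace
   rationale flags whenever it decides an outcome.
3. **TTN truncating (A-band) rule** — positive iff the affected residue
   maps to the A-band of its transcript *and* lies in the region marked as
   shared by all isoforms considered. The band test alone decides; the
   MutationTaster verdict is reported but not required on this branch.
4. **Missense consensus** — all four predictors simultaneously damaging
   (SIFT "damaging", PROVEAN "deleterious", PolyPhen-2 "probably/possibly
   damaging", MutationTaster "disease causing"); any unscored predictor
   breaks the consensus.
5. **Radical rule** — stop-gain, stop-loss, canonical splice, frameshift
   and in-frame indels are positive iff MutationTaster says
   "disease causing"; an absent verdict is negative (but overridable).
6. **Database override** — a negative from (4)/(5) flips positive when
   ClinVar-pathogenic-same-phenotype, HGMD-same-phenotype, or published
   data support pathogenicity.

Evidence codes are computed identically for positive and negative calls:
GS (Grantham > 100, missense only), SI/PR/PP2/MT (damaging verdicts),
PC (PhastCons = 1), PP (PhyloP > 1), CV/HG (database assertion linked to
the same cardiac phenotype), REF (published support). The conservation
codes (GS, PC, PP) are reported metadata and never decisive — worked-
example rows classify without them.

### TTN region map

Titin band boundaries are data, not code: a versioned YAML file gives, per
transcript, an ordered gap-free list of 1-based inclusive residue
intervals labelled Z/I/A/M, with a `shared_all_isoforms` flag on the
portion shared by every isoform considered (default isoform set:
the cardiac N2B transcript NM_003319; novex-3 NM_133379 is mapped but
terminates in the I-band and has no A-band, so novex-3-referred truncations
can never pass). The bundled boundaries are approximate, derived from
public titin domain annotation; the rule logic is independent of the exact
numbers, and the per-variant rationale string records both sub-tests so a
different configured isoform set is visible in the trace.

### Cohort analytics

- **Burden**: rare-variant and potentially-pathogenic counts per patient.
  Zero-carrier patients stay in denominators; means are reported to one
  decimal.
- **Gene tallies**: per-gene totals with phenotype and variant-type
  breakdowns, descending.
- **Phenotype overlap**: genes partitioned by the exact subset of
  phenotypes they were observed in (7 regions; disjoint, covering — the
  count structure of a three-set Venn diagram). No figure rendering.
- **Novelty**: a (gene, carrier-phenotype) pair is novel iff the panel
  catalog lacks that tag for the gene. Channelopathy-only genes are
  therefore novel in any cardiomyopathy. Genes outside the catalog warn
  and count as novel only when configured. Novelty restricted to
  potentially pathogenic calls is always a subset of all-rare novelty.

The bundled 115-gene catalog is a best-effort reconstruction of a
pan-cardiomyopathy panel's prior knowledge; cohort-level novelty *counts*
depend on it and should be read as catalog-relative.

## Synthetic cohorts

The generator emulates the structure of a 38-proband panel study at the
annotated-variant level (no reads, no FASTQ/BAM): per-phenotype patient
counts (16/14/8), Poisson candidate counts (means 85/89/92), Poisson rare
counts (means 4.5/3.6/2.4 — cohort-wide ≈ 3.7), a rank-skewed gene sampler
that makes TTN dominate tallies, and per-branch planting rates that mirror
the observed composition of a rare-variant set (~27 % TTN missense, ~10 %
missense-consensus positives, ~8 % radical positives, rare override and
demotion cases, remainder plainly negative). Candidate variants destined to
fail the filter are planted to fail exactly one criterion (90 % frequency,
5 % depth, 5 % synonymous consequence), with margins: rare MAFs are drawn
below half the carrier's ceiling, common MAFs above twice it.

Ground truth (filter fate, label, branch, novelty) is recorded at
generation time and never recomputed. With zero annotation noise the
pipeline must recover it exactly; with predictor-flip noise *p*, recovery
of planted consensus positives decays as (1−p)⁴, which the suite checks
monotonically. Generation is driven by a single `numpy` generator seeded
from the config, with no string-hash, locale or time dependence.

What the simulator does **not** emulate: linkage between variants,
realistic allele-frequency spectra, per-gene mutational hotspots, multi-
transcript annotation conflicts, or annotation errors beyond independent
predictor flips. Passing the recovery suites therefore demonstrates that
the pipeline implements its own rules faithfully — not that the rules are
clinically valid on real data, where annotations disagree and evidence is
incomplete.

## Numerical and degenerate-input choices

- Genomic positions 1-based (hg19 convention as printed); protein positions
  1-based residue numbers in the row's transcript frame.
- PhastCons code PC requires exactly 1.0 (the score's ceiling), PP requires
  PhyloP > 1.0; Grantham is an integer, absent for non-missense.
- A frameshift token that ends in a stop ("V321GfsX11") is a frameshift
  indel, not a nonsense variant.
- Unparseable protein tokens are a value (`unknown`), not an error; they
  classify as `other` and fall out at the filter.
- Zygosity: X-chromosome variants in males are hemizygous; an X variant
  with unknown carrier sex is flagged `unknown` rather than guessed.
- Empty cohorts flow through every stage as empty-but-valid outputs.
- All writers are byte-stable for fixed inputs (sorted keys, fixed float
  formatting, no timestamps), so re-runs are idempotent.

## Problem sizes

The test suite and the acceptance script run on the 28-variant worked
example, exhaustive truth-table sweeps (~23 000 rule evaluations), and
simulated cohorts of 38 patients (~3 300 candidate variants; the burden-
calibration test scales to 380 patients). The full suite completes in well
under a minute on one CPU.

## Known limitations

- The worked-example annotations are reconstructed from printed evidence
  codes, so predictor verdicts not individually printed (e.g. whether an
  unlisted SIFT verdict was "tolerated" or unscored) are encoded as the
  least-informative value consistent with the codes.
- The demotion-vs-override precedence and the TTN-exemption-first ordering
  are design choices where the source rules are unordered; both reproduce
  every worked-example row.
- Multi-transcript annotations are preserved on input but the engine
  evaluates the designated primary transcript only.
- No statistical testing of burden differences between phenotypes, and no
  clinical (ACMG/AMP) classification — the potentially-pathogenic label is
  a research triage label, not a clinical assertion.
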