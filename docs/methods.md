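# Methods

## Scope and model

`dsdscreen` implements the variant-discovery-and-validation analysis chain of
a control/affected trio study of SRY-negative XX DSD: a recessive-model SNP
screen, a structural-variant (SV) concordance screen, cohort frequency
validation, ligation-probe relative copy-number quantification, in-silico PCR
and ΔΔCt expression analysis. It consumes called, annotated variants; it does
no alignment, assembly, variant calling or annotation, and no GO/KEGG
enrichment (candidate panels enter as static files).

Coordinates are 1-based inclusive everywhere: an interval [s, e] spans
e − s + 1 bases, which is what makes a deletion recorded as 6:9669113–9669182
measure exactly 70 bp. BEDPE input/output is converted from/to 0-based
half-open breakpoint intervals at the boundary.

## Trio screen

Per sample, over variants whose effect passes the filter (default:
nonsynonymous only; a flag widens to stopgain/stoploss), three key sets are
built: `all` (het or hom), `hom`, `het`, keyed by (chrom, pos, REF, ALT).
The four criteria are pure set algebra (A/C: intersections of affected hom
sets minus/intersected with control sets; B/D: control hom/het minus the
union of affected all-sets). With more than two affected genomes the
intersections and unions extend over all of them; the trio is the two-affected
special case. Disjointness of the four result sets follows from hom/het being
disjoint within a sample and presence/absence being complementary, so the
screen total is the plain sum — asserted property-based against a per-variant
brute-force classifier on random tables.

Genotype conventions: VCF `0/0` → absent, `./.` → no-call, mixed ref/alt →
het, all-alt → hom; multi-allelic rows are split per alternate allele before
keying. No-calls enter no set — they are unevaluable, not evidence of
absence — and a count of affected no-calls is logged. This is a design
choice; treating no-calls as absent would fabricate criterion-A hits.

## SV matching and screen

The default `gene_and_type` policy mirrors the gene-level matching criterion
(same gene, same type), guarded positionally: intervals must overlap by ≥1 bp
or have nearest breakpoints within 1,000 bp. Intergenic SVs (empty gene sets)
fall back to the positional test alone, since a gene criterion is undefined
for them. The alternative `reciprocal_overlap` policy (default fraction 0.5,
both records) is the field-standard interval test; inversions under it are
matched on both breakpoints lying within the tolerance, because overlap
fraction is uninformative for balanced events. No positional tolerance is
inherent to the method; 1,000 bp is this package's default and both knobs are
configurable. Both modes are symmetric (property-tested), and
step B output ⊆ step A output ⊆ the affected genome's SV set by construction.

## Cohort statistics

Genotype labels are unordered allele pairs, printed reference-allele-first
when a locus declares its allele pair (TT/TC/CC for a T>C site). Frequencies
are counts over typed individuals; missing genotypes reduce n rather than
being imputed. Allele frequency of x is (2·hom_x + het containing x)/(2n).
Computation carries full precision; display rounding is round-half-even at
three decimals, which reproduces the published display values 0.938, 0.062,
0.906 and 0.094 exactly (no single rounding mode can reproduce the published
0.813/0.187 genotype pair for 26/32 and 6/32; the counts are taken as 26/6
and left as computed). Carrier prevalence counts individuals with ≤1 intact
copy of a deleted segment. The Fisher exact allelic test (with
Haldane–Anscombe +0.5 correction of the odds ratio at zero cells) is an
extension beyond the source analysis, which reports frequencies only, and is
labelled as such in its docstring.

## Copy number

Within a sample: target peak / mean of the three reference-gene peaks
(ACTB, COL10A1, GCG). Across samples: scaled so the median normalized signal
of the control group equals 2 copies. The median (not mean) is deliberate —
a single deletion carrier contaminating the 32 controls cannot shift the
diploid anchor; the upstream protocol does not state its baseline, so this
is the package's choice. Class thresholds at 0.5/1.5/2.5 copy units (0 / 1 /
2 / gain) are likewise package defaults, configurable; the source states
none.

## In-silico PCR and ΔΔCt

Amplicon prediction is exact string matching (assay primers are exact;
mismatch and degenerate-base models are out of scope): forward primer on the
given strand, reverse primer as reverse complement downstream, every ordered
pairing reported, length measured outer edge to outer edge. Excising a d-bp
interval strictly between the sites shortens every spanning product by
exactly d (property-tested; d = 70 gives the 298→228 band pair of the WWOX
intron-5 assay). The duplex SRY assay returns `assay_failure` whenever the
GAPDH internal-control band is absent, regardless of the SRY lane.

ΔCt is the mean of three replicate target Cts minus the mean of three
reference (GAPDH) Cts; ΔΔCt subtracts the calibrator-group mean ΔCt
(default calibrator: the normal-female group); fold = 2^(−ΔΔCt). Exactly
three replicates per gene per individual are enforced as the assay contract.
Group summaries are arithmetic means of per-individual folds. The Welch
t-test on ΔCt between each group and the calibrator is provided because the
source figure marks significance without naming a test; it is flagged as a
package choice.

## Synthetic data

Generators are pure functions of (config, seed) — numpy `default_rng` —
and rerunning writes byte-identical files. Defaults mirror the study
conditions: a trio (NF, D1, D2); 32 affected + 32 control cohort animals;
triplicate qPCR with n = 3 per group; three reference probes.

- **Trio**: plants (kA, kB, kC, kD) = (50, 30, 20, 10) criterion variants by
  default plus background classes — 100 shared homozygotes, 50
  affected-discordant sites, 40 synonymous, 200 intronic (390 background in
  all) — each satisfying exactly its class pattern, at unique positions.
  Recovery by the screen is exact for every seed.
- **SVs**: 20 concordant, 15 primary-affected-only, 10 control-shared by
  default; each SV gets a unique synthetic gene and intervals are spaced far
  beyond the breakpoint tolerance, so the only match for a planted SV is
  itself. Step A must return 35 and step B 20.
- **Cohort**: exact-count mode lays configured genotype counts over a seeded
  permutation of individuals (bit-exact recovery); sampling mode draws from
  configured frequencies, converging at the binomial rate (tested at
  n = 32/320/3200 with a 3·√(p(1−p)/n) band).
- **Probe signals**: target peak ∝ copies/2 × baseline, reference peaks ∝
  baseline, both under multiplicative log-normal noise of CV 10% (mean 1);
  zero-copy samples emit a 0.02×baseline floor so peaks stay positive. The
  noise model and its CV are simulation assumptions — the assay literature
  publishes none. At CV 10% the relative-copy-number standard deviation at
  2 copies is ≈0.23 (target CV 0.10 combined with reference-mean CV
  0.10/√3), so per-sample error bounds are probabilistic; the tested
  contract is classification: ≥99% of 64 samples recover their planted
  class at the default thresholds, and the control median is exactly 2.
- **qPCR**: group-structured Ct values around a reference baseline of 18
  cycles with a base ΔCt of 5; replicate noise Gaussian, sd 0.1 Ct. A
  planted log2 fold of +2 with n = 3 per group is recovered within
  [3.2, 5.0] mean fold.
- **Amplicon fixture**: embeds the published WWOX primer pair exactly 298 bp
  apart around a 70 bp interval, regenerating random filler until neither
  primer site occurs elsewhere in either template; the deletion template is
  the wild type with the interval excised. Labelled synthetic — the real
  intron-5 flanking sequence is not distributed with the package.

What passing tests show — and don't: planted-truth recovery demonstrates the
set algebra, matching policies and estimators are implemented correctly
under the stated noise models. Synthetic inputs have no linkage structure,
no genotyping error model, no batch effects on probe signals and no
amplification-efficiency differences between genes; results on real data
depend on those upstream realities.

## Problem sizes and numerical notes

The shipped test and acceptance workloads are desk-scale by design: random
screen tables up to 10,000 variants, cohorts up to 3,200, 64-sample signal
panels, 1,000-table frequency sweeps. The genome-scale counts of the source
study (≈11.5 M SNPs per genome, 5,140 screened, 1,474 SV genes) require its
deposited raw data and are out of scope; planted-truth recovery replaces
them. Ties and degenerate inputs: N50 is computed by descending sort and
accumulation (permutation-invariant); empty length lists, end < start
intervals, zero typed individuals, empty control sets, missing reference
probes and replicate counts ≠ 3 all raise errors rather than guessing.
The fixture table for cohort SV burden is constructed to satisfy all
published marginals simultaneously (22 single-SV / 10 multi-SV carriers,
WWOX 20/32 etc.); the specific multi-SV combinations are synthetic, so the
burden check is a fixture-consistency check, not an independent reproduction.

## Known limitations

- Exact-match PCR only; no primer thermodynamics or mismatch tolerance.
- The SV screen operates on called SV tables; breakpoint uncertainty beyond
  the tolerance window is not modelled.
- Genotype heterozygosity is consumed as given; how het calls arise from
  haploid de novo assemblies is upstream of this package.
- The association test and Welch test are conveniences, not reproductions of
  any published statistic.
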