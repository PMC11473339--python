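# Methods

## The experimental design being modelled

Two rounds of EMS seed mutagenesis applied in sequence. The first round
produces heterozygous mutations that, by the time a plant grows, are present
in every cell of that plant — so both leaf sectors of a line carry them. The
second round acts on seeds from the first: when the mutagen fails to reach
every cell of the embryo, the plant becomes a chimera, and second-round
mutations are private to the cell lineage (sector) they arose in. Sequencing
the yellow and green sector of each of two independent lines gives four
samples whose presence/absence pattern at each SNP locus identifies the
mutation's provenance.

The package treats mutagenesis abstractly as two mutation layers with a
sector-assignment step; dose, exposure time and germline transmission are
not modelled.

## Provenance classification

A locus is described by the state of each sample: the called alternate
allele, confident reference (`REF_CALLABLE`), or insufficient coverage
(`UNCALLABLE`). The rules, applied in order:

1. conflicting alternate alleles across samples → `AMBIGUOUS`
   (`conflicting-alleles`);
2. all samples carry the allele → `BACKGROUND`;
3. both sectors of exactly one line carry it and *all* remaining samples are
   `REF_CALLABLE` → `EMS1(line)`; if any remaining sample is `UNCALLABLE`
   the required absence is unverifiable → `AMBIGUOUS` (`uncallable-absence`);
4. exactly one sample carries it, all others `REF_CALLABLE` →
   `EMS2(line, sector)`; otherwise `AMBIGUOUS` as above;
5. any other carrier pattern spans lines without covering all samples →
   `AMBIGUOUS` (`cross-line`).

Classes are exhaustive and mutually exclusive by construction (property-
tested over all 81 four-sample state patterns against an independently coded
oracle). Genotype comparison ignores zygosity: pooled sector tissue makes
allele fractions an unreliable zygosity signal, so "same genotype" means
"same alternate allele".

Absence claims require callability. The floor defaults to depth ≥ 8,
mirroring the caller's coverage criterion. When a depth mask is unavailable
(externally produced VCFs), the default policy treats no-call as confident
reference — pragmatic, but it silently converts missing data into absence;
the strict policy (`missing_mask_policy="uncallable"`) is available.

With a single line, `BACKGROUND` and `EMS1` are confounded (no second line
can witness the allele); such loci are reported `UNRESOLVED_SHARED` rather
than forced into either class.

## The caller

A deliberately small single-sample caller over 6-column pileup text, so the
pipeline is end-to-end testable without an external caller. Per site the
best-supported non-reference base is chosen (ties alphabetical; sites with
more than one observed non-reference base are flagged multiallelic, never
split). The site test is the one-sided binomial tail
P(X ≥ alt_reads), X ~ Binomial(depth, ε), ε = 10^(−meanQ/10): the
probability that sequencing error alone produced the observed support.
Full-featured callers use a Fisher-style two-sample read-count test; in the
no-reference-error limit the two coincide, and the binomial form is exactly
specifiable and cheap to verify by enumeration. The mean base quality is the
arithmetic mean of the Phred scores of the alt-supporting reads (not an
error-domain mean) — simpler, and stated.

Filter criteria (defaults): meanQ > 20; depth > 8 ("more than 8 reads" is
read literally as ≥ 9 — some callers default to ≥ 8, selectable via
`--min-depth`); alt reads ≥ 2; p < 0.01. All four comparisons are strict
where the wording is strict; tightening any threshold can only shrink the
call set (property-tested).

## The two-hit rule

A gene is a candidate for focal sample (line, sector) iff its body
(annotation start–end, 1-based inclusive; no promoter/UTR flank) contains
≥ 1 SNP of class `EMS2(line, sector)` and ≥ 1 additional induced SNP —
`EMS1(line)` or `EMS2(line, sector)` — at a distinct position. `BACKGROUND`
SNPs never count: they are cultivar variation, not induced. The biological
rationale (two sister-chromatid alleles each needing a hit) would put the
two hits on different alleles, but without phasing the rule is evaluated on
unordered position pairs; this relaxation can only add candidates, never
drop one. No allele-frequency or consequence filter is applied.

## Substitution spectra

Directed types are recorded on the reference strand, `C/T` meaning C→T, and
the 12 types are kept separate rather than collapsed to 6 strand-symmetric
classes, because the two complementary transitions are reported as separate
classes in this analysis tradition. The canonical EMS fraction is the
combined C/T + G/A percentage. Percentages are exact internally and rounded
only for display.

## The simulator

What it emulates, and its defaults (chosen as the desk-scale image of the
study conditions; all stages draw from streams derived from one master
seed):

| parameter | default | role |
|---|---|---|
| genome_length × n_chromosomes | 1 Mb × 1 | uniform-composition reference |
| n_genes × gene_length | 20 × 1 kb | sparse non-overlapping genes (2% genic), so incidental two-hit co-occurrence is rare |
| n_lines | 2 | independently mutagenized lines |
| background_snv_rate | 2×10⁻⁴ /bp (~200 loci) | cultivar-vs-reference homozygous layer |
| ems1_count / ems2_count | 100 / 100 per line | heterozygous mutation layers |
| green_leak_fraction | 0.05 | share of round-2 hits landing in the green sector (the observed green-unique counts are ~5% of the yellow-unique ones) |
| n_causal_genes | 3 | genes given a planted two-hit pair |
| sector_purity | 1.0 | fraction of sector cells from the focal lineage; < 1 dilutes the heterozygous alt-read fraction 0.5·purity, emulating mixed cell layers |
| coverage_mean | 30 reads | Poisson per-site depth (floored at 1) |
| mean_baseq | 30 | emitted base quality (pileup: normal, sd 2) |
| base_error_rate | 0 | pileup read-base corruption |
| false_positive_rate / false_negative_rate | 0 / 0 | spurious calls per bp; dropped true calls |

Every variant's (ref, alt) is realised by sampling a directed type from the
spectrum and consuming an unused genome position whose reference base
matches, from per-base pools shuffled once per run — this guarantees no
positional collisions across layers (the classes stay disjoint, as the
sector comparison assumes) and makes the empirical spectrum converge to the
configuration (verified at n = 10⁵ within ±0.5 percentage points per type).
The default spectrum puts 37.8% on C/T, 36.9% on G/A and 7.05% on A/G — the
published per-type percentages — with the remaining 18.25% spread uniformly
over the other nine types, which are individually unreported.

Causal planting selects genes at random (cycling lines so each line gets
candidates), placing one `EMS2_YELLOW` hit plus a second hit whose class is
a fair coin flip between `EMS1` and `EMS2_YELLOW`, both inside the gene body
at distinct positions. A gene that cannot host two positions of the required
bases raises an error naming the gene.

Emission: heterozygous calls receive alt reads ~ Binomial(depth,
0.5·sector_purity), homozygous ones all reads (both floored at one read —
negligible at the default coverage, but it keeps zero-noise emission exact).
Depth masks cover the union of all loci, so absence is always assessable at
simulated loci. Pileup emission is an independent surface for the caller:
it re-draws depths from its own stream, so call-level and pileup-level noise
are not coupled.

What the simulator does **not** emulate: read-level artefacts (mapping
error, strand bias, indel misalignment), linked variation, non-uniform base
composition, coverage autocorrelation, or contamination between sectors
beyond the single purity scalar. Passing the recovery tests therefore shows
the *logic* of the pipeline is right under the design's own assumptions, not
that the thresholds are optimal for real sequencing data.

## Whether green-unique SNPs are leak or noise

Observed green sectors carry a handful of private SNPs. These could be a
genuine small second-round leak into the green lineage, or caller false
positives. The simulator deliberately exposes both knobs
(`green_leak_fraction`, `false_positive_rate`) without asserting which the
real data reflects; the default models them as leak because that keeps the
noise-free defaults reproducing the observed Venn structure.

## Chlorophyll quantitation

Two-wavelength equations (coefficients 12.72/−2.59, −4.76/22.88, 8.75/20.29
on A663/A645, scaled by V mL / 1000·m g) give chlA, chlB and total in mg per
g fresh weight. Note the total is an independent regression, not chlA+chlB
(they differ by 0.79·A663·V/(1000·m)). Results are rounded to three
significant digits, round-half-even on the decimal representation (the
rounding mode of the underlying standard is unspecified; half-even is the
analytical default and is configurable). Negative raw values — possible with
a miscalibrated blank — are warned about and reported, not clamped. No
formula is applied to the 470 nm reading, and lutein (an HPLC measurement
with no closed formula) is carried as data only.

## Numerical and determinism choices

- Per-stage RNG streams: `SeedSequence([master_seed, crc32(stage), …])`;
  stages and samples never share a stream, so any stage can be re-run alone.
- Spectrum probabilities must sum to 1 within 1e-9.
- Binomial tails come from `scipy.stats.binom.sf`; they match exhaustive
  enumeration to ≤ 1e-12 for depth ≤ 20 (tested).
- TSV floats are written with `%.10g`; identical config + seed reproduces
  every output byte for byte (hashed in the run manifest).
- Gene placement: sorted uniform offsets plus a per-gene shift — uniform
  over admissible non-overlapping layouts, adjacency allowed.

## Problem sizes used in the test suite

Spectrum recovery uses 10⁵ variants on a 2 Mb genome (seconds). Zero-noise
end-to-end recovery uses the default 1 Mb / two-line configuration. The
noise-recall law (recall ≈ (1−f)² at false-negative rate f, each planted hit
having to survive in the focal yellow sample independently) is checked at
f ∈ {0.1, 0.3} over 50 seeds of a 300 kb configuration with four planted
genes, within three standard errors; gene density is kept low there so
incidental rescues by unplanted mutations stay well below the test
tolerance.

## Known limitations

- The provenance logic assumes exactly two sectors per line and collapses
  zygosity; mericlinal/periclinal sector anatomy is reduced to one purity
  scalar.
- The caller has no indel, strand-bias or joint multi-sample machinery and
  is not a replacement for a production caller on real data — the pipeline
  accepts external VCFs at the partition stage for that.
- With one line, background and first-round classes are unidentifiable.
- The two-hit rule cannot distinguish a causal gene from an incidental
  two-hit gene; at realistic genome-wide mutation densities incidental
  candidates are expected and must be triaged by annotation, which is out
  of scope here.
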