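# Methods

This note documents the models, conventions and numerical choices behind
`ccmosaic`, and what the synthetic experiments do and do not establish
about behavior on real data.

## Breeding simulator

A CC strain is realized as a diploid mosaic of founder-labelled segments.
The funnel is fixed as (AB×CD)×(EF×GH) over a per-pedigree permutation of
the eight founders; generation 0 is the G2:F1, and each subsequent
generation is one brother × sister cross. Meioses draw a Poisson number
of crossovers with expectation `crossover_rate_per_bp × chromosome
length` (default 1 per 100 kb synthetic chromosome), uniformly placed,
without interference or sex-specific maps. If an X chromosome is present,
males are hemizygous (maternal X only) and sires pass their X intact to
daughters; funnel-position effects on the X are ignored.

Under this design the expected heterozygous fraction after g generations
of sib mating is exactly the classical recurrence H_g = H_{g−1}/2 +
H_{g−2}/4 with H_0 = H_{−1} = 1, because the four G2-level source
haplotypes carry disjoint founder sets at every locus, so label identity
coincides with identity by descent. The Monte-Carlo calibration checks
the simulated mean against this recurrence at g ∈ {2, 5, 10} (2,000
replicates, 3-standard-error band).

Markers are biallelic and informative by construction: two alleles drawn
per marker, assigned to founders by fair coin, redrawn until both alleles
occur. A consequence used repeatedly below: for a *fixed* pair of
founders, a marker distinguishes them with probability ≈ ½.

Array genotypes corrupt the true call (founder allele, or H where the two
haplotypes' alleles differ) with mutually exclusive probabilities: a
wrong in-vocabulary call (`error_rate`), an H miscall at homozygous
markers (`h_miscall_rate`), an N no-call (`n_rate`). Reads are sampled
uniformly from both strands of the deletion-excised template,
`round(depth × template/read_length)` of them, with i.i.d. substitution
errors.

## Residual heterozygosity

Markers enter the estimator only if, in the founder panel: exactly two
alleles segregate (biallelic + informative), founders carry no H/N,
replicates agree, and founder alleles exactly predict F1 hybrid calls.
Trio evidence at a retained marker is any H call or disagreement among
non-N calls; all-N markers are unassayed and leave both numerator and
denominator.

Evidence clusters span first to last flagged marker; singleton clusters
take the chromosome's mean inter-marker spacing. Clusters never extend
into flanking non-evidence sequence (the conservative convention). The
estimate is Σ cluster spans / Σ per-chromosome assayed spans.

**Gap tolerance.** Because a biallelic marker is informative for the
specific pair segregating in a heterozygous region only about half the
time, evidence markers arrive interleaved with evidence-free ones.
Breaking a cluster at every unflagged marker fragments heterozygous
regions and drives the estimator to ≈ 0.375× the truth in the
dense-marker limit. `cluster_evidence` therefore bridges up to
`max_gap_markers = 7` consecutive unflagged assayed markers: a genuinely
heterozygous run then splits with probability ≈ 0.5⁸ ≈ 0.4% per gap,
while homozygous stretches longer than 8 markers still separate clusters.
The tolerance was fixed from this geometric argument; `max_gap_markers=0`
restores the strict behavior. At the calibration scale (5,000 markers,
zero noise, 20 strains at generation 6) the estimator's mean absolute
error against the simulator's realized fraction is ≈ 0.028, dominated by
a small residual negative bias (segment edges and remaining splits).

Sample identity uses pairwise concordance (matching non-N calls over
compared calls); argmax matches are reported with all ties, and a best
concordance below 0.9 flags the sample as unrelated.

## Haplotype reconstruction

State space: the 8 inbred states in canonical founder order, then the 28
unordered pairs lexicographically; male X tracks use the 8 inbred states
and are expanded with zero heterozygous mass.

*Emission.* The expected call under a state is the shared founder allele,
or H for a discordant pair; the expected call has probability 1 − ε and
the remainder splits uniformly over the other calls in the marker's
vocabulary ({allele₁, allele₂, H}). N is uninformative (emits 1
everywhere); an all-N chromosome returns the prior at every marker.
Default ε = 0.005.

*Transition.* Each haplotype's founder origin follows a uniform-jump
process with rate ρ per bp: over a gap d the switch probability is
r(d) = ⅞ (1 − e^{−8ρd/7}), spread evenly over the other founders. This is
the matrix exponential of the jump generator, so transitions compose
across gaps and approach the uniform stationary distribution; a simpler
1 − e^{−ρd} switch form has a vanishing diagonal at large d and is not
Chapman–Kolmogorov-consistent. The two haplotypes transition
independently and the ordered product is folded onto unordered pairs.
Default ρ = 2·10⁻⁵/bp, matching the simulator's expected crossover
density at its default chromosome scale (calibrate ρ ≈ 2 × crossover
rate when changing scales, two meioses' worth of switches per sampled
genome being a reasonable prior for nearly fixed strains).

The forward–backward pass is scaled per position; posteriors on ≤3-founder,
≤4-marker instances match exhaustive path enumeration to 10⁻¹⁰ (the test
oracle enumerates all state paths). Cross-grid imputation is elementwise
linear interpolation between flanking markers followed by renormalization;
outside the dense range the nearest end vector is used.

*MRCA merging.* Per marker: find each ancestor's argmax state; if two or
more ancestors have inbred argmaxes on different founders, each such
ancestor's inbred mass moves onto the heterozygous states pairing its
founder with the other conflicting founders (split equally when more than
one) and the inbred entry is zeroed; then take the elementwise maximum
across ancestors and normalize. Merging a track with itself is the
identity; with more than two conflicting founders the support lands on
all pairwise combinations. Inputs are required to be normalized.

*Mosaic extraction.* Per-marker argmax (ties to the lowest canonical
index), runs merged, boundaries at midpoints between flanking markers of
different argmax, segments below `min_posterior` (default 0.5) flagged
uncertain. Boundary precision is limited by the density of markers that
*discriminate* the two flanking states — from ≈ ¼ of markers (two
heterozygous states sharing a founder) to ≈ ¾ (different inbred states) —
so recovered boundaries sit within a few effective spacings of the truth
and short slivers below ~5 marker spacings are not resolvable. At ε =
0.005 noise and 2,000 markers per Mb the per-marker argmax diplotype
matches truth at ≥ 95%.

## Deletion discovery

The read archive is queried only through the k-mer contract: the number
of reads containing a 45-mer forward or reverse-complement, and those
reads. The index is an exact hash of canonical 45-mers (k-mers containing
N never match; reads shorter than 45 are skipped and counted).

Conventions, in order of application:

- tiles start at 1, 16, 31, … while the 45 bp window fits; a tile is
  *present* with ≥ 3 supporting reads (guarding against sequencing error
  and index hopping) and *repetitive* if its 45-mer occurs more than once
  in the reference, either strand;
- candidates are maximal absent runs spanning > 500 bp with < 50%
  repetitive tiles, reported as first/last absent 45-mer start, with
  size_kb = (end − start)/1000 — the same bookkeeping as the reported
  deletion table, which the tests verify against all four printed rows;
- breakpoints: reads containing the last present 45-mer on the left flank
  are assembled by majority vote and extended inward, re-anchoring on the
  growing consensus (any read overlapping the end by ≥ 45 bp is
  recruited, so a local coverage dip does not orphan spanning reads). The
  consensus is compared to the reference in 45 bp windows (edlib, infix
  mode): distances ≤ 5 throughout with reconnection past the interval ⇒
  `closed_polymorphism`; a divergence whose tail re-matches the reference
  downstream of skipped sequence ⇒ `deletion`, with the junction
  normalized to the leftmost micro-homology placement; anything else ⇒
  `unresolved`. If the left flank fails, the mirror procedure runs from
  the right boundary on the reverse-complement strand; a final fallback
  permits single-read consensus columns (two-read majority otherwise);
- classification: homozygous iff every non-repetitive interior tile is
  unsupported (a 1:1 heterozygous mixture keeps interior tiles present
  and is suppressed); junction support is the read count of the 45-mer
  straddling the resolved junction; a call is strain-unique iff every
  comparison read set still supports the interior tiles; the haplotype
  label is the strain mosaic's founder pair at the interval.

At depth 10 with 0.2% read error, implanted 0.6/2/20 kb deletions are
recovered with recall 1.0 and 0 bp breakpoint error (leftmost convention,
truth normalized identically) over 10 replicate read sets, with no false
calls; error-free reads with no events yield no calls. Template ends ramp
up coverage over one read length and are not scored.

## Population statistics

Founder frequencies weight heterozygous segments ½ per founder, so each
strain's eight frequencies sum to 1; per-locus population frequencies
average diploid dosages (1, ½, 0) across strains, and representation
reports per-founder grid runs with zero carriers at ≥ ½ dose.

The wild-derived enrichment statistic is the total wild dosage-length
inside heterozygous intervals summed over strains (wild set default
{CAST/EiJ, PWK/PhJ, WSB/EiJ}; the non-domesticus subset {CAST/EiJ,
PWK/PhJ} is a config option). The null rotates each strain's intervals
circularly, per chromosome, by one shared uniform offset — preserving
interval number, lengths and within-strain structure — and
p = (1 + #{null ≥ observed})/(1 + n_permutations), so p ≥ 1/(n+1).

Calibration on 200 neutral populations (8 strains, generation 6, 199
rotations) gives an empirical type-I rate around 0.05–0.09 at nominal
0.05 — within binomial noise, but tending slightly liberal on these
small genomes: a strain's residual-heterozygosity intervals largely share
one segregating founder pair, so the observed statistic is fat-tailed
relative to the rotation null, which averages over the genome. A
founder-relabeling null (permuting which founders count as wild) would be
exactly exchangeable under neutrality and is a natural alternative; the
rotation null is kept as the least-assumption default. On power
fixtures with heterozygous intervals forced onto wild segments, p reaches
its floor (≤ 10⁻³ at 9,999 rotations).

## Problem sizes and determinism

The test suite and acceptance script run at desk scale: 100 kb–1 Mb
chromosomes, 60–5,000 markers, depth-10 read sets over 100 kb templates,
2,000 breeding replicates, 200 permutation-test datasets. Every routine
is seed-deterministic; derived seeds are spawned from the top-level seed.

## Limitations

The generator's markers are i.i.d.-informative coin-flip biallelics; real
genotyping arrays carry intensity-based cluster calls, linkage-structured
informativeness and platform-specific content, so the accuracy constants
measured here (estimator MAE, boundary blur, recovery rates) characterize
the model, not any array. Line extinction and selection during
inbreeding, realistic genetic maps, and X-funnel position effects are not
modeled. The k-mer index reproduces the BWT query contract exactly but
not its compression; real deletion work must also contend with repeat
families larger than the reference-multiplicity flag captures, and with
heterozygous and complex events that this caller deliberately suppresses.
Published per-strain values are treated as inputs; nothing here
re-derives them from raw data.
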