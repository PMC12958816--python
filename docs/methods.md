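# Methods

## Model and procedure

The package treats mtDNA evolution in a set of natural isolates as clonal
descent on a rooted binary tree. Each observed isolate contributes one
consensus sequence; identical sequences are collapsed into mitotypes
(exact string match, the representative being the lexicographically first
member). Ancestral sequences are reconstructed per aligned column by Fitch
parsimony over the five-state alphabet {A, C, G, T, −}, treating the
alignment gap as an ordinary state so single-base indels are polarized the
same way as substitutions. Ties at the root are broken toward the outgroup
state, below the root toward the parent state, then lexicographically —
the reconstruction is a deterministic function of the input. The number of
implied changes equals the Fitch parsimony score by construction, a fact
the test suite checks against an exhaustive enumeration of all internal
labelings on small trees. The cataloging pass walks the tree in pre-order
and emits one record per state change per branch, so a variant fixed in a
clade is one event on the clade stem; adjacent gap columns changing on the
same branch are merged into a single indel record. Where a probabilistic,
indel-aware reconstruction from an external tool is preferred,
`polarize.attach_ancestral_states` accepts per-node sequences and feeds
the identical cataloging machinery.

A single outgroup cannot polarize changes on its own terminal branch: a
mutation there is indistinguishable from the reverse change on the ingroup
stem, and parsimony (with ties broken toward the outgroup) will mirror
such events onto the stem. Recovery statistics therefore quantify ledger
recovery over ingroup branches, excluding the outgroup edge and the stem;
this is the set of polarizable polymorphisms. With at most two expected
mutations per branch on a ~13.7 kb genome, recovery in the validation runs
is complete (the package asserts ≥ 99%).

Substitutions are pooled into six strand-symmetric classes. Raw class
counts are normalized by dividing each count by the number of source bases
(A/T or G/C) in the site set under consideration and rescaling the six
quotients to sum to one; the normalization is invariant to rescaling both
denominators. Denominators are computed per stratum — for the four-fold
stratum, the A/T and G/C counts among four-fold degenerate sites only.
Between-spectrum contrasts use the asymptotic Pearson χ² test of
independence without continuity correction, which reproduces the published
contrast statistics on the bundled counts exactly; the A/T- vs
G/C-increasing flux balance is a separate 1-d.f. goodness-of-fit χ²
against a 50:50 expectation, with the composition-neutral classes
(A/T→T/A, G/C→C/G) excluded.

Degeneracy of a coding site is established by enumerating the three
alternative bases under the genome's genetic code (invertebrate
mitochondrial, translation table 5, by default; codes are plain data and
pluggable): four-fold iff all three changes are synonymous, nondegenerate
iff none is. The rare three-fold case (two synonymous alternatives, absent
under table 5) pools into "two" unless explicitly split. Synonymous /
nonsynonymous site counts are unweighted Nei–Gojobori-style: each codon
position contributes (synonymous fraction of its three changes)/1 sites,
changes to stop codons count as nonsynonymous, so S + N equals the coding
length exactly; a trailing truncated stop codon is excluded rather than
completed. Per-gene and per-complex expectations under homogeneous
mutation pressure apportion the genome-wide count by each gene's share of
the matching site total (a raw-length weighting is available behind a
flag); observed-vs-rest contrasts use the 1-d.f. G-test
(G = 2 Σ O ln(O/E)) and the N/S balance a two-sided Fisher exact test,
with Bonferroni thresholds 0.05/#genes and 0.05/#complexes.

Codon usage is summarized per codon box (six-fold amino acids split into
their boxes; A/G- and T/C-ending two-fold families kept separate — 13
two-fold families exist under table 5). The composition-adjusted RSCU of a
codon is its observed count over an expectation proportional to the
background frequency of its third base among all synonymous third
positions of the same degeneracy class, renormalized within the family, so
1 means usage fully explained by composition. Family-vs-rest heterogeneity
uses a Pearson χ² whose p-value comes from Monte-Carlo resampling: row
totals fixed, each row drawn from the pooled column proportions,
p = (1 + #{simulated χ² ≥ observed})/(n_sim + 1). This parametric
bootstrap under the pooled null is asymptotically equivalent to fixing
both margins; the calibration against the asymptotic p-value is asserted
at n_sim = 10,000. The preferred codon of a family is its most-used codon
in the reference CDS set (ties broken lexicographically, logged);
selection on codon usage is tested by a 2×2 G-test of to-/from-preferred
synonymous flux in rare (terminal-branch) vs shared (ancestral-branch)
variants.

McDonald–Kreitman counting walks aligned codon columns: polymorphic
columns contribute path-averaged synonymous/nonsynonymous changes of each
minority codon from the majority codon; columns monomorphic in the ingroup
but differing from the outgroup contribute fixed differences. Codons
differing at several positions are decomposed by averaging over all
orderings of the changed positions, discarding orderings that pass through
a stop codon whenever a stop-free ordering exists. NI = (Pn/Ps)/(Dn/Ds)
with a NaN sentinel for empty denominators and a Fisher exact test on the
rounded 2×2.

Structural-variant frequencies come from depth ratios on the circular
reference. For a region R in isolate i, r_i = mean depth inside R / mean
depth outside R over unmasked positions; ρ = r_focal / (mean of r over an
SV-free cohort); frequency = 1 − ρ for deletions and ρ − 1 for
duplications, clipped to [0, 1]. The subtraction form is used because a
deletion carried by a fraction f of genome copies depresses relative
coverage to 1 − f — the ratio itself is not the frequency. The
hypervariable control region is masked from every mean; a variant spanning
the mask is evaluated separately on each unmasked arc — with the outside
baseline always the complement of the whole variant region — and the arc
frequencies averaged. Cohort baselines average per-isolate ratios by
default; depth pooling is available behind a flag. The reference can be
rotated to any origin with an invertible coordinate map, and rotation
followed by estimation equals the direct circular computation exactly.
Heteroplasmy boundaries are inclusive: frequency in [0.03, 0.97] is
heteroplasmic, below is homoplasmic-ancestral, above homoplasmic-derived.
Isolates suspected of cross-contamination are flagged when ≥ k (default 3)
of their heteroplasmic variants match another mitotype's homoplasmic
alleles within a pairwise frequency spread ≤ ε (default 0.05); the median
matching frequency estimates the contaminating fraction.

## Synthetic data

The generator emulates the statistical structure of the target data, not
its sequence content: a ~13.3 kb circle with 12 protein genes named and
grouped into ETC complexes as in *C. elegans* mtDNA (complex I: the seven
NADH-dehydrogenase genes; III: cytochrome b; IV: the three cytochrome-c
oxidase genes; V: ATP6), 22 tRNAs, 2 rRNAs and one noncoding control
region, at 76% A+T (A and T at 0.38, G and C at 0.12 — the published
genome's composition class). Protein genes are stop-free with an ATG
start; all features sit on the plus strand separated by short spacers.
Trees are Yule (uniform random tip splitting) with the outgroup attached
as sister to the ingroup; every branch receives a Poisson number of events
(default mean 2, raised per experiment as stated below). An event is a SNP
with probability 1 − indel_rate: the class is drawn from the six relative
rates, whose default is the natural-isolate normalized spectrum (0.012,
0.050, 0.098, 0.006, 0.233, 0.601 in the order A/T→C/G, A/T→T/A, G/C→T/A,
G/C→C/G, A/T→G/C, G/C→A/T); the site is drawn among class-eligible bases,
weighted by m_GC when either circular neighbor is G or C. Eligibility and
context weights are evaluated on the branch's starting sequence and a site
mutates at most once per branch, which keeps the truth ledger exactly
replayable — `replay_ledger` regenerates the emitted leaf alignment from
the ledger alone and the test suite asserts byte equality. A fraction of
terminal-branch events (default 6.6%, the observed heteroplasmic share)
receives a frequency from the bimodal mixture 70% Uniform(0.03, 0.30) +
30% Uniform(0.70, 0.97); events below frequency 0.5 do not enter the
consensus sequences, mirroring consensus calling on real reads. Depth
profiles are position-wise Poisson with mean depth × (1 ∓ f) inside
deletions/duplications (default 1000×, the published cohort's coverage
scale), optionally modulated by a smooth shared mappability curve.

What the generator does *not* emulate: sequencing error, alignment
artifacts, NUMT contamination, recombination, strand-asymmetric mutation,
rate variation along the genome beyond the neighbor effect, and selection
(mutations land uniformly given class and context). Passing recovery tests
therefore demonstrates the correctness of the estimators under the assumed
generative model, not robustness to real-data artifacts.

## Problem sizes and numerical choices

Validation runs use sizes chosen to make sampling error small relative to
the asserted tolerances while keeping the suite quick: 200 random 5–8
taxon instances against the exhaustive parsimony oracle; four 16-taxon
replicates at 2 expected mutations/branch (~240 polarizable events) for
ledger recovery; one 40-taxon run at 32 events/branch (~2,500 SNPs) for
spectrum recovery, tested by χ² goodness of fit against the configured
process at p > 0.001; eighteen SV estimates (two types × nine frequencies)
at 1000× over a 1.6 kb region, asserting mean absolute bias < 0.01; and
Monte-Carlo calibration at n_sim = 10,000 within 3 binomial standard
errors of the asymptotic p. Published-table statistics are asserted to
their printed precision.

Sentinels are explicit: Ts/Tv returns +inf with zero transversions and NaN
on an empty table; correlations with zero variance return NaN with p = 1;
NI returns NaN on empty denominators. χ² contrasts refuse tables with
zero expected cells and advise merging categories. All randomness flows
from `numpy.random.default_rng` seeded per run; pipeline outputs are
byte-identical across reruns with the same seed.

## Design choices where the design was open

- Degeneracy enumeration (rather than a lookup of family tables) makes the
  classification correct under any pluggable code; the 2-synonymous-
  alternative case defaults into the two-fold class.
- Six-fold amino acids are split by codon box everywhere (9 four-fold
  boxes under table 5); analyses that need "four-fold families" treat all
  four-fold boxes alike.
- The neighbor-context test on synthetic data checks a band rather than
  the planted multiplier itself: the generator boosts a site when *either*
  flank is G/C, so the one-flank marginal enrichment is mathematically
  diluted below m_GC (to ≈ 2/(1 + P(other flank G/C)) for m_GC = 2), and
  the dilution differs between degeneracy classes because their 5′ flanks
  are codon second positions with very different G/C content.
- Per-gene expectations weight by syn/nonsyn site counts, not raw length
  (flag available), because rate comparisons are per-site quantities.
- "Rare" variants are terminal-branch records, "shared" are
  ancestral-branch records, in the preferred-codon flux test.
- The mutation catalog treats parallel changes in both children of a node
  as two events (they are two records in the traversal), never collapsed.

## Known limitations

- Reproducing the published normalized spectrum proportions and the
  four-fold transition ratio of 4.8 requires the real reference genome's
  base composition; reproducing per-gene statistics, the concatenated
  NI of 0.79, the enrichment factors and window counts requires the full
  per-variant supplementary table. Neither is bundled; the corresponding
  machinery is validated on synthetic truth instead.
- Polarity on the two root edges is unidentifiable with a single outgroup
  (see above); affected records are a ~1/(2n) fraction of the catalog on
  an n-taxon tree.
- Inserted bases never mutate further downstream of their insertion
  branch in the simulator.
- The Fitch reconstruction ignores branch lengths and gives maximum-
  parsimony (not maximum-likelihood) ancestors; at the polymorphism
  densities targeted here the two agree for essentially every column, but
  deep, rate-heterogeneous phylogenies would need the external-ASR hook.
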