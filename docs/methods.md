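# Methods

## Study design and data model

The unit of analysis is a 1:1 ortholog shared by 10 species on a fixed
rooted tree:

```
(chicken,(platypus,((opossum,tasmanian_devil)Marsupialia_stem,
 (mouse,(macaque,(gorilla,(human,(chimpanzee,bonobo)Pan_stem)
 Hominini_stem)Homininae_stem)Catarrhini_stem)Eutheria_stem)
 Theria_stem)Mammalia_stem)root;
```

Internal node labels name the branch above the node (a clade's "stem");
terminal branches are named by their leaf. The topology is configuration,
not something estimated from data. Two kinds of input attach to this tree:
a gene × species RPKM matrix, and per-gene codon (or protein) alignments.

## Expression binarization and classification

A gene is scored testis-expressed in a species when RPKM ≥ cutoff
(default 1.0; the boundary value itself counts as expressed) and silent
below it. Classification of a cross-species pattern:

- **strict** (default): `<clade>-specific` iff present in *all* clade
  members and *no* non-member. When clades nest, the most inclusive match
  wins. Genes present everywhere are `universal`, nowhere
  `never_expressed`, anything else `other`.
- **relaxed**: at least one expressing member in each immediate subclade
  of the clade (e.g. ≥ 1 marsupial *and* ≥ 1 eutherian for Theria) and no
  expression outside. This accommodates the looser reading of
  "expressed only in the therian species"; strict is the default because
  it is the reading consistent with a conserved clade-wide gain.
- **dollo**: label by the inferred gain branch (below), which tolerates
  secondary losses inside the clade.

Genes with missing or unparseable cells are dropped and counted, never
imputed: a 1:1 ortholog table is complete by construction, so a hole
signals upstream trouble. Negative values abort loading. No correction is
attempted for genes straddling the cutoff (bulk RNA-seq near RPKM 1 is
genuinely ambiguous); the synthetic generator's `noisy` flag exists to
exercise exactly this regime.

## Dollo gain/loss mapping

Expression presence/absence evolves under a single-origin rule: one gain,
any number of subsequent losses, no regain. Under this rule the gain
branch is forced — the branch above the MRCA of the expressing leaves —
and the minimal loss set is the set of maximal subtrees below the gain
containing no expressing leaf. Because the gain placement is forced,
equal-cost ties cannot arise and no tie-breaking policy is needed; this is
exercised (not assumed) by comparing against exhaustive gain-placement
search over all 2^10 leaf patterns, where the mapping attains the minimum
in every case. Genes absent everywhere go to a `never_expressed` bucket
with cost 0. Every reconstruction is replayed against the observed
pattern as a runtime assertion.

Fitch/unordered parsimony is deliberately not offered for expression:
regain of a silenced testis program is excluded by design, and a
probabilistic reconstruction would need rate parameters the 10-species
design cannot estimate.

## Trees from difference counts

Gene trees are built by Saitou–Nei neighbor joining from raw pairwise
difference counts, not model-corrected distances, so branch lengths remain
in "number of differences" units and can feed count-based exact tests
downstream. Details:

- **Gap handling**: complete deletion by default (columns with any gap in
  the alignment are dropped); pairwise deletion by flag.
- **Tie-break**: when two pairs share the minimal Q, the lowest index pair
  in input order is joined, making the output deterministic.
- **Negative branch lengths**: clamped to zero with the deficit
  transferred to the sister branch created at the same join
  (Kuhner–Felsenstein convention), preserving total tree length; count
  units must stay non-negative to be interpretable as substitution counts.
- On additive input NJ returns the unique additive tree exactly; this is
  checked against a path-length oracle on 100 random 10-taxon trees.
- **Bootstrap**: columns resampled with replacement per replicate
  (default 1000); support = percentage of replicate NJ trees containing
  the bipartition; reproducible under a fixed seed.

Clade statistics root the unrooted NJ tree on the chicken outgroup, verify
monophyly, and report all within-clade branch lengths (stem excluded,
reported separately) with mean and population sd.

**Clade rate-asymmetry test.** The 2×2 table contrasts substitutions with
unchanged site-passages: `[[k_A, b_A·L − k_A], [k_B, b_B·L − k_B]]` where
`k` is the summed within-clade branch length in difference counts, `b` the
branch count and `L` the alignment length. Summing over all clade branches
(not only stems) is the default; the stem can be included by flag. This is
one defensible reading of an exact test on branch lengths — the table
construction is stated here precisely because alternatives exist.

## Nei–Gojobori selection analysis

Counting follows Nei & Gojobori (1986) with equal pathway weighting:

- **Sites**: at each codon position the synonymous fraction is computed
  over the non-stop single-nucleotide neighbours (stops excluded from the
  denominator), so N + S = 3 × codons exactly.
- **Differences**: averaged over all minimal mutational pathways between
  two codons, skipping pathways through stops; nd + sd equals the codon
  Hamming distance whenever a stop-free pathway exists. Codon pairs with
  no stop-free pathway, and columns with gaps, ambiguity codes or stops,
  are excluded and counted per category.
- **ω**: pN/pS on raw proportions by default; Jukes–Cantor-corrected
  dN/dS by flag. A zero synonymous denominator reports ω as undefined,
  never as infinity. The standard nuclear code is the default and the
  code table is configurable.

**Stem-lineage ω.** Ancestral codons are reconstructed by Fitch parsimony
over whole-codon states with parent-preference resolution (a node takes
its parent's resolved state when it lies in the node's state set). The
stem ω compares the resolved sequences at the clade's MRCA and at its
parent, over the columns where both resolve; ambiguous columns are
excluded (conservative) rather than resolved arbitrarily, and the
retained + dropped accounting always sums to the total.

**Selection-asymmetry test.** Fisher's exact test on
`[[Nd_A, Sd_A], [Nd_B, Sd_B]]` with fractional counts rounded half-up
(deltas logged). The Fisher implementation enumerates the full
margin-fixed hypergeometric support; two-sided p sums all tables no more
probable than the observed one (tolerance 1e−9 for probability ties, and
sums within 1e−9 of 1 snap to exactly 1). It is verified against an
independent factorial enumeration for every table with total ≤ 30, and
against `scipy.stats.fisher_exact`.

Both readings of a clade-level ω — the stem-branch contrast and the mean
over within-clade pairwise comparisons — are computed and reported;
they answer different questions (episodic change on one branch vs average
constraint within the clade) and genuinely differ at a shifted locus.

## Synthetic data

The generators produce data with exactly the structure the analysis
assumes, so recovery tests are meaningful end to end.

**Expression.** Gains are planted at named branches; below a gain, each
branch loses expression independently with `loss_prob` (losses nest
maximally, so the planted truth is a valid Dollo history). Expressed
species draw RPKM from a lognormal (default log-mean ln 30, log-sd 1 —
high, clearly-on expression like the observed marsupial values near
RPKM ≈ 190); silent species draw uniform noise on [0, 0.9). Expressed
draws below the cutoff are re-drawn by default so planted truth is
unambiguous; `noisy=True` disables the re-draw to study cutoff straddling.
Genes not assigned to a planted gain are made universal (gained at the
root), mirroring the conserved core that dominates a real ortholog table.
Within-clade variance beyond the lognormal spread is not modelled; the
log-scale parameters are exposed rather than guessed.

**Codon evolution.** Each codon site evolves independently by a Gillespie
process along each branch: single-nucleotide changes are proposed at
kappa-weighted rates (default κ = 2), proposals creating a stop are
rejected (so alignment length is conserved and no in-frame stop can ever
appear), and nonsynonymous changes carry the relative rate ω of the
residing branch. Rates are normalised by the mean exit rate over sense
codons at uniform frequencies, so branch length = expected substitutions
per codon site at uniform composition; the event log's nonsynonymous
fraction converges to the rate-matrix expectation, which is asserted at
10 000 codons within three binomial standard errors. Uniform codon
frequencies and no indels are deliberate simplifications — the simulator
validates counting and reconstruction logic, not codon-usage realism.

A single seeded RNG stream drives each generator call; replaying a seed
reproduces the emitted text files byte for byte, and the fixture writer
records sha256 hashes in a manifest.

**Known estimator bias.** Nei–Gojobori weights all changes equally, so
with κ > 1 the transition-enriched synonymous class is undercounted in
the site totals and neutral sequences estimate ω slightly below 1; the
neutral-recovery test therefore runs at κ = 1, while the scenario
simulations keep κ = 2 and absorb the mild downward shift (planted 0.39
recovers a median near 0.34–0.36).

## Canonical scenarios and problem sizes

`phylotestis.scenarios` freezes the study conditions used by the analysis
scripts and the acceptance computation:

- 100-gene expression matrix with 22 marsupial-stem and 15 therian-stem
  planted gains (the observed clade-specific category sizes), loss-free.
- A 611-codon locus (1833 bp, the ARHGAP28 length) with stem ω 0.39
  (Eutheria) vs 0.10 (Marsupialia) and background ω 0.15, plus 745- and
  752-codon control loci (SYNM/PDZRN3 lengths) without a shift.
- Branch lengths are round therian-divergence-scale values in
  substitutions per codon site (outgroups 0.25–0.30, both stems 0.30 so
  the stem contrast is carried by ω alone, short primate terminals).
  Because only the stem ω is shifted, the clade-wide branch-rate test is
  null on these fixtures by construction; its power is demonstrated
  separately with a six-fold rate contrast at 1833 sites, where detection
  (one-sided p < 0.05) occurs in ≈ 100% of replicates.
- The recovery experiment uses 100 seeds; this keeps the full acceptance
  run near 15 s while giving the medians a sampling error well inside the
  reported bands.

## Limitations

- The mapping rule is parsimony, not a rate model: heavily homoplastic
  expression patterns (many independent gains) are misattributed by
  design.
- Stem ω rests on Fitch ancestors; short stems or sparse taxon sampling
  inflate ambiguity and shrink the usable column count (the accounting is
  reported, and a zero-length stem can retain a residue of apparent
  change from reconstruction error).
- Difference-count branch lengths ignore multiple hits; they are the
  right currency for the exact tests used here but not comparable across
  loci of different divergence.
- The published headline counts for the real 5627-gene table (2989
  universal, 53 mammal-only, 22 marsupial-specific, 15 therian-specific)
  and the real ARHGAP28 stem values are reproducible only given the
  deposited expression table and supplementary alignments; the pipeline
  accepts both as inputs but does not bundle them.
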