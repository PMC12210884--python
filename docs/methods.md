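# Methods

## Conservation profile

The CIS Gene Family (CGF) profile is built from a family membership table
over a fixed panel of reference CIS loci (n = 8 by default, matching the
breadth of well-characterized CIS types: extracellular systems such as
PVC/Afp/MAC, the membrane-anchored T6SS^iv lineage, thylakoid-associated
and Gram-positive systems). A family's conservation frequency is the
fraction of reference genomes carrying ≥ 1 member; duplicated members
within one genome are presence, not count. On an 8-reference panel the
attainable frequencies are exactly k/8.

Categories follow pangenome convention with the bins cloud [0, 0.15),
shell [0.15, 0.95], core (0.95, 1]. The boundary assignments make the
function total over [0, 1]; on the k/8 grid nothing falls in
(0.95, 0.99), so the core bin is equivalently "frequency 0.99–1".

Functional roles (Cis1…Cis15, AIg19) are a curation input, not an
inference: they ship as an explicit family → role table. The package
includes the handful of published assignments for the reference catalog
(spike plug and tail-fiber clusters); synthetic catalogs generate their
own complete map.

## Scoring model

Accepted hits (identity ≥ 25 %, e-value ≤ 1e-5, best bitscore per query
gene, ties broken by e-value then lexicographic family id) yield per
contig

    score = M × Σ_g (3^freq(g) − 1)

with M the number of distinct query genes. The printed form of the
formula is singular in `freq` while a contig carries many genes; since
frequencies are converted to base scores per gene, we sum the per-gene
terms and let the multiplier scale the sum (config `aggregation: sum`;
`mean` is provided as the alternative reading, under which the score
reduces to the plain base-score sum). Genes hitting the same family each
contribute a term, because M counts genes, not families
(`distinct_families_only` disables this). The exponential base score
makes a core-family hit (freq 1 → 2.0) worth ~14× a cloud-family hit
(freq 1/8 → 0.147), so gene-rich contigs dominated by conserved families
separate sharply from sporadic-hit background.

The screening threshold is derived from the reference loci themselves:
each reference genome is scored with every gene an accepted hit to its
own family (no other protocol is available for reference self-scores),
and the cutoff is the nearest-rank quantile at fraction 0.6 of the
ascending self-scores — the top of the "lowest 60 %" block (rank
⌈0.6 n⌉). Alternatives (`fraction_of_min`, linear-interpolated quantile)
are config-selectable. Screening is strict (score > threshold), so a
score equal to the threshold is not a candidate.

## Classification rules

Stage order: threshold → essential classes → exclusion rules. The order
follows the screening narrative and matters only for the reported reason;
a final CIS call requires passing all stages.

The essential screen requires ≥ 1 role per class (baseplate
{Cis8, Cis11, Cis12}, tube {Cis1, Cis5, Cis7}, sheath initiator
{Cis4, Cis9}), not every listed protein — retained loci in real surveys
lack individual members (e.g. Cis11 or Cis5) while keeping the class.

The phage/bacteriocin rule exists in two printed readings that differ on
whether Cis6 must also be absent. Both are implemented
(`variant=results` requires Cis6 absent and is the default, being the
more specific restatement; `variant=methods` drops the Cis6 condition).
They disagree exactly on loci carrying {Cis13, Cis14, Cis6} without
Cis15.

## Co-occurrence

P(j|i) = co-occurrence count of i and j / count of loci containing i,
over the binary presence matrix of final CIS loci (role-level by
default; family-level supported since one role can span several
families). Undefined rows (gene present in zero loci) are encoded as
missing — an empty TSV cell, never 0, since a zero would fabricate
certainty of non-co-occurrence. Network edges require both directed
probabilities strictly > τ (default 0.8).

Column clustering uses Ward's minimum variance in its classical "Ward.D"
form: the Lance–Williams update applied to raw (unsquared) Euclidean
distances. SciPy's `ward` linkage is the Ward.D2 variant, so Ward.D is
implemented directly via the recurrence; `ward_d2` remains available and
is cross-checked against SciPy, while Ward.D is cross-checked against R's
`hclust(method="ward.D")` in the test suite. Distance ties merge the pair
containing the smallest original column index; the merge tree is emitted
as Newick with ultrametric branch lengths derived from merge heights.

## Ecology tabulations

All counts are MAG-level (a MAG with several CIS contigs counts once).
Sub-biome relative abundance divides CIS-bearing MAGs by *all* catalog
MAGs in that sub-biome, so the catalog metadata must cover the full MAG
collection; CIS MAGs missing from the catalog are a hard error, while
CIS MAGs missing from plain metadata are counted under an explicit
"unannotated" bucket with a warning. Species rankings sort by count
descending, ties alphabetical; species-unclassified MAGs are reported
separately rather than dropped.

## Synthetic data generator

The generator emulates the study conditions the pipeline assumes:

* **Reference catalog** — 84 families: the sixteen roles at frequencies
  on the k/8 grid (Cis7, Cis8 universal; essential-class roles at 6–7/8;
  Cis15 at 3/8; AIg19 at 1/8) plus 5 unknown-role shell (2/8) and 63
  cloud (1/8) accessory families. This partitions 2 core / 18 shell /
  64 cloud, the shape of a published-scale reference catalog. Membership
  sampling is seeded; a frequency-preserving repair guarantees every
  reference genome covers each essential class, as a viable reference
  locus must.
* **Community** — MAGs are allocated to planted classes by largest
  remainder (default mix 40 % CIS, 20 % T6SS decoy, 20 % phage decoy,
  20 % background) and seeded-shuffled. Planted loci are *complete*: one
  gene per profile family, minus the roles the class must lack (T6SS
  decoys omit Cis6/Cis13/Cis14/AIg19 families; phage decoys omit
  Cis6/Cis15). Complete rosters mirror how a genuine locus resembles the
  reference systems the threshold is derived from, and guarantee that at
  zero noise every planted locus — including decoys, which must reach
  the exclusion stage — clears the threshold. A `minimal_rosters` switch
  plants one-role-per-essential-class rosters instead for sharp
  rule-boundary testing; these intentionally score below the threshold.
* **Noise** — dropout removes each planted gene hit independently with
  `dropout_rate` (`protect_essential` optionally revives one family per
  silenced essential class); spurious hits are Poisson per contig with
  low identity (20–40 %) and soft e-values, so the standard filters
  remove some but not all. Hit identities (60–95 %), e-values (1e-50 to
  1e-10, log-uniform) and alignment lengths (150–600 aa) are sampled in
  configurable ranges; bitscores are derived from length × identity.
* **Metadata** — biome groups, sub-biomes, five phyla (Bacteroidota-
  weighted) and species labels (15 % unclassified) with fixed weights.

Everything is a pure function of (config, profile): one seed, one
byte-identical community.

What the generator does **not** emulate: sequence-level homology (hits
are planted, not aligned), assembly fragmentation beyond contig-level
dropout, paralog confusion between roles, or realistic between-biome
differences in CIS architecture. Passing recovery tests therefore
demonstrates the correctness of the scoring/screening logic under the
stated noise model, not expected sensitivity on real MAG catalogs.

## Evaluation

`truth_evaluation` compares per-contig calls with planted truth:
sensitivity over planted CIS contigs, specificity over planted non-CIS
contigs, plus a planted-class × status confusion table. Truth contigs
the pipeline produced no call for (no accepted hits, or not their MAG's
representative) count as `no_call`, a negative; calls for contigs absent
from the truth are an error.

## Problem sizes and numerical choices

The default test and acceptance workloads use 8 reference genomes,
84 families, and communities of 100–200 MAGs (~16k hits) — sizes at
which every stage is exact and runs in seconds while exercising all
code paths; the pipeline itself is linear in the number of hits and has
processed-catalog-scale inputs only through the same interfaces.
Floating point: scores are compared with strict inequalities as defined
(no epsilon), frequencies are exact binary fractions on the k/8 grid,
and grid validation of generator plans uses a 1e-9 tolerance.
Tie-breaks are deterministic everywhere (bitscore → e-value →
lexicographic family; score → multiplier → family count → contig id;
Ward ties → smallest column index), so identical inputs give
byte-identical outputs.

## Known limitations

* Role annotation quality bounds classification quality; unknown-role
  families never contribute to screening rules.
* The reference self-score protocol assumes reference gene sets are
  clean CIS loci; contaminating genes would inflate the threshold.
* "Manual screening" steps of survey-style analyses may include
  curation beyond the printed rules; only the printed rules are
  implemented.
* Conditional probabilities carry no significance model (no permutation
  null); the τ = 0.8 network is descriptive.
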