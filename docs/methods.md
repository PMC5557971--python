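# Methods

This note documents the models, parameter choices and numerical decisions
behind `panani`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Orthology: the best-reciprocal-hit rule

Hits are pairwise protein similarities, either read from a 12-column tabular
file produced by an external search tool or computed internally. For each
(query gene, target genome) pair the hits are gated, the survivors ranked by
score, and the top hit accepted only if the runner-up **from the same target
genome** scores strictly below `second_best_ratio` (default 0.90) times the
best score — a tied or near-tied second best means the ortholog call is
ambiguous and is dropped. Strictness at the boundary matters: a second-best
score of exactly 90% of the best rejects the call. A reciprocal pair exists
when two genes are each other's accepted best; COGs are connected components
of that pair graph (a strict-clique mode exists for sensitivity analysis,
splitting non-clique components into their constituent pairs). Core COGs have
exactly one member in every genome — a genome represented twice demotes the
COG to accessory. "Specific" genes have no accepted cross-genome hit at all
under the gate; a looser "no reciprocal pair" definition is available by flag.
Within-genome (paralog) hits are ignored throughout.

### Internal-mode gating

The internal aligner reports raw Smith–Waterman scores (BLOSUM80, gap open 10,
extend 1, i.e. a gap of length L costs 10 + L) and does not compute
Karlin–Altschul e-values; the e-value column carries only a length-normalized
surrogate and is flagged. Gating therefore uses a minimum raw score. The
default floor of 300 was calibrated against an explicit null: local alignments
of unrelated ~300-residue simulated proteins under this scoring reach raw
scores of roughly 65–210 across a ten-genome all-vs-all search (the test suite
asserts this separation), while genuine orthologs at the per-site divergences
the simulator targets (≤ 0.15) score above 1000. The floor sits between the
two regimes with a wide margin on both sides. It is a parameter: searches
involving very short proteins (≲ 50 residues) need a lower floor, and external
e-value-gated input bypasses it entirely.

A shared-5-mer prefilter (≥ 2 shared 5-mers) selects candidate pairs before
alignment. At the identity levels where the score floor accepts a hit, true
pairs share many 5-mers, so the prefilter does not change accepted results; it
only avoids aligning the quadratically many unrelated pairs.

## ANIb

Following the fragment-based average-nucleotide-identity procedure: query
genomes are cut per contig into consecutive 1020-nt windows (a terminal
remainder is kept iff ≥ 100 nt); each fragment is locally aligned to the
subject genome over both strands (match +2, mismatch −3, gap open 5, extend 2);
fragments whose best hit reaches 30% identity and 70% fragment coverage
contribute their percent identity; ANIb is the arithmetic mean. A pair with no
qualifying fragment is *undefined* (NaN, reported in a warnings list), never
zero — averaging zeros would silently bias downstream distances. ANIb is
asymmetric; both directions are preserved and only merged in the distance
transform d(i,j) = 1 − mean(ANIb(i,j), ANIb(j,i))/100.

Long subjects are searched by k-mer anchoring (k = 11): 11-mer matches vote on
alignment diagonals, windows around the best-voted diagonals (vote counts far
below the strongest candidate are discarded; overlapping windows merged) are
aligned exhaustively. Targets under 5 kb skip anchoring and use full dynamic
programming; a test asserts the anchored path reproduces exhaustive-DP scores.

## Neighbor joining

Classical Saitou–Nei: join the pair minimizing
Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), pendant lengths from the
two-point formulas, new distances d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2, final
three-way join emitted as a trifurcating display root of an unrooted tree.
Ties on Q are broken toward the lexicographically smallest pair of subtree
labels (each subtree labelled by its smallest leaf), making output independent
of input row order — the historical implementation this replaces was
input-order dependent. Negative estimated branch lengths are clamped to zero
with the deficit moved to the sister branch, preserving the pair's summed
length; on additive matrices no clamping triggers and the input path-length
matrix is recovered to machine precision.

## Enrichment statistics

`hypergeom_upper_tail(k, K, n, N)` sums the hypergeometric pmf from k upward
in log space (`lgamma`-based binomial coefficients, `fsum` accumulation),
giving exact tails to ~1e-15 without overflow; tests compare it against exact
integer combinatorics. The Bonferroni multiplier is the number of terms
actually observed (k ≥ 1) in the tested gene set — terms never seen among the
DE genes are not tested. The background defaults to *all* protein-coding genes
of the focal genome, annotated or not; an annotated-only background is a flag.
Fold enrichment (k/n)/(K/N) is reported uncapped.

The positional test builds the 2×2 table [[de_A, rest_A], [de_B, rest_B]] and
computes the textbook Pearson statistic Σ(O−E)²/E with df = 1; the Yates
continuity correction is off by default and available by flag. On the
published contig marginals (71 of 3489 vs 33 of 628) the statistic is 22.41
and p ≈ 2.2e-06 uncorrected (21.12, p ≈ 4.3e-06 with Yates). The p-value
printed in the originating study (9.436e-06) is not reproducible from those
printed counts under any standard 2×2 variant, so the implementation targets
the textbook statistic rather than that printed value.

## The synthetic-pangenome generator

The simulator is the package's test bed: it produces genomes whose correct
analysis is known by construction.

- **Families.** Ancestral coding sequences are ATG + uniform random sense
  codons + TAA (translation table 11); lengths vary uniformly within ±20% of
  the configured mean (default 900 nt). Core families occur in every genome,
  accessory families in a random subset, and each genome additionally carries
  fresh strain-specific genes unrelated to any ancestor.
- **Divergence.** Each genome's copy of a gene (and of its upstream spacer)
  is mutated from the ancestor by independent per-site substitution at rate
  *d* ∈ [0, 0.5] to a uniformly chosen different base — a Jukes–Cantor-like
  model with no indels. Two genomes therefore match at a site with probability
  (1−d)² + d²/3, which the calibration tests check by direct mismatch
  counting. Internal stop codons arising from mutation are redrawn to random
  sense codons so proteomes stay valid (a sub-percent perturbation covered by
  the test tolerances).
- **Layout.** Families keep one ancestral order, orientation and intergenic
  spacer context across genomes; strands are drawn uniformly once for the
  ancestor. This collinearity is deliberate: closely related strains conserve
  gene order and intergenic sequence, and without it fragment-based ANI is
  undefined between simulated genomes (local alignments of 1020-nt fragments
  cannot reach 70% coverage across independently scrambled gene orders).
  Strain-specific genes are genome-private insertions; coordinates are 1-based
  inclusive with ≥ 20-nt spacers; a planted cluster stays contiguous and
  co-oriented in designated genomes, complete or as a stated member subset.
- **DE tables.** One `gene_exp.diff`-dialect row per focal-genome gene;
  planted up/down genes draw q uniformly below the 0.05 threshold and fold
  changes of |log2 FC| ∈ [1, 5] with the planted sign; all other genes draw q
  strictly above the threshold — selection at q < 0.05 is threshold-exact by
  construction.
- **Planted enrichment.** One Pfam accession mapping to the enriched GO term
  is given to a configured fraction of up-regulated genes (default 0.30) and a
  background fraction (default 0.05) of the rest, alongside uniform decoy
  Pfam/GO pairs.

All randomness flows from a single integer seed through one generator;
identical configurations are byte-identical on disk. In the pipeline, stage
seeds derive from the global seed plus a CRC32 of the stage name (Python's
built-in `hash` is process-salted and unusable for reproducibility).

**What the simulator does not model:** indels and rearrangements, codon-usage
and GC bias, horizontal transfer, paralogous families, RNA genes, assembly
artifacts. Passing planted-truth tests therefore demonstrates correctness of
the decision rules and statistics at realistic divergence levels, not
robustness to structural variation or annotation noise — on real data the
BRBH second-best rule and the score gate carry the burden the simulator's
clean families do not exercise.

## Problem sizes

Planted-truth recovery runs 10 genomes × (80 core + 5 specific) families at
divergence 0.05; cluster conservation runs 11 genomes with an 11-member
cluster (complete in the reference and two others, a 4-member subset in one);
ANIb calibration uses 30-kb genome pairs at divergences {0.01, 0.05, 0.10}
against a positional mismatch oracle (agreement within 1 percentage point,
observed ≤ 0.05); NJ additivity uses random binary trees of 4–12 leaves;
enrichment calibration uses 1000-gene backgrounds with 60-gene DE sets and
40 decoy terms. Hypergeometric exactness is exhaustively enumerated for
populations up to 25 and densely sampled up to 60.

## Known limitations

- Internal-mode scores are not comparable across substitution matrices, and
  the default floor assumes proteins of roughly 100+ residues.
- ANIb anchoring assumes ≥ 1 shared 11-mer per homologous fragment; beyond
  ~25% per-site divergence fragments start failing the identity threshold
  anyway, so the practical range matches the method's intended use.
- The conservation report's contiguity check requires orthologs to be strictly
  consecutive; a single inserted gene inside the cluster demotes a genome to
  partial when `contiguity_required` is on (presence-only is the default).
- COG formation by connected components can chain distinct families through a
  shared promiscuous member; the strict-clique mode exists to quantify that
  risk on real data.
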