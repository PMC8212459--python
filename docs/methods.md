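# Methods

This note documents the models, parameter choices and numerical decisions
behind `drebtools`, and what the synthetic fixtures do and do not
demonstrate about real data.

## Superfamily decision tree

Proteins enter with a set of domain hits (an HMMER `--domtblout` table, or
the package's consensus scan when no table is supplied). The tree is
applied in order:

1. ≥ 2 AP2 domains → **AP2** subfamily (checked before RAV, so a protein
   with two AP2 domains plus a B3 is labelled AP2);
2. one AP2 domain plus a B3 domain → **RAV**;
3. one AP2 domain without the WLG tripeptide inside the domain span →
   **atypical**, excluded from the DREB/ERF split;
4. one WLG-bearing AP2 domain → **DREB candidate** (Group A) if domain
   residue 14 is V, **ERF** (Group B) if A. Domain-relative numbering
   starts at 1 on the first residue of the hit; the hit must span ≥ 19
   residues for the V14/E19 read. When residue 14 is neither V nor A the
   label falls back to per-position identity against two bundled 60-aa
   representative domain cores. Those cores are synthetic constructions
   (shared scaffold, diagnostic V/A at 14, E at 19, WLG at 29–31,
   subfamily-distinct C-terminal tails) — built for the generator and the
   fallback, not database sequences.

Residue E19 is recorded but deliberately not used as a criterion: DREB1
proteins in several grasses carry a non-glutamate at position 19 while
remaining functional DREBs, so V14 does the discriminating.

The tree is total: every protein with ≥ 1 AP2 hit receives exactly one
label, so label counts partition any input set.

## DREB subgroup diagnostics

Subgroup A-1 (DREB1) requires the DREB1-type NLS
`[PK]K[RK][PR][AT]GR[TK]KFRETRHP` ending within 30 residues upstream of
the domain start; A-2 (DREB2) requires the CMIV-1 core `[KR]GKGGPxN`
there. Both kinds of upstream evidence at once raise an ambiguity error
rather than a silent choice. DSAW is flagged when it starts within 10
residues downstream of the domain; LWSY when it lies in the final 15
residues; the full PKK-like NLS (`RKxPAKGSKKGCMxGKGGPENxx`) is flagged
wherever found upstream. The 30/10/15-residue windows are design choices
("nestles up to the domain" is qualitative in the literature); all three
are keyword arguments. Position 8 of the DREB1 NLS is reported both as
T/K and as unconstrained in different sources; the strict T/K reading is
the default with a `strict_pos8=False` relaxation.

Motif matching is exact per-position set membership with no mismatches,
returning all non-overlapping leftmost matches. With 16- and 23-position
patterns the false-positive rate in random background is negligible, which
is why the synthetic generator can place motifs in uniform-random
background sequence.

## Physicochemical profile

MW sums average residue masses plus one water; GRAVY is the mean
Kyte–Doolittle hydropathy; the aliphatic index is
fA + 2.9 fV + 3.9 (fI + fL) in mole percent; the instability index is
(10/L) × Σ Guruprasad dipeptide weights; pI is solved by bisection (to
10⁻⁴ pH units) on the net-charge function under the Bjellqvist pKa set
with residue-specific terminal pKas. Constant tables come from Biopython's
data modules; formulas are implemented here and cross-checked against
Biopython's ProtParam in the tests. Unknown residues (X) are skipped with
length renormalisation for MW/GRAVY/AI and are an error for pI and the
instability index, whose models assign X no contribution.

One subtlety the tests document: because aspartate/glutamate get a weaker
C-terminal carboxyl pK (4.55/4.75 vs the 3.55 default), literally
*appending* D to a peptide can raise its pI. The charge-monotonicity
property (adding a basic residue never lowers pI, an acidic one never
raises it) is therefore asserted for interior insertion, where it holds
strictly.

## Allele grouping and naming

In an autopolyploid, alleles of one locus sit on homologous chromosomes
(same chromosome number, different haplotype letter, e.g. Chr2A–2D).
Genes are grouped into loci by transitive closure over pairs that are on
homologous chromosomes and whose proteins are ≥ 95% identical under
global alignment (threshold configurable; the grouping procedure is a
design choice — published surveys rarely state one). Near-identical pairs
on the *same* haplotype are warned about and kept apart. Loci are
lettered A, B, C… in (chromosome, start) order of each locus's first
allele; multi-allele loci get -1…-k suffixes in the same order. Naming is
invariant to input order; > 26 loci is an error rather than a silent
two-letter scheme.

## Tandem duplication

A tandem cluster is a connected component of the graph joining
same-chromosome gene pairs that are homologous and separated by at most
the window (200 kb default), measured end-of-upstream to
start-of-downstream — conservative and unambiguous compared to midpoint
distance. Singletons are dropped; members are sorted by start; cluster
ids follow (chromosome, start) order. Homology means a provided edge with
identity ≥ 0.4, or global-alignment identity computed from proteins;
with no edge information every same-chromosome pair is treated as
homologous (pure-distance mode).

The homology requirement is not decorative: on the bundled published
coordinate table, the two clusters on chromosome 2D lie within 135 kb of
each other, so pure-distance clustering merges them into one 7-member
component; only homology edges that separate the groups reproduce the
published 2 + 5 membership. Both behaviours are asserted in the tests.
Genes with inter-chromosomal or beyond-window homology are labelled
segmental/WGD candidates; true collinearity inference (MCScanX-style
blocks) is out of scope.

## Ka/Ks (NG86) and divergence times

Synonymous site counts use single-nucleotide neighbor enumeration: at
each codon position, the fraction of the three changes that preserve the
amino acid (changes to stops count as nonsynonymous), averaged over the
two sequences. Codons containing a gap, N, or stop in either sequence are
masked pairwise. Multi-hit codons are averaged over all minimal
substitution pathways with equal weights; pathways through stop codons
are excluded (and re-included only if every pathway is blocked).
Proportions are Jukes–Cantor corrected; ps ≥ 3/4 or pn ≥ 3/4 marks the
result saturated/undefined rather than raising.

Two properties of pathway averaging worth knowing: past saturation the
averaged substitution counts can exceed the site counts (ps > 1), which
the saturation flag covers; and a codon hit twice by synonymous events
can be scored with a fractional nonsynonymous count when one of its
minimal pathways crosses another amino acid (TTG→CTG→CTC vs
TTG→TTC→CTC). Neither affects the moderate-divergence regime the
estimator is for.

The selection test is a two-sided Fisher exact test on
[[Nd, N−Nd], [Sd, S−Sd]] with fractional counts rounded half away from
zero — explicitly an approximation, since the counts are pathway
averages. Divergence times use T = Ks/(2r) with r = 6.1 × 10⁻⁹
substitutions/site/year (the grass synonymous clock); both the rate and
the formula inputs are plain arguments.

Protein-guided codon threading (pal2nal style) maps each protein gap to
one codon gap and verifies every residue translates from its codon,
erroring with the alignment column on mismatch.

## Distances, NJ and bootstrap

Poisson-corrected distances d = −ln(1 − p) are computed with pairwise
deletion (sites with a gap or X in either member of the pair are removed
for that pair only). A pair with no comparable sites, or with p = 1, is
an error — distances are not silently imputed. Neighbor joining is the
standard Saitou–Nei agglomeration on the Q criterion; ties are broken
deterministically by the smallest pair of clade-minimum leaf labels; the
final three nodes are resolved exactly by the three-point formulas;
negative branch lengths are clamped to zero by default (disable with
`clamp_negative=False`). On additive matrices the algorithm recovers the
generating topology and branch lengths to machine precision, which the
tests assert against an independent random-additive-tree construction and
cross-check against dendropy's NJ.

Bootstrap resamples alignment columns with replacement, rebuilds each
replicate via Poisson distance + NJ, and reports support on the full-data
tree's bipartitions (not a majority-rule consensus). Replicates whose
distances are undefined are skipped and tallied. The generator seed is an
explicit argument; identical seeds give identical supports.

## Expression calls

All calls are descriptive fold-change classifications — the input series
have no replicates, so no differential-expression statistics are fitted.
Undetectable means FPKM < 1 in every sample (the detection threshold is a
design choice; the unit itself has no canonical floor). Ratios carry a
0.01 pseudocount. Group preference needs a ≥ 2-fold mean ratio and the
preferred group above detection. Gradient trends use Spearman ρ against
the ordered positions with |ρ| ≥ 0.8 for monotone calls ("gradually
increased" is qualitative; rank correlation is the least parametric
reading), else an interior ≥ 2-fold peak. Diurnal light-elevation must
hold in each cycle series independently. Stress induction needs fold ≥ 2
with the treated sample above detection, combined across
treated/control pairs with an all/any policy. qPCR concordance is the
squared Pearson correlation of the paired vectors.

## Synthetic fixtures: what they show

Generators are pure functions of (parameters, seed) and write truth
tables sufficient to score every downstream stage.

* **Proteins**: requested domain cores and motifs are planted at
  non-overlapping positions in uniform-random background, with motif
  geometry matching the classifier's windows. Contradictory requests
  (DSAW without a WLG domain; DREB1-NLS together with DREB2 diagnostics)
  are rejected.
* **Genome**: cluster members are placed with gaps below the cluster's
  `max_gap`; all other genes are spaced > 200 kb apart, so planted
  clusters are exactly recoverable. Genes are intronless (the family is
  essentially intronless in the motivating system).
* **Codon pairs**: event counts are Poisson with means Ks·S and Ka·N
  (S, N from the ancestor's NG86 site counts); events land on codons
  weighted by their current synonymous (resp. nonsynonymous, stop-free)
  single-step opportunity — the equal-weight single-step model NG86
  assumes, so recovery tests are unbiased in expectation. Targets are
  capped below 0.7 to stay clear of saturation.
* **Expression**: pattern templates (all margins ≥ 2× the thresholds,
  the cold template at 200-fold) under multiplicative log-normal noise,
  σ = 0.2 by default — a plain noise model chosen in the absence of a
  stated one.

Passing these fixtures shows the operations implement their definitions
and recover planted structure at realistic noise; it does not validate
HMM domain calling (hit tables are inputs), alignment quality (aligned
input is required), FPKM quantification, or the biological thresholds
themselves on real genomes.

## Problem sizes

The bundled test and acceptance runs use: the 12-gene published
coordinate table and 11-pair published Ks table; 200 random codon pairs
of ≤ 6 codons against the exhaustive-pathway oracle; 50 seeds of
300-codon pairs for parameter recovery; 50 random additive matrices of
≤ 8 taxa; a 6-taxon, 100-column alignment with 1000 bootstrap
replicates; a 68-gene planted genome; and 45-gene expression matrices.
These sizes make every property deterministic to check while keeping the
full suite in seconds.
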