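# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical edge cases. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Domain model and the scan

A bZIP domain is treated as three consecutive protein segments:

* **basic region** — the nine residues matching `N-x7-R/K` (invariant Asn,
  seven arbitrary residues, invariant Arg/Lys). When a sequence contains
  several matches, the scanner keeps the one whose 18-residue window (basic
  region plus hinge) has the highest Arg+Lys count, ties to the leftmost —
  the basic region is the most charge-dense segment of a genuine bZIP.
* **hinge** — modelled as exactly the nine residues (`x9`) after the
  invariant R/K. This is the only quantitative anchor the canonical motif
  description provides; real hinges vary by a residue or two, which shifts
  downstream sub-region calls accordingly (a known approximation).
* **leucine zipper** — historically demarcated by hand in family surveys;
  automated here with an anchor rule: the register anchor is the first Leu
  (fallback: first Ile/Val/Met) within 15 residues after the hinge, and is
  assigned position *d* of heptad 1, so heptad 1 begins three residues
  earlier at position *a* (clipped at the sequence start, leaving heptad 1
  partial). The zipper extends in 7-residue steps and stops at the sequence
  end, at a 9-heptad cap, or when two consecutive heptads carry no
  hydrophobic residue (L/I/V/M/F/A) at either *a* or *d*; trailing
  degenerate heptads are excluded, so a zipper never ends in heptads
  without a hydrophobic interface. The search window (15), cap (9), floor
  (4), degenerate-run length (2) and hydrophobic set are all
  `ScanConfig` keys.

Proteins without a canonical basic region or with fewer than four heptads
are carried with a null annotation and excluded from dimerization and
intron-pattern statistics (real surveys pre-filter membership with domain
databases, which is outside this package's scope).

## Dimerization statistics

Residue classes: acidic {D,E}, basic {R,K}, hydrophobic {A,F,I,L,M,V},
polar {C,G,H,N,Q,S,T,W,Y}, other {P}. Histidine is treated as neutral by
default (it is only weakly charged at physiological pH in coiled-coil
pairing rules); `include_his_basic` flips it. The g↔e pair geometry is
*g* of heptad *i* against *e* of heptad *i+1* — the standard interhelical
contact for parallel dimers. Pairs touching partial heptads are skipped,
never imputed, so a table with *n* full heptads yields *n − 1* calls, and
all pooled frequencies exclude empty slots and unknown residues (X).

The sub-family score is

```
score = (#attractive − #repulsive − #incomplete) / max(1, #pairs)
      + w · (#Asn at a) / heptads − w · (#charged at a) / heptads
```

with defaults `w = 1`, sub-family I at score ≥ +0.25, II at ≤ −0.25, III
between. The thresholds are not derivable from published family surveys;
they are explicit `SubfamilyConfig` keys, the forced extremes (all
attractive + all Asn ⇒ I; all repulsive + charged a ⇒ II) are what the test
suite pins down, and intermediate memberships should be read as
qualitative.

## Intron patterns

Splicing phase is the coding offset of the junction mod 3 (P0 between
codons, P1/P2 inside one). Protein position *p* maps to CDS nucleotides
`3p−2..3p`; a P0 junction exactly between codons is owned by its 3′ codon
(a deterministic, configurable convention). The pattern table (defaults):
one region intron — (basic,P2)→a, (hinge,P0)→b, (basic,P0)→c,
(hinge,P2)→d; two region introns — both P0 in basic→f, both P0 spanning
basic+hinge→g, anything else→e; none→h. Any P1 region intron or more than
two region introns is `unclassified` (no P1 pattern exists in the
published scheme). The f/g/e boundaries follow the most parsimonious
reading of the published pattern diagrams and live in an editable
`PatternRules` object. The cohort census deliberately reports
`genes_with_introns`, `intronless_genes`, per-pattern counts and
`genes_with_1_2_region_introns` as independent quantities, because
published tallies of these overlap inconsistently.

## Genome landscape

CpG counting is an overlapping scan for the dinucleotide `CG`; a pair that
spans a window boundary belongs to the window containing the C, and N
positions are excluded from each window's effective length. A window is
"high-CpG" iff its density (count/effective length) is strictly above the
genome-wide 75th percentile — strict inequality makes a uniform genome
all-low. Genes are assigned to the window containing their midpoint, with
half-open window ownership.

Duplicate detection substitutes a transparent rule for syntenic-block
databases: all-vs-all global alignment of the bZIP-domain subsequences
(match +1, mismatch 0, linear gap −1; identity = matches/alignment
columns), pairs reported at identity ≥ 0.7, and a pair is *tandem* iff both
genes share a chromosome with ≤ 100 kb between their nearer ends, else
*segmental*. The 100-kb constant follows the convention of published
duplication screens; "maximal length of 100 kb" is ambiguous between block
length and gene separation, and this package interprets it as pair
separation.

## Phylogeny

p-distance uses pairwise deletion (sites with a gap or X in either row are
dropped per pair); a pair with zero comparable sites is an error naming the
pair, and such a bootstrap replicate is skipped with the support
denominator adjusted. Complete deletion is available via the `exclude`
parameter at the alignment level. Neighbor joining is the Saitou–Nei
algorithm: the Q-criterion minimum joined at each step with ties broken by
lowest (row, column) index, branch lengths from the standard split formula
with negatives clamped to zero (logged), and the final three lineages
joined at an unrooted trifurcation. Bootstrap resamples alignment columns
with replacement; support on each internal edge of the original tree is
the percentage of usable replicates containing the same bipartition. All
randomness flows through one seeded NumPy generator, so identical input
and seed give byte-identical Newick. Trees are left unrooted; clade labels
are downstream annotation, not computed.

## Expression

`ΔCT = Ct(target) − Ct(reference)` per replicate (matched by condition and
replicate index), `ΔΔCT = mean ΔCT(condition) − mean ΔCT(calibrator)`, and
the matrix stores `−ΔΔCT` so the calibrator column is exactly 0 and its
fold change exactly 1. DE calls use a two-sided Welch test on replicate
ΔCT (condition vs calibrator) with up at fold ≥ 2, down at fold ≤ 0.5,
p < 0.05; no multiple-testing correction by default (matching common qPCR
practice at this panel size), with a Benjamini–Hochberg switch off by
default. When both replicate groups have zero variance the Welch statistic
is undefined; the call is decided exactly (p = 0 for unequal means, 1 for
equal), which makes noise-free fixtures decidable. Clustering is
agglomerative with 1 − Pearson distance and average linkage, cut at k = 4;
the distance/linkage are config because the original desktop tools never
documented theirs. Cluster labels I–IV are assigned by descending size
(ties by first-gene order) — a reporting convention, not biology.
Constant-profile genes (undefined correlation) are assigned to the nearest
cluster centroid in Euclidean distance and flagged; missing cells are
imputed by gene mean and logged.

## Synthetic-data generators

The generators' defaults are the study conditions the pipeline is
validated under; they are chosen once, from the cohort properties a plant
bZIP survey reports, and are not tuned per run.

**Protein cohort.** Each protein is random N-terminus (5–20 aa) + basic
motif + hinge + zipper + 18-aa tail. Heptad counts are uniform on 4–9.
Asn-at-*a* probabilities default to 0.448 at heptads 2 and 5 and 0.144
elsewhere — the closed-form solution making the pooled Asn fraction 0.23
with a 0.55 share in heptads 2+5 under the heptad-count distribution.
The anchor heptad's *d* is always Leu (it defines the register); later *d*
slots are Leu with probability 0.622, the value that puts the pooled
Leu-at-*d* fraction at 0.68. g↔e pair classes are drawn per pair index
with attractive probability peaking at pair 1, dipping, rising at pair 5
and vanishing at pair 8 (where only repulsive pairs occur), mirroring the
observed cohort shape. Several construction rules guarantee exact
ground-truth recovery in the absence of noise: Asn occurs only at *a*
slots, so the planted basic motif is the unique `N-x7-R/K` match; the
basic x7 is all R/K, so the planted 18-residue window's charge count (≥10)
strictly exceeds what any zipper window can reach (≤9); L/I/V/M are
excluded from zipper slots that precede the anchor; and the C-terminal
tail contains no hydrophobic residue, so the degenerate-heptad stop rule
fires exactly at the planted zipper end. These constraints mean the
generator does **not** emulate noisy motif boundaries, non-canonical basic
regions, or hinge-length variation — passing recovery tests demonstrate
the pipeline's correctness on canonical architectures, not robustness to
divergent ones.

**Gene models.** Proteins are back-translated with a fixed one-codon-per-
amino-acid table (a synthetic convention; codon usage is not emulated).
Introns (60–150 nt, `GT…AG`) are inserted at offsets producing exactly the
requested (sub-region, phase) combination per pattern a–h; pattern-h genes
may still receive an intron outside the region (probability 0.35), which
reproduces the real distinction between region-intronless and fully
intronless genes. The default pattern mix
{a .05, b .04, c .02, d .02, e .04, f .01, g .01, h .81} follows the
qualitative census of the motivating cohort (a, b, e, h prevalent; ~18% of
genes with 1–2 region introns). Genes are embedded on both strands of a
genome generated by a first-order Markov chain whose C→G transition mass
is set per 100-kb block (density ≈ 0.25 × transition mass): background
0.04 (≈1 CpG per 100 bp), planted high blocks 0.32 (≈8 per 100 bp), three
high blocks among twelve windows by default. Intergenic composition is
otherwise unrealistic by design.

**Ct tables.** 14 conditions in 3 treatment groups (5 environmental,
5 heavy-metal, 4 phytohormone) plus an untreated calibrator, 3 replicates,
reference gene constant at Ct 18. Four cluster archetypes are fixed sign
patterns over the conditions (cluster I down everywhere except ABA/MeJA;
II up under environmental and phytohormone, down under heavy metal; III
and IV contrasting group-level patterns) scaled by separation/2 (default
separation 2 cycles ⇒ planted fold changes of 2, exactly at the DE
threshold); replicate noise is Gaussian (sd 0.5 cycles). Genes are split
evenly across clusters.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each property is statistically meaningful: 800
genes for the pattern round-trip (100 per pattern), 200–500 proteins for
binomial parameter recovery, a ~1.2-Mb genome (twelve 100-kb windows) for
CpG verification, 96 genes × 14 conditions × 3 replicates for expression
recovery, 1000 bootstrap replicates on 10 taxa for support stability. All
generators draw from a single `numpy.random.default_rng(seed)`; reruns at
a fixed seed are byte-identical, including FASTA/GFF3 output and Newick
trees.

## Known limitations

* The zipper anchor rule is an automation of a manual convention; register
  assignments can differ from hand-curated ones for non-canonical spacers
  between hinge and zipper.
* The hinge is fixed at 9 residues; real variation shifts basic/hinge
  sub-region boundaries for intron localisation.
* Sub-family I–III thresholds are package conventions; only the forced
  extremes are sharp.
* Duplicate detection is similarity-plus-distance, not synteny; it will
  not reproduce database-derived duplication block calls, and Ka/Ks values
  are consumed as optional input, never computed.
* The NJ implementation is O(n³) densely in NumPy — fine for hundreds of
  taxa, not for thousands.
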