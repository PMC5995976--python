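# Methods

`pandorapan` implements the comparative-genomics toolchain used to study
giant-virus clades of the pandoravirus type: families of ~2 Mb, GC-rich,
linear dsDNA genomes whose strains share a core gene repertoire but differ
by hundreds of lineage-restricted genes. The package couples each analysis
to a forward simulator that generates genomes, evidence, and proteomes with
full ground truth, so every statistic can be validated against known
parameters before it is pointed at real data.

## Stringent annotation

Ab initio ORF calling scans all six frames for ATG..stop ORFs of at least
`min_orf_len` (default 300 nt, stop included); nested same-frame ORFs
resolve to the first ATG after the previous stop. This is deliberately
permissive: in GC-rich sequence the three stop codons (TAA, TAG, TGA, all
AT-rich) are rare by chance, so random open frames of 300+ nt are common
and ab initio calling overpredicts. The stringent step retains an ORF only
with (i) same-strand transcript coverage of at least `cov_min` (5 reads)
over at least `frac_min` (80%) of its span, (ii) `pep_min` (2) distinct
peptides matching its translation, or (iii) a cross-strain homology hit at
`e_max` (1e-5); self-matches never rescue. Same-strand overlaps above 50%
of the shorter ORF keep the better-evidenced, then longer, model. Start
codons are ATG-only (conservative; GTG/TTG starts are a documented
limitation). The thresholds are package defaults, exposed as parameters;
they are not published values.

Splice junctions with at least `j_min` (3) reads that fall inside a gene
(± the UTR window) split its exons, rejected if the spliced CDS length
would no longer be divisible by 3. UTRs extend from the CDS to the coverage
boundary (cap 2 kb). Transcribed islands of 200+ nt not explained by a
same-strand coding model (using its assigned UTRs, or a 400 bp slack when
UTRs are absent) are emitted as lncRNAs, flagged antisense when they
overlap a coding gene on the other strand.

CAI is the geometric mean of per-codon relative adaptiveness w
(count / max count within each synonymous family, floored at 0.01; stops
excluded; Met/Trp contribute w = 1). Genome fractions: transcribed = union
of gene spans, UTRs and lncRNAs over genome length; translated = union of
CDS exon bases.

## Protein families, orthologs, pan-genome

All-vs-all local alignment (BLOSUM62, gap open/extend −11/−1, Biopython
PairwiseAligner) runs behind a 3-mer prescreen (≥ 2 shared 3-mers), with a
score-only first pass; significance is a Karlin–Altschul-style E-value
(λ = 0.267, K = 0.041) — approximate, used only as a permissive floor.
Families are single-linkage connected components of the graph thresholded
at identity ≥ 0.35 and coverage ≥ 0.7 (coverage = aligned span over the
shorter protein); cluster ids are the lexicographically smallest member, so
clustering is invariant to input order and renaming. Orthologs are
reciprocal best hits per genome pair (score, then identity, then id);
groups are RBH components reduced to at most one gene per genome by total
within-component score.

Pan/core rarefaction permutes genome order (default 1000 seeded
permutations) and reports per-step pan and core sizes. Openness is fitted
on the mean number of new clusters per added genome,
dP(N) = κ·N^(−α) for N ≥ 2 by nonlinear least squares; α < 1 classifies the
pan-genome open, a degenerate all-zero dP is reported closed. Genomic
fluidity is φ = mean over genome pairs of (U_k + U_l)/(M_k + M_l) with U
counting genes in families absent from the partner and M all genes;
variance by leave-one-genome-out jackknife. Categories: a cluster in all
genomes is core; in every member of exactly one clade (≥ 2 genomes)
clade-specific; in exactly one genome strain-specific; otherwise accessory.

## Synteny

Collinear blocks chain ortholog pairs on gene rank (not bp): visiting pairs
in genome-a order, a chain extends while both rank steps are ≤ max_gap + 1
(default gap 5) and the b-direction matches the chain's orientation, fixed
by its first step; chains of ≥ min_block (3) survive, inverted chains count
as collinear. Rank chaining is robust to the large absolute length
differences between related genomes. The family-level collinearity figure
is the mean over genome pairs of the fraction of ortholog pairs inside
blocks. The core-density profile is a sliding-window core-gene frequency
along the gene order plus a two-segment change point (the split maximizing
the density difference, ties leftmost; homogeneous input reports delta 0).

## Duplications and dN/dS

A gene is multi-copy when its cluster holds ≥ 2 genes of the same genome.
Closest-paralog distance is the minimum rank distance within a multi-copy
family (1 = adjacent). The duplication-age analysis correlates paralog
protein divergence with that distance (Spearman, one-sided seeded
permutation p).

dN/dS is Nei–Gojobori (1986) pairwise counting: per codon, the synonymous
fraction of the three single-nucleotide changes at each position
(stop-producing changes counted nonsynonymous, so N + S sites sum to 3 per
codon — the simple widely used convention); observed differences averaged
over shortest mutational pathways excluding those through stops; both
proportions Jukes–Cantor corrected (d = −3/4·ln(1 − 4p/3)); ω undefined at
dS = 0. Codon alignments back-thread triplets through a global protein
alignment, dropping gap columns pairwise. Results are "NG86 pairwise" —
counting estimates, not ML codon-model fits. One consequence of the simple
site convention: a stop-avoiding neutral substitution process measures
ω slightly below 1, by ~15% at GC 0.5 and within a few percent at the
GC-rich compositions this package targets; ω comparisons between groups are
unaffected. Clade comparison: within-clade pairwise ω per ortholog group,
Mann–Whitney statistic with a seeded permutation p on the median
difference; refused below 2 values per clade.

## Gene-origin battery

Positional filter: a strain-specific gene qualifies when both flanks
(within max_flank = 3 annotated neighbours) contain a collinear-block
ortholog of category core/clade-specific; chromosome termini fail.
Gradient test: for GC, spliced ORF length, and CAI, category medians across
core → clade-specific → strain-specific → intergenic, adjacent-pair
Mann–Whitney tests with Benjamini–Hochberg correction, verdict "gradient"
only for strictly decreasing medians ("reversed" for strictly increasing).
The intergenic baseline scores random ORFs (≥ 150 nt) found in the
annotation's intergenic complement with the same three features — note that
conditioning on an open frame inflates the baseline's GC relative to raw
intergenic sequence, which the verdict must overcome.

The intergenic homology scan aligns each strain-specific query protein
against six-frame translations of intergenic and ncRNA regions of other
strains (stops as X). A hit needs E ≤ 1e-3 *and* alignment identity ≥ 0.45
over ≥ 25 columns; the identity floor exists because the crude E-value is
miscalibrated for sequences sharing strong compositional bias. A hit at the
homologous location (overlapping the interval between the subject orthologs
of the query's flanking genes) is the de novo birth signature.

Disorder is a FoldIndex-style proxy: I = 2.785·⟨H⟩ − |⟨q⟩| − 1.151 over
51-residue windows (Kyte–Doolittle hydropathy rescaled to [0,1]; charges
K/R +1, D/E −1, H +0.5); a residue is disordered when its window index is
negative. Absolute fractions are not comparable to published
predictor-specific percentages; only orderings between groups are
interpreted.

HGT classification works on a rooted (or midpoint-rooted) gene tree with
tips labelled family/cellular/other_virus: family monophyletic with < 3
non-family lineages between its clade and the root → ancestral; ≥ 3 →
acquired_by_family; some but not all non-family tips inside the family
clade → donated_by_family; otherwise undecided. The embedding depth is the
package's operationalization of "deeply nested" and is configurable.

## Virion proteomics

Replicate iBAQ columns are total-normalized; proteins rank by mean iBAQ,
ties broken by id. The particle proteome is the top k = 200 by default —
the rank region where host-contaminant identifications accumulate — or an
automatic change point: the split minimizing the two-segment least-squares
error of the cumulative host-protein count. The core proteome partitions
proteome clusters by the set of strains whose retained proteomes hit them;
the core fraction is shared-by-all over total. Correlations are Pearson r
on log10 mean iBAQ of paired proteins (identical ids for replicates, an
ortholog map across strains); non-positive pairs are dropped and counted.

## Gene-content cladistics

Presence/absence of clusters per taxon feeds a Jaccard distance matrix and
a neighbor-joining tree (scikit-bio); support is the fraction of
column-bootstrap replicates containing each bipartition of the main tree.
Pairwise percent identity and percent BLOSUM62-positive similarity come
from concatenating per-group alignment columns over the ortholog groups
present in both taxa (per-pair global alignments by default; precomputed
alignments accepted).

## The simulator and what it does (not) emulate

`simulate_clade` evolves an ancestral repertoire down a fixed two-clade
tree (stem 0.10, tip 0.05 substitutions/site by default). Composition is
generated from explicit codon models: coding sequence from GC-targeted
codon weights (bisection on a Boltzmann weight in codon GC) with a mild
hydrophobic bias (0.1, order-promoting) and one boosted preferred codon per
amino acid (strength 1.0, the source of CAI contrast); intergenic sequence
from independent bases at its own GC; de novo genes as random ORFs whose
length follows the chance occurrence of stops at intergenic-like GC, with a
coding-codon admixture (0.28 tip-born, 0.5 for older stem-born genes —
age-dependent amelioration) and a mild charge bias (−0.15) that makes young
proteins relatively disordered. Substitution is K80 (κ = 2) with rejection
of in-frame stop gains and, per gene, rejection of amino-acid changes with
probability 1 − ω (ω defaults: ancestral 0.4, de novo 0.9, HGT 0.6;
per-clade factors available). Because K80 is compositionally symmetric, GC
decays toward 50% along branches; ancestral targets (coding 0.66,
intergenic 0.57) are set so leaf genomes land at ~60% GC and 1.8–2.5 Mb at
the full-scale defaults (950 ancestral genes, 35% intergenic).

Events per gene per branch: tandem-biased duplication (0.04; offset
geometric p = 0.6), loss (0.02, spacers merge), de novo birth (0.03), HGT
insertion (0.005, foreign GC 0.45). Ancestral families (~20% multi-copy,
occasional 10–30-member families) place diverged paralogs farther from
their founder (Poisson shift scaled by divergence), encoding the
duplication-age signal in the standing genome. Evidence: 97% of genes are
transcribed (depth log-normal above the coverage threshold), UTRs
exponential (mean 150 bp) clipped to a third of the flanking spacer; 10% of
genes carry one in-frame, stop-free GT..AG intron (length divisible by 3) so
the unspliced gene still reads through as one ORF and intron detection is
purely junction-driven — real introns interrupt frames, which would require
a transcript assembler rather than an ORF caller; 70% of expressed genes
yield 1–3 tryptic peptides. lncRNAs are 70% antisense (200–450 nt inside a
gene, opposite strand) and otherwise placed in the middle third of large
spacers. Virion proteomes: a conserved core of families present in all
strains with log-normal abundance (μ 5.5, σ 1.2 dex), strain abundance
noise 0.5 dex (cross-strain r ≈ 0.85), replicate noise 0.1 dex
(replicate r > 0.97), a strain-specific viral accessory tail, and host
contaminants ~2 dex lower (accumulating below the retention cutoff). A few
de novo genes are additionally planted, degraded (8% mutations, broken
start, premature stops), into the homologous spacer of a sister strain —
the ground truth for the intergenic scan.

Not emulated: read-level sequencing noise, assembly errors, recombination,
genuinely frame-breaking introns, alternative starts, compositional strand
asymmetry, and real database homology (ORFan status must be supplied).
Passing tests therefore demonstrate statistical and algorithmic
correctness under a faithful generative regime, not robustness to raw-data
artefacts.

## Problem sizes and determinism

Tests and the acceptance script run desk-scale clades (25–90 ancestral
genes, ~30–60 kb genomes) for the alignment-heavy stages and the full-scale
defaults where only sequence-level statistics are needed; rarefaction uses
100–200 permutations, bootstraps 20–100 replicates, permutation tests 999
draws. A single NumPy Generator keyed by the seed drives the simulator;
pipeline stages derive per-stage seeds from the master seed, making reruns
byte-identical.
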