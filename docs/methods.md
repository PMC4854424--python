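# Methods

## Domain model

A WRKY domain is detected as a heptapeptide core followed by a zinc
finger. The core search matches the variant list `{WRKYGQK, WRKYGKK,
WEKYGQK}` at every offset (overlaps allowed); the highly divergent
4-letter replacements (`WKKY`, `WKRY`, `WSKY`, `WIKY`, `WRIC`, `WRMC`,
`WRRY`, `WVKY`) are matched as a 4-mer plus any three residues and are
off by default, because their full seven-residue extension is not
standardised. `X` never matches a motif position.

The finger parser searches up to 120 residues downstream of a core
(domain ≈ 60 aa, with margin) for `C-Xm-C-Xn-H-X-[H|C]` with
`m ∈ {4,5,7}` and `n ∈ {22,23}` — the spacings observed across the
family groups; both sets are configurable. Among legal arrangements the
smallest first-cysteine position wins, ties broken by smaller *m* then
*n*, which makes parsing deterministic. A core without a legal finger
yields an incomplete domain.

## Classification

Rules: ≥2 complete C2H2 domains → I; one C2H2 domain with m=4 → IIc;
one C2HC (or m=7) domain → group III candidate; one C2H2 with m=5 →
unresolved within II (IIa/IIb/IId/IIe share that spacing). Unresolved
proteins are placed on a neighbor-joining tree of domain sequences
together with labelled references, and take the label of the smallest
clade containing them whose labelled references are unanimous, falling
back to the nearest reference by path distance. C2HC candidates are
group III when they fall inside the clade spanned by the group-III
references; a C2HC protein whose placement is III-like but which sits
outside that spanned clade **and** exceeds the divergence length
(default 800 aa — family members are typically ≤ ~750 aa while the
divergent group-IV proteins run well over 1,300) is group IV; remaining
cases are NG (no group). A protein mixing one C2H2 and one C2HC domain
is labelled by its C-terminal domain with a warning.

Named motifs are scanned as regular expressions: HARF
`RTGHARFRR[AG]P`; co-activator LxxLL `L..LL`; repressor LxLxLx
`L.L.L.` (the trailing residue required by default; a 5-residue
`L.L.L` convention is switchable); leucine zipper = four leucines at
exact heptad spacing (count configurable).

## Physicochemical profile

Computed from constant tables shipped as package data
(`data/physchem_constants.json`): average residue masses plus one
water for MW; the Kyte–Doolittle scale for GRAVY; the aliphatic index
X(A) + 2.9·X(V) + 3.9·(X(I)+X(L)) over mole percentages; the
Guruprasad dipeptide-weight table for the instability index
(10/L · Σ DIWV). The isoelectric point solves the
Henderson–Hasselbalch net-charge equation over the termini and the
D/E/C/Y/H/K/R side chains by bisection on [0, 14] to 1e-4, reported to
two decimals. The default pKa set is Bjellqvist (including its
residue-specific terminal pKa values, so results agree with the
ExPASy-style tools commonly used for census tables); the EMBOSS set is
selectable. `X` residues contribute the mean residue mass to MW and
are excluded from the other denominators.

## Gene structure

One model per gene: the mRNA with the greatest total CDS length.
Coordinates convert from GFF3 (1-based inclusive) to 0-based half-open;
minus-strand CDS are ordered 5′→3′. Intron phase is the upstream coding
length mod 3. For introns inside a WRKY domain, the residue
"immediately 3′ of the junction" is the residue whose codon contains
the first coding nucleotide after the intron — this makes R/V typing
total for phase-1/2 introns. R-type = that residue is arginine;
V-type = valine exactly six residues after the finger's second cysteine
(a ±1 tolerance flag exists because "six residues after" can be counted
inclusively). Everything else inside the domain is `other`; introns
outside it are `none`.

## Chromosomal organization

Family naming numbers placed loci by (natural chromosome order, start)
with unplaced loci last — re-running is idempotent and input-order
invariant. Clusters follow the Holub notion of family genes in a short
interval, implemented as single-linkage chains with start-to-start
gaps ≤ 200 kb (start-to-start is insensitive to gene length; the
threshold is configurable since the cluster definition carries no
universal number). Tandem pairs are consecutive same-chromosome family
members with at most one intervening non-family gene and ≥70%
amino-acid identity over a global (BLOSUM62, affine-gap) alignment —
criteria chosen as conventional defaults. Segmental-duplication /
collinearity analysis is out of scope.

## Phylogeny

Progressive alignment: all pairwise Gotoh global alignments (BLOSUM62,
gap open 10, extend 0.5) give p-distance estimates; an average-linkage
(UPGMA) guide tree orders profile–profile merges scored by
sum-of-pairs. Distances on the final alignment are p-distances
(gapped columns excluded per pair), with a Poisson correction
selectable — both are offered because distance-NJ protein trees are
commonly built with either. NJ follows Saitou–Nei with ties broken by
the lowest (row, column) index pair, so the tree is a deterministic
function of the matrix; negative branch lengths are clamped to zero
with a warning (standard practice). On additive matrices the topology
and branch lengths are recovered exactly; tests verify this against an
exhaustive least-squares topology search (`_exhaustive`, deliberately
naive, n ≤ 5). Bootstrap resamples alignment columns with replacement;
support is the percentage of replicate NJ trees containing each
internal bipartition of the full-data tree, seeded and reproducible.
The alignment is a reimplementation by property — no attempt is made
to reproduce any particular aligner's output bit-for-bit.

## Expression calls

Inputs are nonnegative gene × sample matrices with sample metadata
(tissue, days-after-flowering stage, treatment, paired control). A gene
is expressed in a tissue when its maximum over that tissue's untreated
samples exceeds the detection threshold (default 0, i.e. presence;
configurable for abundance units). Developmental trends use per-stage
means of untreated fruit samples excluding treatment controls: `up`
when last/first ≥ fold (default 2) and the series is non-decreasing
within a relative tolerance (default 0), `down` symmetric, `flat` when
max/min < fold, otherwise `mixed`; a zero baseline with later signal
counts as an infinite fold and is logged. Treatment responses compare
each treated sample with its paired control: `induced`/`repressed` at
≥ fold either way, `undetected` when both sit at or below the detection
threshold. A 2^−ΔΔCt helper converts qPCR cycle differences to linear
folds. No differential-expression statistics are attempted — the calls
are qualitative by design.

## Synthetic data

The generators plant exactly the signals the stages detect. Proteins:
fixed, mutually divergent domain prototypes per group (seeded
independently of the user seed), with members differing by 0–2
substitutions at filler positions only — never the core, the C/H
anchors, or the IIa/IIb valine. Flanks are i.i.d. uniform over the 20
amino acids, rejection-sampled against the core-variant list; spacers
and linkers exclude C/H (unambiguous finger parses) and W (no spurious
cores). Group-IV analogs append ~900 extra residues, reflecting the
extreme lengths of divergent C2HC proteins. Genomes: 1 Mb default
chromosomes (sizes configurable; infeasible plans raise an error naming
the offending entry), genes reverse-translated with a fixed
codon-per-residue table, introns inserted at exact codon junctions
(R-type before the core arginine, V-type before the finger valine),
clusters laid out within their planned spans, tandem pairs as adjacent
near-identical copies, non-cluster neighbours spaced 250 kb apart so no
unplanned clusters arise. Expression: linear-scale base level 10,
16-fold geometric trends over five stages, 8-fold treatment responses,
additive Gaussian noise on the log2 scale clipped at zero; planted
folds must exceed the call threshold by at least two noise standard
deviations, enforced at generation time.

What the generator does **not** emulate: real flanking-sequence
composition biases, alignment-difficult indel variation inside domains,
overlapping/alternatively-spliced gene models, UTRs, sequencing-depth
effects or count noise in expression. Passing recovery tests therefore
demonstrates the correctness of the coordinate arithmetic, rule logic
and tree placement — not robustness to the full messiness of genome
annotations.

## Problem sizes

Desk-scale defaults keep every check cheap: the standard bundle is two
members per group plus four decoys (21 proteins with one tandem
duplicate), the scanner oracle runs 1,000 random sequences, the NJ
oracle 100 random additive matrices (4–5 taxa), the noisy-expression
check 50 genes at noise 0.1, and census bootstraps default to 100
replicates (1,000 via the CLI flag when a final tree is wanted). The
whole validation suite completes in seconds on one CPU.

## Known limitations

- Subgroup resolution requires labelled reference domains; without a
  tree, C-X5 proteins remain NG and III/IV are split by length alone.
- The cluster threshold and tandem-identity defaults are conventions;
  biological conclusions should test sensitivity to them.
- Zero-length branch ties in NJ make within-cluster attachment of
  near-identical domains arbitrary (though deterministic); subgroup
  calls are robust to this, but fine within-subgroup topology is not
  meaningful.
- Full-scale runs on a real annotation require the genome's FASTA/GFF3
  locally; only gene-model coordinates and protein sequences are used.
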