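# Methods

This note records the models, parameter choices and numerical decisions
behind `lipoarch`, in the order the pipeline uses them.

## Modal codon usage and the HGT screen

**Model.** Within each synonymous codon family f (the 18 amino acids
with ≥ 2 codons in the standard/table-11 code; Met, Trp and stops carry
no synonymous choice and are excluded everywhere), a genome has a modal
frequency vector q_f. A gene with family counts n (N_f = Σ n_c) is
scored with the likelihood-ratio statistic

    G = 2 Σ_f Σ_c n_c ln( n_c / (N_f q_c) )

summed over families the gene actually uses. Genes whose usage departs
from the mode at p < 0.10 are putative horizontal acquisitions; p < 0.05
is reported as the conservative flag. Flags use strict inequalities.

**Reference distribution.** Two references are implemented:

* `method="chi2"`: χ² with df = Σ_f (k_f − 1) over represented
  families — the textbook asymptotic. At realistic gene lengths
  (100–500 codons) per-family counts are ~5–30 and this reference is
  **anti-conservative**: measured type-I error at the 0.10 threshold is
  0.14–0.22, and Williams-type corrections still leave ~0.12–0.13. The
  2-codon-family example in the test suite quantifies the error against
  exact enumeration (~0.06 at N = 10).
* `method="mc"` (default): parametric bootstrap. Each represented
  family is resimulated `n_sim = 1999` times as Multinomial(N_f, q_f),
  and p = (1 + #{G* ≥ G}) / (n_sim + 1). This is exact up to Monte
  Carlo error at any gene length; measured type-I error at 0.10 is
  0.094–0.11 over seeds. The bootstrap stream is deterministic — seeded
  from the call's `seed` argument plus a CRC of the gene id, so
  p-values are reproducible and uncorrelated across a genome's genes.

**Modal profile estimation.** Initialize from the pooled counts of all
genes; iterate { score every gene; re-estimate per-family frequencies
from the pooled counts of genes with p ≥ typicality_alpha (default
0.10) } until the typical-gene set is a fixed point (max 50 iterations;
an empty typical set falls back to the pooled profile, and a revisited
set — a cycle — stops early, both with `converged=False`).  Typicality
scoring inside the fit uses the asymptotic reference: the threshold
only carves out a robust core for estimation, so speed matters more
than exact calibration there, while the final gene calls use the
bootstrap. A pseudocount of 0.5 per codon enters profile
estimation only — never the gene counts in G — to keep log terms
finite. With 500 genes of ≥ 100 codons the fitted profile recovers the
generating profile to < 0.02 total-variation distance per family.

## Motif scanning

Patterns are degenerate consensus strings: literal residues, `X`
wildcard, and `(A/B/...)` alternative sets. Two LplA-N motifs are
built in: the 12-position interface/lipoate-binding-loop motif
`RRXTGGG(G/A/S/T)(A/I/V)(I/F/Y)HD`, whose second R and first two Gs
(positions 2, 5, 6) are an invariant core (default: exact matching,
core never relaxable), and the 9-position β9 motif
`G(R/K)K(I/L/V)SGX(A/G)Q` whose first G, S and Q (positions 1, 5, 9)
are substitutable (default tolerance: 1 collective mismatch).
A sequence validates as LplA-N iff both motifs hit at least once.

Numerical/semantic choices: coordinates are 1-based inclusive (the β9
motif spans residues 143–151 in the *T. acidophilum* numbering);
overlapping hits are all reported, sorted by start, with no greedy
masking; an unknown residue `X` in the sequence matches only wildcard
positions — never a core or otherwise constrained position. The scanner
is checked for exact agreement with a brute-force window oracle on
10,000 random sequences.

## Neighbor joining and clade assignment

Classic Saitou–Nei NJ: join the pair minimizing
Q(i,j) = (n−2) d(i,j) − r_i − r_j, assign pendant lengths
l_i = d(i,j)/2 + (r_i − r_j)/(2(n−2)), reduce with
d(u,k) = (d(i,k) + d(j,k) − d(i,j))/2, and finish with the three-taxon
closed form. Ties in Q are broken by the lowest (i, j) index pair, so
results are platform-independent; negative branch lengths are clamped
to zero with a logged warning. The O(n³) implementation is intended for
desk-scale matrices (tens of taxa); on additive matrices it recovers
the generating topology exactly and reproduces the input distances
entrywise to < 1e-9 (verified over 100 random 5–12-taxon trees).

Queries are labelled by the **smallest edge-bounded clade** rule: the
smallest bipartition side containing the query and ≥ 1 labelled
reference, provided all references inside carry one label; mixed-label
clades leave the query `unassigned`. Ties are broken by clade size then
lexicographic leaf content, making assignment deterministic and
order-independent. Note the guarantee of correct assignment applies
when each labelled clade is populated by references; a lone reference
deep inside a neighbouring clade can legitimately capture boundary
queries.

## The inventory rule engine

Per species, from gene-family copy numbers:

* systems: LplA ⟺ (LplA-N ≥ 1 and LplA-C ≥ 1) or fused ≥ 1 (the
  bipartite pair are both required; an orphan LplA-N is audited, not
  called); LipM ⟺ LipM ≥ 1; LipB ⟺ LipB ≥ 1. LipL is tracked but
  never satisfies a route (no archaeal LipL exists).
* completeness: LipB and LipM routes additionally require LipA and E2;
  the LplA route requires E2, or GcvH as the alternative lipoylation
  target — GcvH-only completion is flagged separately.
* aerobiosis: any route complete **with E2** → `aerobic_capable`; zero
  lipoylation genes of any family → `anaerobe_consistent`; everything
  in between (transferase without substrate, GcvH-only LplA) →
  `indeterminate`. GcvH-only routes are deliberately not treated as
  aerobic evidence.
* anomalies (e.g. LipA present where LplA is the sole transferase, the
  *A. pernix* configuration) surface in the audit list; the
  completeness rules never special-case them.
* ambiguous LplA-N/LipM candidates (the "Clade II" situation) resolve
  by correlated evidence: LplA-C present and LipA absent → LplA-N;
  LipA present and LplA-C absent → LipM; otherwise unresolved.

The engine is a pure function of the inventory; the retention summary
tallies species/gene counts per system, single-system exclusivity, and
the co-retention rates (LipA among LipM species, LipA + E2 among LipM
species, E2 among LplA species).

## Statistics

2×2 comparisons use the Yates-corrected χ²,
χ² = N (max(|ad − bc| − N/2, 0))² / ((a+b)(c+d)(a+c)(b+d)), df = 1,
two-sided from the χ² distribution; the one-sided halving is reported
alongside so either reading is auditable. Zero marginals raise rather
than return 0/0. Proportion-vs-reference tests report both the df-1
goodness-of-fit χ² and the exact two-sided binomial p. The concordance
report cross-tabulates {aerobic_capable, anaerobe_consistent} against
{aerobe/facultative/aerotolerant, obligate anaerobe}; indeterminate
predictions and unknown phenotypes are excluded from the test but
counted, and a per-taxonomic-order breakdown is attached.

## Synthetic data: what it emulates, and what it does not

* **Genomes.** The resident profile is drawn per family from a
  symmetric Dirichlet (default concentration 1.0 — codon preferences of
  realistic sharpness; large values approach within-family uniformity).
  An alien profile is an independent draw mixed with the resident at
  weight exp(−divergence), a simple monotone effect-size knob
  (divergence 0 ⇒ identical profiles). Genes are ATG + body + stop,
  lengths log-uniform over 100–500 codons (≥ 30 enforced), amino acids
  uniform over the 18 informative families for both resident and alien
  genes — only synonymous choice differs, which is what the screen
  keys on. Not emulated: operon structure, GC skew, amino-acid
  composition bias, amelioration of transferred genes over time.
* **Inventories.** Phenotype ~ Bernoulli(0.5) aerobe/anaerobe; aerobes
  receive a complete pathway (system drawn from configurable
  frequencies, defaults LplA 0.34 / LipM 0.30 / LipB 0.06, echoing the
  fixture's per-system rates) with probability = the configured
  concordance; anaerobes with probability 0.02. Incomplete species are
  empty or carry a transferase without substrate ("partial",
  probability 0.3). Real phylogenetic correlation between relatives is
  not simulated, so recovered concordance tests sampling behaviour,
  not phylogenetic confounding.
* **Motif beds.** Uniform (or user-specified) residue background with
  exact consensus copies planted at recorded non-overlapping 1-based
  starts. Background windows can produce additional legitimate chance
  hits; recall, not precision, is the guaranteed property.
* **Trees.** Random topologies grown by uniform edge attachment,
  branch lengths uniform on [0.05, 1.0]; the distance matrix is the
  exact path-length matrix plus optional symmetric Gaussian noise.

All generators are driven by `numpy.random.default_rng(seed)`; equal
seeds give byte-identical outputs.

## The 147-species fixture

`fixtures/paper_inventory.tsv` is a synthetic reconstruction of the
survey's species inventory: taxonomic orders, oxygen phenotypes and
per-family copy numbers are assigned so that every published marginal
is reproduced exactly (142 transferase genes in 85 of 147 species; 62
without a pathway; 11 LipB genes in 9 species; 63 LipM genes in 44
taxa; 68 LplA-N genes in 50 taxa; 38/44 LipM species with LipA, 36/44
with LipA + E2; 17/50 LplA species with E2; 67/85 species with exactly
one system; 20/142 genes HGT-flagged). The printed per-system species
counts force 18 dual-system (LplA + LipM) species, so the fixture's
Sulfolobales order has 18 rows. Row-level gene assignments beyond the
marginals are invented; conclusions should be drawn from the marginals
only.

## Problem sizes and limitations

Default test and acceptance runs use 300–2000 simulated genes, 100
random trees of 5–12 taxa, 10,000 60-residue scan sequences and 1000
synthetic species — sizes chosen so the full suite runs in minutes on
one core while keeping Monte-Carlo error well inside the asserted
tolerances. The NJ implementation is cubic and not meant for
thousands-of-leaf trees; the HGT screen assumes in-frame, stop-free
CDS input and treats each gene independently (no correction for
amelioration or strand bias); phenotype labels are inputs — the package
does not curate them.
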