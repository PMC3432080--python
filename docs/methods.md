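# Methods

## Scope and data model

The package reconstructs, as a tested pipeline, the standard desk analysis of
an insect gut serine-protease transcript family: cDNA → deduced protein →
diagnostic residues → putative/homolog designation → phylogenetic grouping,
plus the two statistical analyses that usually accompany such a study
(comparative-Ct qPCR contrasts and a probit LC50). Every stage can run
entirely on synthetic inputs with known truth; the only bundled real data is
the 34-row residue-feature table of the *O. nubilalis* gut protease family
(`data/onub_gut_protease_features.tsv`), which is itself an input, not a
computed artifact.

## ORFs and physical properties (`orf`)

ORFs are scanned on the forward strand only — the transcripts this pipeline
targets are oriented cDNA clones. The longest ATG-initiated ORF wins, ties
break to the smallest start, and an ORF may lack a stop codon only at the 3'
end (flagged `partial`). Translation uses the standard genetic code; a codon
containing N is an error rather than an X, because every downstream residue
matters here.

Masses are average (not monoisotopic) residue masses plus one water,
matching the ExPASy convention for reported kDa values. The isoelectric
point solves net charge = 0 by bisection on pH ∈ [0, 14] to |charge| < 1e-4;
net charge is the Henderson–Hasselbalch sum over termini and D/E/C/Y/H/K/R
side chains with the Bjellqvist pKa set, including its position-specific
N-/C-terminal values. The pKa set is a parameter; note that with the
terminal-specific values, appending a residue can change the C-terminal pKa
class, so pI monotonicity in added charges holds only for
position-independent sets. Properties are computed on the full deduced
protein (signal peptide included), matching how such tables are usually
reported for zymogen cDNAs.

## Anchor transfer (`motifs`)

Diagnostic residues are read off a pairwise global alignment to one curated
reference scaffold per family instead of a full MSA: it is deterministic,
fast, and sufficient for transferring single positions. The aligner is
Needleman–Wunsch/Gotoh with BLOSUM62, gap open 10 and extend 0.5 (a gap run
of length L costs 10 + 0.5·(L−1)); traceback tie-breaks prefer diagonal,
then vertical, then horizontal, so results are reproducible to the byte.
The implementation excludes opening a horizontal gap directly out of another
horizontal gap, which is never optimal when open ≥ extend (enforced).

The shipped references are **synthetic** consensus-like zymogen scaffolds
(`data/synthetic_references.fasta/.json`): a short pro-peptide ending in Arg
followed by a 230-residue mature domain carrying an IVGG-like mature start,
the His/Asp/Ser triad (the catalytic Ser inside its conserved DSGGP
context), six cysteines, and the family S1 residue (Asp for trypsin, Ser for
chymotrypsin); the two families differ at ~35% of unconstrained positions.
All anchor invariants — triad identities, S1 = Ser − 6, cysteine positions —
are validated when the fixture is loaded. Using constructed scaffolds keeps
the package free of downloads; the cost is that anchor transfer is only
demonstrated on sequences that are recognizably protease-like, which is what
the feature-extraction floor is for: a query whose normalized alignment
score (score / reference self-score) falls below 0.2 is labelled family
`unknown` with all fields unresolved. A field whose anchor aligns to a gap
is reported unresolved, never guessed.

`cys_count` counts only the six anchor-aligned positions, so stray
cysteines elsewhere cannot mask a missing conserved one.

The signal-peptide call is a deliberately simple heuristic (hydrophobic-core
run length in the [−13, −3) window plus small-residue bonuses at −3/−1,
cleavage candidates at positions 15–35, threshold 6). It is an annotation
aid only and plays no role in classification or in the reported physical
properties.

## Classification rules (`classify`)

Putative requires: activation residue ∈ {Arg, Lys}; triad exactly
His/Asp/Ser; six conserved cysteines; S1 = Asp (trypsin) or ∈ {Ser, Gly}
(chymotrypsin). Gly is accepted in the chymotrypsin S1 as a common,
tolerated substitution — it is tracked as `s1_class = gly_substituted` so
the canonical-Ser subset stays countable. Any other value of any field makes
the sequence a homolog and is recorded as a named deficiency; a profile can
carry several (e.g. a trypsin-family sequence with a degraded triad *and* a
Gly S1). Family membership is an input to the rules (from the
anchor-alignment score or supplied directly), never inferred from S1: a
trypsin with Ser in S1 is a trypsin homolog, not a chymotrypsin. Partial
cDNAs are classified like all others; partiality travels as a provenance
flag.

## Phylogeny (`phylo`)

Distances are p-distances under pairwise deletion (mismatches over shared
non-gap columns); a Poisson correction −ln(1−p) is available, with p capped
just below 1 to stay finite on extreme bootstrap resamples. The default is
the plain p-distance: for closely related family members the two are nearly
affine transforms of each other and NJ is invariant to that in practice.

Neighbor joining is the Saitou–Nei algorithm with the standard Q-criterion;
ties break to the smallest index pair, and a negative branch length is
clamped to zero with the deficit moved to its sister so path lengths are
preserved. On additive matrices the implementation recovers the generating
topology exactly (tested on 100 random 6–10-taxon trees).

Bootstrap supports are MEGA-style: B column resamples with replacement (each
replicate drawn from its own spawned substream of the seed, so results do
not depend on evaluation order), NJ per replicate, and the support of each
internal edge of the *original* tree is the percentage of replicates whose
tree contains the same leaf-set bipartition. The default B is 5000, the
customary published depth; tests and simulations use B = 100–200, which is
ample to separate ~100% clades from noise.

Because NJ trees are unrooted and the final-join trifurcation is an artifact
of join order, group extraction first midpoint-roots the tree (the usual
display convention); supports are properties of edges and are carried
through rerooting unchanged. Groups are then the maximal clades whose
support meets the threshold, named G1, G2, … in tree order; leaves under no
such clade are `ungrouped`. The default threshold is 75%, with the slightly
laxer 73% reachable through `PhyloConfig` — both conventions appear in the
literature on this family.

The progressive MSA (NJ guide tree on pairwise-alignment p-distances, then
profile–profile alignment with expected-BLOSUM column scores) is a
simplified stand-in for a full aligner; it is deterministic and keeps the
planted anchor columns of simulated families aligned, which is all the
pipeline needs. It is not intended to compete with dedicated MSA tools on
hard alignments.

## Expression statistics (`expression`)

The test statistic operates on replicate ΔCt = Ct_target − Ct_reference
values, the quantity that is approximately normal on the cycle scale, not on
ratios. Technical replicates are averaged into their biological replicate
first. The contrast is an equal-variance two-sample Student t (Welch by
config), two-sided, α = 0.05, per gene and time point with no
multiple-testing correction by default — matching the per-gene testing
convention of this kind of study; Benjamini–Hochberg can be applied
downstream. Ratios are Pfaffl efficiency-corrected with both efficiencies
defaulting to 2.0 fold/cycle; with equal efficiencies the ratio reduces
exactly to 2^(−ΔΔCt) (asserted to 1e-9 in tests, together with reciprocity
ratio(a,b)·ratio(b,a) = 1). Reporting flags combine significance with a
fold-change threshold (default 2-fold).

Tissue patterns are categorical: per gene the set of tissues with detectable
expression over the fixed eight-tissue panel (FG, HG, MG, HL, MT, CA, FB,
SG), "not detected" when empty; per group the consensus is the tissue set
present in at least half the member genes, with dissenting genes listed.

## Bioassay (`bioassay`)

Probit ML on x = log10(dose) — the insecticide-bioassay convention — with
grouped binomial likelihood, Fisher scoring, and step halving so the
log-likelihood is non-decreasing at every accepted step (asserted).
Convergence is gradient norm < 1e-8 (typically 5–10 iterations). The
zero-dose control is excluded from the fit rather than Abbott-corrected,
appropriate when control mortality is zero. All-or-none mortality across
every dose has no finite MLE and raises a `SeparationError`. The LC50
interval is Fieller's solution for −α/β (back-transformed from log10), with
g = z²·Var(β)/β²; when g ≥ 1 the interval is reported unbounded and flagged
rather than fabricated. A delta-method interval can be obtained from the
stored covariance for cross-checking.

## Synthetic data (`synth`)

The generators emulate the study conditions rather than arbitrary data:

* **Protease cDNAs** — signal peptide (default 18 aa) + the family
  pro-peptide ending in Arg/Lys + the family mature scaffold with 10%
  seeded substitutions away from anchors, back-translated with uniform
  synonymous codons; UTR5 (60 nt) is generated ATG-free and the generator
  verifies the planted ORF is the unique longest one. Homologs carry exactly
  one planted deficiency, drawn to mirror the real homologs (Pro/His
  activation, degraded triad residues, a conserved Cys substituted away —
  extracted count 5 — or a swapped S1). Putative chymotrypsins sample Ser
  and Gly S1 variants. Codon usage is uniform because nothing downstream
  depends on codon bias; UTR composition is random and not meant to be
  realistic.
* **Families** — Poisson(branch length × sites) substitutions down a known
  tree, uniform targets; the two-clade benchmark uses 4 + 4 taxa, terminal
  branches 0.05, and a 0.5-substitutions/site internal path on 300-residue
  sequences — clear separation, as in a family with well-differentiated
  subfamilies. Indels are not simulated, so MSA stress is not tested here.
* **Ct tables** — control ΔCt ~ Normal(baseline 5 cycles, σ = 0.3 cycles),
  treated shifted by −log2(fold); 3 biological replicates at 2/6/12/24 h,
  the design of a typical toxin-feeding time course. σ = 0.3 cycles is a
  realistic well-run-qPCR replicate spread.
* **Bioassays** — binomial deaths under Φ(slope·(log10 d − log10 LC50)) at
  the dose series 0, 0.04, 0.20, 1.0, 5.0, 25 µg/ml with 96 larvae per dose
  (six replicate cups of 16), truth LC50 0.25 µg/ml and slope 1.5
  probit/log10 by default. Zero-dose controls never die, matching the
  control-mortality-free setting that justifies excluding them from the fit.

Every generator is a pure function of (spec, seed): reruns are
bit-identical.

What passing on these generators does and does not show: it demonstrates the
pipeline's internal correctness — planted truth is recovered exactly through
transcript → ORF → features → classification, NJ is exact on additive
distances, the t-test holds its nominal size, Fieller intervals are
calibrated — but not robustness to real-data pathologies (sequencing errors,
indel-rich alignments, non-normal Ct noise, heterogeneous bioassay batches).

## Problem sizes used in the checks

The bundled checks run at sizes chosen to make the statistical assertions
sharp while staying quick: 100 ORF/feature/classification round trips; 100
random additive trees; 100 two-clade simulations at B = 100; 10,000 null
t-test simulations (size estimate ± ~0.2% SE); 2,000 Fieller coverage
simulations; 300 LC50 recovery fits. The full suite completes in well under
a minute.

## Known limitations

* Family assignment needs the query to align usably to one of the two
  scaffolds; deeply divergent serine proteases (or non-S1-family enzymes)
  come back `unknown` by design.
* The signal-peptide heuristic is not a trained predictor and should not be
  quoted as one.
* The progressive MSA has no iterative refinement and no terminal-gap
  special-casing.
* The probit model fits a common slope with no natural-response or
  heterogeneity factor.
* Mass/pI ignore post-translational modification and disulfide mass loss,
  as sequence-only predictions always do.
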