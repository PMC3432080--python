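"""Seeded generators for every input the pipeline consumes, with known truth.

These stand in for the wet-lab side of a gut-protease characterization study:
protease-like cDNAs with planted signal peptide, activation residue,
catalytic triad, conserved cysteines and S1 residue (and, for homologs,
exactly one planted deficiency); protein families evolved along a known tree;
replicate qPCR Ct tables with chosen fold changes and Gaussian cycle noise;
and binomial dose-mortality data under a probit response.  Every generator is
a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .bioassay import DoseGroup
from .expression import CtRecord
from .motifs import ReferenceAnchor, FeatureProfile, load_reference_anchors
from .orf import ProteinRecord, TranscriptRecord, STOP_CODONS
from .phylo import DistanceMatrix, TreeNode

_FREE_AA = "ADEFGHIKLMNPQRSTVWY"  # mutation alphabet; Cys reserved for anchors
_HYDROPHOBIC = "LVFI"  # h-region alphabet; no Ala, which would mimic the -3/-1 small residues

_CODONS: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[1].forward_table.items():
    _CODONS.setdefault(aa, []).append(codon)
for aa in _CODONS:
    _CODONS[aa].sort()

DEFICIENCY_FIELDS = ("activation_residue", "catalytic_triad", "cys_count", "s1_pocket")


@dataclass(frozen=True)
class ProteaseSpec:
    family: str = "trypsin"
    designation: str = "putative"  # putative | homolog
    planted_deficiency: str | None = None  # required iff homolog
    signal_length: int = 18
    utr5: int = 60
    utr3: int = 80
    divergence: float = 0.10  # per-site substitution rate away from the family scaffold
    seed: int = 0

    def __post_init__(self):
        if self.family not in ("trypsin", "chymotrypsin"):
            raise ValueError("family must be trypsin or chymotrypsin")
        if (self.planted_deficiency is not None) != (self.designation == "homolog"):
            raise ValueError("planted_deficiency must be given exactly for homologs")
        if self.planted_deficiency is not None and self.planted_deficiency not in DEFICIENCY_FIELDS:
            raise ValueError(f"unknown deficiency {self.planted_deficiency!r}")
        if self.signal_length < 10:
            raise ValueError("signal peptide too short")


def _protected_positions(ref: ReferenceAnchor) -> set[int]:
    a = ref.anchor_positions
    protected = set(a.values())
    protected |= set(range(a["ser"] - 1, a["ser"] + 4))  # DSGGP context
    protected |= set(range(ref.mature_start, ref.mature_start + 4))  # IVGG-like mature start
    return protected


def _mutate_scaffold(seq: str, protected: set[int], rate: float, rng) -> str:
    out = list(seq)
    for i in range(len(out)):
        if i in protected or out[i] == "C":
            continue
        if rng.random() < rate:
            choices = [c for c in _FREE_AA if c != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _make_signal(length: int, rng) -> str:
    # M + basic n-region + hydrophobic core + small residues at -3 and -1
    n_region = "".join(rng.choice(list("KRN"), 2))
    core = "".join(rng.choice(list(_HYDROPHOBIC), length - 6))
    return "M" + n_region + core + "AQA"


def _apply_deficiency(protein: list[str], truth: dict, anchors_abs: dict[str, int], spec, rng) -> None:
    kind = spec.planted_deficiency
    if kind == "activation_residue":
        res = ["P", "H"][rng.integers(2)]
        protein[anchors_abs["activation_site"]] = res
        truth["activation_residue"] = res
    elif kind == "catalytic_triad":
        slot = ("his", "asp", "ser")[rng.integers(3)]
        alternatives = {"his": "YS", "asp": "NE", "ser": "GTV"}[slot]
        res = alternatives[rng.integers(len(alternatives))]
        protein[anchors_abs[slot]] = res
        triad = dict(zip(("his", "asp", "ser"), truth["triad"]))
        triad[slot] = res
        truth["triad"] = (triad["his"], triad["asp"], triad["ser"])
    elif kind == "cys_count":
        slot = f"cys{rng.integers(1, 7)}"
        protein[anchors_abs[slot]] = "S"
        truth["cys_count"] = 5
    elif kind == "s1_pocket":
        res = "S" if spec.family == "trypsin" else "N"
        protein[anchors_abs["s1"]] = res
        truth["s1_residue"] = res


def _random_utr(length: int, rng, forbid_atg: bool) -> str:
    while True:
        utr = "".join(rng.choice(list("ACGT"), length)) if length else ""
        if not forbid_atg or "ATG" not in utr:
            return utr


def _encode_codons(protein: str, rng) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def _longest_orf_is(cdna: str, start: int, end: int) -> bool:
    # the planted span must be the unique longest forward-frame ORF
    best_len, best_start = 0, None
    n = len(cdna)
    for s in range(n - 2):
        if cdna[s : s + 3] != "ATG":
            continue
        e = None
        for j in range(s + 3, n - 2, 3):
            if cdna[j : j + 3] in STOP_CODONS:
                e = j + 3
                break
        if e is None:
            e = s + 3 * ((n - s) // 3)
        if e - s > best_len:
            best_len, best_start = e - s, s
    return best_start == start and best_len == end - start


def synth_protease_cdna(
    spec: ProteaseSpec, anchors: list[ReferenceAnchor] | None = None
) -> tuple[TranscriptRecord, FeatureProfile, ProteinRecord]:
    """A protease-like cDNA plus its ground-truth feature profile and protein.

    The protein is signal peptide + short pro-peptide ending in the activation
    residue + a family mature domain derived from the reference scaffold with
    seeded substitutions away from anchor positions.  Homologs carry exactly
    the planted deficiency.  Codons are uniform over synonymous choices; the
    5' UTR is ATG-free so the planted ORF is the one recovered downstream.
    """
    rng = np.random.default_rng(spec.seed)
    refs = {r.family: r for r in (anchors if anchors is not None else load_reference_anchors())}
    ref = refs[spec.family]

    mature = _mutate_scaffold(ref.sequence[ref.mature_start :],
                              {p - ref.mature_start for p in _protected_positions(ref) if p >= ref.mature_start},
                              spec.divergence, rng)
    activation = ["R", "K"][rng.integers(2)]
    # pro-peptide keeps the reference context so the activation anchor transfers
    pro = ref.sequence[: ref.mature_start - 1] + activation
    signal = _make_signal(spec.signal_length, rng)
    protein = list(signal + pro + mature)
    if spec.family == "chymotrypsin":
        # the family tolerates a Gly substitution in the S1 pocket
        s1_abs = ref.anchor_positions["s1"] - ref.mature_start + len(signal) + len(pro)
        protein[s1_abs] = ["S", "G"][rng.integers(2)]

    offset = len(signal) + len(pro) - ref.mature_start  # reference -> protein coordinates
    anchors_abs = {k: v + offset for k, v in ref.anchor_positions.items()}
    truth = {
        "activation_residue": activation,
        "triad": ("H", "D", "S"),
        "cys_count": 6,
        "s1_residue": protein[anchors_abs["s1"]],
        "mature_start": len(signal) + len(pro),
    }
    if spec.designation == "homolog":
        _apply_deficiency(protein, truth, anchors_abs, spec, rng)
    protein_str = "".join(protein)

    name = f"synth_{spec.family[:3]}_{spec.designation}_{spec.seed}"
    for _ in range(50):
        coding = _encode_codons(protein_str, rng)
        stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
        utr5 = _random_utr(spec.utr5, rng, forbid_atg=True)
        utr3 = _random_utr(spec.utr3, rng, forbid_atg=False)
        cdna = utr5 + coding + stop + utr3
        start = len(utr5)
        end = start + len(coding) + 3
        if _longest_orf_is(cdna, start, end):
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not place the planted ORF as the longest one")

    profile = FeatureProfile(
        id=name,
        family=spec.family,
        activation_residue=truth["activation_residue"],
        triad=truth["triad"],
        cys_count=truth["cys_count"],
        s1_residue=truth["s1_residue"],
        mature_start=truth["mature_start"],
    )
    transcript = TranscriptRecord(name, cdna, description=f"synthetic {spec.family} ({spec.designation})")
    return transcript, profile, ProteinRecord(name, protein_str)


# ---------------------------------------------------------------------------
# sequence families on a tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvolutionSpec:
    tree: TreeNode  # branch lengths in expected substitutions per site
    root_sequence: str
    seed: int = 0


def evolve_sequences(spec: EvolutionSpec) -> dict[str, str]:
    """Evolve the root sequence down the tree: Poisson(branch length x sites)
    substitutions per branch, uniform positions and uniform target residues."""
    rng = np.random.default_rng(spec.seed)
    L = len(spec.root_sequence)
    out: dict[str, str] = {}

    def descend(node: TreeNode, seq: list[str]):
        if node.length < 0:
            raise ValueError("branch lengths must be >= 0")
        nmut = rng.poisson(node.length * L)
        for _ in range(nmut):
            pos = rng.integers(L)
            choices = [c for c in _FREE_AA if c != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
        if node.is_leaf:
            out[node.name] = "".join(seq)
        for child in node.children:
            descend(child, list(seq))

    for child in spec.tree.children:
        descend(child, list(spec.root_sequence))
    return out


def random_protein(length: int, rng) -> str:
    return "".join(rng.choice(list(_FREE_AA), length))


def random_binary_tree(names: list[str], rng, bl_low: float = 0.1, bl_high: float = 1.0) -> TreeNode:
    """Random unrooted topology (trifurcating root) with uniform branch lengths."""
    nodes = [TreeNode(name=n, length=float(rng.uniform(bl_low, bl_high))) for n in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(length=float(rng.uniform(bl_low, bl_high)), children=[a, b]))
    return TreeNode(children=nodes)


def path_distance_matrix(root: TreeNode) -> DistanceMatrix:
    """Additive distances: sum of branch lengths along the path between leaves."""
    import itertools

    names = [l.name for l in root.leaves()]
    dist: dict[frozenset[str], float] = {}

    def leaf_depths(node: TreeNode) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        out = {}
        for c in node.children:
            for k, v in leaf_depths(c).items():
                out[k] = v + c.length
        return out

    def walk(node: TreeNode):
        subs = [(c, leaf_depths(c)) for c in node.children]
        for (c1, s1), (c2, s2) in itertools.combinations(subs, 2):
            for a, da in s1.items():
                for b, db in s2.items():
                    dist[frozenset((a, b))] = da + c1.length + db + c2.length
        for c in node.children:
            walk(c)

    walk(root)
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dist[frozenset((names[i], names[j]))]
    return DistanceMatrix(names, d)


def two_clade_family_tree(
    n_per_clade: int = 4,
    *,
    terminal: float = 0.05,
    clade_depth: float = 0.25,
) -> TreeNode:
    """Two well-separated clades (A*, B*) joined by a long internal branch."""
    clade_a = TreeNode(length=clade_depth, children=[TreeNode(name=f"A{k}", length=terminal) for k in range(n_per_clade)])
    clade_b = TreeNode(length=clade_depth, children=[TreeNode(name=f"B{k}", length=terminal) for k in range(n_per_clade)])
    return TreeNode(children=[clade_a, clade_b])


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CtDesign:
    """True fold changes per gene and time point, plus the noise model.

    ``fold`` maps gene -> {time_h: true treated/control fold change}.  The
    reference-gene Ct is held at ``reference_ct``; the control-arm dCt is
    Normal(baseline_dct, sigma) and the treated arm is shifted by -log2(fold)
    (amplification efficiency 2 per cycle).
    """

    fold: dict[str, dict[float, float]] = field(default_factory=lambda: {"gene1": {24.0: 2.0}})
    sigma: float = 0.3
    n_replicates: int = 3
    baseline_dct: float = 5.0
    reference_ct: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        for gene, per_time in self.fold.items():
            if any(f <= 0 for f in per_time.values()):
                raise ValueError(f"{gene}: fold changes must be positive")


def synth_ct(design: CtDesign) -> list[CtRecord]:
    """Replicate Ct observations for every gene/time/condition in the design."""
    rng = np.random.default_rng(design.seed)
    records = []
    for gene in sorted(design.fold):
        for time_h in sorted(design.fold[gene]):
            fold = design.fold[gene][time_h]
            for condition in ("control", "treated"):
                shift = 0.0 if condition == "control" else -math.log2(fold)
                for rep in range(1, design.n_replicates + 1):
                    dct = design.baseline_dct + shift + rng.normal(0.0, design.sigma)
                    records.append(
                        CtRecord(
                            gene=gene,
                            condition=condition,
                            time_h=time_h,
                            replicate=rep,
                            ct_target=design.reference_ct + dct,
                            ct_reference=design.reference_ct,
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# bioassay
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BioassaySpec:
    """Probit truth for a dose-mortality experiment.

    Defaults mirror a Cry1Ab protoxin feeding assay on third-instar corn borer
    larvae: the published dose series in ug/ml diet, an LC50 of 0.25 ug/ml,
    and six replicate cups of 16 larvae (96 larvae per dose).
    """

    lc50: float = 0.25
    slope: float = 1.5  # probit units per log10(dose)
    doses: tuple[float, ...] = (0.0, 0.04, 0.20, 1.0, 5.0, 25.0)
    n_per_dose: int = 96
    seed: int = 0

    def __post_init__(self):
        if self.lc50 <= 0:
            raise ValueError("lc50 must be positive")
        if any(d < 0 for d in self.doses):
            raise ValueError("doses must be >= 0")


def synth_bioassay(spec: BioassaySpec) -> list[DoseGroup]:
    """Binomial mortality: dead ~ Bin(n, Phi(slope (log10 d - log10 lc50)));
    zero-dose controls have zero mortality."""
    from scipy.stats import norm

    rng = np.random.default_rng(spec.seed)
    groups = []
    for dose in spec.doses:
        if dose == 0:
            groups.append(DoseGroup(0.0, spec.n_per_dose, 0))
            continue
        p = float(norm.cdf(spec.slope * (math.log10(dose) - math.log10(spec.lc50))))
        groups.append(DoseGroup(dose, spec.n_per_dose, int(rng.binomial(spec.n_per_dose, p))))
    return groups
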