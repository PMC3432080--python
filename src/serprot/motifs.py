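"""Diagnostic-residue annotation of serine-protease candidates.

Locates the features that separate catalytically competent trypsins and
chymotrypsins from their inactive homologs: the zymogen activation residue
(the Arg/Lys immediately preceding the mature N-terminus), the His/Asp/Ser
catalytic triad, the six conserved disulfide cysteines, and the S1
specificity-pocket residue six positions upstream of the catalytic serine
(the Asp189/Ser195 relationship in chymotrypsinogen numbering).

Positions are transferred from one curated reference scaffold per family by
pairwise global alignment.  The shipped references are synthetic
consensus-like zymogen scaffolds (see ``data/synthetic_references.fasta``);
they carry every anchor in its canonical sequence context and are validated
at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from ._align import AlignmentMap, global_align, self_score
from .orf import ProteinRecord

ANCHOR_NAMES = ("activation_site", "his", "asp", "ser", "s1") + tuple(f"cys{k}" for k in range(1, 7))

#: residue aligned to an anchored gap; distinct from any amino-acid symbol
UNRESOLVED = "?"


@dataclass(frozen=True)
class ReferenceAnchor:
    """A family reference sequence with 0-based anchor indices."""

    family: str
    sequence: str
    anchor_positions: dict[str, int]

    def __post_init__(self):
        a, s = self.anchor_positions, self.sequence
        missing = set(ANCHOR_NAMES) - set(a)
        if missing:
            raise ValueError(f"{self.family}: missing anchors {sorted(missing)}")
        if s[a["his"]] != "H" or s[a["asp"]] != "D" or s[a["ser"]] != "S":
            raise ValueError(f"{self.family}: triad anchors must read H/D/S")
        if a["s1"] != a["ser"] - 6:
            raise ValueError(f"{self.family}: S1 anchor must sit 6 positions before the catalytic Ser")
        if any(s[a[f"cys{k}"]] != "C" for k in range(1, 7)):
            raise ValueError(f"{self.family}: cysteine anchors must read C")
        if s[a["ser"] - 1 : a["ser"] + 4] != "DSGGP":
            raise ValueError(f"{self.family}: catalytic Ser lacks its conserved DSGGP context")

    @property
    def mature_start(self) -> int:
        return self.anchor_positions["activation_site"] + 1


@dataclass(frozen=True)
class FeatureProfile:
    """The residue features used by the trypsin/chymotrypsin rule classifier."""

    id: str
    family: str  # trypsin | chymotrypsin | unknown
    activation_residue: str = UNRESOLVED
    triad: tuple[str, str, str] = (UNRESOLVED, UNRESOLVED, UNRESOLVED)
    cys_count: int = 0
    s1_residue: str = UNRESOLVED
    mature_start: int | None = None
    partial: bool = False

    def __post_init__(self):
        if not 0 <= self.cys_count <= 6:
            raise ValueError("cys_count must be within 0..6")

    @property
    def resolved(self) -> bool:
        return UNRESOLVED not in (self.activation_residue, self.s1_residue, *self.triad)


def load_reference_anchors(
    fasta: str | Path | None = None, sidecar: str | Path | None = None
) -> list[ReferenceAnchor]:
    """Load the per-family references (shipped synthetic scaffolds by default)."""
    from Bio import SeqIO

    pkg = resources.files("serprot") / "data"
    fasta = Path(fasta) if fasta else pkg / "synthetic_references.fasta"
    sidecar = Path(sidecar) if sidecar else pkg / "synthetic_references.json"
    with resources.as_file(fasta) as fp, resources.as_file(sidecar) as sp:
        seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fp), "fasta")}
        anchors = json.loads(Path(sp).read_text())
    return [ReferenceAnchor(fam, seqs[fam], {k: int(v) for k, v in pos.items()}) for fam, pos in anchors.items()]


def align_to_reference(
    query: str,
    ref: ReferenceAnchor,
    *,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentMap:
    """Global alignment of a query protein to a family reference scaffold."""
    return global_align(query, ref.sequence, gap_open=gap_open, gap_extend=gap_extend)


def extract_features(
    p: ProteinRecord,
    anchors: list[ReferenceAnchor] | None = None,
    *,
    family_floor: float = 0.2,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> FeatureProfile:
    """Read the diagnostic residues of a protein off its best family alignment.

    The family is the best-scoring reference (normalized by the reference
    self-score); below ``family_floor`` the protein is not protease-like and
    every field is left unresolved.  A diagnostic field is unresolved when its
    anchor aligns to a gap - it is never guessed.
    """
    refs = anchors if anchors is not None else load_reference_anchors()
    best_ref: ReferenceAnchor | None = None
    best_map: AlignmentMap | None = None
    best_norm = -float("inf")
    for ref in refs:
        am = align_to_reference(p.sequence, ref, gap_open=gap_open, gap_extend=gap_extend)
        norm = am.score / self_score(ref.sequence)
        if norm > best_norm:
            best_ref, best_map, best_norm = ref, am, norm
    assert best_ref is not None and best_map is not None
    if best_norm < family_floor:
        return FeatureProfile(id=p.id, family="unknown")

    ref_to_query = {r: q for q, r in best_map.pairs if r is not None}

    def residue_at(anchor: str) -> str:
        q = ref_to_query.get(best_ref.anchor_positions[anchor])
        return p.sequence[q] if q is not None else UNRESOLVED

    cys_count = sum(residue_at(f"cys{k}") == "C" for k in range(1, 7))
    act_q = ref_to_query.get(best_ref.anchor_positions["activation_site"])
    return FeatureProfile(
        id=p.id,
        family=best_ref.family,
        activation_residue=residue_at("activation_site"),
        triad=(residue_at("his"), residue_at("asp"), residue_at("ser")),
        cys_count=cys_count,
        s1_residue=residue_at("s1"),
        mature_start=act_q + 1 if act_q is not None else None,
    )


# ---------------------------------------------------------------------------
# signal peptide heuristic
# ---------------------------------------------------------------------------

_HYDROPHOBIC = set("AILMFVWC")
_SMALL = set("AGSCT")


def signal_peptide_heuristic(
    p: ProteinRecord | str,
    *,
    min_cleavage: int = 15,
    max_cleavage: int = 35,
    threshold: float = 6.0,
) -> int | None:
    """Crude secretory signal-peptide call: best-scoring cleavage index or None.

    For each candidate cleavage index the score is the longest hydrophobic run
    within the core window [-13, -3) plus a bonus of 2 for a small residue at
    the -3 and -1 positions.  This is a lightweight annotation aid, not a
    replacement for a trained signal-peptide predictor.
    """
    seq = p if isinstance(p, str) else p.sequence
    if len(seq) < 25:
        raise ValueError("sequence shorter than 25 residues")
    best_k, best_score = None, -1.0
    for k in range(min_cleavage, min(max_cleavage, len(seq) - 1) + 1):
        window = seq[max(k - 13, 0) : k - 3]
        run = longest = 0
        for c in window:
            run = run + 1 if c in _HYDROPHOBIC else 0
            longest = max(longest, run)
        score = float(longest)
        if seq[k - 3] in _SMALL:
            score += 2.0
        if seq[k - 1] in _SMALL:
            score += 2.0
        if score > best_score:
            best_k, best_score = k, score
    return best_k if best_score >= threshold else None


def profile_table(profiles: list[FeatureProfile]):
    """Profiles as a table mirroring the published residue-feature layout."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id": f.id,
                "family": f.family,
                "activation": f.activation_residue,
                "his": f.triad[0],
                "asp": f.triad[1],
                "ser": f.triad[2],
                "cys_count": f.cys_count,
                "s1": f.s1_residue,
            }
            for f in profiles
        ]
    )
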