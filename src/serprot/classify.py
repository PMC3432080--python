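"""Putative-vs-homolog designation of trypsin/chymotrypsin candidates.

A candidate is a *putative* protease only if all four diagnostics conform:

* activation residue Arg or Lys (tryptic zymogen activation),
* catalytic triad exactly His/Asp/Ser,
* all six conserved disulfide cysteines present,
* S1 pocket Asp for trypsins; Ser (canonical) or Gly (a common, tolerated
  substitution) for chymotrypsins.

Anything else is a *homolog* and every non-conforming field is recorded as a
named deficiency.  Family membership is an input (sequence-similarity based),
never inferred from the S1 residue: a trypsin with a Ser S1 is a trypsin
homolog, not a chymotrypsin.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .motifs import UNRESOLVED, FeatureProfile

FAMILIES = ("trypsin", "chymotrypsin")
DEFICIENCY_FIELDS = ("activation_residue", "catalytic_triad", "cys_count", "s1_pocket")

_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


def residue_one_letter(symbol: str) -> str:
    """Accept one- or three-letter residue symbols; return one-letter."""
    s = symbol.strip()
    if len(s) == 1:
        return s.upper()
    return _THREE_TO_ONE[s.capitalize()]


@dataclass(frozen=True)
class Classification:
    id: str
    family: str
    designation: str  # putative | homolog
    deficiencies: tuple[str, ...]
    s1_class: str | None = None  # chymotrypsin only: canonical | gly_substituted | other

    def __post_init__(self):
        if (self.designation == "putative") != (not self.deficiencies):
            raise ValueError("putative designation requires an empty deficiency list")
        if (self.s1_class is not None) != (self.family == "chymotrypsin"):
            raise ValueError("s1_class is defined for chymotrypsins only")


@dataclass(frozen=True)
class ClassificationSummary:
    n_total: int
    n_putative_trypsin: int
    n_putative_chymotrypsin: int
    n_homolog: int
    n_gly_s1_putative_ctp: int
    table: pd.DataFrame

    def __post_init__(self):
        if self.n_total != self.n_putative_trypsin + self.n_putative_chymotrypsin + self.n_homolog:
            raise ValueError("summary counts do not add up")


def classify_profile(f: FeatureProfile) -> Classification:
    """Apply the residue rules to one feature profile."""
    if f.family not in FAMILIES:
        raise ValueError(f"{f.id}: family must be one of {FAMILIES}, got {f.family!r}")
    unresolved = [
        name
        for name, value in [
            ("activation_residue", f.activation_residue),
            ("catalytic_triad", "".join(f.triad)),
            ("s1_pocket", f.s1_residue),
        ]
        if UNRESOLVED in value
    ]
    if unresolved:
        raise ValueError(f"{f.id}: unresolved fields {unresolved}")

    deficiencies = []
    if f.activation_residue not in ("R", "K"):
        deficiencies.append("activation_residue")
    if f.triad != ("H", "D", "S"):
        deficiencies.append("catalytic_triad")
    if f.cys_count != 6:
        deficiencies.append("cys_count")
    allowed_s1 = ("D",) if f.family == "trypsin" else ("S", "G")
    if f.s1_residue not in allowed_s1:
        deficiencies.append("s1_pocket")

    s1_class = None
    if f.family == "chymotrypsin":
        s1_class = {"S": "canonical", "G": "gly_substituted"}.get(f.s1_residue, "other")
    return Classification(
        id=f.id,
        family=f.family,
        designation="homolog" if deficiencies else "putative",
        deficiencies=tuple(deficiencies),
        s1_class=s1_class,
    )


def classify_set(profiles: list[FeatureProfile]) -> ClassificationSummary:
    """Classify a batch, keeping input order; per-profile errors carry the id."""
    rows = []
    classifications = []
    for f in profiles:
        c = classify_profile(f)
        classifications.append(c)
        rows.append(
            {
                "id": c.id,
                "family": c.family,
                "designation": c.designation,
                "deficiencies": ",".join(c.deficiencies),
                "s1_class": c.s1_class or "",
            }
        )
    table = pd.DataFrame(rows, columns=["id", "family", "designation", "deficiencies", "s1_class"])
    return ClassificationSummary(
        n_total=len(classifications),
        n_putative_trypsin=sum(c.family == "trypsin" and c.designation == "putative" for c in classifications),
        n_putative_chymotrypsin=sum(
            c.family == "chymotrypsin" and c.designation == "putative" for c in classifications
        ),
        n_homolog=sum(c.designation == "homolog" for c in classifications),
        n_gly_s1_putative_ctp=sum(
            c.designation == "putative" and c.s1_class == "gly_substituted" for c in classifications
        ),
        table=table,
    )


def profiles_from_table(df: pd.DataFrame) -> list[FeatureProfile]:
    """Build profiles from a residue-feature table.

    Expected columns: id, family, activation, his, asp, ser, cys_count, s1;
    residues may use one- or three-letter symbols.  An optional ``partial``
    column is carried through as a provenance flag.
    """
    required = {"id", "family", "activation", "his", "asp", "ser", "cys_count", "s1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    profiles = []
    for _, row in df.iterrows():
        profiles.append(
            FeatureProfile(
                id=str(row["id"]),
                family=str(row["family"]),
                activation_residue=residue_one_letter(row["activation"]),
                triad=(
                    residue_one_letter(row["his"]),
                    residue_one_letter(row["asp"]),
                    residue_one_letter(row["ser"]),
                ),
                cys_count=int(row["cys_count"]),
                s1_residue=residue_one_letter(row["s1"]),
                partial=bool(int(row["partial"])) if "partial" in df.columns else False,
            )
        )
    return profiles
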