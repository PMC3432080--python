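"""Bundled datasets.

``load_gut_protease_features`` returns the curated residue-feature table for
the 34 trypsin/chymotrypsin-like transcripts characterized from the European
corn borer (*Ostrinia nubilalis*) larval gut: per transcript the family, the
zymogen activation residue, the three catalytic-triad residues, the number of
conserved disulfide cysteines, the S1 pocket residue, the published
putative/homolog designation, and whether the underlying cDNA was partial.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .classify import profiles_from_table
from .motifs import FeatureProfile


def load_gut_protease_features(path: str | Path | None = None) -> pd.DataFrame:
    """The 34-row residue-feature table as a DataFrame (input order preserved)."""
    if path is None:
        src = resources.files("serprot") / "data" / "onub_gut_protease_features.tsv"
        with resources.as_file(src) as fp:
            return pd.read_csv(fp, sep="\t")
    return pd.read_csv(path, sep="\t")


def load_gut_protease_profiles() -> tuple[list[FeatureProfile], pd.DataFrame]:
    """Feature profiles plus the raw table (which carries the published designation)."""
    df = load_gut_protease_features()
    return profiles_from_table(df), df
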