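"""Comparative-Ct (ddCt/Pfaffl) relative expression with replicate t-tests.

Quantities of interest: per gene and time point, the expression ratio of
treated to control guts, normalized to a reference transcript.  With equal
amplification efficiencies E the Pfaffl ratio reduces to the textbook
2^(-ddCt).  Statistics operate on replicate dCt values (the normal-scale
quantity); technical replicates are averaged into their biological replicate
before testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TISSUES = ("FG", "HG", "MG", "HL", "MT", "CA", "FB", "SG")


@dataclass(frozen=True)
class CtRecord:
    """One qPCR observation (a biological replicate, technical reps averaged)."""

    gene: str
    condition: str  # treated | control
    time_h: float
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        if self.condition not in ("treated", "control"):
            raise ValueError(f"condition must be treated/control, got {self.condition!r}")
        for ct in (self.ct_target, self.ct_reference):
            if not 0 < ct < 45:
                raise ValueError(f"Ct value {ct} outside (0, 45)")
        if self.replicate < 1:
            raise ValueError("replicate index starts at 1")
        if self.time_h <= 0:
            raise ValueError("time must be positive")


@dataclass(frozen=True)
class ExpressionConfig:
    efficiency_target: float = 2.0  # fold amplification per cycle
    efficiency_reference: float = 2.0
    alpha: float = 0.05
    fold_flag: float = 2.0
    equal_var: bool = True  # Student t by default; False for Welch

    def __post_init__(self):
        for e in (self.efficiency_target, self.efficiency_reference):
            if not 1 < e <= 2:
                raise ValueError("amplification efficiency must be in (1, 2]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.fold_flag < 1:
            raise ValueError("fold_flag must be >= 1")


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    time_h: float
    ratio: float
    log2_ratio: float
    p_value: float
    significant: bool
    direction: str  # up | down | none
    fold_flagged: bool

    def __post_init__(self):
        if self.ratio <= 0:
            raise ValueError("expression ratio must be positive")
        if self.significant and not self.p_value < 1:
            raise ValueError("significance inconsistent with p-value")


def delta_ct(records: CtRecord | Iterable[CtRecord]) -> float | np.ndarray:
    """dCt = Ct(target) - Ct(reference); vectorized over iterables."""
    if isinstance(records, CtRecord):
        return records.ct_target - records.ct_reference
    return np.array([r.ct_target - r.ct_reference for r in records])


def relative_ratio(
    treated: Sequence[CtRecord],
    control: Sequence[CtRecord],
    cfg: ExpressionConfig | None = None,
) -> float:
    """Efficiency-corrected (Pfaffl) treated/control expression ratio.

    ratio = E_t^(mean Ct_target,control - mean Ct_target,treated)
          / E_r^(mean Ct_ref,control  - mean Ct_ref,treated)

    With E_t = E_r = 2 this equals 2^(-ddCt).
    """
    cfg = cfg or ExpressionConfig()
    if not treated or not control:
        raise ValueError("each group needs at least one replicate")
    dct_target = np.mean([r.ct_target for r in control]) - np.mean([r.ct_target for r in treated])
    dct_ref = np.mean([r.ct_reference for r in control]) - np.mean([r.ct_reference for r in treated])
    return float(cfg.efficiency_target**dct_target / cfg.efficiency_reference**dct_ref)


def differential_test(
    treated: Sequence[CtRecord],
    control: Sequence[CtRecord],
    cfg: ExpressionConfig | None = None,
) -> ExpressionResult:
    """Two-sided two-sample t-test on replicate dCt values, plus ratio flags."""
    cfg = cfg or ExpressionConfig()
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("t-test needs at least 2 replicates per group")
    genes = {r.gene for r in treated} | {r.gene for r in control}
    times = {r.time_h for r in treated} | {r.time_h for r in control}
    if len(genes) != 1 or len(times) != 1:
        raise ValueError("differential_test expects one gene at one time point")
    t_stat, p = stats.ttest_ind(delta_ct(treated), delta_ct(control), equal_var=cfg.equal_var)
    ratio = relative_ratio(treated, control, cfg)
    log2_ratio = math.log2(ratio)
    significant = bool(p < cfg.alpha)
    direction = "none"
    if significant:
        direction = "up" if log2_ratio > 0 else "down"
    return ExpressionResult(
        gene=genes.pop(),
        time_h=times.pop(),
        ratio=ratio,
        log2_ratio=log2_ratio,
        p_value=float(p),
        significant=significant,
        direction=direction,
        fold_flagged=significant and abs(log2_ratio) >= math.log2(cfg.fold_flag),
    )


def analyze_ct_table(df: pd.DataFrame, cfg: ExpressionConfig | None = None) -> pd.DataFrame:
    """Run the comparative-Ct analysis over a replicate Ct table.

    Expected columns: gene, condition, time_h, replicate, ct_target,
    ct_reference.  Rows duplicated at the (gene, condition, time_h, replicate)
    level are treated as technical replicates and averaged first.
    """
    cfg = cfg or ExpressionConfig()
    required = {"gene", "condition", "time_h", "replicate", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns {sorted(missing)}")
    bio = (
        df.groupby(["gene", "condition", "time_h", "replicate"], as_index=False)[["ct_target", "ct_reference"]]
        .mean()
    )
    results = []
    for (gene, time_h), sub in bio.groupby(["gene", "time_h"], sort=False):
        groups = {}
        for cond in ("treated", "control"):
            groups[cond] = [
                CtRecord(gene, cond, float(time_h), int(r.replicate), float(r.ct_target), float(r.ct_reference))
                for r in sub[sub.condition == cond].itertuples()
            ]
        res = differential_test(groups["treated"], groups["control"], cfg)
        results.append(
            {
                "gene": gene,
                "time_h": time_h,
                "ratio": res.ratio,
                "log2_ratio": res.log2_ratio,
                "p_value": res.p_value,
                "significant": res.significant,
                "direction": res.direction,
                "fold_flagged": res.fold_flagged,
            }
        )
    return pd.DataFrame(results)


# ---------------------------------------------------------------------------
# tissue expression patterns
# ---------------------------------------------------------------------------


def tissue_pattern_summary(
    matrix: pd.DataFrame, groups: dict[str, list[str]] | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Categorical tissue-pattern labels from a genes x tissues presence matrix.

    Per gene: the sorted list of tissues with detectable expression, or
    "not detected".  Per group: the consensus tissue set (present in at least
    half of the group's genes) with dissenting genes listed.
    """
    unknown_cols = set(matrix.columns) - set(TISSUES)
    if unknown_cols:
        raise ValueError(f"unknown tissue columns {sorted(unknown_cols)}")
    matrix = matrix.reindex(columns=[t for t in TISSUES if t in matrix.columns]).astype(bool)

    def label(row) -> str:
        present = [t for t in matrix.columns if row[t]]
        return "+".join(present) if present else "not detected"

    per_gene = matrix.apply(label, axis=1)
    per_gene.name = "pattern"

    rows = []
    for gname, members in (groups or {}).items():
        missing = [g for g in members if g not in matrix.index]
        if missing:
            raise ValueError(f"group {gname}: unknown genes {missing}")
        sub = matrix.loc[members]
        if len(sub):
            consensus = [t for t in matrix.columns if sub[t].mean() >= 0.5]
        else:
            consensus = []
        consensus_label = "+".join(consensus) if consensus else ""
        dissent = [g for g in members if per_gene[g] != (consensus_label or "not detected")]
        rows.append({"group": gname, "consensus": consensus_label, "dissenting": ",".join(dissent)})
    return per_gene, pd.DataFrame(rows, columns=["group", "consensus", "dissenting"])
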