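"""Stage orchestration: characterize / phylo / expression / bioassay / simulate.

Each ``run_*`` function is a thin, file-oriented wrapper over the library
modules: it validates its inputs, executes the stage, writes the standard
output tables into an output directory, and returns the in-memory results.
Reports carry the configuration digest and seeds so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import motifs as _motifs
from . import orf as _orf
from . import phylo as _phylo
from . import synth as _synth
from .bioassay import DoseGroup, fit_probit, fit_report
from .expression import ExpressionConfig, analyze_ct_table

log = logging.getLogger("serprot")


class ValidationError(ValueError):
    """Raised before any stage output is written."""


@dataclass
class StageResult:
    outputs: dict[str, Path] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)
    payload: object = None


def _digest(**params) -> str:
    blob = json.dumps({k: repr(v) for k, v in sorted(params.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _require(path: str | Path, what: str) -> Path:
    p = Path(path)
    if not p.is_file():
        raise ValidationError(f"{what} not found: {p}")
    return p


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("stage %s: done in %.2f s", stage, time.perf_counter() - self.t0)

    return _T()


def run_characterize(
    fasta: str | Path | None = None,
    profiles_tsv: str | Path | None = None,
    *,
    outdir: str | Path,
    family_floor: float = 0.2,
) -> StageResult:
    """Sequences (or a residue-feature table) -> properties, profiles, classes.

    With FASTA input the full chain runs: ORF -> translation -> physical
    properties -> anchor-based feature extraction -> rule classification.
    With a feature table only the classification stage runs.  Per-record
    failures are collected and reported; the run continues past them.
    """
    if (fasta is None) == (profiles_tsv is None):
        raise ValidationError("provide exactly one of fasta or profiles_tsv")
    out = Path(outdir)
    result = StageResult()
    with _timed("characterize"):
        out.mkdir(parents=True, exist_ok=True)
        profiles: list[_motifs.FeatureProfile] = []
        if fasta is not None:
            path = _require(fasta, "input FASTA")
            records = _orf.read_fasta(path)
            anchors = _motifs.load_reference_anchors()
            proteins = []
            for rec in records:
                try:
                    if isinstance(rec, _orf.TranscriptRecord):
                        p = _orf.translate(rec, _orf.find_longest_orf(rec))
                    else:
                        p = rec
                    proteins.append(p)
                    profiles.append(_motifs.extract_features(p, anchors, family_floor=family_floor))
                except ValueError as exc:
                    result.errors.append(str(exc))
            props = _orf.property_table(proteins)
            props.to_csv(out / "properties.tsv", sep="\t", index=False)
            result.outputs["properties"] = out / "properties.tsv"
            _motifs.profile_table(profiles).to_csv(out / "profiles.tsv", sep="\t", index=False)
            result.outputs["profiles"] = out / "profiles.tsv"
        else:
            path = _require(profiles_tsv, "feature table")
            profiles = _classify.profiles_from_table(pd.read_csv(path, sep="\t"))

        classifiable = [f for f in profiles if f.family in _classify.FAMILIES and f.resolved]
        for f in profiles:
            if f not in classifiable:
                result.errors.append(f"{f.id}: not classifiable (family {f.family})")
        summary = _classify.classify_set(classifiable)
        summary.table.to_csv(out / "classifications.tsv", sep="\t", index=False)
        result.outputs["classifications"] = out / "classifications.tsv"
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "config_digest": _digest(fasta=fasta, profiles_tsv=profiles_tsv, family_floor=family_floor),
                    "n_total": summary.n_total,
                    "n_putative_trypsin": summary.n_putative_trypsin,
                    "n_putative_chymotrypsin": summary.n_putative_chymotrypsin,
                    "n_homolog": summary.n_homolog,
                    "n_gly_s1_putative_ctp": summary.n_gly_s1_putative_ctp,
                    "n_errors": len(result.errors),
                },
                indent=1,
            )
        )
        result.outputs["summary"] = out / "summary.json"
        result.payload = summary
    return result


def run_phylo(
    fasta: str | Path,
    *,
    outdir: str | Path,
    aligned: bool | None = None,
    distance_model: str = "p_distance",
    bootstrap_replicates: int = 5000,
    support_threshold: float = 75.0,
    seed: int = 0,
) -> StageResult:
    """Protein FASTA -> MSA -> NJ tree with bootstrap supports -> groups.

    Pre-aligned input (rows containing gaps, or ``aligned=True``) bypasses the
    progressive aligner.  ``bootstrap_replicates=0`` skips the bootstrap; the
    tree is written without supports and no groups are extracted.
    """
    path = _require(fasta, "input FASTA")
    out = Path(outdir)
    result = StageResult()
    with _timed("phylo"):
        out.mkdir(parents=True, exist_ok=True)
        from Bio import SeqIO

        raw = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
        if len(raw) < 3:
            raise ValidationError("phylogeny needs at least 3 sequences")
        if aligned is None:
            aligned = any("-" in s for _, s in raw)
        if aligned:
            msa = _phylo.Msa([i for i, _ in raw], [s for _, s in raw])
        else:
            msa = _phylo.progressive_msa(raw)
        with open(out / "alignment.fasta", "w") as fh:
            for i, row in zip(msa.ids, msa.rows):
                fh.write(f">{i}\n{row}\n")
        result.outputs["alignment"] = out / "alignment.fasta"

        if bootstrap_replicates == 0:
            tree = _phylo.neighbor_joining(_phylo.pairwise_distance(msa, distance_model))
            log.warning("bootstrap disabled: supports absent and no groups extracted")
        else:
            cfg = _phylo.PhyloConfig(
                distance_model=distance_model,
                bootstrap_replicates=bootstrap_replicates,
                support_threshold=support_threshold,
                seed=seed,
            )
            tree = _phylo.bootstrap_support(msa, cfg)
        tree = _phylo.midpoint_root(tree)
        (out / "tree.nwk").write_text(tree.to_newick() + "\n")
        result.outputs["tree"] = out / "tree.nwk"
        if bootstrap_replicates > 0:
            groups = _phylo.extract_groups(tree, support_threshold)
            members: dict[str, set[str]] = {}
            for leaf, grp in groups.items():
                members.setdefault(grp, set()).add(leaf)
            supports = {
                grp: node.support
                for node in tree.walk()
                if not node.is_leaf and node.support is not None
                for grp, mem in members.items()
                if grp != "ungrouped" and node.leaf_names() == mem
            }
            df = pd.DataFrame(
                [{"id": leaf, "group": grp, "support": supports.get(grp, "")} for leaf, grp in groups.items()]
            )
            df.to_csv(out / "groups.tsv", sep="\t", index=False)
            result.outputs["groups"] = out / "groups.tsv"
        result.payload = tree
    return result


def run_expression(
    ct_csv: str | Path,
    *,
    outdir: str | Path,
    efficiency_target: float = 2.0,
    efficiency_reference: float = 2.0,
    alpha: float = 0.05,
    fold_flag: float = 2.0,
) -> StageResult:
    """Replicate Ct table (CSV) -> per-gene/per-time relative-expression TSV."""
    path = _require(ct_csv, "Ct table")
    out = Path(outdir)
    result = StageResult()
    with _timed("expression"):
        df = pd.read_csv(path)
        cfg = ExpressionConfig(
            efficiency_target=efficiency_target,
            efficiency_reference=efficiency_reference,
            alpha=alpha,
            fold_flag=fold_flag,
        )
        try:
            res = analyze_ct_table(df, cfg)
        except ValueError as exc:
            raise ValidationError(str(exc)) from exc
        out.mkdir(parents=True, exist_ok=True)
        res.to_csv(out / "expression.tsv", sep="\t", index=False)
        result.outputs["expression"] = out / "expression.tsv"
        result.payload = res
    return result


def run_bioassay(dose_csv: str | Path, *, outdir: str | Path, ci_level: float = 0.95) -> StageResult:
    """Dose-mortality CSV (dose,n,dead) -> probit fit JSON + text report."""
    path = _require(dose_csv, "dose table")
    out = Path(outdir)
    result = StageResult()
    with _timed("bioassay"):
        df = pd.read_csv(path)
        missing = {"dose", "n", "dead"} - set(df.columns)
        if missing:
            raise ValidationError(f"dose table lacks columns {sorted(missing)}")
        groups = []
        for k, row in df.iterrows():
            try:
                groups.append(DoseGroup(float(row["dose"]), int(row["n"]), int(row["dead"])))
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"dose table row {k + 1}: {exc}") from exc
        fit = fit_probit(groups, ci_level=ci_level)
        out.mkdir(parents=True, exist_ok=True)
        (out / "probit.json").write_text(
            json.dumps(
                {
                    "intercept": fit.intercept,
                    "slope": fit.slope,
                    "lc50": fit.lc50,
                    "ci_low": fit.ci_low,
                    "ci_high": None if fit.ci_unbounded else fit.ci_high,
                    "ci_unbounded": fit.ci_unbounded,
                    "g": fit.g,
                    "converged": fit.converged,
                    "iterations": fit.iterations,
                },
                indent=1,
            )
        )
        (out / "probit.txt").write_text(fit_report(fit) + "\n")
        result.outputs["probit"] = out / "probit.json"
        result.outputs["report"] = out / "probit.txt"
        result.payload = fit
    return result


def run_simulate(*, outdir: str | Path, seed: int = 0, n_cohort: int = 34) -> StageResult:
    """Write one synthetic instance of every pipeline input, with truth sidecars."""
    out = Path(outdir)
    result = StageResult()
    with _timed("simulate"):
        out.mkdir(parents=True, exist_ok=True)
        rng = np.random.default_rng(seed)
        anchors = _motifs.load_reference_anchors()

        # cohort of protease cDNAs: put one homolog of each deficiency per family
        specs = []
        deficiencies = list(_synth.DEFICIENCY_FIELDS)
        for k in range(n_cohort):
            family = "trypsin" if k % 2 == 0 else "chymotrypsin"
            if k < 2 * len(deficiencies):
                specs.append(
                    _synth.ProteaseSpec(
                        family=family,
                        designation="homolog",
                        planted_deficiency=deficiencies[k // 2],
                        seed=seed * 1000 + k,
                    )
                )
            else:
                specs.append(_synth.ProteaseSpec(family=family, seed=seed * 1000 + k))
        transcripts, truths = [], {}
        for spec in specs:
            tr, truth, _ = _synth.synth_protease_cdna(spec, anchors)
            transcripts.append(tr)
            truths[tr.id] = {
                "family": truth.family,
                "activation_residue": truth.activation_residue,
                "triad": list(truth.triad),
                "cys_count": truth.cys_count,
                "s1_residue": truth.s1_residue,
                "designation": spec.designation,
                "planted_deficiency": spec.planted_deficiency,
            }
        _orf.write_fasta(transcripts, out / "cohort.fasta")
        (out / "cohort_truth.json").write_text(json.dumps(truths, indent=1))

        # protein family on a two-clade tree
        family_tree = _synth.two_clade_family_tree()
        seqs = _synth.evolve_sequences(
            _synth.EvolutionSpec(family_tree, _synth.random_protein(300, rng), seed=seed)
        )
        with open(out / "family.fasta", "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")

        # qPCR design: a few genes with known folds at the four feeding periods
        times = (2.0, 6.0, 12.0, 24.0)
        fold = {
            "up4x": {t: 4.0 for t in times},
            "up2x": {t: 2.0 for t in times},
            "flat": {t: 1.0 for t in times},
            "down4x": {t: 0.25 for t in times},
        }
        ct = _synth.synth_ct(_synth.CtDesign(fold=fold, seed=seed))
        pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "condition": r.condition,
                    "time_h": r.time_h,
                    "replicate": r.replicate,
                    "ct_target": r.ct_target,
                    "ct_reference": r.ct_reference,
                }
                for r in ct
            ]
        ).to_csv(out / "ct.csv", index=False)

        groups = _synth.synth_bioassay(_synth.BioassaySpec(seed=seed))
        pd.DataFrame([{"dose": g.dose, "n": g.n, "dead": g.dead} for g in groups]).to_csv(
            out / "bioassay.csv", index=False
        )
        result.outputs = {name: out / name for name in
                          ("cohort.fasta", "cohort_truth.json", "family.fasta", "ct.csv", "bioassay.csv")}
    return result
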