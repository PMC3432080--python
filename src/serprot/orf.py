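"""Sequence I/O, ORF finding, translation and deduced-protein properties.

Transcripts here are oriented cDNA clones, so open reading frames are scanned
on the forward strand only.  Physical properties (average molecular mass,
isoelectric point) follow the ExPASy conventions: average residue masses plus
one water, and the Bjellqvist pKa set with position-specific terminal values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqUtils import molecular_weight

NUCLEOTIDES = set("ACGTN")
AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
STOP_CODONS = {"TAA", "TAG", "TGA"}

WATER_MASS = 18.0153


@dataclass(frozen=True)
class TranscriptRecord:
    """An oriented cDNA sequence (uppercase, alphabet A/C/G/T/N)."""

    id: str
    cdna: str
    description: str = ""

    def __post_init__(self):
        if not self.cdna:
            raise ValueError(f"{self.id}: empty cDNA sequence")
        object.__setattr__(self, "cdna", self.cdna.upper())
        bad = set(self.cdna) - NUCLEOTIDES
        if bad:
            raise ValueError(f"{self.id}: illegal nucleotide symbols {sorted(bad)}")


@dataclass(frozen=True)
class OrfSpan:
    """A forward-frame ORF, 0-based half-open; ``partial`` means no stop codon
    was reached before the 3' end."""

    start: int
    end: int
    frame: int
    partial: bool = False

    def __post_init__(self):
        if (self.end - self.start) % 3:
            raise ValueError("ORF length must be a multiple of 3")
        if self.frame != self.start % 3:
            raise ValueError("frame inconsistent with start")


@dataclass(frozen=True)
class ProteinRecord:
    """A deduced (or directly supplied) protein sequence."""

    id: str
    sequence: str
    orf: OrfSpan | None = None
    description: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.id}: empty protein sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"{self.id}: unknown residue symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def read_fasta(path: str | Path, *, kind: str = "auto") -> list[TranscriptRecord] | list[ProteinRecord]:
    """Read a FASTA file into transcript or protein records.

    ``kind`` is "nucleotide", "protein" or "auto"; with "auto" the alphabet of
    the whole file decides (A/C/G/T/N only -> nucleotide).  Raises on an empty
    file or duplicate ids.
    """
    raw = [(r.id, str(r.seq).upper(), r.description) for r in SeqIO.parse(str(path), "fasta")]
    if not raw:
        raise ValueError(f"{path}: no FASTA records")
    seen: set[str] = set()
    for rid, _, _ in raw:
        if rid in seen:
            raise ValueError(f"{path}: duplicate record id {rid!r}")
        seen.add(rid)
    if kind == "auto":
        alphabet = set("".join(s for _, s, _ in raw))
        kind = "nucleotide" if alphabet <= NUCLEOTIDES else "protein"
    if kind == "nucleotide":
        return [TranscriptRecord(rid, s, desc) for rid, s, desc in raw]
    if kind == "protein":
        return [ProteinRecord(rid, s, description=desc) for rid, s, desc in raw]
    raise ValueError(f"unknown kind {kind!r}")


def write_fasta(records, path: str | Path, *, width: int = 60) -> None:
    """Write records (objects with .id and .cdna or .sequence) wrapped at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            seq = getattr(rec, "cdna", None) or rec.sequence
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _orf_candidates(cdna: str):
    n = len(cdna)
    for start in range(n - 2):
        if cdna[start : start + 3] != "ATG":
            continue
        end = None
        for j in range(start + 3, n - 2, 3):
            if cdna[j : j + 3] in STOP_CODONS:
                end = j + 3
                break
        if end is not None:
            yield OrfSpan(start, end, start % 3, partial=False)
        else:
            stop_free_end = start + 3 * ((n - start) // 3)
            yield OrfSpan(start, stop_free_end, start % 3, partial=True)


def find_longest_orf(t: TranscriptRecord) -> OrfSpan:
    """Longest ATG-initiated forward-frame ORF; ties broken by smallest start.

    An ORF lacking a stop codon is allowed only when it runs into the 3' end,
    and is flagged ``partial``.  Raises if no ATG occurs in any forward frame.
    """
    if len(t.cdna) < 6:
        raise ValueError(f"{t.id}: transcript shorter than 6 nt")
    best: OrfSpan | None = None
    for span in _orf_candidates(t.cdna):
        if best is None or (span.end - span.start) > (best.end - best.start):
            best = span
    if best is None:
        raise ValueError(f"{t.id}: no ATG-initiated ORF on the forward strand")
    return best


def translate(t: TranscriptRecord, orf: OrfSpan) -> ProteinRecord:
    """Translate an ORF with the standard genetic code; terminal stop dropped."""
    cds = t.cdna[orf.start : orf.end]
    if not cds or orf.end > len(t.cdna):
        raise ValueError(f"{t.id}: ORF span outside transcript")
    if "N" in cds:
        raise ValueError(f"{t.id}: ORF contains ambiguous nucleotide N")
    aa = str(Seq(cds).translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(f"{t.id}: internal stop codon in ORF")
    return ProteinRecord(t.id, aa, orf=orf, description=t.description)


# ---------------------------------------------------------------------------
# physical properties
# ---------------------------------------------------------------------------


def molecular_mass(p: ProteinRecord | str) -> float:
    """Average (not monoisotopic) molecular mass in Da."""
    seq = p if isinstance(p, str) else p.sequence
    return float(molecular_weight(seq, seq_type="protein", monoisotopic=False))


#: Bjellqvist (ExPASy) side-chain and terminal pKa values.
BJELLQVIST_PKA = {
    "Nterm": 7.5,
    "Cterm": 3.55,
    "K": 10.0,
    "R": 12.0,
    "H": 5.98,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
    # position-specific N-terminal values
    "Nterm_A": 7.59,
    "Nterm_M": 7.0,
    "Nterm_S": 6.93,
    "Nterm_P": 8.36,
    "Nterm_T": 6.82,
    "Nterm_V": 7.44,
    "Nterm_E": 7.7,
    # position-specific C-terminal values
    "Cterm_D": 4.55,
    "Cterm_E": 4.75,
}

_POSITIVE = ("K", "R", "H")
_NEGATIVE = ("D", "E", "C", "Y")


def net_charge(seq: str, ph: float, pka: dict[str, float] | None = None) -> float:
    """Henderson-Hasselbalch net charge of a protein at a given pH."""
    pk = BJELLQVIST_PKA if pka is None else pka
    charge = 1.0 / (1.0 + 10 ** (ph - pk.get(f"Nterm_{seq[0]}", pk["Nterm"])))
    charge -= 1.0 / (1.0 + 10 ** (pk.get(f"Cterm_{seq[-1]}", pk["Cterm"]) - ph))
    for aa in _POSITIVE:
        charge += seq.count(aa) / (1.0 + 10 ** (ph - pk[aa]))
    for aa in _NEGATIVE:
        charge -= seq.count(aa) / (1.0 + 10 ** (pk[aa] - ph))
    return charge


def isoelectric_point(
    p: ProteinRecord | str,
    pka: dict[str, float] | None = None,
    *,
    tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Net charge is monotonically decreasing in pH, so bisection always
    converges; iterate until |charge| < ``tol``.
    """
    seq = p if isinstance(p, str) else p.sequence
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(200):
        c = net_charge(seq, ph, pka)
        if abs(c) < tol:
            break
        if c > 0:
            lo = ph
        else:
            hi = ph
        ph = (lo + hi) / 2.0
    return ph


def property_table(proteins: list[ProteinRecord], accessions: dict[str, str] | None = None):
    """Per-protein physical property table (id, length, mass_kda, pi, accession)."""
    acc = accessions or {}
    rows = [
        {
            "id": p.id,
            "length": len(p),
            "mass_kda": round(molecular_mass(p) / 1000.0, 1),
            "pi": round(isoelectric_point(p), 2),
            "accession": acc.get(p.id, ""),
        }
        for p in proteins
    ]
    return pd.DataFrame(rows)
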