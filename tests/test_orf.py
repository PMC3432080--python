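"""ORF finding, translation and deduced-protein physical properties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from serprot.orf import (
    BJELLQVIST_PKA,
    STOP_CODONS,
    OrfSpan,
    ProteinRecord,
    TranscriptRecord,
    find_longest_orf,
    isoelectric_point,
    molecular_mass,
    net_charge,
    read_fasta,
    translate,
    write_fasta,
)


def brute_force_orfs(cdna: str):
    """Independent oracle: enumerate every forward-frame ATG..stop span."""
    spans = []
    n = len(cdna)
    for s in range(n - 2):
        if cdna[s : s + 3] != "ATG":
            continue
        for j in range(s + 3, n - 2, 3):
            if cdna[j : j + 3] in STOP_CODONS:
                spans.append((s, j + 3, False))
                break
        else:
            spans.append((s, s + 3 * ((n - s) // 3), True))
    return spans


class TestReadFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nATGAAA\n")
        (rec,) = read_fasta(p)
        assert isinstance(rec, TranscriptRecord) and rec.cdna == "ATGAAA"

    def test_duplicate_id_names_offender(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">x\nATG\n>x\nATG\n")
        with pytest.raises(ValueError, match="'x'"):
            read_fasta(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="no FASTA"):
            read_fasta(p)

    def test_order_preserved_and_roundtrip(self, tmp_path, rng):
        recs = [
            TranscriptRecord(f"t{k}", "".join(rng.choice(list("ACGT"), 50)))
            for k in range(34)
        ]
        p = tmp_path / "cohort.fasta"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [r.id for r in back] == [r.id for r in recs]
        assert [r.cdna for r in back] == [r.cdna for r in recs]

    def test_protein_inference(self, tmp_path):
        p = tmp_path / "p.fasta"
        p.write_text(">p\nMKWVF\n")
        (rec,) = read_fasta(p)
        assert isinstance(rec, ProteinRecord)

    def test_illegal_characters(self):
        with pytest.raises(ValueError, match="illegal"):
            TranscriptRecord("x", "ATG#")


class TestFindLongestOrf:
    @pytest.mark.parametrize(
        "cdna, expected",
        [
            ("ATGAAATAA", (0, 9, False)),
            # two candidates; the later one is longer (verified by the oracle below)
            ("CCATGAAATAAATGGGTCATTGA", (11, 23, False)),
        ],
    )
    def test_examples(self, cdna, expected):
        spans = brute_force_orfs(cdna)
        longest = max(spans, key=lambda s: (s[1] - s[0], -s[0]))
        assert (longest[0], longest[1], longest[2]) == expected
        got = find_longest_orf(TranscriptRecord("x", cdna))
        assert (got.start, got.end, got.partial) == expected

    def test_no_orf(self):
        with pytest.raises(ValueError, match="no ATG"):
            find_longest_orf(TranscriptRecord("x", "CCCCCC"))

    def test_partial_flagged_at_three_prime(self):
        got = find_longest_orf(TranscriptRecord("x", "ATGAAAAAA"))
        assert got.partial and got.end == 9

    def test_agrees_with_exhaustive_scan(self, rng):
        for _ in range(1000):
            cdna = "".join(rng.choice(list("ACGT"), int(rng.integers(6, 120))))
            spans = brute_force_orfs(cdna)
            t = TranscriptRecord("x", cdna)
            if not spans:
                with pytest.raises(ValueError):
                    find_longest_orf(t)
                continue
            best = max(spans, key=lambda s: (s[1] - s[0], -s[0]))
            got = find_longest_orf(t)
            assert (got.start, got.end, got.partial) == best


class TestTranslate:
    def test_basic(self):
        t = TranscriptRecord("x", "ATGAAATAA")
        assert translate(t, OrfSpan(0, 9, 0)).sequence == "MK"

    def test_internal_stop(self):
        t = TranscriptRecord("x", "ATGTAAAAATAA")
        with pytest.raises(ValueError, match="internal stop"):
            translate(t, OrfSpan(0, 12, 0))

    def test_ambiguous_codon(self):
        t = TranscriptRecord("x", "ATGANATAA")
        with pytest.raises(ValueError, match="N"):
            translate(t, OrfSpan(0, 9, 0))


class TestMass:
    def test_glycine(self):
        assert molecular_mass("G") == pytest.approx(75.07, abs=0.01)

    def test_diglycine(self):
        assert molecular_mass("GG") == pytest.approx(132.12, abs=0.01)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
        st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30),
    )
    def test_additivity(self, s1, s2):
        water = molecular_mass("G") - (molecular_mass("GG") - molecular_mass("G"))
        assert molecular_mass(s1 + s2) == pytest.approx(
            molecular_mass(s1) + molecular_mass(s2) - water, abs=1e-6
        )

    def test_unknown_residue(self):
        with pytest.raises(ValueError):
            ProteinRecord("x", "GXZ@")


class TestIsoelectricPoint:
    def test_glycine_is_terminal_midpoint(self):
        # one basic and one acidic group with equal magnitudes: pI at the pKa midpoint
        assert isoelectric_point("G") == pytest.approx(
            (BJELLQVIST_PKA["Nterm"] + BJELLQVIST_PKA["Cterm"]) / 2, abs=0.01
        )

    def test_bisection_matches_grid_scan(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 40))
            grid = np.linspace(0, 14, 28001)
            charges = np.array([net_charge(seq, ph) for ph in grid])
            oracle = grid[np.argmin(np.abs(charges))]
            assert isoelectric_point(seq) == pytest.approx(oracle, abs=0.01)

    def test_matches_biopython(self, rng):
        from Bio.SeqUtils.ProtParam import ProteinAnalysis

        for _ in range(20):
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 60))
            assert isoelectric_point(seq) == pytest.approx(
                ProteinAnalysis(seq).isoelectric_point(), abs=0.01
            )

    def test_acidic_tail_drops_below_4(self):
        assert isoelectric_point("DDDD") < 4

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=30))
    def test_monotonic_in_charged_residues(self, seq):
        # under a position-independent pKa set (the terminal-residue-specific
        # Bjellqvist values can shift the C-terminal pKa when the last residue
        # changes, breaking strict monotonicity)
        plain = {k: v for k, v in BJELLQVIST_PKA.items() if "_" not in k}
        base = isoelectric_point(seq, pka=plain)
        assert isoelectric_point(seq + "D", pka=plain) <= base + 1e-6
        assert isoelectric_point(seq + "K", pka=plain) >= base - 1e-6
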