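"""Classify the bundled 34-transcript residue-feature table.

Each row gives the diagnostic residues of one gut serine-protease transcript
from European corn borer larvae.  The rule classifier designates a transcript
putative only when the activation residue, catalytic triad, conserved
cysteines and S1 pocket all conform; otherwise it is a homolog and the
non-conforming fields are listed.
"""

from serprot import classify_set, load_gut_protease_profiles

profiles, table = load_gut_protease_profiles()
summary = classify_set(profiles)

print(f"{summary.n_total} transcripts classified:")
print(f"  putative trypsins        {summary.n_putative_trypsin}")
print(f"  putative chymotrypsins   {summary.n_putative_chymotrypsin}")
print(f"  homologs                 {summary.n_homolog}")
print(f"  Gly-S1 putative chymotrypsins: {summary.n_gly_s1_putative_ctp} "
      "(a tolerated substitution of the canonical Ser)")
print()
print("homologs and their deficiencies:")
hom = summary.table[summary.table.designation == "homolog"]
print(hom[["id", "family", "deficiencies"]].to_string(index=False))
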