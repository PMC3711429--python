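"""Fuse two overlapping ORFs at a predicted frameshift and translate.

The dnaX-style toy below re-reads one nucleotide (-1 shift); the
prfB-style toy skips one and reads through an in-frame TGA (+1 shift).
"""

from fsgene import FsGene, build_fs_protein, extract_frameshift_box

dnax = FsGene(
    id="dnaX_toy", genome_id="g", strand="+",
    orf1=(0, 14), orf2=(8, 14), fs_pos=9, direction=-1,
)
protein = build_fs_protein("ATGAAAAAGGGTAA", dnax)
print("dnaX-style -1 shift")
print("  fused CDS:", protein.cds)            # ATGAAAAAGGGGTAA
print("  fs-protein:", protein.aa, "(junction at residue", protein.fs_aa, ")")

prfb = FsGene(
    id="prfB_toy", genome_id="g", strand="+",
    orf1=(0, 9), orf2=(4, 13), fs_pos=6, direction=+1,
)
protein = build_fs_protein("ATGCTTTGACTAA", prfb)
print("prfB-style +1 shift")
print("  fused CDS:", protein.cds)            # ATGCTTGACTAA, TGA skipped
print("  fs-protein:", protein.aa)

box = extract_frameshift_box("ATGCTTTGACTAA", prfb)
print("frameshift box:", box.seq, "(phase anchor", box.phase_anchor,
      "- the CTT_TGA_C slippery site sits on ORF1 codon boundaries)")
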