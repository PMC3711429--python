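"""Core objects for predicted reading-frame transitions (fs-genes).

A GeneTack-style prediction names two overlapping ORFs on the same strand of
a genome plus the codon boundary at which decoding switches frame (by +1 or
-1 nucleotide).  Joining the two ORFs at that boundary yields the conceptual
protein product, the *fs-protein*; the stop-codon-bounded nucleotide window
around the boundary is the *frameshift box*, the region guaranteed to
contain the true shift site and the substrate for phased motif search.

Coordinates are 0-based, half-open, and always expressed on the coding
strand: minus-strand genes are reverse-complemented at the I/O boundary and
never handled specially here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Seq import Seq

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# 100-nt cap on the frameshift box (high-GC genomes can have very distant
# bounding stops); the 3-nt pad keeps phased heptamers that straddle the
# terminal stop codon (e.g. CTT_TGA_C) inside the box.
BOX_CAP = 100
BOX_PAD = 3


class FsGeneError(ValueError):
    """Inconsistent fs-gene record (coordinates, direction or frame)."""


class InternalStopError(FsGeneError):
    """Fused CDS contains a premature stop codon.

    Signals a wrong frameshift position or direction in the prediction.
    """

    def __init__(self, fs_id: str, codon_index: int):
        self.fs_id = fs_id
        self.codon_index = codon_index
        super().__init__(
            f"fused CDS of {fs_id} has an internal stop at codon {codon_index}"
        )


def _codon_map(table_id: int = 11) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


_CODON_MAPS: dict[int, dict[str, str]] = {}


def translate_cds(cds: str, table_id: int = 11) -> str:
    """Translate a CDS with the bacterial code (table 11 by default).

    Stops are rendered as ``*``; codons with ambiguous nucleotides as ``X``.
    """
    if len(cds) % 3 != 0:
        raise FsGeneError(f"CDS length {len(cds)} not divisible by 3")
    if table_id not in _CODON_MAPS:
        _CODON_MAPS[table_id] = _codon_map(table_id)
    mapping = _CODON_MAPS[table_id]
    cds = cds.upper()
    return "".join(
        mapping.get(cds[i : i + 3], "X") for i in range(0, len(cds), 3)
    )


def coding_sequence(genome: str, strand: str) -> str:
    """Return the coding-strand view of a genome for the given strand."""
    if strand == "+":
        return genome.upper()
    if strand == "-":
        return str(Seq(genome).reverse_complement()).upper()
    raise FsGeneError(f"strand must be '+' or '-', got {strand!r}")


@dataclass(frozen=True)
class FsGene:
    """One predicted frame transition between two overlapping ORFs.

    ``fs_pos`` is the 0-based coding-strand index of the first nucleotide of
    the codon at which the transition applies; it must lie on a codon
    boundary of ORF1.  ``direction`` +1 means decoding skips one nucleotide
    at the junction, -1 means one nucleotide is read twice, so the frame of
    ORF2 differs from ORF1 by exactly ``direction`` modulo 3.
    """

    id: str
    genome_id: str
    strand: str
    orf1: tuple[int, int]
    orf2: tuple[int, int]
    fs_pos: int
    direction: int
    rbs_score: float = 0.0
    genus: str = ""
    annotated_pseudogene: bool = False

    def __post_init__(self):
        if self.direction not in (+1, -1):
            raise FsGeneError(f"{self.id}: direction must be +1 or -1")
        a, b = self.orf1
        c, d = self.orf2
        if not (a < b and c < d):
            raise FsGeneError(f"{self.id}: empty ORF interval")
        if c > b:
            raise FsGeneError(f"{self.id}: ORF1 and ORF2 neither overlap nor abut")
        if not (a <= self.fs_pos < d):
            raise FsGeneError(f"{self.id}: fs_pos outside the gene span")

    @property
    def gene_span(self) -> tuple[int, int]:
        return (self.orf1[0], self.orf2[1])

    @property
    def orf1_frame(self) -> int:
        return self.orf1[0] % 3


@dataclass(frozen=True)
class FsProtein:
    """Conceptual translation of the fused CDS of an fs-gene.

    ``fs_aa`` is the 0-based residue index of the frameshift junction; the
    terminal stop codon is stripped from ``aa``.
    """

    fs_gene_id: str
    cds: str
    aa: str
    fs_aa: int
    direction: int = 0

    def __len__(self) -> int:
        return len(self.aa)


@dataclass(frozen=True)
class FrameshiftBox:
    """Stop-bounded window around a predicted frameshift.

    ``phase_anchor`` is the offset (0-2) such that positions ``p`` in the box
    with ``(p - phase_anchor) % 3 == 0`` are ORF1-frame codon starts.
    ``fs_offset`` is the position of the frameshift codon within the box.
    """

    fs_gene_id: str
    seq: str
    start: int
    end: int
    phase_anchor: int
    fs_offset: int
    direction: int
    truncated: bool = False
    clipped: bool = field(default=False)

    def __len__(self) -> int:
        return len(self.seq)


def _aligned_fs_pos(fs_gene: FsGene) -> int:
    """fs_pos re-anchored to the nearest upstream ORF1 codon boundary."""
    a = fs_gene.orf1[0]
    off = (fs_gene.fs_pos - a) % 3
    if off:
        warnings.warn(
            f"{fs_gene.id}: fs_pos {fs_gene.fs_pos} is not on an ORF1 codon "
            f"boundary; re-anchored {off} nt upstream",
            stacklevel=3,
        )
        return fs_gene.fs_pos - off
    return fs_gene.fs_pos


def build_fs_protein(genome: str, fs_gene: FsGene, table_id: int = 11) -> FsProtein:
    """Fuse the two ORFs at the predicted frameshift and translate.

    The fused CDS is ``coding[orf1_start:fs_pos] + coding[fs_pos+1:orf2_end]``
    for a +1 transition (one nucleotide skipped) and
    ``coding[orf1_start:fs_pos] + coding[fs_pos-1:orf2_end]`` for -1 (one
    nucleotide read twice); this reproduces the classic dnaX (-1) and prfB
    (+1) products.
    """
    s = coding_sequence(genome, fs_gene.strand)
    a = fs_gene.orf1[0]
    d = fs_gene.orf2[1]
    if d > len(s):
        raise FsGeneError(f"{fs_gene.id}: ORF2 end {d} beyond genome length {len(s)}")
    fs = _aligned_fs_pos(fs_gene)
    if fs_gene.direction == +1:
        cds = s[a:fs] + s[fs + 1 : d]
    else:
        cds = s[a:fs] + s[fs - 1 : d]
    if len(cds) % 3 != 0:
        raise FsGeneError(
            f"{fs_gene.id}: fused CDS length {len(cds)} not divisible by 3 "
            "(inconsistent coordinates)"
        )
    aa = translate_cds(cds, table_id)
    internal = aa[:-1].find("*")
    if internal != -1:
        raise InternalStopError(fs_gene.id, internal)
    if aa.endswith("*"):
        aa = aa[:-1]
    return FsProtein(
        fs_gene_id=fs_gene.id,
        cds=cds,
        aa=aa,
        fs_aa=(fs - a) // 3,
        direction=fs_gene.direction,
    )


def extract_frameshift_box(genome: str, fs_gene: FsGene) -> FrameshiftBox:
    """Cut the stop-bounded frameshift box around the predicted shift.

    The 5' bound is the nearest upstream stop codon in ORF2's frame, the 3'
    bound the nearest downstream stop codon in ORF1's frame (both included,
    plus a 3-nt pad past the 3' stop so phased heptamers overlapping it stay
    in-window).  If no bounding stop exists inside the gene the box is
    clipped at the gene boundary.  Boxes spanning more than 100 nt are
    reduced to the 100-nt window centred on the frameshift.
    """
    s = coding_sequence(genome, fs_gene.strand)
    a, gene_end = fs_gene.gene_span
    fs = _aligned_fs_pos(fs_gene)
    # part 2 of the fused CDS starts one nt past (or before) the junction
    q0 = fs + fs_gene.direction

    clipped = False
    # upstream: ORF2-frame codons wholly 5' of the junction
    box_start = a
    p = q0 - 3
    found = False
    while p >= a:
        if s[p : p + 3] in STOP_CODONS:
            box_start = p
            found = True
            break
        p -= 3
    clipped |= not found

    # downstream: ORF1-frame codons at or after the frameshift codon
    box_end = gene_end
    p = fs
    found = False
    while p + 3 <= gene_end:
        if s[p : p + 3] in STOP_CODONS:
            box_end = min(p + 3 + BOX_PAD, gene_end)
            found = True
            break
        p += 3
    clipped |= not found
    if not found:
        warnings.warn(
            f"{fs_gene.id}: no ORF1-frame stop within the gene; box clipped",
            stacklevel=2,
        )

    truncated = False
    if box_end - box_start > BOX_CAP:
        truncated = True
        half = BOX_CAP // 2
        box_start = max(a, fs - half)
        box_end = box_start + BOX_CAP
        if box_end > gene_end:
            box_end = gene_end
            box_start = max(a, box_end - BOX_CAP)

    return FrameshiftBox(
        fs_gene_id=fs_gene.id,
        seq=s[box_start:box_end],
        start=box_start,
        end=box_end,
        phase_anchor=(a - box_start) % 3,
        fs_offset=fs - box_start,
        direction=fs_gene.direction,
        truncated=truncated,
        clipped=clipped,
    )
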