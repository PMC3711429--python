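"""Pairwise local alignment and homology-based validation of fs-proteins.

Exact Smith-Waterman alignment (BLOSUM62, affine gaps costing 11 + L for a
gap of length L) stands in for the heuristic BLASTp step: at desk scale the
exact computation is affordable and removes an external binary.  E-values
follow the Karlin-Altschul formula E = K*m*n*exp(-lambda*S) with the
standard gapped BLOSUM62 constants lambda = 0.267, K = 0.041.

Three thresholds drive the downstream logic: 1e-10 for validating a
frameshift against a reference protein set, 1e-50 for the stringent
all-against-all clustering search, and 1e-3 for domain-coverage evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations

from Bio import Align
from Bio.Align import substitution_matrices

from .model import FsProtein

LAMBDA = 0.267
K = 0.041

EVALUE_VALIDATION = 1e-10
EVALUE_CLUSTERING = 1e-50
EVALUE_DOMAIN = 1e-3

BRIDGE_MIN_LEN = 100  # aa of fs-protein a single hit must cover to bridge
SPLIT_MIN_FLANK = 20  # aa a hit must span wholly on one side to count for a split

_MAX_AMBIGUITY = 0.5


class ValidationStatus(str, Enum):
    BRIDGED = "bridged"
    SPLIT = "split"
    NONE = "none"
    DOMAIN_BRIDGED = "domain_bridged"


@dataclass(frozen=True)
class AlignmentHit:
    """A local alignment between two proteins, BLAST outfmt-6 flavoured.

    ``query_blocks``/``target_blocks`` are the gap-free aligned segments
    ((start, end) pairs, equal aligned lengths per segment) and allow
    projecting a residue index into alignment-column space.
    """

    query: str
    target: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    score: float
    evalue: float
    pident: float
    query_blocks: tuple[tuple[int, int], ...] = ()
    target_blocks: tuple[tuple[int, int], ...] = ()

    def project_query(self, pos: int) -> int:
        return _project(self.query_blocks, self.target_blocks, pos)

    def project_target(self, pos: int) -> int:
        return _project(self.target_blocks, self.query_blocks, pos)


def _project(own: tuple, other: tuple, pos: int) -> int:
    """Map a residue index on one side of the alignment to a column index.

    Positions inside a gap on the own side map to the first column after the
    preceding aligned segment.
    """
    if not own:
        raise ValueError("hit carries no aligned-block information")
    col = 0
    for i, ((os_, oe), (_, te)) in enumerate(zip(own, other)):
        if pos < os_:
            return col
        if pos < oe:
            return col + (pos - os_)
        # columns consumed by this segment plus the following gap (the gap
        # length is the larger of the two sides' inter-segment distances)
        col += oe - os_
        if i + 1 < len(own):
            col += max(own[i + 1][0] - oe, other[i + 1][0] - te)
    return col


def karlin_altschul_evalue(score: float, m: int, n: int) -> float:
    return K * m * n * math.exp(-LAMBDA * score)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -12.0  # first gapped position: open 11 + extend 1
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()
_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX*")


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    bad = sum(1 for c in seq if c not in _ALPHABET or c == "X")
    if bad > _MAX_AMBIGUITY * len(seq):
        raise ValueError("sequence rejected: >50% ambiguous residues")
    return "".join(c if c in _ALPHABET else "X" for c in seq)


def local_align(
    query: str, target: str, query_id: str = "query", target_id: str = "target"
) -> AlignmentHit | None:
    """Best Smith-Waterman local alignment, or None for a non-positive score."""
    q = _sanitize(query)
    t = _sanitize(target)
    alignments = _ALIGNER.align(q, t)
    if len(q) == 0 or len(t) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    qblocks, tblocks = aln.aligned
    qblocks = tuple((int(s), int(e)) for s, e in qblocks)
    tblocks = tuple((int(s), int(e)) for s, e in tblocks)
    matches = sum(
        1
        for (qs, qe), (ts, _) in zip(qblocks, tblocks)
        for i in range(qe - qs)
        if q[qs + i] == t[ts + i]
    )
    aligned_len = sum(qe - qs for qs, qe in qblocks)
    return AlignmentHit(
        query=query_id,
        target=target_id,
        query_start=qblocks[0][0],
        query_end=qblocks[-1][1],
        target_start=tblocks[0][0],
        target_end=tblocks[-1][1],
        score=float(alignments.score),
        evalue=karlin_altschul_evalue(alignments.score, len(q), len(t)),
        pident=100.0 * matches / aligned_len if aligned_len else 0.0,
        query_blocks=qblocks,
        target_blocks=tblocks,
    )


def validate_bridging(fs_protein: FsProtein, hits: list[AlignmentHit]) -> ValidationStatus:
    """Classify reference-set evidence around the frameshift position.

    *bridged*: one hit covers >= 100 aa of the fs-protein including the
    frameshift residue — the fused product has a continuous homolog, so the
    frameshift is real (sequencing error, indel, or recoding).
    *split*: hits exist wholly on both sides of the frameshift (>= 20 aa
    flanks) but none contains it — the signature of two adjacent genes
    mistaken for one frameshifted gene.
    """
    fs_aa = fs_protein.fs_aa
    if not 0 <= fs_aa <= len(fs_protein.aa):
        raise ValueError(f"fs_aa {fs_aa} outside protein of length {len(fs_protein.aa)}")
    left = right = False
    for hit in hits:
        qs, qe = hit.query_start, hit.query_end
        if qs <= fs_aa < qe and qe - qs >= BRIDGE_MIN_LEN:
            return ValidationStatus.BRIDGED
        if qe <= fs_aa and qe - qs >= SPLIT_MIN_FLANK:
            left = True
        if qs > fs_aa and qe - qs >= SPLIT_MIN_FLANK:
            right = True
    if left and right:
        return ValidationStatus.SPLIT
    return ValidationStatus.NONE


def domain_covers_frameshift(
    fs_protein: FsProtein,
    domains: list[tuple[str, int, int, float]],
    evalue_max: float = EVALUE_DOMAIN,
) -> bool:
    """True iff a domain interval with E < 1e-3 strictly contains fs_aa.

    ``domains`` holds (name, start, end, evalue) in aa coordinates of the
    fs-protein, half-open.  A conserved domain cannot span two fused genes,
    so coverage excludes gene fission/fusion artifacts.
    """
    fs_aa = fs_protein.fs_aa
    return any(
        start <= fs_aa < end and ev < evalue_max for _, start, end, ev in domains
    )


def all_against_all(
    proteins: dict[str, str], evalue_max: float = EVALUE_CLUSTERING
) -> list[AlignmentHit]:
    """Best hit per unordered protein pair at the stringent E-value cutoff.

    Self-hits are excluded; the hit set is symmetric by construction (one
    record per unordered pair, Smith-Waterman scores being symmetric).
    """
    if len(proteins) < 2:
        raise ValueError("all-against-all needs at least 2 proteins")
    ids = sorted(proteins)
    hits = []
    for a, b in combinations(ids, 2):
        hit = local_align(proteins[a], proteins[b], a, b)
        if hit is not None and hit.evalue <= evalue_max:
            hits.append(hit)
    return hits


def hits_to_frame(hits: list[AlignmentHit]):
    """Hits as a pandas frame in BLAST outfmt-6-like column order."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "qseqid": h.query,
                "sseqid": h.target,
                "pident": round(h.pident, 2),
                "length": h.query_end - h.query_start,
                "qstart": h.query_start,
                "qend": h.query_end,
                "sstart": h.target_start,
                "send": h.target_end,
                "evalue": h.evalue,
                "bitscore": h.score,
            }
            for h in hits
        ],
        columns=[
            "qseqid", "sseqid", "pident", "length",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ],
    )
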