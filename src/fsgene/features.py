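"""Per-gene and per-cluster features of predicted frameshifts.

Cluster-level fractions drive classification: %AT (members with a 7+ nt
poly-A or poly-T stretch near the frameshift), %R (members with other
tandem repeats near it), %S (members whose ORF2 start codon sits within
10 nt of the ORF1 stop) and %B (members whose frameshift is bridged by a
reference-set homolog).  A Shine-Dalgarno position-weight score calibrated
to the [-11, 8] range stands in for the upstream gene predictor's RBS
model; the >2.2 filter semantics are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from Bio import Align

from .clustering import Cluster
from .homology import ValidationStatus
from .model import FrameshiftBox, FsGene, coding_sequence

FS_WINDOW = 50          # nt on each side of the frameshift for repeat features
MIN_REPEAT_SPAN = 7
MAX_REPEAT_UNIT = 6
COLOCALIZATION_NT = 10
RBS_MIN, RBS_MAX = -11.0, 8.0
RBS_FILTER = 2.2
GS_MIN_SIZE, GS_MAX_SIZE = 5, 100
GS_MAX_IDENTITY = 80.0


@dataclass(frozen=True)
class TandemRepeat:
    unit: str
    copies: float
    start: int
    span: int


@dataclass(frozen=True)
class ClusterFeatures:
    """Aggregated features of one fs-gene cluster (percentages 0-100)."""

    cluster_id: str
    size: int
    n_genera: int
    direction: int
    pct_AT: int
    pct_R: int
    pct_S: int
    pct_B: int
    mean_box_identity: float
    has_annotated_pseudogene: bool
    rbs_mean: float
    gs_eligible: bool = True


def fs_window(sequence: str, fs_pos: int, half: int = FS_WINDOW) -> str:
    """The +-half nt window around a frameshift, clipped to the sequence."""
    return sequence[max(0, fs_pos - half) : fs_pos + half]


def detect_poly_at(window: str, min_len: int = MIN_REPEAT_SPAN) -> list[TandemRepeat]:
    """Maximal runs of a single A or a single T of at least ``min_len`` nt."""
    window = window.upper()
    out = []
    i = 0
    n = len(window)
    while i < n:
        if window[i] in "AT":
            j = i
            while j < n and window[j] == window[i]:
                j += 1
            if j - i >= min_len:
                out.append(TandemRepeat(window[i], float(j - i), i, j - i))
            i = j
        else:
            i += 1
    return out


def _is_primitive(unit: str) -> bool:
    for u in range(1, len(unit)):
        if len(unit) % u == 0 and unit == unit[:u] * (len(unit) // u):
            return False
    return True


def detect_tandem_repeats(
    window: str,
    min_total: int = MIN_REPEAT_SPAN,
    max_unit: int = MAX_REPEAT_UNIT,
) -> list[TandemRepeat]:
    """Exact tandem repeats with unit 1-6 nt and total span >= 7 nt.

    Exhaustive and exact (no mismatches), reporting maximal, non-nested
    stretches; homopolymers count as repeats and partial trailing copies
    give fractional copy numbers.
    """
    window = window.upper()
    n = len(window)
    candidates: list[TandemRepeat] = []
    for u in range(1, max_unit + 1):
        k = u  # first position that can match its u-predecessor
        while k < n:
            if window[k] == window[k - u]:
                j = k
                while j < n and window[j] == window[j - u]:
                    j += 1
                start = k - u
                span = j - start
                unit = window[start : start + u]
                if span >= min_total and _is_primitive(unit):
                    candidates.append(
                        TandemRepeat(unit, round(span / u, 3), start, span)
                    )
                k = j + 1
            else:
                k += 1
    # non-nested: drop repeats whose interval sits inside a shorter-unit one
    out = []
    for rep in candidates:
        nested = any(
            other is not rep
            and len(other.unit) < len(rep.unit)
            and other.start <= rep.start
            and rep.start + rep.span <= other.start + other.span
            for other in candidates
        )
        if not nested:
            out.append(rep)
    out.sort(key=lambda r: (r.start, len(r.unit)))
    return out


def significant_repeats(
    repeats: list[TandemRepeat], min_total: int = MIN_REPEAT_SPAN
) -> list[TandemRepeat]:
    """Repeats long enough to be slippage substrates rather than chance.

    An exact tandem span of barely more than one unit (e.g. 7 nt at unit
    length 6) occurs in almost every random window; phase-variation
    screening therefore requires at least two full copies and at least six
    repeated positions: span >= max(min_total, 2*unit, unit+6).
    """
    return [
        r
        for r in repeats
        if r.span >= max(min_total, 2 * len(r.unit), len(r.unit) + 6)
    ]


_START_CODONS = ("ATG",)
_START_CODONS_GTG = ("ATG", "GTG")
_STOPS = ("TAA", "TAG", "TGA")


def start_stop_distance(
    fs_gene: FsGene,
    genome: str,
    threshold: int = COLOCALIZATION_NT,
    accept_gtg: bool = False,
) -> tuple[int | None, bool]:
    """Signed distance between ORF1's stop and ORF2's predicted start codon.

    ORF2's start is taken from the prediction record (``orf2`` interval
    start, where a gene caller reports the downstream gene's start codon);
    if no start codon sits there, the distance is undefined.  Distance runs
    from the last nucleotide of the first ORF1-frame stop at/after the
    frameshift to the first nucleotide of the start; colocalized iff
    |distance| <= threshold.
    """
    s = coding_sequence(genome, fs_gene.strand)
    a, gene_end = fs_gene.gene_span
    fs = fs_gene.fs_pos - (fs_gene.fs_pos - a) % 3
    stop_last = None
    p = fs
    while p + 3 <= gene_end:
        if s[p : p + 3] in _STOPS:
            stop_last = p + 2
            break
        p += 3
    if stop_last is None:
        return None, False
    starts = _START_CODONS_GTG if accept_gtg else _START_CODONS
    q = fs_gene.orf2[0]
    if s[q : q + 3] not in starts:
        return None, False
    dist = q - stop_last
    return dist, abs(dist) <= threshold


# --- Shine-Dalgarno position-weight scoring ---------------------------------

_SD_CONSENSUS = "AGGAGG"
_MATCH_LLR = np.log2(0.7 / 0.25)
_MISMATCH_LLR = np.log2(0.1 / 0.25)
_SPACER_OK = range(4, 13)      # nt between SD 3' end and the start codon
_SPACER_PENALTY = 0.7          # per nt outside the tolerated spacing
_RBS_SLOPE = (RBS_MAX - RBS_MIN) / (
    6 * _MATCH_LLR - 6 * _MISMATCH_LLR
)
_RBS_OFFSET = RBS_MAX - _RBS_SLOPE * 6 * _MATCH_LLR


def rbs_score(upstream: str) -> float:
    """SD-motif log-odds of a 20-nt window 5' of a candidate start codon.

    The best AGGAGG match over all placements, with a spacing penalty
    outside 4-12 nt, affinely mapped into [-11, 8]; a canonical SD at
    optimal spacing scores 8, well above the 2.2 filter threshold.
    """
    window = upstream.upper()[-20:]
    if len(window) < len(_SD_CONSENSUS):
        return RBS_MIN
    best = -np.inf
    n = len(window)
    for i in range(n - len(_SD_CONSENSUS) + 1):
        raw = sum(
            _MATCH_LLR if window[i + j] == _SD_CONSENSUS[j] else _MISMATCH_LLR
            for j in range(len(_SD_CONSENSUS))
        )
        spacing = n - (i + len(_SD_CONSENSUS))
        if spacing not in _SPACER_OK:
            gap = min(abs(spacing - _SPACER_OK[0]), abs(spacing - _SPACER_OK[-1]))
            raw -= _SPACER_PENALTY * gap
        best = max(best, raw)
    return float(np.clip(_RBS_SLOPE * best + _RBS_OFFSET, RBS_MIN, RBS_MAX))


def relative_fs_position(fs_gene: FsGene) -> float:
    """Frameshift coordinate as a fraction of the fused gene length."""
    a, gene_end = fs_gene.gene_span
    length = gene_end - a
    if length <= 0:
        raise ValueError(f"{fs_gene.id}: zero-length gene")
    return (fs_gene.fs_pos - a) / length


_NT_ALIGNER = Align.PairwiseAligner()
_NT_ALIGNER.mode = "global"
_NT_ALIGNER.match_score = 1.0
_NT_ALIGNER.mismatch_score = -1.0
_NT_ALIGNER.open_gap_score = -2.0
_NT_ALIGNER.extend_gap_score = -0.5

_MAX_IDENTITY_PAIRS = 300


def mean_box_identity(boxes: list[FrameshiftBox]) -> float:
    """Average pairwise percent identity of boxes from global alignment.

    For large clusters a deterministic subset of pairs (first 300 in
    member order) keeps the computation linear-ish.
    """
    pairs = list(combinations(range(len(boxes)), 2))[:_MAX_IDENTITY_PAIRS]
    if not pairs:
        return 100.0
    idents = []
    for i, j in pairs:
        a, b = boxes[i].seq.upper(), boxes[j].seq.upper()
        aln = _NT_ALIGNER.align(a, b)[0]
        qb, tb = aln.aligned
        matches = sum(
            1
            for (qs, qe), (ts, _) in zip(qb, tb)
            for k in range(qe - qs)
            if a[qs + k] == b[ts + k]
        )
        # identity over alignment length (counting end gaps)
        aln_len = max(len(a), len(b))
        idents.append(100.0 * matches / aln_len)
    return float(np.mean(idents))


def compute_cluster_features(
    cluster: Cluster,
    fs_genes: dict[str, FsGene],
    genomes: dict[str, str],
    boxes: dict[str, FrameshiftBox],
    statuses: dict[str, ValidationStatus],
    colocalization_nt: int = COLOCALIZATION_NT,
    accept_gtg: bool = False,
) -> ClusterFeatures:
    """Aggregate member features into the cluster's classification row."""
    n = cluster.size
    at_hits = r_hits = s_hits = b_hits = 0
    rbs_values = []
    annotated = False
    for member in cluster.members:
        gene = fs_genes[member]
        s = coding_sequence(genomes[gene.genome_id], gene.strand)
        window = fs_window(s, gene.fs_pos)
        if detect_poly_at(window):
            at_hits += 1
        if any(
            not (len(r.unit) == 1 and r.unit in "AT")
            for r in significant_repeats(detect_tandem_repeats(window))
        ):
            r_hits += 1
        _, colocalized = start_stop_distance(
            gene, genomes[gene.genome_id], colocalization_nt, accept_gtg
        )
        if colocalized:
            s_hits += 1
        if statuses.get(member) in (
            ValidationStatus.BRIDGED,
            ValidationStatus.DOMAIN_BRIDGED,
        ):
            b_hits += 1
        rbs_values.append(gene.rbs_score)
        annotated = annotated or gene.annotated_pseudogene
    identity = mean_box_identity([boxes[m] for m in cluster.members if m in boxes])
    return ClusterFeatures(
        cluster_id=cluster.id,
        size=n,
        n_genera=cluster.n_genera,
        direction=cluster.direction,
        pct_AT=round(100 * at_hits / n),
        pct_R=round(100 * r_hits / n),
        pct_S=round(100 * s_hits / n),
        pct_B=round(100 * b_hits / n),
        mean_box_identity=round(identity, 1),
        has_annotated_pseudogene=annotated,
        rbs_mean=float(np.mean(rbs_values)) if rbs_values else 0.0,
        gs_eligible=(GS_MIN_SIZE <= n <= GS_MAX_SIZE and identity <= GS_MAX_IDENTITY),
    )
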