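"""Synthetic genomes, prediction tables and truth labels for fs-gene analysis.

The generator emulates the inputs of a genome-scale frameshift survey at
desk scale: for each requested class it plants families of homologous
fs-genes whose statistical structure matches what the downstream stages
assume —

* ``programmed_PRF``: one family with a conserved slippery heptamer
  (default A_AAA_AAG, -1) and a Shine-Dalgarno-like stimulator 10-14 nt
  5' of the shift site, spanning >= 3 genera.
* ``programmed_PTR``: a *pair* of families sharing a domain name but with
  opposite shift directions (polymerase slippage is direction-agnostic),
  default heptamers AAA_AAA_T (+1) and T_AAA_AAA (-1).  ``n_per_class``
  counts members per direction family, so 2n fs-genes are emitted.
* ``phase_variation``: a family with a tandem repeat (default AGTC x 3)
  straddling the shift site and no slippery heptamer.
* ``translational_coupling``: a family whose ORF2 start codon sits within
  10 nt of the ORF1 stop, at member-specific offsets so that co-location,
  not any literal heptamer, is the conserved signal.
* ``pseudogene``: a recent shared 1-nt indel in <= 2 genera, members
  flagged as annotated pseudogenes, no conserved site.
* ``sequencing_error``: unclustered singletons whose full-length homolog
  is planted in the reference protein set (so homology bridges the shift).
* ``overlapping_pair``: a family with the classic ATGA start/stop overlap,
  i.e. a conserved heptamer carrying a downstream-frame start codon.

Members of a family share an ancestral fused protein; each member's codons
are resampled synonymously outside planted windows ("wobble", emulating
synonymous divergence among orthologs) and further substituted at the
configurable ``noise`` rate.  Identical seeds give byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    STOP_CODONS,
    FrameshiftBox,
    FsGene,
    build_fs_protein,
    extract_frameshift_box,
    translate_cds,
)
from .features import detect_tandem_repeats, fs_window, start_stop_distance
from .motif import FramedHeptamer

CLASS_LABELS = (
    "programmed_PRF",
    "programmed_PTR",
    "phase_variation",
    "translational_coupling",
    "pseudogene",
    "sequencing_error",
    "overlapping_pair",
)

DEFAULT_GENERA = (
    "Escherichia",
    "Salmonella",
    "Vibrio",
    "Neisseria",
    "Yersinia",
    "Shigella",
)

_BASES = "ACGT"
_MAX_ATTEMPTS = 60


@dataclass(frozen=True)
class CassetteSpec:
    """A slippery-site plant: phased heptamer, direction and stimulator."""

    heptamer: str            # display form, e.g. "A_AAA_AAG"
    direction: int
    stimulator: str = "none"  # none | SD | hairpin

    def __post_init__(self):
        parsed = FramedHeptamer.from_display(self.heptamer)
        if parsed.direction != self.direction:
            raise ValueError(
                f"heptamer {self.heptamer} has the "
                f"{'NNN_NNN_N' if parsed.direction == 1 else 'N_NNN_NNN'} shape "
                f"and cannot encode a {self.direction:+d} shift"
            )
        if self.stimulator not in ("none", "SD", "hairpin"):
            raise ValueError(f"unknown stimulator {self.stimulator!r}")

    @property
    def seq(self) -> str:
        return FramedHeptamer.from_display(self.heptamer).seq


@dataclass
class SyntheticConfig:
    seed: int = 0
    # 8 members per clustered family keeps majority-vote features (heptamer
    # presence, %AT/%R/%S) away from knife-edge ties at the 50% thresholds;
    # sequencing errors are singletons, so fewer suffice
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {
            label: (4 if label == "sequencing_error" else 8)
            for label in CLASS_LABELS
        }
    )
    gene_length_range: tuple[int, int] = (450, 750)
    gc_content: float = 0.5
    cassette_specs: list[CassetteSpec] = field(
        default_factory=lambda: [
            CassetteSpec("A_AAA_AAG", -1, "SD"),
            CassetteSpec("AAA_AAA_T", +1, "none"),
            CassetteSpec("T_AAA_AAA", -1, "none"),
        ]
    )
    genera_pool: tuple[str, ...] = DEFAULT_GENERA
    # per-site substitution rate on top of synonymous wobble; 0.1 leaves
    # frameshift boxes at roughly 55-70% identity, the divergence regime in
    # which motif conservation is informative (published selection keeps
    # clusters at <= 80% box identity)
    noise: float = 0.10

    def validate(self):
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if sum(self.n_per_class.values()) == 0:
            raise ValueError("zero total genes requested")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")
        if not 0 <= self.noise <= 0.5:
            raise ValueError("noise must be in [0, 0.5]")
        unknown = set(self.n_per_class) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels: {sorted(unknown)}")


@dataclass(frozen=True)
class TruthRecord:
    fs_id: str
    true_class: str
    heptamer: str | None
    direction: int
    fused_protein: str | None


@dataclass
class DatasetBundle:
    genomes: dict[str, str]
    predictions: pd.DataFrame
    reference_proteins: dict[str, str]
    domains: dict[str, list[tuple[str, int, int, float]]]
    truth: pd.DataFrame

    def write(self, outdir: str | Path):
        from . import io

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(outdir / "genomes.fna", self.genomes)
        io.write_predictions(outdir / "predictions.tsv", self.predictions)
        io.write_fasta(outdir / "reference_proteins.faa", self.reference_proteins)
        io.write_domains(outdir / "domains.tsv", self.domains)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


# --- low-level sequence helpers ---------------------------------------------


def _nt_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    idx = rng.choice(4, size=n, p=_nt_probs(gc))
    return "".join(_BASES[i] for i in idx)


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        c = _random_seq(rng, 3, gc)
        if c not in STOP_CODONS:
            return c


_SYNONYMS: dict[str, list[str]] = {}


def _synonyms(codon: str) -> list[str]:
    if not _SYNONYMS:
        by_aa: dict[str, list[str]] = {}
        for i in _BASES:
            for j in _BASES:
                for k in _BASES:
                    c = i + j + k
                    if c not in STOP_CODONS:
                        by_aa.setdefault(translate_cds(c), []).append(c)
        for codons in by_aa.values():
            for c in codons:
                _SYNONYMS[c] = codons
    return _SYNONYMS[codon]


# --- ancestor / member construction -----------------------------------------


@dataclass
class _Ancestor:
    direction: int
    part1: list[str]          # ORF1-frame codons, [0] == ATG
    part2: list[str]          # ORF2-frame codons, [-1] is a stop
    skipped: str              # the extra nt at the junction (+1 only)
    overwrites: list[tuple[int, str]]   # fixed (gene position, nt string)
    protected: set[int]       # gene positions exempt from wobble and noise
    truth_heptamer: str | None = None
    stimulator: str = "none"  # SD spacing varies per member, so planted there
    cassette_start: int | None = None

    @property
    def fs_local(self) -> int:
        return 3 * len(self.part1)

    @property
    def gene_length(self) -> int:
        if self.direction == +1:
            return 3 * len(self.part1) + 1 + 3 * len(self.part2)
        return 3 * len(self.part1) - 1 + 3 * len(self.part2)

    def effective_gene(self) -> str:
        """Base rendering with the ancestral overwrites stamped in."""
        gene = list(_assemble(self.part1, self.part2, self.skipped, self.direction))
        for start, nt in self.overwrites:
            for k, c in enumerate(nt):
                if 0 <= start + k < len(gene):
                    gene[start + k] = c
        return "".join(gene)


def _assemble(part1: list[str], part2: list[str], skipped: str, direction: int) -> str:
    if direction == +1:
        return "".join(part1) + skipped + "".join(part2)
    joined = "".join(part2)
    return "".join(part1) + joined[1:]


def _protect_range(anc: _Ancestor, start: int, end: int):
    anc.protected.update(range(max(0, start), min(anc.gene_length, end)))


def _make_ancestor(
    rng: np.random.Generator,
    direction: int,
    gene_length_range: tuple[int, int],
    gc: float,
) -> _Ancestor:
    lo, hi = gene_length_range
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    n_codons = max(n_codons, 90)
    frac = rng.uniform(0.4, 0.6)
    n1 = max(40, min(n_codons - 40, int(n_codons * frac)))
    n2 = n_codons - n1
    part1 = ["ATG"] + [_random_codon(rng, gc) for _ in range(n1 - 1)]
    part2 = [_random_codon(rng, gc) for _ in range(n2 - 1)] + ["TAA"]
    skipped = ""
    if direction == +1:
        skipped = _BASES[int(rng.integers(4))]
    else:
        # the junction nucleotide is shared between the two frames
        part2[0] = part1[-1][2] + part2[0][1:]
    anc = _Ancestor(direction, part1, part2, skipped, [], set())
    # start and terminal stop stay put
    _protect_range(anc, 0, 3)
    _protect_range(anc, anc.gene_length - 3, anc.gene_length)
    if direction == -1:
        # the shared junction nucleotide belongs to both frames at once
        _protect_range(anc, 3 * n1 - 1, 3 * n1)
    return anc


def _plant_heptamer(
    anc: _Ancestor,
    cassette: CassetteSpec,
    rng: np.random.Generator,
    shift: int = 0,
):
    """Overwrite the phased heptamer (and stimulator) around the shift site.

    ``shift`` moves the plant upstream in whole codons (0, -3, -6): some
    heptamers (e.g. T_AAA_AAA) would place a stop codon in the fused frame
    at the canonical offset, and a phase-preserving shift keeps the site
    readable by the motif search while the fused product stays open.
    """
    fs = anc.fs_local
    start = (fs - 1 if cassette.direction == -1 else fs - 3) + shift
    anc.overwrites.append((start, cassette.seq))
    _protect_range(anc, start, start + 7)
    anc.cassette_start = start
    anc.truth_heptamer = cassette.heptamer
    anc.stimulator = cassette.stimulator
    if cassette.stimulator == "hairpin":
        stem = _random_seq(rng, 6, 0.8)
        loop = _random_seq(rng, 4, 0.5)
        rc = stem.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        hp_start = fs + 8
        anc.overwrites.append((hp_start, stem + loop + rc))
        _protect_range(anc, hp_start, hp_start + 16)


def _plant_repeat(anc: _Ancestor, unit: str, copies: int):
    span = len(unit) * copies
    fs = anc.fs_local
    start = fs - span // 2
    anc.overwrites.append((start, unit * copies))
    _protect_range(anc, start, start + span)


def _constrained_wobble(
    codon: str, fixed: dict[int, str], rng: np.random.Generator
) -> str:
    """A synonymous codon agreeing with any planted (fixed) positions."""
    if codon in STOP_CODONS:
        return codon
    options = [
        c for c in _synonyms(codon) if all(c[k] == v for k, v in fixed.items())
    ]
    if not options:
        return codon
    return options[int(rng.integers(len(options)))]


def _render_member(
    anc: _Ancestor,
    rng: np.random.Generator,
    noise: float,
    extra_overwrites: list[tuple[int, str]] | None = None,
) -> str:
    """One family member: constrained synonymous wobble plus noise.

    Wobble fixes only the exact planted nucleotides, so third positions of
    codons bordering a cassette still vary between members — the planted
    heptamer, not a wider context, is what stays conserved.
    """
    eff = anc.effective_gene()
    fs = anc.fs_local
    base2 = fs + 1 if anc.direction == +1 else fs - 1
    part1 = []
    for i in range(0, fs, 3):
        fixed = {k: eff[i + k] for k in range(3) if (i + k) in anc.protected}
        part1.append(_constrained_wobble(eff[i : i + 3], fixed, rng))
    part2 = []
    for i in range(len(anc.part2)):
        s = base2 + 3 * i
        fixed = {k: eff[s + k] for k in range(3) if (s + k) in anc.protected}
        part2.append(_constrained_wobble(eff[s : s + 3], fixed, rng))
    if anc.direction == -1:
        # the junction nucleotide is shared between the two frames; it is
        # protected, so both wobbled codons already agree on it
        part2[0] = part1[-1][2] + part2[0][1:]
    skipped = eff[fs] if anc.direction == +1 else ""
    gene = list(_assemble(part1, part2, skipped, anc.direction))
    extra_protect = set()
    for start, nt in extra_overwrites or []:
        for k, c in enumerate(nt):
            if 0 <= start + k < len(gene):
                gene[start + k] = c
                extra_protect.add(start + k)
    if noise > 0:
        protected = anc.protected | extra_protect
        hits = np.flatnonzero(rng.random(len(gene)) < noise)
        for p in hits:
            p = int(p)
            if p in protected:
                continue
            alternatives = [b for b in _BASES if b != gene[p]]
            order = rng.permutation(3)
            original = gene[p]
            # substitutions are codon-aware: the fused frame must stay open
            for k in order:
                gene[p] = alternatives[int(k)]
                if not _creates_fused_stop(gene, p, fs, anc.direction, base2):
                    break
            else:
                gene[p] = original
    return "".join(gene)


def _creates_fused_stop(
    gene: list[str], p: int, fs: int, direction: int, base2: int
) -> bool:
    """Does the codon of the fused frame containing position p read stop?"""
    if p < fs:
        start = 3 * (p // 3)
    elif direction == +1 and p == fs:
        return False  # the skipped nucleotide is not decoded
    else:
        start = base2 + 3 * ((p - base2) // 3)
    codon = "".join(gene[start : start + 3])
    return codon in STOP_CODONS


def _orf_intervals(
    gene: str, fs: int, direction: int, planted_start: int | None = None
) -> tuple[tuple[int, int], tuple[int, int]]:
    """ORF1/ORF2 intervals within a gene-local coordinate frame.

    ``orf2`` starts at the downstream gene's predicted start codon, as a
    gene caller would report it: the planted start when one exists, else
    the first ORF2-frame ATG after the frame's upstream stop boundary
    (capped at the frameshift so the two ORFs always overlap); when no
    start codon exists, the frame boundary itself.
    """
    n = len(gene)
    orf1_end = n
    p = fs
    while p + 3 <= n:
        if gene[p : p + 3] in STOP_CODONS:
            orf1_end = p + 3
            break
        p += 3
    q0 = fs + direction
    boundary = q0 % 3
    p = q0 - 3
    while p >= 0:
        if gene[p : p + 3] in STOP_CODONS:
            boundary = p + 3
            break
        p -= 3
    boundary = min(boundary, fs)
    orf2_start = planted_start
    if orf2_start is None:
        q = boundary
        while q + 3 <= n and q <= fs:
            if gene[q : q + 3] == "ATG":
                orf2_start = q
                break
            q += 3
    if orf2_start is None:
        orf2_start = boundary
    return (0, orf1_end), (orf2_start, n)


@dataclass
class _MemberSpec:
    family: str
    true_class: str
    direction: int
    genus: str
    strand: str
    annotated_pseudogene: bool = False
    domain: str | None = None
    tc_plant: bool = False


def _finalize_member(
    anc: _Ancestor,
    spec: _MemberSpec,
    fs_id: str,
    seed_seq: np.random.SeedSequence,
    noise: float,
    gc: float,
) -> tuple[str, FsGene, TruthRecord] | None:
    """Render one member, with bounded retries until it is internally valid."""
    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=seed_seq.entropy, spawn_key=seed_seq.spawn_key + (attempt,)
            )
        )
        extra = []
        # SD spacing (10-14 nt 5' of the shift site) varies per member: the
        # hexamer is conserved but not column-alignable, as in real
        # orthologs where only the ribosome contact distance matters.  The
        # draw happens unconditionally so a stimulator-free variant of the
        # same seed differs only in the stimulator window itself.
        gap = int(rng.integers(10, 15))
        if anc.stimulator == "SD":
            extra.append((anc.fs_local - gap - 6, "AGGAGG"))
        planted_start = None
        if anc.cassette_start is not None and spec.true_class == "overlapping_pair":
            # the cassette's leading ATG is the downstream gene's start
            planted_start = anc.cassette_start
        if spec.tc_plant:
            # re-initiation geometry: stop planted 1-3 codons after the
            # shift, start codon 1-9 nt upstream of the stop's last base,
            # at member-specific offsets (only co-location is conserved)
            k1 = int(rng.integers(1, 6))
            low = -3 if anc.direction == +1 else -2  # keep |distance| <= 10
            m = k1 + int(rng.integers(max(low, -k1), 1))
            fs = anc.fs_local
            base2 = fs + 1 if anc.direction == +1 else fs - 1
            stop = ("TAA", "TGA", "TAG")[int(rng.integers(3))]
            extra.append((fs + 3 * k1, stop))
            q = base2 + 3 * m
            extra.append((q, "ATG"))
            planted_start = q
        gene = _render_member(anc, rng, noise, extra)
        flank_l = _random_seq(rng, int(rng.integers(60, 151)), gc)
        flank_r = _random_seq(rng, int(rng.integers(60, 151)), gc)
        off = len(flank_l)
        contig = flank_l + gene + flank_r
        fs_pos = off + anc.fs_local
        orf1, orf2 = _orf_intervals(
            gene, anc.fs_local, anc.direction, planted_start
        )
        orf1 = (orf1[0] + off, orf1[1] + off)
        orf2 = (orf2[0] + off, orf2[1] + off)
        rbs = float(np.clip(rng.normal(-1.0, 1.2), -11.0, 2.2))
        genome = contig
        if spec.strand == "-":
            genome = contig.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        try:
            gene_rec = FsGene(
                id=fs_id,
                genome_id=f"ctg_{fs_id}",
                strand=spec.strand,
                orf1=orf1,
                orf2=orf2,
                fs_pos=fs_pos,
                direction=anc.direction,
                rbs_score=round(rbs, 2),
                genus=spec.genus,
                annotated_pseudogene=spec.annotated_pseudogene,
            )
            protein = build_fs_protein(genome, gene_rec)
        except Exception:
            continue
        if spec.tc_plant:
            _, coloc = start_stop_distance(gene_rec, genome)
            if not coloc:
                continue
        if spec.true_class == "phase_variation":
            coding = contig
            window = fs_window(coding, fs_pos)
            if not detect_tandem_repeats(window):
                continue
        truth = TruthRecord(
            fs_id=fs_id,
            true_class=spec.true_class,
            heptamer=anc.truth_heptamer,
            direction=anc.direction,
            fused_protein=protein.aa,
        )
        return genome, gene_rec, truth
    return None


# --- family-level orchestration ---------------------------------------------


def _conservation_probs(anc: _Ancestor) -> np.ndarray:
    """Per-position majority-base probability under synonymous wobble.

    1.0 for planted/pinned positions (and single-codon amino acids), the
    modal-base frequency over the constrained synonym set otherwise.  The
    product over a window bounds the chance a member literally carries the
    window's consensus at zero noise.
    """
    eff = anc.effective_gene()
    fs = anc.fs_local
    base2 = fs + 1 if anc.direction == +1 else fs - 1
    pinned = set(anc.protected)
    for start, nt in anc.overwrites:
        pinned.update(range(start, start + len(nt)))
    probs = np.ones(len(eff))
    spans = [3 * i for i in range(len(anc.part1))] + [
        base2 + 3 * i for i in range(len(anc.part2))
    ]
    for s in spans:
        codon = eff[s : s + 3]
        if codon in STOP_CODONS:
            options = [codon]
        else:
            fixed = {k: eff[s + k] for k in range(3) if (s + k) in pinned}
            options = [
                c for c in _synonyms(codon)
                if all(c[k] == v for k, v in fixed.items())
            ] or [codon]
        for k in range(3):
            if (s + k) in pinned:
                continue
            counts = {}
            for o in options:
                counts[o[k]] = counts.get(o[k], 0) + 1
            probs[s + k] = max(counts.values()) / len(options)
    return probs


_AT_RUN = None  # compiled lazily


def _ancestor_is_clean(
    anc: _Ancestor, flank: int = 55, max_presence: float = 0.25
) -> bool:
    """No over-conserved competitor window or stray A/T run near the shift.

    The planted cassette must be the only phased heptamer a motif search
    can find literally conserved across members: any phased window away
    from the plants whose expected member presence under wobble exceeds
    ``max_presence`` rejects the ancestor.  Windows overlapping a plant
    are tolerated: they are phase-connected to the planted optimum (the
    sampler's shift move escapes them) or, for repeats, handled by the
    classifier as repeat evidence.
    """
    import re

    probs = _conservation_probs(anc)
    eff = anc.effective_gene()
    fs = anc.fs_local
    residue = 0 if anc.direction == +1 else 2
    exempt = [
        (start, start + len(nt))
        for start, nt in anc.overwrites
        if anc.cassette_start is None or start != anc.cassette_start
    ]
    lo = max(0, fs - flank)
    hi = min(len(eff) - 7, fs + flank)
    for o in range(lo, hi + 1):
        if o % 3 != residue:
            continue
        if anc.cassette_start is not None and o == anc.cassette_start:
            continue
        if any(o < e and s < o + 7 for s, e in exempt):
            continue
        if float(np.prod(probs[o : o + 7])) > max_presence:
            return False
    region = eff[lo : fs + flank]
    for m in re.finditer(r"A{7,}|T{7,}", region):
        s = lo + m.start()
        c = anc.cassette_start
        if c is None or not (c <= s and lo + m.end() <= c + 7):
            return False
    return True


def _ancestor_is_valid(anc: _Ancestor) -> bool:
    """Overwrites must leave the fused frame stop-free in the base rendering."""
    gene = list(_assemble(anc.part1, anc.part2, anc.skipped, anc.direction))
    for start, nt in anc.overwrites:
        for k, c in enumerate(nt):
            if 0 <= start + k < len(gene):
                gene[start + k] = c
    s = "".join(gene)
    fs = anc.fs_local
    if anc.direction == +1:
        cds = s[:fs] + s[fs + 1 :]
    else:
        cds = s[:fs] + s[fs - 1 :]
    return all(
        cds[i : i + 3] not in STOP_CODONS for i in range(0, len(cds) - 3, 3)
    )


def _family_ancestor(
    true_class: str,
    cassette: CassetteSpec | None,
    seed_seq: np.random.SeedSequence,
    config: SyntheticConfig,
    direction: int,
) -> _Ancestor:
    import copy

    for attempt, child in enumerate(seed_seq.spawn(2 * _MAX_ATTEMPTS)):
        rng = np.random.default_rng(child)
        base = _make_ancestor(rng, direction, config.gene_length_range,
                              config.gc_content)
        # some heptamers only fit at the canonical offset; try codon-wise
        # upstream shifts of the plant before drawing a new ancestor
        for shift in (0, -3, -6) if cassette is not None else (0,):
            anc = copy.deepcopy(base)
            if cassette is not None:
                _plant_heptamer(anc, cassette, rng, shift=shift)
            if true_class == "phase_variation":
                _plant_repeat(anc, "AGTC", 3)
            if _ancestor_is_valid(anc) and _ancestor_is_clean(anc):
                return anc
    raise RuntimeError(
        f"could not build a stop-free {true_class} ancestor after "
        f"{2 * _MAX_ATTEMPTS} attempts"
    )


def plant_programmed_cassette(
    rng: np.random.Generator | int,
    mechanism: str,
    direction: int,
    heptamer: str,
    stimulator: str = "none",
    config: SyntheticConfig | None = None,
) -> tuple[str, FsGene, TruthRecord]:
    """Plant one programmed-frameshift gene and return (genome, record, truth).

    The heptamer is given in display form and must match the direction's
    phase pattern (NNN_NNN_N for +1, N_NNN_NNN for -1).
    """
    if mechanism not in ("PRF", "PTR"):
        raise ValueError("mechanism must be PRF or PTR")
    config = config or SyntheticConfig()
    cassette = CassetteSpec(heptamer, direction, stimulator)
    if isinstance(rng, (int, np.integer)):
        seed_seq = np.random.SeedSequence(int(rng))
    else:
        seed_seq = np.random.SeedSequence(int(rng.integers(2**31)))
    anc = _family_ancestor("programmed_PRF", cassette, seed_seq, config, direction)
    spec = _MemberSpec(
        family="adhoc",
        true_class=f"programmed_{mechanism}",
        direction=direction,
        genus=config.genera_pool[0],
        strand="+",
    )
    member_seed = np.random.SeedSequence(
        entropy=seed_seq.entropy, spawn_key=seed_seq.spawn_key + (1,)
    )
    result = _finalize_member(anc, spec, "fs_adhoc", member_seed, config.noise,
                              config.gc_content)
    if result is None:
        raise RuntimeError("could not plant a stop-free cassette context")
    return result


def plant_degenerate_case(
    rng: np.random.Generator | int,
    kind: str,
    config: SyntheticConfig | None = None,
) -> tuple[str, FsGene, TruthRecord]:
    """Plant one non-programmed case (see module docstring for semantics)."""
    kinds = {
        "pseudogene": "pseudogene",
        "phase_variation": "phase_variation",
        "coupled_pair": "translational_coupling",
        "sequencing_error": "sequencing_error",
    }
    if kind not in kinds:
        raise ValueError(f"unsupported kind {kind!r}")
    config = config or SyntheticConfig()
    if isinstance(rng, (int, np.integer)):
        seed_seq = np.random.SeedSequence(int(rng))
    else:
        seed_seq = np.random.SeedSequence(int(rng.integers(2**31)))
    direction = -1
    anc = _family_ancestor(kinds[kind], None, seed_seq, config, direction)
    if kind == "phase_variation":
        _plant_repeat(anc, "AGTC", 3)
    spec = _MemberSpec(
        family="adhoc",
        true_class=kinds[kind],
        direction=direction,
        genus=config.genera_pool[0],
        strand="+",
        annotated_pseudogene=(kind == "pseudogene"),
        tc_plant=(kind == "coupled_pair"),
    )
    member_seed = np.random.SeedSequence(
        entropy=seed_seq.entropy, spawn_key=seed_seq.spawn_key + (1,)
    )
    result = _finalize_member(anc, spec, "fs_adhoc", member_seed, config.noise,
                              config.gc_content)
    if result is None:
        raise RuntimeError(f"could not plant a valid {kind} case")
    return result


_FAMILY_DOMAINS = {
    "programmed_PRF": "MgChel_synth",
    "programmed_PTR": "Tnp_DDE_synth",
    "translational_coupling": "ABC_tran_synth",
    "overlapping_pair": "HTH_pair_synth",
}


def generate_dataset(config: SyntheticConfig) -> DatasetBundle:
    """Generate the full bundle: genomes, predictions, references, truth.

    Deterministic for a fixed config; per-member RNG substreams are derived
    by counter so records are independent of generation order.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)

    # family plan: (class, cassette, direction, n members, genera, flags)
    cassettes = {c.direction: c for c in config.cassette_specs}
    prf_cassette = next(
        (c for c in config.cassette_specs if c.stimulator != "none"),
        config.cassette_specs[0]
        if config.cassette_specs
        else CassetteSpec("A_AAA_AAG", -1, "SD"),
    )
    plans = []
    for label, n in sorted(config.n_per_class.items()):
        if n == 0:
            continue
        if label == "programmed_PRF":
            plans.append((label, prf_cassette, prf_cassette.direction, n,
                          config.genera_pool, {}))
        elif label == "programmed_PTR":
            for d in (+1, -1):
                cassette = cassettes.get(d)
                if cassette is None or cassette == prf_cassette:
                    cassette = CassetteSpec(
                        "AAA_AAA_T" if d == +1 else "T_AAA_AAA", d
                    )
                plans.append((label, cassette, d, n, config.genera_pool, {}))
        elif label == "phase_variation":
            plans.append((label, None, -1, n, config.genera_pool, {}))
        elif label == "translational_coupling":
            plans.append((label, None, +1, n, config.genera_pool,
                          {"tc_plant": True}))
        elif label == "pseudogene":
            plans.append((label, None, -1, n, config.genera_pool[:2],
                          {"annotated_pseudogene": True}))
        elif label == "sequencing_error":
            # singletons: one independent "family" per gene
            for k in range(n):
                plans.append((label, None, -1 if k % 2 else +1, 1,
                              (config.genera_pool[k % len(config.genera_pool)],),
                              {"reference": True}))
        elif label == "overlapping_pair":
            # conserved ATGA overlap: ORF2-frame ATG over an ORF1-frame TGA
            plans.append((label, CassetteSpec("A_TGA_AAC", -1), -1, n,
                          config.genera_pool, {}))

    genomes: dict[str, str] = {}
    rows = []
    truth_rows = []
    reference: dict[str, str] = {}
    domains: dict[str, list[tuple[str, int, int, float]]] = {}

    for fam_idx, (label, cassette, direction, n, genera, flags) in enumerate(plans):
        fam_seed = np.random.SeedSequence(
            entropy=config.seed, spawn_key=(fam_idx, 9999)
        )
        anc = _family_ancestor(label, cassette, fam_seed, config, direction)
        fam_tag = f"f{fam_idx:02d}"
        domain = _FAMILY_DOMAINS.get(label)
        for m in range(n):
            fs_id = f"fs_{fam_tag}_{m:02d}"
            member_seed = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(fam_idx, m)
            )
            spec = _MemberSpec(
                family=fam_tag,
                true_class=label,
                direction=direction,
                genus=genera[m % len(genera)],
                strand="-" if m % 3 == 2 else "+",
                annotated_pseudogene=flags.get("annotated_pseudogene", False),
                domain=domain,
                tc_plant=flags.get("tc_plant", False),
            )
            result = _finalize_member(
                anc, spec, fs_id, member_seed, config.noise, config.gc_content
            )
            if result is None:
                raise RuntimeError(f"failed to generate member {fs_id}")
            genome, gene_rec, truth = result
            genomes[gene_rec.genome_id] = genome
            rows.append(
                {
                    "fs_id": fs_id,
                    "genome": gene_rec.genome_id,
                    "strand": spec.strand,
                    "orf1_start": gene_rec.orf1[0],
                    "orf1_end": gene_rec.orf1[1],
                    "orf2_start": gene_rec.orf2[0],
                    "orf2_end": gene_rec.orf2[1],
                    "fs_pos": gene_rec.fs_pos,
                    "direction": direction,
                    "rbs_score": gene_rec.rbs_score,
                    "genus": spec.genus,
                    "pseudogene_flag": int(spec.annotated_pseudogene),
                }
            )
            truth_rows.append(truth)
            if domain is not None:
                fs_aa = (gene_rec.fs_pos - gene_rec.orf1[0]) // 3
                n_aa = len(truth.fused_protein)
                domains[fs_id] = [
                    (domain, max(0, fs_aa - 60), min(n_aa, fs_aa + 60), 1e-6)
                ]
            if flags.get("reference"):
                reference[f"ref_{fs_id}"] = truth.fused_protein

    # reference decoys
    decoy_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(77777,))
    )
    for k in range(3):
        aa = "".join(
            "ACDEFGHIKLMNPQRSTVWY"[i] for i in decoy_rng.integers(0, 20, size=180)
        )
        reference[f"ref_decoy_{k}"] = aa

    predictions = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            {
                "fs_id": t.fs_id,
                "true_class": t.true_class,
                "heptamer": t.heptamer or "",
                "direction": t.direction,
                "fused_protein": t.fused_protein or "",
            }
            for t in truth_rows
        ]
    )
    return DatasetBundle(genomes, predictions, reference, domains, truth)


# --- focused fixtures for motif and ranking studies -------------------------


def generate_motif_boxes(
    seed: int,
    n_boxes: int = 30,
    box_len: int = 100,
    gc: float = 0.5,
    heptamer: str = "A_AAA_AAG",
    sd_stimulator: bool = False,
) -> list[FrameshiftBox]:
    """Random frameshift boxes with one planted phased heptamer each.

    The plant position is a uniformly chosen phase-consistent offset; with
    ``sd_stimulator`` an AGGAGG hexamer is placed 12 nt 5' of the site.
    """
    parsed = FramedHeptamer.from_display(heptamer)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    residue = 0 if parsed.direction == +1 else 2
    boxes = []
    for b in range(n_boxes):
        seq = list(_random_seq(rng, box_len, gc))
        lo = max(residue, 18 if sd_stimulator else residue)
        offsets = [
            o for o in range(box_len - 7 + 1) if o % 3 == residue and o >= lo
        ]
        site = offsets[int(rng.integers(len(offsets)))]
        for k, c in enumerate(parsed.seq):
            seq[site + k] = c
        if sd_stimulator:
            for k, c in enumerate("AGGAGG"):
                seq[site - 12 - 6 + k] = c
        boxes.append(
            FrameshiftBox(
                fs_gene_id=f"box{b:03d}",
                seq="".join(seq),
                start=0,
                end=box_len,
                phase_anchor=0,
                fs_offset=site + (1 if parsed.direction == -1 else 3),
                direction=parsed.direction,
            )
        )
    return boxes


def generate_expression_sets(
    seed: int,
    n_genes: int = 30,
    gene_len: int = 900,
    heptamer: str = "A_AAA_AAG",
    depletion: float = 5.0,
) -> tuple[list[str], list[str]]:
    """Two gene sets from one A-rich composition, the first depleted.

    Emulates the contrast between highly expressed genes (which avoid
    slippery heptamers) and the rest of a genome: both sets are drawn from
    the same AT-rich codon background; in the first set, phased occurrences
    of the target heptamer are disrupted with probability 1 - 1/depletion.
    """
    parsed = FramedHeptamer.from_display(heptamer)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    probs = np.array([0.5, 0.15, 0.15, 0.2])  # A-rich background
    residue = 0 if parsed.direction == +1 else 2

    def make_set(deplete: bool) -> list[str]:
        genes = []
        for _ in range(n_genes):
            seq = list(
                "".join(_BASES[i] for i in rng.choice(4, size=gene_len, p=probs))
            )
            if deplete:
                for o in range(residue, gene_len - 7 + 1, 3):
                    if "".join(seq[o : o + 7]) == parsed.seq:
                        if rng.random() < 1 - 1 / depletion:
                            seq[o + 3] = "C"
            genes.append("".join(seq))
        return genes

    return make_set(True), make_set(False)
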