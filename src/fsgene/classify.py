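"""Rule-based classification of fs-gene clusters and singletons.

Clusters are labelled by a first-match cascade over the feature table:
suspected overlapping gene pairs (start-codon consensus heptamer), then
programmed frameshifts (conserved phased site), phase variation (repeats
near the shift and %AT or %R above %S), translational coupling (dominant
%S), pseudogenes (few genera, an annotated pseudogene, no conserved site)
and hypothetical pseudogenes (few genera, majority bridged by homology).
Singletons are explained by their homology evidence alone: an annotated
pseudogene flag, a bridging hit (sequencing error or recent indel), split
hits (a false-positive gene pair) or nothing (orphan).

Mechanism inference runs over programmed clusters grouped by name: a
family seen with both +1 and -1 clusters points at transcriptional
realignment (PTR, polymerase slippage at homopolymers, direction-agnostic),
a single ubiquitous direction at ribosomal frameshifting (PRF).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from enum import Enum

from .features import ClusterFeatures
from .homology import ValidationStatus
from .model import FsGene
from .motif import MotifEvidence


class ClusterLabel(str, Enum):
    PROGRAMMED_FRAMESHIFT = "programmed_frameshift"
    PHASE_VARIATION = "phase_variation"
    TRANSLATIONAL_COUPLING = "translational_coupling"
    PSEUDOGENE = "pseudogene"
    HYPOTHETICAL_PSEUDOGENE = "hypothetical_pseudogene"
    OVERLAPPING_PAIR_SUSPECT = "overlapping_pair_suspect"
    UNCHARACTERIZED = "uncharacterized"


class SingletonLabel(str, Enum):
    ANNOTATED_PSEUDOGENE = "annotated_pseudogene"
    VALIDATED_ERROR_OR_INDEL = "validated_error_or_indel"
    FALSE_POSITIVE_PAIR = "false_positive_pair"
    ORPHAN = "orphan"


class MechanismCall(str, Enum):
    PTR = "PTR"
    PRF = "PRF"
    UNDETERMINED = "undetermined"


MIN_PROGRAMMED_SIZE = 5
MIN_COUPLING_PCT_S = 50
MAX_PSEUDOGENE_GENERA = 2


@dataclass(frozen=True)
class RuleConflict:
    """A cluster satisfying both the programmed and phase-variation rules.

    The cascade resolves it in favour of the earlier rule; conflicts are
    surfaced so rule-order sensitivity stays visible.
    """

    cluster_id: str
    labels: tuple[ClusterLabel, ClusterLabel]


def _phase_variation_applies(features: ClusterFeatures) -> bool:
    # "repeats present" means characteristic of the cluster, not a chance
    # repeat in one member: at least half the members must carry one
    repeats_present = features.pct_AT >= 50 or features.pct_R >= 50
    return (
        features.size >= MIN_PROGRAMMED_SIZE
        and repeats_present
        and (features.pct_AT > features.pct_S or features.pct_R > features.pct_S)
    )


def _programmed_applies(features: ClusterFeatures, motif: MotifEvidence) -> bool:
    return features.size >= MIN_PROGRAMMED_SIZE and motif.conserved_site


def classify_cluster(
    features: ClusterFeatures,
    motif: MotifEvidence | None = None,
    manual_verification: bool = False,
) -> tuple[ClusterLabel, RuleConflict | None]:
    """First-match rule cascade over one cluster's features.

    ``manual_verification`` mirrors the human literature-survey feature of
    the original analysis; it is an input flag, never computed, and is not
    required by any rule here.  Returns the label plus a conflict record
    when both the programmed and phase-variation rules matched.
    """
    motif = motif or MotifEvidence()
    programmed = _programmed_applies(features, motif)
    phase_var = _phase_variation_applies(features)
    conflict = None
    if programmed and phase_var:
        conflict = RuleConflict(
            features.cluster_id,
            (ClusterLabel.PROGRAMMED_FRAMESHIFT, ClusterLabel.PHASE_VARIATION),
        )

    if motif.conserved_site and motif.start_codon_artifact:
        return ClusterLabel.OVERLAPPING_PAIR_SUSPECT, conflict
    if programmed:
        return ClusterLabel.PROGRAMMED_FRAMESHIFT, conflict
    if phase_var:
        return ClusterLabel.PHASE_VARIATION, conflict
    if (
        features.pct_S > features.pct_AT
        and features.pct_S > features.pct_R
        and features.pct_S >= MIN_COUPLING_PCT_S
    ):
        return ClusterLabel.TRANSLATIONAL_COUPLING, conflict
    if (
        features.n_genera <= MAX_PSEUDOGENE_GENERA
        and features.has_annotated_pseudogene
        and not motif.conserved_site
    ):
        return ClusterLabel.PSEUDOGENE, conflict
    if (
        features.n_genera <= MAX_PSEUDOGENE_GENERA
        and features.pct_B > 50
        and not features.has_annotated_pseudogene
        and not motif.conserved_site
    ):
        return ClusterLabel.HYPOTHETICAL_PSEUDOGENE, conflict
    return ClusterLabel.UNCHARACTERIZED, conflict


def infer_mechanism(
    clusters: list[tuple[str, str, int, ClusterLabel]],
) -> dict[str, MechanismCall]:
    """PTR/PRF call per cluster name over programmed clusters.

    ``clusters`` holds (cluster_id, name, direction, label) rows.  Two or
    more same-name programmed clusters with opposite directions yield PTR;
    a single ubiquitous direction yields PRF; clusters named only by their
    id (no functional name) stay undetermined.
    """
    by_name: dict[str, set[int]] = defaultdict(set)
    named: dict[str, list[str]] = defaultdict(list)
    for cid, name, direction, label in clusters:
        if label is not ClusterLabel.PROGRAMMED_FRAMESHIFT:
            continue
        by_name[name].add(direction)
        named[name].append(cid)
    calls = {}
    for cid, name, direction, label in clusters:
        if label is not ClusterLabel.PROGRAMMED_FRAMESHIFT:
            continue
        if name == cid or not name:
            calls[cid] = MechanismCall.UNDETERMINED
        elif len(by_name[name]) >= 2:
            calls[cid] = MechanismCall.PTR
        else:
            calls[cid] = MechanismCall.PRF
    return calls


def classify_singleton(
    fs_gene: FsGene,
    status: ValidationStatus,
    domain_covered: bool = False,
) -> SingletonLabel:
    """Label a non-clustered fs-gene from its validation evidence."""
    if fs_gene.annotated_pseudogene:
        return SingletonLabel.ANNOTATED_PSEUDOGENE
    if status is ValidationStatus.SPLIT:
        return SingletonLabel.FALSE_POSITIVE_PAIR
    if status in (ValidationStatus.BRIDGED, ValidationStatus.DOMAIN_BRIDGED):
        # domain coverage strengthens the call (both kinds of evidence) but
        # does not change the label
        return SingletonLabel.VALIDATED_ERROR_OR_INDEL
    return SingletonLabel.ORPHAN
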