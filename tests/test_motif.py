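"""Phased heptamer machinery, the Gibbs site sampler, logos and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fsgene.model import FrameshiftBox
from fsgene.motif import (
    FramedHeptamer,
    alignment_log_odds,
    build_site_logo,
    candidate_positions,
    enumerate_framed_heptamers,
    evaluate_motif_evidence,
    gibbs_phased_motif,
    heptamer_presence,
    rank_heptamer_usage,
    score_heptamers,
)
from fsgene.simulate import generate_expression_sets, generate_motif_boxes


def make_box(seq, anchor=0, direction=-1, fs_offset=10):
    return FrameshiftBox("b", seq, 0, len(seq), anchor, fs_offset, direction)


class TestFramedHeptamer:
    @pytest.mark.parametrize(
        "seq,direction,display",
        [
            ("CTTTGAC", +1, "CTT_TGA_C"),
            ("AAAAAAG", -1, "A_AAA_AAG"),
        ],
    )
    def test_display(self, seq, direction, display):
        assert FramedHeptamer(seq, direction).display == display

    @given(
        st.text(alphabet="ACGT", min_size=7, max_size=7),
        st.sampled_from([-1, 1]),
    )
    @settings(derandomize=True, max_examples=50)
    def test_display_parse_round_trip(self, seq, direction):
        h = FramedHeptamer(seq, direction)
        assert FramedHeptamer.from_display(h.display) == h

    @pytest.mark.parametrize(
        "display,expected",
        [
            ("ATG_CCC_A", False),  # ATG in the upstream frame is no artifact
            ("CAT_GCC_A", True),   # downstream-frame ATG straddles the mark
            ("AAA_CCC_A", False),
            ("A_TGA_AAC", True),
            ("T_AAA_AAA", False),
        ],
    )
    def test_downstream_start_codon_flag(self, display, expected):
        assert FramedHeptamer.from_display(display).has_downstream_start() is expected


class TestCanonicalARich:
    def test_all_seven_representable_and_poly_a_detected(self):
        """The recurrent A-rich slippery heptamers parse, and the pure
        poly-A ones are caught by the homopolymer detector."""
        from fsgene.features import detect_poly_at
        from fsgene.motif import CANONICAL_A_RICH

        assert len(CANONICAL_A_RICH) == 7
        for display in CANONICAL_A_RICH:
            h = FramedHeptamer.from_display(display)
            assert h.display == display
            if set(h.seq) == {"A"}:
                assert detect_poly_at(h.seq)


class TestCandidatePositions:
    def test_plus_one_codon_starts(self):
        box = make_box("A" * 100, anchor=0, direction=+1)
        assert candidate_positions(box, +1) == list(range(0, 94, 3))

    def test_minus_one_offset_by_two(self):
        box = make_box("A" * 100, anchor=0, direction=-1)
        assert candidate_positions(box, -1) == list(range(2, 93, 3))

    def test_short_box_empty(self):
        assert candidate_positions(make_box("ACGTAC"), -1) == []

    def test_ambiguous_windows_skipped(self):
        box = make_box("AAAANAAAAAAA", anchor=0, direction=+1)
        assert all(
            "N" not in box.seq[o : o + 7] for o in candidate_positions(box, +1)
        )


class TestEnumeration:
    def test_planted_heptamer_counted_in_phase(self):
        # anchor 0, -1 phase => offsets 2, 5, ...; plant AAAAAAG at offset 2
        box = make_box("TT" + "AAAAAAG" + "TTTT", anchor=0, direction=-1)
        counts = enumerate_framed_heptamers([box], -1)
        assert counts["AAAAAAG"] == 1

    def test_counts_conserved(self):
        rng = np.random.default_rng(3)
        boxes = [
            make_box("".join("ACGT"[i] for i in rng.integers(0, 4, 60)))
            for _ in range(5)
        ]
        counts = enumerate_framed_heptamers(boxes, -1)
        assert sum(counts.values()) == sum(
            len(candidate_positions(b, -1)) for b in boxes
        )


class TestScores:
    def test_run_consensus_frequency(self):
        runs = ["A_AAA_AAG"] * 80 + ["C_TTT_GAC"] * 20
        scores = score_heptamers(runs)
        assert scores["A_AAA_AAG"] == pytest.approx(0.8)
        assert list(scores)[0] == "A_AAA_AAG"

    def test_single_run_scores_one(self):
        assert score_heptamers(["A_AAA_AAG"]) == {"A_AAA_AAG": 1.0}


class TestSampler:
    def test_identical_boxes_degenerate_consensus(self):
        seq = "TTGACGTACGAAAAAAGCATGCATAACGTAGCAT"
        boxes = [
            FrameshiftBox(f"b{i}", seq, 0, len(seq), 0, 12, -1) for i in range(4)
        ]
        model = gibbs_phased_motif(boxes, -1, n_runs=10, seed=0)
        assert len(set(model.run_consensus)) == 1

    def test_deterministic_given_seed(self):
        boxes = generate_motif_boxes(seed=2, n_boxes=8, box_len=60)
        a = gibbs_phased_motif(boxes, -1, n_runs=10, seed=5)
        b = gibbs_phased_motif(boxes, -1, n_runs=10, seed=5)
        assert a.run_consensus == b.run_consensus
        assert a.sites == b.sites

    def test_phase_safety_of_reported_sites(self):
        boxes = generate_motif_boxes(seed=4, n_boxes=10, box_len=80)
        model = gibbs_phased_motif(boxes, -1, n_runs=20, seed=1)
        for box in boxes:
            assert model.sites[box.fs_gene_id] in candidate_positions(box, -1)

    def test_needs_two_boxes(self):
        boxes = generate_motif_boxes(seed=4, n_boxes=1)
        with pytest.raises(ValueError):
            gibbs_phased_motif(boxes, -1, n_runs=5, seed=0)

    def test_sampler_matches_or_beats_single_window_oracle(self):
        """Converged log-odds >= the exhaustive common-offset oracle.

        The oracle places one window at the same phased offset in every box
        and maximizes the shared objective exhaustively; the sampler's
        per-box freedom must never do worse (19/20 seeded trials allowed
        one sampling miss).
        """
        wins = 0
        for trial in range(20):
            boxes = generate_motif_boxes(
                seed=100 + trial, n_boxes=8, box_len=60
            )
            model = gibbs_phased_motif(boxes, -1, n_runs=10, seed=trial)
            offsets = [candidate_positions(b, -1) for b in boxes]
            common = sorted(set.intersection(*map(set, offsets)))
            best_oracle = -np.inf
            for o in common:
                windows = np.stack(
                    [
                        np.array(
                            ["ACGT".index(c) for c in b.seq[o : o + 7]]
                        )
                        for b in boxes
                    ]
                )
                bg = np.full(4, 0.25)
                best_oracle = max(
                    best_oracle, alignment_log_odds(windows, bg)
                )
            # compare on the sampler's own background-normalized objective:
            site_windows = np.stack(
                [
                    np.array(
                        ["ACGT".index(c) for c in b.seq[s : s + 7]]
                    )
                    for b, s in ((b, model.sites[b.fs_gene_id]) for b in boxes)
                ]
            )
            if alignment_log_odds(site_windows, np.full(4, 0.25)) >= best_oracle:
                wins += 1
        assert wins >= 19


class TestLogo:
    def test_identical_context_reaches_two_bits(self):
        seq = "GC" + "ATGACGTACGAAAAAAGCATGCATAACGTAGCA"
        boxes = [
            FrameshiftBox(f"b{i}", seq, 0, len(seq), 0, 12, -1)
            for i in range(5)
        ]
        sites = {b.fs_gene_id: 11 for b in boxes}
        pfm, info = build_site_logo(boxes, sites)
        assert pfm.shape == (4, 47)
        covered = pfm.sum(axis=0) > 0
        assert np.allclose(pfm[:, covered].sum(axis=0), 1.0)
        # fully observed, identical columns carry log2(4) = 2 bits
        middle = info[20:27]
        assert np.allclose(middle, 2.0)

    def test_planted_sd_elevates_upstream_information(self):
        """An AGGAGG stimulator 12 nt 5' of the site shows in the logo."""
        boxes = generate_motif_boxes(
            seed=9, n_boxes=40, box_len=100, sd_stimulator=True
        )
        sites = {
            b.fs_gene_id: b.fs_offset - 1 for b in boxes
        }  # planted site offset
        pfm, info = build_site_logo(boxes, sites)
        sd_cols = info[20 - 18 : 20 - 12]   # where AGGAGG was planted
        background_cols = info[:2]
        assert sd_cols.mean() > background_cols.mean() + 0.5
        assert info[20:27].mean() > 1.9


class TestEvidence:
    def test_repeat_dominated_top_heptamer_demoted(self):
        seq = "TTGAC" + "AGTC" * 4 + "GGATCCGTAGGATC"
        boxes = [
            FrameshiftBox(f"b{i}", seq, 0, len(seq), 0, 8, -1)
            for i in range(6)
        ]
        model = gibbs_phased_motif(boxes, -1, n_runs=10, seed=2)
        evidence = evaluate_motif_evidence(model, boxes)
        if evidence.repeat_dominated:
            assert not evidence.conserved_site

    def test_canonical_a_rich_exempt_from_demotion(self):
        # poly-A runs are bona fide slippery sites despite being repeats
        seq = "TTGACCT" + "AAAAAAA" + "GGATCCGTAGGATCC"
        boxes = [
            FrameshiftBox(f"b{i}", seq, 0, len(seq), 0, 8, -1)
            for i in range(6)
        ]
        model = gibbs_phased_motif(boxes, -1, n_runs=10, seed=2)
        evidence = evaluate_motif_evidence(model, boxes)
        if evidence.top_heptamer == "A_AAA_AAA":
            assert evidence.conserved_site

    def test_presence_fraction(self):
        boxes = [
            make_box("TT" + "AAAAAAG" + "TTTT"),
            make_box("TT" + "CCCCCCC" + "TTTT"),
        ]
        assert heptamer_presence(boxes, "AAAAAAG", -1) == 0.5


class TestRanking:
    def test_identical_sets_equal_ranks(self):
        genes = ["CC" + "AAAAAAGCCGTA" * 20]
        (ra, fa), (rb, fb) = rank_heptamer_usage(genes, genes, "A_AAA_AAG")
        assert ra == rb and not fa and not fb

    def test_single_species_ranks_first(self):
        gene = "CC" + "AAAAAAG" * 10  # -1 phase at offsets 2, 9, ...
        (ra, fa), _ = rank_heptamer_usage([gene], [gene], "A_AAA_AAG")
        assert ra == 1

    def test_absent_heptamer_flagged_worst(self):
        genes_a = ["CC" + "GGGGGGG" * 10]
        genes_b = ["CC" + "AAAAAAG" * 10]
        (ra, fa), (rb, fb) = rank_heptamer_usage(genes_a, genes_b, "A_AAA_AAG")
        assert fa and not fb
        assert ra > rb

    def test_depleted_set_ranks_strictly_worse(self):
        depleted, normal = generate_expression_sets(seed=1)
        (ra, _), (rb, _) = rank_heptamer_usage(depleted, normal, "A_AAA_AAG")
        assert ra > rb
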