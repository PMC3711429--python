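"""Repeat detection, start/stop colocalization, RBS scoring, cluster features."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fsgene.features import (
    RBS_MAX,
    RBS_MIN,
    detect_poly_at,
    detect_tandem_repeats,
    mean_box_identity,
    rbs_score,
    relative_fs_position,
    significant_repeats,
    start_stop_distance,
)
from fsgene.model import FrameshiftBox, FsGene


def brute_force_repeats(window, min_total=7, max_unit=6):
    """Independent enumeration of all (unit, start, copies) candidates."""
    window = window.upper()
    n = len(window)
    found = []
    for u in range(1, max_unit + 1):
        for start in range(n):
            if start + u > n:
                break
            # maximality on the left
            if start - 1 >= 0 and start - 1 + u < n and \
               window[start - 1] == window[start - 1 + u]:
                continue
            end = start + u
            while end < n and window[end] == window[end - u]:
                end += 1
            span = end - start
            if span < max(min_total, u + 1):
                continue
            unit = window[start : start + u]
            primitive = all(
                not (u % d == 0 and unit == unit[:d] * (u // d))
                for d in range(1, u)
            )
            if primitive:
                found.append((unit, start, span))
    # non-nested filter, mirroring the reported contract
    out = []
    for unit, start, span in found:
        nested = any(
            (o_unit, o_start, o_span) != (unit, start, span)
            and len(o_unit) < len(unit)
            and o_start <= start
            and start + span <= o_start + o_span
            for o_unit, o_start, o_span in found
        )
        if not nested:
            out.append((unit, start, span))
    return sorted(out)


class TestPolyAT:
    @pytest.mark.parametrize(
        "window,n_stretches",
        [
            ("CCAAAAAAACC", 1),   # A x 7
            ("CCAAAAAACC", 0),    # A x 6: below threshold
            ("TTTTTTTT", 1),      # T x 8
            ("AAAAAAATTTTTTT", 2),
            ("ATATATATATAT", 0),  # mixed A/T is not a homopolymer
        ],
    )
    def test_threshold_behavior(self, window, n_stretches):
        assert len(detect_poly_at(window)) == n_stretches


class TestTandemRepeats:
    def test_agtc_unit(self):
        reps = detect_tandem_repeats("AGTCAGTCAGTC")
        assert any(r.unit == "AGTC" and r.copies == 3 and r.span == 12 for r in reps)

    def test_homopolymer_reported_once_with_primitive_unit(self):
        reps = detect_tandem_repeats("GGGGGGG")
        assert len(reps) == 1
        assert reps[0].unit == "G" and reps[0].copies == 7

    def test_fractional_trailing_copy(self):
        reps = detect_tandem_repeats("AGTCAGT")
        assert any(r.unit == "AGTC" and r.copies == 1.75 and r.span == 7 for r in reps)

    def test_matches_brute_force_on_random_windows(self):
        """Exact agreement with independent enumeration on 200 windows."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            n = int(rng.integers(10, 61))
            window = "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))
            got = sorted((r.unit, r.start, r.span)
                         for r in detect_tandem_repeats(window))
            assert got == brute_force_repeats(window), window

    @given(st.text(alphabet="ACGT", min_size=7, max_size=40))
    @settings(derandomize=True, max_examples=60)
    def test_reported_repeats_verify_in_place(self, window):
        for rep in detect_tandem_repeats(window):
            region = window[rep.start : rep.start + rep.span]
            for k in range(len(rep.unit), rep.span):
                assert region[k] == region[k - len(rep.unit)]

    def test_significance_filter_drops_barely_repeats(self):
        # a single unit-6 recurrence spans 7 nt but is chance-level
        reps = detect_tandem_repeats("ACGTGAACGTGA"[:11])
        assert significant_repeats(reps) == []
        assert significant_repeats(detect_tandem_repeats("AGTCAGTCAGTC")) != []


class TestStartStop:
    """ORF2's interval starts at its predicted start codon."""

    def make_gene(self, genome_len, fs, orf2_start, direction=+1):
        return FsGene(
            "g", "c", "+", (0, genome_len), (orf2_start, genome_len), fs,
            direction,
        )

    def test_overlapping_start_stop_colocalized(self):
        # ORF1 stop TAA at 30-32; predicted ORF2 start ATG at 34
        s = "ATG" + "AAC" * 9 + "TAA" + "CATGCCGCT" + "CCC" * 5 + "TAA"
        gene = self.make_gene(len(s), 27, 34)
        dist, coloc = start_stop_distance(gene, s)
        assert coloc and dist == 2

    def test_distance_11_not_colocalized(self):
        dist_11 = "ATG" + "AAC" * 9 + "TAA" + "CCCCCCCCTT" + "ATG" + "CCC" * 4
        gene = self.make_gene(len(dist_11), 27, 43)
        dist, coloc = start_stop_distance(gene, dist_11)
        assert dist == 11 and not coloc
        assert start_stop_distance(gene, dist_11, threshold=20)[1]

    def test_gtg_start_counted_only_with_variant(self):
        s = "ATG" + "AAC" * 9 + "TAA" + "CGTGCCGCT" + "CCC" * 5 + "TAA"
        gene = self.make_gene(len(s), 27, 34)
        assert not start_stop_distance(gene, s)[1]
        assert start_stop_distance(gene, s, accept_gtg=True)[1]

    def test_no_start_codon_undefined(self):
        s = "ATG" + "AAC" * 9 + "TAA" + "CCC" * 6
        gene = self.make_gene(len(s), 27, 33)
        dist, coloc = start_stop_distance(gene, s)
        assert dist is None and not coloc


class TestRbsScore:
    def test_canonical_sd_beats_filter_threshold(self):
        window = "CCTCCTCC" + "AGGAGG" + "CCTCCTCC"[:6]  # 6-nt spacing
        assert rbs_score(window) > 2.2

    def test_random_windows_average_below_zero_and_bounded(self):
        rng = np.random.default_rng(11)
        scores = []
        for _ in range(2000):
            window = "".join("ACGT"[i] for i in rng.integers(0, 4, size=20))
            s = rbs_score(window)
            assert RBS_MIN <= s <= RBS_MAX
            scores.append(s)
        assert np.mean(scores) < 0

    def test_extending_sd_match_never_lowers_score(self):
        # AGGxGG -> AGGAGG at fixed spacing
        partial = "CCTCCTCC" + "AGGCGG" + "CCTCCT"
        full = "CCTCCTCC" + "AGGAGG" + "CCTCCT"
        assert rbs_score(full) >= rbs_score(partial)

    def test_short_window_minimal(self):
        assert rbs_score("AGGA") == RBS_MIN


class TestRelativePosition:
    def test_bounds_and_midpoint(self):
        gene = FsGene("g", "c", "+", (0, 300), (100, 600), 300, +1)
        assert relative_fs_position(gene) == pytest.approx(0.5)
        gene0 = FsGene("g", "c", "+", (0, 300), (0, 600), 0, +1)
        assert relative_fs_position(gene0) == 0.0

    def test_three_prime_biased_set_has_late_mode(self, rng):
        """Indel-truncation bias shows as a mode in the last decile."""
        positions = []
        for _ in range(300):
            length = int(rng.integers(300, 600)) // 3 * 3
            frac = float(np.clip(rng.beta(6, 1), 0, 0.99))
            fs = int(frac * length) // 3 * 3
            gene = FsGene("g", "c", "+", (0, max(fs + 3, 3)),
                          (max(fs - 3, 0), length), fs, +1)
            positions.append(relative_fs_position(gene))
        hist, _ = np.histogram(positions, bins=10, range=(0, 1))
        assert hist.argmax() == 9


class TestBoxIdentity:
    def test_identical_boxes_100(self):
        boxes = [
            FrameshiftBox(f"b{i}", "ACGT" * 20, 0, 80, 0, 10, -1)
            for i in range(3)
        ]
        assert mean_box_identity(boxes) == 100.0

    def test_unrelated_boxes_low(self, rng):
        boxes = [
            FrameshiftBox(
                f"b{i}",
                "".join("ACGT"[j] for j in rng.integers(0, 4, size=80)),
                0, 80, 0, 10, -1,
            )
            for i in range(4)
        ]
        assert mean_box_identity(boxes) < 80.0
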