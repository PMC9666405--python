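"""Long-read classification: locus filtering, full-length calling, isoform
assignment, aberrance, splice features and distribution tabulation."""

from __future__ import annotations

import numpy as np
import pytest

from isojunct.longread import (
    ClassifyConfig,
    ContigMismatchError,
    PlusMinus,
    ReadStatus,
    classify_read,
    classify_reads,
    call_full_length,
    filter_locus,
    splice_features,
    tabulate,
)
from isojunct.simulate import (
    SimulationConfig,
    conditional_full_length_weights,
    simulate_long_reads,
)

from conftest import read_from_blocks, transcript_read

CFG = ClassifyConfig()


class TestFilterLocus:
    def test_one_bp_edge_overlap_is_kept(self, mouse_model):
        m = mouse_model
        inside = read_from_blocks([(m.locus_end - 1, m.locus_end + 99)], read_id="edge")
        outside = read_from_blocks([(m.locus_end, m.locus_end + 100)], read_id="out")
        kept = filter_locus([inside, outside], m)
        assert [r.read_id for r in kept] == ["edge"]

    def test_contig_mismatch_raises_with_hint(self, mouse_model):
        read = read_from_blocks([(69400000, 69400100)], contig="18")
        with pytest.raises(ContigMismatchError, match="rename map"):
            filter_locus([read], mouse_model)

    def test_order_preserved(self, mouse_model):
        m = mouse_model
        reads = [
            read_from_blocks([(m.locus_start + i * 10, m.locus_start + i * 10 + 100)], read_id=f"r{i}")
            for i in range(5)
        ]
        assert [r.read_id for r in filter_locus(reads, m)] == [f"r{i}" for i in range(5)]


class TestFullLengthCall:
    def test_last_exon_only_read_is_truncated(self, mouse_model):
        tp = mouse_model.three_prime_exon
        read = read_from_blocks([(tp.end - 800, tp.end)])
        assert call_full_length(read, mouse_model, CFG) is ReadStatus.TRUNCATED

    def test_transcript_spanning_read_is_full_length(self, mouse_model):
        read = transcript_read(mouse_model, "TCF4-B")
        assert call_full_length(read, mouse_model, CFG) is ReadStatus.FULL_LENGTH

    def test_start_inside_internal_exon_is_truncated(self, mouse_model):
        blocks = mouse_model.transcript_blocks("TCF4-B")
        # drop the 5' exon and start 5 bp into internal exon 4
        s, e = blocks[1]
        read = read_from_blocks([(s + 5, e), *blocks[2:]])
        assert call_full_length(read, mouse_model, CFG) is ReadStatus.TRUNCATED

    def test_upstream_slack_allows_small_overhang(self, mouse_model):
        blocks = mouse_model.transcript_blocks("TCF4-B")
        s, e = blocks[0]
        read = read_from_blocks([(s - 30, e), *blocks[1:]])
        assert call_full_length(read, mouse_model, CFG) is ReadStatus.FULL_LENGTH

    def test_three_prime_end_outside_terminal_exon_is_truncated(self, mouse_model):
        blocks = mouse_model.transcript_blocks("TCF4-B")
        (s20, e20) = blocks[-1]
        read = read_from_blocks([*blocks[:-1], (s20, e20 - 200), (e20 + 500, e20 + 600)])
        assert call_full_length(read, mouse_model, CFG) is not ReadStatus.FULL_LENGTH


class TestIsoformAssignment:
    @pytest.mark.parametrize(
        "isoform,kwargs,exon",
        [
            ("TCF4-B", {}, "3"),
            ("TCF4-C", {}, "4a"),
            ("TCF4-D", {"extended_start": True}, "7b"),
            ("TCF4-A", {}, "10a"),
            ("TCF4-I", {}, "10b"),
        ],
    )
    def test_transcript_reads_get_their_isoform(self, mouse_model, isoform, kwargs, exon):
        read = transcript_read(mouse_model, isoform, **kwargs)
        call = classify_read(read, mouse_model, CFG)
        assert call.status is ReadStatus.FULL_LENGTH
        assert call.isoform == isoform
        assert call.five_prime_exon == exon

    def test_unassigned_five_prime_exon_is_flagged_not_dropped(self, mouse_model):
        e1 = mouse_model.exon("1")
        blocks = [(e1.start, e1.end)] + list(mouse_model.transcript_blocks("TCF4-B"))[1:]
        call = classify_read(read_from_blocks(blocks), mouse_model, CFG)
        assert call.status is ReadStatus.FULL_LENGTH
        assert call.isoform == "unassigned"
        assert "no_isoform_for_first_exon" in call.flags

    def test_undeclared_exon_skip_is_aberrant(self, mouse_model):
        blocks = mouse_model.transcript_blocks("TCF4-B", skip_exons=["12"])
        call = classify_read(read_from_blocks(blocks), mouse_model, CFG)
        assert call.status is ReadStatus.ABERRANT

    def test_junction_absent_from_model_is_aberrant(self, mouse_model):
        # exon 7 spliced directly to exon 11: neither annotated nor a feature
        blocks = mouse_model.transcript_blocks("TCF4-B", skip_exons=["8", "9", "10"])
        call = classify_read(read_from_blocks(blocks), mouse_model, CFG)
        assert call.status is ReadStatus.ABERRANT

    def test_declared_delta_skip_is_not_aberrant(self, mouse_model):
        read = transcript_read(mouse_model, "TCF4-B", delta=True)
        call = classify_read(read, mouse_model, CFG)
        assert call.status is ReadStatus.FULL_LENGTH
        assert call.isoform == "TCF4-B"
        assert call.delta is True


class TestSpliceFeatures:
    def test_plus_variant_acceptor(self, mouse_model):
        read = transcript_read(mouse_model, "TCF4-B", plus=True)
        delta, pm = splice_features(read, mouse_model, CFG)
        assert pm is PlusMinus.PLUS
        assert delta is False

    def test_minus_variant_acceptor(self, mouse_model):
        read = transcript_read(mouse_model, "TCF4-D", extended_start=True)
        _, pm = splice_features(read, mouse_model, CFG)
        assert pm is PlusMinus.MINUS

    def test_region_not_covered_is_indeterminate(self, mouse_model):
        read = transcript_read(mouse_model, "TCF4-A")
        delta, pm = splice_features(read, mouse_model, CFG)
        assert pm is PlusMinus.INDETERMINATE
        assert delta is None

    def test_balanced_plus_minus_mixture_recovered(self, mouse_model):
        cfg = SimulationConfig(
            model=mouse_model,
            seed=11,
            n_reads=400,
            mixture={"TCF4-B": 1.0},
            truncation_mean_bp=float("inf"),
            aberrant_rate=0.0,
        )
        reads, truth = simulate_long_reads(cfg)
        calls, _ = classify_reads(reads, mouse_model)
        plus = sum(1 for c in calls if c.plus_minus is PlusMinus.PLUS)
        n = sum(1 for c in calls if c.plus_minus is not PlusMinus.INDETERMINATE)
        se = np.sqrt(0.25 / n)
        assert abs(plus / n - 0.5) < 3 * se


class TestTabulate:
    def test_single_isoform_is_hundred_percent(self, mouse_model):
        read = transcript_read(mouse_model, "TCF4-A")
        calls = [classify_read(read, mouse_model, CFG)] * 7
        dist = tabulate(calls)
        assert dist.fractions == {"TCF4-A": 100.0}

    def test_zero_full_length_flagged_not_nan(self, mouse_model):
        tp = mouse_model.three_prime_exon
        read = read_from_blocks([(tp.end - 500, tp.end)])
        dist = tabulate([classify_read(read, mouse_model, CFG)])
        assert dist.n_full_length == 0
        assert dist.undefined
        assert dist.fractions == {}

    def test_fractions_sum_to_100(self, mouse_model):
        cfg = SimulationConfig(model=mouse_model, seed=5, n_reads=300)
        reads, _ = simulate_long_reads(cfg)
        dist = tabulate(classify_reads(reads, mouse_model)[0])
        assert abs(sum(dist.fractions.values()) - 100.0) < 1e-9

    def test_status_partition(self, mouse_model):
        cfg = SimulationConfig(model=mouse_model, seed=3, n_reads=400, aberrant_rate=0.1)
        reads, _ = simulate_long_reads(cfg)
        calls, discordant = classify_reads(filter_locus(reads, mouse_model), mouse_model)
        dist = tabulate(calls, discordant)
        assert discordant == 0
        assert dist.n_total == dist.n_full_length + dist.n_truncated + dist.n_aberrant

    def test_strand_discordant_reads_excluded_and_counted(self, mouse_model):
        read = transcript_read(mouse_model, "TCF4-B")
        flipped = read_from_blocks(
            [(s, s + size) for s, size in read.blocks], strand="-", read_id="flip"
        )
        calls, discordant = classify_reads([read, flipped], mouse_model)
        assert discordant == 1
        assert len(calls) == 1


class TestRecoveryProperties:
    def test_monotone_truncation_never_rescues_a_read(self, mouse_model):
        """Shortening a read from its 5' end can only move it full_length ->
        truncated, never the reverse."""
        from isojunct.simulate import _truncate_blocks

        for isoform, kwargs in [("TCF4-B", {}), ("TCF4-D", {"extended_start": True})]:
            blocks = mouse_model.transcript_blocks(isoform, **kwargs)
            L = sum(e - s for s, e in blocks)
            seen_truncated = False
            for retained in range(L, 200, -137):
                kept = _truncate_blocks(blocks, retained, mouse_model.strand)
                read = read_from_blocks(kept)
                status = call_full_length(read, mouse_model, CFG)
                if status is ReadStatus.TRUNCATED:
                    seen_truncated = True
                else:
                    assert not seen_truncated, (
                        f"{isoform}: read regained full-length at retained={retained}"
                    )
            assert seen_truncated

    def test_mixture_recovery_within_three_binomial_se(self, mouse_model):
        """At n=2000 the full-length composition matches the length-biased
        (conditional) mixture within 3 binomial standard errors."""
        cfg = SimulationConfig(model=mouse_model, seed=123, n_reads=2000)
        reads, _ = simulate_long_reads(cfg)
        calls, _ = classify_reads(filter_locus(reads, mouse_model), mouse_model)
        dist = tabulate(calls)
        expected = conditional_full_length_weights(cfg)
        n = sum(dist.counts.values())
        for isoform, p in expected.items():
            se = np.sqrt(p * (1 - p) / n)
            observed = dist.fractions.get(isoform, 0.0) / 100.0
            assert abs(observed - p) < 3 * se, (isoform, observed, p)

    def test_composition_error_shrinks_with_read_count(self, mouse_model):
        """Mean absolute composition error decreases from n=200 to n=2000
        (averaged over seeds to damp single-draw noise)."""

        def mean_abs_err(n_reads: int, seed: int) -> float:
            cfg = SimulationConfig(
                model=mouse_model,
                seed=seed,
                n_reads=n_reads,
                truncation_mean_bp=float("inf"),
                aberrant_rate=0.0,
            )
            reads, _ = simulate_long_reads(cfg)
            dist = tabulate(classify_reads(reads, mouse_model)[0])
            return float(
                np.mean(
                    [
                        abs(dist.fractions.get(k, 0.0) / 100.0 - w)
                        for k, w in cfg.mixture.items()
                    ]
                )
            )

        small = np.mean([mean_abs_err(200, s) for s in (1, 2, 3)])
        large = np.mean([mean_abs_err(2000, s) for s in (1, 2, 3)])
        assert large < small
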