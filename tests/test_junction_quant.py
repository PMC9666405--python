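"""Junction filtering, normalization, summarisation, composition, SEM and
extended-exon point-region counting."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from isojunct.junction_quant import (
    aggregate_groups,
    annotate_junctions,
    composition_frame,
    filter_junctions,
    isoform_composition,
    normalize,
    point_region_counts,
    point_region_window,
    summarize_by_exon,
    summarize_by_isoform,
    total_expression,
)
from isojunct.simulate import SimulationConfig, simulate_junction_counts

from conftest import make_count_table, read_from_blocks


class TestFilterJunctions:
    def test_prevalence_rule_12_samples(self):
        """With 12 samples the threshold is ceil(1.2) = 2 detections."""
        table = make_count_table(
            {
                "j_in1": [5] + [0] * 11,
                "j_in2": [5, 5] + [0] * 10,
                "j_all": [3] * 12,
            }
        )
        kept = filter_junctions(table).junction_ids
        assert kept == ["j_in2", "j_all"]

    def test_prevalence_rule_10_samples_boundary(self):
        """With 10 samples ceil(1.0) = 1: a single detection survives."""
        table = make_count_table({"j_in1": [7] + [0] * 9, "j_all": [3] * 10})
        kept = filter_junctions(table).junction_ids
        assert set(kept) == {"j_in1", "j_all"}

    def test_mitochondrial_junction_removed_despite_high_counts(self):
        table = make_count_table(
            {"j_mito": [10_000] * 4, "j_ok": [10] * 4},
            contigs={"j_mito": "chrM"},
        )
        assert filter_junctions(table).junction_ids == ["j_ok"]

    def test_non_canonical_motif_removed(self):
        table = make_count_table(
            {"j_nc": [50] * 4, "j_ok": [10] * 4}, motifs={"j_nc": "non_canonical"}
        )
        assert filter_junctions(table).junction_ids == ["j_ok"]

    def test_idempotent(self):
        table = make_count_table(
            {"j_in1": [5] + [0] * 11, "j_all": [3] * 12, "j_mito": [9] * 12},
            contigs={"j_mito": "MT"},
        )
        once = filter_junctions(table)
        twice = filter_junctions(once)
        assert once.junction_ids == twice.junction_ids
        pd.testing.assert_frame_equal(once.counts, twice.counts)

    def test_totals_unchanged_by_filtering(self):
        table = make_count_table({"j_mito": [100] * 4, "j_ok": [10] * 4}, contigs={"j_mito": "chrM"})
        pd.testing.assert_series_equal(filter_junctions(table).totals, table.totals)


class TestNormalize:
    def test_per_million_identity(self):
        table = make_count_table({"j": [50]}, totals=[1_000_000.0])
        assert normalize(table).values.iloc[0, 0] == 50.0

    def test_library_size_scale_invariance(self):
        t1 = make_count_table({"a": [10, 20], "b": [30, 40]}, totals=[1000.0, 2000.0])
        t2 = make_count_table({"a": [70, 20], "b": [210, 40]}, totals=[7000.0, 2000.0])
        pd.testing.assert_frame_equal(normalize(t1).values, normalize(t2).values)

    def test_zero_total_sample_dropped_with_warning(self, caplog):
        table = make_count_table({"a": [10, 0]}, totals=[1000.0, 0.0])
        with caplog.at_level("WARNING", logger="isojunct"):
            usage = normalize(table)
        assert usage.dropped_samples == ("s02",)
        assert list(usage.values.index) == ["s01"]
        assert "zero junction reads" in caplog.text


class TestSummaries:
    def _usage(self, mouse_model, values: dict[str, float]):
        table = make_count_table({k: [int(v * 10)] for k, v in values.items()}, totals=[1e7])
        junctions = table.junctions.copy()
        label_map = {j.junction_id: j for j in mouse_model.junctions}
        for jid in junctions.index:
            j = label_map.get(jid)
            if j is not None:
                junctions.loc[jid, "exon_label"] = j.exon_label
                junctions.loc[jid, "isoform_label"] = j.isoform_label or ""
        table.junctions = junctions
        return normalize(table)

    def test_variant_junctions_pool_into_one_exon_label(self, mouse_model):
        usage = self._usage(mouse_model, {"7-8.I": 3.0, "7-8.II": 2.0})
        summary = summarize_by_exon(usage)
        assert list(summary.columns) == ["7-8"]
        assert summary.iloc[0, 0] == pytest.approx(5.0)

    def test_single_junction_label_passthrough_and_absent_is_zero(self, mouse_model):
        usage = self._usage(mouse_model, {"10-11": 4.0, "11-12": 0.0})
        summary = summarize_by_exon(usage)
        assert summary.loc["s01", "10-11"] == pytest.approx(4.0)
        assert summary.loc["s01", "11-12"] == 0.0

    def test_total_expression_equal_values(self, mouse_model):
        labels = mouse_model.constitutive_junction_labels
        summary = pd.DataFrame({lab: [7.5] for lab in labels}, index=["s01"])
        assert total_expression(summary, mouse_model).loc["s01"] == pytest.approx(7.5)

    def test_total_expression_closed_form_mean(self, mouse_model):
        labels = mouse_model.constitutive_junction_labels
        summary = pd.DataFrame({lab: [float(i + 1)] for i, lab in enumerate(labels)}, index=["s01"])
        assert total_expression(summary, mouse_model).loc["s01"] == pytest.approx(5.5)

    def test_total_expression_missing_label_is_explicit_error(self, mouse_model):
        labels = mouse_model.constitutive_junction_labels[:-1]
        summary = pd.DataFrame({lab: [1.0] for lab in labels}, index=["s01"])
        with pytest.raises(ValueError, match="19-20"):
            total_expression(summary, mouse_model)


class TestComposition:
    def test_single_isoform_is_hundred_percent(self, mouse_model):
        iso = pd.DataFrame({"TCF4-A": [4.2]}, index=pd.Index(["s01"], name="sample_id"))
        meta = pd.DataFrame(
            {"tissue": ["cortex"], "age_group": ["P3"]}, index=iso.index
        )
        (comp,) = isoform_composition(iso, meta, mouse_model)
        assert comp.percentages["TCF4-A"] == pytest.approx(100.0)
        assert comp.percentages["TCF4-B"] == 0.0

    def test_equal_signal_gives_equal_percentages(self, mouse_model):
        names = mouse_model.annotated_isoform_names
        iso = pd.DataFrame({n: [3.0] for n in names}, index=pd.Index(["s01"], name="sample_id"))
        meta = pd.DataFrame({"tissue": ["cortex"], "age_group": ["P3"]}, index=iso.index)
        (comp,) = isoform_composition(iso, meta, mouse_model)
        assert all(v == pytest.approx(20.0) for v in comp.percentages.values())

    def test_all_zero_group_flagged_undefined(self, mouse_model):
        iso = pd.DataFrame(
            {"TCF4-A": [0.0, 5.0]}, index=pd.Index(["s01", "s02"], name="sample_id")
        )
        meta = pd.DataFrame(
            {"tissue": ["liver", "cortex"], "age_group": ["P3", "P3"]}, index=iso.index
        )
        comps = isoform_composition(iso, meta, mouse_model)
        by_group = {c.group: c for c in comps}
        assert by_group[("liver", "P3")].undefined
        assert not by_group[("cortex", "P3")].undefined

    def test_composition_long_format_sums_to_100(self, mouse_model):
        cfg = SimulationConfig(model=mouse_model, seed=2, depth=5e4)
        table, _ = simulate_junction_counts(cfg, 6)
        usage = normalize(filter_junctions(table))
        comps = isoform_composition(summarize_by_isoform(usage), usage.samples, mouse_model)
        frame = composition_frame(comps)
        sums = frame.groupby(["tissue", "age_group"])["percent"].sum()
        assert np.allclose(sums.values, 100.0, atol=1e-9)

    def test_poisson_recovery_within_two_points(self, mouse_model):
        """Known 5-isoform mixture at depth 1e5: composition within ±2 pts."""
        cfg = SimulationConfig(model=mouse_model, seed=42, depth=1e5)
        table, truth = simulate_junction_counts(cfg, 12)
        usage = normalize(filter_junctions(table))
        (comp,) = isoform_composition(summarize_by_isoform(usage), usage.samples, mouse_model)
        for _, row in truth.iterrows():
            assert abs(comp.percentages[row["isoform"]] - row["expected_percent"]) < 2.0


class TestAggregateGroups:
    def _meta(self, groups):
        return pd.DataFrame(
            {
                "tissue": [g for g in groups],
                "age_group": "P3",
            },
            index=pd.Index([f"s{i:02d}" for i in range(len(groups))], name="sample_id"),
        )

    def test_mean_and_sem_closed_form(self):
        meta = self._meta(["ctx", "ctx"])
        values = pd.Series([2.0, 4.0], index=meta.index)
        out = aggregate_groups(values, meta)
        assert out.loc[0, "mean"] == pytest.approx(3.0)
        assert out.loc[0, "sem"] == pytest.approx(1.0)

    def test_single_sample_group_sem_missing(self):
        meta = self._meta(["ctx"])
        out = aggregate_groups(pd.Series([5.0], index=meta.index), meta)
        assert out.loc[0, "mean"] == 5.0
        assert np.isnan(out.loc[0, "sem"])

    def test_sample_order_invariance(self):
        meta = self._meta(["ctx", "cb", "ctx", "cb"])
        values = pd.Series([1.0, 2.0, 3.0, 4.0], index=meta.index)
        perm = ["s03", "s00", "s02", "s01"]
        out1 = aggregate_groups(values, meta)
        out2 = aggregate_groups(values.loc[perm], meta.loc[perm])
        pd.testing.assert_frame_equal(out1, out2)


class TestPointRegionCounts:
    def test_window_is_one_bp_two_bp_upstream(self, mouse_model):
        exon4 = mouse_model.exon("4")
        contig, start, end = point_region_window(mouse_model, "4c")
        assert (contig, start, end) == (mouse_model.contig, exon4.start - 3, exon4.start - 2)

    def test_minus_strand_window_flips(self, minus_model):
        # give the minus toy an extension so the window is defined
        import dataclasses

        e2 = minus_model.exon("e2")
        patched = dataclasses.replace(e2, start_extensions={"x": 50})
        model = dataclasses.replace(
            minus_model,
            exons=tuple(patched if e.name == "e2" else e for e in minus_model.exons),
        )
        contig, start, end = point_region_window(model, "e2x")
        assert (start, end) == (e2.end + 2, e2.end + 3)

    def test_read_ending_at_exon_start_not_counted(self, mouse_model):
        exon4 = mouse_model.exon("4")
        read = read_from_blocks([(exon4.start, exon4.end)])
        counts = point_region_counts({"s01": [read]}, mouse_model, "4c")
        assert counts["s01"] == 0

    def test_spanning_read_counted_once_despite_blocks(self, mouse_model):
        exon4 = mouse_model.exon("4")
        read = read_from_blocks(
            [(exon4.start - 100, exon4.start + 10), (exon4.start + 500, exon4.start + 600)]
        )
        counts = point_region_counts({"s01": [read]}, mouse_model, "4c")
        assert counts["s01"] == 1

    def test_counts_proportional_to_abundance(self, mouse_model):
        """Reads from the extended-exon transcript at known abundance give
        point counts tracking that abundance."""
        from isojunct.simulate import simulate_long_reads

        rng_counts = {}
        for frac, seed in [(0.2, 1), (0.6, 2)]:
            cfg = SimulationConfig(
                model=mouse_model,
                seed=seed,
                n_reads=600,
                mixture={"TCF4-D": frac, "TCF4-A": 1 - frac},
                truncation_mean_bp=float("inf"),
                aberrant_rate=0.0,
            )
            reads, _ = simulate_long_reads(cfg)
            rng_counts[frac] = point_region_counts({"s": reads}, mouse_model, "7bII")["s"]
        assert rng_counts[0.2] == pytest.approx(0.2 * 600, abs=3 * np.sqrt(600 * 0.2 * 0.8))
        assert rng_counts[0.6] == pytest.approx(0.6 * 600, abs=3 * np.sqrt(600 * 0.6 * 0.4))


class TestAnnotation:
    def test_model_labels_attached_by_coordinates(self, mouse_model):
        cfg = SimulationConfig(model=mouse_model, seed=9, depth=1e4)
        table, _ = simulate_junction_counts(cfg, 3)
        stripped = table.junctions.assign(exon_label="", isoform_label="")
        table.junctions = stripped
        annotated = annotate_junctions(table, mouse_model)
        labelled = annotated.junctions["exon_label"]
        assert (labelled != "").sum() > 10
        diag = annotated.junctions["isoform_label"]
        assert set(diag[diag != ""]) <= set(mouse_model.isoform_names)
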