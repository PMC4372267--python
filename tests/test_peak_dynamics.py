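"""Peak comparison, genic context and silent-gene activation."""

import numpy as np
import pandas as pd
import pytest

from azadem.core_io import ExpressionTable, GeneModel, GenomicInterval
from azadem.peak_dynamics import (
    classify_context,
    compare_peaks,
    intragenic_enrichment,
    methylation_shift_at,
    silent_activation,
)


def _peaks(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "summit"])


class TestComparePeaks:
    def test_identical_sets_fully_concordant(self):
        p = _peaks([("chr1", 100, 200, "a", 150)])
        comp = compare_peaks(p, p.copy())
        assert comp.counts == {"concordant": 1, "new": 0, "lost": 0,
                               "n_treated": 1, "n_control": 1}

    def test_treated_peak_without_control_is_new(self):
        control = _peaks([]).astype({"start": int, "end": int})
        treated = _peaks([("chr1", 100, 200, "a", 150)])
        comp = compare_peaks(control, treated)
        assert list(comp.treated["status"]) == ["new"]

    def test_min_overlap_boundary(self):
        control = _peaks([("chr1", 199, 300, "c", 250)])
        treated = _peaks([("chr1", 100, 200, "t", 150)])
        assert compare_peaks(control, treated, min_overlap=1).treated["status"][0] == "concordant"
        assert compare_peaks(control, treated, min_overlap=2).treated["status"][0] == "new"

    def test_disjoint_chromosome_sets_rejected(self):
        control = _peaks([("chr1", 0, 10, "c", 5)])
        treated = _peaks([("chrX", 0, 10, "t", 5)])
        with pytest.raises(ValueError, match="chrX"):
            compare_peaks(control, treated)

    def test_statuses_partition_both_sets(self, bundle):
        comp = compare_peaks(bundle.peak_sets["control"],
                             bundle.peak_sets["acute_1.0"])
        c = comp.counts
        assert c["concordant"] + c["new"] == c["n_treated"]
        assert c["lost"] <= c["n_control"]


def _gene(start=10_000, end=50_000, strand="+", gene_id="gA"):
    iv = GenomicInterval("chr1", start, end, strand)
    return GeneModel(gene_id, "coding", iv, (iv,))


class TestClassifyContext:
    def test_summit_near_tss_is_promoter(self):
        out = classify_context(_peaks([("chr1", 10_800, 11_200, "p", 11_000)]),
                               [_gene()])
        assert out.loc[0, "context"] == "promoter"
        assert out.loc[0, "gene_id"] == "gA"

    def test_summit_deep_in_body_is_intragenic(self):
        out = classify_context(_peaks([("chr1", 29_800, 30_200, "p", 30_000)]),
                               [_gene()])
        assert out.loc[0, "context"] == "intragenic"

    def test_far_from_any_gene_is_intergenic(self):
        out = classify_context(_peaks([("chr1", 499_800, 500_200, "p", 500_000)]),
                               [_gene()])
        assert out.loc[0, "context"] == "intergenic"
        assert out.loc[0, "gene_id"] == ""

    def test_promoter_has_priority_over_other_gene_body(self):
        # peak in gene A's body but within 2 kb of gene B's TSS
        gene_b = _gene(start=29_000, end=35_000, gene_id="gB")
        out = classify_context(_peaks([("chr1", 28_800, 29_200, "p", 29_000)]),
                               [_gene(), gene_b])
        assert out.loc[0, "context"] == "promoter"
        assert out.loc[0, "gene_id"] == "gB"

    def test_classes_exhaustive_and_exclusive(self, bundle):
        out = classify_context(bundle.peak_sets["acute_1.0"], bundle.gene_models)
        assert set(out["context"]) <= {"promoter", "intragenic", "intergenic"}
        assert out["context"].notna().all()


class TestMethylationShift:
    def _tracks(self, delta):
        base = pd.DataFrame({"chrom": ["chr1"] * 5, "pos": [100, 200, 300, 400, 500],
                             "score": [40.0] * 5})
        shifted = base.assign(score=base["score"] + delta)
        return base, shifted

    def test_planted_demethylation_detected(self, bundle, tracks):
        new = bundle.truth.new_peaks
        shift = methylation_shift_at(new, tracks["control"], tracks["acute_1.0"])
        assert shift.median_delta > 0
        assert shift.p_value < 0.01

    def test_single_peak_skips_test_but_reports_delta(self):
        ctrl, trt = self._tracks(10.0)
        peaks = _peaks([("chr1", 100, 500, "p", 300)])
        with pytest.warns(UserWarning, match="too few"):
            shift = methylation_shift_at(peaks, ctrl, trt)
        assert shift.p_value is None
        assert shift.median_delta == pytest.approx(10.0)

    def test_siteless_peaks_excluded_and_counted(self):
        ctrl, trt = self._tracks(5.0)
        peaks = _peaks([("chr1", 100, 500, "a", 300),
                        ("chr1", 90_000, 90_400, "b", 90_200)])
        with pytest.warns(UserWarning):
            shift = methylation_shift_at(peaks, ctrl, trt)
        assert shift.n_peaks_used == 1
        assert shift.n_peaks_empty == 1

    def test_no_usable_peak_rejected(self):
        ctrl, trt = self._tracks(5.0)
        peaks = _peaks([("chr1", 90_000, 90_400, "b", 90_200)])
        with pytest.raises(ValueError, match="no peak region"):
            methylation_shift_at(peaks, ctrl, trt)


def _expr(genes, before, after):
    rows = []
    for g, b, a in zip(genes, before, after):
        for cond, val in (("control", b), ("acute_1.0", a)):
            for rep in range(2):
                rows.append({"gene_id": g, "condition": cond,
                             "replicate": rep, "fpkm": val})
    return ExpressionTable(pd.DataFrame(rows))


class TestSilentActivation:
    def test_counting_example(self):
        genes = [f"g{i}" for i in range(10)]
        before = [0.1] * 6 + [5.0] * 4
        after = [3.0, 3.0] + [0.1] * 4 + [5.0] * 4
        rep = silent_activation(genes, _expr(genes, before, after),
                                "control", "acute_1.0")
        assert rep.fraction_silent_before == pytest.approx(0.6)
        assert rep.fraction_silent_after == pytest.approx(0.4)
        assert rep.activated_genes == ["g0", "g1"]

    def test_zero_threshold_means_nothing_is_silent(self):
        genes = ["g0", "g1"]
        rep = silent_activation(genes, _expr(genes, [0.1, 0.1], [0.1, 5.0]),
                                "control", "acute_1.0", silence_threshold=0.0)
        assert rep.fraction_silent_before == 0.0
        assert rep.fraction_silent_after == 0.0

    def test_empty_gene_list_rejected(self, bundle):
        with pytest.raises(ValueError, match="empty"):
            silent_activation([], bundle.expression, "control", "acute_1.0")

    def test_planted_activation_recovered_exactly(self, bundle):
        truth = bundle.truth.genes
        hosts = truth.loc[truth["peak_host"], "gene_id"].tolist()
        rep = silent_activation(hosts, bundle.expression, "control", "acute_1.0")
        planted = set(truth.loc[truth["activated"], "gene_id"])
        assert set(rep.activated_genes) == planted
        assert rep.fraction_silent_before == pytest.approx(1.0)
        assert rep.fraction_silent_after == pytest.approx(
            1.0 - len(planted) / len(hosts))


class TestIntragenicEnrichment:
    def test_planted_new_peaks_beat_uniform_null(self, bundle):
        comp = compare_peaks(bundle.peak_sets["control"],
                             bundle.peak_sets["acute_1.0"])
        ctx = classify_context(comp.treated[comp.treated["status"] == "new"],
                               bundle.gene_models)
        p0, p = intragenic_enrichment(ctx, bundle.gene_models, bundle.chrom_sizes)
        assert 0 < p0 < 0.5
        assert p < 0.01
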