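"""CG observed/expected ratios, bimodal cutoff and promoter subsets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from azadem.core_io import GeneModel, GenomicInterval
from azadem.promoter_cg import (
    UnimodalityError,
    attach_region_methylation,
    bimodal_cutoff,
    cg_obs_exp,
    classify_promoters,
    expression_of_subset,
    methylated_lcg_subset,
    peak_promoters,
    promoter_records,
)


class TestCgObsExp:
    def test_hand_counted_example(self):
        # one CG, 3 C, 3 G, L 6 -> 6/9
        assert cg_obs_exp("CCCGGG") == pytest.approx(2 / 3)

    def test_alternating_cg_is_two(self):
        assert cg_obs_exp("CGCGCGCG") == pytest.approx(2.0)

    def test_no_c_or_g_is_zero_by_convention(self):
        assert cg_obs_exp("ATATAT") == 0.0

    def test_empty_and_all_n_rejected(self):
        with pytest.raises(ValueError):
            cg_obs_exp("")
        with pytest.raises(ValueError):
            cg_obs_exp("NNNN")

    @given(st.text(alphabet="ACGT", min_size=4, max_size=120),
           st.integers(0, 30))
    @settings(max_examples=100, derandomize=True)
    def test_case_and_trailing_n_invariance(self, seq, n_run):
        base = cg_obs_exp(seq)
        assert cg_obs_exp(seq.lower()) == pytest.approx(base)
        assert cg_obs_exp(seq + "N" * n_run) == pytest.approx(base)


class TestBimodalCutoff:
    def test_symmetric_mixture_valley_near_midpoint(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0.2, 0.05, 5000), rng.normal(0.6, 0.05, 5000)])
        assert bimodal_cutoff(x) == pytest.approx(0.40, abs=0.02)

    def test_unimodal_density_raises_with_mode(self):
        rng = np.random.default_rng(1)
        with pytest.raises(UnimodalityError) as exc:
            bimodal_cutoff(rng.normal(0.4, 0.05, 5000))
        assert 0.3 < exc.value.mode < 0.5

    def test_unbalanced_mixture_valley_shifts_toward_minor_mode(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0.2, 0.05, 9000), rng.normal(0.6, 0.05, 1000)])
        cut = bimodal_cutoff(x)
        # numeric minimization of the known 0.9/0.1 mixture density gives
        # a valley above the midpoint but between the component means
        assert 0.40 < cut < 0.6

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 100"):
            bimodal_cutoff([0.2, 0.6] * 10)

    def test_generator_mixture_valley_recovered_at_scale(self, bundle):
        """10k draws from the generator's planted mixture localize the valley."""
        cfg = bundle.config
        rng = np.random.default_rng(123)
        w_hcg = (cfg.euchromatin_fraction * cfg.p_hcg_eu
                 + (1 - cfg.euchromatin_fraction) * cfg.p_hcg_het)
        comp = rng.random(10_000) < w_hcg
        mu = np.where(comp, cfg.cg_means[1], cfg.cg_means[0])
        sd = np.where(comp, cfg.cg_sds[1], cfg.cg_sds[0])
        x = np.clip(rng.normal(mu, sd), 0.02, None)
        assert bimodal_cutoff(x) == pytest.approx(0.40, abs=0.03)


class TestClassification:
    def test_cutoff_splits_and_tie_is_hcg(self):
        recs = pd.DataFrame({"cg_ratio": [0.2, 0.5, 0.366]})
        out = classify_promoters(recs, 0.366)
        assert list(out["cg_class"]) == ["LCG", "HCG", "HCG"]
        assert out.attrs["class_counts"] == {"HCG": 2, "LCG": 1}

    def test_partition_property(self):
        rng = np.random.default_rng(4)
        recs = pd.DataFrame({"cg_ratio": rng.uniform(0, 1, 500)})
        out = classify_promoters(recs, 0.366)
        counts = out.attrs["class_counts"]
        assert counts["HCG"] + counts["LCG"] == 500

    def test_fixture_classification_matches_planted_components(self, bundle):
        """Sequence-derived ratios recover >= 95% of planted mixture labels."""
        recs = promoter_records(bundle.gene_models, bundle.genome)
        out = classify_promoters(recs, bimodal_cutoff(recs["cg_ratio"]))
        truth = bundle.truth.genes.set_index("gene_id")["cg_component"]
        agree = (out.set_index("gene_id")["cg_class"] == truth).mean()
        assert agree >= 0.95


class TestMethylatedLcgSubset:
    def _records(self, hcg_scores, lcg_scores):
        return pd.DataFrame({
            "cg_class": ["HCG"] * len(hcg_scores) + ["LCG"] * len(lcg_scores),
            "meth_control": list(hcg_scores) + list(lcg_scores),
        })

    def _hcg_sample(self, mean=80.0, sd=5.0, n=30):
        # symmetric sample with exact mean and exact ddof=1 sd
        d = sd * np.sqrt((n - 1) / n)
        return [mean - d] * (n // 2) + [mean + d] * (n // 2)

    def test_normal_band_threshold_and_inclusion(self):
        recs = self._records(self._hcg_sample(), [50.0, 75.0])
        subset, threshold = methylated_lcg_subset(recs)
        assert threshold == pytest.approx(80 - 1.96 * 5, abs=1e-9)
        assert list(subset["meth_control"]) == [50.0]

    def test_all_lcg_above_threshold_gives_empty_subset(self):
        recs = self._records(self._hcg_sample(), [75.0, 78.0])
        subset, _ = methylated_lcg_subset(recs)
        assert len(subset) == 0

    def test_too_few_hcg_records_rejected(self):
        recs = self._records([80.0] * 5, [50.0])
        with pytest.raises(ValueError, match="HCG"):
            methylated_lcg_subset(recs)


class TestPeakPromoters:
    def _genome(self):
        rng = np.random.default_rng(6)
        return {"chr1": "".join(rng.choice(list("ACGT"), 50_000))}

    def _gene(self, start=10_000, end=15_000):
        iv = GenomicInterval("chr1", start, end, "+")
        return GeneModel("gX", "coding", iv, (iv,))

    def test_nearby_summit_links_to_gene(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [9900], "end": [10300],
                              "summit": [10010], "name": ["p1"]})
        (rec,) = peak_promoters(peaks, [self._gene()], self._genome()).to_dict("records")
        assert rec["gene_id"] == "gX"

    def test_distant_peak_stays_unlinked(self):
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [29_800], "end": [30_200],
                              "summit": [30_000], "name": ["p2"]})
        (rec,) = peak_promoters(peaks, [self._gene()], self._genome()).to_dict("records")
        assert rec["gene_id"] == ""

    def test_active_promoter_peaks_deplete_lcg_fraction(self, bundle):
        """Peak-defined promoters (active genes) carry fewer LCG members
        than the full annotation when silent LCG annotations are planted."""
        recs_all = promoter_records(bundle.gene_models, bundle.genome)
        cut = bimodal_cutoff(recs_all["cg_ratio"])
        all_cls = classify_promoters(recs_all, cut)
        peak_recs = peak_promoters(bundle.peak_sets["control"], bundle.gene_models,
                                   bundle.genome)
        peak_cls = classify_promoters(peak_recs, cut)
        assert peak_cls.attrs["lcg_fraction"] < all_cls.attrs["lcg_fraction"]


class TestExpressionOfSubset:
    def test_null_subset_gives_moderate_p(self):
        rng = np.random.default_rng(8)
        bg = rng.lognormal(1, 1, 2000)
        ps = [expression_of_subset(rng.choice(bg, 100, replace=False), bg).p_value
              for _ in range(20)]
        # under the null, p-values should not concentrate at tiny values
        assert np.mean(np.array(ps) < 0.05) <= 0.25

    def test_silent_subset_separates_strongly(self):
        rng = np.random.default_rng(9)
        bg = rng.lognormal(2, 0.5, 1000)
        rep = expression_of_subset(np.zeros(50), bg)
        assert rep.p_value < 1e-10

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            expression_of_subset([1.0], [])


class TestRegionMethylation:
    def test_mean_over_region_and_nan_when_empty(self):
        recs = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 1000],
                             "end": [100, 1100]})
        track = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 50],
                              "score": [40.0, 60.0]})
        out = attach_region_methylation(recs, track, "m")
        assert out.loc[0, "m"] == pytest.approx(50.0)
        assert np.isnan(out.loc[1, "m"])
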