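"""The somatic filter chain and read-backed phasing."""

import numpy as np
import pandas as pd
import pytest

from mitovar.variant_calling import (
    CallParams,
    RCRS_BLACKLIST,
    call_somatic,
    phase_pair,
    variants_to_frame,
)
from mitovar.synthetic_data import (
    ConfigurationError,
    default_signature_rates,
    simulate_cohort,
    simulate_phasing_reads,
    simulate_pileups,
)


def _site(sample, pos, ref, counts, split=None):
    """One pileup row; ``counts`` maps allele -> total reads (split 50/50
    unless ``split`` gives explicit (fwd, rev))."""
    row = {"sample": sample, "position": pos, "ref": ref}
    for b in "ACGT":
        n = counts.get(b, 0)
        fwd, rev = (split or {}).get(b, (n // 2, n - n // 2))
        row[f"{b}_fwd"], row[f"{b}_rev"] = fwd, rev
    return row


def _tables(tumor_sites, normal_sites):
    return pd.DataFrame(tumor_sites), pd.DataFrame(normal_sites)


class TestFilterChain:
    def test_three_percent_vaf_at_high_depth_called(self):
        # 240 variant reads of 8000 informative reads: VAF exactly 3%
        tumor, normal = _tables(
            [_site(0, 10, "A", {"A": 7760, "C": 240})],
            [_site(0, 10, "A", {"A": 8000})],
        )
        calls = call_somatic(tumor, normal, vaf_floor=0.0)
        assert len(calls) == 1
        assert calls[0].vaf == pytest.approx(0.03)
        assert not calls[0].rescue_tags

    def test_low_read_rescue_at_high_vaf(self):
        # 3 variant reads at VAF 25%: rescued
        tumor, normal = _tables(
            [_site(0, 10, "A", {"A": 9, "C": 3}, split={"C": (2, 1)})],
            [_site(0, 10, "A", {"A": 12})],
        )
        calls = call_somatic(tumor, normal, vaf_floor=0.0)
        assert len(calls) == 1
        assert "low_read_rescue" in calls[0].rescue_tags

    def test_four_reads_at_two_percent_filtered(self):
        # read count passes but VAF fails: both criteria must hold
        tumor, normal = _tables(
            [_site(0, 10, "A", {"A": 196, "C": 4})],
            [_site(0, 10, "A", {"A": 200})],
        )
        calls = call_somatic(tumor, normal, vaf_floor=0.0, keep_failed=True)
        assert len(calls) == 1
        assert calls[0].filters_failed == {"min_vaf"}

    def test_blacklisted_site_filtered(self):
        tumor, normal = _tables(
            [_site(0, 309, "C", {"C": 500, "T": 100})],
            [_site(0, 309, "C", {"C": 600})],
        )
        calls = call_somatic(tumor, normal, vaf_floor=0.0, keep_failed=True)
        assert calls and "blacklist" in calls[0].filters_failed
        assert (309, "T") in RCRS_BLACKLIST and len(RCRS_BLACKLIST) == 13

    def test_contamination_floor_filters_low_vaf(self):
        tumor, normal = _tables(
            [_site(0, 10, "A", {"A": 900, "C": 100})],  # VAF 0.10
            [_site(0, 10, "A", {"A": 1000})],
        )
        assert call_somatic(tumor, normal, vaf_floor=0.15) == []
        assert len(call_somatic(tumor, normal, vaf_floor=0.05)) == 1

    def test_strand_filter_and_bias_rescue(self):
        # all 20 variant reads on one strand; reference balanced -> filtered
        biased = _site(0, 10, "A", {"A": 400, "C": 20}, split={"C": (20, 0)})
        balanced_normal = _site(0, 10, "A", {"A": 400})
        tumor, normal = _tables([biased], [balanced_normal])
        calls = call_somatic(tumor, normal, vaf_floor=0.0, keep_failed=True)
        assert calls[0].filters_failed == {"strand_filter"}
        # reference reads equally one-sided -> bias difference < 0.1 -> rescued
        onesided = _site(0, 10, "A", {"A": 400, "C": 20},
                         split={"A": (400, 0), "C": (20, 0)})
        tumor, normal = _tables([onesided], [balanced_normal])
        calls = call_somatic(tumor, normal, vaf_floor=0.0)
        assert len(calls) == 1 and "strand_bias_rescue" in calls[0].rescue_tags

    def test_germline_allele_not_called(self):
        tumor, normal = _tables(
            [_site(0, 10, "A", {"A": 500, "C": 500})],
            [_site(0, 10, "A", {"A": 520, "C": 480})],
        )
        calls = call_somatic(tumor, normal, vaf_floor=0.0, keep_failed=True)
        assert calls and "present_in_normal" in calls[0].filters_failed

    def test_missing_normal_is_an_error(self):
        tumor = pd.DataFrame([_site(0, 10, "A", {"A": 100, "C": 10})])
        with pytest.raises(ValueError):
            call_somatic(tumor, None)

    def test_monotone_in_vaf_threshold(self):
        rng = np.random.default_rng(0)
        sites_t, sites_n = [], []
        for pos in range(1, 40):
            d = int(rng.integers(50, 400))
            v = int(rng.integers(0, d // 3))
            sites_t.append(_site(0, pos, "A", {"A": d - v, "G": v}))
            sites_n.append(_site(0, pos, "A", {"A": d}))
        tumor, normal = _tables(sites_t, sites_n)
        loose = {(c.position, c.alt) for c in call_somatic(
            tumor, normal, vaf_floor=0.0, params=CallParams(min_vaf=0.03))}
        strict = {(c.position, c.alt) for c in call_somatic(
            tumor, normal, vaf_floor=0.0, params=CallParams(min_vaf=0.10))}
        assert strict <= loose

    def test_exactness_on_error_free_simulation(self, small_genome, rates):
        """No sequencing error, depth 500, truth VAF >= 10%: every truth site
        is called and nothing else."""
        ref, ann = small_genome
        truth = simulate_cohort(
            ref, ann, rates, n_samples=20, mutation_rate=3.0,
            vaf_model=("uniform", 0.10, 1.0), seed=17,
        )
        tumor, normal = simulate_pileups(truth, ref, depth=500, error_rate=0.0, seed=18)
        calls = call_somatic(tumor, normal, vaf_floor=0.0)
        called = {(c.sample, c.position, c.alt) for c in calls}
        expected = {
            (r.sample, r.position, r.alt) for r in truth.variants.itertuples(index=False)
        }
        assert called == expected  # sensitivity 1.0, zero false calls

    def test_variants_to_frame_schema(self):
        tumor, normal = _tables(
            [_site(0, 10, "A", {"A": 7760, "C": 240})],
            [_site(0, 10, "A", {"A": 8000})],
        )
        df = variants_to_frame(call_somatic(tumor, normal, vaf_floor=0.0))
        assert list(df.columns[:5]) == ["sample", "position", "ref", "alt", "vaf"]
        assert df.iloc[0]["filters_failed"] == "PASS"


class TestPhasing:
    @pytest.mark.parametrize(
        "evidence,expected,sub",
        [
            ({"wt1_wt2": 30, "subs1_subs2": 20}, "co_clonal", None),
            ({"subs1_wt2": 15, "wt1_subs2": 12, "subs1_subs2": 0}, "different_strand", None),
            ({"subs1_subs2": 10, "subs1_wt2": 8}, "sub_clonal", 2),
            ({"subs1_subs2": 10, "wt1_subs2": 8}, "sub_clonal", 1),
            ({}, "unresolved", None),
            ({"subs1_subs2": 1}, "unresolved", None),  # below min_phasing_reads
        ],
    )
    def test_classification_rules(self, evidence, expected, sub):
        call = phase_pair(evidence)
        assert call.classification == expected
        assert call.subclonal_variant == sub

    @pytest.mark.parametrize("config", ["co_clonal", "sub_clonal", "different_strand"])
    def test_simulated_configurations_recovered(self, config):
        evidence = simulate_phasing_reads(config, n_reads=200, seed=5)
        assert phase_pair(evidence).classification == config

    def test_distant_pair_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_phasing_reads("co_clonal", 50, positions=(100, 5000), fragment_span=500)
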