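"""Opportunity enumeration, Poisson dN/dS fitting and selection tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from mitovar.genome_model import GeneAnnotation, MtReference
from mitovar.selection import (
    OpportunityTable,
    fit_dnds,
    gene_dnds,
    observed_counts,
    opportunity_counts,
    recurrence_analysis,
    recurrence_resample,
    trna_anticodon_test,
    vaf_selection_test,
)
from mitovar.signature import class_index
from mitovar.synthetic_data import default_signature_rates, simulate_cohort


def _synthetic_opportunities(l_syn=100, l_mis=200, l_non=20):
    idx = class_index(12)
    tbl = pd.DataFrame(
        {"L_syn": l_syn, "L_mis": l_mis, "L_non": l_non, "L_stoploss": 0}, index=idx
    )
    return OpportunityTable(table=tbl, model=12)


def _counts_from_rates(opp, r, w_mis=1.0, w_non=1.0):
    t = opp.table
    return pd.DataFrame(
        {
            "N_syn": np.round(r * t["L_syn"]),
            "N_mis": np.round(r * w_mis * t["L_mis"]),
            "N_non": np.round(r * w_non * t["L_non"]),
            "N_stoploss": 0,
        },
        index=t.index,
    )


class TestOpportunities:
    def test_single_atg_codon(self):
        # ATG: 1 synonymous (ATG>ATA), 1 nonsense (ATG>AGG), 7 missense
        ref = MtReference("ATGCCCGGG")
        ann = [GeneAnnotation(gene="G", start=1, end=3, feature="protein")]
        opp = opportunity_counts(ref, ann, model=12)
        totals = opp.table.sum()
        assert totals["L_syn"] == 1
        assert totals["L_non"] == 1
        assert totals["L_mis"] == 7

    def test_tandem_duplication_doubles(self):
        seq = "ATGTGGCGATAA"
        ref1 = MtReference(seq + "CCGG")
        ann1 = [GeneAnnotation(gene="G", start=1, end=12, feature="protein")]
        ref2 = MtReference(seq + seq + "CCGG")
        ann2 = [
            GeneAnnotation(gene="G", start=1, end=12, feature="protein"),
            GeneAnnotation(gene="G2", start=13, end=24, feature="protein"),
        ]
        t1 = opportunity_counts(ref1, ann1, model=12).table
        t2 = opportunity_counts(ref2, ann2, model=12).table
        assert (t2 == 2 * t1).all().all()

    def test_totals_conserved(self, small_genome):
        ref, ann = small_genome
        coding = sum(a.length(len(ref)) for a in ann if a.feature == "protein")
        opp = opportunity_counts(ref, ann, model=192)
        assert opp.table.sum().sum() == 3 * coding

    def test_frame_violation_rejected(self):
        ref = MtReference("ATGCC" + "A" * 10)
        ann = [GeneAnnotation(gene="bad", start=1, end=5, feature="protein")]
        with pytest.raises(ValueError):
            opportunity_counts(ref, ann)


class TestFitDnds:
    def test_neutral_construction_recovers_w_one(self):
        opp = _synthetic_opportunities()
        rng = np.random.default_rng(2)
        r = pd.Series(rng.uniform(0.02, 0.08, 12).round(2), index=opp.table.index)
        obs = _counts_from_rates(opp, r, w_mis=1.0)
        fit = fit_dnds(obs, opp, targets=("w_mis",))
        assert fit.w_mis == pytest.approx(1.0, abs=1e-4)
        assert fit.lrt_stat == pytest.approx(0.0, abs=1e-6)
        assert fit.ci_w_mis[0] < 1.0 < fit.ci_w_mis[1]

    def test_doubled_missense_matches_grid_search_oracle(self):
        """Hill-climbing agrees with a dense grid over the profile
        likelihood to 3 decimals."""
        opp = _synthetic_opportunities()
        rng = np.random.default_rng(3)
        r = pd.Series(rng.uniform(0.02, 0.08, 12).round(2), index=opp.table.index)
        obs = _counts_from_rates(opp, r, w_mis=2.0)
        fit = fit_dnds(obs, opp, targets=("w_mis",))

        L = opp.table[["L_syn", "L_mis"]].to_numpy(float)
        N = obs[["N_syn", "N_mis"]].to_numpy(float)

        def profile_ll(w):
            rr = N.sum(axis=1) / (L[:, 0] + w * L[:, 1])
            lam = np.column_stack([rr * L[:, 0], rr * w * L[:, 1]])
            ok = lam > 0
            return np.sum(N[ok] * np.log(lam[ok]) - lam[ok] - special.gammaln(N[ok] + 1))

        grid = np.arange(0.2, 5.0, 1e-4)
        w_grid = grid[np.argmax([profile_ll(w) for w in grid])]
        assert fit.w_mis == pytest.approx(w_grid, abs=1e-3)
        assert fit.w_mis == pytest.approx(2.0, rel=0.1)
        assert fit.lrt_p < 0.001

    def test_joint_missense_and_nonsense_fit(self):
        opp = _synthetic_opportunities(l_non=200)
        r = pd.Series(0.05, index=opp.table.index)
        obs = _counts_from_rates(opp, r, w_mis=1.0, w_non=0.2)
        fit = fit_dnds(obs, opp, targets=("w_mis", "w_non"))
        assert fit.w_mis == pytest.approx(1.0, abs=0.02)
        assert fit.w_non == pytest.approx(0.2, abs=0.05)
        assert fit.ci_w_non[1] < 1.0  # negative selection detected

    def test_likelihood_at_optimum_dominates_null(self):
        opp = _synthetic_opportunities()
        rng = np.random.default_rng(4)
        r = pd.Series(0.05, index=opp.table.index)
        t = opp.table
        obs = pd.DataFrame(
            {
                "N_syn": rng.poisson(r * t["L_syn"]),
                "N_mis": rng.poisson(r * 0.7 * t["L_mis"]),
                "N_non": 0,
                "N_stoploss": 0,
            },
            index=t.index,
        )
        fit = fit_dnds(obs, opp, targets=("w_mis",), compute_ci=False)
        assert fit.lrt_stat >= 0.0

    def test_no_synonymous_observations_unidentifiable(self):
        opp = _synthetic_opportunities()
        obs = _counts_from_rates(opp, pd.Series(0.0, index=opp.table.index))
        obs["N_mis"] = 5
        with pytest.raises(ValueError):
            fit_dnds(obs, opp)

    def test_12_and_192_rate_models_agree_without_context_dependence(
        self, small_genome
    ):
        ref, ann = small_genome
        # context-free generator: constant rate within each 12-class
        flat = pd.Series(
            [1.0 if sub in ("C>T", "T>C") else 0.2 for (sub, _st, _ctx) in class_index(192)],
            index=class_index(192),
        )
        truth = simulate_cohort(ref, ann, flat, n_samples=400, mutation_rate=3.0, seed=13)
        fits = {}
        for model in (12, 192):
            opp = opportunity_counts(ref, ann, model=model)
            obs = observed_counts(truth.variants, ref, ann, model=model)
            fits[model] = fit_dnds(obs, opp, targets=("w_mis",))
        # generator is selection-free: both models should cover w = 1 and agree
        assert fits[12].ci_w_mis[0] < 1.0 < fits[12].ci_w_mis[1]
        assert fits[12].ci_w_mis[0] < fits[192].w_mis < fits[12].ci_w_mis[1]

    def test_gene_level_neutral_simulation_no_significant_gene(
        self, small_genome, rates
    ):
        ref, ann = small_genome
        truth = simulate_cohort(ref, ann, rates, n_samples=300, mutation_rate=3.0, seed=14)
        table = gene_dnds(truth.variants, ref, ann, model=12)
        assert not table["significant"].fillna(False).any()


class TestAnticodon:
    @staticmethod
    def _trna_setup():
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        ref = MtReference(seq)
        # one tRNA of 30 bp, anticodon covering exactly 10% of its bases
        ann = [GeneAnnotation(gene="T1", start=11, end=40, feature="tRNA",
                              anticodon_span=(21, 23))]
        uniform = pd.Series(1.0, index=class_index(192))
        return ref, ann, uniform

    def test_zero_trna_mutations(self):
        ref, ann, uniform = self._trna_setup()
        empty = pd.DataFrame(columns=["position", "ref", "alt"])
        obs, exp, p = trna_anticodon_test(empty, ref, ann, uniform)
        assert (obs, exp, p) == (0, 0.0, 1.0)

    def test_uniform_signature_proportional_expectation(self):
        ref, ann, uniform = self._trna_setup()
        rng = np.random.default_rng(9)
        pos = rng.integers(11, 41, size=100)
        variants = pd.DataFrame({
            "position": pos,
            "ref": [ref.base(p) for p in pos],
            "alt": ["A"] * 100,
        })
        obs, exp, p = trna_anticodon_test(variants, ref, ann, uniform)
        assert exp == pytest.approx(10.0)

    def test_depletion_p_is_lower_poisson_tail(self):
        ref, ann, uniform = self._trna_setup()
        # 76 tRNA mutations, none in the anticodon -> expected 7.6, p = e^-7.6
        pos = [p for p in range(11, 41) if not (21 <= p <= 23)]
        pos = (pos * 3)[:76]
        variants = pd.DataFrame({
            "position": pos, "ref": [ref.base(p) for p in pos], "alt": ["A"] * 76,
        })
        obs, exp, p = trna_anticodon_test(variants, ref, ann, uniform)
        assert obs == 0
        assert exp == pytest.approx(7.6)
        assert p == pytest.approx(float(stats.poisson.cdf(0, 7.6)))
        assert p < 0.001


class TestRecurrence:
    def test_all_distinct_positions(self):
        ref = MtReference("ACGT" * 300)
        v = pd.DataFrame({"sample": range(10), "position": range(1, 11)})
        out = recurrence_analysis(v, ref, n_sims=100, seed=1)
        assert out["n_recurrent"] == 0 and out["fold_enrichment"] == 0.0

    def test_uniform_null_matches_occupancy_closed_form(self):
        """Mean recurrent count under uniform placement equals the
        birthday-problem expectation n * (1 - (1 - 1/L)^(n-1))."""
        rng = np.random.default_rng(10)
        L, n = 16569, 1907
        ref = MtReference("".join(rng.choice(list("ACGT"), size=L)))
        v = pd.DataFrame({
            "sample": range(n),
            "position": rng.integers(1, L + 1, size=n),
        })
        out = recurrence_analysis(v, ref, null_model="uniform", n_sims=400, seed=11)
        closed_form = n * (1 - (1 - 1 / L) ** (n - 1))
        assert out["null_mean"] == pytest.approx(closed_form, rel=0.05)
        # the uniformly placed "observed" variants show no enrichment
        assert 0.5 < out["fold_enrichment"] < 2.0
        assert out["p"] > 0.01

    def test_hotspot_cohort_enriched(self, small_genome, cohort):
        ref, _ = small_genome
        out = recurrence_analysis(cohort.variants, ref, n_sims=200, seed=12)
        assert out["fold_enrichment"] > 1.5
        assert out["p"] < 0.05

    def test_signature_null_reduces_apparent_enrichment(self, small_genome, cohort, rates):
        ref, _ = small_genome
        uni = recurrence_analysis(cohort.variants, ref, "uniform", n_sims=200, seed=13)
        sig = recurrence_analysis(cohort.variants, ref, "signature", n_sims=200,
                                  seed=13, rates=rates)
        assert sig["null_mean"] > uni["null_mean"]
        assert sig["fold_enrichment"] < uni["fold_enrichment"]

    def test_resampling_identical_groups_not_significant(self, cohort):
        groups = {"a": cohort.variants, "b": cohort.variants.copy()}
        out = recurrence_resample(cohort.variants, groups, n_draw=80, n_iter=60, seed=14)
        assert out["anova_p"] > 0.05

    def test_group_smaller_than_draw_rejected(self, cohort):
        with pytest.raises(ValueError):
            recurrence_resample(
                cohort.variants, {"tiny": cohort.variants.iloc[:5]}, n_draw=100
            )


class TestVafSelection:
    def test_identical_groups(self):
        v = [0.1, 0.4, 0.9, 0.3]
        out = vaf_selection_test({"a": v, "b": list(v)})
        assert out["pairwise_p"][("a", "b")] == 1.0
        assert out["means"]["a"] == out["means"]["b"]

    def test_truncating_cap_detected(self):
        rng = np.random.default_rng(15)
        missense = rng.uniform(0.05, 1.0, 200)
        truncating = rng.uniform(0.05, 0.30, 200)
        out = vaf_selection_test({"missense": missense, "truncating": truncating})
        assert out["means"]["truncating"] < out["means"]["missense"]
        assert out["pairwise_p"][("missense", "truncating")] < 0.01

    def test_small_group_excluded(self):
        with pytest.warns(UserWarning):
            out = vaf_selection_test({"a": [0.5, 0.6], "b": [0.4, 0.5], "c": [0.9]})
        assert "c" not in out["means"]
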