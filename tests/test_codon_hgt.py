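"""Codon counting, the usage G test, and the modal-usage fit."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2

from lipoarch import codon_hgt, synthetic
from lipoarch.codon_hgt import (
    CodonCounts,
    call_hgt,
    count_codons,
    fit_modal_usage,
    gene_usage_pvalue,
)
from lipoarch.errors import DataError, ParameterError
from lipoarch.genetic_code import INFORMATIVE_FAMILIES, STOP_CODONS


class TestCountCodons:
    def test_hand_counted_lys_family(self):
        cc = count_codons("ATGAAAAAGTGA")
        assert cc.counts["AAA"] == 1
        assert cc.counts["AAG"] == 1
        assert cc.counts["ATG"] == 1  # Met counted...
        assert cc.n_codons_informative == 2  # ...but not informative

    def test_empty_sequence(self):
        cc = count_codons("")
        assert cc.counts == {}
        assert cc.n_codons_informative == 0

    def test_internal_stop_rejected(self):
        with pytest.raises(DataError, match="internal stop"):
            count_codons("ATGTAAAAATGA")

    def test_frame_violation_rejected(self):
        with pytest.raises(DataError, match="divisible by 3"):
            count_codons("ATGAA")

    def test_ambiguous_codon_skipped(self):
        cc = count_codons("ATGANAAAGTGA")
        assert "ANA" not in cc.counts
        assert cc.counts["AAG"] == 1

    def test_total_matches_independent_3mer_splitter(self):
        rng = np.random.default_rng(0)
        config = synthetic.SimulationConfig(seed=5, n_genes=1)
        (gene_id, seq), _ = (lambda r: (r[0][0], r[1]))(synthetic.gen_genome(config))
        cc = count_codons(seq, gene_id=gene_id)
        # independent splitter: textwrap-style 3-mers, drop stops
        independent = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        non_stop = [c for c in independent if c not in STOP_CODONS]
        assert sum(cc.counts.values()) == len(non_stop)


def _uniform_profile():
    freqs = {}
    for codons in INFORMATIVE_FAMILIES.values():
        for c in codons:
            freqs[c] = 1.0 / len(codons)
    return freqs


class TestGeneUsagePvalue:
    def test_counts_proportional_to_profile_give_p_one(self):
        # equal counts within every family against the uniform profile: G = 0
        counts = {}
        for codons in INFORMATIVE_FAMILIES.values():
            for c in codons:
                counts[c] = 6
        cc = CodonCounts("g", counts, sum(counts.values()))
        assert gene_usage_pvalue(cc, _uniform_profile(), method="chi2") == 1.0
        assert gene_usage_pvalue(cc, _uniform_profile(), method="mc") == 1.0

    def test_two_codon_family_vs_exact_enumeration(self):
        """Single Lys-family gene {AAA:8, AAG:2} against q = (0.5, 0.5).

        The exact null p-value enumerates all Binomial(10, 0.5) outcomes
        whose G is at least G(8, 2).  The chi-square reference is an
        approximation at N = 10; its error here (~0.06) is the documented
        cost of the asymptotic method, while the bootstrap reference
        should track the enumeration closely.
        """
        counts = CodonCounts("g", {"AAA": 8, "AAG": 2}, 10)
        profile = {c: (0.5 if c in ("AAA", "AAG") else f)
                   for c, f in _uniform_profile().items()}

        def g_of(k):
            out = 0.0
            for n, q in ((k, 0.5), (10 - k, 0.5)):
                if n > 0:
                    out += 2 * n * math.log(n / (10 * q))
            return out

        g_obs = g_of(8)
        p_exact = sum(
            math.comb(10, k) * 0.5**10
            for k in range(11)
            if g_of(k) >= g_obs - 1e-12
        )
        assert p_exact == pytest.approx(112 / 1024)
        p_chi2 = gene_usage_pvalue(counts, profile, method="chi2")
        assert abs(p_chi2 - p_exact) < 0.07  # documented approximation error
        p_mc = gene_usage_pvalue(counts, profile, method="mc", n_sim=19999)
        assert abs(p_mc - p_exact) < 0.01

    def test_profile_gap_is_data_error(self):
        counts = CodonCounts("g", {"AAA": 3}, 3)
        with pytest.raises(DataError):
            gene_usage_pvalue(counts, {"AAG": 1.0}, method="chi2")

    def test_gene_without_informative_codons_gets_p_one(self):
        counts = CodonCounts("g", {"ATG": 5}, 0)
        assert gene_usage_pvalue(counts, _uniform_profile()) == 1.0

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_pvalue_bounds_and_flag_nesting(self, a, b, c):
        counts = CodonCounts("g", {"AAA": a, "AAG": b, "GGG": c}, a + b + c)
        profile = _uniform_profile()
        for method in ("chi2", "mc"):
            p = gene_usage_pvalue(counts, profile, method=method)
            assert 0.0 <= p <= 1.0
        (call,) = call_hgt([counts], profile)
        if call.flagged_p05:
            assert call.flagged_p10


class TestFitModalUsage:
    def test_duplicated_gene_corpus_recovers_relative_counts(self):
        counts = {"AAA": 30, "AAG": 10, "GGG": 5, "GGA": 5, "GGC": 5, "GGT": 5}
        gene = CodonCounts("g", counts, sum(counts.values()))
        profile = fit_modal_usage([gene] * 10, pseudocount=0.5)
        # pooled Lys family: (10·30 + .5) / (10·40 + 1)
        assert profile.freqs["AAA"] == pytest.approx(300.5 / 401)
        assert profile.freqs["AAG"] == pytest.approx(100.5 / 401)
        # approaches the single gene's relative counts as copies accumulate
        assert profile.freqs["AAA"] == pytest.approx(0.75, abs=0.01)
        assert profile.converged

    def test_fit_is_order_invariant(self):
        config = synthetic.SimulationConfig(seed=9, n_genes=40)
        records, _ = synthetic.gen_genome(config)
        genes = [count_codons(s, g) for g, s in records]
        p1 = fit_modal_usage(genes, method="chi2")
        p2 = fit_modal_usage(list(reversed(genes)), method="chi2")
        assert p1.freqs == p2.freqs

    def test_too_few_genes_rejected(self):
        gene = CodonCounts("g", {"AAA": 2}, 2)
        with pytest.raises(ParameterError):
            fit_modal_usage([gene])

    def test_threshold_semantics(self):
        # p just under 0.10 flags at the primary threshold only
        config = synthetic.SimulationConfig(seed=3, n_genes=120, hgt_fraction=0.0)
        records, truth = synthetic.gen_genome(config)
        genes = [count_codons(s, g) for g, s in records]
        calls = call_hgt(genes, truth.resident_profile)
        for call in calls:
            assert call.flagged_p10 == (call.p_value < 0.10)
            assert call.flagged_p05 == (call.p_value < 0.05)

    def test_refit_at_fixed_point_changes_nothing(self):
        """At convergence the profile is estimated from exactly the genes
        it accepts, so one more refit pass reproduces the same profile and
        the same rejection count."""
        config = synthetic.SimulationConfig(seed=13, n_genes=150, hgt_fraction=0.0)
        records, _ = synthetic.gen_genome(config)
        genes = [count_codons(s, g) for g, s in records]
        fitted = fit_modal_usage(genes, method="chi2")
        assert fitted.converged
        pvals = [gene_usage_pvalue(g, fitted, method="chi2") for g in genes]
        typical = [g for g, p in zip(genes, pvals) if p >= 0.10]
        assert len(typical) == fitted.n_typical_genes
        refit = codon_hgt._estimate_profile(typical, 0.5)
        n_before = sum(p < 0.10 for p in pvals)
        n_after = sum(
            gene_usage_pvalue(g, refit, method="chi2") < 0.10 for g in genes
        )
        assert n_after <= n_before
        assert refit == pytest.approx(fitted.freqs)

    def test_power_increases_with_divergence(self):
        rates = []
        for div in (0.2, 1.0, 4.0):
            config = synthetic.SimulationConfig(
                seed=21, n_genes=160, hgt_fraction=0.5, alien_divergence=div,
                gene_length_codons=(150, 300),
            )
            records, truth = synthetic.gen_genome(config)
            genes = [count_codons(s, g) for g, s in records]
            calls = call_hgt(genes, truth.resident_profile, method="chi2")
            flagged = {c.gene_id: c.flagged_p10 for c in calls}
            alien = [g for g, v in truth.hgt_labels.items() if v]
            rates.append(np.mean([flagged[g] for g in alien]))
        assert rates[0] <= rates[1] + 0.05 <= rates[2] + 0.10
        assert rates[2] > rates[0]
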