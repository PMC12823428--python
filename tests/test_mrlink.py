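"""Instrument construction and the two-sample MR estimator battery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from triagen import mrlink, synthio
from .conftest import summary_frame


def make_instruments(rng, k, causal, pleio_sd=0.0, se_out=0.04):
    bx = rng.uniform(0.15, 0.5, k) * rng.choice([-1, 1], k)
    sx = np.full(k, 0.02)
    by = causal * bx + rng.normal(0, se_out, k) + rng.normal(0, pleio_sd, k)
    sy = np.full(k, se_out)
    return [
        mrlink.Instrument(f"v{i}", bx[i], sx[i], by[i], sy[i]) for i in range(k)
    ]


class TestInstrumentFilters:
    def test_f_statistic_formula(self):
        iv = mrlink.Instrument("v", 0.05, 0.02, 0.1, 0.05)
        assert iv.f_stat == pytest.approx((0.05 / 0.02) ** 2, abs=1e-10)

    def _clumped(self, pos, chrom="1"):
        return pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(len(pos))],
                "chrom": chrom,
                "pos": pos,
                "beta": 0.4,
                "se": 0.02,
                "p": 1e-30,
            }
        )

    def test_cis_window_inclusive_and_exclusions(self):
        clumped = self._clumped([100_000, 1_200_000 + 100_000 + 1_000])
        outcome = summary_frame(["v0", "v1"], [0.1, 0.1], [0.05, 0.05])
        gene = ("1", 100_000, 101_000)
        ivs, log = mrlink.build_instruments(clumped, gene, outcome)
        log = log.set_index("id")
        assert not log.loc["v0", "excluded"]
        assert log.loc["v1", "reason"] == "not_cis"  # 1.2 Mb away

    def test_weak_instrument_excluded(self):
        clumped = self._clumped([100_000])
        clumped.loc[0, ["beta", "se"]] = [0.05, 0.02]  # F = 6.25
        outcome = summary_frame(["v0"], [0.1], [0.05])
        ivs, log = mrlink.build_instruments(clumped, ("1", 100_000, 101_000), outcome)
        assert not ivs
        assert log.iloc[0]["reason"] == "weak_instrument"

    def test_pleiotropy_filter_strictly_fewer_than_five(self):
        clumped = self._clumped([100_000, 110_000])
        outcome = summary_frame(["v0", "v1"], [0.1, 0.1], [0.05, 0.05])
        ivs, log = mrlink.build_instruments(
            clumped,
            ("1", 100_000, 101_000),
            outcome,
            proteins_per_variant={"v0": 5, "v1": 4},
        )
        log = log.set_index("id")
        assert log.loc["v0", "reason"] == "pleiotropic"
        assert not log.loc["v1", "excluded"]


class TestClump:
    def test_high_ld_pair_keeps_one(self):
        arch = synthio.GenArchitecture(n_variants=60, n_blocks=2, block_r=0.9)
        b = synthio.simulate_cohort(arch, None, 3000, 0.1, seed=5)
        af = pd.DataFrame(
            {
                "id": ["var00000", "var00001", "var00030"],
                "chrom": ["1", "1", "2"],
                "pos": [10_000, 20_000, 10_000],
                "beta": [0.5, 0.45, 0.3],
                "se": [0.05] * 3,
                "p": [1e-20, 1e-18, 1e-9],
            }
        )
        kept = mrlink.clump(af, b.genotypes)
        assert set(kept["id"]) == {"var00000", "var00030"}

    def test_independent_blocks_both_kept(self):
        arch = synthio.GenArchitecture(n_variants=60, n_blocks=2, block_r=0.0)
        b = synthio.simulate_cohort(arch, None, 3000, 0.1, seed=6)
        af = pd.DataFrame(
            {
                "id": ["var00000", "var00005"],
                "chrom": ["1", "1"],
                "pos": [10_000, 60_000],
                "beta": [0.5, 0.45],
                "se": [0.05] * 2,
                "p": [1e-20, 1e-18],
            }
        )
        kept = mrlink.clump(af, b.genotypes)
        assert len(kept) == 2

    def test_strict_mode_never_increases_instruments(self):
        arch = synthio.GenArchitecture(n_variants=30, n_blocks=1, block_r=0.5)
        b = synthio.simulate_cohort(arch, None, 2000, 0.1, seed=7)
        ids = [f"var{i:05d}" for i in range(10)]
        af = pd.DataFrame(
            {
                "id": ids,
                "chrom": "1",
                "pos": 10_000 * (1 + np.arange(10)),
                "beta": 0.4,
                "se": 0.02,
                "p": 10.0 ** -np.linspace(20, 10, 10),
            }
        )
        loose = mrlink.clump(af, b.genotypes, r2_max=0.2)
        strict = mrlink.clump(af, b.genotypes, r2_max=0.001)
        assert len(strict) <= len(loose)

    def test_variant_missing_from_ld_reference_dropped(self):
        arch = synthio.GenArchitecture(n_variants=10, n_blocks=1, block_r=0.0)
        b = synthio.simulate_cohort(arch, None, 500, 0.1, seed=8)
        af = pd.DataFrame(
            {
                "id": ["var00000", "ghost"],
                "chrom": ["1", "1"],
                "pos": [10_000, 20_000],
                "beta": [0.4, 0.4],
                "se": [0.02, 0.02],
                "p": [1e-20, 1e-20],
            }
        )
        kept = mrlink.clump(af, b.genotypes)
        assert kept["id"].tolist() == ["var00000"]
        assert kept.attrs["dropped_no_ld"] == ["ghost"]


class TestBattery:
    def test_single_instrument_wald_ratio(self):
        iv = mrlink.Instrument("v", 0.4, 0.02, 0.2, 0.05)
        res = mrlink.mr_battery([iv])
        assert set(res.estimates) == {"wald"}
        b, s, _ = res.estimates["wald"]
        assert b == pytest.approx(0.5, abs=1e-12)
        assert s == pytest.approx(0.05 / 0.4, abs=1e-12)
        assert res.q_df is None

    def test_identical_ratio_consistency(self):
        bx = np.array([0.2, 0.3, 0.45, 0.6])
        ivs = [
            mrlink.Instrument(f"v{i}", bx[i], 0.03, 0.5 * bx[i], 0.05)
            for i in range(4)
        ]
        res = mrlink.mr_battery(ivs)
        for method in ("ivw", "wm", "ml", "egger"):
            assert res.estimates[method][0] == pytest.approx(0.5, abs=1e-6)
        assert res.q_stat == pytest.approx(0.0, abs=1e-20)
        assert res.egger_intercept[0] == pytest.approx(0.0, abs=1e-12)

    def test_q_df_is_k_minus_one(self, rng):
        res = mrlink.mr_battery(make_instruments(rng, 7, 0.3))
        assert res.q_df == 6

    def test_ivw_equals_wald_with_one_instrument(self, rng):
        ivs = make_instruments(rng, 5, 0.3)
        one = mrlink.mr_battery(ivs[:1])
        w = 1.0 / ivs[0].ratio_se**2
        assert one.estimates["wald"][0] == pytest.approx(
            (w * ivs[0].ratio) / w, abs=1e-12
        )

    def test_allele_recoding_invariance(self, rng):
        ivs = make_instruments(rng, 6, 0.3)
        flipped = [
            mrlink.Instrument(
                iv.variant_id, -iv.beta_exp, iv.se_exp, -iv.beta_out, iv.se_out
            )
            for iv in ivs
        ]
        a = mrlink.mr_battery(ivs, seed=1)
        b = mrlink.mr_battery(flipped, seed=1)
        assert a.estimates["ivw"][0] == pytest.approx(b.estimates["ivw"][0], 1e-12)
        assert a.q_stat == pytest.approx(b.q_stat, abs=1e-10)

    def test_q_invariant_to_instrument_order(self, rng):
        ivs = make_instruments(rng, 8, 0.2, pleio_sd=0.05)
        a = mrlink.mr_battery(ivs, seed=0)
        b = mrlink.mr_battery(ivs[::-1], seed=0)
        assert a.q_stat == pytest.approx(b.q_stat, abs=1e-10)
        assert a.estimates["ivw"][0] == pytest.approx(b.estimates["ivw"][0], 1e-12)

    def test_zero_exposure_effect_dropped(self, rng):
        ivs = make_instruments(rng, 4, 0.3)
        ivs.append(mrlink.Instrument("z", 0.0, 0.02, 0.1, 0.04))
        res = mrlink.mr_battery(ivs)
        assert res.n_instruments == 4
        assert "z" not in res.instruments

    def test_causal_recovery_and_clean_egger_intercept(self, rng):
        hits, clean_intercepts = 0, 0
        for rep in range(60):
            ivs = make_instruments(rng, 8, 0.3)
            res = mrlink.mr_battery(ivs, seed=rep)
            b, s, _ = res.estimates["ivw"]
            hits += abs(b - 0.3) < 2 * s
            clean_intercepts += res.egger_intercept[2] > 0.05
        assert hits >= 51  # ~95% nominal
        assert clean_intercepts >= 54  # >=90% without generated pleiotropy

    def test_null_p_uniform(self, rng):
        """Fixed-effect IVW p-values are uniform under the null; the default
        multiplicative over-dispersion makes them (intentionally)
        conservative, so it is disabled for the calibration check."""
        rng = np.random.default_rng(2024)
        ps, ps_od = [], []
        for rep in range(500):
            ivs = make_instruments(rng, 10, 0.0)
            ps.append(
                mrlink.mr_battery(ivs, seed=rep, overdispersion=False)
                .estimates["ivw"][2]
            )
            ps_od.append(mrlink.mr_battery(ivs, seed=rep).estimates["ivw"][2])
        assert kstest(ps, "uniform").pvalue > 0.01
        # over-dispersed p never smaller than the fixed-effect p
        assert np.all(np.asarray(ps_od) >= np.asarray(ps) - 1e-15)


class TestCohortPipeline:
    def test_two_sample_mr_recovers_causal_proteins(self):
        """End to end: pQTL scans in a proteomic cohort, disease GWAS in a
        separate cohort, clumping + filters + battery + panel FDR.  The two
        generated causal proteins come out significant with the right sign
        and within 2 se; null proteins stay non-significant."""
        from triagen import assoc, pwas

        arch = synthio.GenArchitecture(n_variants=100, n_blocks=5, block_r=0.5)
        parch = synthio.default_protein_architecture(
            arch, n_proteins=10, n_causal=2, causal_logor=0.5,
            cis_beta=0.45, seed=3,
        )
        prot_cohort = synthio.simulate_cohort(arch, parch, 4000, 0.10, seed=101)
        gwas_cohort = synthio.simulate_cohort(arch, parch, 20_000, 0.10, seed=202)
        outcome = assoc.scan(
            gwas_cohort.genotypes,
            gwas_cohort.phenotypes["delirium"],
            gwas_cohort.phenotypes[["age", "sex"]],
            variants=gwas_cohort.variants,
        )
        mat = pwas.preprocess(pwas.ProteinMatrix(prot_cohort.proteins))
        results = mrlink.mr_from_cohort(
            prot_cohort.genotypes, prot_cohort.variants, mat.values,
            prot_cohort.genes, outcome, seed=0,
        )
        panel = mrlink.mr_panel(results).set_index("protein")
        causal = ["prot0000", "prot0001"]
        for prot in causal:
            assert panel.loc[prot, "significant"]
            assert (
                abs(panel.loc[prot, "beta"] - 0.5) < 2 * panel.loc[prot, "se"]
            )
        nulls = [p for p in panel.index if p not in causal]
        assert not panel.loc[nulls, "significant"].any()


class TestPanel:
    def _result(self, beta, se, p):
        return mrlink.MrResult(1, {"wald": (beta, se, p)})

    def test_bh_hand_computation_and_significance(self):
        panel = mrlink.mr_panel(
            {
                "A": self._result(0.5, 0.1, 0.001),
                "B": self._result(0.4, 0.1, 0.01),
                "C": self._result(0.3, 0.1, 0.02),
                "D": self._result(0.0, 0.1, 0.8),
            }
        ).set_index("protein")
        # hand BH: q_i = min_{j >= i} p_(j) * m / j
        np.testing.assert_allclose(
            panel["q"], [0.004, 0.02, 0.02 * 4 / 3, 0.8], atol=1e-12
        )
        assert panel["significant"].tolist() == [True, True, True, False]

    def test_untestable_protein_outside_fdr_denominator(self):
        panel = mrlink.mr_panel({"A": self._result(0.5, 0.1, 0.01)})
        assert len(panel) == 1
        assert panel.iloc[0]["q"] == pytest.approx(0.01)

    def test_replication_requires_p_and_direction(self):
        disc = {"A": self._result(0.5, 0.1, 1e-5), "B": self._result(0.5, 0.1, 1e-5)}
        rep = {
            "A": self._result(0.4, 0.1, 0.01),  # same sign, p < 0.05
            "B": self._result(-0.4, 0.1, 0.01),  # opposite sign
        }
        panel = mrlink.mr_panel(disc, replication=rep).set_index("protein")
        assert panel.loc["A", "replicated"]
        assert not panel.loc["B", "replicated"]

    def test_sensitivity_retest_uses_fdr_within_subset(self):
        disc = {
            "A": self._result(0.5, 0.1, 1e-6),
            "B": self._result(0.5, 0.1, 1e-6),
            "C": self._result(0.5, 0.1, 0.9),  # not significant, not re-tested
        }
        sens = {
            "A": self._result(0.4, 0.1, 0.01),
            "B": self._result(-0.4, 0.1, 0.01),  # opposite direction
            "C": self._result(0.4, 0.1, 0.001),
        }
        panel = mrlink.mr_panel(disc, sensitivity=sens).set_index("protein")
        assert panel.loc["A", "sensitivity_pass"]
        assert not panel.loc["B", "sensitivity_pass"]  # direction clash
        assert np.isnan(panel.loc["C", "sensitivity_q"])  # never re-tested
        # BH within the two re-tested proteins: q = 0.01 * 2 / rank
        assert panel.loc["A", "sensitivity_q"] == pytest.approx(0.01)

    def test_synthetic_replication_power(self, rng):
        flags = 0
        for rep in range(50):
            disc = mrlink.mr_battery(make_instruments(rng, 8, 0.4), seed=rep)
            repl = mrlink.mr_battery(make_instruments(rng, 8, 0.4), seed=500 + rep)
            panel = mrlink.mr_panel(
                {"prot": disc}, replication={"prot": repl}
            )
            flags += bool(panel.iloc[0]["replicated"])
        assert flags >= 40
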