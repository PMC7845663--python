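"""Association scans, summary-statistics I/O, harmonization and pruning."""

import logging

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from survivormr.simulate import Cohort, SimulationConfig, simulate_cohort
from survivormr.sumstats import (
    SummaryStatsTable,
    VariantAssociation,
    association_scan,
    harmonize,
    harmonize_tables,
    prune_instruments,
)


def tiny_cohort(doses, trait, binary=False):
    """One-variant cohort with explicit doses and trait values."""
    n = len(doses)
    doses = np.asarray(doses)
    zeros = np.zeros(n)
    trait = np.asarray(trait, dtype=float)
    return Cohort(
        genotypes=doses[:, None].astype(np.int8),
        variant_ids=["v1"], effect_alleles=["A"], other_alleles=["G"],
        instrument_of=["x"],
        u1=zeros, u2=zeros,
        x=trait if not binary else zeros,
        y2=np.zeros(n, dtype=np.int8),
        s=np.ones(n, dtype=np.int8),
        y=trait.astype(np.int8) if binary else np.zeros(n, dtype=np.int8),
    )


class TestVariantAssociation:
    def test_invariants_enforced(self):
        ok = dict(variant_id="v", effect_allele="A", other_allele="G",
                  eaf=0.3, beta=0.1, se=0.05, pval=0.5, n=100)
        VariantAssociation(**ok)
        for bad in (dict(se=0.0), dict(eaf=1.0), dict(pval=1.5),
                    dict(other_allele="A")):
            with pytest.raises(ValueError):
                VariantAssociation(**{**ok, **bad})


class TestLinearScan:
    def test_slope_matches_normal_equations_oracle(self):
        doses = [0, 0, 1, 1, 2, 2]
        trait = [1.0, 1.2, 2.1, 1.9, 3.0, 3.2]
        table = association_scan(tiny_cohort(doses, trait), "x", "linear")
        # independent closed-form least squares via the normal equations
        X = np.column_stack([np.ones(6), doses])
        coef = np.linalg.solve(X.T @ X, X.T @ np.asarray(trait))
        assert table.df["beta"].iloc[0] == pytest.approx(coef[1], abs=1e-10)

    def test_null_variant_stays_within_sampling_noise(self):
        rng = np.random.default_rng(0)
        n = 100_000
        doses = rng.binomial(2, 0.3, n)
        trait = rng.normal(0, 1, n)  # independent of the variant
        table = association_scan(tiny_cohort(doses, trait), "x", "linear")
        row = table.df.iloc[0]
        assert abs(row["beta"]) < 4 * row["se"]

    def test_allele_recoding_negates_beta_and_flips_eaf(self):
        rng = np.random.default_rng(1)
        doses = rng.binomial(2, 0.3, 500)
        trait = 0.3 * doses + rng.normal(0, 1, 500)
        fwd = association_scan(tiny_cohort(doses, trait), "x", "linear")
        rev_cohort = tiny_cohort(2 - doses, trait)
        rev_cohort.effect_alleles, rev_cohort.other_alleles = ["G"], ["A"]
        rev = association_scan(rev_cohort, "x", "linear")
        assert rev.df["beta"].iloc[0] == pytest.approx(-fwd.df["beta"].iloc[0], abs=1e-12)
        assert rev.df["eaf"].iloc[0] == pytest.approx(1 - fwd.df["eaf"].iloc[0], abs=1e-12)
        assert rev.df["se"].iloc[0] == pytest.approx(fwd.df["se"].iloc[0], abs=1e-12)


class TestLogisticScan:
    def test_matches_statsmodels_maximum_likelihood(self):
        sm = pytest.importorskip("statsmodels.api")
        cfg = SimulationConfig(n_individuals=3000, n_variants=3,
                               maf=[0.2, 0.3, 0.4], beta_zx=[0.3, 0.2, 0.1],
                               beta_xy=0.5, intercept_y=-1.0, seed=2)
        cohort = simulate_cohort(cfg)
        table = association_scan(cohort, "y", "logistic")
        for j, vid in enumerate(cohort.variant_ids):
            X = sm.add_constant(cohort.genotypes[:, j].astype(float))
            fit = sm.Logit(cohort.y, X).fit(disp=0)
            row = table.df.set_index("variant_id").loc[vid]
            assert row["beta"] == pytest.approx(fit.params[1], abs=1e-6)
            assert row["se"] == pytest.approx(fit.bse[1], rel=1e-4)

    def test_monomorphic_variant_dropped(self, caplog):
        doses = np.array([1, 1, 1, 1, 1, 1, 1, 1])
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        with caplog.at_level(logging.WARNING):
            table = association_scan(tiny_cohort(doses, y, binary=True), "y", "logistic")
        assert len(table) == 0
        assert "monomorphic" in caplog.text

    def test_separated_variant_dropped_with_warning(self, caplog):
        # dose perfectly predicts the outcome: no finite MLE
        rng = np.random.default_rng(3)
        doses = rng.binomial(2, 0.5, 200)
        y = (doses >= 1).astype(int)
        with caplog.at_level(logging.WARNING):
            table = association_scan(tiny_cohort(doses, y, binary=True), "y", "logistic")
        assert len(table) == 0

    def test_model_trait_mismatch_rejected(self):
        cohort = simulate_cohort(SimulationConfig(
            n_individuals=100, n_variants=1, maf=[0.3], beta_zx=[0.2], seed=0))
        with pytest.raises(ValueError):
            association_scan(cohort, "x", "logistic")
        with pytest.raises(ValueError):
            association_scan(cohort, "y", "linear")


class TestTableIO:
    def test_round_trip_lossless_to_ten_significant_digits(self, tmp_path):
        rng = np.random.default_rng(4)
        betas = rng.normal(0, 0.123456789, 5)
        ses = np.abs(rng.normal(0.05, 0.01, 5)) + 1e-3
        table = make_table([f"v{i}" for i in range(5)], betas, ses,
                           pvals=rng.uniform(size=5).tolist())
        path = tmp_path / "sumstats.tsv"
        table.write_tsv(path)
        back = SummaryStatsTable.read_tsv(path, trait_id=table.trait_id)
        for col in ("beta", "se", "pval", "eaf"):
            np.testing.assert_allclose(back.df[col], table.df[col], rtol=1e-10)
        assert back.variant_ids == table.variant_ids

    def test_reader_tolerates_column_reordering(self, tmp_path):
        table = make_table(["v1", "v2"], [0.1, -0.2], [0.05, 0.06])
        path = tmp_path / "shuffled.tsv"
        table.df[list(reversed(table.COLUMNS))].to_csv(path, sep="\t", index=False)
        back = SummaryStatsTable.read_tsv(path)
        np.testing.assert_allclose(back.df["beta"], [0.1, -0.2])

    def test_duplicate_variant_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_table(["v1", "v1"], [0.1, 0.2], [0.05, 0.05])


class TestHarmonize:
    def test_already_aligned_tables_unchanged(self):
        exp = make_table(["v1", "v2"], [0.2, 0.3], [0.02, 0.03], trait_id="x")
        out = make_table(["v1", "v2"], [0.05, -0.04], [0.01, 0.01], trait_id="y")
        h = harmonize([exp], out)
        np.testing.assert_allclose(h.bx[:, 0], [0.2, 0.3])
        np.testing.assert_allclose(h.by, [0.05, -0.04])
        assert h.exposure_ids == ["x"]

    def test_swapped_alleles_flip_outcome_beta(self):
        exp = make_table(["v1", "v2"], [0.2, 0.3], [0.02, 0.03])
        out = make_table(["v1", "v2"], [0.05, -0.04], [0.01, 0.01],
                         ea=["A", "G"], oa=["G", "A"], eaf=[0.3, 0.7], trait_id="y")
        h = harmonize([exp], out)
        np.testing.assert_allclose(h.by, [0.05, 0.04])

    def test_strand_flip_resolved_by_complement(self):
        exp = make_table(["v1"], [0.2], [0.02])
        out = make_table(["v1"], [0.05], [0.01], ea="T", oa="C", trait_id="y")
        h = harmonize([exp], out)  # T/C is the complement of A/G, same orientation
        np.testing.assert_allclose(h.by, [0.05])

    def test_intersection_semantics(self):
        t1 = make_table(["v1", "v2", "v3"], [0.1, 0.2, 0.3], [0.02] * 3, trait_id="x")
        t2 = make_table(["v2", "v3"], [0.1, 0.2], [0.02] * 2, trait_id="bp")
        out = make_table(["v1", "v2", "v3"], [0.01, 0.02, 0.03], [0.01] * 3, trait_id="y")
        h = harmonize([t1, t2], out)
        assert h.variant_ids == ["v2", "v3"]
        assert h.k == 2 and h.K == 2

    def test_empty_intersection_raises(self):
        t1 = make_table(["v1"], [0.1], [0.02])
        out = make_table(["v9"], [0.01], [0.01], trait_id="y")
        with pytest.raises(ValueError, match="intersection"):
            harmonize([t1], out)

    def test_incompatible_allele_pairs_dropped(self):
        exp = make_table(["v1", "v2"], [0.2, 0.3], [0.02, 0.02])
        out = make_table(["v1", "v2"], [0.05, 0.06], [0.01, 0.01],
                         ea=["A", "C"], oa=["G", "A"], trait_id="y")
        h = harmonize([exp], out)  # v2's C/A cannot match A/G by label or strand
        assert h.variant_ids == ["v1"]

    @pytest.mark.parametrize("eaf_out,expected_by", [(0.2, 0.05), (0.8, -0.05)])
    def test_palindromic_resolved_by_frequency(self, eaf_out, expected_by):
        exp = make_table(["v1"], [0.2], [0.02], ea="A", oa="T", eaf=0.2)
        out = make_table(["v1"], [0.05], [0.01], ea="A", oa="T", eaf=eaf_out,
                         trait_id="y")
        h = harmonize([exp], out)
        np.testing.assert_allclose(h.by, [expected_by])

    def test_palindromic_near_half_frequency_dropped(self):
        exp = make_table(["v1", "v2"], [0.2, 0.3], [0.02, 0.02],
                         ea=["A", "A"], oa=["T", "G"], eaf=[0.48, 0.3])
        out = make_table(["v1", "v2"], [0.05, 0.06], [0.01, 0.01],
                         ea=["A", "A"], oa=["T", "G"], eaf=[0.48, 0.3],
                         trait_id="y")
        h = harmonize([exp], out)
        assert h.variant_ids == ["v2"]

    def test_idempotent(self):
        exp = make_table(["v1", "v2"], [0.2, 0.3], [0.02, 0.03])
        out = make_table(["v1", "v2"], [0.05, -0.04], [0.01, 0.01],
                         ea=["G", "A"], oa=["A", "G"], eaf=[0.7, 0.3], trait_id="y")
        exp1, out1 = harmonize_tables([exp], out)
        exp2, out2 = harmonize_tables(exp1, out1)
        pd.testing.assert_frame_equal(exp1[0].df, exp2[0].df)
        pd.testing.assert_frame_equal(out1.df, out2.df)


class TestPruneInstruments:
    @staticmethod
    def dosages(seed=0, n=500):
        rng = np.random.default_rng(seed)
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g3 = rng.binomial(2, 0.4, n).astype(float)
        return pd.DataFrame({"v1": g1, "v2": g1, "v3": g3})

    def test_independent_variants_all_retained(self):
        d = self.dosages()
        table = make_table(["v1", "v3"], [0.2, 0.3], [0.02, 0.02],
                           pvals=[1e-8, 1e-6])
        pruned = prune_instruments(table, d[["v1", "v3"]])
        assert pruned.variant_ids == ["v1", "v3"]

    def test_perfect_proxy_keeps_smaller_pvalue(self):
        d = self.dosages()
        table = make_table(["v1", "v2"], [0.2, 0.2], [0.02, 0.02],
                           pvals=[1e-6, 1e-9])
        pruned = prune_instruments(table, d)
        assert pruned.variant_ids == ["v2"]

    def test_greedy_rule_on_constructed_fixture(self):
        """v2 proxies v1 (best p) and is pruned; independent v3 survives.

        Expected set derived by enumerating the greedy rule by hand on the
        constructed dosage matrix."""
        d = self.dosages()
        table = make_table(["v1", "v2", "v3"], [0.2, 0.2, 0.3], [0.02] * 3,
                           pvals=[1e-9, 1e-6, 1e-4])
        pruned = prune_instruments(table, d)
        assert pruned.variant_ids == ["v1", "v3"]
        # output preserves the input row order
        assert pruned.df["variant_id"].tolist() == ["v1", "v3"]

    def test_missing_dosage_column_raises(self):
        table = make_table(["v1", "v9"], [0.2, 0.3], [0.02, 0.02])
        with pytest.raises(KeyError):
            prune_instruments(table, self.dosages())
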