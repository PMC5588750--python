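"""Size factors, dispersions, the exact NB test and the eFC statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from conftest import make_dataset
from gutmtx import de as de_mod
from gutmtx import quantify as qt
from gutmtx.data_model import COMPARISONS, DEFAULT_TAXA
from gutmtx.synthetic import SynthConfig, generate_dataset


def _fit(data):
    expr = qt.rpkm(data)
    sf = de_mod.size_factors(data.counts)
    groups = [
        list(data.samples.index[data.group_labels == g])
        for g in sorted(data.group_labels.unique())
    ]
    model = de_mod.fit_dispersions(data.counts, sf, groups)
    return expr, sf, model


class TestSizeFactors:
    def test_identical_columns(self):
        counts = pd.DataFrame([[10, 10], [3, 3]], columns=["a", "b"])
        np.testing.assert_allclose(de_mod.size_factors(counts), [1.0, 1.0])

    def test_exact_scaling(self):
        counts = pd.DataFrame([[10, 20], [7, 14], [1, 2]], columns=["a", "b"])
        sf = de_mod.size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        counts = pd.DataFrame([[10, 20], [30, 60]], columns=["a", "b"])
        sf = de_mod.size_factors(counts)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_no_all_positive_transcript(self):
        counts = pd.DataFrame([[0, 5], [5, 0]], columns=["a", "b"])
        with pytest.raises(ValueError, match="pseudo_reference"):
            de_mod.size_factors(counts)
        sf = de_mod.size_factors(counts, pseudo_reference=True)
        assert (sf > 0).all()


class TestDispersions:
    def test_recovers_planted_dispersion(self, synth_null):
        data, _ = synth_null  # phi = 0.2
        _, _, model = _fit(data)
        assert model.final.median() == pytest.approx(0.2, rel=0.25)

    def test_poisson_limit_raw_near_zero(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(100.0, size=(2000, 8))
        data = make_dataset(counts, n_groups=4)
        _, _, model = _fit(data)
        assert abs(np.median(model.raw)) < 0.02

    def test_constant_counts_zero_raw(self):
        counts = np.tile([[50, 50, 50, 50, 80, 80, 80, 80]], (3, 1))
        data = make_dataset(counts, n_groups=2)
        sf = pd.Series(1.0, index=data.counts.columns)
        groups = [list(data.counts.columns[:4]), list(data.counts.columns[4:])]
        model = de_mod.fit_dispersions(data.counts, sf, groups)
        np.testing.assert_allclose(model.raw, 0.0, atol=1e-12)

    def test_no_replication_raises(self):
        counts = pd.DataFrame([[5, 6]], columns=["a", "b"])
        with pytest.raises(ValueError, match="replication"):
            de_mod.fit_dispersions(
                counts, pd.Series(1.0, index=["a", "b"]), [["a"], ["b"]]
            )


class TestNbTest:
    def test_symmetric_identical_groups_p_one(self):
        counts = np.tile([[30]], (1, 8))
        data = make_dataset(counts, n_groups=4)
        _, sf, model = _fit(data)
        p = de_mod.nb_test(data.counts, model, COMPARISONS["Geno-HF"], data.samples)
        assert p.iloc[0] == pytest.approx(1.0)

    def test_zero_totals_p_one(self):
        counts = np.zeros((1, 8), dtype=int)
        counts[0, 4:] = 5  # expression confined to the LF samples
        counts = np.vstack([counts, np.full((2, 8), 20)])
        data = make_dataset(counts, n_groups=4)
        _, sf, model = _fit(data)
        spec = COMPARISONS["Geno-HF"]  # both HF groups have zero totals
        p = de_mod.nb_test(data.counts, model, spec, data.samples)
        assert p.iloc[0] == 1.0

    def test_poisson_limit_matches_conditional_binomial(self):
        """phi -> 0: the conditioned allocation is binomial, p within 1e-3."""
        counts = np.array([[40, 35, 42, 38, 70, 80, 75, 73]])
        counts = np.vstack([counts, np.full((3, 8), 50)])
        data = make_dataset(counts, n_groups=2)
        sf = pd.Series(1.0, index=data.counts.columns)
        model = de_mod.DispersionModel(
            size_factors=sf,
            base_mean=pd.Series(50.0, index=data.counts.index),
            raw=pd.Series(0.0, index=data.counts.index),
            trend_coef=(0.0, 0.0),
            final=pd.Series(1e-14, index=data.counts.index),
        )
        spec = COMPARISONS["Geno-HF"]  # Plin2-HF (first 4) vs WT-HF (last 4)
        g1, g2 = spec.sample_ids(data.samples)
        ka = int(data.counts.loc["T0", g1].sum())
        ks = ka + int(data.counts.loc["T0", g2].sum())
        pmf = binom.pmf(np.arange(ks + 1), ks, 0.5)
        oracle = pmf[pmf <= pmf[ka] * (1 + 1e-8)].sum()
        p = de_mod.nb_test(data.counts, model, spec, data.samples)
        assert p.loc["T0"] == pytest.approx(oracle, abs=1e-3)

    def test_null_type_one_error_calibrated(self, synth_null):
        data, _ = synth_null
        expr, _, model = _fit(data)
        res = de_mod.run_comparison(data, expr, model, COMPARISONS["Diet-WT"])
        frac = (res["p"] < 0.05).mean()
        sd = np.sqrt(0.05 * 0.95 / len(res))
        assert frac == pytest.approx(0.05, abs=3 * sd)

    def test_size_factor_invariance_under_column_scaling(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(10, 10 / 110, size=(300, 8))
        data = make_dataset(counts, n_groups=4)
        scaled_counts = counts.copy()
        scaled_counts[:, 0] *= 3
        scaled = make_dataset(scaled_counts, n_groups=4)
        _, sf1, m1 = _fit(data)
        _, sf2, m2 = _fit(scaled)
        ratio = (sf2 / sf1.to_numpy()).to_numpy()
        assert ratio[0] / np.median(ratio[1:]) == pytest.approx(3.0, rel=1e-6)
        # normalized counts are exactly invariant, so dispersions shift only
        # through the shot-noise correction; the conditional exact test sees
        # the amplified per-read noise of the scaled sample, so p-values are
        # concordant rather than identical
        p1 = de_mod.nb_test(data.counts, m1, COMPARISONS["Geno-HF"], data.samples)
        p2 = de_mod.nb_test(scaled.counts, m2, COMPARISONS["Geno-HF"], scaled.samples)
        assert np.median(np.abs(p1.to_numpy() - p2.to_numpy())) < 0.15
        calls1, calls2 = p1.to_numpy() < 0.01, p2.to_numpy() < 0.01
        assert (calls1 == calls2).mean() >= 0.95


class TestEfc:
    @pytest.mark.parametrize(
        "r1, r2, expected",
        [
            (1.49, 345.2, 345.2 / 1.49),
            (1.10, 95.6, 95.6 / 1.10),
            (0.0, 5.0, 5.0),
            (5.0, 0.0, -5.0),
            (3.0, 3.0, 0.0),
            (10.0, 2.0, -5.0),
        ],
    )
    def test_piecewise_values(self, r1, r2, expected):
        assert de_mod.efc(r1, r2) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            de_mod.efc(-1.0, 2.0)

    @given(
        st.floats(0, 1e6, allow_nan=False),
        st.floats(0, 1e6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, r1, r2):
        assert de_mod.efc(r1, r2) == pytest.approx(-de_mod.efc(r2, r1), rel=1e-12)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_magnitude_at_least_one_for_positive_inputs(self, r1, r2):
        assert r1 == r2 or abs(de_mod.efc(r1, r2)) >= 1.0


class TestSignificance:
    @pytest.mark.parametrize(
        "q, efc, expected",
        [(0.04, 5.0, True), (0.04, -3.0, False), (0.06, 100.0, False), (0.04, -5.0, True)],
    )
    def test_gates(self, q, efc, expected):
        frame = pd.DataFrame({"efc": [efc], "q": [q]})
        out = de_mod.call_significant(frame)
        assert bool(out["is_sig"].iloc[0]) is expected

    def test_planted_effect_sensitivity(self):
        """|log2FC| = 3 transcripts at high mean are recovered at >= 0.8."""
        config = SynthConfig(
            n_transcripts=2000,
            pi_de=0.1,
            phi=0.1,
            effect_low=3.0,
            effect_high=3.0,
            seed=11,
        )
        data, truth = generate_dataset(config)
        data, _ = qt.filter_low_expression(data)
        expr, _, model = _fit(data)
        res = de_mod.run_comparison(data, expr, model, COMPARISONS["Geno-LF"])
        tr = truth.transcripts.loc[data.counts.index]
        planted = tr["de_Geno-LF"] & (model.base_mean >= 200)
        sig = res.set_index("transcript_id")["is_sig"]
        assert planted.sum() >= 20
        assert sig[planted[planted].index].mean() >= 0.8

    def test_null_fdr_controlled(self, synth_null):
        data, _ = synth_null
        expr, _, model = _fit(data)
        res = de_mod.run_comparison(data, expr, model, COMPARISONS["Geno-HF"])
        assert int(res["is_sig"].sum()) == 0


class TestEnzymeAggregate:
    def _toy(self):
        # T0 alone on EC a; T1+T2 share EC b; T3 unannotated
        ecs = [
            frozenset({"1.1.1.1"}),
            frozenset({"2.2.2.2"}),
            frozenset({"2.2.2.2"}),
            frozenset(),
        ]
        counts = np.array(
            [
                [100, 90, 110, 100, 10, 12, 9, 11],
                [50, 60, 55, 50, 200, 180, 190, 200],
                [10, 12, 9, 10, 50, 40, 45, 50],
                [20, 20, 20, 20, 20, 20, 20, 20],
            ]
        )
        taxa = [DEFAULT_TAXA[0], DEFAULT_TAXA[0], DEFAULT_TAXA[1], DEFAULT_TAXA[2]]
        data = make_dataset(counts, ecs=ecs, taxa=taxa, n_groups=2, totals=[10**6] * 8)
        return data

    def test_single_transcript_enzyme_aefc_equals_efc(self):
        data = self._toy()
        expr, _, model = _fit(data)
        spec = COMPARISONS["Geno-HF"]
        res = de_mod.run_comparison(data, expr, model, spec)
        enz, _ = de_mod.enzyme_aggregate(
            res, expr, data.annotations, spec, data.samples, DEFAULT_TAXA
        )
        row = enz.set_index("ec").loc["1.1.1.1"]
        assert row["n"] == 1
        assert row["aefc"] == pytest.approx(row["efc"])

    def test_two_member_enzyme_halves_efc(self):
        data = self._toy()
        expr, _, model = _fit(data)
        spec = COMPARISONS["Geno-HF"]
        res = de_mod.run_comparison(data, expr, model, spec)
        enz, _ = de_mod.enzyme_aggregate(
            res, expr, data.annotations, spec, data.samples, DEFAULT_TAXA
        )
        row = enz.set_index("ec").loc["2.2.2.2"]
        assert row["n"] == 2
        assert row["aefc"] == pytest.approx(row["efc"] / 2)
        # summed member group means drive the enzyme-level efc
        g1, g2 = spec.sample_ids(data.samples)
        r1 = expr.rpkm.loc[["T1", "T2"], g1].mean(axis=1).sum()
        r2 = expr.rpkm.loc[["T1", "T2"], g2].mean(axis=1).sum()
        assert row["efc"] == pytest.approx(de_mod.efc(r1, r2))

    def test_sig_propagation_and_taxon_restriction(self):
        data = self._toy()
        expr, _, model = _fit(data)
        spec = COMPARISONS["Geno-HF"]
        res = de_mod.run_comparison(data, expr, model, spec)
        res.loc[res["transcript_id"] == "T1", "is_sig"] = True
        enz, per_taxon = de_mod.enzyme_aggregate(
            res, expr, data.annotations, spec, data.samples, DEFAULT_TAXA
        )
        row = enz.set_index("ec").loc["2.2.2.2"]
        assert bool(row["is_sig"])
        # taxa expressing no member have NaN; expressing taxa carry values
        assert np.isfinite(per_taxon.loc["2.2.2.2", DEFAULT_TAXA[0]])
        assert np.isfinite(per_taxon.loc["2.2.2.2", DEFAULT_TAXA[1]])
        assert np.isnan(per_taxon.loc["2.2.2.2", DEFAULT_TAXA[2]])
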