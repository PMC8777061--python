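import numpy as np
import pandas as pd
import pytest

from gmqn.between_array import normalize_type1
from gmqn.io_signals import compute_beta
from gmqn.simulate import SimulationConfig, simulate_dataset
from gmqn.within_array import bmiq_adjust, normalize_pipeline, swan_adjust


@pytest.fixture(scope="module")
def clean_dataset():
    """One clean sample with the default type II compression bias."""
    cfg = SimulationConfig(n_samples=1, seed=17, type2_bias=0.25)
    return simulate_dataset(cfg)


@pytest.fixture(scope="module")
def unbiased_dataset():
    """Type II beta distributed identically to type I (no design bias)."""
    cfg = SimulationConfig(n_samples=1, seed=18, type2_bias=0.0)
    return simulate_dataset(cfg)


class TestBmiq:
    def test_identity_when_type2_matches_type1(self, unbiased_dataset):
        samples, ann, _ = unbiased_dataset
        beta = compute_beta(samples[0])
        adjusted = bmiq_adjust(beta, ann)
        t2 = ann.index[ann["design_type"] == "II"]
        assert float((adjusted.values[t2] - beta.values[t2]).abs().mean()) < 0.01

    def test_reduces_known_type2_bias(self, clean_dataset):
        samples, ann, truth = clean_dataset
        beta = compute_beta(samples[0])
        adjusted = bmiq_adjust(beta, ann)
        t2 = ann.index[ann["design_type"] == "II"]
        true = truth.true_beta.iloc[:, 0]
        err_before = float((beta.values[t2] - true[t2]).abs().mean())
        err_after = float((adjusted.values[t2] - true[t2]).abs().mean())
        assert err_after <= 0.5 * err_before

    def test_monotone_and_bounded(self, clean_dataset):
        samples, ann, _ = clean_dataset
        beta = compute_beta(samples[0])
        adjusted = bmiq_adjust(beta, ann)
        t2 = ann.index[ann["design_type"] == "II"]
        x = beta.values[t2].to_numpy()
        y = adjusted.values[t2].to_numpy()
        order = np.argsort(x, kind="stable")
        assert (np.diff(y[order]) >= -1e-9).all()
        assert ((y >= 0) & (y <= 1)).all()

    def test_type1_untouched(self, clean_dataset):
        samples, ann, _ = clean_dataset
        beta = compute_beta(samples[0])
        adjusted = bmiq_adjust(beta, ann)
        t1 = ann.index[ann["design_type"] == "I"]
        pd.testing.assert_series_equal(adjusted.values[t1], beta.values[t1])


class TestSwan:
    def test_near_identity_when_type2_equals_type1_within_strata(self, rng):
        """Type II intensities copied from type I stratum-wise map to themselves
        up to order-statistic interpolation."""
        from gmqn.between_array import NormalizedSignals

        n = 900
        rows = []
        for stratum in (1, 2, 3):
            vals = np.sort(rng.lognormal(8.7, 0.4, n))
            for kind in ("I", "II"):
                for i, v in enumerate(vals):
                    rows.append((f"cg_{kind}_{stratum}_{i}", kind, stratum, v))
        ann = pd.DataFrame(
            {
                "design_type": [r[1] for r in rows],
                "channel": ["red" if r[1] == "I" else "none" for r in rows],
                "chromosome": "chr1",
                "position": range(len(rows)),
                "probe_cpg_count": [r[2] for r in rows],
            },
            index=pd.Index([r[0] for r in rows], name="probe_id"),
        )
        frame = pd.DataFrame(
            {"M": [r[3] for r in rows], "U": [r[3] for r in rows]}, index=ann.index
        )
        out = swan_adjust(NormalizedSignals("s", frame), ann)
        t2 = ann.index[ann["design_type"] == "II"]
        rel = (out.signals.loc[t2, "M"] - frame.loc[t2, "M"]).abs() / frame.loc[t2, "M"]
        assert float(rel.median()) < 0.01

    def test_type2_deciles_match_type1_within_strata(self, clean_dataset, reference):
        samples, ann, _ = clean_dataset
        out = swan_adjust(normalize_type1(samples[0], ann, reference), ann)
        strata = ann["probe_cpg_count"].clip(1, 3)
        q = np.linspace(0.1, 0.9, 9)
        for s in (1, 2, 3):
            for col in ("M", "U"):
                v1 = out.signals.loc[(ann["design_type"] == "I") & (strata == s), col]
                v2 = out.signals.loc[(ann["design_type"] == "II") & (strata == s), col]
                d1, d2 = np.quantile(v1, q), np.quantile(v2, q)
                np.testing.assert_allclose(d2, d1, rtol=0.02)

    def test_rank_order_preserved_within_strata(self, clean_dataset, reference):
        samples, ann, _ = clean_dataset
        norm = normalize_type1(samples[0], ann, reference)
        out = swan_adjust(norm, ann)
        strata = ann["probe_cpg_count"].clip(1, 3)
        for s in (1, 2, 3):
            sel = (ann["design_type"] == "II") & (strata == s)
            before = norm.signals.loc[sel, "M"].to_numpy()
            after = out.signals.loc[sel, "M"].to_numpy()
            assert (np.argsort(before, kind="stable") == np.argsort(after, kind="stable")).all()

    def test_type1_untouched(self, clean_dataset, reference):
        samples, ann, _ = clean_dataset
        norm = normalize_type1(samples[0], ann, reference)
        out = swan_adjust(norm, ann)
        t1 = ann.index[ann["design_type"] == "I"]
        pd.testing.assert_frame_equal(out.signals.loc[t1], norm.signals.loc[t1])


class TestPipeline:
    def test_none_method_is_pure_composition(self, ref_cohort, reference):
        samples, ann, _ = ref_cohort
        via_pipeline = normalize_pipeline(samples[0], ann, reference, method="none")
        direct = compute_beta(normalize_type1(samples[0], ann, reference).to_sample())
        pd.testing.assert_series_equal(via_pipeline.values, direct.values)

    @pytest.mark.parametrize("method", ["none", "bmiq", "swan"])
    def test_outputs_in_unit_interval_and_missing_preserved(
        self, ref_cohort, reference, method
    ):
        samples, ann, _ = ref_cohort
        s = samples[3].copy()
        victim = ann.index[ann["design_type"] == "I"][0]
        s.signals.loc[victim, "M"] = np.nan
        beta = normalize_pipeline(s, ann, reference, method=method)
        v = beta.values
        assert np.isnan(v[victim])
        finite = v.dropna()
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_rejects_unknown_method(self, ref_cohort, reference):
        from gmqn.errors import ParameterError

        samples, ann, _ = ref_cohort
        with pytest.raises(ParameterError):
            normalize_pipeline(samples[0], ann, reference, method="quantile")
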