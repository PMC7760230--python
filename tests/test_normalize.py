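import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dspforge import normalize as nz
from dspforge.normalize import (
    GlobalScalingNormalizer,
    HousekeeperNormalizer,
    NormalizationError,
    assess_normalizers,
    build_factor_table,
    log2_transform,
    normalize_counts,
    normalize_hk,
    pearson_r,
    rle_factors,
    tmm_factors,
)


class TestPearsonR:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 7.0])
        # direct product-moment formula as an independent oracle
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson_r(x, y) == pytest.approx(num / den)
        assert pearson_r(x, y) == pytest.approx(0.993399, abs=1e-6)

    def test_errors(self):
        with pytest.raises(NormalizationError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])
        with pytest.raises(NormalizationError, match="equal-length"):
            pearson_r([1, 2, 3], [1, 2])
        with pytest.raises(NormalizationError, match="at least 3"):
            pearson_r([1, 2], [3, 4])


class TestFactorTable:
    def test_hand_values(self, tiny_counts, tiny_panel, tiny_rois):
        table = build_factor_table(tiny_counts, tiny_panel, tiny_rois)
        assert table.loc["R1", "hk_mean"] == pytest.approx(300.0)  # (200+400)/2
        assert table.loc["R1", "igg_mean"] == pytest.approx(100.0)  # (80+120)/2
        assert table.loc["R1", "area"] == pytest.approx(1000.0)

    def test_missing_housekeeper_logs_and_omits(self, tiny_counts, tiny_panel,
                                                caplog):
        counts = tiny_counts.drop(columns=["S6"])
        with caplog.at_level("WARNING", logger="dspforge"):
            table = build_factor_table(counts, tiny_panel)
        assert "hk_mean" not in table.columns
        assert any("hk_mean unavailable" in m for m in caplog.messages)

    def test_size_factor_structure_recovered(self, default_sim):
        # housekeeper and IgG factors share the ROI size factor
        design, counts, rois, truth = default_sim
        table = build_factor_table(counts, design.panel, rois)
        assert pearson_r(table["hk_mean"], table["igg_mean"]) > 0.8
        assert pearson_r(table["hk_mean"],
                         truth.size_factors.loc[table.index]) > 0.9


class TestAssessNormalizers:
    def test_matrix_matches_elementwise_oracle(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(rng.lognormal(0, 0.3, size=(6, 3)),
                             columns=["hk_mean", "igg_mean", "nuclei"])
        out = assess_normalizers(table)
        for a in table.columns:
            for b in table.columns:
                expected = 1.0 if a == b else pearson_r(table[a], table[b])
                assert out.correlations.loc[a, b] == pytest.approx(expected)
        assert (out.correlations.values == out.correlations.values.T).all()

    def test_proportional_factors_fully_correlated(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        table = pd.DataFrame({"hk_mean": base, "igg_mean": 2 * base,
                              "area": 0.5 * base})
        out = assess_normalizers(table)
        np.testing.assert_allclose(out.correlations.to_numpy(), 1.0)

    def test_constant_area_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "hk_mean": rng.lognormal(0, 0.2, 8),
            "igg_mean": rng.lognormal(0, 0.2, 8),
            "area": np.full(8, 282_743.0),  # every ROI at maximum geometry
        })
        with caplog.at_level("WARNING", logger="dspforge"):
            out = assess_normalizers(table)
        assert "area" in out.excluded
        assert np.isnan(out.correlations.loc["area", "hk_mean"])
        assert out.recommended != "area"
        assert any("constant" in m for m in caplog.messages)

    def test_requires_three_complete_rois(self):
        table = pd.DataFrame({"hk_mean": [1.0, 2.0], "igg_mean": [1.0, 2.0]})
        with pytest.raises(NormalizationError, match=">=3"):
            assess_normalizers(table)


class TestHousekeeperNormalization:
    def test_identical_factors_identity(self, tiny_panel):
        counts = pd.DataFrame({
            "A": [10.0, 20.0], "Histone H3": [100.0, 100.0],
            "S6": [200.0, 200.0],
        }, index=["R1", "R2"])
        nm = normalize_hk(counts, tiny_panel)
        pd.testing.assert_frame_equal(nm.values, counts)

    def test_two_roi_proportionality(self, tiny_panel):
        # ROI A's factor is twice ROI B's; identical raw target counts
        counts = pd.DataFrame({
            "A": [10.0, 10.0],
            "Histone H3": [200.0, 100.0],
            "S6": [200.0, 100.0],
        }, index=["RA", "RB"])
        nm = normalize_hk(counts, tiny_panel)
        ratio = nm.values.loc["RA", "A"] / nm.values.loc["RB", "A"]
        assert ratio == pytest.approx(0.5)
        # grand geometric mean of factors preserved: output is count-scaled
        assert np.exp(np.log(nm.factors).mean()) == pytest.approx(1.0)

    def test_idempotence(self, default_sim):
        design, counts, _, _ = default_sim
        once = normalize_hk(counts, design.panel)
        twice = normalize_hk(once.values, design.panel)
        np.testing.assert_allclose(twice.values.to_numpy(),
                                   once.values.to_numpy(), rtol=1e-10)

    def test_reduces_cv_of_null_probes(self, default_sim):
        design, counts, rois, _ = default_sim
        tme = rois.loc[rois["compartment"] == "TME", "roi_id"]
        nm = normalize_hk(counts, design.panel)
        null_targets = [p for p in design.panel.targets
                        if p not in design.effect_table][:20]
        cv = lambda df: (df.std() / df.mean()).median()
        assert cv(nm.values.loc[tme, null_targets]) \
            < cv(counts.loc[tme, null_targets])

    def test_missing_probe_and_zero_factor(self, tiny_panel, caplog):
        counts = pd.DataFrame({"A": [1.0, 2.0], "Histone H3": [10.0, 0.0],
                               "S6": [10.0, 0.0]}, index=["R1", "R2"])
        with pytest.raises(NormalizationError, match="absent"):
            normalize_hk(counts.drop(columns="S6"), tiny_panel)
        with caplog.at_level("WARNING", logger="dspforge"):
            nm = normalize_hk(counts, tiny_panel)
        assert list(nm.values.index) == ["R1"]

    def test_geometric_mean_option(self, tiny_panel):
        counts = pd.DataFrame({"A": [8.0], "Histone H3": [100.0],
                               "S6": [400.0]}, index=["R1"])
        est = HousekeeperNormalizer(tiny_panel, mean="geometric").fit(counts)
        assert est.factors_["R1"] == pytest.approx(200.0)

    def test_equivariance_to_relabeling(self, default_sim):
        design, counts, _, _ = default_sim
        nm = normalize_hk(counts, design.panel)
        shuffled = counts.sample(frac=1.0, random_state=0)
        shuffled = shuffled[list(reversed(counts.columns))]
        nm2 = normalize_hk(shuffled, design.panel)
        pd.testing.assert_frame_equal(
            nm2.values.loc[nm.values.index, nm.values.columns], nm.values)


def _tmm_oracle(counts: pd.DataFrame, logratio_trim=0.30, sum_trim=0.05):
    """Straightforward re-implementation of the doubly trimmed weighted
    mean of M-values, written from the definition."""
    X = counts.to_numpy(dtype=float)
    lib = X.sum(axis=1)
    uq = np.array([np.quantile(x / l, 0.75) for x, l in zip(X, lib)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = []
    for i in range(X.shape[0]):
        o, r = X[i], X[ref]
        keep = (o > 0) & (r > 0)
        o, r = o[keep], r[keep]
        m = np.log2((o / lib[i]) / (r / lib[ref]))
        a = 0.5 * np.log2((o / lib[i]) * (r / lib[ref]))
        if np.max(np.abs(m)) < 1e-6:
            factors.append(1.0)
            continue
        w = (lib[i] - o) / (lib[i] * o) + (lib[ref] - r) / (lib[ref] * r)
        n = len(m)
        lo_m = np.floor(n * logratio_trim) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * sum_trim) + 1
        hi_a = n + 1 - lo_a
        rm, ra = stats.rankdata(m), stats.rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors.append(2.0 ** (np.sum(w[sel] * m[sel]) / np.sum(w[sel])))
    scale = lib * np.array(factors)
    return scale / np.exp(np.mean(np.log(scale)))


class TestGlobalScaling:
    def test_identical_rois_unit_factors(self):
        row = np.array([10.0, 50.0, 200.0, 1000.0])
        counts = pd.DataFrame([row, row], index=["R1", "R2"])
        np.testing.assert_allclose(tmm_factors(counts), 1.0)
        np.testing.assert_allclose(rle_factors(counts), 1.0)

    def test_rle_closed_form_for_doubled_roi(self):
        row = np.array([10.0, 50.0, 200.0, 1000.0])
        counts = pd.DataFrame([row, 2 * row], index=["RA", "RB"])
        f = rle_factors(counts)
        np.testing.assert_allclose(f.to_numpy(),
                                   [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_tmm_matches_independent_oracle(self):
        rng = np.random.default_rng(12)
        counts = pd.DataFrame(
            rng.negative_binomial(20, 0.05, size=(5, 40)).astype(float) + 1.0,
            index=[f"R{i}" for i in range(5)])
        np.testing.assert_allclose(tmm_factors(counts).to_numpy(),
                                   _tmm_oracle(counts), rtol=1e-8)

    def test_factor_products_are_one(self, default_sim):
        _, counts, _, _ = default_sim
        for fn in (tmm_factors, rle_factors):
            logsum = np.log(fn(counts)).sum()
            assert abs(logsum) < 1e-10

    def test_all_zero_probe_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(100, size=(4, 10)).astype(float))
        counts[3] = 0.0
        with caplog.at_level("WARNING", logger="dspforge"):
            f = tmm_factors(counts)
        assert np.isfinite(f).all()
        assert any("all-zero" in m for m in caplog.messages)

    def test_estimator_interface(self, default_sim):
        _, counts, _, _ = default_sim
        est = GlobalScalingNormalizer(method="rle").fit(counts)
        out = est.transform(counts)
        np.testing.assert_allclose(
            out.to_numpy(),
            counts.div(est.factors_, axis=0).to_numpy())
        with pytest.raises(NormalizationError, match="unknown"):
            GlobalScalingNormalizer(method="upper").fit(counts)


class TestLog2Transform:
    @pytest.mark.parametrize("value,expected", [(0.0, 0.0), (3.0, 2.0),
                                                (1023.0, 10.0)])
    def test_known_values(self, value, expected):
        frame = pd.DataFrame({"a": [value]})
        out = log2_transform(frame, pseudo_count=1.0)
        assert out.values.iloc[0, 0] == pytest.approx(expected)
        assert out.log2 and out.pseudo_count == 1.0

    def test_negative_rejected(self):
        with pytest.raises(NormalizationError, match="nonnegative"):
            log2_transform(pd.DataFrame({"a": [-1.0]}))

    def test_applied_once(self, default_sim):
        design, counts, _, _ = default_sim
        nm = normalize_hk(counts, design.panel)
        logged = log2_transform(nm)
        again = log2_transform(logged)
        assert again is logged


def test_dispatch_unknown_method(tiny_counts, tiny_panel):
    with pytest.raises(NormalizationError, match="unknown normalization"):
        normalize_counts(tiny_counts, tiny_panel, method="quantile")


class TestWithinGroupNormalization:
    def test_groups_anchored_independently(self, default_sim):
        # per-compartment normalization preserves each compartment's own
        # count level instead of inflating the depressed group
        design, counts, rois, _ = default_sim
        comp = rois.set_index("roi_id")["compartment"]
        nm = nz.normalize_within_groups(counts, design.panel, comp)
        assert nm.method == "hk_mean:within_group"
        for c in ("Tumour", "TME", "NAT"):
            idx = comp[comp == c].index
            sub = np.log(nm.factors.loc[idx])
            assert abs(sub.mean()) < 1e-10  # per-group geometric mean 1
        single = nz.normalize_hk(counts, design.panel)
        assert not np.allclose(nm.values.to_numpy(),
                               single.values.loc[nm.values.index].to_numpy())

    def test_missing_group_label_rejected(self, tiny_counts, tiny_panel):
        groups = pd.Series({"R1": "Tumour", "R2": "Tumour"})
        with pytest.raises(NormalizationError, match="group label"):
            nz.normalize_within_groups(tiny_counts, tiny_panel, groups)
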