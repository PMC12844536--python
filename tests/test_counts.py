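"""Normalization, batch handling, moderated differential testing and the
DAR/DEG taxonomies."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency, kstest

import strainatac.counts as cm
from strainatac import (
    SimConfig,
    classify_dars,
    classify_degs,
    detect_confounded_cluster,
    differential_test,
    filter_features,
    generate,
    normalize_logcpm,
    residualize_batch,
)

from conftest import null_config


def make_samples(n_per=3):
    rows = []
    for strain in ("B6", "S129"):
        for diet in ("chow", "HFD"):
            for i in range(n_per):
                rows.append(
                    {"sample_id": f"{strain}_{diet}_{i}", "strain": strain,
                     "diet": diet}
                )
    return pd.DataFrame(rows)


class TestNormalizeLogCPM:
    def test_direct_formula(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(rng.integers(0, 1000, size=(50, 4)))
        got = normalize_logcpm(raw, prior_count=0.5)
        lib = raw.sum(axis=0).to_numpy()
        expected = np.log2(
            (raw.to_numpy() + 0.5) / (lib + 1.0) * 1e6
        )
        assert np.allclose(got.to_numpy(), expected)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        raw = pd.DataFrame(rng.integers(100, 1000, size=(50, 3)))
        doubled = raw * 2
        a = normalize_logcpm(raw)
        b = normalize_logcpm(doubled)
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 0.01

    def test_zero_library_rejected(self):
        raw = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError, match="s2"):
            normalize_logcpm(raw)


class TestFilterFeatures:
    def test_strict_threshold_boundary(self):
        logcpm = pd.DataFrame(
            {"s1": [-2.9, -3.0, -3.1], "s2": [-2.9, -3.0, -3.1]},
            index=["keep", "drop_eq", "drop_lt"],
        )
        kept = filter_features(logcpm, -3.0)
        assert list(kept) == ["keep"]

    def test_generator_decoys_all_dropped(self, sim, run):
        decoys = {
            f for f, t in sim.truth["peaks"].items() if t["decoy"]
        }
        retained = set(run["retained_peaks"]["feature_id"])
        assert decoys.isdisjoint(retained)
        assert len(retained) == len(sim.peaks) - len(decoys)


class TestConfoundedCluster:
    def test_planted_contamination_samples_recovered(self, sim, run):
        labels = run["batch_labels"].set_index("sample_id")["batch_cluster"]
        assert sorted(labels[labels == 2].index) == sim.truth[
            "contamination_samples"
        ]

    def test_null_split_uncorrelated_with_design(self):
        d = generate(null_config(seed=21))
        lc = normalize_logcpm(d.atac_counts)
        labels, _ = detect_confounded_cluster(lc, d.samples, seed=0)
        sheet = d.samples.set_index("sample_id").loc[labels.index]
        for factor in ("strain", "diet"):
            tab = pd.crosstab(labels, sheet[factor])
            if tab.shape == (2, 2):
                p = chi2_contingency(tab)[1]
                assert p > 0.05

    def test_duplicate_samples_never_split(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, size=(200, 10))
        base[:50, 5:] += 3.0  # clear 2-group structure
        X = np.column_stack([base, base[:, [0]]])  # sample 10 = sample 0
        cols = [f"s{i}" for i in range(11)]
        lc = pd.DataFrame(X, columns=cols)
        samples = pd.DataFrame(
            {"sample_id": cols, "strain": "B6", "diet": "chow"}
        )
        labels, _ = detect_confounded_cluster(lc, samples, seed=0)
        assert labels["s0"] == labels["s10"]


class TestResidualizeBatch:
    def setup_data(self, delta=2.0, seed=0):
        rng = np.random.default_rng(seed)
        samples = make_samples(4)
        n = len(samples)
        X = rng.normal(0, 0.3, size=(300, n))
        batch = pd.Series(1, index=samples["sample_id"])
        # 2 batch samples in every group (spans the design evenly)
        chosen = [0, 1, 4, 5, 8, 9, 12, 13]
        batch.iloc[chosen] = 2
        X[:, chosen] += delta
        lc = pd.DataFrame(X, columns=samples["sample_id"])
        return lc, batch, samples

    def test_planted_shift_removed(self):
        delta = 2.0
        lc, batch, samples = self.setup_data(delta)
        corrected = residualize_batch(lc, batch, samples)
        in2 = (batch == 2).to_numpy()
        gap = (
            corrected.loc[:, in2].mean(axis=1)
            - corrected.loc[:, ~in2].mean(axis=1)
        )
        assert np.abs(gap.mean()) < 0.05 * delta

    def test_no_batch_effect_identity(self):
        lc, batch, samples = self.setup_data(delta=0.0)
        corrected = residualize_batch(lc, batch, samples)
        # estimated batch coefficient is pure noise; tiny perturbation only
        assert np.abs(corrected.to_numpy() - lc.to_numpy()).max() < 0.5
        uniform = pd.Series(1, index=batch.index)
        same = residualize_batch(lc, uniform, samples)
        assert np.abs(same.to_numpy() - lc.to_numpy()).max() < 1e-10

    def test_group_means_preserved(self):
        lc, batch, samples = self.setup_data()
        corrected = residualize_batch(lc, batch, samples)
        sheet = samples.set_index("sample_id")
        group = sheet["strain"] + ":" + sheet["diet"]
        for g in group.unique():
            cols = group.index[group == g]
            before = lc[cols].mean(axis=1)
            after = corrected[cols].mean(axis=1)
            assert np.abs(before - after).max() < 1e-8

    def test_confounded_batch_rejected(self):
        lc, _, samples = self.setup_data()
        sheet = samples.set_index("sample_id")
        confounded = pd.Series(
            np.where(sheet["strain"] == "B6", 2, 1), index=sheet.index
        )
        with pytest.raises(ValueError, match="confounded"):
            residualize_batch(lc, confounded, samples)


class TestDifferentialTest:
    def test_equal_group_means_null(self):
        samples = make_samples(4)
        rng = np.random.default_rng(0)
        X = rng.normal(5, 0.001, size=(20, len(samples)))
        lc = pd.DataFrame(X, columns=samples["sample_id"])
        lc.iloc[0] = 5.0  # exactly constant feature
        res = differential_test(lc, samples, "strain_chow")
        assert abs(res["log2fc"].iloc[0]) < 1e-12
        assert res["p"].iloc[0] > 0.99

    def test_planted_lfc_recovered(self):
        rng = np.random.default_rng(5)
        samples = make_samples(6)
        sheet = samples.set_index("sample_id")
        n = len(samples)
        # NB counts, dispersion 0.1, planted strain log2fc 1.5
        mu = np.full((200, n), 500.0)
        cols_129 = (sheet["strain"] == "S129").to_numpy()
        mu[:, cols_129] *= 2**1.5
        r = 10.0
        counts = pd.DataFrame(
            rng.poisson(rng.gamma(r, mu / r)), columns=samples["sample_id"]
        )
        lc = normalize_logcpm(counts)
        # normalization removes the library-size component of the shift;
        # recover it from the median feature-wise offset
        res = differential_test(lc, samples, "strain_chow")
        assert abs(res["log2fc"].mean() - res["log2fc"].median()) < 0.1
        spread = res["log2fc"].std()
        assert spread < 0.35  # tight around the common planted effect

    def test_null_generator_calibration(self):
        d = generate(null_config(seed=31, n_peaks=2000))
        lc = normalize_logcpm(d.atac_counts)
        lc = lc.loc[filter_features(lc)]
        res = differential_test(lc, d.samples, "strain_HFD")
        assert kstest(res["p"], "uniform").pvalue > 0.01
        assert (res["fdr"] < 0.01).mean() <= 0.02

    def test_too_few_samples_rejected(self):
        samples = make_samples(1)
        lc = pd.DataFrame(
            np.zeros((5, len(samples))), columns=samples["sample_id"]
        )
        with pytest.raises(ValueError):
            differential_test(lc, samples, "strain_chow")


def res_frame(fdrs, lfcs, comparison):
    return pd.DataFrame(
        {
            "feature_id": [f"f{i}" for i in range(len(fdrs))],
            "comparison": comparison,
            "log2fc": lfcs,
            "p": fdrs,
            "fdr": fdrs,
        }
    )


class TestClassifyDARs:
    def test_class_taxonomy(self):
        chow = res_frame([0.005, 0.005, 0.005], [0.8, 0.8, 0.5], "strain_chow")
        hfd = res_frame([0.004, 0.5, 0.5], [0.9, 0.1, 0.1], "strain_HFD")
        out = classify_dars(chow, hfd)
        assert list(out["dar_class"]) == ["Common", "Chow", "NonDAR"]
        assert out["representative_fdr"].tolist() == [0.004, 0.005, 0.005]

    def test_both_thresholds_required(self):
        # significant FDR but |log2fc| = 0.5 < log2(1.5): not a DAR
        chow = res_frame([0.005], [0.5], "strain_chow")
        hfd = res_frame([0.5], [0.0], "strain_HFD")
        assert classify_dars(chow, hfd)["dar_class"].iloc[0] == "NonDAR"

    def test_mismatched_features_rejected(self):
        chow = res_frame([0.005], [0.8], "strain_chow")
        hfd = res_frame([0.005, 0.005], [0.8, 0.8], "strain_HFD")
        with pytest.raises(ValueError):
            classify_dars(chow, hfd)


class TestClassifyDEGs:
    def make(self, sig):
        return {
            cmp_: res_frame(
                [0.01 if s else 0.5 for s in flags], [1.0] * len(flags), cmp_
            )
            for cmp_, flags in sig.items()
        }

    def test_strain_class(self):
        res = self.make(
            {"strain_chow": [1], "strain_HFD": [1],
             "diet_B6": [0], "diet_129": [0]}
        )
        assert classify_degs(res)["deg_class"].iloc[0] == "Strain"

    def test_diet_class(self):
        res = self.make(
            {"strain_chow": [0], "strain_HFD": [0],
             "diet_B6": [1], "diet_129": [0]}
        )
        assert classify_degs(res)["deg_class"].iloc[0] == "Diet"

    def test_diet_plus_strain_class(self):
        res = self.make(
            {"strain_chow": [1], "strain_HFD": [0],
             "diet_B6": [1], "diet_129": [0]}
        )
        assert classify_degs(res)["deg_class"].iloc[0] == "DietStrain"

    def test_missing_comparison_rejected(self):
        res = self.make({"strain_chow": [1], "strain_HFD": [1]})
        with pytest.raises(ValueError):
            classify_degs(res)
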