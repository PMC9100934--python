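import numpy as np
import pandas as pd
import pytest

import glycomicrobe as g
from glycomicrobe import microqc


def _meta(n_lib, rng, n_dates=4, n_ind=None):
    """Minimal metadata table with a 3x1 location/amplicon layout."""
    n_ind = n_ind or n_lib
    idx = [f"lib{i}" for i in range(n_lib)]
    return pd.DataFrame({
        "individual_id": [f"i{i % n_ind}" for i in range(n_lib)],
        "location": [("ileum", "rectum", "transversum")[i % 3] for i in range(n_lib)],
        "amplicon": "V1V2",
        "run_batch": [f"run{i % 3}" for i in range(n_lib)],
        "collection_date": [f"d{i % n_dates}" for i in range(n_lib)],
        "coverage": rng.integers(10_000, 20_000, n_lib),
        "replicate_group": "",
        "negative_control": False,
    }, index=idx)


class TestImputeAndClr:
    def test_hand_computed_three_by_three(self):
        counts = pd.DataFrame([[2, 1, 1], [0, 3, 1], [1, 0, 3]],
                              index=list("abc"), columns=["t1", "t2", "t3"])
        out = microqc.impute_zeros(counts)
        # fractions: a=(.5,.25,.25) b=(0,.75,.25) c=(.25,0,.75)
        # min positive fractions per taxon: t1=.25, t2=.25, t3=.25
        np.testing.assert_allclose(out.loc["a"], [0.5, 0.25, 0.25])
        np.testing.assert_allclose(out.loc["b"], [0.25 / 1.25, 0.75 / 1.25, 0.25 / 1.25])
        np.testing.assert_allclose(out.loc["c"], [0.25 / 1.25, 0.25 / 1.25, 0.75 / 1.25])

    def test_all_zero_taxon_rejected(self):
        counts = pd.DataFrame({"t1": [0, 0], "t2": [5, 5]})
        with pytest.raises(ValueError, match="t1"):
            microqc.impute_zeros(counts)

    def test_clr_closed_form_and_closure(self, rng):
        row = pd.DataFrame([[0.5, 0.25, 0.25]])
        ln2 = np.log(2.0)
        np.testing.assert_allclose(microqc.clr(row).to_numpy()[0],
                                   [2 * ln2 / 3, -ln2 / 3, -ln2 / 3], atol=1e-12)
        rel = pd.DataFrame(rng.dirichlet(np.ones(6), size=10))
        np.testing.assert_allclose(microqc.clr(rel).sum(axis=1), 0, atol=1e-12)
        with pytest.raises(ValueError, match="non-positive"):
            microqc.clr(pd.DataFrame([[0.0, 1.0]]))


class TestFiltering:
    def _counts(self, samples, rng, n_taxa=4):
        return pd.DataFrame(
            rng.integers(1, 100, (len(samples), n_taxa)),
            index=samples.index, columns=[f"t{i}" for i in range(n_taxa)])

    def test_coverage_boundaries_inclusive(self, rng):
        samples = _meta(4, rng)
        samples["amplicon"] = ["V3V4", "V3V4", "V1V2", "V1V2"]
        samples["coverage"] = [5_000, 4_999, 9_999, 10_000]
        counts = self._counts(samples, rng)
        kept, meta = microqc.filter_libraries_and_taxa(counts, samples)
        assert list(kept.index) == ["lib0", "lib3"]

    def test_abundance_filter_any_stratum(self, rng):
        samples = _meta(12, rng)
        samples["location"] = ["ileum"] * 6 + ["rectum"] * 6
        counts = pd.DataFrame(1000, index=samples.index,
                              columns=[f"t{i}" for i in range(5)])
        # t3 low in one stratum only, t4 low in both
        counts.loc[samples["location"] == "ileum", "t3"] = 0
        counts["t4"] = 0
        counts.iloc[0, 4] = 1
        kept, _ = microqc.filter_libraries_and_taxa(counts, samples)
        assert list(kept.columns) == ["t0", "t1", "t2"]
        kept_all, _ = microqc.filter_libraries_and_taxa(
            counts, samples, abundance_filter_mode="all")
        assert "t3" in kept_all.columns and "t4" not in kept_all.columns

    def test_contaminants_dropped_and_fixed_point(self, small_data):
        counts, samples = small_data["counts"], small_data["samples"]
        report = g.detect_contaminants(counts, samples,
                                       small_data["covariates"],
                                       set(small_data["truth"].gut_taxa))
        kept, meta = microqc.filter_libraries_and_taxa(counts, samples, report)
        assert not (set(kept.columns) & report.contaminants)
        again, _ = microqc.filter_libraries_and_taxa(kept, meta)
        assert list(again.columns) == list(kept.columns)
        assert list(again.index) == list(kept.index)

    def test_empty_output_rejected(self, rng):
        samples = _meta(3, rng)
        samples["coverage"] = 100
        with pytest.raises(ValueError, match="no data"):
            microqc.filter_libraries_and_taxa(self._counts(samples, rng), samples)


class TestContaminantScreen:
    def test_replicate_identical_taxon_scores_r_one(self, rng):
        # taxon counts identical across each replicate pair -> r = 1
        n_pairs = 12
        rows = []
        meta_rows = []
        for p in range(n_pairs):
            val = int(rng.integers(50, 5000))
            other = rng.integers(100, 1000, 2)  # whole profile fixed per pair
            for rep in range(2):
                rows.append([val, *other])
                meta_rows.append(dict(
                    library_id=f"p{p}_{rep}", individual_id=f"i{p}",
                    location="ileum", amplicon="V1V2", run_batch=f"run{p % 2}",
                    collection_date=f"d{p % 3}",
                    coverage=val + int(other.sum()),
                    replicate_group=f"g{p}", negative_control=False))
        samples = pd.DataFrame(meta_rows).set_index("library_id")
        counts = pd.DataFrame(rows, index=samples.index,
                              columns=["stable", "x1", "x2"])
        cov = pd.DataFrame(
            {"age": 50.0, "sex": 0, "bmi": 25.0, "smoking": 0},
            index=pd.Index([f"i{p}" for p in range(n_pairs)]))
        cov["age"] += rng.standard_normal(n_pairs)
        cov["bmi"] += rng.standard_normal(n_pairs)
        report = g.detect_contaminants(counts, samples, cov, {"stable"})
        row = report.frame.loc["stable"]
        assert row["replicate_r"] > 0.99
        assert not row["R2"] and not row["R3"]

    def test_no_replicates_rules_not_evaluable(self):
        cfg = g.SynthConfig(n_individuals=20, n_taxa=25,
                            n_contaminants_per_mechanism=2,
                            n_replicated_pairs=0, seed=5)
        counts, samples, truth = g.synthdata.simulate_microbiome(cfg)
        gly = g.synthdata.simulate_glycome(cfg, counts, samples)
        cov, _ = g.synthdata.simulate_covariates_and_prs(cfg, gly)
        report = g.detect_contaminants(counts, samples, cov,
                                       set(truth.gut_taxa))
        assert "R2" not in report.rules_evaluated
        assert not report.flagged_by("R2") and not report.flagged_by("R3")

    def test_missing_covariate_rejected(self, small_data):
        cov = small_data["covariates"].drop(columns=["bmi"])
        with pytest.raises(ValueError, match="bmi"):
            g.detect_contaminants(small_data["counts"], small_data["samples"],
                                  cov, set())

    def test_verdict_iff_any_rule(self, small_data):
        report = g.detect_contaminants(
            small_data["counts"], small_data["samples"],
            small_data["covariates"], set(small_data["truth"].gut_taxa))
        f = report.frame
        assert (f["verdict"] == f[["R1", "R2", "R3", "R4"]].any(axis=1)).all()

    def test_null_simulation_r1_false_positive_rate(self):
        flagged, total = 0, 0
        for seed in range(5):
            cfg = g.SynthConfig(n_individuals=60, n_taxa=60,
                                n_contaminants_per_mechanism=0,
                                n_replicated_pairs=10, seed=seed)
            counts, samples, truth = g.synthdata.simulate_microbiome(cfg)
            gly = g.synthdata.simulate_glycome(cfg, counts, samples)
            cov, _ = g.synthdata.simulate_covariates_and_prs(cfg, gly)
            rep = g.detect_contaminants(counts, samples, cov,
                                        set(truth.gut_taxa))
            flagged += len(rep.flagged_by("R1"))
            total += cfg.n_taxa
        assert flagged / total <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / total)


class TestBatchCorrect:
    def test_noop_on_unstructured_data(self, rng):
        samples = _meta(180, rng, n_ind=60)
        clrm = pd.DataFrame(rng.standard_normal((180, 5)), index=samples.index)
        clrm = clrm.sub(clrm.mean(axis=1), axis=0)
        out = microqc.batch_correct(clrm, samples)
        # fitted group means are pure noise ~ sd/sqrt(group size)
        rms = float(np.sqrt(((out - clrm) ** 2).mean().mean()))
        assert rms < 3 * np.sqrt(12 / 180)

    def test_removes_planted_run_variance(self):
        cfg = g.SynthConfig(n_individuals=60, n_taxa=30,
                            n_contaminants_per_mechanism=0,
                            n_replicated_pairs=8, batch_effect_sd=1.0, seed=21)
        counts, samples, _ = g.synthdata.simulate_microbiome(cfg)
        clrm = microqc.clr(microqc.impute_zeros(counts))
        out = microqc.batch_correct(clrm, samples)
        runs = samples.loc[out.index, "run_batch"]
        fracs = []
        for c in out.columns:
            y = out[c]
            gm = y.groupby(runs).transform("mean")
            fracs.append(((gm - y.mean()) ** 2).sum() / ((y - y.mean()) ** 2).sum())
        assert np.mean(fracs) < 0.01

    def test_order_invariance(self, rng):
        samples = _meta(60, rng, n_ind=20)
        clrm = pd.DataFrame(rng.standard_normal((60, 4)), index=samples.index)
        out = microqc.batch_correct(clrm, samples)
        perm = rng.permutation(60)
        out_perm = microqc.batch_correct(clrm.iloc[perm], samples.iloc[perm])
        np.testing.assert_allclose(out_perm.loc[out.index], out, atol=1e-8)


class TestAveragingAndPca:
    def test_idempotent_and_symmetric(self, rng):
        samples = _meta(6, rng, n_ind=2)
        v = rng.standard_normal(4)
        clrm = pd.DataFrame([v, v, v, v, v, -v], index=samples.index)
        samples["individual_id"] = ["a"] * 3 + ["b"] * 3
        out = microqc.average_profiles(clrm, samples)
        np.testing.assert_allclose(out.loc["a"], v)
        np.testing.assert_allclose(out.loc["b"], v / 3)

    def test_hand_computed_mean(self, rng):
        samples = _meta(3, rng, n_ind=1)
        samples["individual_id"] = "a"
        clrm = pd.DataFrame([[1.0, 2.0], [3.0, 4.0], [5.0, 9.0]],
                            index=samples.index)
        out = microqc.average_profiles(clrm, samples)
        np.testing.assert_allclose(out.loc["a"], [3.0, 5.0])

    def test_pca_matches_oracle(self, rng):
        mat = pd.DataFrame(rng.standard_normal((10, 6)))
        scores, frac = microqc.microbial_pca(mat, k=4)
        Xc = mat.to_numpy() - mat.to_numpy().mean(axis=0)
        lam = np.linalg.eigvalsh(np.cov(Xc, rowvar=False))[::-1]
        np.testing.assert_allclose(frac, lam[:4] / lam.sum(), atol=1e-9)
        np.testing.assert_allclose(scores.var(ddof=1), lam[:4], atol=1e-9)
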