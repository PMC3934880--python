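"""Scale estimators: laboratory polyA+ percentages and TMM factors."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from bsnorm import (
    CountMatrix,
    RnaMeasurements,
    bio_scales,
    rebase_scales,
    sqrt_transform,
    tmm_content_scales,
    tmm_factors,
    tmm_pair_factor,
    tmm_reference,
)

from _oracles import random_count_matrix, tmm_factor_oracle


def _meas(rows):
    return RnaMeasurements(
        pd.DataFrame(rows, columns=["stage", "replicate", "total_ng", "polya_ng"])
    )


class TestBioScales:
    def test_percentage_ratio(self):
        m = _meas([("ref", "r1", 100, 2), ("B", "r1", 90, 2.7)])
        z = bio_scales(m, "ref")
        np.testing.assert_allclose(z.scales, [1.0, 1.5])
        assert z["ref"] == 1.0
        assert z.kind == "bio"

    def test_identical_measurements_give_unit_scales(self):
        m = _meas([(s, "r1", 80, 1.6) for s in ("a", "b", "c")])
        np.testing.assert_allclose(bio_scales(m, "a").scales, 1.0)

    def test_amounts_averaged_before_ratio(self):
        # mean-of-amounts: p = mean(2, 4)/mean(100, 100) = 3%, not mean(2%, 4%)
        m = _meas(
            [("ref", "r1", 100, 2), ("ref", "r2", 100, 4), ("B", "r1", 50, 3)]
        )
        z = bio_scales(m, "ref")
        np.testing.assert_allclose(z["B"], (3 / 50) / (3 / 100))

    def test_unit_invariance(self):
        rows = [("ref", "r1", 100, 2), ("B", "r1", 90, 2.7)]
        ng = bio_scales(_meas(rows), "ref")
        ug = bio_scales(
            _meas([(s, r, t / 1000, p / 1000) for s, r, t, p in rows]), "ref"
        )
        np.testing.assert_allclose(ng.scales, ug.scales)

    def test_zero_reference_polya_is_error(self):
        m = _meas([("ref", "r1", 100, 0), ("B", "r1", 90, 2.7)])
        with pytest.raises(ValueError, match="zero polyA"):
            bio_scales(m, "ref")

    def test_missing_reference_stage_is_error(self):
        with pytest.raises(ValueError, match="not measured"):
            bio_scales(_meas([("A", "r1", 1, 0.1)]), "Z")


class TestSqrtTransform:
    def test_definition_and_fixed_point(self):
        from bsnorm import ScaleSet

        z = ScaleSet(["a", "b"], [1.0, 2.25], kind="user", reference="a")
        np.testing.assert_allclose(sqrt_transform(z).scales, [1.0, 1.5])
        ones = ScaleSet(["a", "b"], [1.0, 1.0], kind="user")
        np.testing.assert_allclose(sqrt_transform(ones).scales, 1.0)

    def test_twice_is_fourth_root_with_provenance(self):
        from bsnorm import ScaleSet

        z = ScaleSet(["a", "b"], [1.0, 16.0], kind="user", reference="a")
        zz = sqrt_transform(sqrt_transform(z))
        np.testing.assert_allclose(zz.scales, [1.0, 2.0])
        assert zz.provenance.count("sqrt transform") == 2


class TestTmmReference:
    def test_nearest_to_mean_upper_quartile(self, rng):
        # engineer three samples whose 75th-percentile count fractions are
        # roughly (small, medium, large); medium must win
        cols = {
            "s1": [1] * 15 + [5] * 5,
            "s2": [1] * 15 + [10] * 5,
            "s3": [1] * 15 + [60] * 5,
        }
        cm = CountMatrix(pd.DataFrame(cols))
        f75 = {
            s: np.quantile(np.array(cols[s]) / sum(cols[s]), 0.75) for s in cols
        }
        mean75 = np.mean(list(f75.values()))
        expected = min(cols, key=lambda s: abs(f75[s] - mean75))
        assert tmm_reference(cm) == expected

    def test_tie_breaks_to_first_sample(self):
        cm = CountMatrix(pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]}))
        assert tmm_reference(cm) == "s1"

    def test_single_sample_is_error(self):
        with pytest.raises(ValueError, match=">=2 samples"):
            tmm_reference(CountMatrix(pd.DataFrame({"s1": [1, 2]})))

    def test_zero_library_is_error(self):
        cm = CountMatrix(pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}))
        with pytest.raises(ValueError, match="zero library"):
            tmm_reference(cm)


class TestTmmPairFactor:
    def test_identity_is_exactly_one(self, rng):
        df = random_count_matrix(rng, 50, 2)
        df["s2"] = df["s1"]
        cm = CountMatrix(df)
        assert tmm_pair_factor(cm, "s2", "s1") == 1.0

    def test_pure_depth_change_is_exactly_one(self, rng):
        df = random_count_matrix(rng, 50, 1)
        df["s2"] = 2 * df["s1"]
        cm = CountMatrix(df)
        assert tmm_pair_factor(cm, "s2", "s1") == 1.0

    def test_matches_bruteforce_oracle_on_asymmetric_instance(self, rng):
        # 20 genes, 2 genes 8-fold up in the sample, rest equal fractions
        base = rng.integers(50, 500, 20)
        df = pd.DataFrame(
            {"ref": base, "s": base}, index=[f"g{i}" for i in range(20)]
        )
        df.loc[["g3", "g7"], "s"] *= 8
        cm = CountMatrix(df)
        got = tmm_pair_factor(cm, "s", "ref")
        want = tmm_factor_oracle(df, "s", "ref")
        assert got == pytest.approx(want, abs=1e-12)
        assert got != 1.0

    def test_depth_rescaling_invariance(self, rng):
        # M, A and the trim set are depth-free, so the unweighted factor is
        # exactly invariant; the precision weights carry a library-size
        # term, so the weighted factor is only asymptotically invariant
        df = random_count_matrix(rng, 80, 2)
        df2 = df.copy()
        df2["s2"] = df2["s2"] * 7
        f1 = tmm_pair_factor(CountMatrix(df), "s2", "s1", weighted=False)
        f2 = tmm_pair_factor(CountMatrix(df2), "s2", "s1", weighted=False)
        assert f1 == pytest.approx(f2, rel=1e-9)
        w1 = tmm_pair_factor(CountMatrix(df), "s2", "s1")
        w2 = tmm_pair_factor(CountMatrix(df2), "s2", "s1")
        assert w1 == pytest.approx(w2, rel=0.02)

    def test_antisymmetry_on_symmetric_instance(self):
        # mirror-symmetric M distribution so the trim sets mirror exactly
        n = 40
        base = np.full(n, 100)
        up = np.ones(n)
        up[:5] = 4.0
        up[-5:] = 0.25
        df = pd.DataFrame(
            {"a": base, "b": (base * up).astype(int)},
            index=[f"g{i}" for i in range(n)],
        )
        cm = CountMatrix(df)
        prod = tmm_pair_factor(cm, "a", "b") * tmm_pair_factor(cm, "b", "a")
        assert prod == pytest.approx(1.0, rel=1e-9)

    def test_disjoint_support_falls_back_to_one(self):
        df = pd.DataFrame({"a": [5, 0], "b": [0, 7]}, index=["g1", "g2"])
        with pytest.warns(UserWarning, match="no gene expressed in both"):
            assert tmm_pair_factor(CountMatrix(df), "a", "b") == 1.0


class TestTmmFactors:
    def test_identical_samples_all_one(self):
        df = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3], "c": [5, 10, 3]})
        np.testing.assert_allclose(tmm_factors(CountMatrix(df)).scales, 1.0)

    def test_geometric_mean_is_one(self, rng):
        df = random_count_matrix(rng, 200, 4)
        z = tmm_factors(CountMatrix(df))
        assert np.exp(np.mean(np.log(z.scales))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_oracle_pairwise_then_renormalized(self, rng):
        df = random_count_matrix(rng, 120, 4)
        cm = CountMatrix(df)
        ref = tmm_reference(cm)
        raw = np.array([tmm_factor_oracle(df, s, ref) for s in df.columns])
        want = raw / np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(tmm_factors(cm).scales, want, atol=1e-12)

    def test_agrees_with_edger_calcnormfactors(self, rng, tmp_path):
        # independent cross-check against the reference implementation
        df = random_count_matrix(rng, 300, 4, depth=5e5)
        df.to_csv(tmp_path / "c.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim(commandArgs(TRUE)[1], row.names=1))
            cat(sprintf("%.12f", calcNormFactors(x)), sep="\\n")
            """
        )
        (tmp_path / "f.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "f.R"), str(tmp_path / "c.tsv")],
            capture_output=True, text=True, check=True,
        )
        r_factors = np.array([float(x) for x in out.stdout.split()])
        np.testing.assert_allclose(
            tmm_factors(CountMatrix(df)).scales, r_factors, rtol=1e-9
        )


class TestRebaseAndContent:
    def test_rebase_definition(self):
        from bsnorm import ScaleSet

        z = ScaleSet(["a", "b"], [0.5, 2.0], kind="tmm",
                     convention="geometric-mean-1")
        zr = rebase_scales(z, "a")
        np.testing.assert_allclose(zr.scales, [1.0, 4.0])
        assert zr.convention == "relative-to-reference"

    def test_rebase_idempotent_and_composable(self):
        from bsnorm import ScaleSet

        z = ScaleSet(["a", "b", "c"], [1.0, 2.0, 4.0], kind="user", reference="a")
        np.testing.assert_allclose(rebase_scales(z, "a").scales, z.scales)
        twice = rebase_scales(rebase_scales(z, "b"), "c")
        once = rebase_scales(z, "c")
        np.testing.assert_allclose(twice.scales, once.scales)

    def test_content_scales_invert_factor_orientation(self, rng):
        # sample with decayed content must get factor > 1 but content < 1
        base = rng.lognormal(5, 1, 400)
        t2 = base.copy()
        t2[:120] /= 4
        c1 = rng.poisson(1e6 * base / base.sum())
        c2 = rng.poisson(1e6 * t2 / t2.sum())
        cm = CountMatrix(pd.DataFrame({"a": c1, "b": c2}))
        factors = tmm_factors(cm)
        content = tmm_content_scales(cm, rebase_to="a")
        assert factors["b"] / factors["a"] > 1.0
        assert content["b"] < 1.0
        assert content["a"] == 1.0
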