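"""Signature scoring: reference statistics, clamped z-scores, and the three
per-sample scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hypoxikit import (
    GeneSignature,
    NormalizedMatrix,
    aggregate_scores,
    build_reference,
    hypoxia_score,
    read_signature,
    rle_normalize,
    score_signatures,
    simple_signature_score,
    zscore_matrix,
    zsum_score,
)
from conftest import make_count_matrix


def make_nm(values_by_sample, gene_ids=None, sample_type="cdx"):
    values = pd.DataFrame(values_by_sample, dtype=float)
    values.index = gene_ids or [f"g{i}" for i in range(len(values))]
    ann = pd.DataFrame(
        {
            "sample_id": list(values.columns),
            "sample_type": sample_type,
            "model_id": [f"m{i}" for i in range(len(values.columns))],
            "replicate": 1,
            "group": "",
        }
    ).set_index("sample_id")
    sf = pd.Series(1.0, index=values.columns, name="size_factor")
    return NormalizedMatrix(values=values, size_factors=sf, annotations=ann)


class TestReference:
    def test_two_point_statistics(self):
        nm = make_nm({"s1": [4.0], "s2": [6.0]})
        ref = build_reference(nm, ["s1", "s2"])
        assert ref.mean.iloc[0] == pytest.approx(5.0)
        assert ref.sd.iloc[0] == pytest.approx(np.sqrt(2.0))
        assert ref.median.iloc[0] == pytest.approx(5.0)

    def test_median_matches_brute_force_sort(self):
        rng = np.random.default_rng(7)
        vals = {f"s{i}": rng.integers(1, 100, size=6) for i in range(5)}
        nm = make_nm(vals)
        ref = build_reference(nm, list(nm.sample_ids))
        arr = nm.values.to_numpy()
        for g in range(arr.shape[0]):
            row = sorted(arr[g])
            mid = len(row) // 2
            expected = row[mid] if len(row) % 2 else (row[mid - 1] + row[mid]) / 2
            assert ref.median.iloc[g] == pytest.approx(expected)

    def test_single_reference_sample_rejected(self):
        nm = make_nm({"s1": [4.0], "s2": [6.0]})
        with pytest.raises(ValueError):
            build_reference(nm, ["s1"])

    def test_default_reference_is_xenografts(self):
        nm = make_nm({"c": [1.0], "x1": [2.0], "x2": [4.0]})
        ann = nm.annotations.copy()
        ann["sample_type"] = ["cell", "cdx", "pdx"]
        nm = NormalizedMatrix(nm.values, nm.size_factors, ann)
        ref = build_reference(nm)
        assert set(ref.sample_ids) == {"x1", "x2"}
        assert ref.mean.iloc[0] == pytest.approx(3.0)


class TestZScores:
    def test_centring_unit_and_clamp(self):
        # reference s1/s2: mean 10, sd sqrt(2) per gene row constructed below
        nm = make_nm(
            {
                "s1": [9.0, 9.0, 9.0],
                "s2": [11.0, 11.0, 11.0],
                "probe": [10.0, 10.0 + 10 * np.sqrt(2), 10.0 - np.sqrt(2)],
            }
        )
        ref = build_reference(nm, ["s1", "s2"])
        z = zscore_matrix(nm, ref)
        assert z.loc["g0", "probe"] == pytest.approx(0.0)  # value at mean
        assert z.loc["g1", "probe"] == pytest.approx(3.0)  # +10 sd clamps to 3
        assert z.loc["g2", "probe"] == pytest.approx(-1.0)  # one sd below

    def test_zero_sd_gene_scores_zero(self):
        nm = make_nm({"s1": [5.0], "s2": [5.0], "probe": [99.0]})
        ref = build_reference(nm, ["s1", "s2"])
        z = zscore_matrix(nm, ref)
        assert z.loc["g0", "probe"] == 0.0


class TestZsumScore:
    def test_cancellation(self):
        z = pd.DataFrame({"s": [1.0, -1.0, 0.0]}, index=["a", "b", "c"])
        sig = GeneSignature("sig", ("a", "b", "c"))
        assert zsum_score(z, sig)["s"] == pytest.approx(0.0)

    def test_upper_bound_3n(self):
        genes = tuple(f"g{i}" for i in range(15))
        z = pd.DataFrame({"s": [3.0] * 15}, index=genes)
        assert zsum_score(z, GeneSignature("sig", genes))["s"] == pytest.approx(45.0)

    def test_matches_element_wise_oracle(self):
        rng = np.random.default_rng(11)
        vals = {f"s{i}": rng.uniform(1, 50, size=20) for i in range(6)}
        nm = make_nm(vals)
        ref = build_reference(nm, list(nm.sample_ids))
        genes = tuple(rng.choice(nm.gene_ids, size=5, replace=False))
        sig = GeneSignature("rand", genes)
        got = zsum_score(zscore_matrix(nm, ref), sig)
        for s in nm.sample_ids:
            total = 0.0
            for g in genes:
                z = (nm.values.loc[g, s] - ref.mean[g]) / ref.sd[g]
                total += min(3.0, max(-3.0, z))
            assert got[s] == pytest.approx(total)

    def test_absent_signature_errors(self):
        z = pd.DataFrame({"s": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="ghost"):
            zsum_score(z, GeneSignature("ghost", ("nope",)))


class TestSimpleAndHypoxiaScore:
    def _nm_with_probe(self, probe_vals, n_genes):
        rng = np.random.default_rng(3)
        data = {f"s{i}": rng.uniform(10, 20, size=n_genes) for i in range(4)}
        data["probe"] = probe_vals
        return make_nm(data)

    def test_all_above_and_below_bounds(self):
        n = 10
        nm = self._nm_with_probe([100.0] * n, n)
        ref = build_reference(nm, [s for s in nm.sample_ids if s != "probe"])
        sig = GeneSignature("sig", tuple(nm.gene_ids))
        assert simple_signature_score(nm, ref, sig)["probe"] == n
        assert hypoxia_score(nm, ref, sig)["probe"] == pytest.approx(1.0)
        nm_lo = self._nm_with_probe([0.5] * n, n)
        ref_lo = build_reference(nm_lo, [s for s in nm_lo.sample_ids if s != "probe"])
        assert simple_signature_score(nm_lo, ref_lo, sig)["probe"] == -n
        assert hypoxia_score(nm_lo, ref_lo, sig)["probe"] == pytest.approx(0.0)

    def test_ties_score_zero(self):
        nm = make_nm({"s1": [4.0, 4.0], "s2": [6.0, 6.0], "probe": [5.0, 5.0]})
        ref = build_reference(nm, ["s1", "s2"])
        sig = GeneSignature("sig", ("g0", "g1"))
        assert simple_signature_score(nm, ref, sig)["probe"] == 0
        assert hypoxia_score(nm, ref, sig)["probe"] == pytest.approx(0.0)

    def test_mixed_counting(self):
        # 7 of 10 genes above the reference median, 3 below -> +4 and 0.7
        probe = [100.0] * 7 + [0.5] * 3
        nm = self._nm_with_probe(probe, 10)
        ref = build_reference(nm, [s for s in nm.sample_ids if s != "probe"])
        sig = GeneSignature("sig", tuple(nm.gene_ids))
        assert simple_signature_score(nm, ref, sig)["probe"] == 4
        assert hypoxia_score(nm, ref, sig)["probe"] == pytest.approx(0.7)

    @given(st.integers(0, 2**31 - 1))
    def test_hypoxia_score_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        vals = {f"s{i}": rng.uniform(0.1, 100, size=8) for i in range(4)}
        nm = make_nm(vals)
        ref = build_reference(nm, list(nm.sample_ids))
        sig = GeneSignature("sig", tuple(nm.gene_ids))
        hs = hypoxia_score(nm, ref, sig)
        assert ((hs >= 0) & (hs <= 1)).all()


class TestProperties:
    def test_monotonicity_in_gene_expression(self):
        rng = np.random.default_rng(5)
        vals = {f"s{i}": rng.uniform(1, 50, size=6) for i in range(5)}
        nm = make_nm(vals)
        sig = GeneSignature("sig", tuple(nm.gene_ids[:4]))
        ref = build_reference(nm, list(nm.sample_ids))
        before = (
            zsum_score(zscore_matrix(nm, ref), sig)["s0"],
            simple_signature_score(nm, ref, sig)["s0"],
            hypoxia_score(nm, ref, sig)["s0"],
        )
        bumped = nm.values.copy()
        bumped.loc["g1", "s0"] += 100.0
        nm2 = NormalizedMatrix(bumped, nm.size_factors, nm.annotations)
        after = (
            zsum_score(zscore_matrix(nm2, ref), sig)["s0"],
            simple_signature_score(nm2, ref, sig)["s0"],
            hypoxia_score(nm2, ref, sig)["s0"],
        )
        assert all(a >= b for a, b in zip(after, before))

    def test_clamp_saturation(self):
        nm = make_nm({"s1": [9.0], "s2": [11.0], "probe": [1000.0]})
        ref = build_reference(nm, ["s1", "s2"])
        sig = GeneSignature("sig", ("g0",))
        z1 = zsum_score(zscore_matrix(nm, ref), sig)["probe"]
        nm.values.loc["g0", "probe"] = 1.0e6
        z2 = zsum_score(zscore_matrix(nm, ref), sig)["probe"]
        assert z1 == z2 == pytest.approx(3.0)

    def test_invariance_to_common_size_factor_rescaling(self, toy_matrix):
        nm = rle_normalize(toy_matrix)
        sig = GeneSignature("sig", tuple(nm.gene_ids))
        ref = build_reference(nm, list(nm.sample_ids))
        base = hypoxia_score(nm, ref, sig)
        scaled = NormalizedMatrix(nm.values / 7.0, nm.size_factors * 7.0, nm.annotations)
        ref2 = build_reference(scaled, list(scaled.sample_ids))
        pd.testing.assert_series_equal(base, hypoxia_score(scaled, ref2, sig))


class TestAggregation:
    def _table(self, scores_by_model):
        rows = []
        for model, scores in scores_by_model.items():
            for i, s in enumerate(scores):
                rows.append(
                    {
                        "sample_id": f"{model}_{i}",
                        "model_id": model,
                        "signature": "sig",
                        "zsum_score": 0.0,
                        "simple_score": 0,
                        "hypoxia_score": s,
                        "n_genes_used": 10,
                    }
                )
        return pd.DataFrame(rows)

    def test_mean_and_sem(self):
        per_model, _ = aggregate_scores(self._table({"m1": [0.2, 0.4, 0.6]}))
        row = per_model.iloc[0]
        assert row["mean"] == pytest.approx(0.4)
        assert row["sem"] == pytest.approx(0.2 / np.sqrt(3), abs=1e-6)

    def test_single_replicate_flagged(self):
        per_model, _ = aggregate_scores(self._table({"m1": [0.3]}))
        row = per_model.iloc[0]
        assert row["mean"] == pytest.approx(0.3)
        assert row["sem"] == 0.0
        assert row["single_replicate"]

    def test_cross_signature_mean_of_means(self):
        table = pd.concat(
            [
                self._table({"m1": [0.3]}).assign(signature="sigA"),
                self._table({"m1": [0.5]}).assign(signature="sigB"),
            ]
        )
        _, cross = aggregate_scores(table)
        assert cross.loc[cross.model_id == "m1", "mean_score"].iloc[0] == pytest.approx(0.4)


def test_signature_file_reading(tmp_path):
    path = tmp_path / "sig.txt"
    path.write_text("# hypoxia genes\nVEGFA\nCA9\n\nSLC2A1\n")
    sig = read_signature(path, name="toy")
    assert sig.genes == ("VEGFA", "CA9", "SLC2A1")
    with pytest.raises(ValueError, match="duplicate"):
        GeneSignature("bad", ("A", "A"))
    with pytest.raises(ValueError, match="empty"):
        GeneSignature("bad", ())


def test_score_signatures_table_shape(toy_matrix):
    nm = rle_normalize(toy_matrix)
    sigs = [GeneSignature("a", ("g0", "g1")), GeneSignature("b", ("g2",))]
    ref = build_reference(nm, list(nm.sample_ids))
    table = score_signatures(nm, sigs, ref=ref)
    assert len(table) == len(nm.sample_ids) * 2
    assert set(table.columns) >= {
        "sample_id", "model_id", "signature",
        "zsum_score", "simple_score", "hypoxia_score", "n_genes_used",
    }
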