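import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbpipe import (
    FeatureTable,
    build_group_index,
    group_mean,
    group_sub_pca,
    group_sum,
    parse_taxonomy,
)

# ---------------------------------------------------------------------------
# independent oracles


def dict_accumulation_oracle(table, index, how):
    """Brute-force per-sample dictionary accumulation of group values."""
    out = {key: {} for key in index.groups}
    for key, members in index.groups.items():
        for sample in table.sample_ids:
            vals = [table.data.loc[sample, f] for f in members]
            out[key][sample] = sum(vals) / (len(vals) if how == "mean" else 1)
    return pd.DataFrame(out).loc[table.sample_ids]


def eigh_subpca_oracle(block):
    """Dense eigendecomposition of the scatter matrix: k and projections."""
    centered = block - block.mean(axis=0, keepdims=True)
    scatter = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(scatter)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    ratios = eigvals / eigvals.sum()
    k = int(np.searchsorted(np.cumsum(ratios), 0.5 - 1e-12) + 1)
    proj = []
    for j in range(k):
        v = eigvecs[:, j]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        proj.append(centered @ v)
    return k, np.column_stack(proj)


# ---------------------------------------------------------------------------
# parsing


class TestParseTaxonomy:
    def test_full_greengenes_string(self):
        path = parse_taxonomy(
            "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
            "f__Lactobacillaceae; g__Lactobacillus; s__"
        )
        assert path.depth == 7
        assert path.name_at(6) == "Lactobacillus"
        assert path.name_at(7) == ""

    def test_prefixes_imputed_positionally(self):
        path = parse_taxonomy("Bacteria;Firmicutes")
        assert path.depth == 2
        assert path.ranks == (("k", "Bacteria"), ("p", "Firmicutes"))

    def test_silva_prefixes_normalized(self):
        path = parse_taxonomy("D_0__Bacteria;D_1__Firmicutes")
        assert path.ranks == (("k", "Bacteria"), ("p", "Firmicutes"))

    def test_out_of_order_prefixes_raise(self):
        with pytest.raises(ValueError, match="out-of-order"):
            parse_taxonomy("g__X; k__Y")

    def test_empty_string_raises(self):
        with pytest.raises(ValueError, match="empty"):
            parse_taxonomy("   ")


# ---------------------------------------------------------------------------
# group index


class TestGroupIndex:
    def test_partition_at_genus(self, toy_taxonomy):
        taxa = {f: parse_taxonomy(s) for f, s in toy_taxonomy.items()}
        index = build_group_index(taxa, "genus")
        assert index.n_groups == 3
        sizes = sorted(len(m) for m in index.groups.values())
        assert sizes == [1, 2, 3]
        # partition: every feature in exactly one group
        assert sorted(index.feature_ids()) == sorted(taxa)

    def test_single_group_at_order(self):
        taxa = {
            f"f{i}": parse_taxonomy("k__B; p__F; c__C; o__Clostridiales; f__X; g__Y")
            for i in range(4)
        }
        index = build_group_index(taxa, "order")
        assert index.n_groups == 1
        assert len(next(iter(index.groups.values()))) == 4

    def test_unresolved_feature_falls_back_to_ancestor_key(self):
        taxa = {
            "u1": parse_taxonomy("k__B; p__F; c__C; o__O; f__Ruminococcaceae; g__"),
            "r1": parse_taxonomy("k__B; p__F; c__C; o__O; f__Ruminococcaceae; g__X"),
        }
        index = build_group_index(taxa, "genus")
        unresolved_key = "k__B;p__F;c__C;o__O;f__Ruminococcaceae;g__"
        assert index.groups[unresolved_key] == ["u1"]
        assert unresolved_key in index.unresolved
        assert index.groups["k__B;p__F;c__C;o__O;f__Ruminococcaceae;g__X"] == ["r1"]


# ---------------------------------------------------------------------------
# sum / mean merging


@pytest.mark.parametrize("how,fn", [("sum", group_sum), ("mean", group_mean)])
def test_sum_and_mean_match_dictionary_oracle(how, fn):
    rng = np.random.default_rng(11)
    taxa = {
        f"f{i}": parse_taxonomy(f"k__B; p__P; c__C; o__O; f__F; g__G{i % 2}")
        for i in range(5)
    }
    table = FeatureTable(
        pd.DataFrame(
            rng.integers(0, 20, size=(6, 5)),
            index=[f"s{i}" for i in range(6)],
            columns=list(taxa),
        )
    )
    index = build_group_index(taxa, "genus")
    result = fn(table, index)
    expected = dict_accumulation_oracle(table, index, how)
    pd.testing.assert_frame_equal(
        result.data.sort_index(axis=1).astype(float),
        expected.sort_index(axis=1).astype(float),
        check_exact=(how == "sum"),
    )


def test_group_sum_conserves_per_sample_totals(toy_table, toy_taxonomy):
    taxa = {f: parse_taxonomy(s) for f, s in toy_taxonomy.items()}
    for level in ("order", "family", "genus"):
        merged = group_sum(toy_table, build_group_index(taxa, level))
        np.testing.assert_array_equal(
            merged.data.sum(axis=1).to_numpy(), toy_table.data.sum(axis=1).to_numpy()
        )


def test_group_mean_is_sum_over_size(toy_table, toy_taxonomy):
    taxa = {f: parse_taxonomy(s) for f, s in toy_taxonomy.items()}
    index = build_group_index(taxa, "genus")
    s = group_sum(toy_table, index)
    m = group_mean(toy_table, index)
    for key, members in index.groups.items():
        np.testing.assert_allclose(m.data[key], s.data[key] / len(members))


def test_singleton_group_column_is_identity(toy_table, toy_taxonomy):
    taxa = {f: parse_taxonomy(s) for f, s in toy_taxonomy.items()}
    index = build_group_index(taxa, "genus")
    merged = group_sum(toy_table, index)
    key = next(k for k, v in index.groups.items() if len(v) == 1)
    (member,) = index.groups[key]
    np.testing.assert_array_equal(merged.data[key], toy_table.data[member])


def test_missing_feature_in_index_raises(toy_table, toy_taxonomy):
    taxa = {f: parse_taxonomy(s) for f, s in toy_taxonomy.items()}
    taxa["ghost"] = parse_taxonomy("k__B; p__P; c__C; o__O; f__F; g__Z")
    index = build_group_index(taxa, "genus")
    with pytest.raises(ValueError, match="ghost"):
        group_sum(toy_table, index)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_sum_conservation_property(seed):
    """Per-sample totals are invariant under sum-merging at any level."""
    rng = np.random.default_rng(seed)
    n_feat = int(rng.integers(2, 10))
    taxa = {
        f"f{i}": parse_taxonomy(
            f"k__B; p__P; c__C; o__O{rng.integers(2)}; f__F{rng.integers(3)}; "
            f"g__G{rng.integers(4)}"
        )
        for i in range(n_feat)
    }
    table = FeatureTable(
        pd.DataFrame(
            rng.integers(0, 100, size=(3, n_feat)),
            index=["a", "b", "c"],
            columns=list(taxa),
        )
    )
    merged = group_sum(table, build_group_index(taxa, "genus"))
    np.testing.assert_array_equal(
        merged.data.sum(axis=1).to_numpy(), table.data.sum(axis=1).to_numpy()
    )


# ---------------------------------------------------------------------------
# sub-PCA merging


def _table_from_groups(columns: dict[str, np.ndarray], genus_of: dict[str, str]):
    taxa = {
        f: parse_taxonomy(f"k__B; p__P; c__C; o__O; f__F; g__{genus_of[f]}")
        for f in columns
    }
    n = len(next(iter(columns.values())))
    table = FeatureTable(
        pd.DataFrame(columns, index=[f"s{i}" for i in range(n)]), stage="scaled"
    )
    return table, build_group_index(taxa, "genus")


def test_singleton_group_is_centered_column():
    v = np.array([1.0, 4.0, 7.0, 10.0])
    table, index = _table_from_groups({"f1": v}, {"f1": "A"})
    out = group_sub_pca(table, index)
    assert out.data.shape == (4, 1)
    np.testing.assert_allclose(out.data.iloc[:, 0].to_numpy(), v - v.mean(), atol=1e-12)


def test_perfectly_correlated_pair_keeps_one_component():
    rng = np.random.default_rng(3)
    f1 = rng.normal(size=30)
    table, index = _table_from_groups({"f1": f1, "f2": 2 * f1}, {"f1": "A", "f2": "A"})
    out = group_sub_pca(table, index)
    assert out.data.shape[1] == 1  # one PC explains 100% >= 50%


def test_independent_equal_variance_columns_keep_two_components():
    rng = np.random.default_rng(5)
    cols = {f"f{i}": rng.normal(size=4000) for i in range(4)}
    genus_of = {f: "A" for f in cols}
    table, index = _table_from_groups(cols, genus_of)
    out = group_sub_pca(table, index)
    block = np.column_stack(list(cols.values()))
    k_oracle, proj_oracle = eigh_subpca_oracle(block)
    assert k_oracle == 2  # each PC ~25%, cumulative crosses 0.5 at k=2
    assert out.data.shape[1] == k_oracle
    np.testing.assert_allclose(out.data.to_numpy(), proj_oracle, atol=1e-8)


def test_projections_zero_mean_and_nonincreasing_variance(small_dataset):
    from mbpipe import build_group_index as bgi, log_scale, parse_taxonomy as pt

    table, taxonomy, _ = small_dataset
    scaled = log_scale(table)
    index = bgi({f: pt(s) for f, s in taxonomy.items()}, "genus")
    out = group_sub_pca(scaled, index)
    for key, members in index.groups.items():
        cols = [c for c in out.data.columns if c.startswith(key + "|")]
        assert 1 <= len(cols) <= len(members)
        block = out.data[cols].to_numpy()
        np.testing.assert_allclose(block.mean(axis=0), 0.0, atol=1e-9)
        variances = block.var(axis=0)
        assert (np.diff(variances) <= 1e-9).all()


def test_sub_pca_is_bit_stable(small_dataset):
    from mbpipe import build_group_index as bgi, log_scale, parse_taxonomy as pt

    table, taxonomy, _ = small_dataset
    scaled = log_scale(table)
    index = bgi({f: pt(s) for f, s in taxonomy.items()}, "family")
    a = group_sub_pca(scaled, index)
    b = group_sub_pca(scaled, index)
    pd.testing.assert_frame_equal(a.data, b.data, check_exact=True)


def test_zero_variance_group_emits_zero_column():
    const = np.full(5, 3.0)
    table, index = _table_from_groups(
        {"f1": const, "f2": const}, {"f1": "A", "f2": "A"}
    )
    out = group_sub_pca(table, index)
    assert out.data.shape[1] == 1
    np.testing.assert_array_equal(out.data.iloc[:, 0].to_numpy(), np.zeros(5))
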