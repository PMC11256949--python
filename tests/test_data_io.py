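import numpy as np
import pytest

from perturbcycle.data_io import (
    DataError,
    ExpressionDataset,
    PerturbationKind,
    PerturbationRecord,
    SplitSpec,
    build_pairs,
    load_expression,
    preprocess,
    split_by_perturbation,
    write_expression,
)

from conftest import control_record, drug_record


# ---------------------------------------------------------------------------
# records and dataset invariants
# ---------------------------------------------------------------------------


def test_record_invariants():
    with pytest.raises(DataError):
        PerturbationRecord("s", "d1", PerturbationKind.DRUG)  # drug needs SMILES
    with pytest.raises(DataError):
        PerturbationRecord("s", "g1", PerturbationKind.GENETIC)  # needs target
    with pytest.raises(DataError):
        PerturbationRecord("s", "control", PerturbationKind.CONTROL, smiles="CC")
    with pytest.raises(DataError):
        PerturbationRecord("s", "d1", PerturbationKind.DRUG, smiles="CC", dose=-1.0)


def test_dataset_rejects_nonfinite():
    m = np.array([[1.0, np.nan]])
    with pytest.raises(DataError, match="row 0, column 1"):
        ExpressionDataset(m, [control_record()], ["g0", "g1"])


def test_dataset_rejects_misaligned():
    with pytest.raises(DataError):
        ExpressionDataset(np.zeros((2, 2)), [control_record()], ["g0", "g1"])
    with pytest.raises(DataError):
        ExpressionDataset(np.zeros((1, 2)), [control_record()], ["g0"])


def test_pairing_must_point_at_controls():
    recs = [control_record(0), drug_record(1)]
    with pytest.raises(DataError):
        ExpressionDataset(np.zeros((2, 1)), recs, ["g0"], pairing={1: 1})


# ---------------------------------------------------------------------------
# load / write round trips
# ---------------------------------------------------------------------------


def _toy_ds():
    matrix = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    records = [
        control_record(0),
        control_record(1),
        drug_record(2, pert="drugA", smiles="CC", dose=1.5),
    ]
    return ExpressionDataset(matrix, records, ["gene1", "gene2"])


def test_delimited_fixture_shape(tmp_path):
    # 3x2 delimited file with control/drugA labels
    p = tmp_path / "toy.csv"
    write_expression(_toy_ds(), p, format="delimited")
    ds = load_expression(p, format="delimited")
    assert ds.n_samples == 3
    assert ds.n_genes == 2
    assert ds.perturbation_ids() == ["drugA"]
    assert ds.gene_ids == ["gene1", "gene2"]


@pytest.mark.parametrize("fmt", ["delimited", "mtx", "h5ad"])
def test_round_trip(tmp_path, fmt):
    ds = _toy_ds()
    suffix = {"delimited": ".csv", "mtx": ".mtx", "h5ad": ".h5ad"}[fmt]
    p = tmp_path / f"toy{suffix}"
    write_expression(ds, p, format=fmt)
    back = load_expression(p, format=fmt)
    np.testing.assert_allclose(back.matrix, ds.matrix, atol=1e-12)
    assert back.gene_ids == ds.gene_ids
    for a, b in zip(back.records, ds.records):
        assert a == b


def test_delimited_integer_round_trip_bitwise(tmp_path):
    matrix = np.array([[1.0, 2.0], [3.0, 4.0]])
    ds = ExpressionDataset(matrix, [control_record(0), control_record(1)], ["a", "b"])
    p = tmp_path / "ints.csv"
    write_expression(ds, p, format="delimited")
    back = load_expression(p, format="delimited")
    np.testing.assert_array_equal(back.matrix, matrix)


def test_mtx_five_nonzeros(tmp_path):
    # hand-written triplet file; densified oracle built by hand
    p = tmp_path / "m.mtx"
    p.write_text(
        "%%MatrixMarket matrix coordinate real general\n"
        "3 4 5\n"
        "1 1 1.5\n"
        "1 3 2.0\n"
        "2 2 -1.0\n"
        "3 4 7.0\n"
        "3 1 0.5\n"
    )
    (tmp_path / "m_features.txt").write_text("g1\ng2\ng3\ng4\n")
    (tmp_path / "m_obs.csv").write_text(
        "sample_id,perturbation_id,kind\ns1,control,control\ns2,control,control\ns3,control,control\n"
    )
    ds = load_expression(p, format="mtx")
    oracle = np.zeros((3, 4))
    oracle[0, 0], oracle[0, 2], oracle[1, 1], oracle[2, 3], oracle[2, 0] = (
        1.5,
        2.0,
        -1.0,
        7.0,
        0.5,
    )
    np.testing.assert_array_equal(ds.matrix, oracle)
    assert (ds.matrix != 0).sum() == 5


def test_load_missing_metadata_column(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("sample_id,g1,g2\ns1,1.0,2.0\n")
    with pytest.raises(DataError, match="metadata"):
        load_expression(p, format="delimited")


def test_load_non_numeric_entry(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text(
        "sample_id,perturbation_id,kind,g1,g2\ns1,control,control,1.0,oops\n"
    )
    with pytest.raises(DataError, match="g2"):
        load_expression(p, format="delimited")


def test_tab_autodetect(tmp_path):
    p = tmp_path / "toy.tsv"
    p.write_text(
        "sample_id\tperturbation_id\tkind\tg1\tg2\ns1\tcontrol\tcontrol\t1.0\t2.0\n"
    )
    ds = load_expression(p, format="delimited")
    np.testing.assert_array_equal(ds.matrix, [[1.0, 2.0]])


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _multi_drug_ds(n_drugs, rng, per_drug=2, n_controls=3):
    records = [control_record(i) for i in range(n_controls)]
    for d in range(n_drugs):
        for k in range(per_drug):
            records.append(
                drug_record(1000 + d * per_drug + k, pert=f"drug{d:02d}", smiles="CC")
            )
    matrix = rng.normal(size=(len(records), 4))
    return ExpressionDataset(matrix, records, [f"g{i}" for i in range(4)])


def test_split_deterministic(rng):
    ds = _multi_drug_ds(10, rng)
    spec = SplitSpec(fractions=(0.8, 0.1, 0.1), seed=7)
    a = split_by_perturbation(ds, spec)
    b = split_by_perturbation(ds, spec)
    for x, y in zip(a, b):
        assert [r.sample_id for r in x.records] == [r.sample_id for r in y.records]
    assert len(a[0].perturbation_ids()) == 8
    assert len(a[1].perturbation_ids()) == 1
    assert len(a[2].perturbation_ids()) == 1


def test_split_all_train(rng):
    ds = _multi_drug_ds(5, rng)
    tr, va, te = split_by_perturbation(ds, SplitSpec(fractions=(1.0, 0.0, 0.0), seed=1))
    assert len(tr.perturbation_ids()) == 5
    assert len(va.perturbation_ids()) == 0
    assert len(te.perturbation_ids()) == 0


def test_split_matches_shuffle_oracle(rng):
    # independent oracle: shuffle the sorted drug list with the same seeded
    # generator and slice it
    ds = _multi_drug_ds(5, rng)
    seed = 11
    tr, va, te = split_by_perturbation(
        ds, SplitSpec(fractions=(0.6, 0.2, 0.2), seed=seed)
    )
    ids = sorted({f"drug{d:02d}" for d in range(5)})
    gen = np.random.default_rng(seed)
    shuffled = [ids[i] for i in gen.permutation(5)]
    assert sorted(tr.perturbation_ids()) == sorted(shuffled[:3])
    assert sorted(va.perturbation_ids()) == sorted(shuffled[3:4])
    assert sorted(te.perturbation_ids()) == sorted(shuffled[4:])


def test_split_partitions_perturbations(rng):
    ds = _multi_drug_ds(13, rng)
    tr, va, te = split_by_perturbation(ds, SplitSpec(fractions=(0.5, 0.25, 0.25), seed=3))
    groups = [set(s.perturbation_ids()) for s in (tr, va, te)]
    assert groups[0] | groups[1] | groups[2] == set(ds.perturbation_ids())
    assert not (groups[0] & groups[1] or groups[0] & groups[2] or groups[1] & groups[2])


def test_split_controls_replicated(rng):
    ds = _multi_drug_ds(4, rng, n_controls=2)
    for part in split_by_perturbation(ds, SplitSpec(seed=0)):
        assert part.control_rows().size == 2


def test_split_too_few_perturbations(rng):
    ds = _multi_drug_ds(2, rng)
    with pytest.raises(DataError):
        split_by_perturbation(ds, SplitSpec(seed=0))


def test_split_spec_validation():
    with pytest.raises(DataError):
        SplitSpec(fractions=(0.5, 0.2, 0.2), seed=0)
    with pytest.raises(DataError):
        SplitSpec(level="bogus")


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------


def test_build_pairs_explicit(rng):
    matrix = rng.normal(size=(4, 3))
    records = [control_record(0), control_record(1), drug_record(2), drug_record(3)]
    ds = ExpressionDataset(matrix, records, ["a", "b", "c"], pairing={2: 0, 3: 1})
    pairs = build_pairs(ds, "paired")
    assert len(pairs) == 2
    np.testing.assert_array_equal(pairs.x[0], matrix[0])
    np.testing.assert_array_equal(pairs.y[0], matrix[2])


def test_build_pairs_unpaired_pools(rng):
    matrix = rng.normal(size=(4, 3))
    records = [control_record(0), control_record(1), drug_record(2), drug_record(3)]
    ds = ExpressionDataset(matrix, records, ["a", "b", "c"], pairing={2: 0, 3: 1})
    pools = build_pairs(ds, "unpaired")
    assert pools.controls.shape[0] == 2
    assert pools.treated.shape[0] == 2
    assert not hasattr(pools, "x")


def test_build_pairs_context_join(rng):
    matrix = rng.normal(size=(4, 2))
    records = [
        control_record(0, context="lineA"),
        control_record(1, context="lineB"),
        drug_record(2, context="lineA"),
        drug_record(3, context="lineB"),
    ]
    ds = ExpressionDataset(matrix, records, ["a", "b"])
    pairs = build_pairs(ds, "paired")
    np.testing.assert_array_equal(pairs.x[0], matrix[0])
    np.testing.assert_array_equal(pairs.x[1], matrix[1])


def test_build_pairs_missing_context_named(rng):
    matrix = rng.normal(size=(3, 2))
    records = [
        control_record(0, context="lineA"),
        drug_record(1, context="lineA"),
        drug_record(2, context="lineC"),
    ]
    ds = ExpressionDataset(matrix, records, ["a", "b"])
    with pytest.raises(DataError, match="lineC"):
        build_pairs(ds, "paired")


def test_build_pairs_orphans_listed(rng):
    matrix = rng.normal(size=(3, 2))
    records = [control_record(0), drug_record(1), drug_record(2)]
    ds = ExpressionDataset(matrix, records, ["a", "b"], pairing={1: 0})
    with pytest.raises(DataError, match="t2"):
        build_pairs(ds, "paired")


def test_build_pairs_count_property(small_dataset):
    pairs = build_pairs(small_dataset, "paired")
    assert len(pairs) == small_dataset.treated_rows().size


def test_preprocess_default_off(small_dataset):
    out = preprocess(small_dataset)
    np.testing.assert_array_equal(out.matrix, small_dataset.matrix)


def test_preprocess_standardize(rng):
    matrix = np.abs(rng.normal(size=(20, 3))) + 0.1
    ds = ExpressionDataset(matrix, [control_record(i) for i in range(20)], ["a", "b", "c"])
    out = preprocess(ds, log1p=True, standardize=True)
    np.testing.assert_allclose(out.matrix.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(out.matrix.std(axis=0), 1.0, atol=1e-12)
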