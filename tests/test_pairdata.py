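"""Activity cleaning, pair enumeration, similarity filtering, label balancing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem

from pairbind.pairdata import (CongenericSeries, Ligand, LigandPair,
                               balance_labels, clean_activities, enumerate_pairs,
                               log_convert, pair_similarity_stats,
                               similarity_filter, tanimoto)


def _series(values, sid="s"):
    return CongenericSeries(sid, [Ligand(f"L{i}", pic50=v, synth_order=i)
                                  for i, v in enumerate(values)])


# ------------------------------------------------------------------ cleaning

def test_qualified_rows_are_discarded():
    df = pd.DataFrame({
        "ligand_id": ["a", "b", "c", "d"],
        "series_id": ["s1"] * 4,
        "ic50_nM": [10.0, 10000.0, 25.0, 50.0],
        "qualifier": ["=", ">", "=", "<"],
    })
    series = clean_activities(df)
    assert len(series) == 1
    assert {l.ligand_id for l in series[0].ligands} == {"a", "c"}


def test_string_qualified_values_are_discarded():
    df = pd.DataFrame({
        "ligand_id": ["a", "b", "c"],
        "series_id": ["s1"] * 3,
        "ic50_nM": ["10", ">10000", "100"],
    })
    series = clean_activities(df)
    assert [l.ligand_id for l in series[0].ligands] == ["a", "c"]


def test_series_reduced_to_single_ligand_is_dropped():
    df = pd.DataFrame({
        "ligand_id": ["a", "b", "c"],
        "series_id": ["s1", "s1", "s2"],
        "ic50_nM": [10.0, 20.0, 30.0],
        "qualifier": ["=", ">", "="],   # s1 keeps one ligand, s2 has one
    })
    assert clean_activities(df) == []


def test_clean_series_passes_through_unchanged():
    df = pd.DataFrame({
        "ligand_id": ["a", "b", "c"],
        "series_id": ["s1"] * 3,
        "pic50": [6.2, 5.0, 7.4],
        "synth_order": [0, 1, 2],
    })
    (series,) = clean_activities(df)
    assert [l.pic50 for l in series.ligands] == [6.2, 5.0, 7.4]


def test_unparseable_table_raises():
    with pytest.raises(ValueError):
        clean_activities(pd.DataFrame({"ligand_id": [], "series_id": [],
                                       "ic50_nM": []}))
    with pytest.raises(ValueError):
        clean_activities(pd.DataFrame({"x": [1]}))


# ------------------------------------------------------------ log conversion

@pytest.mark.parametrize("ic50_molar, expected", [
    (1e-6, 6.0),            # 1 µM
    (1e-8, 8.0),            # 10 nM
    (5e-8, 7.30103),        # 50 nM
])
def test_ic50_to_pic50(ic50_molar, expected):
    assert log_convert(ic50_molar) == pytest.approx(expected, abs=1e-5)


def test_nonpositive_ic50_rejected():
    with pytest.raises(ValueError):
        log_convert(0.0)
    with pytest.raises(ValueError):
        log_convert(-1e-9)


# ------------------------------------------------------------------- pairing

def test_five_ligands_give_ten_pairs():
    pairs = enumerate_pairs(_series([5.0, 5.5, 6.0, 6.5, 7.0]))
    assert len(pairs) == 10
    assert len(enumerate_pairs(_series([5.0] * 5), bidirectional=True)) == 20


def test_pair_label_is_activity_difference():
    (pair,) = enumerate_pairs(_series([6.2, 5.0]))
    assert pair.label == pytest.approx(1.2)
    assert pair.cls_label == 1.0


def test_bidirectional_pairs_are_antisymmetric():
    pairs = enumerate_pairs(_series([5.1, 6.3, 7.2, 4.4]), bidirectional=True)
    by_key = {(p.i, p.j): p.label for p in pairs}
    for (i, j), label in by_key.items():
        assert by_key[(j, i)] == pytest.approx(-label)


def test_pair_labels_reconstruct_from_ligand_labels():
    series = _series([5.3, 6.1, 7.8, 4.9, 6.6])
    by_id = {l.ligand_id: l.pic50 for l in series.ligands}
    for p in enumerate_pairs(series):
        assert p.label == pytest.approx(by_id[p.i] - by_id[p.j])


def test_tie_pairs_get_soft_class_label():
    (pair,) = enumerate_pairs(_series([6.0, 6.0]))
    assert pair.cls_label == 0.5


def test_single_ligand_series_cannot_pair():
    with pytest.raises(ValueError):
        enumerate_pairs(_series([6.0]))


# -------------------------------------------------------- similarity filter

SMILES_10 = [
    "c1ccccc1C(=O)N", "c1ccc(C)cc1C(=O)N", "c1ccc(O)cc1C(=O)N",
    "c1ccc(Cl)cc1C(=O)N", "c1ccc(F)cc1C(=O)N", "c1ccc(N)cc1C(=O)N",
    "CCCCCCCC", "CC(C)(C)C", "c1ccncc1", "OCC(O)CO",
]


def test_identical_smiles_retained():
    pairs = [LigandPair("s", "a", "b", 0.5)]
    kept = similarity_filter(pairs, {"a": SMILES_10[0], "b": SMILES_10[0]})
    assert kept == pairs and kept[0].similarity == pytest.approx(1.0)


def test_filter_threshold_is_strict():
    pairs = [LigandPair("s", "a", "b", 0.5)]
    sim = tanimoto(SMILES_10[0], SMILES_10[1])
    assert similarity_filter(pairs, {"a": SMILES_10[0], "b": SMILES_10[1]},
                             threshold=sim) == []
    assert similarity_filter(pairs, {"a": SMILES_10[0], "b": SMILES_10[1]},
                             threshold=sim - 1e-9) == pairs


def test_filter_matches_brute_force_fingerprint_oracle():
    """Ten-ligand fixture vs an independent all-pairs fingerprint comparison."""
    ids = [f"L{i}" for i in range(len(SMILES_10))]
    smiles = dict(zip(ids, SMILES_10))
    pairs = [LigandPair("s", a, b, 0.1)
             for i, a in enumerate(ids) for b in ids[i + 1:]]
    kept = {(p.i, p.j) for p in similarity_filter(pairs, smiles, threshold=0.3)}

    gen = AllChem.GetMorganGenerator(radius=2, fpSize=2048)
    expected = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            fa = gen.GetFingerprint(Chem.MolFromSmiles(smiles[a]))
            fb = gen.GetFingerprint(Chem.MolFromSmiles(smiles[b]))
            if DataStructs.TanimotoSimilarity(fa, fb) > 0.3:
                expected.add((a, b))
    assert kept == expected


def test_unparseable_smiles_drops_pair_with_warning(caplog):
    pairs = [LigandPair("s", "a", "b", 0.5)]
    with caplog.at_level("WARNING"):
        assert similarity_filter(pairs, {"a": "garbage(", "b": "CC"}) == []
    assert "dropping pair" in caplog.text


def test_similarity_stats_bins_and_fraction():
    ids = [f"L{i}" for i in range(len(SMILES_10))]
    smiles = dict(zip(ids, SMILES_10))
    pairs = [LigandPair("s", a, b, 0.1)
             for i, a in enumerate(ids) for b in ids[i + 1:]]
    stats = pair_similarity_stats(pairs, smiles)
    assert sum(stats["bin_counts"]) == stats["n"] == len(pairs)
    assert stats["proportions"] == pytest.approx(
        [c / stats["n"] for c in stats["bin_counts"]])
    below = sum(stats["bin_counts"][:3])  # bins below 0.6
    assert stats["fraction_below_0.6"] == pytest.approx(below / stats["n"])


# ------------------------------------------------------------------ balance

def _normal_pairs(n=400, seed=0):
    rng = np.random.default_rng(seed)
    return [LigandPair("s", f"a{i}", f"b{i}", float(x))
            for i, x in enumerate(rng.normal(0, 1, n))]


def test_balancing_reduces_bin_count_spread():
    pairs = _normal_pairs(seed=0)
    before = np.array([p.label for p in pairs])
    balanced = balance_labels(pairs, seed=0)
    after = np.array([p.label for p in balanced])

    def bin_counts(labels):
        bins = np.floor(labels / 0.5).astype(int)
        return np.unique(bins, return_counts=True)[1]

    assert bin_counts(after).std() < bin_counts(before).std()
    counts = bin_counts(after)
    assert counts.max() / counts.min() <= 4.0 + 1e-9


def test_balancing_preserves_label_values():
    pairs = _normal_pairs(seed=1)
    balanced = balance_labels(pairs, seed=1)
    assert set(p.label for p in balanced) <= set(p.label for p in pairs)
    assert all(p in pairs for p in balanced)   # multiplicities only, same objects


def test_balancing_is_seeded():
    pairs = _normal_pairs(seed=2)
    a = balance_labels(pairs, seed=5)
    b = balance_labels(pairs, seed=5)
    assert [id(p) for p in a] == [id(p) for p in b]


def test_uniform_histogram_left_unchanged():
    labels = np.repeat(np.arange(-2.0, 2.0, 0.5) + 0.25, 20)
    pairs = [LigandPair("s", f"a{i}", f"b{i}", float(x))
             for i, x in enumerate(labels)]
    balanced = balance_labels(pairs, seed=0)
    assert sorted(p.label for p in balanced) == sorted(p.label for p in pairs)


def test_single_occupied_bin_warns_and_passes_through():
    pairs = [LigandPair("s", f"a{i}", f"b{i}", 0.1) for i in range(5)]
    with pytest.warns(UserWarning):
        assert balance_labels(pairs) == pairs


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_balancing_never_invents_labels(seed):
    pairs = _normal_pairs(n=60, seed=3)
    balanced = balance_labels(pairs, seed=seed)
    assert {p.label for p in balanced} <= {p.label for p in pairs}


def test_pairs_never_cross_series():
    s1 = _series([5.0, 6.0], sid="s1")
    s2 = _series([7.0, 8.0], sid="s2")
    pairs = enumerate_pairs(s1) + enumerate_pairs(s2)
    for p in pairs:
        assert p.series_id in ("s1", "s2")
        # ids stay within their series
        src = s1 if p.series_id == "s1" else s2
        assert {p.i, p.j} <= {l.ligand_id for l in src.ligands}
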