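import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aquapred import (
    FeatureMatrix,
    ProteinRecord,
    aac,
    ctd_composition,
    ctd_distribution,
    ctd_transition,
    default_schema,
    encode_188,
    encode_matrix,
    feature_name,
    load_partitions,
)
from aquapred.encoder import N_FEATURES, PropertyPartition
from aquapred.io import CANONICAL_ALPHABET

from reference import naive_encode

SCHEMA = default_schema()
HYDRO = SCHEMA.partitions[0]  # hydrophobicity partition

sequences = st.text(alphabet=CANONICAL_ALPHABET, min_size=2, max_size=60)


# ---------------------------------------------------------------- schema

def test_schema_has_188_unique_names_in_documented_blocks():
    names = SCHEMA.feature_names
    assert len(names) == N_FEATURES == 188
    assert len(set(names)) == 188
    assert all(n.startswith("AAC.") for n in names[:20])
    # 8 properties x (3 C + 3 T + 15 D)
    for start in range(20, 188, 21):
        block = names[start : start + 21]
        prop = block[0].split(".")[0]
        assert [n.split(".")[1] for n in block] == ["C"] * 3 + ["T"] * 3 + ["D"] * 15
        assert all(n.startswith(prop + ".") for n in block)


def test_named_feature_indices_match_hydrophobicity_contract():
    assert feature_name(1) == "AAC.A"
    assert feature_name(21) == "hydrophobicity.C.hydrophobic"
    assert feature_name(26) == "hydrophobicity.T.neutral~hydrophobic"
    with pytest.raises(IndexError):
        feature_name(0)
    with pytest.raises(IndexError):
        feature_name(189)


def test_partition_validation_rejects_bad_tables():
    with pytest.raises(ValueError):
        PropertyPartition("bad", (("a", frozenset("ACD")), ("b", frozenset("EFG")),
                                  ("c", frozenset("HIK"))))  # does not cover 20


def test_partitions_load_from_plain_text(tmp_path):
    path = tmp_path / "parts.tsv"
    lines = []
    for p in SCHEMA.partitions:
        fields = [p.name] + [f"{lab}:{''.join(sorted(res))}" for lab, res in p.groups]
        lines.append("\t".join(fields))
    path.write_text("# comment\n" + "\n".join(lines) + "\n")
    loaded = load_partitions(path)
    assert loaded == SCHEMA.partitions


# ---------------------------------------------------------------- blocks

def test_aac_direct_counts():
    v = aac("AAAAA")
    assert v[0] == 1.0 and v[1:].sum() == 0
    assert np.allclose(aac(CANONICAL_ALPHABET), 0.05)
    v = aac("AAC")
    assert v[0] == pytest.approx(2 / 3) and v[1] == pytest.approx(1 / 3)


def test_ctd_composition_hydrophobicity_examples():
    assert np.allclose(ctd_composition("CCCC", HYDRO), [1, 0, 0])
    assert np.allclose(ctd_composition("RRGG", HYDRO), [0, 0.5, 0.5])
    assert np.allclose(ctd_composition("RGCRGC", HYDRO), [1 / 3, 1 / 3, 1 / 3])


def test_ctd_transition_hydrophobicity_examples():
    assert np.allclose(ctd_transition("RRRR", HYDRO), [0, 0, 0])
    # pairs ordered (hyd~pol, pol~neu, neu~hyd)
    assert np.allclose(ctd_transition("RG", HYDRO), [0, 1.0, 0])
    # adjacent pairs of RGCRGC: RG, GC, CR, RG, GC
    assert np.allclose(ctd_transition("RGCRGC", HYDRO), [1 / 5, 2 / 5, 2 / 5])


def test_ctd_distribution_quantile_convention():
    d = ctd_distribution("CCCC", HYDRO)
    assert np.allclose(d[0:5], [1 / 4, 1 / 4, 2 / 4, 3 / 4, 4 / 4])  # hydrophobic group
    assert np.allclose(d[5:], 0)  # polar and neutral groups empty
    d = ctd_distribution("RRGG", HYDRO)
    assert np.allclose(d[5:10], [0.25, 0.25, 0.25, 0.5, 0.5])  # polar at positions 1,2


def test_encode_is_deterministic_and_188_long():
    v1 = encode_188("MKVLWAQPGHILVRTW")
    v2 = encode_188("MKVLWAQPGHILVRTW")
    assert v1.shape == (188,)
    assert np.array_equal(v1, v2)


# ------------------------------------------------------------ properties

@settings(max_examples=60, deadline=None, derandomize=True)
@given(sequences)
def test_structural_invariants_hold_for_random_sequences(seq):
    v = encode_188(seq)
    assert v.shape == (188,)
    assert np.all(v >= 0) and np.all(v <= 1)
    assert abs(v[:20].sum() - 1) < 1e-12
    for b, part in enumerate(SCHEMA.partitions):
        off = 20 + 21 * b
        assert abs(v[off : off + 3].sum() - 1) < 1e-12  # C sums to 1
        assert v[off + 3 : off + 6].sum() <= 1 + 1e-12  # T sums to <= 1
        for g in range(3):
            dd = v[off + 6 + 5 * g : off + 11 + 5 * g]
            assert np.all(np.diff(dd) >= -1e-15)  # quantiles non-decreasing


@settings(max_examples=60, deadline=None, derandomize=True)
@given(sequences)
def test_reversal_leaves_composition_and_transition_blocks_unchanged(seq):
    v, w = encode_188(seq), encode_188(seq[::-1])
    assert np.allclose(v[:20], w[:20], atol=1e-15)
    for b in range(8):
        off = 20 + 21 * b
        assert np.allclose(v[off : off + 6], w[off : off + 6], atol=1e-15)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(sequences)
def test_encoder_agrees_with_naive_direct_count_oracle(seq):
    assert np.allclose(encode_188(seq), naive_encode(seq, SCHEMA), atol=1e-12)


def test_single_group_sequence_degenerate_pattern():
    # all residues hydrophobic: C = (1,0,0), T = 0, D nonzero only for group 1
    v = encode_188("CLVIMFWCLVIMFW")
    off = 20
    assert np.allclose(v[off : off + 3], [1, 0, 0])
    assert np.allclose(v[off + 3 : off + 6], 0)
    assert np.all(v[off + 6 : off + 11] > 0)
    assert np.allclose(v[off + 11 : off + 21], 0)


# ---------------------------------------------------------------- matrix

def test_encode_matrix_orders_rows_and_carries_labels():
    recs = [
        ProteinRecord("a", "MKVLW", 1),
        ProteinRecord("b", "GGGGAA", 0),
        ProteinRecord("c", "CCRRGG", 1),
    ]
    fm = encode_matrix(recs)
    assert fm.X.shape == (3, 188)
    assert fm.ids == ["a", "b", "c"]
    assert list(fm.labels) == [1, 0, 1]
    perm = encode_matrix([recs[2], recs[0], recs[1]])
    assert np.array_equal(perm.X[1], fm.X[0])


def test_encode_matrix_rejects_empty_and_unlabelled_input():
    with pytest.raises(ValueError):
        encode_matrix([])
    with pytest.raises(ValueError):
        encode_matrix([ProteinRecord("a", "MKVLW")])


def test_feature_matrix_csv_round_trip(tmp_path):
    fm = encode_matrix([ProteinRecord("a", "MKVLW", 1), ProteinRecord("b", "GGGGAA", 0)])
    path = tmp_path / "m.csv"
    fm.to_csv(path)
    back = FeatureMatrix.read_csv(path)
    assert back.feature_names == fm.feature_names
    assert back.ids == fm.ids
    assert np.allclose(back.X, fm.X)
    assert np.array_equal(back.labels, fm.labels)
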