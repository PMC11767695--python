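"""Corpus parsing, SOM labelling, dataset assembly and splitting."""

import pandas as pd
import pytest

from hydrosom.chem import mol_from_smiles
from hydrosom.corpus import (
    CorpusError,
    ReactionRecord,
    build_atom_datasets,
    label_record,
    label_som_atoms,
    parse_reaction_corpus,
    split_dataset,
    write_corpus,
)
from hydrosom.features import N_FEATURES, feature_frame
from hydrosom.synth import GeneratorConfig, generate_corpus


def test_parse_freeform_row(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text("acetanilide-row: CC(=O)Nc1ccccc1 >> CC(=O)O . Nc1ccccc1\n")
    res = parse_reaction_corpus(p)
    assert len(res.records) == 1 and not res.rejected
    rec = res.records[0]
    assert rec.record_id == "acetanilide-row"
    assert len(rec.products) == 2


def test_parse_reports_invalid_structures(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text(
        "ok: CC(=O)Nc1ccccc1 >> CC(=O)O\n"
        "bad: C1CC >> CC(=O)O\n"  # unclosed ring
    )
    res = parse_reaction_corpus(p)
    assert len(res.records) == 1
    assert len(res.rejected) == 1 and res.rejected[0][0] == "bad"


def test_parse_empty_corpus_errors(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text("bad: C1CC >> CC\n")
    with pytest.raises(CorpusError):
        parse_reaction_corpus(p)
    with pytest.raises(FileNotFoundError):
        parse_reaction_corpus(tmp_path / "absent.tsv")


def test_write_parse_roundtrip_canonical(tmp_path):
    corpus = generate_corpus(GeneratorConfig(n_molecules=10, seed=7, target_som_ratio=None))
    subset = corpus.records[:3]
    p = tmp_path / "fixture.tsv"
    write_corpus(subset, p)
    back = parse_reaction_corpus(p).records
    assert [r.parent for r in back] == [r.parent for r in subset]
    assert [r.products for r in back] == [r.products for r in subset]


def test_label_acetanilide(rulebase):
    """Only the amide nitrogen of acetanilide is a hydrolysis site."""
    rec = ReactionRecord(
        record_id="a", parent="CC(=O)Nc1ccccc1",
        products=("CC(=O)O", "Nc1ccccc1"),
    )
    labels = label_som_atoms(rec, rulebase)
    mol = mol_from_smiles(rec.parent)
    assert len(labels) == mol.GetNumHeavyAtoms()  # all atoms are C/N/O
    pos = [l for l in labels if l.label == "SOM+"]
    assert len(pos) == 1 and pos[0].element == "N"


def test_unexplained_record_flagged(rulebase):
    rec = ReactionRecord(record_id="u", parent="CC(=O)NC", products=("CC(=O)NC",))
    lab = label_record(rec, rulebase)
    assert not lab.explained
    assert all(l.label == "SOM-" for l in lab.labels)


def test_labeling_idempotent(small_corpus, rulebase):
    rec = small_corpus.records[0]
    assert label_som_atoms(rec, rulebase) == label_som_atoms(rec, rulebase)


def test_class_tables_partition_global(small_datasets):
    t = small_datasets.tables
    class_sum = sum(
        (t["Global-Hydrolysis"]["atom_class"] == c).sum() for c in "NOCSX"
    )
    assert len(t["Global-Hydrolysis"]) == class_sum
    for name in ("N-Hydrolysis", "O-Hydrolysis", "C-Hydrolysis"):
        sub = t[name]
        assert (sub["atom_class"] == name[0]).all()
        assert len(sub) == (t["Global-Hydrolysis"]["atom_class"] == name[0]).sum()


def test_single_amide_corpus_counts(rulebase):
    rec = ReactionRecord(
        record_id="a", parent="CC(=O)Nc1ccccc1",
        products=("CC(=O)O", "Nc1ccccc1"),
    )
    ds = build_atom_datasets([rec], rulebase)
    mol = mol_from_smiles(rec.parent)
    n_c = sum(a.GetSymbol() == "C" for a in mol.GetAtoms())
    n_o = sum(a.GetSymbol() == "O" for a in mol.GetAtoms())
    assert len(ds.tables["N-Hydrolysis"]) >= 1
    assert len(ds.tables["C-Hydrolysis"]) == n_c
    assert len(ds.tables["O-Hydrolysis"]) == n_o
    assert ds.summary["N-Hydrolysis"]["SOM+"] == 1


def test_unexplained_excluded_and_reported(rulebase):
    good = ReactionRecord("g", "CC(=O)NC", ("CC(=O)O", "CN"))
    bad = ReactionRecord("b", "CC(=O)NC", ("CC(=O)NC",))
    ds = build_atom_datasets([good, bad], rulebase)
    assert ds.unexplained == ["b"]
    assert set(ds.tables["Global-Hydrolysis"]["record_id"]) == {"g"}


def test_feature_join_width(small_datasets):
    table = small_datasets.tables["N-Hydrolysis"].head(5)
    joined = feature_frame(table)
    assert joined.shape[1] == table.shape[1] + N_FEATURES
    assert N_FEATURES == 1032


def test_split_exact_ratio_and_determinism(small_datasets):
    table = small_datasets.tables["Global-Hydrolysis"]
    ten = table[table["record_id"].isin(sorted(table["record_id"].unique())[:10])]
    s1 = split_dataset(ten, 0.8, seed=1)
    s2 = split_dataset(ten, 0.8, seed=1)
    assert s1.train_rows["record_id"].nunique() == 8
    assert s1.test_rows["record_id"].nunique() == 2
    pd.testing.assert_frame_equal(s1.train_rows, s2.train_rows)
    pd.testing.assert_frame_equal(s1.test_rows, s2.test_rows)


def test_split_no_molecule_leakage(small_datasets):
    table = small_datasets.tables["Global-Hydrolysis"]
    for seed in (0, 3, 99):
        s = split_dataset(table, 0.8, seed=seed)
        assert not (
            set(s.train_rows["record_id"]) & set(s.test_rows["record_id"])
        )


def test_split_too_few_molecules(small_datasets):
    table = small_datasets.tables["Global-Hydrolysis"]
    one = table[table["record_id"] == table["record_id"].iloc[0]]
    with pytest.raises(CorpusError):
        split_dataset(one, 0.8, seed=0)
    with pytest.raises(CorpusError):
        split_dataset(table.iloc[0:0], 0.8, seed=0)
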