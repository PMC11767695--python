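"""Reaction-corpus ingestion, per-atom SOM labelling, and dataset assembly.

A corpus is a list of parent molecules with their observed single-step
hydrolysis products.  Labelling derives per-atom site-of-metabolism (SOM)
classes by rule matching: an atom is SOM+ exactly when some hydrolysis rule
applied at that atom yields a product set sharing an organic fragment with
the record's observed products; every other tracked atom of the parent is
SOM-.  Records no rule can explain are flagged and excluded from the
training tables (they are reported, never silently dropped).

Four datasets are assembled: N-, O- and C-Hydrolysis hold only their own
element; Global-Hydrolysis holds all tracked classes including sulfur and
halogens, which are too scarce to train on alone.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chem import (
    ELEMENT_CLASS,
    MoleculeError,
    canonical_smiles,
    is_organic,
    largest_organic_fragment,
    mol_from_smiles,
    split_fragments,
)
from .rules import RuleBase, enumerate_applications

DATASET_NAMES = ("N-Hydrolysis", "O-Hydrolysis", "C-Hydrolysis", "Global-Hydrolysis")
GLOBAL_CLASSES = ("N", "O", "C", "S", "X")

LABEL_COLUMNS = ["record_id", "parent_smiles", "atom_index", "element", "atom_class", "label"]


class CorpusError(ValueError):
    """Unusable corpus input (empty, malformed, unsplittable)."""


@dataclass(frozen=True)
class ReactionRecord:
    """One parent with its observed hydrolysis products."""

    record_id: str
    parent: str
    products: tuple[str, ...]
    environment: tuple[str, ...] = ("unspecified",)
    source: str = ""


@dataclass(frozen=True)
class AtomLabel:
    record_id: str
    atom_index: int
    element: str
    atom_class: str
    label: str  # "SOM+" or "SOM-"


@dataclass
class LabeledRecord:
    record: ReactionRecord
    labels: list[AtomLabel]
    explained: bool


@dataclass
class ParseResult:
    records: list[ReactionRecord]
    rejected: list[tuple[str, str]]  # (row identifier, reason)


@dataclass
class DatasetSplit:
    dataset_name: str
    train_rows: pd.DataFrame
    test_rows: pd.DataFrame
    split_seed: int
    split_ratio: float


def _make_record(record_id, parent, products, environment, source) -> ReactionRecord:
    parent_c = canonical_smiles(parent)
    prods = []
    for p in products:
        prods.extend(split_fragments(p))
    if not prods:
        raise MoleculeError("empty product list")
    return ReactionRecord(
        record_id=str(record_id),
        parent=parent_c,
        products=tuple(prods),
        environment=tuple(environment) if environment else ("unspecified",),
        source=source or "",
    )


def parse_reaction_corpus(path: str | Path, format: str = "smiles-table") -> ParseResult:
    """Read a reaction corpus from a delimited SMILES table or an SDF.

    The SMILES table is tab-separated with an optional header naming
    ``parent_smiles`` and ``products_smiles`` (plus optional ``record_id``,
    ``environment``, ``source``); header-less files may also use the free
    form ``[id:] parent >> product [. product ...]`` per line.  The SDF
    variant takes products from a ``PRODUCTS`` property.

    Unparsable entries are collected in the result's ``rejected`` list; a
    file yielding zero valid records raises CorpusError.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"corpus file not found: {p}")
    records: list[ReactionRecord] = []
    rejected: list[tuple[str, str]] = []

    if format == "sdf":
        supplier = Chem.SDMolSupplier(str(p), sanitize=True)
        for i, mol in enumerate(supplier):
            rid = f"sdf-{i}"
            if mol is None:
                rejected.append((rid, "unparsable SDF entry"))
                continue
            if mol.HasProp("_Name") and mol.GetProp("_Name").strip():
                rid = mol.GetProp("_Name").strip()
            if not mol.HasProp("PRODUCTS"):
                rejected.append((rid, "missing PRODUCTS property"))
                continue
            env = (
                tuple(x.strip() for x in mol.GetProp("ENVIRONMENT").split(",") if x.strip())
                if mol.HasProp("ENVIRONMENT")
                else ()
            )
            src = mol.GetProp("SOURCE") if mol.HasProp("SOURCE") else ""
            try:
                records.append(
                    _make_record(
                        rid,
                        Chem.MolToSmiles(mol),
                        mol.GetProp("PRODUCTS").split("."),
                        env,
                        src,
                    )
                )
            except MoleculeError as exc:
                rejected.append((rid, str(exc)))
    elif format == "smiles-table":
        lines = [
            ln.rstrip("\n")
            for ln in p.read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        if not lines:
            raise CorpusError(f"empty corpus file: {p}")
        header = None
        if "parent_smiles" in lines[0]:
            header = lines[0].split("\t")
            lines = lines[1:]
        for i, ln in enumerate(lines):
            rid = f"row-{i}"
            try:
                if header is not None:
                    vals = dict(zip(header, ln.split("\t")))
                    rid = vals.get("record_id", rid)
                    parent = vals["parent_smiles"]
                    prod_field = vals["products_smiles"]
                    if ">>" in prod_field:
                        prod_field = prod_field.split(">>", 1)[1]
                    env = tuple(
                        x.strip()
                        for x in vals.get("environment", "").split(",")
                        if x.strip()
                    )
                    src = vals.get("source", "")
                else:
                    if ">>" not in ln:
                        raise MoleculeError("no '>>' and no header columns")
                    left, right = ln.split(">>", 1)
                    tokens = left.replace("\t", " ").split()
                    if not tokens:
                        raise MoleculeError("missing parent SMILES")
                    parent = tokens[-1]
                    rid = " ".join(tokens[:-1]).rstrip(":") or rid
                    prod_field = right
                    env, src = (), ""
                products = [s.strip() for s in prod_field.split(".") if s.strip()]
                records.append(_make_record(rid, parent, products, env, src))
            except (MoleculeError, KeyError) as exc:
                rejected.append((rid, str(exc)))
    else:
        raise ValueError(f"unknown corpus format {format!r}")

    if not records:
        raise CorpusError(f"no valid records in {p} ({len(rejected)} rejected)")
    return ParseResult(records=records, rejected=rejected)


def write_corpus(records: list[ReactionRecord], path: str | Path) -> None:
    """Write records as the tab-separated table parse_reaction_corpus reads."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["record_id", "parent_smiles", "products_smiles", "environment", "source"])
        for r in records:
            w.writerow(
                [r.record_id, r.parent, ".".join(r.products), ",".join(r.environment), r.source]
            )


def label_record(record: ReactionRecord, rules: RuleBase) -> LabeledRecord:
    """Derive SOM labels for every tracked heavy atom of one record.

    Salt/multi-fragment parents are reduced to their largest organic
    fragment first.  Evidence matching ignores small inorganic by-products
    (CO2, ammonia, halide...) so that, e.g., an observed CO2 from one
    carbamate cannot vouch for an unrelated one.
    """
    if len(rules) == 0:
        raise CorpusError("empty rule base")
    parent = largest_organic_fragment(record.parent)
    mol = mol_from_smiles(parent)
    observed = set(record.products)
    positives: set[int] = set()
    explained = False
    for rule in rules:
        for app in enumerate_applications(mol, rule):
            if any(f in observed and is_organic(f) for f in app.products):
                positives.add(app.atom_index)
                explained = True
    labels = []
    for atom in mol.GetAtoms():
        cls = ELEMENT_CLASS.get(atom.GetSymbol())
        if cls is None:
            continue
        labels.append(
            AtomLabel(
                record_id=record.record_id,
                atom_index=atom.GetIdx(),
                element=atom.GetSymbol(),
                atom_class=cls,
                label="SOM+" if atom.GetIdx() in positives else "SOM-",
            )
        )
    return LabeledRecord(record=record, labels=labels, explained=explained)


def label_som_atoms(record: ReactionRecord, rules: RuleBase) -> list[AtomLabel]:
    """Per-atom SOM labels for one record (see label_record)."""
    return label_record(record, rules).labels


@dataclass
class AtomDatasets:
    """The four labelled atom tables plus corpus bookkeeping."""

    tables: dict[str, pd.DataFrame]
    summary: dict[str, dict[str, int]]
    unexplained: list[str] = field(default_factory=list)


def build_atom_datasets(records: list[ReactionRecord], rules: RuleBase) -> AtomDatasets:
    """Label all records and assemble the four per-class atom tables.

    Unexplained records (no rule reproduces any observed product) are
    excluded from the tables and listed in ``unexplained``.
    """
    rows = []
    unexplained = []
    for rec in records:
        lab = label_record(rec, rules)
        if not lab.explained:
            unexplained.append(rec.record_id)
            continue
        parent = largest_organic_fragment(rec.parent)
        for al in lab.labels:
            rows.append(
                (al.record_id, parent, al.atom_index, al.element, al.atom_class, al.label)
            )
    all_atoms = pd.DataFrame(rows, columns=LABEL_COLUMNS)
    tables = {}
    for name in DATASET_NAMES:
        if name == "Global-Hydrolysis":
            sub = all_atoms[all_atoms["atom_class"].isin(GLOBAL_CLASSES)]
        else:
            sub = all_atoms[all_atoms["atom_class"] == name[0]]
        tables[name] = sub.reset_index(drop=True)
    summary = {
        name: {
            "SOM+": int((t["label"] == "SOM+").sum()),
            "SOM-": int((t["label"] == "SOM-").sum()),
        }
        for name, t in tables.items()
    }
    return AtomDatasets(tables=tables, summary=summary, unexplained=unexplained)


def split_dataset(
    table: pd.DataFrame,
    ratio: float = 0.8,
    seed: int = 0,
    dataset_name: str = "",
) -> DatasetSplit:
    """Molecule-grouped train/test split, deterministic for a fixed seed.

    No molecule contributes atoms to both sides; atom-level splitting would
    leak near-duplicate circular environments across the boundary.
    """
    if table.empty:
        raise CorpusError("cannot split an empty table")
    mols = sorted(table["record_id"].unique())
    if len(mols) < 2:
        raise CorpusError(f"need >= 2 molecules to split, got {len(mols)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(mols))
    n_train = int(round(ratio * len(mols)))
    n_train = min(max(n_train, 1), len(mols) - 1)
    train_ids = {mols[i] for i in order[:n_train]}
    is_train = table["record_id"].isin(train_ids)
    return DatasetSplit(
        dataset_name=dataset_name,
        train_rows=table[is_train].reset_index(drop=True),
        test_rows=table[~is_train].reset_index(drop=True),
        split_seed=seed,
        split_ratio=ratio,
    )


def write_labels_csv(datasets: AtomDatasets, path: str | Path) -> None:
    pd.concat(
        [t.assign(dataset=name) for name, t in datasets.tables.items()],
        ignore_index=True,
    ).to_csv(path, index=False)


def write_summary_json(datasets: AtomDatasets, path: str | Path) -> None:
    doc = {
        "datasets": datasets.summary,
        "unexplained_records": datasets.unexplained,
    }
    Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")
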