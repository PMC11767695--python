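"""SMARTS hydrolysis rule base: loading, site matching, and transformation.

A rule is a one-reactant reaction SMARTS whose mapped atom ``center_map``
marks the site-of-metabolism atom (the atom the machine-learned site
classifiers score).  Applying a rule at a matched site yields the product
fragments of one hydrolysis step; fragment lists are returned as canonical
stereo-free SMILES.

Heavy-atom bookkeeping: every rule declares ``balance_delta``, the expected
gain in total heavy atoms over all product fragments relative to the parent
(+1 for the single water-derived oxygen in ordinary hydrolyses, +2 where a
second water equivalent is consumed, as in full nitrile hydrolysis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from rdkit import Chem
from rdkit.Chem import AllChem

from .chem import (
    TRACKED_CLASSES,
    atom_orbits,
    canonical_smiles,
    is_organic,
    mol_from_smiles,
)


class RuleError(ValueError):
    """Malformed rule base or rule application failure."""


@dataclass(frozen=True)
class HydrolysisRule:
    """One SMARTS hydrolysis transformation with its metadata."""

    rule_id: str
    name: str
    family: str
    smarts: str
    atom_class: str
    center_map: int
    environments: tuple[str, ...]
    balance_delta: int
    reference: str = ""
    golden_reactant: str = ""
    golden_products: tuple[str, ...] = ()

    def reaction(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.smarts)
        if rxn is None or rxn.GetNumReactantTemplates() != 1:
            raise RuleError(
                f"rule {self.rule_id!r}: SMARTS must be a one-reactant reaction"
            )
        rxn.Initialize()
        return rxn

    def validate(self) -> None:
        rxn = self.reaction()
        maps = {
            a.GetAtomMapNum()
            for a in rxn.GetReactantTemplate(0).GetAtoms()
            if a.GetAtomMapNum()
        }
        if self.center_map not in maps:
            raise RuleError(
                f"rule {self.rule_id!r}: center_map {self.center_map} not in "
                f"reactant pattern (maps {sorted(maps)})"
            )
        if self.atom_class not in TRACKED_CLASSES:
            raise RuleError(
                f"rule {self.rule_id!r}: unknown atom_class {self.atom_class!r}"
            )


@dataclass
class RuleBase:
    """Ordered, validated collection of hydrolysis rules."""

    rules: list[HydrolysisRule]
    version: str = "unversioned"
    _by_id: dict = field(init=False, repr=False)

    def __post_init__(self):
        ids = [r.rule_id for r in self.rules]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise RuleError(f"duplicate rule_ids: {sorted(dup)}")
        for r in self.rules:
            try:
                r.validate()
            except RuleError:
                raise
            except Exception as exc:  # SMARTS compile errors
                raise RuleError(f"rule {r.rule_id!r}: {exc}") from exc
        covered = {r.atom_class for r in self.rules}
        missing = set(TRACKED_CLASSES) - covered
        if missing:
            raise RuleError(f"no rule for atom class(es): {sorted(missing)}")
        self._by_id = {r.rule_id: r for r in self.rules}

    def __iter__(self):
        return iter(self.rules)

    def __len__(self):
        return len(self.rules)

    def get(self, rule_id: str) -> HydrolysisRule:
        try:
            return self._by_id[rule_id]
        except KeyError:
            raise RuleError(f"unknown rule_id {rule_id!r}") from None


@dataclass(frozen=True)
class SiteMatch:
    """A rule matched with its reaction-center atom in a query molecule."""

    rule_id: str
    atom_index: int
    #: atom-map number -> query-molecule atom index, for the mapped pattern atoms
    match_atoms: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class RuleApplication:
    """Internal: one concrete application of a rule at one center atom."""

    rule_id: str
    atom_index: int
    match_atoms: tuple[tuple[int, int], ...]
    products: tuple[str, ...]  # canonical fragment SMILES


def load_rulebase(path: str | Path | None = None) -> RuleBase:
    """Load a rule base from JSON; with no path, the shipped default base.

    Loading is atomic: any malformed rule aborts the whole load with an
    error naming the offending rule_id.
    """
    if path is None:
        text = (
            resources.files("hydrosom.data")
            .joinpath("hydrolysis_rules.json")
            .read_text(encoding="utf-8")
        )
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"rule base not found: {p}")
        text = p.read_text(encoding="utf-8")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise RuleError(f"rule base is not valid JSON: {exc}") from exc
    rules = []
    for row in doc.get("rules", []):
        try:
            rules.append(
                HydrolysisRule(
                    rule_id=row["rule_id"],
                    name=row["name"],
                    family=row.get("family", row["rule_id"]),
                    smarts=row["smarts"],
                    atom_class=row["atom_class"],
                    center_map=int(row["center_map"]),
                    environments=tuple(row.get("environments", ["aquatic", "plant", "animal"])),
                    balance_delta=int(row.get("balance_delta", 1)),
                    reference=row.get("reference", ""),
                    golden_reactant=row.get("golden_reactant", ""),
                    golden_products=tuple(row.get("golden_products", ())),
                )
            )
        except KeyError as exc:
            raise RuleError(f"rule row missing field {exc}: {row!r}") from exc
    if not rules:
        raise RuleError("rule base contains no rules")
    return RuleBase(rules=rules, version=str(doc.get("version", "unversioned")))


def default_rulebase() -> RuleBase:
    return load_rulebase(None)


def _sanitize_products(product_mol: Chem.Mol) -> tuple[str, ...] | None:
    """Sanitize a raw RunReactants product and return canonical fragments."""
    try:
        Chem.SanitizeMol(product_mol)
    except Exception:
        return None
    frags = Chem.GetMolFrags(product_mol, asMols=True, sanitizeFrags=False)
    out = []
    for f in frags:
        try:
            Chem.SanitizeMol(f)
            out.append(canonical_smiles(f))
        except Exception:
            return None
    return tuple(sorted(out))


def enumerate_applications(mol: Chem.Mol, rule: HydrolysisRule) -> list[RuleApplication]:
    """All distinct (center atom, product set) applications of one rule.

    The reaction-center atom in the parent is recovered through the
    ``old_mapno``/``react_atom_idx`` properties RDKit stamps on product
    atoms, so no assumption is made about match enumeration order.
    Unsanitizable product sets are skipped.
    """
    rxn = rule.reaction()
    seen: set[tuple[int, tuple[str, ...]]] = set()
    apps: list[RuleApplication] = []
    for product_set in rxn.RunReactants((mol,)):
        mapping: dict[int, int] = {}
        for pmol in product_set:
            for atom in pmol.GetAtoms():
                if atom.HasProp("old_mapno") and atom.HasProp("react_atom_idx"):
                    mapping[atom.GetIntProp("old_mapno")] = atom.GetIntProp(
                        "react_atom_idx"
                    )
        center = mapping.get(rule.center_map)
        if center is None:
            continue
        frags: list[str] = []
        ok = True
        for pmol in product_set:
            san = _sanitize_products(pmol)
            if san is None:
                ok = False
                break
            frags.extend(san)
        if not ok:
            continue
        key = (center, tuple(sorted(frags)))
        if key in seen:
            continue
        seen.add(key)
        apps.append(
            RuleApplication(
                rule_id=rule.rule_id,
                atom_index=center,
                match_atoms=tuple(sorted(mapping.items())),
                products=tuple(sorted(frags)),
            )
        )
    return apps


def match_sites(mol: Chem.Mol, rules: RuleBase) -> list[SiteMatch]:
    """All distinct (rule, center-atom) matches in a molecule.

    Automorphism-equivalent centers that yield identical product sets are
    reported once (lowest atom index kept): applying a rule at either
    methoxy of a symmetric phosphate is the same transformation.
    """
    orbits = atom_orbits(mol)
    matches: list[SiteMatch] = []
    for rule in rules:
        apps = enumerate_applications(mol, rule)
        by_center: dict[int, RuleApplication] = {}
        for app in apps:
            by_center.setdefault(app.atom_index, app)
        kept: dict[tuple[int, tuple[str, ...]], int] = {}
        for center in sorted(by_center):
            app = by_center[center]
            key = (orbits[center], app.products)
            if key in kept:
                continue
            kept[key] = center
            matches.append(
                SiteMatch(
                    rule_id=rule.rule_id,
                    atom_index=center,
                    match_atoms=app.match_atoms,
                )
            )
    return matches


def apply_rule(mol: Chem.Mol, match: SiteMatch, rules: RuleBase) -> list[str]:
    """Product fragments (canonical SMILES) of one rule applied at one site."""
    rule = rules.get(match.rule_id)
    for app in enumerate_applications(mol, rule):
        if app.atom_index == match.atom_index:
            return list(app.products)
    raise RuleError(
        f"rule {match.rule_id!r} does not apply at atom {match.atom_index} "
        f"of {canonical_smiles(mol)!r}"
    )


@dataclass
class ValidationEntry:
    rule_id: str
    reactant: str
    expected: tuple[str, ...]
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    entries: list[ValidationEntry]

    @property
    def all_passed(self) -> bool:
        return all(e.passed for e in self.entries)

    @property
    def failures(self) -> list[ValidationEntry]:
        return [e for e in self.entries if not e.passed]


def validate_rulebase(
    rules: RuleBase,
    known_pairs: list[tuple[str | None, str, list[str]]] | None = None,
) -> ValidationReport:
    """Check that rules reproduce known reactant/product pairs.

    Each pair is ``(rule_id, reactant_smiles, product_smiles_list)``.  With a
    named rule the full product-fragment multiset of some application must
    equal the expected set; with ``rule_id=None`` the pair passes if any
    rule application shares an organic fragment with the observed products
    (the evidence criterion used for corpus labelling).  With no argument,
    the rule base's own golden pairs are validated.
    """
    if known_pairs is None:
        known_pairs = [
            (r.rule_id, r.golden_reactant, list(r.golden_products))
            for r in rules
            if r.golden_reactant
        ]
    if not known_pairs:
        raise RuleError("no known pairs to validate against")
    entries: list[ValidationEntry] = []
    for rule_id, reactant, products in known_pairs:
        try:
            mol = mol_from_smiles(reactant)
            expected = tuple(sorted(canonical_smiles(p) for p in products))
        except Exception as exc:
            entries.append(
                ValidationEntry(rule_id or "*", reactant, tuple(products), False, str(exc))
            )
            continue
        if rule_id is not None:
            apps = enumerate_applications(mol, rules.get(rule_id))
            ok = any(app.products == expected for app in apps)
            detail = "" if ok else (
                f"no application of {rule_id} yields {expected}; "
                f"got {[a.products for a in apps]}"
            )
        else:
            observed = set(expected)
            ok = False
            detail = "no rule application shares an organic fragment"
            for rule in rules:
                for app in enumerate_applications(mol, rule):
                    if any(f in observed and is_organic(f) for f in app.products):
                        ok, detail = True, ""
                        break
                if ok:
                    break
        entries.append(
            ValidationEntry(rule_id or "*", reactant, expected, ok, detail)
        )
    return ValidationReport(entries=entries)
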