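"""Metabolite generation: combine site probabilities with the rule engine.

For every rule match whose reaction-center atom scores at or above the
probability threshold, the transformation is applied and its product
fragments emitted, scored with the site's probability.  One *transformation*
is one (rule family, reaction-center) event; automorphism-equivalent
centers and same-family rules hitting the same center or producing the
same major fragment are collapsed, so a symmetric phosphate counts its two
methyl cleavages once.  Ranking is by score descending with deterministic
tie-breaks, so higher-probability products are examined first and the
combinatorial explosion of unranked rule application is avoided.

Passing ``bundle=None`` scores every site 1.0, which reduces the engine to
the pure expert system (useful for rule auditing and for products whose
evidence does not depend on a trained model).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .chem import (
    INORGANIC_FRAGMENTS,
    atom_orbits,
    canonical_smiles,
    heavy_atom_count,
    is_organic,
    largest_organic_fragment,
    mol_from_smiles,
)
from .models import ModelBundle, predict_sites
from .rules import RuleBase, SiteMatch, apply_rule, match_sites


@dataclass(frozen=True)
class MetabolitePrediction:
    """One product fragment of one predicted transformation."""

    product: str
    score: float
    rule_id: str
    rule_name: str
    family: str
    site_atom_index: int
    environments: tuple[str, ...]
    fragment_role: str  # "major" | "minor" | "inorganic"
    transformation_id: str


@dataclass(frozen=True)
class ProductEvaluation:
    n_reference: int
    n_predicted: int
    n_hit: int
    n_extra: int

    @property
    def hit_rate(self) -> float:
        return self.n_hit / self.n_reference if self.n_reference else 0.0

    @property
    def false_positive_rate(self) -> float:
        return self.n_extra / self.n_predicted if self.n_predicted else 0.0


def _fragment_role(fragment: str, major: str) -> str:
    if fragment in INORGANIC_FRAGMENTS or not is_organic(fragment):
        return "inorganic"
    return "major" if fragment == major else "minor"


def generate(
    mol_or_smiles,
    bundle: ModelBundle | None,
    rules: RuleBase,
    threshold: float = 0.5,
) -> list[MetabolitePrediction]:
    """Ranked product fragments of all above-threshold transformations.

    Output is sorted by score descending, then rule_id, then site index;
    fragments of one transformation stay adjacent and share a
    ``transformation_id``.  Lowering the threshold can only add
    transformations, never remove one.
    """
    mol = mol_from_smiles(mol_or_smiles) if isinstance(mol_or_smiles, str) else mol_or_smiles
    if bundle is None:
        prob = {a.GetIdx(): 1.0 for a in mol.GetAtoms()}
    else:
        prob = {
            sp.atom_index: sp.probability
            for sp in predict_sites(bundle, mol, threshold=threshold)
        }
    orbits = atom_orbits(mol)

    candidates = []  # (score, match, products, major, family)
    for match in match_sites(mol, rules):
        p = prob.get(match.atom_index)
        if p is None or p < threshold:
            continue
        rule = rules.get(match.rule_id)
        try:
            products = apply_rule(mol, match, rules)
        except Exception:
            continue  # per-site rule failure: skip, never fatal
        major = largest_organic_fragment(".".join(products))
        candidates.append((p, match, tuple(products), major, rule))

    candidates.sort(key=lambda c: (-c[0], c[1].rule_id, c[1].atom_index))

    kept: list[tuple[float, SiteMatch, tuple[str, ...], str, object]] = []
    for cand in candidates:
        p, match, products, major, rule = cand
        duplicate = any(
            rule.family == k_rule.family
            and (
                orbits[match.atom_index] == orbits[k_match.atom_index]
                or major == k_major
            )
            for _, k_match, _, k_major, k_rule in kept
        )
        if not duplicate:
            kept.append(cand)

    out: list[MetabolitePrediction] = []
    for t, (p, match, products, major, rule) in enumerate(kept, start=1):
        role_order = {"major": 0, "minor": 1, "inorganic": 2}
        frags = sorted(
            products, key=lambda f: (role_order[_fragment_role(f, major)], f)
        )
        for frag in frags:
            out.append(
                MetabolitePrediction(
                    product=frag,
                    score=float(p),
                    rule_id=rule.rule_id,
                    rule_name=rule.name,
                    family=rule.family,
                    site_atom_index=match.atom_index,
                    environments=rule.environments,
                    fragment_role=_fragment_role(frag, major),
                    transformation_id=f"T{t}",
                )
            )
    return out


def transformations(predictions: list[MetabolitePrediction]) -> list[str]:
    """Distinct transformation ids, in rank order."""
    seen: list[str] = []
    for p in predictions:
        if p.transformation_id not in seen:
            seen.append(p.transformation_id)
    return seen


def major_products(predictions: list[MetabolitePrediction]) -> list[str]:
    """The major fragment of each transformation, in rank order."""
    return [p.product for p in predictions if p.fragment_role == "major"]


def rank_consistency(predictions: list[MetabolitePrediction]) -> list[MetabolitePrediction]:
    """Stable sort: score descending, ties by rule_id then site index."""
    return sorted(
        predictions,
        key=lambda p: (-p.score, p.rule_id, p.site_atom_index),
    )


def evaluate_products(
    predicted: list[str], reference: list[str]
) -> ProductEvaluation:
    """Set comparison of predicted against reference product structures.

    Matching is on canonical, stereo-stripped, largest-fragment SMILES.
    ``n_extra`` counts distinct predictions absent from the reference.
    """
    if not reference:
        raise ValueError("reference product list is empty")
    ref = {largest_organic_fragment(canonical_smiles(s)) for s in reference}
    pred = {largest_organic_fragment(canonical_smiles(s)) for s in predicted}
    n_hit = len(ref & pred)
    return ProductEvaluation(
        n_reference=len(ref),
        n_predicted=len(pred),
        n_hit=n_hit,
        n_extra=len(pred) - n_hit,
    )


def aggregate_evaluations(parts: list[ProductEvaluation]) -> ProductEvaluation:
    """Corpus-level evaluation as the sum of per-compound evaluations."""
    return ProductEvaluation(
        n_reference=sum(p.n_reference for p in parts),
        n_predicted=sum(p.n_predicted for p in parts),
        n_hit=sum(p.n_hit for p in parts),
        n_extra=sum(p.n_extra for p in parts),
    )


def predictions_to_frame(predictions: list[MetabolitePrediction]) -> pd.DataFrame:
    """Report table: one row per product fragment, rank = transformation order."""
    t_rank = {t: i + 1 for i, t in enumerate(transformations(predictions))}
    rows = [
        {
            "rank": t_rank[p.transformation_id],
            "transformation_id": p.transformation_id,
            "product_smiles": p.product,
            "score": p.score,
            "rule_id": p.rule_id,
            "rule_name": p.rule_name,
            "site_atom_index": p.site_atom_index,
            "environments": ",".join(p.environments),
            "fragment_role": p.fragment_role,
        }
        for p in predictions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "rank", "transformation_id", "product_smiles", "score", "rule_id",
            "rule_name", "site_atom_index", "environments", "fragment_role",
        ],
    )
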