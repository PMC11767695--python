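"""Synthetic hydrolysis-reaction corpus with exact ground-truth sites.

Each parent is a small scaffold decorated with 1-3 hydrolyzable groups
(amide, ester, carbamate, urea, nitrile, carbonate, oxime, phosphoester,
thioether, haloalkane, alkyne, acid chloride) and 0-2 hydrolytically inert
decoys (ethers, amines, alcohols, ketones, fluorine).  Observed products
are computed by applying the shipped rule base at every matched site, so a
record's ground truth is a deterministic function of its structure and the
corpus is labelable with perfect closure: re-deriving SOM labels by rule
matching recovers the generator's truth exactly.  The class imbalance of
the default configuration is set so the positive:negative ratio of the
global atom table sits near 0.24, the regime typical of curated hydrolysis
corpora where reactive sites are much rarer than inert atoms.

The generator emulates site/label structure, not agrochemical realism:
molecules are small, substituents are simple, and every matched site
reacts.  See the methods note for what that implies about test coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from rdkit import Chem

import numpy as np

from .chem import ELEMENT_CLASS, canonical_smiles, mol_from_smiles
from .corpus import AtomLabel, ReactionRecord
from .rules import RuleBase, default_rulebase, enumerate_applications


class GeneratorError(ValueError):
    pass


#: hydrolyzable substituents: family -> fragment with [*] attachment point
GROUP_FRAGMENTS = {
    "amide": "[*]NC(C)=O",
    "ester": "[*]C(=O)OC",
    "acyloxy": "[*]OC(C)=O",
    "carbamate": "[*]OC(=O)NC",
    "urea": "[*]NC(=O)NC",
    "nitrile": "[*]C#N",
    "carbonate": "[*]OC(=O)OC",
    "oxime": "[*]C(C)=NO",
    "phosphoester": "[*]OP(=O)(OC)OC",
    "thioether": "[*]SC",
    "haloalkane": "[*]CCl",
    "alkyne": "[*]C#C",
    "acid_chloride": "[*]C(=O)Cl",
}

#: hydrolytically inert substituents
DECOY_FRAGMENTS = {
    "methoxy": "[*]OC",
    "dimethylamino": "[*]N(C)C",
    "hydroxyl": "[*]O",
    "methylketone": "[*]C(C)=O",
    "ethyl": "[*]CC",
    "fluoro": "[*]F",
    "trifluoromethyl": "[*]C(F)(F)F",
}

DEFAULT_SCAFFOLDS = (
    "c1ccccc1",        # benzene
    "Cc1ccccc1",       # toluene
    "c1ccncc1",        # pyridine
    "C1CCCC1",         # cyclopentane
    "CCC",             # propane
    "CCCC",            # butane
    "CC(C)C",          # isobutane
    "CCCCC",           # pentane
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpus."""

    n_molecules: int = 300
    seed: int = 0
    scaffolds: tuple[str, ...] = DEFAULT_SCAFFOLDS
    group_freqs: dict = field(
        default_factory=lambda: {
            "amide": 3.0, "ester": 3.0, "acyloxy": 2.0, "carbamate": 3.0,
            "urea": 2.0, "nitrile": 1.5, "carbonate": 1.5, "oxime": 1.0,
            "phosphoester": 2.5, "thioether": 1.0, "haloalkane": 1.0,
            "alkyne": 0.5, "acid_chloride": 0.5,
        }
    )
    decoy_freqs: dict = field(
        default_factory=lambda: {
            "methoxy": 1.0, "dimethylamino": 1.0, "hydroxyl": 1.0,
            "methylketone": 1.0, "ethyl": 1.0, "fluoro": 0.5,
            "trifluoromethyl": 0.5,
        }
    )
    groups_per_molecule: tuple[int, int] = (1, 3)
    decoys_per_molecule: tuple[int, int] = (0, 2)
    #: requested positive:negative ratio of the global atom table; achieved
    #: value is reported and generation fails if it misses by more than
    #: ``ratio_tolerance``.
    target_som_ratio: float | None = 0.24
    ratio_tolerance: float = 0.10
    #: test-machinery knob: fraction of ground-truth labels flipped at random
    label_flip_rate: float = 0.0

    def validate(self) -> None:
        if self.n_molecules < 10:
            raise GeneratorError("n_molecules must be >= 10 for split-ability")
        if any(v < 0 for v in self.group_freqs.values()) or any(
            v < 0 for v in self.decoy_freqs.values()
        ):
            raise GeneratorError("frequencies must be non-negative")
        if not any(v > 0 for v in self.group_freqs.values()):
            raise GeneratorError(
                "no hydrolyzable group has positive frequency: every record "
                "would be SOM-free and unexplainable"
            )
        unknown = set(self.group_freqs) - set(GROUP_FRAGMENTS)
        if unknown:
            raise GeneratorError(f"unknown group families: {sorted(unknown)}")


@dataclass
class SynthCorpus:
    records: list[ReactionRecord]
    labels: list[AtomLabel]
    config: GeneratorConfig
    achieved_ratio: float


def _attachment_sites(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]


def _attach(core: Chem.Mol, frag_smiles: str, site_idx: int) -> Chem.Mol:
    """Bond a [*]-marked fragment to one core atom."""
    frag = Chem.MolFromSmiles(frag_smiles)
    n_core = core.GetNumAtoms()
    combo = Chem.RWMol(Chem.CombineMols(core, frag))
    star = next(
        a.GetIdx()
        for a in combo.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetIdx() >= n_core
    )
    nbr = combo.GetAtomWithIdx(star).GetNeighbors()[0].GetIdx()
    combo.AddBond(site_idx, nbr, Chem.BondType.SINGLE)
    combo.RemoveAtom(star)
    mol = combo.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def _weighted_choice(rng: np.random.Generator, freqs: dict, k: int) -> list[str]:
    names = sorted(n for n, w in freqs.items() if w > 0)
    if not names or k == 0:
        return []
    w = np.array([freqs[n] for n in names], dtype=float)
    return list(rng.choice(names, size=k, replace=True, p=w / w.sum()))


def _build_parent(rng: np.random.Generator, config: GeneratorConfig) -> str | None:
    lo_g, hi_g = config.groups_per_molecule
    lo_d, hi_d = config.decoys_per_molecule
    n_groups = int(rng.integers(lo_g, hi_g + 1))
    n_decoys = int(rng.integers(lo_d, hi_d + 1))
    scaffold_smiles = str(rng.choice(list(config.scaffolds)))
    mol = mol_from_smiles(scaffold_smiles)
    sites = _attachment_sites(mol)
    if len(sites) < n_groups + n_decoys:
        return None
    chosen = list(rng.choice(sites, size=n_groups + n_decoys, replace=False))
    groups = _weighted_choice(rng, config.group_freqs, n_groups)
    decoys = _weighted_choice(rng, config.decoy_freqs, n_decoys)
    frags = [GROUP_FRAGMENTS[g] for g in groups] + [DECOY_FRAGMENTS[d] for d in decoys]
    try:
        for site, frag in zip(chosen, frags):
            mol = _attach(mol, frag, int(site))
    except Exception:
        return None
    return canonical_smiles(mol)


def generate_corpus(config: GeneratorConfig | None = None, rules: RuleBase | None = None) -> SynthCorpus:
    """Generate records + exact ground-truth atom labels, deterministically.

    Every rule-matched site of every parent is reacted, so ground truth is
    `all reaction centers`; observed products are the union of all product
    fragments.  Parents with no matched site are redrawn.
    """
    config = config or GeneratorConfig()
    config.validate()
    rules = rules or default_rulebase()
    rng = np.random.default_rng(config.seed)
    # separate stream so the noise knob never perturbs the structures
    flip_rng = np.random.default_rng(config.seed + 987654321)
    records: list[ReactionRecord] = []
    labels: list[AtomLabel] = []
    pos = {c: 0 for c in ("N", "O", "C", "S", "X")}
    neg = dict(pos)

    made = 0
    attempts = 0
    max_attempts = config.n_molecules * 60
    seen_parents: set[str] = set()
    while made < config.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise GeneratorError(
                f"could not generate {config.n_molecules} molecules in "
                f"{max_attempts} attempts (got {made})"
            )
        parent = _build_parent(rng, config)
        if parent is None or parent in seen_parents:
            continue
        mol = mol_from_smiles(parent)
        apps = [a for rule in rules for a in enumerate_applications(mol, rule)]
        if not apps:
            continue
        seen_parents.add(parent)
        rid = f"syn-{config.seed}-{made:04d}"
        products = sorted({f for a in apps for f in a.products})
        centers = {a.atom_index for a in apps}
        records.append(
            ReactionRecord(
                record_id=rid,
                parent=parent,
                products=tuple(products),
                environment=("unspecified",),
                source="synthetic",
            )
        )
        for atom in mol.GetAtoms():
            cls = ELEMENT_CLASS.get(atom.GetSymbol())
            if cls is None:
                continue
            positive = atom.GetIdx() in centers
            if config.label_flip_rate > 0 and flip_rng.random() < config.label_flip_rate:
                positive = not positive
            labels.append(
                AtomLabel(
                    record_id=rid,
                    atom_index=atom.GetIdx(),
                    element=atom.GetSymbol(),
                    atom_class=cls,
                    label="SOM+" if positive else "SOM-",
                )
            )
            (pos if positive else neg)[cls] += 1
        made += 1

    n_pos, n_neg = sum(pos.values()), sum(neg.values())
    achieved = n_pos / n_neg if n_neg else float("inf")
    if config.target_som_ratio is not None:
        if abs(achieved - config.target_som_ratio) > config.ratio_tolerance:
            raise GeneratorError(
                f"achieved global SOM+/SOM- ratio {achieved:.3f} misses the "
                f"requested {config.target_som_ratio:.3f} by more than "
                f"{config.ratio_tolerance:.3f}; adjust group/decoy frequencies"
            )
    return SynthCorpus(
        records=records, labels=labels, config=config, achieved_ratio=achieved
    )


def corpus_statistics(records: list[ReactionRecord], labels: list[AtomLabel]) -> dict:
    """Per-dataset SOM+/SOM- counts (the corpus summary table shape).

    Classes with no atoms appear with zero counts rather than being
    omitted; counts over merged corpora are additive by construction.
    """
    counts = {
        name: {"SOM+": 0, "SOM-": 0}
        for name in ("N-Hydrolysis", "O-Hydrolysis", "C-Hydrolysis", "Global-Hydrolysis")
    }
    for lab in labels:
        if lab.atom_class in ("N", "O", "C"):
            counts[f"{lab.atom_class}-Hydrolysis"][lab.label] += 1
        counts["Global-Hydrolysis"][lab.label] += 1
    return counts
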