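"""Rule base loading, matching, transformation and mass balance."""

import pytest

from hydrosom.chem import heavy_atom_count, mol_from_smiles
from hydrosom.rules import (
    HydrolysisRule,
    RuleBase,
    RuleError,
    apply_rule,
    enumerate_applications,
    match_sites,
    validate_rulebase,
)

FAMILIES_REQUIRED = {
    "amide", "nitrile", "urea", "carbamate", "ester", "carbonate",
    "oxime", "phosphoester", "thioether", "acid_halide", "haloalkane",
}


def test_shipped_base_coverage(rulebase):
    """The default base covers every functional-group family and atom class."""
    assert len(rulebase) >= 12
    assert FAMILIES_REQUIRED <= {r.family for r in rulebase}
    assert {r.atom_class for r in rulebase} == {"N", "O", "C", "S", "X"}


def _rule(**kw):
    base = dict(
        rule_id="t1", name="t", family="t",
        smarts="[#6:1][C:2](=[O:3])[N:4]>>([#6:1][C:2](=[O:3])[OX2H1].[N:4])",
        atom_class="N", center_map=4, environments=("aquatic",),
        balance_delta=1,
    )
    base.update(kw)
    return HydrolysisRule(**base)


def test_malformed_base_rejected(rulebase):
    with pytest.raises(RuleError, match="duplicate"):
        RuleBase(rules=[_rule(), _rule()])
    with pytest.raises(RuleError):
        RuleBase(rules=[_rule(rule_id="bad", smarts="C(=O>>C")]).rules
    with pytest.raises(RuleError, match="center_map"):
        _rule(center_map=99).validate()
    # missing atom classes must be flagged too
    with pytest.raises(RuleError, match="atom class"):
        RuleBase(rules=[_rule()])


def test_golden_pairs_all_reproduced(rulebase):
    """Every shipped rule regenerates its golden reactant/product pair."""
    report = validate_rulebase(rulebase)
    assert len(report.entries) == len(rulebase)
    assert report.all_passed, [e.rule_id for e in report.failures]


def test_fault_injection_fails_exactly_one_pair(rulebase):
    pairs = [
        (r.rule_id, r.golden_reactant, list(r.golden_products)) for r in rulebase
    ]
    pairs[3] = (pairs[3][0], pairs[3][1], ["C1CCCCC1"])  # corrupted product
    report = validate_rulebase(rulebase, pairs)
    assert [e.rule_id for e in report.failures] == [pairs[3][0]]


@pytest.mark.parametrize(
    "smiles,expected_products",
    [
        ("CC(=O)NC", {"CC(=O)O", "CN"}),          # N-methylacetamide
        ("CC(=O)Nc1ccccc1", {"CC(=O)O", "Nc1ccccc1"}),  # acetanilide
    ],
)
def test_amide_rule_products(rulebase, smiles, expected_products):
    mol = mol_from_smiles(smiles)
    matches = [m for m in match_sites(mol, rulebase) if m.rule_id == "R01_amide"]
    assert len(matches) == 1
    assert mol.GetAtomWithIdx(matches[0].atom_index).GetSymbol() == "N"
    assert set(apply_rule(mol, matches[0], rulebase)) == expected_products


def test_flamprop_methyl_two_sites(rulebase):
    """Ester O and amide N are the only matched hydrolysis centers."""
    mol = mol_from_smiles("COC(=O)C(C)N(c1ccc(F)c(Cl)c1)C(=O)c1ccccc1")
    matches = match_sites(mol, rulebase)
    centers = {m.atom_index for m in matches}
    assert len(centers) == 2
    assert sorted(mol.GetAtomWithIdx(i).GetSymbol() for i in centers) == ["N", "O"]


def test_desmedipham_carbamate_products(rulebase):
    mol = mol_from_smiles("CCOC(=O)Nc1cccc(OC(=O)Nc2ccccc2)c1")
    products = set()
    for m in match_sites(mol, rulebase):
        products.update(apply_rule(mol, m, rulebase))
    assert "CCOC(=O)Nc1cccc(O)c1" in products        # ethyl (3-hydroxyphenyl)carbamate
    assert "Nc1cccc(OC(=O)Nc2ccccc2)c1" in products  # 3-aminophenyl phenylcarbamate


def test_no_hydrolyzable_group_empty(rulebase):
    assert match_sites(mol_from_smiles("C"), rulebase) == []
    assert match_sites(mol_from_smiles("c1ccccc1"), rulebase) == []


def test_mass_balance_on_golden_reactants(rulebase):
    """Product heavy atoms = parent + declared water-derived gain, per rule."""
    for rule in rulebase:
        mol = mol_from_smiles(rule.golden_reactant)
        apps = enumerate_applications(mol, rule)
        assert apps, rule.rule_id
        for app in apps:
            total = sum(heavy_atom_count(f) for f in app.products)
            assert total == mol.GetNumHeavyAtoms() + rule.balance_delta, (
                rule.rule_id, app.products)


def test_symmetric_centers_collapsed(rulebase):
    """Automorphic sites with identical products are reported once."""
    # dimethyl carbonate: the two ester oxygens are equivalent
    mol = mol_from_smiles("COC(=O)OC")
    carb = [m for m in match_sites(mol, rulebase) if m.rule_id == "R08_carbonate"]
    assert len(carb) == 1
    # cyanophos: two equivalent O-methyls collapse, the aryl O stays distinct
    cp = mol_from_smiles("COP(=O)(OC)Oc1ccc(C#N)cc1")
    phos = [m for m in match_sites(cp, rulebase) if m.rule_id == "R10_phosphoester"]
    assert len(phos) == 2


def test_match_and_apply_deterministic(rulebase):
    mol = mol_from_smiles("CCOC(=O)Nc1cccc(OC(=O)Nc2ccccc2)c1")
    a, b = match_sites(mol, rulebase), match_sites(mol, rulebase)
    assert a == b
    for m in a:
        assert apply_rule(mol, m, rulebase) == apply_rule(mol, m, rulebase)


def test_apply_rule_at_wrong_atom_errors(rulebase):
    mol = mol_from_smiles("CC(=O)NC")
    good = match_sites(mol, rulebase)[0]
    from hydrosom.rules import SiteMatch

    bad = SiteMatch(rule_id=good.rule_id, atom_index=0)
    with pytest.raises(RuleError, match="does not apply"):
        apply_rule(mol, bad, rulebase)
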