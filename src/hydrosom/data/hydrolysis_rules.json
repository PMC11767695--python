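{
  "version": "1.0",
  "comment": "Reconstructed hydrolysis transformation rule base. Reaction SMARTS are written against aromatic (perceived) forms; the mapped atom named by center_map is the site-of-metabolism atom scored by the site classifiers. balance_delta is the expected heavy-atom gain over all product fragments relative to the parent (+1 for a single water-derived oxygen; +2 where two water equivalents are consumed). Each rule carries one golden reactant/product pair used by validate_rulebase and the test suite.",
  "rules": [
    {
      "rule_id": "R01_amide",
      "name": "Carboxylic amide hydrolysis to acid and amine",
      "family": "amide",
      "smarts": "[#6:1][C:2](=[O:3])[N:4]>>([#6:1][C:2](=[O:3])[OX2H1].[N:4])",
      "atom_class": "N",
      "center_map": 4,
      "environments": ["aquatic", "plant", "animal"],
      "balance_delta": 1,
      "reference": "amide bond cleavage (amidase / base-catalysed)",
      "golden_reactant": "CC(=O)Nc1ccccc1",
      "golden_products": ["CC(=O)O", "Nc1ccccc1"]
    },
    {
      "rule_id": "R02_nitrile_amide",
      "name": "Nitrile hydration to carboxylic amide",
      "family": "nitrile",
      "smarts": "[#6:1][C:2]#[N:3]>>[#6:1][C:2](=[O])[N:3]",
      "atom_class": "N",
      "center_map": 3,
      "environments": ["aquatic", "plant"],
      "balance_delta": 1,
      "reference": "nitrile hydratase-type conversion",
      "golden_reactant": "N#Cc1ccccc1",
      "golden_products": ["NC(=O)c1ccccc1"]
    },
    {
      "rule_id": "R03_nitrile_acid",
      "name": "Nitrile hydrolysis to carboxylic acid and ammonia",
      "family": "nitrile",
      "smarts": "[#6:1][C:2]#[N:3]>>([#6:1][C:2](=[O])[OX2H1].[N:3])",
      "atom_class": "N",
      "center_map": 3,
      "environments": ["aquatic", "plant", "animal"],
      "balance_delta": 2,
      "reference": "nitrilase-type full hydrolysis",
      "golden_reactant": "N#Cc1ccccc1",
      "golden_products": ["O=C(O)c1ccccc1", "N"]
    },
    {
      "rule_id": "R04_urea",
      "name": "Urea hydrolysis to amines and carbon dioxide",
      "family": "urea",
      "smarts": "[#7:1][C:2](=[O:3])[#7:4]>>([#7:1].[#7:4].[C:2](=[O:3])=O)",
      "atom_class": "N",
      "center_map": 1,
      "environments": ["aquatic", "plant"],
      "balance_delta": 1,
      "reference": "urea linkage breakdown",
      "golden_reactant": "CNC(=O)NC",
      "golden_products": ["CN", "CN", "O=C=O"]
    },
    {
      "rule_id": "R05_carbamate_o",
      "name": "Carbamate hydrolysis (ester-oxygen site)",
      "family": "carbamate",
      "smarts": "[#6:1][O:2][C:3](=[O:4])[N:5]>>([#6:1][O:2].[N:5].[C:3](=[O:4])=O)",
      "atom_class": "O",
      "center_map": 2,
      "environments": ["aquatic", "plant", "animal"],
      "balance_delta": 1,
      "reference": "carbamate cleavage to alcohol/phenol, amine and CO2",
      "golden_reactant": "CCOC(=O)Nc1ccccc1",
      "golden_products": ["CCO", "Nc1ccccc1", "O=C=O"]
    },
    {
      "rule_id": "R06_carbamate_n",
      "name": "Carbamate hydrolysis (nitrogen site)",
      "family": "carbamate",
      "smarts": "[#6:1][O:2][C:3](=[O:4])[N:5]>>([#6:1][O:2].[N:5].[C:3](=[O:4])=O)",
      "atom_class": "N",
      "center_map": 5,
      "environments": ["aquatic", "plant", "animal"],
      "balance_delta": 1,
      "reference": "carbamate cleavage to alcohol/phenol, amine and CO2",
      "golden_reactant": "CCOC(=O)Nc1ccccc1",
      "golden_products": ["CCO", "Nc1ccccc1", "O=C=O"]
    },
    {
      "rule_id": "R07_ester",
      "name": "Carboxylic ester hydrolysis to acid and alcohol",
      "family": "ester",
      "smarts": "[#6:1][C:2](=[O:3])[O:4][#6:5]>>([#6:1][C:2](=[O:3])[OX2H1].[O:4][#6:5])",
      "atom_class": "O",
      "center_map": 4,
      "environments": ["aquatic", "plant", "animal"],
      "balance_delta": 1,
      "reference": "esterase / base-catalysed ester cleavage",
      "golden_reactant": "COC(=O)c1ccccc1",
      "golden_products": ["CO", "O=C(O)c1ccccc1"]
    },
    {
      "rule_id": "R08_carbonate",
      "name": "Carbonate ester hydrolysis to alcohols and carbon dioxide",
      "family": "carbonate",
      "smarts": "[#6:1][O:2][C:3](=[O:4])[O:5][#6:6]>>([#6:1][O:2].[#6:6][O:5].[C:3](=[O:4])=O)",
      "atom_class": "O",
      "center_map": 2,
      "environments": ["aquatic"],
      "balance_delta": 1,
      "reference": "carbonate diester breakdown",
      "golden_reactant": "COC(=O)OC",
      "golden_products": ["CO", "CO", "O=C=O"]
    },
    {
      "rule_id": "R09_oxime",
      "name": "Oxime hydrolysis to carbonyl and hydroxylamine",
      "family": "oxime",
      "smarts": "[#6:1][C:2]=[N:3][OX2H1:4]>>([#6:1][C:2]=[O].[N:3][O:4])",
      "atom_class": "O",
      "center_map": 4,
      "environments": ["aquatic", "plant"],
      "balance_delta": 1,
      "reference": "oxime C=N hydrolysis",
      "golden_reactant": "CC(C)=NO",
      "golden_products": ["CC(C)=O", "NO"]
    },
    {
      "rule_id": "R10_phosphoester",
      "name": "Phosphoester hydrolysis (hydroxide substitution at phosphorus)",
      "family": "phosphoester",
      "smarts": "[#6:1][O:2][P:3]>>([#6:1][O:2].[P:3][OX2H1])",
      "atom_class": "O",
      "center_map": 2,
      "environments": ["aquatic", "animal"],
      "balance_delta": 1,
      "reference": "nucleophilic attack of hydroxide at P displacing the leaving-group oxygen; applies to phosphate and phosphorothionate esters",
      "golden_reactant": "COP(=O)(OC)OC",
      "golden_products": ["CO", "COP(=O)(O)OC"]
    },
    {
      "rule_id": "R11_alkyne",
      "name": "Terminal alkyne hydration to methyl ketone",
      "family": "alkyne",
      "smarts": "[#6:1][C:2]#[CH1:3]>>[#6:1][C:2](=[O])[CH3:3]",
      "atom_class": "C",
      "center_map": 2,
      "environments": ["aquatic", "plant"],
      "balance_delta": 1,
      "reference": "Markovnikov water addition across the triple bond",
      "golden_reactant": "CC#C",
      "golden_products": ["CC(C)=O"]
    },
    {
      "rule_id": "R12_thioether",
      "name": "Thioether hydrolytic cleavage to thiol and alcohol",
      "family": "thioether",
      "smarts": "[#6:1][S:2][#6:3]>>([#6:1][S:2].[#6:3][OX2H1])",
      "atom_class": "S",
      "center_map": 2,
      "environments": ["aquatic", "animal"],
      "balance_delta": 1,
      "reference": "C-S bond cleavage with water",
      "golden_reactant": "CSC",
      "golden_products": ["CS", "CO"]
    },
    {
      "rule_id": "R13_acid_chloride",
      "name": "Acid chloride hydrolysis to carboxylic acid",
      "family": "acid_halide",
      "smarts": "[#6:1][C:2](=[O:3])[Cl:4]>>([#6:1][C:2](=[O:3])[OX2H1].[Cl:4])",
      "atom_class": "X",
      "center_map": 4,
      "environments": ["aquatic"],
      "balance_delta": 1,
      "reference": "fast abiotic acyl chloride hydrolysis",
      "golden_reactant": "O=C(Cl)c1ccccc1",
      "golden_products": ["O=C(O)c1ccccc1", "Cl"]
    },
    {
      "rule_id": "R14_haloalkane",
      "name": "Haloalkane hydrolytic dehalogenation",
      "family": "haloalkane",
      "smarts": "[CX4:1][Cl,Br,I:2]>>([CX4:1][OX2H1].[Cl,Br,I:2])",
      "atom_class": "X",
      "center_map": 2,
      "environments": ["aquatic", "plant", "animal"],
      "balance_delta": 1,
      "reference": "SN2 substitution of halide by water/hydroxide at sp3 carbon",
      "golden_reactant": "CCCCCl",
      "golden_products": ["CCCCO", "Cl"]
    }
  ]
}
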