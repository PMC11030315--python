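{
 "comment": "Hand-curated fragment library for the synthetic ligand generator. Cores are SMILES templates with numbered substitution sites; substituents are SMILES fragments valid in branch context. Tags are approximate substructure contributions used only to broaden/steer sampling distributions; true counts are always recomputed on the assembled molecule. Every core x substituent combination is validated with RDKit at library build.",
 "cores": [
  {
   "name": "benzene",
   "template": "c1ccc({0})cc1",
   "sites": 1,
   "pool_only": false
  },
  {
   "name": "pyridine",
   "template": "c1ccc({0})nc1",
   "sites": 1,
   "pool_only": false
  },
  {
   "name": "cyclohexane",
   "template": "C1CCC({0})C({1})C1",
   "sites": 2,
   "pool_only": false
  },
  {
   "name": "piperidine",
   "template": "C1CC({0})N({1})CC1",
   "sites": 2,
   "pool_only": false
  },
  {
   "name": "tetrahydropyran",
   "template": "C1CCC({0})CO1",
   "sites": 1,
   "pool_only": false
  },
  {
   "name": "morpholine",
   "template": "C1COCCN1{0}",
   "sites": 1,
   "pool_only": false
  },
  {
   "name": "biphenyl",
   "template": "c1ccc(-c2ccc({0})cc2)cc1",
   "sites": 1,
   "pool_only": false
  },
  {
   "name": "tetralin",
   "template": "c1ccc2c(c1)CCC({0})C2",
   "sites": 1,
   "pool_only": false
  },
  {
   "name": "pyrrole",
   "template": "c1cc({0})[nH]c1",
   "sites": 1,
   "pool_only": false
  },
  {
   "name": "quinoline",
   "template": "c1ccc2nc({0})ccc2c1",
   "sites": 1,
   "pool_only": false
  },
  {
   "name": "naphthalene",
   "template": "c1ccc2cc({0})ccc2c1",
   "sites": 1,
   "pool_only": true
  },
  {
   "name": "cyclopentane",
   "template": "C1CCC({0})C1",
   "sites": 1,
   "pool_only": true
  },
  {
   "name": "benzene_di",
   "template": "c1cc({0})ccc1{1}",
   "sites": 2,
   "pool_only": false
  },
  {
   "name": "pyridine_di",
   "template": "c1cc({0})cnc1{1}",
   "sites": 2,
   "pool_only": false
  },
  {
   "name": "tetrahydropyran_di",
   "template": "C1CC({0})C({1})CO1",
   "sites": 2,
   "pool_only": false
  },
  {
   "name": "cyclohexane_tri",
   "template": "C1CC({0})C({1})CC1{2}",
   "sites": 3,
   "pool_only": false
  },
  {
   "name": "piperidine_tri",
   "template": "C1C({0})CC({1})N({2})C1",
   "sites": 3,
   "pool_only": false
  }
 ],
 "substituents": [
  {
   "name": "hydrogen",
   "smiles": "[H]",
   "tags": []
  },
  {
   "name": "methyl",
   "smiles": "C",
   "tags": []
  },
  {
   "name": "ethyl",
   "smiles": "CC",
   "tags": []
  },
  {
   "name": "propyl",
   "smiles": "CCC",
   "tags": []
  },
  {
   "name": "isopropyl",
   "smiles": "C(C)C",
   "tags": []
  },
  {
   "name": "tert_butyl",
   "smiles": "C(C)(C)C",
   "tags": []
  },
  {
   "name": "fluoro",
   "smiles": "F",
   "tags": []
  },
  {
   "name": "chloro",
   "smiles": "Cl",
   "tags": []
  },
  {
   "name": "bromo",
   "smiles": "Br",
   "tags": []
  },
  {
   "name": "methoxy",
   "smiles": "OC",
   "tags": []
  },
  {
   "name": "nitrile",
   "smiles": "C#N",
   "tags": []
  },
  {
   "name": "carboxyl",
   "smiles": "C(=O)O",
   "tags": []
  },
  {
   "name": "amide",
   "smiles": "C(=O)N",
   "tags": []
  },
  {
   "name": "phenyl",
   "smiles": "c8ccccc8",
   "tags": []
  },
  {
   "name": "hydroxymethyl",
   "smiles": "CO",
   "tags": [
    "oh"
   ]
  },
  {
   "name": "hydroxyethyl",
   "smiles": "CCO",
   "tags": [
    "oh"
   ]
  },
  {
   "name": "hydroxypropyl",
   "smiles": "CCCO",
   "tags": [
    "oh"
   ]
  },
  {
   "name": "sec_alcohol",
   "smiles": "CC(O)C",
   "tags": [
    "oh"
   ]
  },
  {
   "name": "diol",
   "smiles": "C(CO)CO",
   "tags": [
    "oh",
    "oh"
   ]
  },
  {
   "name": "glyceryl",
   "smiles": "CC(O)CO",
   "tags": [
    "oh",
    "oh"
   ]
  },
  {
   "name": "triol",
   "smiles": "C(CO)(CO)CO",
   "tags": [
    "oh",
    "oh",
    "oh"
   ]
  },
  {
   "name": "dimethylamino",
   "smiles": "N(C)C",
   "tags": [
    "amine"
   ]
  },
  {
   "name": "dimethylaminomethyl",
   "smiles": "CN(C)C",
   "tags": [
    "amine"
   ]
  },
  {
   "name": "dimethylaminoethyl",
   "smiles": "CCN(C)C",
   "tags": [
    "amine"
   ]
  },
  {
   "name": "diethylaminoethyl",
   "smiles": "CCN(CC)CC",
   "tags": [
    "amine"
   ]
  },
  {
   "name": "pyrrolidinylmethyl",
   "smiles": "CN8CCCC8",
   "tags": [
    "amine"
   ]
  },
  {
   "name": "pyridyl",
   "smiles": "c8ccncc8",
   "tags": [
    "aromhet"
   ]
  },
  {
   "name": "furyl",
   "smiles": "c8ccco8",
   "tags": [
    "aromhet"
   ]
  },
  {
   "name": "thienyl",
   "smiles": "c8cccs8",
   "tags": [
    "aromhet"
   ]
  },
  {
   "name": "imidazolylmethyl",
   "smiles": "Cn8ccnc8",
   "tags": [
    "imid",
    "aromhet"
   ]
  },
  {
   "name": "imidazolyl",
   "smiles": "c8cnc[nH]8",
   "tags": [
    "imid",
    "aromhet"
   ]
  },
  {
   "name": "pyrazolyl",
   "smiles": "c8cc[nH]n8",
   "tags": [
    "aromhet"
   ]
  },
  {
   "name": "sec_butanol",
   "smiles": "C(O)CC",
   "tags": [
    "oh"
   ]
  },
  {
   "name": "hydroxybutyl",
   "smiles": "CCC(O)CO",
   "tags": [
    "oh",
    "oh"
   ]
  },
  {
   "name": "tert_alcohol",
   "smiles": "C(C)(O)C",
   "tags": [
    "oh"
   ]
  },
  {
   "name": "hydroxyisobutyl",
   "smiles": "C(CO)C",
   "tags": [
    "oh"
   ]
  },
  {
   "name": "pentanol",
   "smiles": "CCC(O)C",
   "tags": [
    "oh"
   ]
  },
  {
   "name": "fluoro_ethanol",
   "smiles": "C(F)CO",
   "tags": [
    "oh"
   ]
  }
 ]
}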