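"""Small hand-checkable fixture molecules for tests and examples.

Each entry is (name, smiles, alternative_smiles): two different spellings
of the same molecule, used to exercise the graph-invariance of shinglings
and fingerprints.  All molecules are small enough to enumerate substructure
environments by hand.
"""

FIXTURE_MOLECULES: list[tuple[str, str, str]] = [
    ("ethane", "CC", "CC"),
    ("propane", "CCC", "C(C)C"),
    ("butane", "CCCC", "C(C)CC"),
    ("isobutane", "CC(C)C", "C(C)(C)C"),
    ("pentane", "CCCCC", "C(CC)CC"),
    ("neopentane", "CC(C)(C)C", "C(C)(C)(C)C"),
    ("hexane", "CCCCCC", "C(CCC)CC"),
    ("2-methylpentane", "CC(C)CCC", "CCCC(C)C"),
    ("cyclopropane", "C1CC1", "C1CC1"),
    ("cyclobutane", "C1CCC1", "C1CCC1"),
    ("cyclopentane", "C1CCCC1", "C1CCCC1"),
    ("cyclohexane", "C1CCCCC1", "C1CCCCC1"),
    ("methylcyclohexane", "CC1CCCCC1", "C1CCCCC1C"),
    ("benzene", "c1ccccc1", "C1=CC=CC=C1"),
    ("toluene", "Cc1ccccc1", "c1ccccc1C"),
    ("styrene", "C=Cc1ccccc1", "c1ccccc1C=C"),
    ("ethylbenzene", "CCc1ccccc1", "c1ccccc1CC"),
    ("xylene-o", "Cc1ccccc1C", "c1ccc(C)c(C)c1"),
    ("naphthalene", "c1ccc2ccccc2c1", "c1ccc2c(c1)cccc2"),
    ("pyridine", "c1ccncc1", "n1ccccc1"),
    ("pyrimidine", "c1cncnc1", "c1ncncc1"),
    ("pyrrole", "c1cc[nH]c1", "[nH]1cccc1"),
    ("furan", "c1ccoc1", "o1cccc1"),
    ("thiophene", "c1ccsc1", "s1cccc1"),
    ("imidazole", "c1c[nH]cn1", "n1cc[nH]c1"),
    ("ethanol", "CCO", "OCC"),
    ("methanol", "CO", "OC"),
    ("isopropanol", "CC(O)C", "CC(C)O"),
    ("acetic-acid", "CC(=O)O", "OC(C)=O"),
    ("acetone", "CC(=O)C", "CC(C)=O"),
    ("acetaldehyde", "CC=O", "O=CC"),
    ("formic-acid", "OC=O", "C(=O)O"),
    ("dimethyl-ether", "COC", "O(C)C"),
    ("methylamine", "CN", "NC"),
    ("dimethylamine", "CNC", "N(C)C"),
    ("trimethylamine", "CN(C)C", "N(C)(C)C"),
    ("acetonitrile", "CC#N", "N#CC"),
    ("acetamide", "CC(N)=O", "NC(C)=O"),
    ("urea", "NC(N)=O", "O=C(N)N"),
    ("glycine", "NCC(=O)O", "OC(=O)CN"),
    ("alanine", "CC(N)C(=O)O", "OC(=O)C(C)N"),
    ("ethylene-glycol", "OCCO", "C(O)CO"),
    ("glycerol", "OCC(O)CO", "C(O)(CO)CO"),
    ("chloroform", "ClC(Cl)Cl", "C(Cl)(Cl)Cl"),
    ("dichloromethane", "ClCCl", "C(Cl)Cl"),
    ("fluorobenzene", "Fc1ccccc1", "c1ccccc1F"),
    ("phenol", "Oc1ccccc1", "c1ccccc1O"),
    ("aniline", "Nc1ccccc1", "c1ccccc1N"),
    ("benzoic-acid", "OC(=O)c1ccccc1", "c1ccccc1C(=O)O"),
    ("anisole", "COc1ccccc1", "c1ccccc1OC"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", "Cn1c(=O)c2c(ncn2C)n(C)c1=O"),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", "OC(=O)c1ccccc1OC(C)=O"),
]
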