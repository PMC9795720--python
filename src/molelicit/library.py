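"""Synthetic drug-like SMILES library generator.

The elicitation experiments need a fixed pool of candidate molecules standing
in for the output of a generative model or a public compound database. This
module enumerates a combinatorial library of scaffold x substituent
combinations spanning a wide range of molecular weight, lipophilicity,
polarity and flexibility, so that desirability parameters are identifiable
from feedback on pool members. The library is synthetic: it contains valid,
broadly drug-like structures but does not emulate the bioactivity landscape,
synthesizability or scaffold diversity of a curated screening collection.
"""

from __future__ import annotations

import itertools

import numpy as np
from rdkit import Chem

from .chem_io import Molecule

# Aromatic/heteroaromatic cores with two substitution points.
_SCAFFOLDS = [
    "{a}c1ccc({b})cc1",            # para-benzene
    "{a}c1cccc({b})c1",            # meta-benzene
    "{a}c1ccc({b})cn1",            # pyridine
    "{a}c1ccc2ccccc2c1{b}",        # naphthalene
    "{a}c1ccc(-c2ccc({b})cc2)cc1", # biphenyl
    "{a}c1ccc2[nH]c({b})cc2c1",    # indole
    "{a}c1ccc2occ({b})c2c1",       # benzofuran
    "{a}c1nc({b})cs1",             # thiazole
    "{a}c1cc({b})no1",             # isoxazole
    "{a}c1ccc(C(=O)N{b})cc1",      # benzamide linker
    "{a}c1ccc(OCC(=O)N{b})cc1",    # aryloxyacetamide linker
    "{a}c1ccc(CN{b})cc1",          # benzylamine linker
]

# Substituents written so that plain string substitution yields valid SMILES
# when attached through a single bond.
_SUBSTITUENTS_A = [
    "", "C", "CC", "CCC", "CCCC", "CCCCCC", "O", "OC", "OCC", "N", "NC",
    "Cl", "F", "Br", "C(F)(F)F", "C(C)(C)C", "C#N", "OCCO", "NC(C)=O",
    "S(C)(=O)=O", "C(=O)O", "C(=O)OC", "CN(C)C", "CCN1CCOCC1", "CCCN(C)C",
]
_SUBSTITUENTS_B = [
    "C", "CC", "CCO", "CCN", "CCCC", "C(C)C", "CC(C)C", "CCOC", "CCOCC",
    "Cc1ccccc1", "CCc1ccccn1", "CC(=O)N", "CCS(C)(=O)=O", "CC(=O)O",
    "CCN(C)C", "CCCN1CCCC1", "C1CCCCC1", "CC1CCNCC1", "CCn1ccnc1",
    "CCOc1ccccc1",
    # heavier, more polar groups so MW/PSA span the drug-like range
    "CC(=O)Nc1ccc(S(N)(=O)=O)cc1",
    "CCN(CCO)C(=O)c1ccc(OC)c(OC)c1",
    "CC(=O)NCCc1ccc(O)c(O)c1",
    "CCOC(=O)C1CCN(Cc2ccccc2)CC1",
    "CCNC(=O)c1ccc(N2CCN(C)CC2)cc1",
    "CC(NC(=O)c1ccc(O)cc1O)C(=O)NC",
]


def generate_library(
    n: int = 2000, seed: int = 0, shuffle: bool = True
) -> list[Molecule]:
    """Enumerate a deterministic library of *n* unique valid molecules.

    Scaffold/substituent combinations are enumerated in a fixed order,
    validated with RDKit, canonicalized and deduplicated; *seed* only
    controls the final shuffle (which subset of the full enumeration is
    returned is therefore stable for fixed *n*).
    """
    seen: set[str] = set()
    smiles_list: list[str] = []
    combos = itertools.product(_SCAFFOLDS, _SUBSTITUENTS_A, _SUBSTITUENTS_B)
    for scaffold, a, b in combos:
        smi = scaffold.format(a=a, b=b)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        can = Chem.MolToSmiles(mol)
        if can in seen:
            continue
        seen.add(can)
        smiles_list.append(can)
        if len(smiles_list) >= 4 * n:
            break
    if shuffle:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(smiles_list))[:n]
    else:
        idx = np.arange(min(n, len(smiles_list)))
    return [Molecule(smiles_list[i]) for i in idx]
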