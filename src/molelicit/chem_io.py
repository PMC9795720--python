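"""Molecule parsing, canonicalization, descriptors, fingerprints and file I/O.

Every molecule entering the package is canonicalized once; descriptor vectors
and fingerprints are cached on the :class:`Molecule` so repeated scoring during
an elicitation run never recomputes RDKit properties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdFingerprintGenerator

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # parse errors are reported through exceptions

#: Fixed descriptor order; scoring components refer to descriptors by index
#: into this tuple and nothing else.
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "MW",
    "SlogP",
    "HBD",
    "HBA",
    "PSA",
    "RotatableBonds",
    "AromaticRings",
)

N_DESCRIPTORS = len(DESCRIPTOR_NAMES)


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"invalid SMILES: {smiles!r}")


def canonicalize(smiles: str) -> str:
    """Return the RDKit-canonical form of *smiles*.

    Idempotent, and invariant under atom-order permutations of the same
    molecule. Raises :class:`SmilesParseError` on unparseable input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return Chem.MolToSmiles(mol)


@dataclass
class Molecule:
    """A molecule with lazily cached descriptor vector and fingerprint.

    ``smiles`` is always the canonical form; construct via
    :meth:`Molecule.from_smiles` unless the string is already canonical.
    """

    smiles: str
    _rdkit: Chem.Mol | None = field(default=None, repr=False, compare=False)
    _descriptors: np.ndarray | None = field(default=None, repr=False, compare=False)
    _fingerprints: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_smiles(cls, smiles: str) -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise SmilesParseError(smiles)
        return cls(smiles=Chem.MolToSmiles(mol), _rdkit=mol)

    @property
    def rdkit(self) -> Chem.Mol:
        if self._rdkit is None:
            self._rdkit = Chem.MolFromSmiles(self.smiles)
            if self._rdkit is None:  # pragma: no cover - smiles is canonical
                raise SmilesParseError(self.smiles)
        return self._rdkit

    @property
    def descriptors(self) -> np.ndarray:
        """7-vector of physicochemical properties in :data:`DESCRIPTOR_NAMES` order."""
        if self._descriptors is None:
            self._descriptors = compute_descriptors(self)
        return self._descriptors

    def fingerprint(self, radius: int = 3, nbits: int = 2048) -> np.ndarray:
        """Binary Morgan fingerprint (ECFP-style; radius 3 = ECFP6)."""
        key = (radius, nbits)
        if key not in self._fingerprints:
            self._fingerprints[key] = morgan_fingerprint(self, radius, nbits)
        return self._fingerprints[key]


def compute_descriptors(mol: Molecule | Chem.Mol) -> np.ndarray:
    """Compute the 7 descriptors in :data:`DESCRIPTOR_NAMES` order.

    MW is the average molecular weight, SlogP the Crippen partition
    coefficient, HBD/HBA the Lipinski donor/acceptor counts, PSA the
    topological polar surface area.
    """
    rd = mol.rdkit if isinstance(mol, Molecule) else mol
    return np.array(
        [
            Descriptors.MolWt(rd),
            Crippen.MolLogP(rd),
            Lipinski.NumHDonors(rd),
            Lipinski.NumHAcceptors(rd),
            Descriptors.TPSA(rd),
            Lipinski.NumRotatableBonds(rd),
            Lipinski.NumAromaticRings(rd),
        ],
        dtype=float,
    )


def morgan_fingerprint(mol: Molecule | Chem.Mol, radius: int = 3, nbits: int = 2048) -> np.ndarray:
    """Binary Morgan fingerprint of length *nbits* as a uint8 array in {0,1}."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if nbits < 64:
        raise ValueError("nbits must be >= 64")
    rd = mol.rdkit if isinstance(mol, Molecule) else mol
    gen = _fp_generator(radius, nbits)
    bv = gen.GetFingerprint(rd)
    arr = np.zeros(nbits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


_GENERATORS: dict = {}


def _fp_generator(radius: int, nbits: int):
    key = (radius, nbits)
    if key not in _GENERATORS:
        _GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits
        )
    return _GENERATORS[key]


def descriptor_matrix(mols: list[Molecule]) -> np.ndarray:
    """Stack cached descriptor vectors into an (N, 7) matrix."""
    return np.array([m.descriptors for m in mols], dtype=float)


def fingerprint_matrix(mols: list[Molecule], radius: int = 3, nbits: int = 2048) -> np.ndarray:
    """Stack fingerprints into an (N, nbits) binary matrix."""
    return np.array([m.fingerprint(radius, nbits) for m in mols], dtype=np.uint8)


def read_smiles(path) -> list[Molecule]:
    """Read a SMILES file (one SMILES per line, optional tab-separated name).

    Invalid SMILES are skipped with a logged warning; the count of skipped
    rows is logged at the end.
    """
    mols: list[Molecule] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smiles = line.split("\t")[0].split()[0]
            try:
                mols.append(Molecule.from_smiles(smiles))
            except SmilesParseError:
                skipped += 1
                logger.warning("skipping invalid SMILES %r in %s", smiles, path)
    if skipped:
        logger.warning("%d invalid SMILES skipped in %s", skipped, path)
    return mols


def write_smiles(path, mols: list[Molecule]) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write(m.smiles + "\n")


def write_feedback_csv(path, records: list[tuple[Molecule, float]]) -> None:
    """Write feedback records as a CSV with header ``smiles,label``."""
    df = pd.DataFrame(
        {"smiles": [m.smiles for m, _ in records], "label": [y for _, y in records]}
    )
    df.to_csv(path, index=False)


def read_feedback_csv(path) -> list[tuple[Molecule, float]]:
    """Read a ``smiles,label`` CSV into (Molecule, label) pairs.

    Labels must lie in [0, 1] (binary labels are the endpoints). Rows with
    invalid SMILES are skipped with a warning.
    """
    df = pd.read_csv(path)
    missing = {"smiles", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"feedback CSV {path} missing columns: {sorted(missing)}")
    records: list[tuple[Molecule, float]] = []
    skipped = 0
    for smiles, label in zip(df["smiles"], df["label"]):
        label = float(label)
        if not 0.0 <= label <= 1.0:
            raise ValueError(f"label {label} for {smiles!r} outside [0, 1]")
        try:
            records.append((Molecule.from_smiles(str(smiles)), label))
        except SmilesParseError:
            skipped += 1
            logger.warning("skipping invalid SMILES %r in %s", smiles, path)
    if skipped:
        logger.warning("%d invalid rows skipped in %s", skipped, path)
    return records
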