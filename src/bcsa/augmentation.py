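"""Dataset expansion by SMILES enumeration.

One molecule admits many valid SMILES strings (CCO, OCC and C(O)C all
denote ethanol).  Enumerating randomized atom-order rewritings of each
molecule multiplies the number of training sequences without changing the
chemistry, and grouping the variants by parent molecule lets predictions be
averaged per molecule at evaluation time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

#: Random atom orderings attempted per requested variant before giving up.
ATTEMPT_BUDGET_FACTOR = 10


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string does not parse to a molecule."""


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule: identifier, SMILES and scalar property target."""

    molecule_id: str
    smiles: str
    target: float


@dataclass(frozen=True)
class AugmentedRecord:
    """An enumerated SMILES variant tied back to its parent molecule."""

    molecule_id: str
    variant_smiles: str
    target: float


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"SMILES does not parse: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    """Canonical form used as the molecular-identity oracle."""
    return Chem.MolToSmiles(_parse(smiles))


def enumerate_smiles(
    smiles: str,
    k: int,
    seed: int,
    include_source: bool = True,
) -> list[str]:
    """Return up to ``k`` distinct SMILES rewritings of one molecule.

    Variants are produced by renumbering the atoms with a seeded random
    permutation and writing a non-canonical SMILES from the new order, so
    every variant canonicalizes back to the input molecule.  Up to
    ``ATTEMPT_BUDGET_FACTOR * k`` orderings are tried; simple molecules that
    admit fewer than ``k`` distinct strings yield fewer variants.  With
    ``include_source`` the input string itself is the first variant, which
    makes ``k=1`` reproduce the un-augmented input exactly.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    mol = _parse(smiles)
    rng = np.random.default_rng(seed)
    variants: list[str] = []
    seen: set[str] = set()
    if include_source:
        variants.append(smiles)
        seen.add(smiles)
    n_atoms = mol.GetNumAtoms()
    for _ in range(ATTEMPT_BUDGET_FACTOR * k):
        if len(variants) >= k:
            break
        order = rng.permutation(n_atoms).tolist()
        shuffled = Chem.RenumberAtoms(mol, order)
        variant = Chem.MolToSmiles(shuffled, canonical=False)
        if variant not in seen:
            seen.add(variant)
            variants.append(variant)
    return variants[:k]


def augment_dataset(
    records: list[MoleculeRecord], k: int, seed: int
) -> list[AugmentedRecord]:
    """Expand each record into up to ``k`` de-duplicated SMILES variants.

    Targets and molecule ids are copied unchanged; an unparseable SMILES
    aborts the whole augmentation naming the offending molecule.  Each
    molecule gets an independent stream drawn from ``seed`` so the output is
    reproducible and insensitive to record order within a molecule.
    """
    if not records:
        raise ValueError("records must be non-empty")
    root = np.random.default_rng(seed)
    child_seeds = root.integers(0, 2**31 - 1, size=len(records))
    out: list[AugmentedRecord] = []
    for record, child_seed in zip(records, child_seeds):
        try:
            variants = enumerate_smiles(record.smiles, k, int(child_seed))
        except InvalidSmilesError as exc:
            raise InvalidSmilesError(
                f"molecule {record.molecule_id!r}: {exc}"
            ) from exc
        out.extend(
            AugmentedRecord(record.molecule_id, v, record.target)
            for v in variants
        )
    return out


def group_by_molecule(
    records: list[AugmentedRecord],
) -> dict[str, list[AugmentedRecord]]:
    """Partition augmented records by parent molecule id (insertion order)."""
    groups: dict[str, list[AugmentedRecord]] = {}
    for record in records:
        groups.setdefault(record.molecule_id, []).append(record)
    return groups


def as_augmented(records: list[MoleculeRecord]) -> list[AugmentedRecord]:
    """View plain records as single-variant augmented records (k=1 identity)."""
    return [
        AugmentedRecord(r.molecule_id, r.smiles, r.target) for r in records
    ]
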