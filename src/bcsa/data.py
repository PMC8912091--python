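"""Dataset file handling, splitting, and synthetic molecule generation.

Datasets are plain CSV (UTF-8, header, "." decimal) with a ``smiles`` column
and a scalar ``target`` column; ``molecule_id`` is optional and auto-assigned.
The synthetic generator emulates a small-molecule property dataset at desk
scale: molecules are assembled from a fragment grammar (alkyl units, ether
or hydroxyl oxygen, halogens, benzene rings) and the noise-free target is an
exact additive function of fragment counts — a group-contribution toy
property in the spirit of logP/logS increments, so the structure-property
relation is deterministic and learnable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .augmentation import InvalidSmilesError, MoleculeRecord, canonical_smiles

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# CSV input/output


def read_dataset(path: str | Path, strict: bool = True) -> list[MoleculeRecord]:
    """Read a CSV with ``smiles`` and ``target`` columns into records.

    Every SMILES is validated; in strict mode an invalid one aborts with its
    row number, otherwise invalid rows are skipped with a logged count.
    """
    frame = pd.read_csv(path)
    missing = {"smiles", "target"} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if "molecule_id" not in frame.columns:
        frame["molecule_id"] = [f"m{i:06d}" for i in range(len(frame))]
    records = []
    n_skipped = 0
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        if Chem.MolFromSmiles(row.smiles) is None:
            if strict:
                raise InvalidSmilesError(
                    f"{path}: row {row_number}: invalid SMILES {row.smiles!r}"
                )
            n_skipped += 1
            continue
        records.append(
            MoleculeRecord(str(row.molecule_id), row.smiles, float(row.target))
        )
    if n_skipped:
        logger.warning("%s: skipped %d invalid row(s)", path, n_skipped)
    return records


def write_dataset(records, path: str | Path) -> None:
    """Write molecule or augmented records back to CSV."""
    rows = []
    for r in records:
        if hasattr(r, "variant_smiles"):
            rows.append(
                {"molecule_id": r.molecule_id, "smiles": r.variant_smiles,
                 "variant_smiles": r.variant_smiles, "target": r.target}
            )
        else:
            rows.append(
                {"molecule_id": r.molecule_id, "smiles": r.smiles,
                 "target": r.target}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_augmented(path: str | Path):
    """Read an augmented CSV (variant_smiles column) back into records."""
    from .augmentation import AugmentedRecord

    frame = pd.read_csv(path)
    col = "variant_smiles" if "variant_smiles" in frame.columns else "smiles"
    return [
        AugmentedRecord(str(r.molecule_id), getattr(r, col), float(r.target))
        for r in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# splitting


def split_dataset(
    records: list[MoleculeRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
):
    """Random 8:1:1 (by default) partition into train/validation/test.

    Sizes are floor(f_train N) and floor(f_val N) with the remainder going
    to the test split, so the partition is exhaustive and disjoint.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n = len(records)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(fractions[0] * n)
    n_val = int(fractions[1] * n)
    train = [records[i] for i in order[:n_train]]
    val = [records[i] for i in order[n_train : n_train + n_val]]
    test = [records[i] for i in order[n_train + n_val :]]
    return train, val, test


# ---------------------------------------------------------------------------
# synthetic molecules with an additive ground-truth property

#: Fragment grammar: name -> (SMILES piece, additive coefficient).  Chain
#: pieces concatenate into a backbone; halogen pieces terminate it.  The
#: coefficients loosely echo hydrophobicity increments: each aliphatic
#: carbon contributes +0.5, an oxygen -1.0, a benzene ring +2.0, Cl +0.7
#: and F +0.25.
FRAGMENTS: dict[str, tuple[str, float]] = {
    "methyl": ("C", 0.5),
    "ethyl": ("CC", 1.0),
    "propyl": ("CCC", 1.5),
    "oxygen": ("O", -1.0),
    "benzene": ("c1ccccc1", 2.0),
    "chloro": ("Cl", 0.7),
    "fluoro": ("F", 0.25),
}

_CHAIN = ("methyl", "ethyl", "propyl", "oxygen", "benzene")
_TERMINAL = ("chloro", "fluoro")


@dataclass
class SyntheticSpec:
    """Generator settings for a synthetic molecule dataset.

    ``n_molecules`` unique molecules of 2-8 fragments each; the target is
    the exact dot product of fragment counts with :data:`FRAGMENTS`
    coefficients plus Gaussian noise of standard deviation ``noise_sd``.
    """

    n_molecules: int = 100
    noise_sd: float = 0.0
    seed: int = 0
    min_fragments: int = 2
    max_fragments: int = 8
    retry_factor: int = 20

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 1 <= self.min_fragments <= self.max_fragments:
            raise ValueError("fragment count bounds are inconsistent")


def generate_synthetic(spec: SyntheticSpec) -> list[MoleculeRecord]:
    """Generate unique, valid molecules with an additive ground-truth target.

    Molecules are assembled by seeded random fragment composition, validated
    and de-duplicated by canonical SMILES; duplicates are regenerated up to
    ``retry_factor * n_molecules`` attempts, after which fewer molecules are
    returned with a warning.
    """
    # separate streams: the structures drawn are invariant to noise_sd
    struct_seq, noise_seq = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(struct_seq)
    noise_rng = np.random.default_rng(noise_seq)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    attempts = 0
    budget = spec.retry_factor * spec.n_molecules
    while len(records) < spec.n_molecules and attempts < budget:
        attempts += 1
        n_frag = int(rng.integers(spec.min_fragments, spec.max_fragments + 1))
        n_terminal = int(rng.integers(0, min(2, n_frag - 1) + 1))
        names = [str(rng.choice(_CHAIN)) for _ in range(n_frag - n_terminal)]
        names += [str(rng.choice(_TERMINAL)) for _ in range(n_terminal)]
        smiles = "".join(FRAGMENTS[name][0] for name in names)
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # grammar guarantees validity; guard anyway
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        target = sum(FRAGMENTS[name][1] for name in names)
        if spec.noise_sd > 0:
            target += float(noise_rng.normal(0.0, spec.noise_sd))
        records.append(
            MoleculeRecord(f"syn{len(records):06d}", smiles, float(target))
        )
    if len(records) < spec.n_molecules:
        logger.warning(
            "retry budget exhausted: generated %d of %d molecules",
            len(records), spec.n_molecules,
        )
    return records
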