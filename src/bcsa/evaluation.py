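"""Regression metrics and per-molecule averaged prediction.

Metrics are the four standard regression indicators: coefficient of
determination (R2), Spearman rank correlation (average-rank ties), root mean
squared error and mean absolute error.  Because one molecule may be
represented by many enumerated SMILES, evaluation first averages the
predictions of a molecule's variants and scores at the molecule level —
test-time augmentation that reduces the variance of the final estimate.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .augmentation import AugmentedRecord, enumerate_smiles, group_by_molecule
from .model import BCSARegressor
from .tokenizer import TokenizerSpec, Vocabulary, encode_batch


@dataclass(frozen=True)
class MetricsReport:
    """R2, Spearman, RMSE and MAE for one prediction set."""

    r2: float
    spearman: float
    rmse: float
    mae: float
    n_molecules: int

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def compute_metrics(predictions, targets) -> MetricsReport:
    """Score a prediction vector against its targets."""
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predictions.shape != targets.shape:
        raise ValueError("length mismatch between predictions and targets")
    if targets.size < 2:
        raise ValueError("need at least two observations")
    if np.all(targets == targets[0]):
        raise ValueError("zero target variance: R2 undefined")
    if np.all(predictions == predictions[0]):
        rho = float("nan")  # rank correlation undefined for constant input
    else:
        rho = spearmanr(predictions, targets).statistic
    return MetricsReport(
        r2=float(r2_score(targets, predictions)),
        spearman=float(rho),
        rmse=float(math.sqrt(mean_squared_error(targets, predictions))),
        mae=float(mean_absolute_error(targets, predictions)),
        n_molecules=int(targets.size),
    )


def averaged_prediction(
    model: BCSARegressor,
    vocab: Vocabulary,
    tokenizer_spec: TokenizerSpec,
    smiles: str,
    k: int,
    seed: int,
    include_source: bool = True,
) -> float:
    """Mean model prediction over up to ``k`` enumerated SMILES variants.

    With ``k=1`` (and the source form included) this equals the plain
    single-SMILES prediction.
    """
    variants = enumerate_smiles(smiles, k, seed, include_source=include_source)
    X = encode_batch(variants, vocab, tokenizer_spec)
    return float(model.predict(X).mean())


def evaluate_split(
    model: BCSARegressor,
    vocab: Vocabulary,
    tokenizer_spec: TokenizerSpec,
    records: list[AugmentedRecord],
) -> tuple[MetricsReport, pd.DataFrame]:
    """Molecule-level metrics over a stored augmented split.

    Each molecule's prediction is the mean over its stored enumerated
    variants; metrics compare one averaged prediction per molecule against
    one target per molecule.  Also returns a per-molecule table
    (molecule_id, target, prediction mean and standard deviation, variant
    count).  Molecules with inconsistent targets are rejected.
    """
    groups = group_by_molecule(records)
    if not groups:
        raise ValueError("empty split")
    rows = []
    for molecule_id, group in groups.items():
        targets = {r.target for r in group}
        if len(targets) != 1:
            raise ValueError(
                f"molecule {molecule_id!r} has inconsistent targets: {targets}"
            )
        X = encode_batch(
            [r.variant_smiles for r in group], vocab, tokenizer_spec
        )
        preds = model.predict(X)
        rows.append(
            {
                "molecule_id": molecule_id,
                "target": group[0].target,
                "prediction_mean": float(preds.mean()),
                "prediction_sd": float(preds.std(ddof=0)),
                "n_variants": len(group),
            }
        )
    table = pd.DataFrame(rows)
    report = compute_metrics(
        table["prediction_mean"].to_numpy(), table["target"].to_numpy()
    )
    report = MetricsReport(**{**report.to_dict(), "n_molecules": len(table)})
    return report, table
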