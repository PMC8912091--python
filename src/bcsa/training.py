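"""Model training and hyperparameter search.

Training minimizes mean squared error over shuffled mini-batches with Adam,
monitors molecule-averaged validation R-squared after every epoch, keeps the
best-R2 parameters as the checkpoint, and stops early when the monitor fails
to improve for ``patience`` epochs.

Hyperparameter search minimizes the negated coefficient of determination
(-R2) on the validation split with a Tree-structured Parzen Estimator: after
a few random startup trials, completed trials are split into a good and a bad
set at an objective quantile, each hyperparameter dimension is modelled by a
Parzen density over each set, and candidates maximizing the good/bad density
ratio are selected.  The sampler is written here directly because the search
space is small and fully factorized.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .augmentation import AugmentedRecord
from .model import BCSARegressor, ModelConfig
from .nn import Adam
from .tokenizer import TokenizerSpec, Vocabulary, build_vocab, encode_batch, tokenize

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


# ---------------------------------------------------------------------------
# losses / objectives


def mse_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Mean squared error (1/N) sum (yhat_i - y_i)^2."""
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predictions.shape != targets.shape:
        raise ValueError(
            f"length mismatch: {predictions.shape} vs {targets.shape}"
        )
    if predictions.size == 0:
        raise ValueError("empty prediction vector")
    return float(np.mean((predictions - targets) ** 2))


def neg_r2_objective(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Negated coefficient of determination, the search minimization target.

    -(1 - SS_res / SS_tot): -1 for perfect prediction, 0 when predicting the
    target mean.  Undefined (rejected) when the targets have zero variance.
    """
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if predictions.shape != targets.shape:
        raise ValueError("length mismatch")
    if targets.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((targets - targets.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("zero target variance: R2 undefined")
    ss_res = float(np.sum((predictions - targets) ** 2))
    return -(1.0 - ss_res / ss_tot)


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainSettings:
    """Epoch budget, early-stopping patience and the reproducibility seed."""

    max_epochs: int = 400
    patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 1 <= self.patience <= self.max_epochs:
            raise ValueError("patience must lie in [1, max_epochs]")


class EarlyStopper:
    """Track a maximized monitor; signal a stop after ``patience`` epochs
    without improvement.  The best epoch is remembered for checkpointing."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = -np.inf
        self.best_epoch: int | None = None
        self.wait = 0

    def update(self, epoch: int, value: float) -> bool:
        """Record one epoch's monitor value; return True to stop now."""
        if value > self.best:
            self.best = value
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


@dataclass
class TrainResult:
    model: BCSARegressor
    vocab: Vocabulary
    tokenizer_spec: TokenizerSpec
    history: pd.DataFrame
    best_epoch: int
    best_val_r2: float


def prepare_encoder(
    records: list[AugmentedRecord], config: ModelConfig
) -> tuple[Vocabulary, TokenizerSpec]:
    """Build vocabulary and tokenizer settings from the training split only."""
    spec = TokenizerSpec(max_len=config.smiles_max_len)
    vocab = build_vocab(
        (tokenize(r.variant_smiles, spec) for r in records),
        max_size=config.vocab_size,
    )
    return vocab, spec


def _grouped_mean(pred: np.ndarray, ids: np.ndarray, targets: np.ndarray):
    """Average predictions (and targets) per molecule id; order of first
    appearance."""
    frame = pd.DataFrame({"id": ids, "pred": pred, "target": targets})
    g = frame.groupby("id", sort=False).mean()
    return g["pred"].to_numpy(), g["target"].to_numpy()


def _predict_in_chunks(model: BCSARegressor, X: np.ndarray,
                       chunk: int = 2048) -> np.ndarray:
    parts = [model.predict(X[i : i + chunk]) for i in range(0, len(X), chunk)]
    return np.concatenate(parts)


def train(
    train_records: list[AugmentedRecord],
    val_records: list[AugmentedRecord],
    config: ModelConfig,
    settings: TrainSettings,
    vocab: Vocabulary | None = None,
    tokenizer_spec: TokenizerSpec | None = None,
    init_model: BCSARegressor | None = None,
) -> TrainResult:
    """Fit the network by mini-batch MSE minimization with Adam.

    The vocabulary is built from the training split unless supplied.  After
    every epoch the molecule-averaged validation R2 is computed; the
    best-R2 parameters are checkpointed and restored at the end.  Passing
    ``init_model`` resumes from existing parameters (fine-tuning for a few
    additional epochs).
    """
    if not train_records or not val_records:
        raise ValueError("train and validation sets must be non-empty")
    if vocab is None or tokenizer_spec is None:
        vocab, tokenizer_spec = prepare_encoder(train_records, config)

    X_train = encode_batch(
        [r.variant_smiles for r in train_records], vocab, tokenizer_spec
    )
    y_train = np.array([r.target for r in train_records], dtype=np.float64)
    X_val = encode_batch(
        [r.variant_smiles for r in val_records], vocab, tokenizer_spec
    )
    y_val = np.array([r.target for r in val_records], dtype=np.float64)
    val_ids = np.array([r.molecule_id for r in val_records])

    model = init_model or BCSARegressor(replace(config, seed=settings.seed))
    optimizer = Adam(model.params, lr=config.learning_rate)
    stopper = EarlyStopper(settings.patience)
    rng = np.random.default_rng(settings.seed)
    best_state = model.state_dict()
    rows = []

    n = len(X_train)
    for epoch in range(1, settings.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            preds, cache = model.forward(X_train[idx], training=True)
            residual = preds - y_train[idx]
            loss = float(np.mean(residual**2))
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}; "
                    "consider lowering the learning rate"
                )
            grads = model.backward(2.0 * residual / len(idx), cache)
            optimizer.step(model.params, grads)
            epoch_loss += loss * len(idx)
        epoch_loss /= n

        val_pred = _predict_in_chunks(model, X_val)
        mol_pred, mol_target = _grouped_mean(val_pred, val_ids, y_val)
        val_r2 = -neg_r2_objective(mol_pred, mol_target)
        val_rmse = math.sqrt(mse_loss(mol_pred, mol_target))
        rows.append(
            {"epoch": epoch, "train_loss": epoch_loss,
             "val_r2": val_r2, "val_rmse": val_rmse}
        )
        logger.info(
            "epoch %d: train MSE %.5f, val R2 %.4f", epoch, epoch_loss, val_r2
        )
        improved = val_r2 > stopper.best
        stop = stopper.update(epoch, val_r2)
        if improved:
            best_state = model.state_dict()
        if stop:
            logger.info("early stop at epoch %d (patience %d)",
                        epoch, settings.patience)
            break

    model.load_state_dict(best_state)
    return TrainResult(
        model=model,
        vocab=vocab,
        tokenizer_spec=tokenizer_spec,
        history=pd.DataFrame(rows),
        best_epoch=int(stopper.best_epoch),
        best_val_r2=float(stopper.best),
    )


# ---------------------------------------------------------------------------
# hyperparameter search


@dataclass(frozen=True)
class SearchSpace:
    """Per-hyperparameter domains.

    Each entry is ``("choice", values)``, ``("int", lo, hi)``,
    ``("uniform", lo, hi)`` or ``("loguniform", lo, hi)``.  The default is
    the published search space: batch size {512, 1024}, vocabulary size
    {120, 150}, sequence length {150, 200}, hidden size {16, 32, 64},
    3-5 stacked layers, dropout in [0, 0.6], head width {32, 64} and
    learning rate in [0.001, 0.01].
    """

    domains: dict = field(
        default_factory=lambda: {
            "batch_size": ("choice", (512, 1024)),
            "vocab_size": ("choice", (120, 150)),
            "smiles_max_len": ("choice", (150, 200)),
            "hidden_size": ("choice", (16, 32, 64)),
            "num_layers": ("int", 3, 5),
            "dropout": ("uniform", 0.0, 0.6),
            "mlp_hidden_size": ("choice", (32, 64)),
            "learning_rate": ("loguniform", 0.001, 0.01),
        }
    )

    def contains(self, params: dict) -> bool:
        for name, domain in self.domains.items():
            v = params[name]
            kind = domain[0]
            if kind == "choice" and v not in domain[1]:
                return False
            if kind == "int" and not (
                domain[1] <= v <= domain[2] and float(v).is_integer()
            ):
                return False
            if kind in ("uniform", "loguniform") and not (
                domain[1] <= v <= domain[2]
            ):
                return False
        return True


class _TPESampler:
    """Factorized Tree-structured Parzen Estimator over a SearchSpace."""

    def __init__(self, space: SearchSpace, rng, n_startup: int = 5,
                 gamma: float = 0.25, n_candidates: int = 24):
        self.space = space
        self.rng = rng
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates

    # random draw from the prior
    def _random(self, domain):
        kind = domain[0]
        if kind == "choice":
            return domain[1][self.rng.integers(len(domain[1]))]
        if kind == "int":
            return int(self.rng.integers(domain[1], domain[2] + 1))
        if kind == "uniform":
            return float(self.rng.uniform(domain[1], domain[2]))
        if kind == "loguniform":
            lo, hi = math.log(domain[1]), math.log(domain[2])
            return float(math.exp(self.rng.uniform(lo, hi)))
        raise ValueError(f"unknown domain kind {kind!r}")

    @staticmethod
    def _categorical_logpdf(value, observed, values):
        counts = {v: 1.0 for v in values}  # Laplace smoothing
        for o in observed:
            counts[o] += 1.0
        total = sum(counts.values())
        return math.log(counts[value] / total)

    def _continuous_logpdf(self, x, observed, lo, hi):
        width = hi - lo
        sigma = width * max(0.05, 1.0 / math.sqrt(len(observed) + 1))
        comps = [
            -0.5 * ((x - mu) / sigma) ** 2 - math.log(sigma * math.sqrt(2 * math.pi))
            for mu in observed
        ]
        # small uniform floor keeps the density positive everywhere
        comps.append(math.log(1.0 / width))
        m = max(comps)
        return m + math.log(
            sum(math.exp(c - m) for c in comps) / len(comps)
        )

    def _suggest_dim(self, name, domain, good_vals, bad_vals):
        kind = domain[0]
        if kind in ("choice", "int"):
            values = (
                list(domain[1]) if kind == "choice"
                else list(range(domain[1], domain[2] + 1))
            )
            best, best_score = None, -np.inf
            for v in values:
                score = self._categorical_logpdf(
                    v, good_vals, values
                ) - self._categorical_logpdf(v, bad_vals, values)
                if score > best_score:
                    best, best_score = v, score
            return best
        log_scale = kind == "loguniform"
        lo_orig, hi_orig = domain[1], domain[2]
        lo, hi = lo_orig, hi_orig
        if log_scale:
            lo, hi = math.log(lo), math.log(hi)
            good_vals = [math.log(v) for v in good_vals]
            bad_vals = [math.log(v) for v in bad_vals]
        width = hi - lo
        sigma = width * max(0.05, 1.0 / math.sqrt(len(good_vals) + 1))
        best, best_score = None, -np.inf
        for _ in range(self.n_candidates):
            mu = good_vals[self.rng.integers(len(good_vals))]
            x = float(np.clip(self.rng.normal(mu, sigma), lo, hi))
            score = self._continuous_logpdf(
                x, good_vals, lo, hi
            ) - self._continuous_logpdf(x, bad_vals, lo, hi)
            if score > best_score:
                best, best_score = x, score
        value = math.exp(best) if log_scale else best
        # exp/log round trips can overshoot the bounds by one ulp
        return min(max(value, lo_orig), hi_orig)

    def suggest(self, history: list[tuple[dict, float]]) -> dict:
        done = [(p, o) for p, o in history if math.isfinite(o)]
        if len(done) < self.n_startup:
            return {
                name: self._random(domain)
                for name, domain in self.space.domains.items()
            }
        done.sort(key=lambda t: t[1])
        n_good = max(1, math.ceil(self.gamma * len(done)))
        good = [p for p, _ in done[:n_good]]
        bad = [p for p, _ in done[n_good:]] or good
        return {
            name: self._suggest_dim(
                name, domain,
                [p[name] for p in good], [p[name] for p in bad],
            )
            for name, domain in self.space.domains.items()
        }


def tpe_search(
    space: SearchSpace,
    train_records: list[AugmentedRecord],
    val_records: list[AugmentedRecord],
    n_trials: int,
    settings: TrainSettings,
    seed: int = 0,
    base_config: ModelConfig | None = None,
) -> tuple[ModelConfig, pd.DataFrame]:
    """Minimize -R2 on the validation split over the hyperparameter space.

    Each trial samples a configuration, trains it under the trial budget in
    ``settings`` and scores the checkpointed validation R2.  A trial whose
    loss diverges is recorded with an infinite objective and skipped.
    Returns the best configuration and the full trial log.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    base = base_config or ModelConfig()
    sampler = _TPESampler(space, np.random.default_rng(seed))
    history: list[tuple[dict, float]] = []
    rows = []
    best_params: dict | None = None
    best_objective = np.inf
    for trial in range(n_trials):
        params = sampler.suggest(history)
        config = replace(
            base,
            **params,
            seed=(seed + trial) % (2**31 - 1),
            embed_dim=None,
        )
        trial_settings = replace(settings, seed=config.seed)
        try:
            result = train(train_records, val_records, config, trial_settings)
            objective = -result.best_val_r2
            epochs_run = int(result.history["epoch"].max())
        except TrainingDivergedError as exc:
            logger.warning("trial %d diverged: %s", trial, exc)
            objective = np.inf
            epochs_run = 0
        history.append((params, objective))
        rows.append(
            {"trial": trial, **params, "objective": objective,
             "epochs_run": epochs_run}
        )
        if objective < best_objective:
            best_objective = objective
            best_params = params
        logger.info("trial %d: objective %.4f", trial, objective)
    if best_params is None:
        raise TrainingDivergedError("every trial diverged")
    best_config = replace(
        base, **best_params, seed=settings.seed, embed_dim=None
    )
    return best_config, pd.DataFrame(rows)
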