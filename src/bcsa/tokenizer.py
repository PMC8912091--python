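"""SMILES tokenization, vocabulary construction and integer encoding.

A SMILES string is split into chemically meaningful tokens — bracket atom
expressions (``[nH]``, ``[O-]``), two-letter halogens (``Cl``, ``Br``),
organic-subset atoms, bond/branch/ring punctuation and ``%NN`` two-digit ring
labels — using the tokenization regex that is standard for sequence models
over SMILES.  Token sequences are mapped through a frequency-ordered
vocabulary to fixed-length integer vectors, truncated and right-padded.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Standard SMILES tokenization pattern: bracket atoms, two-letter halogens,
#: single-letter atoms (aromatic lowercase included), bonds, branches, ring
#: bond digits and %NN ring labels.
SMILES_TOKEN_PATTERN = (
    r"(\[[^\]]+]|Br?|Cl?|N|O|S|P|F|I|b|c|n|o|s|p|\(|\)|\.|=|#|-|\+|\\|\/|:"
    r"|~|@|\?|>|\*|\$|%[0-9]{2}|[0-9])"
)

PAD_TOKEN = "<pad>"
UNK_TOKEN = "<unk>"
PAD_INDEX = 0
UNK_INDEX = 1


class TokenizationError(ValueError):
    """Raised when a SMILES string contains characters the regex cannot match."""


@dataclass(frozen=True)
class TokenizerSpec:
    """Tokenization settings: the token regex and the fixed encoding length.

    ``max_len`` is the number of token positions every encoded molecule
    occupies (default 150); longer token sequences are truncated, shorter
    ones right-padded with ``pad_token``.
    """

    pattern: str = SMILES_TOKEN_PATTERN
    max_len: int = 150
    pad_token: str = PAD_TOKEN
    unk_token: str = UNK_TOKEN

    def __post_init__(self) -> None:
        if self.max_len <= 0:
            raise ValueError(f"max_len must be positive, got {self.max_len}")

    @property
    def regex(self) -> re.Pattern:
        return re.compile(self.pattern)


@dataclass(frozen=True)
class Vocabulary:
    """Injective token -> index map with reserved pad (0) and unk (1) slots."""

    token_to_index: dict[str, int]

    def __post_init__(self) -> None:
        if self.token_to_index.get(PAD_TOKEN) != PAD_INDEX:
            raise ValueError("pad token must map to index 0")
        if self.token_to_index.get(UNK_TOKEN) != UNK_INDEX:
            raise ValueError("unk token must map to index 1")
        indices = sorted(self.token_to_index.values())
        if indices != list(range(len(indices))):
            raise ValueError("indices must be contiguous from 0 and unique")

    @property
    def size(self) -> int:
        return len(self.token_to_index)

    def index_of(self, token: str) -> int:
        return self.token_to_index.get(token, UNK_INDEX)

    def save(self, path: str | Path) -> None:
        """Write a two-column text file (token TAB index), sorted by index."""
        lines = sorted(self.token_to_index.items(), key=lambda kv: kv[1])
        text = "".join(f"{tok}\t{idx}\n" for tok, idx in lines)
        Path(path).write_text(text, encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        mapping: dict[str, int] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line:
                continue
            tok, idx = line.rsplit("\t", 1)
            mapping[tok] = int(idx)
        return cls(mapping)


@dataclass
class EncodedMolecule:
    """A SMILES mapped to a fixed-length integer index vector."""

    indices: np.ndarray
    n_real: int
    source_smiles: str

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.n_real > self.indices.shape[0]:
            raise ValueError("n_real exceeds vector length")


def tokenize(smiles: str, spec: TokenizerSpec | None = None) -> list[str]:
    """Split a SMILES string into tokens.

    Every character must be consumed by the token regex; an unmatched
    character raises :class:`TokenizationError` naming its position rather
    than being silently dropped.
    """
    if not smiles:
        raise TokenizationError("empty SMILES string")
    spec = spec or TokenizerSpec()
    tokens: list[str] = []
    pos = 0
    for match in spec.regex.finditer(smiles):
        if match.start() != pos:
            raise TokenizationError(
                f"unrecognized character {smiles[pos]!r} at position {pos} "
                f"in SMILES {smiles!r}"
            )
        tokens.append(match.group(0))
        pos = match.end()
    if pos != len(smiles):
        raise TokenizationError(
            f"unrecognized character {smiles[pos]!r} at position {pos} "
            f"in SMILES {smiles!r}"
        )
    return tokens


def build_vocab(corpus, max_size: int = 120) -> Vocabulary:
    """Build a vocabulary from an iterable of token lists.

    Slots beyond pad/unk are filled by descending corpus frequency with
    lexicographic tie-breaking, so the result is identical across runs.
    """
    if max_size < 3:
        raise ValueError("max_size must be at least 3 (pad, unk, one token)")
    counts: Counter[str] = Counter()
    n_lists = 0
    for tokens in corpus:
        counts.update(tokens)
        n_lists += 1
    if n_lists == 0:
        raise ValueError("corpus is empty")
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    mapping = {PAD_TOKEN: PAD_INDEX, UNK_TOKEN: UNK_INDEX}
    for token, _ in ordered[: max_size - 2]:
        mapping[token] = len(mapping)
    return Vocabulary(mapping)


def encode(
    tokens: list[str], vocab: Vocabulary, spec: TokenizerSpec
) -> EncodedMolecule:
    """Map tokens to indices, truncate at ``max_len`` and right-pad with 0."""
    kept = tokens[: spec.max_len]
    indices = np.full(spec.max_len, PAD_INDEX, dtype=np.int64)
    for i, tok in enumerate(kept):
        indices[i] = vocab.index_of(tok)
    return EncodedMolecule(
        indices=indices, n_real=len(kept), source_smiles="".join(tokens)
    )


def encode_smiles(
    smiles: str, vocab: Vocabulary, spec: TokenizerSpec
) -> EncodedMolecule:
    """Convenience composition of :func:`tokenize` and :func:`encode`."""
    enc = encode(tokenize(smiles, spec), vocab, spec)
    enc.source_smiles = smiles
    return enc


def encode_batch(
    smiles_list, vocab: Vocabulary, spec: TokenizerSpec
) -> np.ndarray:
    """Encode many SMILES into a (batch, max_len) int64 index matrix."""
    out = np.empty((len(smiles_list), spec.max_len), dtype=np.int64)
    for i, smi in enumerate(smiles_list):
        out[i] = encode_smiles(smi, vocab, spec).indices
    return out
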