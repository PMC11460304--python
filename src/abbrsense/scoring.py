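"""Binary pair classifiers: the (50, 2) ReLU head and trainable scorer backends.

The disambiguation decision is a binary classification of each
context-candidate pair: class 1 means "this candidate is the correct
expansion".  The classification head is two linear layers with a rectified
linear unit between them — pooled input vector → hidden width 50 → 2 logits —
followed by a softmax; ranking uses the class-1 probability.

Two interchangeable backends satisfy the :class:`Scorer` contract:

``lexical``
    A logistic-regression model over sparse lexical features of the pair:
    a candidate-identity indicator, candidate-word × context-word
    co-occurrence counts, the count of candidate tokens literally present in
    the context, and the candidate token length.  Deterministic, CPU-trainable
    in seconds, and convex (continued training refits on the expanded pair
    multiset, which for a convex objective reaches the same optimum as
    warm-started descent).

``mlp``
    The classification head itself, trained end to end by seeded mini-batch
    gradient descent on a fixed-width hashed encoding of the same sparse
    features.  This is the head architecture doing real work; a pretrained
    bidirectional-encoder backend would plug into the same contract by
    replacing the hashed features with the encoder's [CLS] vector.

Scores are reproducible bit for bit for a fixed trained scorer.
"""

from __future__ import annotations

import json
import zlib
from collections import Counter
from collections.abc import Sequence
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .pairs import ContextCandidatePair

__all__ = [
    "ClassificationHead",
    "TrainConfig",
    "Scorer",
    "LexicalScorer",
    "MLPScorer",
    "DegenerateDataError",
    "FormatError",
    "head_forward",
    "train_scorer",
    "score_pair",
    "save_scorer",
    "load_scorer",
]

SCORER_FORMAT_VERSION = 1


class DegenerateDataError(ValueError):
    """Training set lacks one of the two classes (or is empty)."""


class FormatError(ValueError):
    """A scorer archive is corrupted or has an incompatible version."""


# ---------------------------------------------------------------------------
# classification head
# ---------------------------------------------------------------------------


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - np.max(logits)
    exp = np.exp(shifted)
    return exp / exp.sum()


@dataclass
class ClassificationHead:
    """Two linear layers with ReLU: input width d → hidden 50 → 2 classes.

    ``w1`` has shape (d, hidden), ``w2`` shape (hidden, 2); the output is the
    softmax over the two logits.
    """

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=np.float64)
        self.b1 = np.asarray(self.b1, dtype=np.float64)
        self.w2 = np.asarray(self.w2, dtype=np.float64)
        self.b2 = np.asarray(self.b2, dtype=np.float64)
        if self.w2.shape[1] != 2 or self.b2.shape != (2,):
            raise ValueError("output dimensionality must be exactly 2")
        if self.w1.shape[1] != self.b1.shape[0] or self.w1.shape[1] != self.w2.shape[0]:
            raise ValueError("hidden widths of the two layers do not match")

    @property
    def input_width(self) -> int:
        return self.w1.shape[0]

    @property
    def hidden_width(self) -> int:
        return self.w1.shape[1]

    @classmethod
    def initialize(cls, input_width: int, hidden: int = 50, seed: int = 0) -> "ClassificationHead":
        rng = np.random.default_rng(seed)
        scale1 = 1.0 / np.sqrt(input_width)
        scale2 = 1.0 / np.sqrt(hidden)
        return cls(
            w1=rng.normal(0.0, scale1, size=(input_width, hidden)),
            b1=np.zeros(hidden),
            w2=rng.normal(0.0, scale2, size=(hidden, 2)),
            b2=np.zeros(2),
        )


def head_forward(x: Sequence[float] | np.ndarray, head: ClassificationHead) -> tuple[float, float]:
    """Forward pass linear → ReLU → linear → softmax; returns (p0, p1)."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (head.input_width,):
        raise ValueError(
            f"input width {x.shape} does not match head input width ({head.input_width},)"
        )
    hidden = np.maximum(x @ head.w1 + head.b1, 0.0)
    probs = _softmax(hidden @ head.w2 + head.b2)
    return float(probs[0]), float(probs[1])


# ---------------------------------------------------------------------------
# sparse lexical features
# ---------------------------------------------------------------------------


def _pair_features(pair: ContextCandidatePair) -> dict[str, float]:
    """Sparse named features of one context-candidate pair."""
    context = [t for t in pair.context_tokens]
    cand_tokens = list(pair.candidate_tokens)
    cand_set = set(cand_tokens)
    feats: dict[str, float] = {f"cand={pair.candidate}": 1.0}
    for word, count in Counter(context).items():
        feats[f"cooc|{pair.candidate}|{word}"] = float(count)
    feats["overlap"] = float(sum(1 for t in context if t in cand_set))
    feats["candlen"] = float(len(cand_tokens))
    return feats


def _hash_features(feats: dict[str, float], dim: int) -> np.ndarray:
    """Fixed-width hashed encoding (signed hashing trick, crc32-based)."""
    vec = np.zeros(dim, dtype=np.float64)
    for name, value in feats.items():
        h = zlib.crc32(name.encode("utf-8"))
        sign = 1.0 if (h >> 31) & 1 == 0 else -1.0
        vec[h % dim] += sign * value
    return vec


# ---------------------------------------------------------------------------
# configuration and scorer contract
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Training configuration; the seed is mandatory for reproducibility."""

    backend: str = "lexical"
    seed: int = 0
    epochs: int = 3
    learning_rate: float = 0.1
    batch_size: int = 16
    token_budget: int = 512
    hidden_size: int = 50
    feature_dim: int = 1024
    regularization_c: float = 10.0
    encoder_checkpoint: str | None = None

    def __post_init__(self) -> None:
        if self.backend not in ("lexical", "mlp"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainConfig":
        return cls(**json.loads(Path(path).read_text()))


def _pair_to_obj(p: ContextCandidatePair) -> dict:
    return {
        "index": p.index,
        "target": p.target,
        "candidate": p.candidate,
        "label": p.label,
        "tokens": list(p.tokens),
        "segment_boundary": p.segment_boundary,
        "attention_mask": list(p.attention_mask),
    }


def _pair_from_obj(o: dict) -> ContextCandidatePair:
    return ContextCandidatePair(
        index=str(o["index"]),
        target=o["target"],
        candidate=o["candidate"],
        tokens=tuple(o["tokens"]),
        segment_boundary=int(o["segment_boundary"]),
        label=int(o["label"]),
        attention_mask=tuple(o["attention_mask"]),
    )


def _check_trainable(pairs: Sequence[ContextCandidatePair]) -> None:
    labels = {p.label for p in pairs}
    if not pairs:
        raise DegenerateDataError("empty training pair set")
    if labels != {0, 1}:
        raise DegenerateDataError(
            f"training pairs must contain both classes; saw labels {sorted(labels)}"
        )


class Scorer:
    """Contract: a trained binary classifier exposing a class-1 probability."""

    backend: str
    config: TrainConfig
    metadata: dict

    def score(self, pair: ContextCandidatePair) -> float:
        raise NotImplementedError

    def update(self, pairs: Sequence[ContextCandidatePair]) -> "Scorer":
        """Continue training with additional pairs; returns self."""
        raise NotImplementedError


class LexicalScorer(Scorer):
    """Logistic regression over the sparse lexical features (deterministic)."""

    backend = "lexical"

    def __init__(self, config: TrainConfig):
        self.config = config
        self.metadata = {"seed": config.seed, "epochs": config.epochs}
        self._feature_index: dict[str, int] = {}
        self._coef: np.ndarray | None = None
        self._intercept: float = 0.0
        self._train_pairs: list[ContextCandidatePair] = []

    # -- training ----------------------------------------------------------

    def fit(self, pairs: Sequence[ContextCandidatePair]) -> "LexicalScorer":
        _check_trainable(pairs)
        self._train_pairs = list(pairs)
        feats_per_pair = [_pair_features(p) for p in pairs]
        index: dict[str, int] = {}
        for feats in feats_per_pair:
            for name in feats:
                if name not in index:
                    index[name] = len(index)
        X = np.zeros((len(pairs), len(index)))
        y = np.fromiter((p.label for p in pairs), dtype=np.int64, count=len(pairs))
        for i, feats in enumerate(feats_per_pair):
            for name, value in feats.items():
                X[i, index[name]] = value
        model = LogisticRegression(
            solver="liblinear",
            C=self.config.regularization_c,
            random_state=self.config.seed,
            max_iter=1000,
        )
        model.fit(X, y)
        self._feature_index = index
        self._coef = model.coef_[0].copy()
        self._intercept = float(model.intercept_[0])
        return self

    def update(self, pairs: Sequence[ContextCandidatePair]) -> "LexicalScorer":
        # convex objective: refit on the expanded pair multiset
        return self.fit(self._train_pairs + list(pairs))

    # -- inference ---------------------------------------------------------

    def _margin(self, pair: ContextCandidatePair) -> float:
        if self._coef is None:
            raise RuntimeError("scorer is untrained")
        z = self._intercept
        for name, value in _pair_features(pair).items():
            col = self._feature_index.get(name)
            if col is not None:
                z += self._coef[col] * value
        return z

    def score(self, pair: ContextCandidatePair) -> float:
        z = self._margin(pair)
        return float(1.0 / (1.0 + np.exp(-z)))

    def feature_weight(self, name: str) -> float:
        """Learned weight of a named feature (0.0 if unseen in training)."""
        col = self._feature_index.get(name)
        return 0.0 if col is None or self._coef is None else float(self._coef[col])

    # -- persistence -------------------------------------------------------

    def _state(self) -> dict:
        return {
            "feature_index": self._feature_index,
            "coef": self._coef.tolist() if self._coef is not None else None,
            "intercept": self._intercept,
            "train_pairs": [_pair_to_obj(p) for p in self._train_pairs],
        }

    def _load_state(self, state: dict) -> None:
        self._feature_index = dict(state["feature_index"])
        self._coef = np.asarray(state["coef"]) if state["coef"] is not None else None
        self._intercept = float(state["intercept"])
        self._train_pairs = [_pair_from_obj(o) for o in state["train_pairs"]]


class MLPScorer(Scorer):
    """The (50, 2) head trained by seeded mini-batch gradient descent.

    Pairs are encoded as fixed-width hashed feature vectors (L2-normalized);
    the head is optimized with softmax cross-entropy.  Continued training
    resumes from the current parameters on the expanded pair multiset.
    """

    backend = "mlp"

    def __init__(self, config: TrainConfig):
        self.config = config
        self.metadata = {"seed": config.seed, "epochs": config.epochs}
        self.head: ClassificationHead | None = None
        self.loss_history: list[float] = []
        self._train_pairs: list[ContextCandidatePair] = []

    def _encode(self, pair: ContextCandidatePair) -> np.ndarray:
        vec = _hash_features(_pair_features(pair), self.config.feature_dim)
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec

    def fit(self, pairs: Sequence[ContextCandidatePair]) -> "MLPScorer":
        _check_trainable(pairs)
        self._train_pairs = list(pairs)
        self.head = ClassificationHead.initialize(
            self.config.feature_dim, self.config.hidden_size, self.config.seed
        )
        self.loss_history = []
        self._descend(self._train_pairs, self.config.epochs)
        return self

    def update(self, pairs: Sequence[ContextCandidatePair]) -> "MLPScorer":
        if self.head is None:
            raise RuntimeError("scorer is untrained")
        self._train_pairs = self._train_pairs + list(pairs)
        self._descend(self._train_pairs, self.config.epochs)
        return self

    def _descend(self, pairs: Sequence[ContextCandidatePair], epochs: int) -> None:
        assert self.head is not None
        X = np.stack([self._encode(p) for p in pairs])
        y = np.fromiter((p.label for p in pairs), dtype=np.int64, count=len(pairs))
        rng = np.random.default_rng(self.config.seed + 1)
        lr = self.config.learning_rate
        bs = self.config.batch_size
        h = self.head
        for _ in range(epochs):
            order = rng.permutation(len(pairs))
            epoch_loss = 0.0
            for start in range(0, len(pairs), bs):
                idx = order[start : start + bs]
                xb, yb = X[idx], y[idx]
                pre = xb @ h.w1 + h.b1
                hid = np.maximum(pre, 0.0)
                logits = hid @ h.w2 + h.b2
                shifted = logits - logits.max(axis=1, keepdims=True)
                exp = np.exp(shifted)
                probs = exp / exp.sum(axis=1, keepdims=True)
                epoch_loss += -np.log(
                    np.clip(probs[np.arange(len(idx)), yb], 1e-12, None)
                ).sum()
                grad_logits = probs.copy()
                grad_logits[np.arange(len(idx)), yb] -= 1.0
                grad_logits /= len(idx)
                grad_w2 = hid.T @ grad_logits
                grad_b2 = grad_logits.sum(axis=0)
                grad_hid = grad_logits @ h.w2.T
                grad_hid[pre <= 0] = 0.0
                grad_w1 = xb.T @ grad_hid
                grad_b1 = grad_hid.sum(axis=0)
                h.w1 -= lr * grad_w1
                h.b1 -= lr * grad_b1
                h.w2 -= lr * grad_w2
                h.b2 -= lr * grad_b2
            self.loss_history.append(epoch_loss / len(pairs))

    def score(self, pair: ContextCandidatePair) -> float:
        if self.head is None:
            raise RuntimeError("scorer is untrained")
        _, p1 = head_forward(self._encode(pair), self.head)
        return p1

    def _state(self) -> dict:
        assert self.head is not None
        return {
            "w1": self.head.w1.tolist(),
            "b1": self.head.b1.tolist(),
            "w2": self.head.w2.tolist(),
            "b2": self.head.b2.tolist(),
            "loss_history": self.loss_history,
            "train_pairs": [_pair_to_obj(p) for p in self._train_pairs],
        }

    def _load_state(self, state: dict) -> None:
        self.head = ClassificationHead(
            w1=np.asarray(state["w1"]),
            b1=np.asarray(state["b1"]),
            w2=np.asarray(state["w2"]),
            b2=np.asarray(state["b2"]),
        )
        self.loss_history = list(state["loss_history"])
        self._train_pairs = [_pair_from_obj(o) for o in state["train_pairs"]]


_BACKENDS = {"lexical": LexicalScorer, "mlp": MLPScorer}


def train_scorer(
    pairs: Sequence[ContextCandidatePair], config: TrainConfig
) -> Scorer:
    """Train a scorer of the configured backend on labelled pairs.

    Raises :class:`DegenerateDataError` when the pairs carry fewer than two
    classes.  Training is reproducible for a fixed seed.
    """
    scorer = _BACKENDS[config.backend](config)
    return scorer.fit(pairs)


def score_pair(scorer: Scorer, pair: ContextCandidatePair) -> float:
    """Class-1 probability of the pair under a trained scorer (in [0, 1])."""
    return scorer.score(pair)


def save_scorer(scorer: Scorer, path: str | Path) -> Path:
    """Persist a scorer to a directory with a JSON manifest + parameters."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": SCORER_FORMAT_VERSION,
        "backend": scorer.backend,
        "config": asdict(scorer.config),
        "metadata": scorer.metadata,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    (path / "params.json").write_text(json.dumps(scorer._state()) + "\n")
    return path


def load_scorer(path: str | Path) -> Scorer:
    """Load a scorer archive; scores identically to the saved scorer."""
    path = Path(path)
    try:
        manifest = json.loads((path / "manifest.json").read_text())
        if manifest.get("format_version") != SCORER_FORMAT_VERSION:
            raise FormatError(
                f"unsupported scorer format version {manifest.get('format_version')}"
            )
        config = TrainConfig(**manifest["config"])
        scorer = _BACKENDS[manifest["backend"]](config)
        scorer.metadata = manifest["metadata"]
        scorer._load_state(json.loads((path / "params.json").read_text()))
    except FormatError:
        raise
    except (OSError, ValueError, KeyError, TypeError) as exc:
        raise FormatError(f"corrupted or unreadable scorer archive at {path}: {exc}") from exc
    return scorer
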