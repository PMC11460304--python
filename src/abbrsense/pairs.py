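"""Context-candidate pair assembly: tokenization, special tokens, FIFO truncation.

Every instance with ``n`` candidate expansions becomes ``n`` binary-labelled
sequences — one per candidate, exactly one labelled 1 (the gold expansion).
Each sequence follows the two-segment sentence-pair layout

    [CLS] <left> <target> <right> [SEP] <candidate> [SEP]

with segment A running from [CLS] through the first [SEP] (the context, target
included in place) and segment B covering the candidate expansion.  Sequences
longer than the token budget are trimmed first-in-first-out: the oldest context
tokens are dropped until the sequence fits.  The candidate segment is never
trimmed — it is the class descriptor — and note that the target abbreviation
itself is *not* protected: if it sits early in a very long context it can be
truncated away, a known failure mode of FIFO trimming.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Protocol, runtime_checkable

from .corpus import AbbrevInstance, SenseInventory

__all__ = [
    "TokenizerContract",
    "WhitespaceTokenizer",
    "WordPieceTokenizer",
    "ContextCandidatePair",
    "CapacityError",
    "assemble_sequence",
    "fifo_truncate",
    "generate_pairs",
    "pad_batch",
    "read_pairs_jsonl",
    "write_pairs_jsonl",
]

CLS, SEP, PAD, UNK = "[CLS]", "[SEP]", "[PAD]", "[UNK]"
DEFAULT_BUDGET = 512


@runtime_checkable
class TokenizerContract(Protocol):
    """Minimal subword-tokenizer surface the pipeline depends on.

    ``tokenize`` must be deterministic and must never emit the special tokens
    on plain text; ``model_max_length`` is the token budget (512 for standard
    bidirectional encoders).
    """

    cls_token: str
    sep_token: str
    pad_token: str
    model_max_length: int

    def tokenize(self, text: str) -> list[str]: ...


class WhitespaceTokenizer:
    """Whitespace word tokenizer satisfying :class:`TokenizerContract`.

    Suitable for normalized text and synthetic corpora where the
    disambiguation signal is whole-word co-occurrence.
    """

    cls_token = CLS
    sep_token = SEP
    pad_token = PAD

    def __init__(self, model_max_length: int = DEFAULT_BUDGET):
        self.model_max_length = model_max_length

    def tokenize(self, text: str) -> list[str]:
        specials = {self.cls_token, self.sep_token, self.pad_token}
        return [tok for tok in text.split() if tok not in specials]


class WordPieceTokenizer:
    """Greedy longest-match-first subword tokenizer over an explicit vocabulary.

    Words absent from the vocabulary are split into the longest known prefix
    followed by ``##``-prefixed continuation pieces (e.g. ``amputation`` →
    ``['amp', '##utation']`` when the vocabulary holds those pieces); a word
    with no decomposition becomes ``[UNK]``.
    """

    cls_token = CLS
    sep_token = SEP
    pad_token = PAD
    unk_token = UNK

    def __init__(self, vocab: Iterable[str], model_max_length: int = DEFAULT_BUDGET):
        self.vocab = frozenset(vocab)
        self.model_max_length = model_max_length

    def _split_word(self, word: str) -> list[str]:
        pieces: list[str] = []
        start = 0
        while start < len(word):
            end = len(word)
            piece = None
            while end > start:
                sub = word[start:end]
                if start > 0:
                    sub = "##" + sub
                if sub in self.vocab:
                    piece = sub
                    break
                end -= 1
            if piece is None:
                return [self.unk_token]
            pieces.append(piece)
            start = end
        return pieces

    def tokenize(self, text: str) -> list[str]:
        specials = {self.cls_token, self.sep_token, self.pad_token}
        out: list[str] = []
        for word in text.split():
            if word in specials:
                continue
            out.extend(self._split_word(word))
        return out


class CapacityError(ValueError):
    """Token budget cannot hold the specials, the candidate, and any context."""


@dataclass(frozen=True)
class ContextCandidatePair:
    """One assembled token sequence tying an instance to one candidate.

    ``segment_boundary`` is the position of the first [SEP]; tokens before it
    (plus [CLS]) are segment A (context), tokens after it through the final
    [SEP] are segment B (candidate).  ``label`` is 1 iff the candidate is the
    instance's gold expansion.  ``attention_mask`` is 1 over real tokens and 0
    over [PAD] suffix tokens.
    """

    index: str
    target: str
    candidate: str
    tokens: tuple[str, ...]
    segment_boundary: int
    label: int
    attention_mask: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "attention_mask", tuple(self.attention_mask))
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if len(self.tokens) != len(self.attention_mask):
            raise ValueError("attention mask length differs from token count")

    @property
    def context_tokens(self) -> tuple[str, ...]:
        return self.tokens[1 : self.segment_boundary]

    @property
    def candidate_tokens(self) -> tuple[str, ...]:
        end = len(self.tokens)
        while end > 0 and self.tokens[end - 1] == PAD:
            end -= 1
        return self.tokens[self.segment_boundary + 1 : end - 1]


def assemble_sequence(
    left: str,
    target: str,
    right: str,
    candidate: str,
    tokenizer: TokenizerContract,
) -> tuple[list[str], int]:
    """Assemble the two-segment layout; returns (tokens, first-SEP position).

    No padding and no truncation happen here.  Raises ``ValueError`` when the
    candidate tokenizes to nothing (it would leave the pair classless).
    """
    cand_tokens = tokenizer.tokenize(candidate)
    if not cand_tokens:
        raise ValueError(f"candidate {candidate!r} tokenizes to zero tokens")
    context = (
        tokenizer.tokenize(left) + tokenizer.tokenize(target) + tokenizer.tokenize(right)
    )
    tokens = (
        [tokenizer.cls_token]
        + context
        + [tokenizer.sep_token]
        + cand_tokens
        + [tokenizer.sep_token]
    )
    return tokens, 1 + len(context)


def fifo_truncate(
    tokens: Sequence[str], segment_boundary: int, budget: int
) -> tuple[list[str], int]:
    """Trim the oldest context tokens until the sequence fits the budget.

    Preserves [CLS], both [SEP]s and the whole candidate segment; the
    surviving context is a contiguous suffix of the original context token
    list.  Raises :class:`CapacityError` when even an empty context would not
    fit.
    """
    tokens = list(tokens)
    if len(tokens) <= budget:
        return tokens, segment_boundary
    overflow = len(tokens) - budget
    context_len = segment_boundary - 1
    # a truncated sequence must keep at least one context token
    if overflow >= context_len:
        candidate = " ".join(tokens[segment_boundary + 1 : -1])
        raise CapacityError(
            f"budget {budget} cannot hold the special tokens and candidate "
            f"{candidate!r} with any context"
        )
    truncated = [tokens[0]] + tokens[1 + overflow :]
    return truncated, segment_boundary - overflow


def generate_pairs(
    instance: AbbrevInstance,
    inventory: SenseInventory,
    tokenizer: TokenizerContract,
    budget: int | None = None,
    require_gold: bool = True,
) -> list[ContextCandidatePair]:
    """Produce one truncated, labelled pair per candidate expansion.

    Pairs come out in inventory (lexicographic) order with exactly one label-1
    pair — the gold expansion.  With ``require_gold=False`` (inference on
    unlabelled instances) the gold-membership check is skipped and labels
    simply flag whichever candidate equals ``instance.label``.
    """
    if instance.target not in inventory:
        raise KeyError(f"abbreviation {instance.target!r} not in sense inventory")
    candidates = inventory.candidates(instance.target)
    if require_gold and instance.label not in candidates:
        raise ValueError(
            f"gold label {instance.label!r} not among candidates {candidates} "
            f"for {instance.target!r}"
        )
    budget = budget if budget is not None else tokenizer.model_max_length
    pairs = []
    for cand in candidates:
        tokens, boundary = assemble_sequence(
            instance.left, instance.target, instance.right, cand, tokenizer
        )
        tokens, boundary = fifo_truncate(tokens, boundary, budget)
        pairs.append(
            ContextCandidatePair(
                index=instance.index,
                target=instance.target,
                candidate=cand,
                tokens=tuple(tokens),
                segment_boundary=boundary,
                label=int(cand == instance.label),
                attention_mask=(1,) * len(tokens),
            )
        )
    return pairs


def pad_batch(
    pairs: Sequence[ContextCandidatePair], tokenizer: TokenizerContract
) -> list[ContextCandidatePair]:
    """Pad every pair to the batch maximum length with [PAD] / mask zeros."""
    if not pairs:
        return []
    width = max(len(p.tokens) for p in pairs)
    out = []
    for p in pairs:
        deficit = width - len(p.tokens)
        if deficit == 0:
            out.append(p)
        else:
            out.append(
                replace(
                    p,
                    tokens=p.tokens + (tokenizer.pad_token,) * deficit,
                    attention_mask=p.attention_mask + (0,) * deficit,
                )
            )
    return out


def write_pairs_jsonl(pairs: Sequence[ContextCandidatePair], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for p in pairs:
            fh.write(
                json.dumps(
                    {
                        "index": p.index,
                        "target": p.target,
                        "candidate": p.candidate,
                        "label": p.label,
                        "tokens": list(p.tokens),
                        "segment_boundary": p.segment_boundary,
                        "attention_mask": list(p.attention_mask),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    return path


def read_pairs_jsonl(path: str | Path) -> list[ContextCandidatePair]:
    pairs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            pairs.append(
                ContextCandidatePair(
                    index=str(obj["index"]),
                    target=obj["target"],
                    candidate=obj["candidate"],
                    tokens=tuple(obj["tokens"]),
                    segment_boundary=int(obj["segment_boundary"]),
                    label=int(obj["label"]),
                    attention_mask=tuple(obj["attention_mask"]),
                )
            )
    return pairs
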