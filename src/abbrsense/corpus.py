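"""Canonical corpus schema, normalization, sense inventories, and interchange I/O.

An ambiguous-abbreviation corpus is a flat list of instances, one per marked
occurrence of an abbreviation in a clinical note.  Each instance carries the
surrounding text split positionally into ``left`` / ``target`` / ``right`` (the
target abbreviation is never folded into the context, which is how it stays
"marked" without inline sentinel tokens), the gold expansion (``label``) and the
remaining incorrect candidate expansions (``negs``).

Two interchange formats are supported:

* the canonical tab-separated file with a six-column header
  (``index  target  left  right  label  negs``), negs joined by ``","`` —
  expansions containing commas cannot be stored here unambiguously;
* JSON Lines with the same six fields and ``negs`` as a JSON array, which has
  no such restriction.
"""

from __future__ import annotations

import csv
import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

__all__ = [
    "AbbrevInstance",
    "SenseInventory",
    "NormalizationPolicy",
    "CorpusDialect",
    "SchemaError",
    "RowValidationError",
    "read_corpus",
    "write_corpus",
    "read_corpus_jsonl",
    "write_corpus_jsonl",
    "normalize_instance",
    "normalize_text",
    "build_sense_inventory",
]

CORPUS_COLUMNS = ("index", "target", "left", "right", "label", "negs")


class SchemaError(ValueError):
    """Header of a corpus file does not match the canonical schema."""


class RowValidationError(ValueError):
    """A data row violates an instance invariant; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class AbbrevInstance:
    """One occurrence of an ambiguous abbreviation with its candidate senses.

    Invariants (enforced by :meth:`validate`): ``target`` and ``label`` are
    non-empty, ``label`` is not among ``negs``, and ``negs`` holds no
    duplicates.  ``left``/``right`` may be empty.
    """

    index: str
    target: str
    left: str
    right: str
    label: str
    negs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "negs", tuple(self.negs))
        self.validate()

    def validate(self) -> None:
        if not self.target:
            raise ValueError("target must be non-empty")
        if not self.label:
            raise ValueError("label must be non-empty")
        if self.label in self.negs:
            raise ValueError(f"label {self.label!r} also listed in negs")
        if len(set(self.negs)) != len(self.negs):
            raise ValueError("negs contains duplicates")

    @property
    def candidates(self) -> tuple[str, ...]:
        """Gold label plus negatives, lexicographically ordered."""
        return tuple(sorted({self.label, *self.negs}))


class SenseInventory:
    """Mapping from abbreviation surface form to its candidate expansions.

    Candidate sets are deduplicated and kept in lexicographic order so every
    downstream enumeration (pair generation, prediction argmax) is
    reproducible.
    """

    def __init__(self, mapping: dict[str, Iterable[str]] | None = None):
        self._senses: dict[str, tuple[str, ...]] = {}
        for target, cands in (mapping or {}).items():
            self.add(target, cands)

    def add(self, target: str, candidates: Iterable[str]) -> None:
        merged = set(self._senses.get(target, ())) | {c.strip() for c in candidates}
        merged.discard("")
        if not merged:
            raise ValueError(f"candidate set for {target!r} is empty")
        self._senses[target] = tuple(sorted(merged))

    def candidates(self, target: str) -> tuple[str, ...]:
        try:
            return self._senses[target]
        except KeyError:
            raise KeyError(f"abbreviation {target!r} not in sense inventory") from None

    def __contains__(self, target: str) -> bool:
        return target in self._senses

    def __iter__(self):
        return iter(sorted(self._senses))

    def __len__(self) -> int:
        return len(self._senses)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SenseInventory) and self._senses == other._senses

    def as_dict(self) -> dict[str, list[str]]:
        return {t: list(self._senses[t]) for t in sorted(self._senses)}

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.as_dict(), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SenseInventory":
        return cls(json.loads(Path(path).read_text()))


# default whitelist: letters, digits, space, and a small set of punctuation that
# is meaningful inside clinical expansions and measurements
DEFAULT_WHITELIST_EXTRA = ".,()/-#"


@dataclass(frozen=True)
class NormalizationPolicy:
    """Text normalization applied to contexts before tokenization.

    ``whitelist_extra`` lists the non-alphanumeric characters retained besides
    the space; everything else becomes a space and runs of whitespace collapse.
    The rule set is explicit and configurable because which "special symbols"
    to strip is a deployment decision, not a fixed constant.  With
    ``preserve_target`` set (the default) the abbreviation surface form is
    never altered, keeping it in its original written form.
    """

    lowercase: bool = True
    whitelist_extra: str = DEFAULT_WHITELIST_EXTRA
    preserve_target: bool = True

    def _keep(self, ch: str) -> bool:
        return ch.isalnum() or ch == " " or ch in self.whitelist_extra

    def apply(self, text: str) -> str:
        if self.lowercase:
            text = text.lower()
        cleaned = "".join(ch if self._keep(ch) else " " for ch in text)
        return " ".join(cleaned.split())


def normalize_text(text: str, policy: NormalizationPolicy | None = None) -> str:
    """Normalize free text under ``policy`` (idempotent)."""
    return (policy or NormalizationPolicy()).apply(text)


def normalize_instance(
    instance: AbbrevInstance, policy: NormalizationPolicy | None = None
) -> AbbrevInstance:
    """Normalize the contexts of an instance.

    ``label`` and ``negs`` are inventory keys, not free text, and are left
    untouched; ``target`` is only normalized when the policy does not preserve
    it.
    """
    policy = policy or NormalizationPolicy()
    target = instance.target if policy.preserve_target else policy.apply(instance.target)
    return replace(
        instance,
        target=target,
        left=policy.apply(instance.left),
        right=policy.apply(instance.right),
    )


@dataclass(frozen=True)
class CorpusDialect:
    """Delimited-text dialect of the canonical corpus file."""

    delimiter: str = "\t"
    list_separator: str = ","
    encoding: str = "utf-8"


def read_corpus(
    path: str | Path, dialect: CorpusDialect | None = None
) -> list[AbbrevInstance]:
    """Read a canonical delimited corpus file into validated instances.

    Raises :class:`SchemaError` if the header differs from the six canonical
    columns, :class:`RowValidationError` (with the row number) when a row
    violates an instance invariant, and ``OSError`` for unreadable files.
    """
    dialect = dialect or CorpusDialect()
    instances: list[AbbrevInstance] = []
    with open(path, encoding=dialect.encoding, newline="") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("corpus file is empty (no header row)") from None
        header = [h.strip().lower() for h in header]
        if tuple(header) != CORPUS_COLUMNS:
            missing = [c for c in CORPUS_COLUMNS if c not in header]
            detail = f"missing column(s) {missing}" if missing else f"got {header}"
            raise SchemaError(f"expected header {list(CORPUS_COLUMNS)}; {detail}")
        for rownum, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(CORPUS_COLUMNS):
                raise RowValidationError(
                    rownum, f"expected {len(CORPUS_COLUMNS)} fields, got {len(row)}"
                )
            index, target, left, right, label, negs_cell = (c.strip() for c in row)
            negs = tuple(
                n.strip() for n in negs_cell.split(dialect.list_separator) if n.strip()
            )
            try:
                instances.append(
                    AbbrevInstance(index, target, left, right, label, negs)
                )
            except ValueError as exc:
                raise RowValidationError(rownum, str(exc)) from exc
    return instances


def write_corpus(
    instances: Sequence[AbbrevInstance],
    path: str | Path,
    dialect: CorpusDialect | None = None,
) -> Path:
    """Write instances to the canonical delimited format (round-trips read_corpus).

    Expansions containing the list separator cannot be represented in this
    format; use :func:`write_corpus_jsonl` for those.
    """
    dialect = dialect or CorpusDialect()
    path = Path(path)
    for inst in instances:
        for cand in (inst.label, *inst.negs):
            if dialect.list_separator in cand:
                raise ValueError(
                    f"expansion {cand!r} contains the list separator "
                    f"{dialect.list_separator!r}; use the JSONL corpus format"
                )
    with open(path, "w", encoding=dialect.encoding, newline="") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(CORPUS_COLUMNS)
        for inst in instances:
            writer.writerow(
                [
                    inst.index,
                    inst.target,
                    inst.left,
                    inst.right,
                    inst.label,
                    dialect.list_separator.join(inst.negs),
                ]
            )
    return path


def read_corpus_jsonl(path: str | Path) -> list[AbbrevInstance]:
    """Read the JSON Lines corpus format (negs as an array)."""
    instances = []
    with open(path, encoding="utf-8") as fh:
        for rownum, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            obj = json.loads(line)
            missing = [c for c in CORPUS_COLUMNS if c not in obj]
            if missing:
                raise SchemaError(f"line {rownum}: missing field(s) {missing}")
            try:
                instances.append(
                    AbbrevInstance(
                        str(obj["index"]).strip(),
                        str(obj["target"]).strip(),
                        str(obj["left"]).strip(),
                        str(obj["right"]).strip(),
                        str(obj["label"]).strip(),
                        tuple(str(n).strip() for n in obj["negs"]),
                    )
                )
            except ValueError as exc:
                raise RowValidationError(rownum, str(exc)) from exc
    return instances


def write_corpus_jsonl(instances: Sequence[AbbrevInstance], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for inst in instances:
            fh.write(
                json.dumps(
                    {
                        "index": inst.index,
                        "target": inst.target,
                        "left": inst.left,
                        "right": inst.right,
                        "label": inst.label,
                        "negs": list(inst.negs),
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    return path


def build_sense_inventory(instances: Iterable[AbbrevInstance]) -> SenseInventory:
    """Union each abbreviation's observed candidates ({label} ∪ negs) per target.

    Output is order-invariant over the instance list: candidate sets are plain
    set unions, then lexicographically sorted.
    """
    inventory = SenseInventory()
    for inst in instances:
        inventory.add(inst.target, (inst.label, *inst.negs))
    return inventory
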