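"""Experiment protocols: coverage-constrained splitting, within-corpus runs,
and cross-site incremental learning.

The split keeps a simple train:test ratio (9:1 by default, no
cross-validation) but screens the corpus first so that every
(abbreviation, gold sense) class is represented at least once in training —
a candidate whose pairs never appear in training cannot be learned by a
pair classifier.  When singleton classes force the training side above the
requested fraction, a warning is emitted rather than an error.

The incremental protocol mirrors adapting a model trained on an external
corpus to a new hospital site: train on the base corpus, then for each k in
{0, 5, 10} add k new-site documents (one marked abbreviation occurrence each)
to training — selected by seeded sampling stratified across abbreviations —
continue training, and evaluate on the remaining new-site instances.
"""

from __future__ import annotations

import copy
import random
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

from .corpus import AbbrevInstance, SenseInventory, build_sense_inventory
from .evaluation import EvalReport, evaluate, predict
from .pairs import TokenizerContract, WhitespaceTokenizer, generate_pairs
from .scoring import Scorer, TrainConfig, train_scorer

__all__ = [
    "SplitSpec",
    "IncrementalSpec",
    "CoverageWarning",
    "CompatibilityError",
    "coverage_split",
    "run_within_corpus",
    "run_incremental",
    "WithinCorpusResult",
    "IncrementalResult",
]


class CoverageWarning(UserWarning):
    """The coverage constraint forced the split away from the requested ratio."""


class CompatibilityError(ValueError):
    """New-site corpus uses senses incompatible with the inventory."""


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split parameters; the seed is mandatory."""

    train_fraction: float = 0.9
    seed: int = 0
    coverage: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be strictly between 0 and 1")


def coverage_split(
    instances: Sequence[AbbrevInstance], spec: SplitSpec
) -> tuple[list[AbbrevInstance], list[AbbrevInstance]]:
    """Seeded disjoint, exhaustive partition with per-class training coverage.

    With ``spec.coverage`` set, every (target, label) class contributes at
    least one training instance; classes with a single instance are therefore
    always placed in training.  Emits :class:`CoverageWarning` when the
    constraint pushes |train| above ``round(fraction * n)``.
    """
    if not instances:
        raise ValueError("cannot split an empty corpus")
    rng = random.Random(spec.seed)
    order = list(range(len(instances)))
    rng.shuffle(order)

    n_train = round(spec.train_fraction * len(instances))
    n_train = min(max(n_train, 1), len(instances) - 1)

    train_idx: list[int] = []
    if spec.coverage:
        seen: set[tuple[str, str]] = set()
        for i in order:
            key = (instances[i].target, instances[i].label)
            if key not in seen:
                seen.add(key)
                train_idx.append(i)
        if len(train_idx) > n_train:
            warnings.warn(
                f"coverage constraint requires {len(train_idx)} training instances, "
                f"exceeding the requested {n_train}",
                CoverageWarning,
                stacklevel=2,
            )
            n_train = len(train_idx)
    chosen = set(train_idx)
    for i in order:
        if len(chosen) >= n_train:
            break
        chosen.add(i)
    train = [instances[i] for i in sorted(chosen)]
    test = [instances[i] for i in sorted(set(range(len(instances))) - chosen)]
    return train, test


def _pairs_for(
    instances: Sequence[AbbrevInstance],
    inventory: SenseInventory,
    tokenizer: TokenizerContract,
    budget: int,
):
    pairs = []
    for inst in instances:
        pairs.extend(generate_pairs(inst, inventory, tokenizer, budget))
    return pairs


@dataclass
class WithinCorpusResult:
    report: EvalReport
    manifest: dict
    scorer: Scorer
    train: list[AbbrevInstance]
    test: list[AbbrevInstance]


def run_within_corpus(
    corpus: Sequence[AbbrevInstance],
    inventory: SenseInventory | None,
    train_config: TrainConfig,
    split_spec: SplitSpec,
    tokenizer: TokenizerContract | None = None,
) -> WithinCorpusResult:
    """Split, train on the training pairs only, evaluate on the held-out test set."""
    inventory = inventory or build_sense_inventory(corpus)
    tokenizer = tokenizer or WhitespaceTokenizer(train_config.token_budget)
    train, test = coverage_split(corpus, split_spec)
    train_pairs = _pairs_for(train, inventory, tokenizer, train_config.token_budget)
    scorer = train_scorer(train_pairs, train_config)
    predictions = [
        predict(inst, inventory, scorer, tokenizer, train_config.token_budget)
        for inst in test
    ]
    report = evaluate(predictions, test)
    manifest = {
        "protocol": "within_corpus",
        "split": {
            "train_fraction": split_spec.train_fraction,
            "seed": split_spec.seed,
            "coverage": split_spec.coverage,
        },
        "train_config": {"backend": train_config.backend, "seed": train_config.seed},
        "counts": {
            "instances": len(corpus),
            "train_instances": len(train),
            "test_instances": len(test),
            "train_pairs": len(train_pairs),
        },
        "train_indices": sorted(i.index for i in train),
        "test_indices": sorted(i.index for i in test),
    }
    return WithinCorpusResult(report, manifest, scorer, train, test)


@dataclass(frozen=True)
class IncrementalSpec:
    """Cross-site incremental protocol parameters.

    ``ks`` are the numbers of new-site documents (one abbreviation occurrence
    each) added to training; documents added at a given k are excluded from
    that k's test set.
    """

    base: tuple[AbbrevInstance, ...]
    site: tuple[AbbrevInstance, ...]
    ks: tuple[int, ...] = (0, 5, 10)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "base", tuple(self.base))
        object.__setattr__(self, "site", tuple(self.site))
        object.__setattr__(self, "ks", tuple(self.ks))
        if any(k > len(self.site) for k in self.ks):
            raise ValueError("k exceeds the new-site corpus size")
        if any(k < 0 for k in self.ks):
            raise ValueError("k must be non-negative")


def _site_selection_order(
    site: Sequence[AbbrevInstance], seed: int
) -> list[AbbrevInstance]:
    """Round-robin over abbreviations, seeded shuffle within each; prefixes of
    this order give nested, abbreviation-stratified selections for any k."""
    rng = random.Random(seed)
    by_target: dict[str, list[AbbrevInstance]] = {}
    for inst in site:
        by_target.setdefault(inst.target, []).append(inst)
    targets = sorted(by_target)
    rng.shuffle(targets)
    for t in targets:
        rng.shuffle(by_target[t])
    order: list[AbbrevInstance] = []
    while any(by_target[t] for t in targets):
        for t in targets:
            if by_target[t]:
                order.append(by_target[t].pop())
    return order


@dataclass
class IncrementalResult:
    """Per-abbreviation accuracy (%) by number of added site documents."""

    table: dict[str, dict[int, float]]  # target -> k -> accuracy
    reports: dict[int, EvalReport]
    manifest: dict

    def render_text(self) -> str:
        ks = sorted(next(iter(self.table.values())).keys()) if self.table else []
        header = f"{'Abbreviation':<16}" + "".join(f"{f'k={k} (%)':>12}" for k in ks)
        lines = [header, "-" * len(header)]
        for target in sorted(self.table):
            row = f"{target:<16}" + "".join(
                f"{self.table[target].get(k, float('nan')):>12.2f}" for k in ks
            )
            lines.append(row)
        return "\n".join(lines) + "\n"


def run_incremental(
    spec: IncrementalSpec,
    inventory: SenseInventory | None,
    train_config: TrainConfig,
    tokenizer: TokenizerContract | None = None,
) -> IncrementalResult:
    """Train on the base corpus, adapt with k new-site documents, evaluate.

    At k=0 this is exactly the base scorer evaluated on the whole new-site
    corpus.  For k>0 the k selected documents join the training pair multiset
    and training continues from the base scorer's state; evaluation uses the
    remaining site instances.
    """
    inventory = inventory or build_sense_inventory(list(spec.base) + list(spec.site))
    tokenizer = tokenizer or WhitespaceTokenizer(train_config.token_budget)

    bad = sorted(
        {
            inst.target
            for inst in spec.site
            if inst.target not in inventory
            or inst.label not in inventory.candidates(inst.target)
            or any(n not in inventory.candidates(inst.target) for n in inst.negs)
        }
    )
    if bad:
        raise CompatibilityError(
            f"new-site candidate sets incompatible with the inventory for: {bad}"
        )

    budget = train_config.token_budget
    base_pairs = _pairs_for(spec.base, inventory, tokenizer, budget)
    base_scorer = train_scorer(base_pairs, train_config)
    selection_order = _site_selection_order(spec.site, spec.seed)

    table: dict[str, dict[int, float]] = {}
    reports: dict[int, EvalReport] = {}
    counts: dict[int, dict[str, int]] = {}
    for k in spec.ks:
        added = selection_order[:k]
        added_keys = {(i.index, i.target) for i in added}
        test = [i for i in spec.site if (i.index, i.target) not in added_keys]
        if k == 0:
            scorer = base_scorer
            added_pairs = []
        else:
            added_pairs = _pairs_for(added, inventory, tokenizer, budget)
            scorer = copy.deepcopy(base_scorer).update(added_pairs)
        predictions = [
            predict(inst, inventory, scorer, tokenizer, budget) for inst in test
        ]
        report = evaluate(predictions, test)
        reports[k] = report
        counts[k] = {
            "added_documents": len(added),
            "added_pairs": len(added_pairs),
            "test_instances": len(test),
        }
        for target, stats in report.per_abbrev.items():
            table.setdefault(target, {})[k] = stats.accuracy

    manifest = {
        "protocol": "incremental",
        "seed": spec.seed,
        "ks": list(spec.ks),
        "train_config": {"backend": train_config.backend, "seed": train_config.seed},
        "counts": {
            "base_instances": len(spec.base),
            "site_instances": len(spec.site),
            "base_pairs": len(base_pairs),
            **{str(k): counts[k] for k in spec.ks},
        },
        "selection_order": [i.index for i in selection_order[: max(spec.ks)]],
    }
    return IncrementalResult(table=table, reports=reports, manifest=manifest)
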