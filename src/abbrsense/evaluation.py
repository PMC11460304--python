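"""Candidate ranking and per-abbreviation accuracy evaluation.

Prediction picks, for each instance, the candidate expansion whose
context-candidate pair gets the highest class-1 probability (exact ties go to
the lexicographically smaller candidate, for reproducibility).  Evaluation
builds one confusion matrix per abbreviation (gold expansion × predicted
expansion) and reports, on the percent scale:

* per-abbreviation accuracy = correct / count × 100;
* macroaccuracy = unweighted mean of per-abbreviation accuracies;
* microaccuracy = total correct / total instances × 100.

Macro weights every abbreviation equally regardless of frequency; micro is the
pooled accuracy, equivalently the instance-count-weighted mean of the
per-abbreviation accuracies.
"""

from __future__ import annotations

import json
from collections.abc import Sequence
from dataclasses import dataclass, field
from pathlib import Path

from .corpus import AbbrevInstance, SenseInventory
from .pairs import TokenizerContract, generate_pairs
from .scoring import Scorer

__all__ = [
    "PredictionResult",
    "AbbrevStats",
    "EvalReport",
    "AlignmentError",
    "predict",
    "evaluate",
    "render_report",
]


class AlignmentError(ValueError):
    """Predictions and gold instances do not align one-to-one."""


@dataclass(frozen=True)
class PredictionResult:
    """Chosen expansion for one instance plus the full candidate score table."""

    index: str
    target: str
    chosen: str
    scores: dict[str, float]
    correct: bool | None = None

    def __post_init__(self) -> None:
        if self.chosen not in self.scores:
            raise ValueError("chosen expansion is not in the score table")
        best = max(self.scores.values())
        winners = sorted(c for c, s in self.scores.items() if s == best)
        if self.chosen != winners[0]:
            raise ValueError(
                "chosen expansion does not attain the maximum score under the tie rule"
            )


def predict(
    instance: AbbrevInstance,
    inventory: SenseInventory,
    scorer: Scorer,
    tokenizer: TokenizerContract,
    budget: int | None = None,
) -> PredictionResult:
    """Score every candidate pair for the instance and take the argmax.

    The gold label is not consulted for the decision (it only populates the
    ``correct`` flag when present in the candidate set).
    """
    pairs = generate_pairs(instance, inventory, tokenizer, budget, require_gold=False)
    scores = {p.candidate: scorer.score(p) for p in pairs}
    best = max(scores.values())
    chosen = min(c for c, s in scores.items() if s == best)
    return PredictionResult(
        index=instance.index,
        target=instance.target,
        chosen=chosen,
        scores=scores,
        correct=(chosen == instance.label) if instance.label in scores else None,
    )


@dataclass
class AbbrevStats:
    count: int
    correct: int
    accuracy: float  # percent
    confusion: dict[str, dict[str, int]]  # gold expansion -> predicted -> count


@dataclass
class EvalReport:
    per_abbrev: dict[str, AbbrevStats]
    macro_accuracy: float  # percent, unweighted mean over abbreviations
    micro_accuracy: float  # percent, pooled over instances

    @property
    def total_instances(self) -> int:
        return sum(s.count for s in self.per_abbrev.values())

    def as_dict(self) -> dict:
        return {
            "per_abbrev": {
                t: {
                    "count": s.count,
                    "correct": s.correct,
                    "accuracy": s.accuracy,
                    "confusion": s.confusion,
                }
                for t, s in self.per_abbrev.items()
            },
            "macro_accuracy": self.macro_accuracy,
            "micro_accuracy": self.micro_accuracy,
        }

    @classmethod
    def from_dict(cls, obj: dict) -> "EvalReport":
        return cls(
            per_abbrev={
                t: AbbrevStats(
                    count=d["count"],
                    correct=d["correct"],
                    accuracy=d["accuracy"],
                    confusion={g: dict(p) for g, p in d["confusion"].items()},
                )
                for t, d in obj["per_abbrev"].items()
            },
            macro_accuracy=obj["macro_accuracy"],
            micro_accuracy=obj["micro_accuracy"],
        )


def evaluate(
    predictions: Sequence[PredictionResult], gold: Sequence[AbbrevInstance]
) -> EvalReport:
    """Score predictions against gold instances, aligned by instance index.

    Raises :class:`AlignmentError` when the two lists do not match one-to-one
    on (index, target).
    """
    pred_by_key = {(p.index, p.target): p for p in predictions}
    gold_keys = [(g.index, g.target) for g in gold]
    if len(pred_by_key) != len(predictions) or set(pred_by_key) != set(gold_keys) or len(
        gold_keys
    ) != len(set(gold_keys)):
        raise AlignmentError(
            "predictions and gold instances do not align one-to-one by (index, target)"
        )

    counts: dict[str, int] = {}
    corrects: dict[str, int] = {}
    confusion: dict[str, dict[str, dict[str, int]]] = {}
    for g in gold:
        p = pred_by_key[(g.index, g.target)]
        counts[g.target] = counts.get(g.target, 0) + 1
        corrects.setdefault(g.target, 0)
        if p.chosen == g.label:
            corrects[g.target] += 1
        cm = confusion.setdefault(g.target, {})
        row = cm.setdefault(g.label, {})
        row[p.chosen] = row.get(p.chosen, 0) + 1

    per_abbrev = {
        t: AbbrevStats(
            count=counts[t],
            correct=corrects[t],
            accuracy=100.0 * corrects[t] / counts[t],
            confusion=confusion[t],
        )
        for t in sorted(counts)
    }
    accuracies = [s.accuracy for s in per_abbrev.values()]
    macro = sum(accuracies) / len(accuracies) if accuracies else 0.0
    total = sum(counts.values())
    micro = 100.0 * sum(corrects.values()) / total if total else 0.0
    return EvalReport(per_abbrev=per_abbrev, macro_accuracy=macro, micro_accuracy=micro)


def render_report(report: EvalReport, path: str | Path) -> Path:
    """Write the report as full-precision JSON plus a plain-text table.

    ``path`` is the JSON destination; a sibling ``.txt`` file holds the
    human-readable table with accuracies at two decimals.
    """
    path = Path(path)
    path.write_text(json.dumps(report.as_dict(), indent=2) + "\n")

    lines = [
        f"{'Abbreviation':<16}{'Instances':>10}{'Correct':>10}{'Accuracy (%)':>14}",
        "-" * 50,
    ]
    for target, stats in report.per_abbrev.items():
        lines.append(
            f"{target:<16}{stats.count:>10}{stats.correct:>10}{stats.accuracy:>14.2f}"
        )
    lines += [
        "-" * 50,
        f"{'Macroaccuracy':<36}{report.macro_accuracy:>14.2f}",
        f"{'Microaccuracy':<36}{report.micro_accuracy:>14.2f}",
    ]
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return path
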