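"""Seeded synthetic ambiguous-abbreviation corpora with controllable separability.

The generator emulates the structure of clinical abbreviation-disambiguation
corpora: a handful of abbreviations, each with several candidate expansions,
where the words surrounding an occurrence statistically signal the intended
sense.  Each sense owns a disjoint *signature vocabulary*; every context word
is drawn from that vocabulary with probability ``p_sig`` and from a shared
background vocabulary otherwise, so ``p_sig`` is a direct dial on
separability (0 = no signal, 1 = perfect signal).  Contexts are exchangeable
word multisets — no syntax — because the pipeline under test exploits lexical
co-occurrence only.

A second "site" can be generated for cross-site transfer studies: it shares
surface forms and candidate sets with the base corpus, but a configurable
fraction of (abbreviation, sense) classes is withheld from the base corpus
entirely (the unseen-sense condition), a fraction of signature vocabulary is
replaced by site-specific words, and sense priors shift toward the withheld
sense.

Everything is a pure function of the configuration: a fixed seed yields a
byte-identical corpus.  The master seed expands into named substreams (world
construction, base sampling, site sampling) so stages are independently
reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable

from .corpus import AbbrevInstance, SenseInventory
from .evaluation import PredictionResult

__all__ = [
    "SynthConfig",
    "SitePair",
    "generate_corpus",
    "generate_site_pair",
    "signature_vocabularies",
    "oracle_classifier",
]

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters (see module docstring for the sampling model).

    Context length bounds apply per side (left and right independently), in
    whitespace tokens.  Setting ``context_len`` maxima above the token budget
    guarantees the truncation path is exercised downstream.
    """

    n_abbrevs: int = 5
    senses_range: tuple[int, int] = (2, 6)  # senses per abbreviation, inclusive
    instances_per_sense: int = 20
    signature_size: int = 8
    p_sig: float = 0.8
    background_vocab_size: int = 200
    context_len: tuple[int, int] = (3, 12)  # min/max tokens per side
    site_withheld_fraction: float = 0.0  # fraction of classes absent from base
    site_vocab_replace_rate: float = 0.0
    site_withheld_prior: float = 0.8  # site sense prior mass on a withheld sense
    site_instances_per_abbrev: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_sig <= 1.0:
            raise ValueError("p_sig must lie in [0, 1]")
        if self.senses_range[0] < 1 or self.senses_range[0] > self.senses_range[1]:
            raise ValueError("invalid senses_range")
        if min(
            self.n_abbrevs,
            self.instances_per_sense,
            self.signature_size,
            self.background_vocab_size,
            self.context_len[0],
            self.site_instances_per_abbrev,
        ) <= 0 or self.context_len[1] < self.context_len[0]:
            raise ValueError("all counts must be positive and max >= min")
        if not 0.0 <= self.site_withheld_fraction <= 1.0:
            raise ValueError("site_withheld_fraction must lie in [0, 1]")
        if not 0.0 <= self.site_vocab_replace_rate <= 1.0:
            raise ValueError("site_vocab_replace_rate must lie in [0, 1]")
        if not 0.0 <= self.site_withheld_prior <= 1.0:
            raise ValueError("site_withheld_prior must lie in [0, 1]")


def _stream(config: SynthConfig, name: str) -> random.Random:
    # string seeding is stable across runs and Python versions (sha512-based)
    return random.Random(f"{config.seed}:{name}")


def _random_word(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_LETTERS) for _ in range(length))


@dataclass(frozen=True)
class _World:
    """The latent ground truth: abbreviations, senses, vocabularies."""

    targets: tuple[str, ...]
    expansions: dict[str, tuple[str, ...]]  # target -> sense expansions
    signatures: dict[tuple[str, str], tuple[str, ...]]  # (target, expansion) -> words
    background: tuple[str, ...]


def _build_world(config: SynthConfig) -> _World:
    rng = _stream(config, "world")
    targets = tuple(f"AB{a}" for a in range(config.n_abbrevs))
    background = tuple(f"bg{_random_word(rng, 6)}{i}" for i in range(config.background_vocab_size))
    expansions: dict[str, tuple[str, ...]] = {}
    signatures: dict[tuple[str, str], tuple[str, ...]] = {}
    used: set[str] = set()
    for a, target in enumerate(targets):
        n_senses = rng.randint(*config.senses_range)
        sense_expansions = []
        for s in range(n_senses):
            while True:  # multiword expansion, unique across the world
                exp = f"{_random_word(rng, rng.randint(4, 8))} {_random_word(rng, rng.randint(4, 8))}"
                if exp not in used:
                    used.add(exp)
                    break
            sense_expansions.append(exp)
            signatures[(target, exp)] = tuple(
                f"sig-a{a}s{s}-{_random_word(rng, 5)}" for _ in range(config.signature_size)
            )
        expansions[target] = tuple(sense_expansions)
    return _World(targets, expansions, signatures, background)


def _sample_context(
    rng: random.Random, config: SynthConfig, signature: tuple[str, ...], background: tuple[str, ...]
) -> str:
    length = rng.randint(*config.context_len)
    words = [
        rng.choice(signature) if rng.random() < config.p_sig else rng.choice(background)
        for _ in range(length)
    ]
    return " ".join(words)


def _make_instance(
    rng: random.Random,
    config: SynthConfig,
    world: _World,
    target: str,
    expansion: str,
    index: str,
    signatures: dict[tuple[str, str], tuple[str, ...]],
) -> AbbrevInstance:
    sig = signatures[(target, expansion)]
    return AbbrevInstance(
        index=index,
        target=target,
        left=_sample_context(rng, config, sig, world.background),
        right=_sample_context(rng, config, sig, world.background),
        label=expansion,
        negs=tuple(e for e in world.expansions[target] if e != expansion),
    )


def _inventory(world: _World) -> SenseInventory:
    return SenseInventory({t: world.expansions[t] for t in world.targets})


def generate_corpus(config: SynthConfig) -> tuple[list[AbbrevInstance], SenseInventory]:
    """Generate A×S×m validated instances and their sense inventory."""
    world = _build_world(config)
    rng = _stream(config, "corpus")
    instances: list[AbbrevInstance] = []
    counter = 0
    for target in world.targets:
        for expansion in world.expansions[target]:
            for _ in range(config.instances_per_sense):
                instances.append(
                    _make_instance(
                        rng, config, world, target, expansion,
                        f"d{counter:05d}", world.signatures,
                    )
                )
                counter += 1
    return instances, _inventory(world)


def signature_vocabularies(
    config: SynthConfig, site: bool = False
) -> dict[tuple[str, str], tuple[str, ...]]:
    """Recompute the true per-sense signature vocabularies (oracle metadata).

    Pure function of the config; with ``site=True`` returns the new-site
    vocabularies after seeded replacement.
    """
    world = _build_world(config)
    if not site:
        return dict(world.signatures)
    return _site_signatures(config, world)


def _site_signatures(
    config: SynthConfig, world: _World
) -> dict[tuple[str, str], tuple[str, ...]]:
    rng = _stream(config, "site-vocab")
    out: dict[tuple[str, str], tuple[str, ...]] = {}
    for key, words in world.signatures.items():
        out[key] = tuple(
            f"site{_random_word(rng, 5)}" if rng.random() < config.site_vocab_replace_rate else w
            for w in words
        )
    return out


def _withheld_classes(config: SynthConfig, world: _World) -> set[tuple[str, str]]:
    """Seeded choice of (target, expansion) classes absent from the base site;
    at most one sense per abbreviation so base coverage of the rest survives."""
    classes = [
        (t, e)
        for t in world.targets
        for e in world.expansions[t]
        if len(world.expansions[t]) >= 2
    ]
    n_withheld = round(config.site_withheld_fraction * len(classes))
    rng = _stream(config, "withheld")
    rng.shuffle(classes)
    chosen: set[tuple[str, str]] = set()
    taken_targets: set[str] = set()
    for t, e in classes:
        if len(chosen) >= n_withheld:
            break
        if t not in taken_targets:
            chosen.add((t, e))
            taken_targets.add(t)
    return chosen


@dataclass
class SitePair:
    """A base corpus and a distribution-shifted new-site corpus."""

    base: list[AbbrevInstance]
    site: list[AbbrevInstance]
    inventory: SenseInventory
    withheld: set[tuple[str, str]]  # (target, expansion) absent from base
    base_signatures: dict[tuple[str, str], tuple[str, ...]]
    site_signatures: dict[tuple[str, str], tuple[str, ...]]


def generate_site_pair(config: SynthConfig) -> SitePair:
    """Generate the cross-site transfer scenario.

    The two corpora share targets and candidate sets.  Withheld classes have
    zero base instances; the site's sense prior for an affected abbreviation
    puts ``site_withheld_prior`` mass on the withheld sense.  Site contexts
    draw from the replaced signature vocabularies.
    """
    world = _build_world(config)
    withheld = _withheld_classes(config, world)
    site_sigs = _site_signatures(config, world)

    base_rng = _stream(config, "base-site")
    base: list[AbbrevInstance] = []
    counter = 0
    for target in world.targets:
        for expansion in world.expansions[target]:
            if (target, expansion) in withheld:
                continue
            for _ in range(config.instances_per_sense):
                base.append(
                    _make_instance(
                        base_rng, config, world, target, expansion,
                        f"b{counter:05d}", world.signatures,
                    )
                )
                counter += 1

    site_rng = _stream(config, "new-site")
    site: list[AbbrevInstance] = []
    counter = 0
    for target in world.targets:
        senses = world.expansions[target]
        withheld_here = [e for e in senses if (target, e) in withheld]
        others = [e for e in senses if (target, e) not in withheld]
        for _ in range(config.site_instances_per_abbrev):
            if withheld_here and (
                not others or site_rng.random() < config.site_withheld_prior
            ):
                expansion = withheld_here[0]
            else:
                expansion = site_rng.choice(others)
            site.append(
                _make_instance(
                    site_rng, config, world, target, expansion,
                    f"s{counter:05d}", site_sigs,
                )
            )
            counter += 1

    return SitePair(
        base=base,
        site=site,
        inventory=_inventory(world),
        withheld=withheld,
        base_signatures=dict(world.signatures),
        site_signatures=site_sigs,
    )


def oracle_classifier(
    instances: Iterable[AbbrevInstance],
    inventory: SenseInventory,
    signatures: dict[tuple[str, str], tuple[str, ...]],
) -> list[PredictionResult]:
    """Predict each instance's sense by counting signature-vocabulary hits.

    This is the independent accuracy ceiling for generated corpora: it sees
    the generator's true signature vocabularies, which no trained scorer
    does.  Ties break to the lexicographically smaller candidate.
    """
    results = []
    for inst in instances:
        context = (inst.left + " " + inst.right).split()
        scores: dict[str, float] = {}
        for cand in inventory.candidates(inst.target):
            vocab = set(signatures.get((inst.target, cand), ()))
            scores[cand] = float(sum(1 for w in context if w in vocab))
        best = max(scores.values())
        chosen = min(c for c, s in scores.items() if s == best)
        results.append(
            PredictionResult(
                index=inst.index,
                target=inst.target,
                chosen=chosen,
                scores=scores,
                correct=chosen == inst.label,
            )
        )
    return results
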