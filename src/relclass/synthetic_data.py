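"""Synthetic labeled feature records with controllable class signal.

No public corpus of labeled entity-pair feature records exists for this
task, so the generator emulates one with the statistical structure the
classifiers assume: each relation class owns a verb lexicon (causal verbs
for directed cause-effect classes, associative verbs for correlations),
Increase/Decrease subclasses add an effect trigger word, and the
``Negative*`` classes set the negation flag.  The ``signal`` knob is the
probability that a record's verb/trigger/flags are drawn from its class
lexicon rather than uniformly from the union of all lexicons: ``signal=1``
gives a corpus a verb/trigger lookup rule classifies perfectly, ``signal=0``
a corpus where features carry no label information at all.

The generator aims for structural fidelity — field schema, lexicon-class
coupling, class imbalance — not linguistic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .records_io import (
    BINARY_CLASSES,
    MULTICLASS_CLASSES,
    NA,
    FeatureRecord,
    LabelScheme,
    write_records,
)

# Disjoint verb families: the family a verb belongs to identifies the
# directedness (and, for the coarse fallback classes, the class itself).
CAUSAL_VERBS = ("induce", "increase", "prohibit", "inhibit", "stimulate", "suppress")
ASSOCIATIVE_VERBS = ("associate", "correlate", "relate", "link")
DIRECTED_FALLBACK_VERBS = ("regulate", "affect", "modulate", "alter")
UNDIRECTED_FALLBACK_VERBS = ("accompany", "coincide", "co-occur", "coexist")
ALL_VERBS = (
    CAUSAL_VERBS
    + ASSOCIATIVE_VERBS
    + DIRECTED_FALLBACK_VERBS
    + UNDIRECTED_FALLBACK_VERBS
)

# Effect trigger words: nouns/verbs expressing the direction of the effect.
INCREASE_TRIGGERS = ("activation", "increased", "active", "elevation")
DECREASE_TRIGGERS = ("reduction", "decreased", "suppression", "decline")
ALL_TRIGGERS = INCREASE_TRIGGERS + DECREASE_TRIGGERS

ENTITY_TYPES = ("COMPOUND", "GENE", "PROTEIN", "DISEASE")
CONTEXTS = ("male f-344 rats", "liver tissue", "cell culture", "serum samples",
            "mouse models", "clinical trials")

#: Per-class feature signature: (verb family, trigger family, negation).
#: Signatures are pairwise distinct, so a lookup rule over these three
#: features separates the classes exactly when signal = 1.
CLASS_SIGNATURES: dict[str, tuple[tuple[str, ...], tuple[str, ...] | None, str]] = {
    "PositiveCause": (CAUSAL_VERBS, None, "POSITIVE"),
    "NegativeCause": (CAUSAL_VERBS, None, "NEGATIVE"),
    "PositiveIncrease": (CAUSAL_VERBS, INCREASE_TRIGGERS, "POSITIVE"),
    "PositiveDecrease": (CAUSAL_VERBS, DECREASE_TRIGGERS, "POSITIVE"),
    "NegativeIncrease": (CAUSAL_VERBS, INCREASE_TRIGGERS, "NEGATIVE"),
    "NegativeDecrease": (CAUSAL_VERBS, DECREASE_TRIGGERS, "NEGATIVE"),
    "PositiveCorrelation": (ASSOCIATIVE_VERBS, None, "POSITIVE"),
    "NegativeCorrelation": (ASSOCIATIVE_VERBS, None, "NEGATIVE"),
    "DirectedLink": (DIRECTED_FALLBACK_VERBS, None, "POSITIVE"),
    "UndirectedLink": (UNDIRECTED_FALLBACK_VERBS, None, "POSITIVE"),
}

#: Binary view: directed classes use any directed-family verb.
BINARY_SIGNATURES: dict[str, tuple[tuple[str, ...], tuple[str, ...] | None, str]] = {
    "DirectedLink": (CAUSAL_VERBS + DIRECTED_FALLBACK_VERBS, None, "POSITIVE"),
    "UndirectedLink": (ASSOCIATIVE_VERBS + UNDIRECTED_FALLBACK_VERBS, None, "POSITIVE"),
}

#: Fine class -> coarse binary class.
TO_BINARY = {
    c: ("UndirectedLink" if "Correlation" in c or c == "UndirectedLink" else "DirectedLink")
    for c in MULTICLASS_CLASSES
}

RELATION_WORDS = {"DirectedLink": "CAUSES", "UndirectedLink": "ASSOCIATED_WITH"}
ALL_RELATION_WORDS = ("CAUSES", "ASSOCIATED_WITH", "LOCATION_OF", "PART_OF")

_SYLLABLES = ("dehydro", "epi", "andro", "sterone", "ubi", "quin", "gluco",
              "lipo", "cortico", "cyto", "kin", "ase", "ol", "ine", "gen")


class GeneratorConfigError(ValueError):
    """An inconsistent generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions for one synthetic corpus.

    ``class_probs`` is the label distribution over ``scheme.classes`` (None
    means uniform); ``signal`` in [0, 1] is the probability that a record's
    class-identifying features come from its class lexicon rather than
    uniformly from all lexicons; ``entity_lexicon`` is the number of
    distinct synthesized entity names.
    """

    n_records: int
    scheme: LabelScheme = field(default_factory=LabelScheme.binary)
    class_probs: tuple[float, ...] | None = None
    signal: float = 1.0
    entity_lexicon: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_probs is not None:
            if len(self.class_probs) != len(self.scheme.classes):
                raise GeneratorConfigError(
                    f"class_probs has {len(self.class_probs)} entries for "
                    f"{len(self.scheme.classes)} classes"
                )
            if abs(sum(self.class_probs) - 1.0) > 1e-9:
                raise GeneratorConfigError("class_probs must sum to 1")
        if not 0.0 <= self.signal <= 1.0:
            raise GeneratorConfigError("signal must lie in [0, 1]")
        if self.n_records < 0 or self.entity_lexicon < 1:
            raise GeneratorConfigError("n_records >= 0 and entity_lexicon >= 1")


def _entity_lexicon(rng: np.random.Generator, size: int) -> list[str]:
    """Synthesized entity names, with hyphenated-numeral variants
    ("compound-9" style) to exercise tokenization."""
    names = []
    seen = set()
    while len(names) < size:
        parts = rng.choice(_SYLLABLES, size=rng.integers(2, 4), replace=True)
        name = "".join(parts)
        if rng.random() < 0.3:
            name = f"{name}-{rng.integers(1, 20)}"
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def _signature_for(label: str, scheme: LabelScheme):
    table = BINARY_SIGNATURES if scheme.name == "binary" else CLASS_SIGNATURES
    sig = table.get(label)
    if sig is None:
        raise GeneratorConfigError(
            f"no lexicon signature for class {label!r}; "
            "custom schemes need signatures for every class"
        )
    return sig


def generate(config: GeneratorConfig) -> list[FeatureRecord]:
    """Generate ``config.n_records`` labeled records, seeded.

    Each record draws a label from ``class_probs``, then with probability
    ``signal`` takes its verb, trigger and negation from the class
    signature, otherwise uniformly from the union of lexicons.  The sentence
    is the template ``"<entity_l> <verb> <trigger?> <entity_r> in <context>"``.
    Records always carry both the binary and (when derivable) fine labels.
    """
    scheme = config.scheme
    rng = np.random.default_rng(config.seed)
    entities = _entity_lexicon(rng, config.entity_lexicon)
    entity_types = {e: ENTITY_TYPES[i % len(ENTITY_TYPES)]
                    for i, e in enumerate(entities)}
    probs = config.class_probs
    classes = list(scheme.classes)
    records: list[FeatureRecord] = []
    for i in range(config.n_records):
        label = classes[rng.choice(len(classes), p=probs)]
        verbs, triggers, negation = _signature_for(label, scheme)
        if rng.random() < config.signal:
            verb = str(rng.choice(verbs))
            trigger = str(rng.choice(triggers)) if triggers else None
            relation = RELATION_WORDS.get(
                TO_BINARY.get(label, label), ALL_RELATION_WORDS[0]
            )
        else:
            verb = str(rng.choice(ALL_VERBS))
            trigger = (
                str(rng.choice(ALL_TRIGGERS)) if rng.random() < 0.5 else None
            )
            negation = str(rng.choice(("POSITIVE", "NEGATIVE")))
            relation = str(rng.choice(ALL_RELATION_WORDS))
        e_l, e_r = rng.choice(entities, size=2, replace=False)
        context = str(rng.choice(CONTEXTS))
        middle = f"{verb} {trigger}" if trigger else verb
        sentence = f"{e_l} {middle} {e_r} in {context}"
        if scheme.name == "binary":
            binary_label, multiclass_label = label, None
        else:
            binary_label, multiclass_label = TO_BINARY[label], label
        records.append(
            FeatureRecord(
                doc_id=f"synth{config.seed}_{i}",
                sent_id=int(rng.integers(0, 10)),
                entity_left=str(e_l),
                type_left=entity_types[str(e_l)],
                context_left=NA,
                entity_right=str(e_r),
                type_right=entity_types[str(e_r)],
                context_right=NA,
                negation=negation,
                tense=str(rng.choice(("ACTIVE", "PASSIVE"))),
                verb=verb,
                relation=relation,
                context_level="level=0",
                verb_phrase=f"{middle} {e_r}",
                sentence=sentence,
                binary_label=binary_label,
                multiclass_label=multiclass_label,
            )
        )
    return records


def lexicon_lookup_rule(record: FeatureRecord, scheme: LabelScheme) -> str:
    """Classify a record from its verb/trigger/negation alone.

    This is the generator's own separability oracle: at ``signal=1`` it
    recovers every label exactly; at ``signal=0`` it performs at chance.
    """
    verb = record.verb
    if scheme.name == "binary":
        directed = CAUSAL_VERBS + DIRECTED_FALLBACK_VERBS
        return "DirectedLink" if verb in directed else "UndirectedLink"
    trigger = None
    tokens = record.verb_phrase.split()
    for tok in tokens:
        if tok in INCREASE_TRIGGERS:
            trigger = "inc"
        elif tok in DECREASE_TRIGGERS:
            trigger = "dec"
    neg = record.negation
    if verb in CAUSAL_VERBS:
        if trigger == "inc":
            return "PositiveIncrease" if neg == "POSITIVE" else "NegativeIncrease"
        if trigger == "dec":
            return "PositiveDecrease" if neg == "POSITIVE" else "NegativeDecrease"
        return "PositiveCause" if neg == "POSITIVE" else "NegativeCause"
    if verb in ASSOCIATIVE_VERBS:
        return "PositiveCorrelation" if neg == "POSITIVE" else "NegativeCorrelation"
    if verb in DIRECTED_FALLBACK_VERBS:
        return "DirectedLink"
    return "UndirectedLink"


def make_benchmark_suite(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write the standard synthetic fixtures as TSV files.

    ``binary_balanced`` (50/50), ``binary_imbalanced`` (80/20, max/min class
    ratio >= 3, the qualitative skew of the real corpus), ``multiclass``
    (10 classes, mildly skewed), and a 20-record ``smoke`` set.  Regenerating
    with the same seed reproduces the files byte for byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    binary = LabelScheme.binary()
    multi = LabelScheme.multiclass()
    skewed_multi = tuple(
        np.array([3, 2, 2, 2, 1, 1, 2, 1, 3, 3], dtype=float) / 20.0
    )
    configs = {
        "binary_balanced": GeneratorConfig(
            n_records=1000, scheme=binary, class_probs=(0.5, 0.5),
            signal=0.9, seed=seed,
        ),
        "binary_imbalanced": GeneratorConfig(
            n_records=1000, scheme=binary, class_probs=(0.8, 0.2),
            signal=0.9, seed=seed + 1,
        ),
        "multiclass": GeneratorConfig(
            n_records=1500, scheme=multi, class_probs=skewed_multi,
            signal=0.9, seed=seed + 2,
        ),
        "smoke": GeneratorConfig(
            n_records=20, scheme=binary, class_probs=(0.5, 0.5),
            signal=1.0, seed=seed + 3,
        ),
    }
    paths = {}
    for name, cfg in configs.items():
        paths[name] = write_records(generate(cfg), out_dir / f"{name}.tsv")
    return paths
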