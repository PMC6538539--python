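import numpy as np
import pytest

from relclass import (
    CNNTextClassifier,
    FeatureRecord,
    GeneratorConfig,
    GroupSpec,
    LabelScheme,
    build_dataset,
    generate,
    random_embeddings,
)
from relclass.embeddings import vocabulary_of


@pytest.fixture
def table1_record():
    """The worked-example record: two compounds linked by 'increase'."""
    return FeatureRecord(
        doc_id="15248468",
        sent_id=0,
        entity_left="dehydroepiandrosterone sulfate",
        type_left="COMPOUND",
        context_left="NA",
        entity_right="ubiquinone-9",
        type_right="COMPOUND",
        context_right="NA",
        negation="POSITIVE",
        tense="ACTIVE",
        verb="increase",
        relation="LOCATION_OF",
        context_level="level=0",
        verb_phrase="increases hepatic ubiquinone-9 in male F-344",
        sentence=(
            "Dehydroepiandrosterone sulfate increases hepatic "
            "ubiquinone-9 in male F-344 rats"
        ),
        binary_label="DirectedLink",
        multiclass_label="PositiveCause",
    )


def make_text_dataset(n=120, signal=1.0, seed=0, group=2, scheme=None):
    """Synthetic (texts, labels) pairs for one feature group."""
    scheme = scheme or LabelScheme.binary()
    records = generate(
        GeneratorConfig(n_records=n, scheme=scheme, signal=signal, seed=seed)
    )
    pairs = build_dataset(records, GroupSpec.for_group(group), scheme)
    texts = [t for t, _ in pairs]
    labels = np.array([lab for _, lab in pairs])
    return texts, labels


def small_cnn(texts, seed=0, **overrides):
    """A deliberately tiny model for fast unit tests."""
    emb = random_embeddings(
        vocabulary_of(t.text for t in texts), k=16, seed=seed
    )
    params = dict(
        embedding=emb,
        n_maps=8,
        fixed_len=12,
        max_epochs=10,
        patience=5,
        dropout=0.0,
        l2=0.0,
        seed=seed,
    )
    params.update(overrides)
    return CNNTextClassifier(**params)


@pytest.fixture
def binary_dataset():
    return make_text_dataset(n=120, signal=1.0, seed=0)
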