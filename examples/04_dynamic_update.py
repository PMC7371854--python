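"""Extend a trained model with a newly discovered riboswitch family.

Trains a 4-class model, then feeds a fifth family to the updater: the
dataset is augmented (existing class indices unchanged, the new family
appended) and a fresh model is trained and evaluated.  The update manifest
records the class orders and the before/after metrics.
"""

import tempfile
from pathlib import Path

from riboclass import SyntheticSpec, generate_dataset
from riboclass.dynamic import update_and_retrain
from riboclass.models import ModelSpec, train_on_dataset
from riboclass.sequence_io import RiboswitchDataset, SequenceRecord, write_fasta

full = generate_dataset(
    SyntheticSpec(
        n_classes=5,
        n_per_class=120,
        length_range=(50, 70),
        motif_mutation_rate=0.02,
        seed=21,
    )
).dataset

# hold the fifth family back as the "new discovery"
known = RiboswitchDataset(
    [r for r in full if r.label != "class_04"],
    class_names=full.class_names[:4],
)
new_family = [
    SequenceRecord(r.id, r.sequence)
    for r in full
    if r.label == "class_04"
]

with tempfile.TemporaryDirectory() as tmp:
    fasta = Path(tmp) / "class_04.fa"
    write_fasta(new_family, fasta)

    old_model, _ = train_on_dataset(
        known, ModelSpec("mlp", {"max_iter": 300}, random_seed=2), seed=2
    )
    print("before:", len(old_model.class_names), "classes")

    new_model, manifest = update_and_retrain(
        known,
        {"class_04": fasta},
        "mlp",
        config={"max_iter": 300},
        seed=2,
    )

print("after: ", len(new_model.class_names), "classes")
print("class order:", manifest.resulting_classes)
print("held-out metrics after update:")
for metric, value in manifest.metrics_after.items():
    print(f"  {metric}: {value:.3f}")
probe = new_model.predict_proba_sequences([full.records[0].sequence])
print("probability vector width:", probe.shape[1])
# Old classes keep their indices (class_00..class_03 unchanged); only the
# appended class_04 column is new, so downstream consumers of the
# probability vectors stay compatible.
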