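"""Train one conventional and one deep classifier on synthetic families.

Generates an 8-family planted-motif dataset, trains Gaussian naive Bayes
(on k-mer features) and a small CNN (on the raw encoded sequence), and
prints held-out accuracy, macro F-score and micro/macro AUROC for both.
The deep model reads positional motif signal the k-mer features blur, so
it separates the families much better.
"""

from riboclass import SyntheticSpec, generate_dataset
from riboclass.evaluation import evaluate_classifier
from riboclass.models import ModelSpec, stratified_split, train_on_dataset

dataset = generate_dataset(
    SyntheticSpec(
        n_classes=8,
        n_per_class=150,
        length_range=(60, 100),
        motif_length=12,
        motif_mutation_rate=0.05,
        seed=11,
    )
).dataset

split = stratified_split(dataset, seed=3)
test = dataset.subset(split.test)

specs = {
    "gaussian_nb": ModelSpec("gaussian_nb", random_seed=3),
    "cnn": ModelSpec(
        "cnn",
        {
            "filters": (32, 32),
            "kernel_size": 5,
            "pool_size": 92,  # covers the conv output: global max pooling
            "dropout": 0.2,
            "epochs": 15,
            "learning_rate": 2e-3,
            "encoding_length": 100,
        },
        random_seed=3,
    ),
}

for name, spec in specs.items():
    clf, _ = train_on_dataset(dataset, spec, split=split, seed=3)
    report = evaluate_classifier(
        clf.predict_proba_sequences(test.sequences), test.labels, clf.class_names
    )
    print(
        f"{name:12s} accuracy={report.accuracy:.3f} "
        f"macro-F={report.macro_f:.3f} "
        f"micro-AUROC={report.micro_auroc:.3f} "
        f"macro-AUROC={report.macro_auroc:.3f}"
    )
# Expect the CNN well above the naive Bayes on every metric: the planted
# 12-mer is positional information that 1-/2-mer frequencies wash out.
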