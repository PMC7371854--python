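"""Synthetic riboswitch-like sequence families with controllable separability.

Real riboswitch families share a conserved aptamer core embedded in variable
flanking sequence, and families differ both in that core and in overall base
composition.  The generator emulates the minimal version of this structure:
each class has (i) an i.i.d. background base composition and (ii) a planted
class motif, copied into every sequence at a random admissible position with
per-base mutations.  That is enough structure to exercise every downstream
claim — k-mer separability for the conventional models, positional signal
for the deep models, and calibrated within/between-class identity for the
clustering module.

A "hard mode" plants the motif as a long-range dependency instead: the motif
is split into two halves placed at correlated positions with a variable gap,
and classes come in pairs whose motifs are half-swapped versions of each
other.  Paired classes then have (near-)identical 1-mer and 2-mer content —
differing only in the order of the halves — so k-mer classifiers are blind
to the pairing while sequence-reading models are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .sequence_io import RiboswitchDataset, SequenceRecord, write_fasta, write_dataset

__all__ = ["SyntheticSpec", "GeneratedDataset", "generate_family", "generate_dataset"]

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic multi-family dataset.

    Defaults mirror the statistical shape of curated riboswitch collections:
    sequence lengths spanning 45-220 bases (the range of family average
    lengths in the Rfam riboswitch pull), a 12-base conserved motif, a 5%
    per-base motif mutation rate, and modestly class-specific background
    composition.
    """

    n_classes: int = 8
    n_per_class: int | Sequence[int] = 200
    length_range: tuple[int, int] = (45, 220)
    motif_length: int = 12
    motif_mutation_rate: float = 0.05
    background_composition: np.ndarray | None = None  # (n_classes, 4) simplices
    composition_concentration: float = 20.0  # Dirichlet conc. when drawn
    hard_mode: bool = False
    hard_gap_range: tuple[int, int] = (8, 24)
    seed: int = 0

    def per_class_sizes(self) -> list[int]:
        if isinstance(self.n_per_class, int):
            return [self.n_per_class] * self.n_classes
        sizes = list(self.n_per_class)
        if len(sizes) != self.n_classes:
            raise ValueError("n_per_class list length must equal n_classes")
        return sizes

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        lo, hi = self.length_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid length range {self.length_range}")
        span = self.motif_length
        if self.hard_mode:
            span = self.motif_length + self.hard_gap_range[1]
        if span >= lo:
            raise ValueError(
                f"planted motif span {span} must be shorter than the minimum "
                f"sequence length {lo}"
            )
        if not 0.0 <= self.motif_mutation_rate <= 1.0:
            raise ValueError("motif_mutation_rate must be in [0, 1]")
        if any(n < 1 for n in self.per_class_sizes()):
            raise ValueError("class sizes must be positive")
        if self.background_composition is not None:
            comp = np.asarray(self.background_composition, dtype=float)
            if comp.shape != (self.n_classes, 4):
                raise ValueError("background_composition must be (n_classes, 4)")
            if (comp < 0).any() or not np.allclose(comp.sum(axis=1), 1.0):
                raise ValueError("compositions must be probability simplices")


@dataclass
class GeneratedDataset:
    """A labeled dataset plus the ground truth used to generate it."""

    dataset: RiboswitchDataset
    motifs: dict[str, str]
    compositions: dict[str, list[float]]
    # per record id: implant position(s) of the (possibly split) motif
    motif_positions: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        """Emit one FASTA per family, the combined CSV, and ground truth JSON."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for label in self.dataset.class_names:
            fam = [r for r in self.dataset if r.label == label]
            write_fasta(fam, out_dir / f"{label}.fa")
        write_dataset(self.dataset, out_dir / "dataset.csv")
        truth = {
            "motifs": self.motifs,
            "compositions": self.compositions,
            "motif_positions": {k: list(v) for k, v in self.motif_positions.items()},
        }
        (out_dir / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def _mutate(motif: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return motif
    chars = list(motif)
    for i, ch in enumerate(chars):
        if rng.random() < rate:
            chars[i] = str(rng.choice(_BASES[_BASES != ch]))
    return "".join(chars)


def generate_family(
    label: str,
    n: int,
    motif: str,
    composition: np.ndarray,
    length_range: tuple[int, int],
    mutation_rate: float,
    rng: np.random.Generator,
    hard_mode: bool = False,
    hard_gap_range: tuple[int, int] = (8, 24),
) -> tuple[list[SequenceRecord], dict[str, tuple[int, ...]]]:
    """Generate ``n`` records of one family and the implant positions.

    Each sequence is i.i.d. background from the class composition with a
    mutated copy of the class motif implanted at a uniform-random admissible
    position (two correlated positions in hard mode).
    """
    lo, hi = length_range
    records: list[SequenceRecord] = []
    positions: dict[str, tuple[int, ...]] = {}
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = rng.choice(_BASES, size=length, p=composition)
        planted = _mutate(motif, mutation_rate, rng)
        rid = f"{label}_{i:04d}"
        if hard_mode:
            half = len(planted) // 2
            h1, h2 = planted[:half], planted[half:]
            gap = int(rng.integers(hard_gap_range[0], hard_gap_range[1] + 1))
            span = len(planted) + gap
            p1 = int(rng.integers(0, length - span + 1))
            p2 = p1 + len(h1) + gap
            seq[p1 : p1 + len(h1)] = list(h1)
            seq[p2 : p2 + len(h2)] = list(h2)
            positions[rid] = (p1, p2)
        else:
            p = int(rng.integers(0, length - len(planted) + 1))
            seq[p : p + len(planted)] = list(planted)
            positions[rid] = (p,)
        records.append(SequenceRecord(id=rid, sequence="".join(seq), label=label))
    return records, positions


def _draw_motifs(spec: SyntheticSpec, rng: np.random.Generator) -> list[str]:
    """Distinct class motifs; in hard mode classes pair up with half-swapped
    motifs so paired classes share k-mer content."""
    motifs: list[str] = []
    while len(motifs) < spec.n_classes:
        m = "".join(rng.choice(_BASES, size=spec.motif_length))
        if m in motifs:
            continue
        motifs.append(m)
        if spec.hard_mode and len(motifs) < spec.n_classes:
            half = spec.motif_length // 2
            swapped = m[half:] + m[:half]
            if swapped not in motifs and swapped != m:
                motifs.append(swapped)
    return motifs[: spec.n_classes]


def generate_dataset(spec: SyntheticSpec) -> GeneratedDataset:
    """Generate all families of ``spec`` independently, deterministically.

    Class labels are ``class_00 .. class_NN`` in manifest order.  A fixed
    seed yields a byte-identical dataset across runs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = [f"class_{i:02d}" for i in range(spec.n_classes)]
    if spec.background_composition is not None:
        comps = np.asarray(spec.background_composition, dtype=float)
    else:
        comps = rng.dirichlet(
            [spec.composition_concentration] * 4, size=spec.n_classes
        )
    motifs = _draw_motifs(spec, rng)
    all_records: list[SequenceRecord] = []
    all_positions: dict[str, tuple[int, ...]] = {}
    for label, n, motif, comp in zip(labels, spec.per_class_sizes(), motifs, comps):
        recs, pos = generate_family(
            label,
            n,
            motif,
            comp,
            spec.length_range,
            spec.motif_mutation_rate,
            rng,
            hard_mode=spec.hard_mode,
            hard_gap_range=spec.hard_gap_range,
        )
        all_records.extend(recs)
        all_positions.update(pos)
    dataset = RiboswitchDataset(all_records, class_names=labels)
    return GeneratedDataset(
        dataset=dataset,
        motifs=dict(zip(labels, motifs)),
        compositions={l: c.tolist() for l, c in zip(labels, comps)},
        motif_positions=all_positions,
    )
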