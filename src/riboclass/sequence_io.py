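"""Reading, sanitizing, and persisting labeled riboswitch sequence datasets.

Riboswitch sequences come from RNA databases and arrive with a mix of
upper/lower case, uracil instead of thymine, alignment gap characters and
IUPAC ambiguity codes.  Everything downstream (k-mer featurization, integer
encoding for the deep classifiers, identity clustering) expects a clean
``ACGT`` alphabet, so sanitization is centralised here.

The on-disk dataset format is a CSV with columns ``id,sequence,label`` and
optionally the 20 k-mer feature columns ``f1..f20``; the class order is
persisted as a plain-text manifest (one class per line) so that probability
vectors are reported in a stable order across runs.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SequenceRecord",
    "RiboswitchDataset",
    "SanitizationError",
    "sanitize_sequence",
    "read_fasta",
    "write_fasta",
    "load_dataset",
    "write_dataset",
    "AMBIGUITY_MAP",
    "EXTENDED_AMBIGUITY_MAP",
]

# Mapping of ambiguity codes that occurred in the original Rfam pull.
AMBIGUITY_MAP: Mapping[str, str] = {
    "R": "G",
    "Y": "T",
    "K": "G",
    "S": "G",
    "W": "A",
    "H": "A",
}

# Extension to the remaining IUPAC codes (default policy; prefers the purine /
# first-listed base, consistent with the core map's apparent preference).
EXTENDED_AMBIGUITY_MAP: Mapping[str, str] = {
    **AMBIGUITY_MAP,
    "M": "A",
    "B": "G",
    "D": "G",
    "V": "G",
    "N": "A",
}

_GAP_CHARS = {"-", "."}
_STANDARD = {"A", "C", "G", "T"}
_IUPAC = _STANDARD | set(EXTENDED_AMBIGUITY_MAP) | {"U"}


class SanitizationError(ValueError):
    """A raw sequence cannot be sanitized to the ACGT alphabet."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


def sanitize_sequence(raw: str, policy: str = "map") -> str:
    """Sanitize a raw nucleotide string to the ``ACGT`` alphabet.

    Uppercases, strips alignment gap characters (``-``/``.``), replaces
    uracil by thymine and maps ambiguity codes to a single base.

    Parameters
    ----------
    raw
        Input nucleotide string (DNA or RNA, any case, gaps allowed).
    policy
        ``"map"`` (default) maps every IUPAC ambiguity code via
        :data:`EXTENDED_AMBIGUITY_MAP`; ``"strict"`` accepts only the codes
        observed in the original data (:data:`AMBIGUITY_MAP`) and rejects
        M/B/D/V/N.

    Raises
    ------
    SanitizationError
        If the input is empty (or all gaps), or contains a character outside
        the IUPAC nucleotide codes; the offending position is reported.
    """
    if policy not in ("map", "strict"):
        raise ValueError(f"unknown sanitization policy: {policy!r}")
    if not raw:
        raise SanitizationError("empty sequence")
    mapping = EXTENDED_AMBIGUITY_MAP if policy == "map" else AMBIGUITY_MAP
    out: list[str] = []
    for pos, ch in enumerate(raw):
        c = ch.upper()
        if c in _GAP_CHARS:
            continue
        if c == "U":
            c = "T"
        if c in _STANDARD:
            out.append(c)
            continue
        if c in _IUPAC:
            if c in mapping:
                out.append(mapping[c])
                continue
            raise SanitizationError(
                f"ambiguity code {ch!r} at position {pos} rejected under "
                f"strict policy",
                position=pos,
            )
        raise SanitizationError(
            f"character {ch!r} at position {pos} is not an IUPAC nucleotide code",
            position=pos,
        )
    if not out:
        raise SanitizationError("sequence contains only gap characters")
    return "".join(out)


@dataclass(frozen=True)
class SequenceRecord:
    """One sanitized nucleotide sequence with an optional family label."""

    id: str
    sequence: str
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - _STANDARD
        if bad:
            raise ValueError(
                f"record {self.id!r}: unsanitized characters {sorted(bad)}"
            )


@dataclass
class RiboswitchDataset:
    """An ordered collection of records with a fixed class order.

    The class order (``class_names``) is established on construction — first
    occurrence order by default — and persisted with the dataset; every
    probability vector produced by a classifier trained on this dataset is
    reported in this order.
    """

    records: list[SequenceRecord]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = [i for i, n in collections.Counter(ids).items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate record ids: {dupes[:5]}")
        labels_seen: list[str] = []
        for r in self.records:
            if r.label is not None and r.label not in labels_seen:
                labels_seen.append(r.label)
        if not self.class_names:
            self.class_names = labels_seen
        else:
            missing = set(labels_seen) - set(self.class_names)
            if missing:
                raise ValueError(
                    f"record labels not in class manifest: {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_sizes(self) -> dict[str, int]:
        counts = collections.Counter(
            r.label for r in self.records if r.label is not None
        )
        return {name: counts.get(name, 0) for name in self.class_names}

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> list[str | None]:
        return [r.label for r in self.records]

    def subset(self, indices: Sequence[int]) -> "RiboswitchDataset":
        """Subset by record index, keeping the full class manifest."""
        return RiboswitchDataset(
            [self.records[i] for i in indices], class_names=list(self.class_names)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "label": [r.label for r in self.records],
            }
        )


def read_fasta(
    path: str | Path,
    label: str | None = None,
    policy: str = "map",
    dedup_ids: bool = False,
) -> list[SequenceRecord]:
    """Read a FASTA file into sanitized records, all given the same label.

    Multi-line sequence entries are concatenated and blank lines ignored (the
    standard FASTA conventions).  Raises on an empty file, a malformed file
    (sequence data before the first ``>`` header) or a duplicate id unless
    ``dedup_ids`` appends a numeric suffix instead.
    """
    path = Path(path)
    # detect sequence-before-header with a line number, which Bio.SeqIO
    # silently tolerates
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}:{lineno}: sequence data before first FASTA header"
                )
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            if not dedup_ids:
                raise ValueError(f"{path}: duplicate record id {rid!r}")
            seen[rid] += 1
            rid = f"{rid}_{seen[rid]}"
        else:
            seen[rid] = 1
        records.append(
            SequenceRecord(
                id=rid,
                sequence=sanitize_sequence(str(entry.seq), policy=policy),
                label=label,
            )
        )
    if not records:
        raise ValueError(f"{path}: no FASTA entries found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    entries = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def _manifest_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(csv_path.suffix + ".classes")


def write_dataset(dataset: RiboswitchDataset, path: str | Path) -> None:
    """Persist a dataset as CSV plus a plain-text class manifest.

    The manifest (``<path>.classes``, one class per line) fixes the class
    index order; :func:`load_dataset` restores it byte-identically.
    """
    path = Path(path)
    dataset.to_dataframe().to_csv(path, index=False)
    _manifest_path(path).write_text(
        "".join(f"{name}\n" for name in dataset.class_names)
    )


def load_dataset(path: str | Path, policy: str = "map") -> RiboswitchDataset:
    """Load a dataset CSV (columns ``id,sequence,label``).

    Sequences are (re-)sanitized on load, so a hand-made CSV with RNA
    sequences works.  If a class manifest sits beside the CSV it fixes the
    class order; otherwise first-occurrence order is used.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = {"id", "sequence", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    records = [
        SequenceRecord(
            id=str(row.id),
            sequence=sanitize_sequence(str(row.sequence), policy=policy),
            label=None if pd.isna(row.label) else str(row.label),
        )
        for row in df.itertuples(index=False)
    ]
    manifest = _manifest_path(path)
    class_names: list[str] = []
    if manifest.exists():
        class_names = manifest.read_text().splitlines()
    return RiboswitchDataset(records, class_names=class_names)
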