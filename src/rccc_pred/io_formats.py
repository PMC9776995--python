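"""Readers and writers for the on-disk formats used by the pipeline.

Three formats are handled: multi-record FASTA reference files, the
mutation-catalog CSV (``gene_id,position,ref,alt,label``) and the feature
table CSV (``sample_id,M1,M2,M3,M4,Min,Max,label``).  All CSVs are
comma-separated UTF-8 with a mandatory header row and ``.`` as the decimal
point.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import ContractError, FormatError

#: Canonical class labels, in the fixed order used everywhere downstream.
KIDNEY = "kidney_tumor_driver"
OTHER = "other_tumor_driver"
UNKNOWN = "unknown"
CLASS_ORDER: tuple[str, str, str] = (KIDNEY, OTHER, UNKNOWN)

# Variant spellings seen in the wild are accepted on read and normalized.
_LABEL_ALIASES = {
    KIDNEY: KIDNEY,
    "kindey_tumor_driver": KIDNEY,
    "kindey_tumour_driver": KIDNEY,
    "kidney_tumour_driver": KIDNEY,
    "rccc": KIDNEY,
    OTHER: OTHER,
    "other_tumour_driver": OTHER,
    "other_tumer_driver": OTHER,
    UNKNOWN: UNKNOWN,
    "non-tumor driver": UNKNOWN,
    "non-tumour driver": UNKNOWN,
    "non_tumor_driver": UNKNOWN,
    "unknown (non-tumor driver)": UNKNOWN,
    "unknown (non-tumour driver)": UNKNOWN,
}

FEATURE_COLUMNS = ("M1", "M2", "M3", "M4", "Min", "Max")
_TABLE_COLUMNS = ("sample_id", *FEATURE_COLUMNS, "label")

VALID_BASES = frozenset("ACGT")


def normalize_label(raw: str) -> str:
    """Map a class-label spelling onto the canonical three-label set."""
    key = raw.strip().lower()
    try:
        return _LABEL_ALIASES[key]
    except KeyError:
        raise FormatError(
            f"unknown class label {raw!r}; expected one of {sorted(set(_LABEL_ALIASES.values()))}"
        ) from None


@dataclass(frozen=True)
class FastaRecord:
    """One FASTA entry: whitespace-free id plus an upper-cased sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ContractError(f"FASTA id must be non-empty and whitespace-free: {self.id!r}")
        if not self.sequence:
            raise ContractError(f"FASTA record {self.id!r} has an empty sequence")


@dataclass(frozen=True)
class MutationRecord:
    """A single-nucleotide substitution with its class label.

    ``position`` is 1-based within the named gene's reference sequence.
    """

    gene_id: str
    position: int
    ref_base: str
    alt_base: str
    class_label: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ContractError(f"position must be >= 1, got {self.position}")
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise ContractError(
                f"ref/alt bases must be in {sorted(VALID_BASES)}: "
                f"{self.ref_base!r} -> {self.alt_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise ContractError(f"ref and alt base identical ({self.ref_base!r})")
        if self.class_label not in CLASS_ORDER:
            raise ContractError(f"class label {self.class_label!r} not in {CLASS_ORDER}")


@dataclass(frozen=True)
class FeatureRow:
    """One sample's 6-value feature vector, optionally labeled."""

    sample_id: str
    features: tuple[float, ...]
    class_label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(float(v) for v in self.features))
        if len(self.features) != 6:
            raise ContractError(
                f"feature row {self.sample_id!r} must carry exactly 6 values, got {len(self.features)}"
            )
        if not all(math.isfinite(v) for v in self.features):
            raise ContractError(f"feature row {self.sample_id!r} contains non-finite values")
        if self.class_label is not None and self.class_label not in CLASS_ORDER:
            raise ContractError(f"class label {self.class_label!r} not in {CLASS_ORDER}")


def read_fasta(path: str | os.PathLike) -> list[FastaRecord]:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Sequences are upper-cased; record order is preserved.  A body line before
    the first header or an empty sequence under a header is a
    :class:`FormatError`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}: sequence data before the first FASTA header")
            break
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(FastaRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: Sequence[FastaRecord], path: str | os.PathLike, width: int = 70) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_mutation_catalog(path: str | os.PathLike) -> list[MutationRecord]:
    """Parse the mutation-catalog CSV into validated records.

    Every data row either yields a record or raises a :class:`FormatError`
    naming the 1-based data-row number; nothing is silently dropped.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    required = {"gene_id", "position", "ref", "alt", "label"}
    missing = required - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: catalog header is missing columns {sorted(missing)}")

    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            position = int(str(row.position))
        except ValueError:
            raise FormatError(f"{path}: row {i}: non-integer position {row.position!r}") from None
        try:
            records.append(
                MutationRecord(
                    gene_id=str(row.gene_id),
                    position=position,
                    ref_base=str(row.ref).upper(),
                    alt_base=str(row.alt).upper(),
                    class_label=normalize_label(str(row.label)),
                )
            )
        except (ContractError, FormatError) as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from None
    return records


def write_mutation_catalog(records: Sequence[MutationRecord], path: str | os.PathLike) -> None:
    """Write a catalog CSV readable by :func:`read_mutation_catalog`."""
    frame = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "position": [r.position for r in records],
            "ref": [r.ref_base for r in records],
            "alt": [r.alt_base for r in records],
            "label": [r.class_label for r in records],
        },
        columns=["gene_id", "position", "ref", "alt", "label"],
    )
    frame.to_csv(path, index=False)


def write_feature_table(rows: Sequence[FeatureRow], path: str | os.PathLike) -> None:
    """Write the feature table CSV; values round-trip to >= 12 significant digits."""
    frame = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                **dict(zip(FEATURE_COLUMNS, r.features)),
                "label": r.class_label if r.class_label is not None else "",
            }
            for r in rows
        ],
        columns=list(_TABLE_COLUMNS),
    )
    # repr-based formatting: shortest string that round-trips the double exactly
    frame.to_csv(path, index=False, float_format=None)


def read_feature_table(path: str | os.PathLike) -> list[FeatureRow]:
    """Read a feature table written by :func:`write_feature_table`."""
    frame = pd.read_csv(path, dtype={"sample_id": str, "label": str}, keep_default_na=False)
    missing = set(_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: feature table is missing columns {sorted(missing)}")
    rows = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            values = tuple(float(getattr(row, c)) for c in FEATURE_COLUMNS)
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: non-numeric feature value ({exc})") from None
        label = str(row.label).strip()
        try:
            rows.append(
                FeatureRow(
                    sample_id=str(row.sample_id),
                    features=values,
                    class_label=normalize_label(label) if label else None,
                )
            )
        except (ContractError, FormatError) as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from None
    return rows


def read_label_map(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column ``sample_id,label`` CSV into a dict."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if not {"sample_id", "label"} <= set(frame.columns):
        raise FormatError(f"{path}: label file needs columns sample_id,label")
    return {
        str(r.sample_id): normalize_label(str(r.label)) for r in frame.itertuples(index=False)
    }


def write_label_map(labels: dict[str, str], path: str | os.PathLike) -> None:
    pd.DataFrame(
        {"sample_id": list(labels), "label": [labels[k] for k in labels]}
    ).to_csv(path, index=False)
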