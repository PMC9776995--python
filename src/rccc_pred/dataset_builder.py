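"""Benchmark construction: mutation application, redundancy removal, splitting.

The benchmark is built by applying each catalog substitution to its reference
sequence, then pruning near-identical sequences with a greedy longest-first
identity clustering (an internal stand-in for CD-HIT-style redundancy
removal), and finally producing a seeded stratified train/test split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ContractError, MutationError
from .io_formats import CLASS_ORDER, FastaRecord, MutationRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceSample:
    """A (possibly mutated) labeled DNA sequence."""

    sample_id: str
    sequence: str
    class_label: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ContractError(f"sample {self.sample_id!r} has an empty sequence")
        if self.class_label not in CLASS_ORDER:
            raise ContractError(f"class label {self.class_label!r} not in {CLASS_ORDER}")


@dataclass(frozen=True)
class SplitResult:
    """A stratified partition of samples; ``train`` and ``test`` are disjoint."""

    train: tuple
    test: tuple
    seed: int


def apply_mutation(
    reference: FastaRecord, mutation: MutationRecord, strict: bool = True
) -> Optional[SequenceSample]:
    """Apply one substitution to a reference, yielding a labeled sample.

    The returned sequence differs from the reference at exactly the 1-based
    ``mutation.position``.  When the base found there does not equal
    ``mutation.ref_base``: strict mode raises :class:`MutationError`,
    non-strict mode warns and returns ``None``.
    """
    if mutation.gene_id != reference.id:
        raise ContractError(
            f"mutation targets gene {mutation.gene_id!r} but reference is {reference.id!r}"
        )
    pos = mutation.position
    if pos > len(reference.sequence):
        raise MutationError(
            f"{reference.id}: position {pos} out of range (length {len(reference.sequence)})"
        )
    found = reference.sequence[pos - 1]
    if found != mutation.ref_base:
        msg = (
            f"{reference.id}: expected {mutation.ref_base!r} at position {pos}, found {found!r}"
        )
        if strict:
            raise MutationError(msg)
        warnings.warn(msg, stacklevel=2)
        return None
    mutated = reference.sequence[: pos - 1] + mutation.alt_base + reference.sequence[pos:]
    sample_id = f"{reference.id}_c.{pos}{mutation.ref_base}>{mutation.alt_base}"
    return SequenceSample(sample_id=sample_id, sequence=mutated, class_label=mutation.class_label)


def build_benchmark(
    references: Sequence[FastaRecord],
    catalog: Sequence[MutationRecord],
    strict: bool = True,
) -> list[SequenceSample]:
    """Apply every catalog row to its reference, in catalog order.

    In strict mode an unresolvable gene id or a ref-base mismatch aborts the
    build; non-strict skips the offending rows with a warning.
    """
    by_id = {r.id: r for r in references}
    samples: list[SequenceSample] = []
    for mut in catalog:
        ref = by_id.get(mut.gene_id)
        if ref is None:
            if strict:
                raise ContractError(f"catalog names unknown gene {mut.gene_id!r}")
            warnings.warn(f"skipping mutation for unknown gene {mut.gene_id!r}", stacklevel=2)
            continue
        sample = apply_mutation(ref, mut, strict=strict)
        if sample is not None:
            samples.append(sample)
    log.info("built benchmark: %d samples from %d catalog rows", len(samples), len(catalog))
    return samples


def _identity(a: str, b: str) -> float:
    """Fraction of matching positions aligning the shorter onto the longer,
    ungapped, anchored at the left end; denominator = shorter length."""
    if len(a) > len(b):
        a, b = b, a
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / len(a)


def redundancy_filter(
    samples: Sequence[SequenceSample], threshold: float = 0.7
) -> list[SequenceSample]:
    """Greedy longest-first identity clustering; returns the representatives.

    Samples are visited by decreasing length (input order breaks ties); a
    sample is kept unless its identity to an already-kept representative is
    >= ``threshold``.  Output preserves the retained (longest-first) order.
    """
    if not 0.0 < threshold <= 1.0:
        raise ContractError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(samples, key=lambda s: -len(s.sequence))
    kept: list[SequenceSample] = []
    for cand in ordered:
        if all(_identity(cand.sequence, rep.sequence) < threshold for rep in kept):
            kept.append(cand)
    log.info("redundancy filter: kept %d of %d samples", len(kept), len(samples))
    return kept


def stratified_split(
    samples: Sequence, train_fraction: float = 0.7, seed: int = 0
) -> SplitResult:
    """Seeded stratified split into train/test partitions.

    Any items carrying ``sample_id`` and ``class_label`` attributes are
    accepted (sequence samples and feature rows alike).  The overall train
    size is ``round(train_fraction * n)``; per-class counts are apportioned
    by the largest-remainder rule, which keeps every class within one sample
    of ``train_fraction * class_size``.
    """
    if not samples:
        raise ContractError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ContractError(f"train_fraction must be in (0, 1), got {train_fraction}")

    rng = np.random.default_rng(seed)
    by_class: dict[str, list] = {}
    for s in samples:
        by_class.setdefault(s.class_label, []).append(s)

    target = int(round(train_fraction * len(samples)))
    quotas = {c: train_fraction * len(v) for c, v in by_class.items()}
    counts = {c: int(q) for c, q in quotas.items()}
    leftover = target - sum(counts.values())
    for c in sorted(by_class, key=lambda c: quotas[c] - counts[c], reverse=True):
        if leftover <= 0:
            break
        if counts[c] < len(by_class[c]):
            counts[c] += 1
            leftover -= 1

    train: list = []
    test: list = []
    for c in sorted(by_class):
        members = by_class[c]
        order = rng.permutation(len(members))
        k = counts[c]
        train.extend(members[i] for i in order[:k])
        test.extend(members[i] for i in order[k:])
    return SplitResult(train=tuple(train), test=tuple(test), seed=seed)
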