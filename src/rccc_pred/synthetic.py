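"""Seeded generators for references, catalogs and separable class datasets.

These stand in for the external gene/mutation databases so the whole
pipeline can be exercised, tested and benchmarked offline.  Class
separability is encoded in base composition: each class's base-probability
vector is the uniform vector pulled toward a class-specific corner by a
``delta`` in [0, 1] (class 0 A-rich, class 1 T-rich, class 2 G-rich), which
the moment features pick up through the numeric encoding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_builder import SequenceSample
from .errors import ContractError
from .io_formats import CLASS_ORDER, FastaRecord, MutationRecord

_BASES = np.array(list("ACGT"))
#: favored base per class, in CLASS_ORDER: kidney -> A, other -> T, unknown -> G
_CLASS_CORNERS = {CLASS_ORDER[0]: "A", CLASS_ORDER[1]: "T", CLASS_ORDER[2]: "G"}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a three-class synthetic dataset."""

    n_per_class: int
    length_range: tuple[int, int] = (800, 1000)
    delta: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ContractError("n_per_class must be >= 1")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ContractError(f"invalid length range {self.length_range}")
        if not 0.0 <= self.delta <= 1.0:
            raise ContractError(f"delta must be in [0, 1], got {self.delta}")


def class_base_probs(label: str, delta: float) -> np.ndarray:
    """Base-probability vector (A, C, G, T order) for one class."""
    p = np.full(4, 0.25) * (1.0 - delta)
    p["ACGT".index(_CLASS_CORNERS[label])] += delta
    return p


def gen_references(
    count: int, length_range: tuple[int, int] = (800, 1000), seed: int = 0
) -> list[FastaRecord]:
    """Uniform-random A/C/G/T reference sequences with ids gene_0001, ..."""
    if count < 1:
        raise ContractError("count must be >= 1")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ContractError(f"invalid length range {length_range}")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(count):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(_BASES[rng.integers(0, 4, size=length)])
        records.append(FastaRecord(id=f"gene_{i + 1:04d}", sequence=seq))
    return records


def gen_catalog(
    references: list[FastaRecord],
    counts_per_class: tuple[int, int, int],
    seed: int = 0,
    corrupt: bool = False,
) -> list[MutationRecord]:
    """Mutation records consistent with the given references.

    Each record names an existing gene, a valid 1-based position, the true
    base at that position as ref and a different alt base.  ``corrupt=True``
    deliberately falsifies the ref base of the first record (negative
    control for strict mutation application).
    """
    total = sum(counts_per_class)
    positions = [(i, p) for i, ref in enumerate(references) for p in range(1, len(ref.sequence) + 1)]
    if total > len(positions):
        raise ContractError(
            f"requested {total} mutations but only {len(positions)} positions exist"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(positions), size=total, replace=False)
    labels = [
        lbl for lbl, cnt in zip(CLASS_ORDER, counts_per_class) for _ in range(cnt)
    ]
    records = []
    for j, (flat, lbl) in enumerate(zip(chosen, labels)):
        gi, pos = positions[flat]
        ref = references[gi]
        ref_base = ref.sequence[pos - 1]
        alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
        if corrupt and j == 0:
            ref_base = next(b for b in "ACGT" if b not in (ref_base, alt_base))
        records.append(
            MutationRecord(
                gene_id=ref.id, position=pos, ref_base=ref_base, alt_base=alt_base,
                class_label=lbl,
            )
        )
    return records


def gen_separable_dataset(spec: SyntheticSpec) -> list[SequenceSample]:
    """Three-class dataset whose classes differ in base composition by delta.

    In the strong-separation regime (delta > 0.5) all sequences share a
    fixed length (the midpoint of ``length_range``) so matrix size cannot
    act as a confound; otherwise lengths vary uniformly within the range.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    fixed_length = (lo + hi) // 2 if spec.delta > 0.5 else None
    samples = []
    for label in CLASS_ORDER:
        p = class_base_probs(label, spec.delta)
        for i in range(spec.n_per_class):
            length = fixed_length if fixed_length is not None else int(rng.integers(lo, hi + 1))
            seq = "".join(_BASES[rng.choice(4, size=length, p=p)])
            samples.append(
                SequenceSample(
                    sample_id=f"synth_{label}_{i + 1:04d}", sequence=seq, class_label=label
                )
            )
    return samples
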