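"""Sharing partition: assign each marker to a class by which samples carry it.

With one normal-mucosa sample and two or more tumour samples per patient,
every non-zero marker column falls in exactly one class:

* ``ALL_SHARED`` — carried by every sample; the individual's germline genotype.
* ``TUMOUR_SHARED`` — all tumours, absent from normal; the clonal "trunk".
* ``TUMOUR_PRIVATE`` — exactly one tumour sample; recent, branch-specific.
* ``OTHER_TUMOUR`` — two or more but not all tumours, absent from normal.
* ``NORMAL_PRIVATE`` — the normal sample only.
* ``OTHER_NORMAL`` — the normal sample plus some but not all tumours.

"Tumour-associated" markers are those absent from the normal sample
(TUMOUR_SHARED, TUMOUR_PRIVATE, OTHER_TUMOUR).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .variant_matrix import NORMAL, REFERENCE_LABEL, TUMOUR, BinaryMarkerMatrix


class SharingClass(str, enum.Enum):
    ALL_SHARED = "ALL_SHARED"
    TUMOUR_SHARED = "TUMOUR_SHARED"
    TUMOUR_PRIVATE = "TUMOUR_PRIVATE"
    NORMAL_PRIVATE = "NORMAL_PRIVATE"
    OTHER_NORMAL = "OTHER_NORMAL"
    OTHER_TUMOUR = "OTHER_TUMOUR"


TUMOUR_ASSOCIATED = (
    SharingClass.TUMOUR_SHARED,
    SharingClass.TUMOUR_PRIVATE,
    SharingClass.OTHER_TUMOUR,
)


@dataclass(frozen=True)
class Assignment:
    sharing: SharingClass
    private_sample: Optional[str] = None  # set only for TUMOUR_PRIVATE


def classify_marker(
    column: Sequence[int] | np.ndarray,
    samples: Sequence[str],
    roles: Mapping[str, str],
) -> Assignment:
    """Classify one marker column (0/1 per sample, reference row excluded)."""
    column = np.asarray(column, dtype=int)
    normals = [s for s in samples if roles.get(s) == NORMAL]
    tumours = [s for s in samples if roles.get(s) == TUMOUR]
    if len(normals) != 1:
        raise ValueError(f"expected exactly one normal sample, got {normals}")
    if len(tumours) < 2:
        raise ValueError("need at least two tumour samples")
    n_bit = int(column[samples.index(normals[0])])
    t_bits = {s: int(column[samples.index(s)]) for s in tumours}
    carriers = [s for s, b in t_bits.items() if b]
    if n_bit == 0 and not carriers:
        raise ValueError("all-zero column violates the matrix invariant")
    if n_bit and len(carriers) == len(tumours):
        return Assignment(SharingClass.ALL_SHARED)
    if not n_bit and len(carriers) == len(tumours):
        return Assignment(SharingClass.TUMOUR_SHARED)
    if not n_bit and len(carriers) == 1:
        return Assignment(SharingClass.TUMOUR_PRIVATE, carriers[0])
    if n_bit and not carriers:
        return Assignment(SharingClass.NORMAL_PRIVATE)
    if n_bit:
        return Assignment(SharingClass.OTHER_NORMAL)
    return Assignment(SharingClass.OTHER_TUMOUR)


@dataclass
class PartitionSummary:
    """Per-class marker counts and derived fractions for one patient."""

    counts: dict[SharingClass, int]
    private_by_tumour: dict[str, int]
    total: int
    assignments: list[Assignment] = field(repr=False, default_factory=list)

    @property
    def tumour_associated(self) -> int:
        return sum(self.counts[c] for c in TUMOUR_ASSOCIATED)

    @property
    def tumour_associated_fraction(self) -> float:
        return self.tumour_associated / self.total if self.total else 0.0

    def fraction(self, cls: SharingClass) -> float:
        return self.counts[cls] / self.total if self.total else 0.0

    def tumour_fraction(self, cls: SharingClass) -> float:
        """Fraction among tumour-associated markers."""
        ta = self.tumour_associated
        return self.counts[cls] / ta if ta else 0.0

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "counts": {c.value: self.counts[c] for c in SharingClass},
            "fractions": {c.value: self.fraction(c) for c in SharingClass},
            "private_by_tumour": dict(self.private_by_tumour),
            "tumour_associated": self.tumour_associated,
            "tumour_associated_fraction": self.tumour_associated_fraction,
            "tumour_shared_fraction_of_tumour_associated":
                self.tumour_fraction(SharingClass.TUMOUR_SHARED),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def partition_counts(matrix: BinaryMarkerMatrix) -> PartitionSummary:
    """Classify every marker of the matrix and tabulate class sizes.

    The all-zero reference pseudo-sample, if present, is ignored.
    """
    samples = [s for s in matrix.samples if s != REFERENCE_LABEL]
    idx = [matrix.samples.index(s) for s in samples]
    counts = {c: 0 for c in SharingClass}
    private = {s: 0 for s in matrix.tumour_samples}
    assignments = []
    for j in range(matrix.n_markers):
        a = classify_marker(matrix.data[idx, j], samples, matrix.roles)
        counts[a.sharing] += 1
        if a.private_sample is not None:
            private[a.private_sample] += 1
        assignments.append(a)
    return PartitionSummary(counts, private, matrix.n_markers, assignments)


def partition_table(matrix: BinaryMarkerMatrix, summary: PartitionSummary) -> pd.DataFrame:
    """Per-marker table (chrom, pos, ref, alt, sharing class, private sample)."""
    rows = [
        (m.chrom, m.pos, m.ref, m.alt, a.sharing.value, a.private_sample or "")
        for m, a in zip(matrix.markers, summary.assignments)
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "sharing_class", "private_sample"]
    )
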