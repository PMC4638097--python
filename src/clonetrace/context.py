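"""Strand-collapsed dinucleotide / trinucleotide mutation contexts.

APOBEC cytidine deaminases mutate cytosines preceded by a 5' thymine
("TpC*" sites, most specifically TpC*pA).  To tally such contexts
strand-symmetrically, every SNV is collapsed onto the strand whose
reference base is A or C: an SNV at a G or T reference position is read on
the minus strand, so its 5' neighbour is the complement of the plus-strand
base *following* the site, and its central and alternate bases are
complemented.  Each valid SNV therefore maps to exactly one of the eight
dinucleotide classes {A,C,G,T}p{A,C}*.

Positions at contig edges or with an ambiguous (non-ACGT) neighbour get an
UNKNOWN label and are excluded from frequency tables (counted separately).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

DINUCLEOTIDE_CLASSES = tuple(
    f"{five}p{central}*" for central in "AC" for five in "ACGT"
)


def complement(base: str) -> str:
    return _COMPLEMENT[base]


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class ContextLabel:
    """Strand-collapsed mutation context of one SNV.

    ``five_prime``/``central``/``alt``/``three_prime`` are on the collapsed
    strand (central base is always A or C when valid).
    """

    five_prime: Optional[str]
    central: Optional[str]
    alt: Optional[str]
    three_prime: Optional[str] = None
    valid: bool = True

    UNKNOWN: "ContextLabel" = None  # set below

    @property
    def dinucleotide(self) -> Optional[str]:
        if not self.valid:
            return None
        return f"{self.five_prime}p{self.central}*"

    @property
    def trinucleotide(self) -> Optional[str]:
        if not self.valid or self.three_prime is None:
            return None
        return f"{self.five_prime}p{self.central}*p{self.three_prime}"

    @property
    def substitution(self) -> Optional[str]:
        if not self.valid:
            return None
        return f"{self.five_prime}p{self.central}*>{self.five_prime}p{self.alt}*"

    @property
    def is_tpc(self) -> bool:
        return self.valid and self.five_prime == "T" and self.central == "C"


ContextLabel.UNKNOWN = ContextLabel(None, None, None, None, valid=False)


def _plus_base(genome: Mapping[str, str], chrom: str, pos: int) -> Optional[str]:
    """Plus-strand base at 1-based ``pos``; None outside the contig."""
    seq = genome[chrom]
    if pos < 1 or pos > len(seq):
        return None
    return str(seq[pos - 1 : pos]).upper()


def dinucleotide_context(
    genome: Mapping[str, str],
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    with_three_prime: bool = False,
) -> ContextLabel:
    """Classify one SNV's strand-collapsed context from the reference genome.

    ``genome`` is any mapping of contig name to sliceable sequence (a plain
    dict of strings or a :class:`pyfaidx.Fasta`).  The reference allele must
    match the genome at ``pos`` (a mismatch signals a coordinate bug and is
    fatal).
    """
    ref, alt = ref.upper(), alt.upper()
    site = _plus_base(genome, chrom, pos)
    if site is None:
        raise ValueError(f"position {chrom}:{pos} outside the contig")
    if site != ref:
        raise ValueError(
            f"reference allele mismatch at {chrom}:{pos}: VCF says {ref}, genome has {site}"
        )
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        return ContextLabel.UNKNOWN
    if ref in "AC":  # read on the plus strand
        five = _plus_base(genome, chrom, pos - 1)
        three = _plus_base(genome, chrom, pos + 1) if with_three_prime else None
        central, alt_c = ref, alt
    else:  # G or T: collapse onto the minus strand
        plus_next = _plus_base(genome, chrom, pos + 1)
        five = complement(plus_next) if plus_next in _COMPLEMENT else plus_next
        central, alt_c = complement(ref), complement(alt)
        three = None
        if with_three_prime:
            plus_prev = _plus_base(genome, chrom, pos - 1)
            three = complement(plus_prev) if plus_prev in _COMPLEMENT else plus_prev
    if five is None or five not in "ACGT":
        return ContextLabel.UNKNOWN
    if with_three_prime and (three is None or three not in "ACGT"):
        return ContextLabel.UNKNOWN
    return ContextLabel(five, central, alt_c, three)


def trinucleotide_context(
    genome: Mapping[str, str], chrom: str, pos: int, ref: str, alt: str
) -> ContextLabel:
    """Dinucleotide context plus the (strand-collapsed) 3' neighbour."""
    return dinucleotide_context(genome, chrom, pos, ref, alt, with_three_prime=True)


def tally_contexts(
    labels: Sequence[ContextLabel],
    groups: Mapping[str, Iterable[int]],
) -> pd.DataFrame:
    """Dinucleotide-class counts and within-group frequencies.

    ``groups`` maps a group name (e.g. a sharing class) to marker indices
    into ``labels``.  UNKNOWN-context markers are excluded from frequencies
    and reported in their own column; frequencies over the eight classes sum
    to 1 within each non-empty group.
    """
    rows = []
    for name, idx in groups.items():
        members = [labels[i] for i in idx]
        known = [m for m in members if m.valid]
        counts = {cls: 0 for cls in DINUCLEOTIDE_CLASSES}
        for m in known:
            counts[m.dinucleotide] += 1
        total = len(known)
        row = {"group": name, "n": total, "n_unknown": len(members) - len(known)}
        for cls in DINUCLEOTIDE_CLASSES:
            row[cls] = counts[cls]
            row[f"freq_{cls}"] = counts[cls] / total if total else float("nan")
        row["tpc_fraction"] = counts["TpC*"] / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def substitution_table(
    labels: Sequence[ContextLabel],
    groups: Mapping[str, Iterable[int]],
) -> pd.DataFrame:
    """Counts of each context-resolved substitution (e.g. ``TpC*>TpT*``) per group."""
    rows = []
    for name, idx in groups.items():
        for lab in (labels[i] for i in idx):
            if lab.valid:
                rows.append({"group": name, "substitution": lab.substitution})
    if not rows:
        return pd.DataFrame(columns=["group", "substitution", "count"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["group", "substitution"]).size().rename("count").reset_index()
    )


def tpc_counts(labels: Sequence[ContextLabel], idx: Iterable[int]) -> tuple[int, int]:
    """(TpC* count, valid-context count) over the given marker indices."""
    members = [labels[i] for i in idx if labels[i].valid]
    return sum(1 for m in members if m.is_tpc), len(members)
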