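"""Functional-impact classification from snpEff-style ANN annotations.

A variant is "functional" when any transcript annotation predicts LOW,
MODERATE or HIGH impact on the protein (splice-site loss, non-synonymous
substitution, stop gain, ...); MODIFIER-only and unannotated variants are
non-functional.  The site's tier is the maximum severity over all its
transcript annotations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

IMPACT_TIERS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_SEVERITY = {t: i for i, t in enumerate(IMPACT_TIERS)}  # lower index = more severe
FUNCTIONAL_TIERS = frozenset({"HIGH", "MODERATE", "LOW"})
UNANNOTATED = "UNANNOTATED"


@dataclass(frozen=True)
class Annotation:
    """One transcript annotation: effect term, impact tier, gene symbol."""

    effect: str
    impact: str
    gene: str


@dataclass(frozen=True)
class ImpactCall:
    tier: str  # HIGH/MODERATE/LOW/MODIFIER/UNANNOTATED
    annotations: tuple[Annotation, ...] = field(default_factory=tuple)

    @property
    def functional(self) -> bool:
        return self.tier in FUNCTIONAL_TIERS

    @property
    def genes(self) -> tuple[str, ...]:
        seen, out = set(), []
        for a in self.annotations:
            if a.gene and a.gene not in seen:
                seen.add(a.gene)
                out.append(a.gene)
        return tuple(out)


def classify_functional(annotation: Optional[str]) -> ImpactCall:
    """Parse an ANN string ("Allele|Effect|Impact|Gene|..." entries joined by
    commas) and classify by the most severe transcript impact.

    Malformed entries are ignored with a warning; a record with no usable
    annotation is UNANNOTATED (non-functional, counted separately).
    """
    if not annotation:
        return ImpactCall(UNANNOTATED)
    parsed: list[Annotation] = []
    for entry in str(annotation).split(","):
        fields = entry.split("|")
        if len(fields) < 4 or fields[2].strip().upper() not in _SEVERITY:
            logger.warning("malformed ANN entry ignored: %r", entry[:80])
            continue
        parsed.append(
            Annotation(fields[1].strip(), fields[2].strip().upper(), fields[3].strip())
        )
    if not parsed:
        return ImpactCall(UNANNOTATED)
    tier = min((a.impact for a in parsed), key=_SEVERITY.__getitem__)
    return ImpactCall(tier, tuple(parsed))


def impact_summary(calls: Sequence[ImpactCall]) -> dict:
    n_func = sum(1 for c in calls if c.functional)
    n_unann = sum(1 for c in calls if c.tier == UNANNOTATED)
    return {
        "total": len(calls),
        "functional": n_func,
        "non_functional": len(calls) - n_func - n_unann,
        "unannotated": n_unann,
    }


def read_gene_list(path) -> list[str]:
    """Plain-text gene list, one symbol per line; blank lines and '#' comments skipped."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line)
    return genes


def driver_overlap(
    markers,
    calls: Sequence[ImpactCall],
    sharing: Sequence,
    tumour_presence: Sequence[bool],
    tpc_flags: Sequence[bool],
    gene_list: Iterable[str],
) -> pd.DataFrame:
    """Overlap of functional, tumour-present SNVs with a candidate driver list.

    One row per (gene, marker) for functional markers carried by at least
    one tumour sample whose annotation hits a listed gene; multiple genes on
    one SNV yield one row each.  The ``missense_tpc_fraction`` attribute of
    the returned frame gives the fraction of listed-gene missense rows that
    are TpC*.
    """
    genes = set(gene_list)
    rows = []
    for m, call, assign, in_tumour, tpc in zip(
        markers, calls, sharing, tumour_presence, tpc_flags
    ):
        if not call.functional or not in_tumour:
            continue
        for ann in call.annotations:
            if ann.gene in genes and ann.impact in FUNCTIONAL_TIERS:
                rows.append(
                    {
                        "gene": ann.gene,
                        "chrom": m.chrom,
                        "pos": m.pos,
                        "ref": m.ref,
                        "alt": m.alt,
                        "effect": ann.effect,
                        "impact": ann.impact,
                        "sharing_class": getattr(assign.sharing, "value", str(assign.sharing)),
                        "tpc": bool(tpc),
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["gene", "chrom", "pos", "ref", "alt", "effect", "impact",
                 "sharing_class", "tpc"],
    )
    missense = df[df["effect"].str.contains("missense", case=False, na=False)]
    df.attrs["missense_tpc_fraction"] = (
        float(missense["tpc"].mean()) if len(missense) else float("nan")
    )
    return df
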