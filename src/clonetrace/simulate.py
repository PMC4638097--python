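"""Synthetic multifocal-patient generator.

Emulates, at the variant-call level, one patient of a synchronous
multifocal bladder-tumour study: one normal-mucosa sample plus several
tumour samples, a random reference genome, and a multi-sample VCF whose
markers fall into planted sharing classes:

* germline markers carried by every sample,
* clonal-model "trunk" markers carried by all tumours (optionally leaked
  into the normal sample to emulate neoplastic contamination),
* per-tumour private markers,
* small "other" classes (partial sharing) acting as homoplasy/noise.

Each marker is planted on a genome site whose strand-collapsed dinucleotide
context is TpC* or non-TpC* according to a per-class fraction, so the
APOBEC-style trunk enrichment is a controlled truth.  Functional impact is
planted per class as snpEff-style ANN strings.  Sequencing noise is
expressed at the call level only (supporting-read depth, genotype dropout,
site-filter failures); no reads are simulated.

Under the field-effect model the tumours share no somatic markers
(``n_trunk`` must be 0): each focus carries only its own private set on top
of the germline.

One seed drives a single generator stream, so every artifact is
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .sharing import classify_marker
from .variant_matrix import NORMAL, TUMOUR, BinaryMarkerMatrix, Marker

_BASES = np.array(["A", "C", "G", "T"])

CLONAL = "clonal"
FIELD = "field"

# planted class labels
GERMLINE = "germline"
TRUNK = "trunk"
PRIVATE = "private"
OTHER_NORMAL = "other_normal"
OTHER_TUMOUR = "other_tumour"
NORMAL_PRIVATE = "normal_private"


@dataclass(frozen=True)
class SimConfig:
    """All generator knobs.  Defaults follow the scale of a well-behaved
    patient: ~900 germline markers, a 450-marker trunk, 40/25/15 private
    markers, and TpC* fractions of 0.10 (germline) / 0.60 (trunk) / 0.20
    (private)."""

    model: str = CLONAL
    seed: int = 0
    contig_lengths: tuple[int, ...] = (100_000, 50_000)
    gc: float = 0.41
    n_tumours: int = 3
    n_germline: int = 900
    n_trunk: int = 450
    n_private: tuple[int, ...] = (40, 25, 15)
    n_other_normal: int = 10
    n_other_tumour: int = 12
    n_normal_private: int = 3
    tpc_germline: float = 0.10
    tpc_trunk: float = 0.60
    tpc_private: float = 0.20
    tpc_other: float = 0.15
    functional_germline: float = 0.20
    functional_trunk: float = 0.40
    functional_private: float = 0.40
    functional_other: float = 0.30
    contamination: float = 0.0  # per-trunk-marker leak probability into normal
    depth_mean: float = 50.0
    dropout: float = 0.0  # per (marker, sample) chance of <4 supporting reads
    missing_rate: float = 0.0  # per (marker, sample) chance of ./. genotype
    fail_filter_rate: float = 0.0  # per-marker chance of FILTER=LowQual
    known_fraction: float = 0.0  # fraction of germline markers put in known-sites VCF
    unannotated_rate: float = 0.05  # non-functional markers with no ANN at all
    min_reads: int = 4
    bootstrap_reps: int = 1000

    def __post_init__(self):
        if self.model not in (CLONAL, FIELD):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model == FIELD and self.n_trunk > 0:
            raise ValueError("field model is inconsistent with n_trunk > 0")
        if self.model == CLONAL and self.n_trunk <= 0:
            raise ValueError("clonal model requires n_trunk > 0")
        if len(self.n_private) != self.n_tumours:
            raise ValueError("n_private must give one count per tumour sample")
        if self.n_tumours < 2:
            raise ValueError("need at least two tumour samples")
        if self.n_tumours < 3 and self.n_other_tumour > 0:
            raise ValueError("other_tumour class needs at least three tumours")
        for name in ("tpc_germline", "tpc_trunk", "tpc_private", "tpc_other",
                     "functional_germline", "functional_trunk",
                     "functional_private", "functional_other",
                     "contamination", "dropout", "missing_rate",
                     "fail_filter_rate", "known_fraction", "gc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def sample_names(self) -> list[str]:
        if self.n_tumours == 3:
            tumours = ["T1A", "T1B", "T2B"]
        else:
            tumours = [f"T{i + 1}" for i in range(self.n_tumours)]
        return ["N"] + tumours

    @property
    def roles(self) -> dict[str, str]:
        names = self.sample_names
        return {names[0]: NORMAL, **{t: TUMOUR for t in names[1:]}}

    @classmethod
    def field_default(cls, seed: int = 0, **overrides) -> "SimConfig":
        """Field-effect counterpart of the default patient: no trunk, each
        focus carrying its own full somatic load instead."""
        kwargs = dict(
            model=FIELD, seed=seed, n_trunk=0, n_private=(490, 475, 465)
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_genome(config: SimConfig, rng: np.random.Generator) -> dict[str, str]:
    """Random reference contigs at the configured GC fraction."""
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    genome = {}
    for i, length in enumerate(config.contig_lengths, start=1):
        genome[f"chr{i}"] = "".join(rng.choice(_BASES, size=length, p=p))
    return genome


def _site_pools(genome: dict[str, str]) -> tuple[list, list]:
    """Internal genome sites split by strand-collapsed TpC* context.

    A site is TpC* when its plus-strand base is C preceded by T, or G
    followed by A (the minus-strand reading of the same motif).
    """
    tpc, non_tpc = [], []
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        base, prev_, next_ = arr[1:-1], arr[:-2], arr[2:]
        is_tpc = ((base == b"C") & (prev_ == b"T")) | ((base == b"G") & (next_ == b"A"))
        pos = np.arange(2, len(seq))  # 1-based internal positions
        tpc.extend((chrom, int(p)) for p in pos[is_tpc])
        non_tpc.extend((chrom, int(p)) for p in pos[~is_tpc])
    return tpc, non_tpc


@dataclass
class TruthMarker:
    chrom: str
    pos: int
    ref: str
    alt: str
    planted_class: str
    private_sample: Optional[str]
    tpc: bool
    functional: bool
    gene: Optional[str]
    effect: Optional[str]
    impact: Optional[str]
    genotype: tuple[int, ...]  # realized carrier bits, samples in config order
    het: tuple[bool, ...]
    support: tuple[int, ...]  # reads supporting the called allele, per sample
    ref_reads: tuple[int, ...]
    missing: tuple[bool, ...]
    fail_filter: bool
    in_known: bool

    def expected_kept(self, min_reads: int = 4) -> bool:
        """Will this marker survive the high-confidence + known-site filters?"""
        return (
            not self.fail_filter
            and not any(self.missing)
            and all(s >= min_reads for s in self.support)
            and not self.in_known
        )

    @property
    def ann(self) -> Optional[str]:
        if self.effect is None:
            return None
        return (
            f"{self.alt}|{self.effect}|{self.impact}|{self.gene}|{self.gene}"
            f"|transcript|{self.gene}.t1|protein_coding|1/1|c.1A>G|p.Lys1Glu||||||"
        )


@dataclass
class PatientTruth:
    config: SimConfig
    genome: dict[str, str] = field(repr=False)
    markers: list[TruthMarker] = field(repr=False)

    @property
    def samples(self) -> list[str]:
        return self.config.sample_names

    @property
    def roles(self) -> dict[str, str]:
        return self.config.roles

    def truth_matrix(self, kept_only: bool = True) -> BinaryMarkerMatrix:
        """Binary matrix of the planted carrier bits (the filter-surviving
        markers by default), bypassing VCF emission."""
        cols, metas = [], []
        for m in self.markers:
            if kept_only and not m.expected_kept(self.config.min_reads):
                continue
            cols.append(m.genotype)
            metas.append(Marker(m.chrom, m.pos, m.ref, m.alt, m.ann))
        data = (
            np.array(cols, dtype=np.int8).T
            if cols else np.zeros((len(self.samples), 0), dtype=np.int8)
        )
        return BinaryMarkerMatrix(self.samples, self.roles, data, metas)

    def expected_sharing(self, marker: TruthMarker):
        """Sharing-class assignment implied by the realized carrier bits."""
        return classify_marker(marker.genotype, self.samples, self.roles)


def simulate_patient(config: SimConfig) -> PatientTruth:
    """Generate genome + planted marker truth for one patient."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    tpc_pool, non_tpc_pool = _site_pools(genome)

    samples = config.sample_names
    normal_i, tumour_idx = 0, list(range(1, len(samples)))
    T = config.n_tumours

    # (class label, private tumour index or None, count, tpc frac, functional frac)
    plan = [(GERMLINE, None, config.n_germline, config.tpc_germline, config.functional_germline)]
    if config.n_trunk:
        plan.append((TRUNK, None, config.n_trunk, config.tpc_trunk, config.functional_trunk))
    for t, n in enumerate(config.n_private):
        plan.append((PRIVATE, t, n, config.tpc_private, config.functional_private))
    plan.append((OTHER_NORMAL, None, config.n_other_normal, config.tpc_other, config.functional_other))
    plan.append((OTHER_TUMOUR, None, config.n_other_tumour, config.tpc_other, config.functional_other))
    plan.append((NORMAL_PRIVATE, None, config.n_normal_private, config.tpc_other, config.functional_other))

    tpc_counts = [int(rng.binomial(n, f)) if n else 0 for (_, _, n, f, _) in plan]
    need_tpc, need_non = sum(tpc_counts), sum(n for (_, _, n, _, _) in plan) - sum(tpc_counts)
    if need_tpc > len(tpc_pool) or need_non > len(non_tpc_pool):
        raise ValueError(
            f"genome too short for requested placements: need {need_tpc} TpC* "
            f"sites (have {len(tpc_pool)}) and {need_non} other sites "
            f"(have {len(non_tpc_pool)}); increase contig_lengths"
        )
    tpc_sites = [tpc_pool[i] for i in rng.choice(len(tpc_pool), size=need_tpc, replace=False)]
    non_sites = [non_tpc_pool[i] for i in rng.choice(len(non_tpc_pool), size=need_non, replace=False)]

    markers: list[TruthMarker] = []
    gene_serial = 0
    ti, ni = 0, 0
    for (cls, priv_t, n, _, func_frac), n_tpc in zip(plan, tpc_counts):
        for k in range(n):
            is_tpc = k < n_tpc
            if is_tpc:
                chrom, pos = tpc_sites[ti]
                ti += 1
            else:
                chrom, pos = non_sites[ni]
                ni += 1
            ref = genome[chrom][pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))

            bits = np.zeros(len(samples), dtype=np.int8)
            if cls == GERMLINE:
                bits[:] = 1
            elif cls == TRUNK:
                bits[tumour_idx] = 1
                if rng.random() < config.contamination:
                    bits[normal_i] = 1
            elif cls == PRIVATE:
                bits[1 + priv_t] = 1
            elif cls == OTHER_NORMAL:
                bits[normal_i] = 1
                k_t = int(rng.integers(1, T))  # 1 .. T-1 tumours
                bits[rng.choice(tumour_idx, size=k_t, replace=False)] = 1
            elif cls == OTHER_TUMOUR:
                k_t = int(rng.integers(2, T))  # 2 .. T-1 tumours
                bits[rng.choice(tumour_idx, size=k_t, replace=False)] = 1
            else:  # NORMAL_PRIVATE
                bits[normal_i] = 1

            functional = bool(rng.random() < func_frac)
            gene_serial += 1
            gene = f"GENE{gene_serial:04d}"
            if functional:
                effect, impact = [
                    ("missense_variant", "MODERATE"),
                    ("stop_gained", "HIGH"),
                    ("splice_region_variant", "LOW"),
                ][int(rng.choice(3, p=[0.8, 0.1, 0.1]))]
            elif rng.random() < config.unannotated_rate:
                effect = impact = gene = None
            else:
                effect, impact = "intergenic_region", "MODIFIER"

            het = tuple(bool(b) and rng.random() < 0.8 for b in bits)
            support, ref_reads, missing = [], [], []
            for s in range(len(samples)):
                sup = max(config.min_reads, int(rng.poisson(config.depth_mean)))
                if rng.random() < config.dropout:
                    sup = int(rng.integers(0, config.min_reads))
                support.append(sup)
                if bits[s]:
                    ref_reads.append(
                        int(rng.poisson(config.depth_mean / 2)) if het[s]
                        else int(rng.integers(0, 2))
                    )
                else:
                    ref_reads.append(sup)
                missing.append(bool(rng.random() < config.missing_rate))
            fail = bool(rng.random() < config.fail_filter_rate)
            in_known = cls == GERMLINE and bool(rng.random() < config.known_fraction)

            markers.append(
                TruthMarker(
                    chrom, pos, ref, alt, cls,
                    samples[1 + priv_t] if priv_t is not None else None,
                    is_tpc, functional, gene, effect, impact,
                    tuple(int(b) for b in bits), het,
                    tuple(support), tuple(ref_reads), tuple(missing),
                    fail, in_known,
                )
            )

    markers.sort(key=lambda m: (m.chrom, m.pos))
    return PatientTruth(config, genome, markers)


# ---------------------------------------------------------------------------
# emission

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=clonetrace-simulate
{contigs}
##FILTER=<ID=LowQual,Description="Simulated site-filter failure">
##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: 'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p | cDNA.pos / cDNA.length | CDS.pos / CDS.length | AA.pos / AA.length | Distance | ERRORS / WARNINGS / INFO'">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


@dataclass
class SimOutput:
    genome_fasta: Path
    calls_vcf: Path
    known_vcf: Path
    truth_tsv: Path
    config_json: Path


def _sample_field(m: TruthMarker, s: int) -> str:
    if m.missing[s]:
        return "./.:.:."
    if m.genotype[s]:
        gt = "0/1" if m.het[s] else "1/1"
        ad = f"{m.ref_reads[s]},{m.support[s]}"
        dp = m.ref_reads[s] + m.support[s]
    else:
        gt = "0/0"
        ad = f"{m.support[s]},0"
        dp = m.support[s]
    return f"{gt}:{ad}:{dp}"


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def emit_vcf(truth: PatientTruth, outdir) -> SimOutput:
    """Write genome.fa, calls.vcf, known.vcf, truth.tsv and config.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = SimOutput(
        outdir / "genome.fa", outdir / "calls.vcf", outdir / "known.vcf",
        outdir / "truth.tsv", outdir / "config.json",
    )
    write_fasta(truth.genome, out.genome_fasta)

    contigs = "\n".join(
        f"##contig=<ID=chr{i + 1},length={L}>"
        for i, L in enumerate(truth.config.contig_lengths)
    )
    header = _VCF_HEADER.format(contigs=contigs, samples="\t".join(truth.samples))

    with open(out.calls_vcf, "w") as fh:
        fh.write(header)
        for m in truth.markers:
            info = f"ANN={m.ann}" if m.ann else "."
            flt = "LowQual" if m.fail_filter else "PASS"
            cells = "\t".join(_sample_field(m, s) for s in range(len(truth.samples)))
            fh.write(
                f"{m.chrom}\t{m.pos}\t.\t{m.ref}\t{m.alt}\t100\t{flt}\t{info}"
                f"\tGT:AD:DP\t{cells}\n"
            )

    with open(out.known_vcf, "w") as fh:
        fh.write(
            "##fileformat=VCFv4.2\n##source=clonetrace-simulate-known\n"
            + contigs + "\n"
            + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        for m in truth.markers:
            if m.in_known:
                fh.write(f"{m.chrom}\t{m.pos}\t.\t{m.ref}\t{m.alt}\t.\tPASS\t.\n")

    truth_frame(truth).to_csv(out.truth_tsv, sep="\t", index=False)
    truth.config.to_json(out.config_json)
    return out


def truth_frame(truth: PatientTruth):
    import pandas as pd

    rows = []
    for m in truth.markers:
        rows.append(
            {
                "chrom": m.chrom,
                "pos": m.pos,
                "ref": m.ref,
                "alt": m.alt,
                "planted_class": m.planted_class,
                "private_sample": m.private_sample or "",
                "tpc": m.tpc,
                "functional": m.functional,
                "gene": m.gene or "",
                "fail_filter": m.fail_filter,
                "in_known": m.in_known,
                "n_missing": sum(m.missing),
                "min_support": min(m.support),
                "expected_kept": m.expected_kept(truth.config.min_reads),
                **{f"gt_{s}": g for s, g in zip(truth.samples, m.genotype)},
            }
        )
    return pd.DataFrame(rows)


def simulate_to_dir(config: SimConfig, outdir) -> tuple[PatientTruth, SimOutput]:
    truth = simulate_patient(config)
    return truth, emit_vcf(truth, outdir)
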