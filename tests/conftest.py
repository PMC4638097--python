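import textwrap
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from clonetrace import SimConfig, simulate_patient, simulate_to_dir

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


VCF_TEMPLATE = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr1,length=1000000>
    ##contig=<ID=chr2,length=1000000>
    ##FILTER=<ID=LowQual,Description="fail">
    ##INFO=<ID=ANN,Number=.,Type=String,Description="ann">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
    ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="ad">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="dp">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
    """
)


def make_vcf(path: Path, rows: list[str], samples=("N", "T1", "T2", "T3")) -> Path:
    """Write a small VCF from raw data lines (tab-separated strings)."""
    path.write_text(VCF_TEMPLATE.format(samples="\t".join(samples)) + "".join(r + "\n" for r in rows))
    return path


@pytest.fixture
def vcf_factory(tmp_path):
    def _make(rows, samples=("N", "T1", "T2", "T3"), name="test.vcf"):
        return make_vcf(tmp_path / name, rows, samples)

    return _make


ROLES4 = {"N": "normal", "T1": "tumour", "T2": "tumour", "T3": "tumour"}


@pytest.fixture(scope="session")
def default_truth():
    """Default clonal patient, zero noise (session-shared; treat as read-only)."""
    return simulate_patient(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_sim_dir(tmp_path_factory, default_truth):
    """Emitted artifacts (genome.fa, calls.vcf, ...) for the default patient."""
    outdir = tmp_path_factory.mktemp("sim_default")
    from clonetrace.simulate import emit_vcf

    return default_truth, emit_vcf(default_truth, outdir)


@pytest.fixture(scope="session")
def noisy_sim_dir(tmp_path_factory):
    """Patient with call-level noise: low-depth, missing, failed-filter, known sites."""
    cfg = SimConfig(
        seed=2, dropout=0.01, missing_rate=0.005, fail_filter_rate=0.01,
        known_fraction=0.10,
    )
    outdir = tmp_path_factory.mktemp("sim_noisy")
    return simulate_to_dir(cfg, outdir)
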