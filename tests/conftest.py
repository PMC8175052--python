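import numpy as np
import pytest

from gbgc import polarize as pol
from gbgc import simulate as sim


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    """Hand-built 5-record VCF with reference FASTA and repeat/exon BEDs."""
    return sim.write_toy_fixture(tmp_path_factory.mktemp("toy"))


@pytest.fixture(scope="session")
def small_dataset():
    """10 kb single-contig dataset with single-individual outgroups."""
    cfg = sim.SimulationConfig(genome_length=10_000, n_contigs=1, window_size=500,
                               target_snps=150, repeat_fraction=0.05,
                               outgroup_sizes=(1, 1))
    return sim.simulate_sites(cfg, sim.make_genome(cfg, 101), 102)


@pytest.fixture(scope="session")
def pipeline_data(tmp_path_factory):
    """Default-scale error-free dataset written to disk (the closure fixture)."""
    cfg = sim.SimulationConfig()
    ds = sim.simulate_sites(cfg, sim.make_genome(cfg, 11), 12)
    paths = sim.write_dataset(tmp_path_factory.mktemp("pipe"), ds)
    return ds, paths


@pytest.fixture(scope="session")
def polarized_pipeline(pipeline_data):
    """The closure dataset run through the real readers and polarization."""
    ds, paths = pipeline_data
    records = pol.load_variants(paths["vcf"], ds.ingroup, ds.outgroups)
    rep = pol.read_bed(paths["repeats"])
    ex = pol.read_bed(paths["exons"])
    kept = pol.filter_variants(records, rep, ex)
    sites, rejections = pol.polarize_all(kept, "strict")
    genome = pol.build_ancestral_genome(paths["reference"], sites, rep, ex)
    return {"ds": ds, "paths": paths, "sites": sites, "rejections": rejections,
            "genome": genome, "repeats": rep, "exons": ex}


def make_variant(ref="G", alt="A", ing_alt=17, n=20, out_gts=None,
                 chrom="chr1", pos=100, alts=None, missing=0):
    """Hand-built VariantRecord for polarization unit tests."""
    return pol.VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=alts or (alt,), n_ingroup=n,
        ingroup_alt=ing_alt, ingroup_missing=missing,
        outgroup_gts=out_gts if out_gts is not None
        else {"og1": [(1, 1)], "og2": [(1, 1)]})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
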