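import pytest

from grannot import pipeline as pl
from grannot import synthetic_data as sd


@pytest.fixture(scope="session")
def small_spec() -> sd.RepertoireSpec:
    """A scaled-down repertoire: 41 genes, one implanted type3 array."""
    return sd.RepertoireSpec(
        n_co2=2, n_sugar=3, n_gr43a_like=2,
        n_type1=5, n_type2=9, n_type3=20,
        n_pseudogenes=2, n_partial=3,
        arrays=(sd.ArraySpec("type3", 10),),
    )


@pytest.fixture(scope="session")
def small_repertoire(small_spec):
    return sd.generate_repertoire_genome(small_spec, seed=7)


@pytest.fixture(scope="session")
def repertoire_dir(small_repertoire, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("repertoire")
    paths = small_repertoire.write(outdir)
    return paths


@pytest.fixture(scope="session")
def pipeline_run(repertoire_dir, tmp_path_factory):
    """One full pipeline run on the small synthetic repertoire."""
    outdir = tmp_path_factory.mktemp("run")
    config = pl.PipelineConfig(
        genome=str(repertoire_dir["genome"]),
        gff3=str(repertoire_dir["gff3"]),
        anchors_fasta=str(repertoire_dir["anchors"]),
        anchors_map=str(repertoire_dir["anchor_map"]),
        outdir=str(outdir),
        seed=1,
    )
    return pl.run_pipeline(config)
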