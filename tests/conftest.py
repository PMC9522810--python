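import numpy as np
import pysam
import pytest

from ironspot import regions as rg, scoring as sc, simulate as sim
from ironspot.cli import collect_training_windows
from ironspot.detect import load_af_table


@pytest.fixture(scope="session")
def planted_scene(tmp_path_factory):
    """A small planted scene shared by read-level tests: 6 genes (both
    strands), one essential-site IRAV per gene, depth 50, 0.1% errors."""
    cfg = sim.make_recovery_config(n_genes=6, n_plants=6, seed=11)
    return sim.simulate_scene(cfg, str(tmp_path_factory.mktemp("scene")))


@pytest.fixture(scope="session")
def clean_scene(tmp_path_factory):
    """Error-free planted scene for exact-count assertions."""
    cfg = sim.make_recovery_config(n_genes=5, n_plants=5, seed=23, error_rate=0.0)
    return sim.simulate_scene(cfg, str(tmp_path_factory.mktemp("clean")))


@pytest.fixture(scope="session")
def scene_genome(planted_scene):
    with pysam.FastaFile(planted_scene.reference) as fa:
        yield fa


@pytest.fixture(scope="session")
def scene_models(planted_scene, scene_genome):
    """Donor/acceptor motif models trained on the scene's own annotation."""
    donor = sc.train_model(
        collect_training_windows(planted_scene.models, scene_genome, rg.DONOR), rg.DONOR
    )
    acceptor = sc.train_model(
        collect_training_windows(planted_scene.models, scene_genome, rg.ACCEPTOR),
        rg.ACCEPTOR,
    )
    return donor, acceptor


@pytest.fixture(scope="session")
def scene_af(planted_scene):
    return load_af_table(planted_scene.af_table)


@pytest.fixture()
def two_exon_plus():
    return rg.TranscriptModel(
        transcript_id="TXP", gene_symbol="GP", chrom="chr1", strand="+",
        exons=((100, 200), (300, 400)), cds_start=120, cds_end=380,
    )


@pytest.fixture()
def two_exon_minus():
    return rg.TranscriptModel(
        transcript_id="TXM", gene_symbol="GM", chrom="chr1", strand="-",
        exons=((100, 200), (300, 400)), cds_start=120, cds_end=380,
    )
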