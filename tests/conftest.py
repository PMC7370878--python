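import warnings

import pytest

from regudyn.models import TranscriptModel, TranscriptModelSet
from regudyn.synth import SyntheticConfig, generate_dataset


def make_transcript(tid, gid, chrom, strand, exons):
    return TranscriptModel(
        transcript_id=tid, gene_id=gid, chrom=chrom, strand=strand, exons=exons
    )


def make_set(transcripts):
    s = TranscriptModelSet()
    for t in transcripts:
        s.add(t)
    return s


@pytest.fixture(scope="session")
def noise_free_dataset(tmp_path_factory):
    """A small noise-free dataset with the default cis-logic mix."""
    out = tmp_path_factory.mktemp("ds0")
    config = SyntheticConfig(n_genes=150, seed=1, noise_sd=0.0)
    generate_dataset(config, out)
    return config, out


@pytest.fixture(scope="session")
def noise_free_pipeline(noise_free_dataset, tmp_path_factory):
    """Pipeline run over the noise-free dataset (reduced null repeats)."""
    from regudyn.pipeline import PipelineConfig, run_pipeline

    config, ds = noise_free_dataset
    out = tmp_path_factory.mktemp("out0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_pipeline(
            PipelineConfig(
                input_dir=str(ds), output_dir=str(out), seed=1,
                thresholds={"null_repeats": 30},
            )
        )
    return config, ds, out, report
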