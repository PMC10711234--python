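"""Shared fixtures: one synthetic study and one full pipeline run per session."""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import pytest

from rsrnakit import pipeline
from rsrnakit.config import PipelineConfig
from rsrnakit.simulate import (
    FixtureSpec,
    FixtureReference,
    FixtureTruth,
    generate_reference,
    simulate_reads,
    write_fastq,
    write_feature_table,
    write_genome_fasta,
    write_sam,
)


@pytest.fixture(scope="session")
def default_spec() -> FixtureSpec:
    return FixtureSpec(seed=42)


@pytest.fixture(scope="session")
def fixture_ref(default_spec) -> FixtureReference:
    return generate_reference(default_spec)


@pytest.fixture(scope="session")
def fixture_truth(default_spec, fixture_ref) -> FixtureTruth:
    return simulate_reads(default_spec, fixture_ref)


@dataclass
class Workspace:
    """One materialized synthetic data set plus a completed pipeline run."""

    root: Path
    config: PipelineConfig
    spec: FixtureSpec
    ref: FixtureReference
    truth: FixtureTruth
    run: pipeline.RunReport
    elapsed_s: float
    sample: str = "sample1"

    @property
    def bundle(self):
        return self.run.bundles[self.sample]


def materialize(spec: FixtureSpec, root: Path, sample: str = "sample1") -> Workspace:
    """Write the fixture files, run the pipeline once, time it."""
    data = root / "data"
    (data / "aln").mkdir(parents=True)
    ref = generate_reference(spec)
    truth = simulate_reads(spec, ref)
    write_genome_fasta(ref, data / "genome.fa")
    write_feature_table(ref, data / "feature_table.txt")
    write_fastq(truth, data / f"{sample}.fastq")
    write_sam(truth, ref, data / "aln" / f"{sample}.sam")
    config = PipelineConfig(
        genome_fasta=data / "genome.fa",
        species_ncbi_feature_table=data / "feature_table.txt",
        trimmed_dir=data,
        alignment_dir=data / "aln",
        output_dir=root / "out",
    )
    t0 = time.monotonic()
    run = pipeline.run_pipeline(config)
    elapsed = time.monotonic() - t0
    assert run.ok, f"pipeline failed: {run.failures}"
    return Workspace(
        root=root,
        config=config,
        spec=spec,
        ref=ref,
        truth=truth,
        run=run,
        elapsed_s=elapsed,
        sample=sample,
    )


@pytest.fixture(scope="session")
def workspace(default_spec, tmp_path_factory) -> Workspace:
    """Full pipeline run on the error-free 5,000-read study."""
    return materialize(default_spec, tmp_path_factory.mktemp("ws_clean"))
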