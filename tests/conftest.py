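"""Shared fixtures: one synthetic data set + cache per test session."""

from __future__ import annotations

import pytest

from conseq.cache import build_cache
from conseq.fixtures import FixtureSpec, make_fixture, make_random_vcf
from conseq.pipeline import AnnotateConfig, run_annotation
from conseq.store import AnnotationStore
from conseq.variants import WarningsLog, read_vcf

FIXTURE_SEED = 1


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    make_fixture(FixtureSpec(seed=FIXTURE_SEED), out)
    return out


@pytest.fixture(scope="session")
def cache_dir(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("cache")
    build_cache(
        fixture_dir / "transcripts.gff3", fixture_dir / "genome.fa", out,
        regulatory=fixture_dir / "regulatory.gff3",
        motifs=fixture_dir / "motifs.jaspar",
        known_variants=fixture_dir / "known.vcf",
        selenocysteine=fixture_dir / "selenocysteine.tsv",
        species="synthetic",
    )
    return out


@pytest.fixture(scope="session")
def store(cache_dir):
    return AnnotationStore(cache_dir)


@pytest.fixture(scope="session")
def fixture_variants(fixture_dir):
    """Curated fixture variants, keyed by id."""
    variants = read_vcf(fixture_dir / "variants.vcf", WarningsLog())
    return {v.id: v for v in variants}


@pytest.fixture(scope="session")
def truth_rows(fixture_dir):
    """(variant_id, allele, feature_id) -> set of expected terms."""
    rows = {}
    with open(fixture_dir / "truth.tsv") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            vid, chrom, start, end, ref, alt, feat, terms = (
                line.rstrip("\n").split("\t"))
            rows[(vid, alt, feat)] = set(terms.split(","))
    return rows


@pytest.fixture(scope="session")
def big_vcf(fixture_dir, tmp_path_factory):
    """12,000 random SNVs over the fixture genome."""
    path = tmp_path_factory.mktemp("big") / "big.vcf"
    make_random_vcf(fixture_dir, path, 12000, seed=77)
    return path


@pytest.fixture(scope="session")
def big_runs(big_vcf, cache_dir, tmp_path_factory):
    """The 12k-variant fixture annotated with 1 and with 4 workers.

    Returns (bytes of 1-worker output, bytes of 4-worker output,
    buffer sizes of the 1-worker run).
    """
    out = tmp_path_factory.mktemp("bigout")
    outputs = {}
    buffer_sizes = None
    for workers in (1, 4):
        path = out / f"w{workers}.tab"
        rr = run_annotation(AnnotateConfig(
            input=str(big_vcf), cache=str(cache_dir), output=str(path),
            workers=workers))
        assert rr.exit_status == 0
        outputs[workers] = path.read_bytes()
        if workers == 1:
            buffer_sizes = rr.buffer_sizes
    return outputs[1], outputs[4], buffer_sizes
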