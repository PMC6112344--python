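from __future__ import annotations

from pathlib import Path

import pytest

from srna_profiler.fixtures import Fixture, FixtureSpec, generate
from srna_profiler.report import RunConfig, run_pipeline


def make_fixture_with_mods(
    out_dir: Path,
    seed: int,
    mod_targets: list[tuple[str, int, float]],
    **spec_kwargs,
) -> Fixture:
    """Generate a fixture with modification sites at (ref_id, pos, fraction).

    Reference sequences depend only on the seed (they are drawn before the
    reads), so a probe run discovers the reference base at each target and
    an alternate base is chosen before the real generation.
    """
    probe = generate(FixtureSpec(seed=seed, **spec_kwargs), out_dir / "probe")
    seq_by_id = {
        ref_id: seq
        for entries in probe.references.values()
        for ref_id, seq in entries
    }
    sites = []
    for ref_id, pos, frac in mod_targets:
        ref_base = seq_by_id[ref_id][pos - 1]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
        sites.append((ref_id, pos, alt, frac))
    spec = FixtureSpec(seed=seed, modification_sites=tuple(sites), **spec_kwargs)
    return generate(spec, out_dir / "study")


@pytest.fixture(scope="session")
def study(tmp_path_factory) -> Fixture:
    """The main toy study: error-free reads, two planted rRNA modification
    sites covered by >= 50 reads each, half the rRNA precursors left out of
    the genome."""
    out = tmp_path_factory.mktemp("study")
    return make_fixture_with_mods(
        out,
        seed=11,
        mod_targets=[("18S_rRNA_toy_2", 60, 0.3), ("28S_rRNA_toy_3", 80, 0.3)],
        reads_per_source=300,
        n_rrna=6,
        umg_rrna_fraction=0.5,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def study_out(study, tmp_path_factory) -> Path:
    out = tmp_path_factory.mktemp("pipeline") / "out"
    config = RunConfig(
        input_path=str(study.fastq),
        bundle_path=str(study.bundle_manifest),
        out_dir=str(out),
        max_mismatch=1,
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def read_sequences(study) -> dict[str, str]:
    """read_id -> sequence, straight from the generated FASTQ."""
    lines = study.fastq.read_text().splitlines()
    return {lines[i][1:]: lines[i + 1] for i in range(0, len(lines), 4)}
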