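"""Shared fixtures: hand-built SAM files and small simulated datasets."""

from __future__ import annotations

import random

import pytest

from circjunction import SimConfig, run_simulation

SAM_REF = "chr1"
SAM_REF_LEN = 1_000_000


def sam_text(rows: list[dict]) -> str:
    """Render SAM records from keyword dicts (defaults for optional fields)."""
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{SAM_REF}\tLN:{SAM_REF_LEN}",
        "@SQ\tSN:chr2\tLN:100000",
    ]
    for r in rows:
        seq = r.get("seq", "A" * 100)
        lines.append("\t".join(map(str, [
            r["qname"], r.get("flag", 0x1 | 0x40), r.get("rname", SAM_REF),
            r["pos"], r.get("mapq", 60), r["cigar"],
            r.get("rnext", "="), r.get("pnext", r["pos"]), r.get("tlen", 0),
            seq, r.get("qual", "I" * len(seq) if seq != "*" else "*"),
        ])))
    return "\n".join(lines) + "\n"


@pytest.fixture
def write_sam(tmp_path):
    def _write(rows: list[dict], name: str = "test.sam") -> str:
        path = tmp_path / name
        path.write_text(sam_text(rows))
        return str(path)
    return _write


def random_seq(n: int, seed: int = 0) -> str:
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small noiseless simulated dataset shared by slower tests."""
    outdir = tmp_path_factory.mktemp("sim")
    config = SimConfig(
        genome_length=120_000, n_genes=12, n_circ=8,
        depth_circ=15, depth_linear=10, error_rate=0.0, seed=11,
    )
    return run_simulation(config, str(outdir))
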