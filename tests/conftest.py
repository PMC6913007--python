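"""Shared fixtures: all data is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from tekit.filters import RemovalLog, run_stage0, run_stage1
from tekit.model import Genome, LibraryEntry, TEClass
from tekit.simulate import (
    SimulationConfig,
    make_exemplars,
    make_noisy_candidates,
    simulate_genome,
)


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    codes = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)
    return codes.tobytes().decode()


def mutate_positions(seq: str, positions: list[int]) -> str:
    """Substitute a different base at each given position."""
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for i in positions:
        out[i] = rot[out[i]]
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def entry_factory():
    def make(name: str, sequence: str, class_name: str = "TIR",
             subclass: str | None = None, **meta) -> LibraryEntry:
        return LibraryEntry(name, TEClass(class_name, subclass=subclass),
                            sequence, structural_meta=meta)
    return make


# ---------------------------------------------------------------------------
# shared simulations (session scope: built once, reused by several tests)


@pytest.fixture(scope="session")
def roundtrip_sim():
    """The reference round-trip condition: 500-kb chromosome, 5 families
    per class, 10% divergence."""
    cfg = SimulationConfig(seed=42)
    exemplars = make_exemplars(cfg)
    genome, truth = simulate_genome(exemplars, cfg)
    return cfg, exemplars, genome, truth


@pytest.fixture(scope="session")
def corruption_config():
    """Corrupted-candidate condition: 300-kb chromosome with >= 10 planted
    candidates of each corruption type."""
    return SimulationConfig(
        seed=7, chrom_length=300_000,
        corruption={"tandem": 10, "short": 10, "mislabel": 10,
                    "bad_helitron": 10, "boundary_shift": 5,
                    "nested_span": 5})


@pytest.fixture(scope="session")
def corruption_sim(corruption_config):
    cfg = corruption_config
    exemplars = make_exemplars(cfg)
    genome, truth = simulate_genome(exemplars, cfg)
    candidates = make_noisy_candidates(genome, truth, cfg)
    return cfg, exemplars, genome, truth, candidates


@pytest.fixture(scope="session")
def cascade_result(corruption_sim):
    """Stage-0 and stage-1 libraries from the corrupted candidate set."""
    _, exemplars, genome, truth, candidates = corruption_sim
    by_class: dict[str, list] = {"LTR": [], "TIR": [], "Helitron": []}
    for c in candidates:
        cls = c.entry.te_class.class_name
        if cls in by_class:
            by_class[cls].append(c)
    log: RemovalLog = []
    stage0 = run_stage0(by_class, genome, None, log)
    stage1 = run_stage1(stage0, genome, None, None, log)
    return stage0, stage1, log
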