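from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fusionneo import default_plan, make_toy_annotation, plant_fusions


@pytest.fixture(scope="session")
def toy_world():
    """Deterministic toy genome + annotation (seed 1)."""
    genome, annotation = make_toy_annotation(1)
    return genome, annotation


@pytest.fixture(scope="session")
def planted(toy_world):
    """Seed-1 planted fixture: candidates, contigs, and the truth manifest."""
    _, annotation = toy_world
    candidates, contigs, manifest = plant_fusions(annotation, default_plan(), 1)
    return annotation, candidates, contigs, manifest
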