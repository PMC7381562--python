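"""Shared fixtures: published study inputs and small synthetic bundles."""

from __future__ import annotations

import pandas as pd
import pytest

from ribarriers.pollinators import VisitationTable

# Observed pollinator visits per morphospecies (white-sand, brown-sand),
# pooled across trees; antagonistic episodes excluded.
VISITS_WHITE_SAND = (22, 6, 9, 0, 0, 0, 0, 0, 2, 0, 0, 0, 0, 0, 1)
VISITS_BROWN_SAND = (4, 4, 84, 2, 9, 10, 7, 1, 34, 10, 2, 8, 1, 1, 0)

# Published per-barrier strengths (white-sand, brown-sand); None = unmeasured.
BARRIER_VALUES = {
    "ecogeography": (0.83, 0.45),
    "phenology": (-0.23, 0.69),
    "pollinator_assemblage": (0.82, 0.82),
    "pollen_adhesion": (None, 0.18),
    "pollen_germination": (None, 0.02),
    "seed_development": (None, 0.40),
}

# Habitat pixel counts: model-only suitable (white, brown, both) and the
# buffer-reclassified totals.
PIXELS_MODEL = {"white_only": 2690, "brown_only": 627, "shared": 96}
PIXELS_FINAL = {"white_only": 2485, "brown_only": 424, "shared": 504}
PIXELS_BUFFER_RECLASSIFIED = 408


@pytest.fixture
def visitation_table() -> VisitationTable:
    df = pd.DataFrame(
        {"white_sand": VISITS_WHITE_SAND, "brown_sand": VISITS_BROWN_SAND},
        index=pd.Index([f"sp{i}" for i in range(len(VISITS_WHITE_SAND))], name="morphospecies"),
    )
    return VisitationTable(df)
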