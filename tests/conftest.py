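import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from toxscore.dge import run_dge
from toxscore.enrichment import BackgroundSpec, build_universe, enrich_overlap
from toxscore.pb_score import fit_score
from toxscore.synthetic_data import clinical_frame, generate_small_fixture


class FixtureBundle:
    """One desk-scale synthetic cohort plus the derived pipeline stages,
    shared across test modules (seed 7 throughout)."""

    def __init__(self, seed: int = 7):
        (self.matrix, self.records, self.exposure_set, self.collection, self.truth) = generate_small_fixture(seed=seed)
        self.clinical = clinical_frame(self.records)
        self.dge = run_dge(self.matrix)
        self.universe = build_universe(self.matrix, BackgroundSpec())
        self.enrichment, self.overlap = enrich_overlap(
            self.exposure_set, self.dge.deg_set(), self.universe, dge_frame=self.dge.frame
        )
        self.score_model = fit_score(self.matrix, self.overlap, self.dge)
        self.scores = pd.Series(self.score_model.scores_sd_units, index=self.score_model.barcodes)


@pytest.fixture(scope="session")
def bundle() -> FixtureBundle:
    return FixtureBundle(seed=7)
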