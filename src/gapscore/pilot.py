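"""The published 13-condition pilot score table, as an ingestible example.

The pilot study reported composite scores (public health burden, health care
cost, biomedical product innovation, overall gap) for 13 conditions selected
as the deduplicated union of the top-10 lists by mortality, prevalence, and
YLD.  The raw metric tables behind those composites were not deposited, so
the printed score table is carried here as a worked example for report-only
runs: ranking, tier classification, and opportunity identification on
published domain scores.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .io_config import RunConfig
from .pipeline import PipelineResult, results_from_scores


def load_pilot_scores() -> pd.DataFrame:
    """The pilot score table: condition, three domain scores, overall gap."""
    with files("gapscore.data").joinpath("pilot_scores.csv").open("r") as fh:
        return pd.read_csv(fh)


def rank_pilot(config: RunConfig | None = None) -> PipelineResult:
    """Rank, tier, and flag the pilot conditions from their published scores."""
    return results_from_scores(load_pilot_scores(), config)
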