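"""Model-vs-experiment scorecard: per-scenario proximity profiles against
the ssNMR reference percentages, ranked by aggregate mismatch."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Structure
from .proximity import EXPERIMENTAL_REFERENCE, proximity_profile

__all__ = ["Scorecard", "scorecard"]

_METRIC_ORDER = (
    ("xylan_AcMe", "lignin"),
    ("xylan_AcMe", "cellulose"),
    ("lignin_ring", "xylan"),
    ("lignin_ring", "cellulose"),
)


@dataclass
class Scorecard:
    names: list
    profiles: list          # list of {pair: percent}
    reference: dict
    table: pd.DataFrame = field(default=None)

    def __post_init__(self):
        rows = []
        for name, prof in zip(self.names, self.profiles):
            row = {"model": name}
            devs = []
            for pair in _METRIC_ORDER:
                val = prof.get(pair, float("nan"))
                ref = self.reference[pair]
                row[f"{pair[0]}->{pair[1]}"] = val
                row[f"|d| {pair[0]}->{pair[1]}"] = abs(val - ref)
                devs.append(abs(val - ref))
            row["aggregate_mismatch"] = float(np.mean(devs))
            row["lignin_cellulose_mismatch"] = abs(
                prof.get(("lignin_ring", "cellulose"), float("nan"))
                - self.reference[("lignin_ring", "cellulose")]
            )
            rows.append(row)
        df = pd.DataFrame(rows)
        # rank by aggregate; ties broken by the most diagnostic metric
        df = df.sort_values(
            ["aggregate_mismatch", "lignin_cellulose_mismatch", "model"],
            kind="stable",
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        self.table = df

    def ranked_models(self) -> list:
        return list(self.table["model"])


def scorecard(
    models: list,
    names: list | None = None,
    cutoff: float = 10.0,
    reference: dict | None = None,
) -> Scorecard:
    """Score structures against the experimental reference percentages.

    models: list of Structures (periodic).  Returns a Scorecard whose table
    is ranked by mean absolute deviation over the four metrics, ties broken
    by the lignin->cellulose mismatch.
    """
    if names is None:
        names = [f"model_{k}" for k in range(len(models))]
    reference = dict(EXPERIMENTAL_REFERENCE if reference is None else reference)
    profiles = []
    for m in models:
        prof = {}
        for r in proximity_profile(m, cutoff=cutoff):
            prof[(r.source_label, r.sink_class)] = r.percent
        profiles.append(prof)
    return Scorecard(names=list(names), profiles=profiles, reference=reference)
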