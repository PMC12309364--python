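"""Two-level (DNA + RNA) dual-controller prediction.

When one DNA-level and one RNA-level G4 component share a cassette, the
combined output is predicted multiplicatively on the REU scale:

    REU_combined = REU_DNA * REU_RNA / 100

The formula is treated as exact — deviations of observations from it are
reported, never refitted away.  Observed dual controllers landed within
+/-12 REU of this prediction, which is the default tolerance flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .activity import pearson_r

DEFAULT_TOLERANCE_REU = 12.0


def predict_combined(reu_dna: float, reu_rna: float) -> float:
    """Multiplicative two-level prediction: REU_DNA * REU_RNA / 100."""
    if reu_dna < 0 or reu_rna < 0:
        raise ValueError("REU inputs must be >= 0")
    return reu_dna * reu_rna / 100.0


@dataclass(frozen=True)
class DualController:
    """One DNA+RNA component pair with its prediction and (optional) observation."""

    dna_label: str
    rna_label: str
    reu_dna: float
    reu_rna: float
    reu_predicted: float
    reu_observed: Optional[float] = None

    def __post_init__(self):
        expected = predict_combined(self.reu_dna, self.reu_rna)
        if abs(self.reu_predicted - expected) > 1e-9:
            raise ValueError(
                f"reu_predicted {self.reu_predicted} != REU_DNA*REU_RNA/100 = {expected}"
            )

    @property
    def deviation(self) -> Optional[float]:
        if self.reu_observed is None:
            return None
        return self.reu_observed - self.reu_predicted


@dataclass(frozen=True)
class DualPanelSummary:
    table: pd.DataFrame
    pearson_r: float
    pearson_p: float
    n_within_tolerance: int
    tolerance: float

    @property
    def all_within_tolerance(self) -> bool:
        return self.n_within_tolerance == len(self.table)


def evaluate_matrix(
    dna_set: Mapping[str, float],
    rna_set: Mapping[str, float],
    observations: Mapping[Tuple[str, str], float],
    tolerance: float = DEFAULT_TOLERANCE_REU,
) -> DualPanelSummary:
    """Evaluate a full DNA x RNA combination panel against observations.

    ``dna_set`` / ``rna_set`` map component labels to their single-controller
    REUs; ``observations`` maps (dna_label, rna_label) to the observed REU of
    the dual construct and must cover the full Cartesian product.  Returns a
    table with one row per pair (prediction, observation, deviation,
    within-tolerance flag) and the observed-vs-predicted Pearson r.
    """
    pairs = [(d, r) for d in dna_set for r in rna_set]
    missing = sorted(p for p in pairs if p not in observations)
    if missing:
        raise ValueError(f"observations missing for pairs: {missing}")
    rows = []
    for d, r in pairs:
        ctrl = DualController(
            dna_label=d,
            rna_label=r,
            reu_dna=dna_set[d],
            reu_rna=rna_set[r],
            reu_predicted=predict_combined(dna_set[d], rna_set[r]),
            reu_observed=float(observations[(d, r)]),
        )
        rows.append(
            {
                "dna_label": ctrl.dna_label,
                "rna_label": ctrl.rna_label,
                "reu_dna": ctrl.reu_dna,
                "reu_rna": ctrl.reu_rna,
                "reu_predicted": ctrl.reu_predicted,
                "reu_observed": ctrl.reu_observed,
                "deviation": ctrl.deviation,
                "within_tolerance": abs(ctrl.deviation) <= tolerance,
            }
        )
    table = pd.DataFrame(rows)
    r, p = pearson_r(table["reu_predicted"], table["reu_observed"])
    return DualPanelSummary(
        table=table,
        pearson_r=r,
        pearson_p=p,
        n_within_tolerance=int(table["within_tolerance"].sum()),
        tolerance=tolerance,
    )
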