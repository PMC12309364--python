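"""Heavy-chain : light-chain expression-ratio design space.

Multichain products (e.g. monoclonal antibodies) need their chains expressed
at a product-specific stoichiometry.  Pairing G4-controlled cassettes of
varying strength on the heavy chain (HC) and light chain (LC) — at equal
gene copy numbers — encodes an HC:LC expression ratio equal to the quotient
of the two components' REUs.  The default five strength levels (10, 30, 50,
70, 100 REU, the last being the unengineered chassis) give a 25-point
design space; titer measurements over it yield the optimal point plus
simple extracted design rules.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from .activity import pearson_r

DEFAULT_STRENGTH_LEVELS = (10.0, 30.0, 50.0, 70.0, 100.0)


@dataclass(frozen=True)
class RatioDesignPoint:
    """One (HC component, LC component) pairing."""

    hc_component: str
    lc_component: str
    reu_hc: float
    reu_lc: float
    titer: Optional[float] = None  # % of the unengineered-both control

    def __post_init__(self):
        if self.reu_hc <= 0 or self.reu_lc <= 0:
            raise ValueError("REU levels must be > 0")

    @property
    def encoded_ratio(self) -> float:
        """Encoded HC:LC expression ratio (REU_HC / REU_LC)."""
        return self.reu_hc / self.reu_lc


def _component_name(reu: float) -> str:
    return "BPCU" if reu == 100 else f"DNA.{reu:g}REU"


def build_design_space(
    hc_levels: Sequence[float] = DEFAULT_STRENGTH_LEVELS,
    lc_levels: Optional[Sequence[float]] = None,
) -> List[RatioDesignPoint]:
    """Full Cartesian product of HC strength levels x LC strength levels."""
    hc_levels = tuple(float(x) for x in hc_levels)
    lc_levels = hc_levels if lc_levels is None else tuple(float(x) for x in lc_levels)
    for levels, chain in ((hc_levels, "HC"), (lc_levels, "LC")):
        if len(levels) < 1:
            raise ValueError(f"{chain} levels must be nonempty")
        if any(x <= 0 for x in levels):
            raise ValueError(f"{chain} levels must all be > 0")
    return [
        RatioDesignPoint(
            hc_component=_component_name(h),
            lc_component=_component_name(l),
            reu_hc=h,
            reu_lc=l,
        )
        for h in hc_levels
        for l in lc_levels
    ]


@dataclass(frozen=True)
class DesignRules:
    """Product-specific rules extracted from a titer surface.

    ``lc_correlation_by_hc``: Pearson r of titer vs REU_LC within each
    fixed-HC row (positive everywhere when yield rises with LC supply).
    ``hc_peak_by_lc``: the REU_HC of the max-titer point within each
    fixed-LC column (where HC must be set to hit the optimum).
    """

    lc_correlation_by_hc: Dict[float, float]
    hc_peak_by_lc: Dict[float, float]


def find_optimum(
    points: Sequence[RatioDesignPoint],
) -> Tuple[RatioDesignPoint, DesignRules]:
    """Best design point by titer, plus extracted design rules.

    Ties break deterministically toward the lowest REU_HC, then the lowest
    encoded ratio.  All points must carry a titer.
    """
    missing = [
        (p.hc_component, p.lc_component) for p in points if p.titer is None
    ]
    if missing:
        raise ValueError(f"points without titer: {missing}")
    best = max(
        points, key=lambda p: (p.titer, -p.reu_hc, -p.encoded_ratio)
    )
    rows: Dict[float, List[RatioDesignPoint]] = {}
    cols: Dict[float, List[RatioDesignPoint]] = {}
    for p in points:
        rows.setdefault(p.reu_hc, []).append(p)
        cols.setdefault(p.reu_lc, []).append(p)
    lc_corr = {}
    for hc, row in sorted(rows.items()):
        if len(row) >= 3:
            try:
                r, _ = pearson_r([p.reu_lc for p in row], [p.titer for p in row])
            except ValueError:  # constant titer across the row
                r = float("nan")
            lc_corr[hc] = r
    hc_peak = {}
    for lc, col in sorted(cols.items()):
        peak = max(col, key=lambda p: (p.titer, -p.reu_hc))
        hc_peak[lc] = peak.reu_hc
    return best, DesignRules(lc_correlation_by_hc=lc_corr, hc_peak_by_lc=hc_peak)


def with_titers(
    points: Sequence[RatioDesignPoint], titers: Dict[Tuple[float, float], float]
) -> List[RatioDesignPoint]:
    """Attach titers keyed by (reu_hc, reu_lc)."""
    out = []
    for p in points:
        key = (p.reu_hc, p.reu_lc)
        if key not in titers:
            raise ValueError(f"no titer for design point {key}")
        out.append(replace(p, titer=float(titers[key])))
    return out
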