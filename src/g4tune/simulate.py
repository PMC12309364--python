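"""Synthetic measurement generator.

Stands in for the wet-lab REU measurements the pipeline was built around:
per-component activities as a noisy monotone function of the three design
features, triplicate replicate noise, cell-context mean shifts, dual-
controller panels scattered within a bounded band of the multiplicative
prediction, and an HC:LC titer surface with a planted optimum at an encoded
ratio of 0.5 (HC:LC = 1:2).

Ground-truth parameters travel with every simulation so downstream recovery
tests can compare estimates against what was planted.  All randomness is
driven by a single integer seed; identical (seed, config) pairs give
byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .activity import ActivityRecord, Context
from .motifs import ComponentNamer, G4MotifSpec, Level
from .ratio import RatioDesignPoint
from .synergy import predict_combined


@dataclass(frozen=True)
class TiterParams:
    """Shape of the synthetic mAb titer surface.

    titer(hc, lc) = scale * (lc/100)^lc_slope * exp(-tent(log ratio)), where
    ratio = hc/lc, the tent rises with slope ``hc_penalty`` above
    ``peak_ratio`` and ``lc_penalty`` below it, and ``scale`` normalizes the
    unengineered control point (100, 100) to a titer of 100%.  The
    asymmetric tent keeps the surface strictly increasing in LC at every
    fixed HC (lc_slope > lc_penalty) while the peak along each LC column
    stays sharply located, with the global optimum planted at
    ``peak_ratio``.

    Measurement noise is multiplicative lognormal (``noise_cv`` is the
    fractional SD), as is typical of titer assays: the SD at the surface
    peak is ~``noise_cv`` times the peak titer, and simulated titers stay
    strictly positive.
    """

    peak_ratio: float = 0.5
    lc_slope: float = 1.0
    hc_penalty: float = 1.3
    lc_penalty: float = 0.8
    noise_cv: float = 0.05  # fractional SD of the lognormal measurement noise

    def __post_init__(self):
        if self.peak_ratio <= 0:
            raise ValueError("peak_ratio must be > 0")
        if self.lc_slope <= 0 or self.hc_penalty <= 0 or self.lc_penalty <= 0:
            raise ValueError("lc_slope, hc_penalty and lc_penalty must be > 0")
        if self.lc_penalty >= self.lc_slope:
            raise ValueError(
                "lc_penalty must be < lc_slope so titer stays increasing in LC"
            )
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def noiseless_titer(self, reu_hc: float, reu_lc: float) -> float:
        u = math.log((reu_hc / reu_lc) / self.peak_ratio)
        tent = self.hc_penalty * u if u >= 0 else -self.lc_penalty * u
        control_u = math.log(1.0 / self.peak_ratio)
        control = math.exp(-self.hc_penalty * control_u)  # value at (100, 100)
        return 100.0 / control * (reu_lc / 100.0) ** self.lc_slope * math.exp(-tent)


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth model and noise structure of the generator.

    The truth model is REU = clip(intercept + b.features + level_offset,
    reu_bounds); with the defaults the 40-spec default library spans roughly
    13-100 REU at the DNA level and 5-92 at the RNA level.  Replicate noise
    is Gaussian (SD 5 REU, triplicates); dual-controller noise is bounded
    uniform so the +/-12 REU property holds by construction; context shifts
    default to +7 (HEK) and +17 (HepG2) REU.
    """

    seed: int = 0
    truth_intercept: float = 140.0
    truth_betas: tuple = (-12.0, -9.0, 4.0)  # per (tract_length, tract_count, mean_loop)
    level_offsets: tuple = ((Level.DNA, 0.0), (Level.RNA, -8.0))
    noise_sd: float = 5.0
    n_replicates: int = 3
    reu_bounds: tuple = (0.0, 110.0)
    context_shifts: tuple = (("HEK", 7.0), ("HepG2", 17.0))
    dual_noise_halfwidth: float = 10.0
    titer_params: TiterParams = field(default_factory=TiterParams)

    def __post_init__(self):
        b = tuple(float(x) for x in self.truth_betas)
        object.__setattr__(self, "truth_betas", b)
        object.__setattr__(self, "level_offsets", tuple(self.level_offsets))
        object.__setattr__(self, "context_shifts", tuple(self.context_shifts))
        if len(b) != 3:
            raise ValueError("truth_betas must have 3 entries")
        if not (b[0] < 0 and b[1] < 0 and b[2] > 0):
            raise ValueError(
                "truth beta signs must be (negative tract_length, negative "
                "tract_count, positive loop_length)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dual_noise_halfwidth < 0:
            raise ValueError("dual_noise_halfwidth must be >= 0")
        lo, hi = self.reu_bounds
        if not lo < hi:
            raise ValueError("reu_bounds must be an increasing pair")

    @property
    def level_offset_map(self) -> Dict[Level, float]:
        return {Level(k): float(v) for k, v in self.level_offsets}

    @property
    def context_shift_map(self) -> Dict[str, float]:
        return {str(k): float(v) for k, v in self.context_shifts}

    def true_reu(self, spec: G4MotifSpec) -> float:
        raw = (
            self.truth_intercept
            + float(np.dot(self.truth_betas, spec.features))
            + self.level_offset_map.get(spec.level, 0.0)
        )
        lo, hi = self.reu_bounds
        return min(max(raw, lo), hi)


@dataclass(frozen=True)
class SimulatedActivities:
    """Generated activity table plus its ground truth."""

    records: tuple
    truth: tuple  # (label, true REU) pairs, registration order

    @property
    def truth_map(self) -> Dict[str, float]:
        return dict(self.truth)


def simulate_activities(
    motif_specs: Sequence[G4MotifSpec],
    config: GeneratorConfig,
    context: Context = Context(),
    rng: Optional[np.random.Generator] = None,
) -> SimulatedActivities:
    """Simulate per-component activity measurements.

    Each spec's true REU comes from the configured linear truth model;
    the observed value is the mean of ``n_replicates`` Gaussian draws
    truncated to ``reu_bounds``.  Components are named from their observed
    REU with the canonical ``<LEVEL>.<R>REU`` scheme (collisions suffixed).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    namer = ComponentNamer()
    lo, hi = config.reu_bounds
    records, truth = [], []
    for spec in motif_specs:
        true = config.true_reu(spec)
        draws = np.clip(
            rng.normal(true, config.noise_sd, size=config.n_replicates), lo, hi
        )
        mean = float(draws.mean())
        sd = float(draws.std(ddof=1)) if config.n_replicates > 1 else 0.0
        label = namer.name(spec.level, mean)
        records.append(
            ActivityRecord(
                component_label=label,
                level=spec.level,
                features=spec.features,
                reu_mean=mean,
                reu_sd=sd,
                n_replicates=config.n_replicates,
                context=context,
            )
        )
        truth.append((label, true))
    return SimulatedActivities(records=tuple(records), truth=tuple(truth))


def simulate_dual_panel(
    dna_components: Mapping[str, float],
    rna_components: Mapping[str, float],
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> Dict[Tuple[str, str], float]:
    """Simulate observations for the full DNA x RNA combination panel.

    observed = multiplicative prediction + Uniform(-h, h), clipped at 0,
    with h = ``dual_noise_halfwidth`` (default 10, inside the 12-REU
    agreement band).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    h = config.dual_noise_halfwidth
    obs = {}
    for d, reu_d in dna_components.items():
        for r, reu_r in rna_components.items():
            pred = predict_combined(reu_d, reu_r)
            obs[(d, r)] = float(max(pred + rng.uniform(-h, h), 0.0))
    return obs


def simulate_context_panel(
    records: Sequence[ActivityRecord],
    target_context: str,
    config: GeneratorConfig,
    truth: Optional[Mapping[str, float]] = None,
    rng: Optional[np.random.Generator] = None,
) -> List[ActivityRecord]:
    """Re-measure a CHO panel in another cell host.

    The target-context true value is the source true REU (or the source
    observed mean when no ground truth is supplied) plus the configured
    context shift; observations are replicate means as in
    :func:`simulate_activities`.  ``target_context`` "CHO" returns an
    identical re-labelled panel (zero shift).
    """
    if any(r.context.cell_host != "CHO" for r in records):
        raise ValueError("source records must all be in the CHO context")
    shifts = config.context_shift_map
    if target_context == "CHO":
        shift = 0.0
    elif target_context in shifts:
        shift = shifts[target_context]
    else:
        raise ValueError(
            f"unknown target context {target_context!r}; known: CHO, {sorted(shifts)}"
        )
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.reu_bounds
    out = []
    for rec in records:
        base = truth[rec.component_label] if truth is not None else rec.reu_mean
        target_true = min(max(base + shift, lo), hi)
        if target_context == "CHO" and truth is None:
            mean, sd = rec.reu_mean, rec.reu_sd  # identity round-trip
        else:
            draws = np.clip(
                rng.normal(target_true, config.noise_sd, size=config.n_replicates),
                lo, hi,
            )
            mean = float(draws.mean())
            sd = float(draws.std(ddof=1)) if config.n_replicates > 1 else 0.0
        out.append(
            ActivityRecord(
                component_label=rec.component_label,
                level=rec.level,
                features=rec.features,
                reu_mean=mean,
                reu_sd=sd,
                n_replicates=config.n_replicates,
                context=Context(cell_host=target_context,
                                format=rec.context.format,
                                system=rec.context.system),
            )
        )
    return out


@dataclass(frozen=True)
class SimulatedTiterSurface:
    points: tuple  # RatioDesignPoints with titers
    planted_peak_ratio: float
    planted_optimum: tuple  # (reu_hc, reu_lc) of the noiseless argmax


def simulate_titer_surface(
    design_points: Sequence[RatioDesignPoint],
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedTiterSurface:
    """Simulate mAb titers over an HC:LC design space.

    Titer (as % of the unengineered-both control) follows the configured
    surface with multiplicative lognormal measurement noise (all observed
    titers > 0); the noiseless argmax over the supplied points is recorded
    as the planted optimum.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tp = config.titer_params
    noiseless = [tp.noiseless_titer(p.reu_hc, p.reu_lc) for p in design_points]
    best = max(range(len(design_points)), key=lambda i: noiseless[i])
    pts = []
    for p, t in zip(design_points, noiseless):
        observed = t * math.exp(rng.normal(0.0, tp.noise_cv))
        pts.append(replace(p, titer=float(observed)))
    return SimulatedTiterSurface(
        points=tuple(pts),
        planted_peak_ratio=tp.peak_ratio,
        planted_optimum=(design_points[best].reu_hc, design_points[best].reu_lc),
    )
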