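"""Seeded generators for every input the analysis consumes.

Raw optode traces and per-individual morphometric datasets behind this kind
of study are rarely deposited, so the package ships generators that emulate
them with known ground truth:

* noisy Monod drawdown traces at the 5-minute optode cadence (incubations
  run until oxygen depletion, 5–30 h);
* blank (seawater-only) chambers consuming a set fraction — typically
  10–20% — of the faunal rate;
* two-phase Ostracod-like traces (Monod decline, plateau, linear fall);
* log-normal nematode communities with depth-decaying density.

Every generator is a pure function of its spec and seed: the same seed
yields byte-identical output. Optode noise is i.i.d. Gaussian on
concentration (default σ = 2 µmol l⁻¹, an assumption — real noise
magnitudes are instrument-specific), clipped at 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .budget import CommunityLayer, NematodeRecord
from .kinetics import ChamberTrace, MonodParams, simulate_chamber

__all__ = [
    "TraceGenSpec",
    "CommunityGenSpec",
    "gen_chamber_trace",
    "gen_blank_trace",
    "gen_two_phase_trace",
    "gen_community",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20130328


@dataclass(frozen=True)
class TraceGenSpec:
    """Ground truth and sampling scheme for one synthetic drawdown trace.

    ``duration_h=None`` stops at the predicted depletion time plus a 2 h
    margin, capped at 30 h — mimicking incubations run until anoxia.
    """

    params: MonodParams
    interval_min: float = 5.0
    duration_h: Optional[float] = None
    noise_sd: float = 2.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.interval_min <= 0:
            raise ValueError("sampling interval must be > 0")
        if self.duration_h is not None and self.duration_h <= 0:
            raise ValueError("duration must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class CommunityGenSpec:
    """Spec for a synthetic layered nematode community.

    Individual carbon masses are log-normal with parameters moment-matched
    to ``mass_mean_ugC`` ± ``mass_sd_ugC`` (field communities have sd of
    the same order as — often exceeding — the mean, which rules out
    symmetric distributions). Density decays exponentially with depth with
    e-folding scale ``efolding_mm``.
    """

    n_layers: int = 5
    layer_thickness_mm: float = 10.0
    density0_per_10cm2: float = 1000.0
    efolding_mm: float = 15.0
    mass_mean_ugC: float = 0.62
    mass_sd_ugC: float = 0.97
    n_ind_per_layer: int = 50
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_layers <= 0 or self.layer_thickness_mm <= 0:
            raise ValueError("need positive layer count and thickness")
        if self.density0_per_10cm2 < 0:
            raise ValueError("density must be >= 0")
        if self.mass_mean_ugC <= 0 or self.mass_sd_ugC <= 0:
            raise ValueError("mass mean and sd must be > 0")


def _depletion_time_h(p: MonodParams) -> float:
    """Time for the drawdown to come within 1 µmol l⁻¹ of its floor."""
    u0 = p.o2_init - p.o2_min
    u1 = min(1.0, 0.5 * u0)
    return (p.k_s * np.log(u0 / u1) + (u0 - u1)) / p.r_max_vol


def _time_grid(interval_min: float, duration_h: float) -> np.ndarray:
    n = int(np.floor(duration_h * 60.0 / interval_min)) + 1
    return np.arange(n) * interval_min / 60.0


def gen_chamber_trace(
    spec: TraceGenSpec, chamber_id: str = "synthetic"
) -> Tuple[ChamberTrace, MonodParams]:
    """Simulated drawdown plus optode noise; returns (trace, ground truth)."""
    dur = spec.duration_h
    if dur is None:
        dur = float(np.clip(_depletion_time_h(spec.params) + 2.0, 5.0, 30.0))
    t = _time_grid(spec.interval_min, dur)
    clean = simulate_chamber(spec.params, t).o2_umol_l
    rng = np.random.default_rng(spec.seed)
    o2 = np.clip(clean + rng.normal(0.0, spec.noise_sd, t.size), 0.0, None)
    if spec.noise_sd == 0:
        o2 = clean
    return (
        ChamberTrace(times_h=t, o2_umol_l=o2, chamber_id=chamber_id),
        spec.params,
    )


def gen_blank_trace(
    fauna_rate_vol: float,
    fraction: float = 0.15,
    duration_h: float = 15.0,
    interval_min: float = 5.0,
    noise_sd: float = 2.0,
    start_o2: float = 230.0,
    seed: int = DEFAULT_SEED,
    chamber_id: str = "blank",
) -> ChamberTrace:
    """Seawater-only control declining at ``fraction`` of the faunal rate."""
    if not 0 <= fraction < 1:
        raise ValueError("blank fraction must lie in [0, 1)")
    t = _time_grid(interval_min, duration_h)
    clean = np.clip(start_o2 - fraction * fauna_rate_vol * t, 0.0, None)
    rng = np.random.default_rng(seed)
    o2 = np.clip(clean + rng.normal(0.0, noise_sd, t.size), 0.0, None)
    return ChamberTrace(times_h=t, o2_umol_l=o2, chamber_id=chamber_id, is_blank=True)


def gen_two_phase_trace(
    monod: MonodParams,
    plateau_o2: float,
    plateau_hours: float,
    linear_rate_vol: float,
    interval_min: float = 5.0,
    noise_sd: float = 2.0,
    seed: int = DEFAULT_SEED,
    chamber_id: str = "ostracod",
) -> Tuple[ChamberTrace, dict]:
    """Ostracod-like trace: Monod decline, plateau, then linear fall to 0.

    The Monod phase runs the supplied kinetics with its floor moved to
    ``plateau_o2`` so consumption levels off there; after ``plateau_hours``
    of near-zero consumption a linear decline at ``linear_rate_vol`` sets
    in (the stress response). Returns (trace, truth) where truth records
    the true breakpoint time and linear rate.
    """
    if plateau_o2 >= monod.o2_init:
        raise ValueError("plateau must lie below the initial concentration")
    if linear_rate_vol <= 0 or plateau_hours < 0:
        raise ValueError("linear rate must be > 0 and plateau_hours >= 0")
    p = MonodParams(
        r_max_vol=monod.r_max_vol,
        k_s=monod.k_s,
        o2_init=monod.o2_init,
        o2_min=plateau_o2,
    )
    t_settle = _depletion_time_h(p)
    t_break = t_settle + plateau_hours
    # stop at depletion: a flat anoxic tail is not part of the drawdown
    duration = t_break + plateau_o2 / linear_rate_vol
    t = _time_grid(interval_min, duration)
    # snap the true breakpoint to the sampling grid
    i_break = int(np.searchsorted(t, t_break))
    t_break = float(t[min(i_break, t.size - 1)])
    clean = simulate_chamber(p, t).o2_umol_l.copy()
    after = t >= t_break
    clean[after] = np.clip(
        clean[~after][-1] - linear_rate_vol * (t[after] - t_break), 0.0, None
    )
    rng = np.random.default_rng(seed)
    o2 = np.clip(clean + rng.normal(0.0, noise_sd, t.size), 0.0, None)
    if noise_sd == 0:
        o2 = clean
    truth = {
        "breakpoint_h": t_break,
        "linear_rate_vol": linear_rate_vol,
        "monod": monod,
        "plateau_o2": plateau_o2,
    }
    return ChamberTrace(times_h=t, o2_umol_l=o2, chamber_id=chamber_id), truth


def lognormal_params(mean: float, sd: float) -> Tuple[float, float]:
    """(mu, sigma) of the log-normal with the requested mean and sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - 0.5 * sigma2, np.sqrt(sigma2)


def gen_community(spec: CommunityGenSpec) -> List[CommunityLayer]:
    """Layered community with log-normal masses and depth-decaying density."""
    mu, sigma = lognormal_params(spec.mass_mean_ugC, spec.mass_sd_ugC)
    rng = np.random.default_rng(spec.seed)
    layers = []
    for i in range(spec.n_layers):
        top = i * spec.layer_thickness_mm
        bottom = top + spec.layer_thickness_mm
        mid = 0.5 * (top + bottom)
        density = spec.density0_per_10cm2 * np.exp(-mid / spec.efolding_mm)
        masses = rng.lognormal(mu, sigma, spec.n_ind_per_layer)
        layers.append(
            CommunityLayer(
                top_mm=top,
                bottom_mm=bottom,
                density_per_10cm2=float(density),
                individuals=tuple(NematodeRecord(carbon_ugC=float(m)) for m in masses),
            )
        )
    return layers
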