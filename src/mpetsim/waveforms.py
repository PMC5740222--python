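"""Per-territory arterial inflow waveforms and their boundary fluxes.

Each of the four perfusion territories (left/right internal carotid
ICA_L/ICA_R feeding the cerebrum, left/right vertebral VA_L/VA_R feeding
the cerebellum) receives a volumetric inflow waveform Q(t).  A parametric
synthesizer stands in for subject-specific circulation modelling: each
cardiac cycle is a half-sine systolic pulse occupying one third of the
period on top of an exponentially decaying diastolic baseline, calibrated
so the waveform peak matches the configured peak flow exactly and the
cycle mean matches ``mean_to_peak * peak``.

Flows are SI (m^3/s) internally; interfaces accept and report ml/min, the
unit clinical flow tables are printed in.  ``PEAK_FLOW_ML_MIN`` carries
the published peak flow rates for one control and one mild-cognitive-
impairment (MCI) subject in high/low activity states, used as synthesizer
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import LabeledMesh, TERRITORIES, surface_area

ML_PER_MIN = 1e-6 / 60.0     # m^3/s per ml/min

#: Published peak flow rates, ml/min, by case / activity state / territory
#: (the two VA territories share one printed value).
PEAK_FLOW_ML_MIN = {
    ("control", "high"): {"ICA_L": 540.6, "ICA_R": 493.1,
                          "VA_L": 129.2, "VA_R": 129.2},
    ("control", "low"): {"ICA_L": 324.3, "ICA_R": 294.5,
                         "VA_L": 77.3, "VA_R": 77.3},
    ("mci", "high"): {"ICA_L": 449.9, "ICA_R": 460.2,
                      "VA_L": 113.8, "VA_R": 113.8},
    ("mci", "low"): {"ICA_L": 308.1, "ICA_R": 313.7,
                     "VA_L": 77.7, "VA_R": 77.7},
}

# shape constants of the synthetic cycle (dimensionless fractions)
_SYSTOLE_FRACTION = 1.0 / 3.0    # systole occupies T/3
_DIASTOLE_FLOOR = 0.75           # diastolic decay asymptote, fraction of b
_DIASTOLE_TAU_FRACTION = 1.0 / 3.0  # decay time constant, fraction of T


class WaveformError(ValueError):
    pass


@dataclass
class InflowWaveform:
    """Sampled volumetric inflow of one territory (SI units)."""

    territory: str
    times: np.ndarray        # s, strictly increasing
    flows: np.ndarray        # m^3/s, >= 0
    activity: str = "high"   # {high, low}
    period: float = 1.0      # cardiac period, s

    def __post_init__(self):
        self.times = np.ascontiguousarray(self.times, dtype=float)
        self.flows = np.ascontiguousarray(self.flows, dtype=float)
        if self.times.shape != self.flows.shape or self.times.ndim != 1:
            raise WaveformError("times and flows must be matching 1-D arrays")
        if (np.diff(self.times) <= 0).any():
            raise WaveformError("times must be strictly increasing")
        if (self.flows < 0).any():
            raise WaveformError("flows must be non-negative")

    @property
    def peak(self) -> float:
        return float(self.flows.max())

    @property
    def peak_ml_min(self) -> float:
        return self.peak / ML_PER_MIN

    @property
    def mean(self) -> float:
        return float(np.trapezoid(self.flows, self.times) /
                     (self.times[-1] - self.times[0]))

    def __call__(self, t):
        """Flow at time t (periodic extension over the sampled span)."""
        t0, t1 = self.times[0], self.times[-1]
        span = t1 - t0
        tt = t0 + np.mod(np.asarray(t, dtype=float) - t0, span)
        return np.interp(tt, self.times, self.flows)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times,
                      "flow_ml_per_min": self.flows / ML_PER_MIN}
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, territory, activity="high", period=1.0):
        df = pd.read_csv(path)
        for col in ("time_s", "flow_ml_per_min"):
            if col not in df.columns:
                raise WaveformError(f"{path}: missing column {col!r}")
        return cls(territory, df["time_s"].to_numpy(),
                   df["flow_ml_per_min"].to_numpy() * ML_PER_MIN,
                   activity=activity, period=period)


def _cycle_shape(peak, mean_to_peak, period, tau, floor_frac):
    """Solve the diastolic baseline b so the cycle mean is m * peak."""
    m = float(mean_to_peak)
    Ts = _SYSTOLE_FRACTION * period
    Td = period - Ts
    # integral contributions linear in b:
    #   systole: b*Ts + (peak - b) * (2/pi) * Ts
    #   diastole: b * (floor*Td + (1 - floor)*tau*(1 - exp(-Td/tau)))
    dia = floor_frac * Td + (1 - floor_frac) * tau * \
        (1.0 - np.exp(-Td / tau))
    coef_b = Ts * (1.0 - 2.0 / np.pi) + dia
    const = (2.0 / np.pi) * Ts * peak
    b = (m * peak * period - const) / coef_b
    return b, Ts


def synthesize_inflow(peak_flow: float, mean_to_peak: float = 0.55,
                      period: float = 1.0, n_cycles: int = 2,
                      samples_per_cycle: int = 100, seed: int = 0,
                      territory: str = "ICA_L",
                      activity: str = "high") -> InflowWaveform:
    """Pulsatile inflow waveform with an exactly calibrated peak.

    ``peak_flow`` is in ml/min.  Each cycle: half-sine systolic pulse over
    one third of the period rising from the diastolic baseline ``b`` to
    the peak, then exponential diastolic decay from ``b`` toward
    ``0.75 b`` with time constant ``period/3``.  ``b`` is solved so the
    cycle-averaged flow equals ``mean_to_peak * peak``; ``mean_to_peak=1``
    degenerates to constant flow at the peak.  Deterministic for a fixed
    seed (the seed is reserved for optional beat-to-beat variability and
    does not perturb the default waveform).
    """
    if peak_flow <= 0:
        raise WaveformError(f"peak_flow must be > 0, got {peak_flow}")
    if period <= 0:
        raise WaveformError(f"period must be > 0, got {period}")
    if n_cycles < 1 or samples_per_cycle < 8:
        raise WaveformError("need n_cycles >= 1 and samples_per_cycle >= 8")
    if not (0.0 < mean_to_peak <= 1.0):
        raise WaveformError(f"mean_to_peak must lie in (0, 1], got "
                            f"{mean_to_peak}")
    peak = float(peak_flow) * ML_PER_MIN
    n = n_cycles * samples_per_cycle + 1
    times = np.linspace(0.0, n_cycles * period, n)
    if mean_to_peak == 1.0:
        flows = np.full(n, peak)
        return InflowWaveform(territory, times, flows, activity, period)
    tau = _DIASTOLE_TAU_FRACTION * period
    b, Ts = _cycle_shape(peak, mean_to_peak, period, tau, _DIASTOLE_FLOOR)
    if not (0.0 <= b <= peak):
        lo = (2.0 / np.pi) * _SYSTOLE_FRACTION
        raise WaveformError(
            f"mean_to_peak={mean_to_peak} is not realizable with this cycle "
            f"shape (feasible range is about ({lo:.3f}, 1])")
    tc = np.mod(times, period)
    # half-sine grid alignment: put a sample exactly at the systolic peak
    flows = np.where(
        tc <= Ts,
        b + (peak - b) * np.sin(np.pi * tc / Ts),
        b * (_DIASTOLE_FLOOR + (1 - _DIASTOLE_FLOOR) *
             np.exp(-(tc - Ts) / tau)))
    i_peak = np.argmin(np.abs(np.mod(times, period) - 0.5 * Ts))
    flows[i_peak] = peak     # exact peak calibration on the sample grid
    return InflowWaveform(territory, times, np.maximum(flows, 0.0),
                          activity, period)


def autoregulate(w: InflowWaveform, baseline_floor: float,
                 gain: float = 1.0, tau: float = 2.0) -> InflowWaveform:
    """First-order feedback preserving a minimum baseline flow.

    Two-element control model: a feedback state x relaxes toward
    ``gain * max(floor - Q, 0)`` with time constant ``tau`` (s), and the
    output is ``Q' = max(Q + x, floor)``.  When the input never dips below
    the floor the feedback stays at rest and the output equals the input;
    for any input the output never falls below the floor.  ``gain=0``
    reduces to pointwise clamping, ``tau=0`` to instantaneous feedback.
    """
    if baseline_floor < 0:
        raise WaveformError("baseline_floor must be >= 0")
    if tau < 0:
        raise WaveformError("tau must be >= 0")
    F = float(baseline_floor)
    err = gain * np.maximum(F - w.flows, 0.0)
    x = np.zeros_like(w.flows)
    if tau == 0.0:
        x = err
    else:
        for k in range(1, len(x)):
            dt = w.times[k] - w.times[k - 1]
            decay = np.exp(-dt / tau)
            x[k] = x[k - 1] * decay + (1.0 - decay) * err[k - 1]
    out = np.maximum(w.flows + x, F)
    return replace(w, flows=out)


@dataclass
class TerritoryFlux:
    """Uniform normal Darcy influx (m/s) over one territory's facets."""

    territory: str
    facet_ids: np.ndarray
    area: float              # m^2
    waveform: InflowWaveform

    def flux(self, t):
        """Inward normal flux Q(t)/area at time t (scalar)."""
        return float(self.waveform(t)) / self.area

    def total_inflow(self, t):
        return float(self.waveform(t))


def inflow_to_flux(w: InflowWaveform, mesh: LabeledMesh) -> TerritoryFlux:
    """Distribute a territory inflow uniformly over its cortical facets.

    The flux is Q(t)/area(territory), so the integral of flux over the
    territory reproduces Q(t) exactly by construction.
    """
    if w.territory not in TERRITORIES:
        raise WaveformError(f"unknown territory {w.territory!r}")
    mask = mesh.facets_where(w.territory)
    if not mask.any():
        raise WaveformError(f"territory {w.territory} has no facets on "
                            "this mesh")
    area = surface_area(mesh, w.territory)
    return TerritoryFlux(w.territory, np.where(mask)[0], area, w)


def territory_fluxes(waveforms, mesh: LabeledMesh) -> dict:
    """Map each of the four territories to its TerritoryFlux."""
    out = {}
    for w in waveforms:
        out[w.territory] = inflow_to_flux(w, mesh)
    missing = set(TERRITORIES) - set(out)
    if missing:
        raise WaveformError(f"missing waveforms for territories "
                            f"{sorted(missing)}")
    return out


@dataclass
class ConstantFlux:
    """Time-constant territory influx (steady-state boundary data)."""

    territory: str
    facet_ids: np.ndarray
    area: float
    q: float                 # inward normal flux, m/s

    def flux(self, t):
        return self.q

    def total_inflow(self, t):
        return self.q * self.area


def steady_territory_fluxes(waveforms_, mesh: LabeledMesh) -> dict:
    """Constant-flux BCs at each waveform's cycle-mean flow."""
    out = {}
    for w in waveforms_:
        tf = inflow_to_flux(w, mesh)
        out[w.territory] = ConstantFlux(w.territory, tf.facet_ids, tf.area,
                                        w.mean / tf.area)
    missing = set(TERRITORIES) - set(out)
    if missing:
        raise WaveformError(f"missing waveforms for territories "
                            f"{sorted(missing)}")
    return out


def default_waveforms(case="control", activity="high", mean_to_peak=0.55,
                      period=1.0, n_cycles=2, samples_per_cycle=100,
                      seed=0):
    """Four-territory waveform set from the published peak-flow table."""
    key = (case, activity)
    if key not in PEAK_FLOW_ML_MIN:
        raise WaveformError(f"unknown case/activity {key}")
    return [synthesize_inflow(PEAK_FLOW_ML_MIN[key][t],
                              mean_to_peak=mean_to_peak, period=period,
                              n_cycles=n_cycles,
                              samples_per_cycle=samples_per_cycle,
                              seed=seed, territory=t, activity=activity)
            for t in TERRITORIES]
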