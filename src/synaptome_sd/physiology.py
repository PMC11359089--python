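"""Event-driven short-term-plasticity model of CA1 stratum radiatum synapses.

Each synapse responds to a spike train with an EPSP whose amplitude is
modulated by one depressing and two facilitating components in the
Tsodyks-Markram / Varela tradition.  For event ``k`` at time ``t_k`` with
preceding events ``i < k`` (``dt_i = t_k - t_i``):

    A_td(k) = max(1 - sum_i A_d * exp(-dt_i / tau_d), 0)
    A_tf(k) = min(1 + sum_i (A_f * exp(-dt_i / tau_f)
                             + A_s * exp(-dt_i / tau_s)), cap)
    A_e(k)  = A_tf(k) * A_td(k)

so the first response is exactly 1 (all amplitudes are normalized to it)
and the total facilitatory multiplier saturates at ``cap`` (default 3.3
times the unit response).  The voltage time course of one event is the
bi-exponential kernel ``exp(-t/tau1) - exp(-t/tau2)`` scaled by ``A_e``.

Spatial structure enters through per-synapse scale factors derived from
normalized PSD95 / SAP102 puncta-size gradients: tangential size factors
scale the amplitudes (``A_d = A_d0 * S_Ad``, ``A_f = A_f0 * S_Af``) and
radial size factors scale the time constants (``tau_d = tau_d0 * S_Td``,
``tau_f = tau_f0 * S_Tf``); the slow facilitation component is spatially
uniform.  A model "slice" is an 11 x 11 grid of such synapses (121 in
total) spanning the radial x tangential axes of CA1sr.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .stats import bh_adjust

__all__ = [
    "STPParams",
    "ScaleFactors",
    "SpikeTrain",
    "AmplitudeSeries",
    "SynapseGrid",
    "ResponseMap",
    "DEFAULT_PATTERNS",
    "PATTERN_NAMES",
    "epsp_kernel",
    "epsp_peak_time",
    "simulate_amplitudes",
    "simulate_trace",
    "normalize_size_profiles",
    "build_grid",
    "build_stimulus",
    "simulate_grid",
    "compare_maps",
    "run_pattern_battery",
]

GRID_SHAPE = (11, 11)
FACILITATION_CAP = 3.3


@dataclass(frozen=True)
class STPParams:
    """Base (unscaled) short-term-plasticity parameters.

    Time constants in ms, amplitudes in arbitrary units.  ``tau1``/``tau2``
    shape the AMPA-type EPSP kernel; the remaining pairs are the base
    amplitude and time constant of depression (d), fast facilitation (f)
    and slow facilitation (s).  Default time constants follow classic
    cortical short-term-plasticity estimates; the per-spike increments
    are kept small enough that 100 Hz bursts modulate rather than
    silence the synapse.
    """

    tau1: float = 3.0
    tau2: float = 0.4
    a_d0: float = 0.10
    tau_d0: float = 300.0
    a_f0: float = 0.20
    tau_f0: float = 94.0
    a_s0: float = 0.03
    tau_s0: float = 380.0
    cap: float = FACILITATION_CAP

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("EPSP time constants must be positive")
        if self.tau1 <= self.tau2:
            raise ValueError("tau1 must exceed tau2 for a well-formed EPSP kernel")
        for name in ("tau_d0", "tau_f0", "tau_s0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("a_d0", "a_f0", "a_s0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cap < 1:
            raise ValueError("facilitation cap must be >= 1")

    def with_updates(self, **kwargs: float) -> "STPParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ScaleFactors:
    """Normalized size factors in [0, 1] applied to one synapse.

    ``s_ad``/``s_td``: tangential/radial PSD95 factors scaling depression
    amplitude and time constant; ``s_af``/``s_tf``: tangential/radial
    SAP102 factors scaling fast facilitation.
    """

    s_ad: float = 1.0
    s_td: float = 1.0
    s_af: float = 1.0
    s_tf: float = 1.0

    def __post_init__(self) -> None:
        for name in ("s_ad", "s_td", "s_af", "s_tf"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class SpikeTrain:
    pattern: str
    times: np.ndarray  # event times, ms, strictly increasing

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size == 0:
            raise ValueError("spike train needs at least one event time")
        if not np.all(np.isfinite(t)):
            raise ValueError("event times must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class AmplitudeSeries:
    """Per-event state of one simulated synapse (arrays indexed by event)."""

    times: np.ndarray
    a_td: np.ndarray  # total depression in [0, 1]
    a_tf: np.ndarray  # total facilitation in [1, cap]
    a_e: np.ndarray   # event amplitude, first event exactly 1


@dataclass(frozen=True)
class SynapseGrid:
    """Grid of per-synapse scale factors (radial rows x tangential cols)."""

    group: str
    s_ad: np.ndarray
    s_td: np.ndarray
    s_af: np.ndarray
    s_tf: np.ndarray

    def __post_init__(self) -> None:
        shape = np.asarray(self.s_ad).shape
        for name in ("s_ad", "s_td", "s_af", "s_tf"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError("scale-factor arrays must share one shape")
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} entries outside [0, 1]")
            object.__setattr__(self, name, arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.s_ad.shape

    @property
    def n_synapses(self) -> int:
        return int(np.prod(self.shape))

    def factors_at(self, row: int, col: int) -> ScaleFactors:
        return ScaleFactors(
            s_ad=float(self.s_ad[row, col]),
            s_td=float(self.s_td[row, col]),
            s_af=float(self.s_af[row, col]),
            s_tf=float(self.s_tf[row, col]),
        )


@dataclass(frozen=True)
class ResponseMap:
    """Summed EPSP amplitude per synapse for one group x pattern."""

    group: str
    pattern: str
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values)


def epsp_kernel(t: float | np.ndarray, params: STPParams) -> float | np.ndarray:
    """Unit-amplitude bi-exponential EPSP kernel at time ``t`` (ms) past the event."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("kernel is defined for t >= 0")
    out = np.exp(-t / params.tau1) - np.exp(-t / params.tau2)
    return float(out) if out.ndim == 0 else out


def epsp_peak_time(params: STPParams) -> float:
    """Closed-form argmax of the kernel: tau1*tau2/(tau1-tau2) * ln(tau1/tau2)."""
    t1, t2 = params.tau1, params.tau2
    return t1 * t2 / (t1 - t2) * np.log(t1 / t2)


def simulate_amplitudes(
    train: SpikeTrain,
    params: STPParams | None = None,
    scale: ScaleFactors | None = None,
) -> AmplitudeSeries:
    """Compute per-event depression, facilitation and amplitude for one synapse."""
    params = params or STPParams()
    scale = scale or ScaleFactors()
    t = train.times
    n = t.size

    a_d = params.a_d0 * scale.s_ad
    tau_d = params.tau_d0 * scale.s_td
    a_f = params.a_f0 * scale.s_af
    tau_f = params.tau_f0 * scale.s_tf
    a_s = params.a_s0
    tau_s = params.tau_s0

    # strictly-lower-triangular dt matrix: dt[k, i] = t_k - t_i for i < k
    dt = t[:, None] - t[None, :]
    past = np.tril(np.ones((n, n), dtype=bool), k=-1)

    def decayed_total(amplitude: float, tau: float) -> np.ndarray:
        if amplitude == 0.0 or tau <= 0.0:
            return np.zeros(n)
        return np.where(past, amplitude * np.exp(-np.where(past, dt, 0.0) / tau),
                        0.0).sum(axis=1)

    dep = decayed_total(a_d, tau_d)
    fac = decayed_total(a_f, tau_f) + decayed_total(a_s, tau_s)
    a_td = np.maximum(1.0 - dep, 0.0)
    a_tf = np.minimum(1.0 + fac, params.cap)
    a_e = a_tf * a_td
    return AmplitudeSeries(times=t.copy(), a_td=a_td, a_tf=a_tf, a_e=a_e)


def simulate_trace(
    train: SpikeTrain,
    params: STPParams | None = None,
    scale: ScaleFactors | None = None,
    dt: float = 1.0,
    pad: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose per-event EPSP kernels into a voltage trace sampled every ``dt`` ms."""
    params = params or STPParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    series = simulate_amplitudes(train, params, scale)
    t_end = train.times[-1] + (pad if pad is not None else 10.0 * params.tau1)
    grid = np.arange(0.0, t_end + dt, dt)
    v = np.zeros_like(grid)
    for t_k, amp in zip(train.times, series.a_e):
        mask = grid >= t_k
        v[mask] += amp * (
            np.exp(-(grid[mask] - t_k) / params.tau1)
            - np.exp(-(grid[mask] - t_k) / params.tau2)
        )
    return grid, v


# ---------------------------------------------------------------------------
# Spatial scaling: 4x4 group size profiles -> normalized direction factors
# ---------------------------------------------------------------------------

def normalize_size_profiles(
    profiles: Mapping[str, Mapping[str, np.ndarray]],
) -> dict[str, dict[tuple[str, str], float]]:
    """Normalized directional span factors per group, protein and direction.

    ``profiles`` maps group -> protein -> 4x4 geometric-mean size matrix
    (rows: tangential subregions CA1, CA2, CA3, DG; columns: radial layers).
    For each protein and direction the directional gradient of a group is
    the span (largest minus smallest) of the mean profile along that axis;
    spans are then normalized across groups by subtracting the minimum
    span and dividing by the maximum span, giving factors in [0, 1].

    Returns group -> {(protein, direction): factor} with direction in
    {"tangential", "radial"}.
    """
    groups = list(profiles)
    if not groups:
        raise ValueError("no groups in profiles")
    proteins = sorted({p for g in groups for p in profiles[g]})

    spans: dict[tuple[str, str], dict[str, float]] = {}
    for protein in proteins:
        for direction, axis in (("tangential", 1), ("radial", 0)):
            per_group: dict[str, float] = {}
            for g in groups:
                mat = np.asarray(profiles[g][protein], dtype=float)
                if mat.ndim != 2:
                    raise ValueError("size profiles must be 2-D matrices")
                if np.any(~np.isfinite(mat)) or np.any(mat <= 0):
                    raise ValueError("size profiles must be finite and positive")
                # mean over the orthogonal axis yields the directional profile
                prof = mat.mean(axis=axis)
                per_group[g] = float(prof.max() - prof.min())
            spans[(protein, direction)] = per_group

    factors: dict[str, dict[tuple[str, str], float]] = {g: {} for g in groups}
    for key, per_group in spans.items():
        vals = np.array([per_group[g] for g in groups])
        max_span = vals.max()
        if max_span == 0:
            raise ValueError(f"degenerate profile: zero span for {key} in all groups")
        min_span = vals.min()
        for g in groups:
            factors[g][key] = float((per_group[g] - min_span) / max_span)
    return factors


def build_grid(
    profiles: "object",
    group: str,
    blend: float = 0.5,
) -> SynapseGrid:
    """Build the 11x11 scale-factor grid for one animal group.

    ``profiles`` is a :class:`~synaptome_sd.synth.SpatialSizeProfiles`
    (or any object with ``group_matrices`` mapping group -> protein -> 4x4
    and ``baselines`` mapping protein -> 11x11 baseline profile in (0, 1]).
    Each baseline is multiplied by a scalar ``blend + (1-blend) * factor``
    where the tangential factor feeds the amplitude factors and the radial
    factor the time-constant factors; results are clipped to [0, 1].
    """
    group_matrices = profiles.group_matrices
    baselines = profiles.baselines
    if group not in group_matrices:
        raise KeyError(f"group {group!r} not present in profiles")
    if not (0.0 <= blend <= 1.0):
        raise ValueError("blend must lie in [0, 1]")
    factors = normalize_size_profiles(group_matrices)[group]

    def modulated(protein: str, direction: str) -> np.ndarray:
        if protein not in baselines:
            raise KeyError(f"missing {protein} CA1sr baseline profile")
        base = np.asarray(baselines[protein], dtype=float)
        f = factors[(protein, direction)]
        return np.clip(base * (blend + (1.0 - blend) * f), 0.0, 1.0)

    return SynapseGrid(
        group=group,
        s_ad=modulated("psd95", "tangential"),
        s_td=modulated("psd95", "radial"),
        s_af=modulated("sap102", "tangential"),
        s_tf=modulated("sap102", "radial"),
    )


# ---------------------------------------------------------------------------
# Stimulus patterns
# ---------------------------------------------------------------------------

def _burst_times(n_bursts: int, burst_hz: float, n_pulses: int, pulse_hz: float) -> np.ndarray:
    burst_starts = np.arange(n_bursts) * 1000.0 / burst_hz
    within = np.arange(n_pulses) * 1000.0 / pulse_hz
    return (burst_starts[:, None] + within[None, :]).ravel()


#: Default oscillatory stimulation patterns (all times in ms).  The battery
#: covers the rhythms of waking and sleep: tonic gamma and theta trains,
#: nested gamma/theta bursts and a single high-frequency sharp-wave ripple.
DEFAULT_PATTERNS: dict[str, np.ndarray] = {
    "gamma_train": np.arange(10) * 25.0,               # 10 pulses @ 40 Hz
    "gamma_burst": _burst_times(5, 5.0, 4, 40.0),      # 5 bursts @ 5 Hz of 4 @ 40 Hz
    "theta_train": np.arange(10) * 200.0,              # 10 pulses @ 5 Hz
    "theta_burst": _burst_times(10, 5.0, 4, 100.0),    # 10 bursts @ 5 Hz of 4 @ 100 Hz
    "sharp_wave_ripple": np.arange(10) * (1000.0 / 180.0),  # 10 pulses @ 180 Hz
}

PATTERN_NAMES: tuple[str, ...] = tuple(DEFAULT_PATTERNS)


def build_stimulus(name: str, config: Mapping[str, np.ndarray] | None = None) -> SpikeTrain:
    """Return the deterministic spike train for a named activity pattern."""
    table = dict(DEFAULT_PATTERNS)
    if config:
        table.update({k: np.asarray(v, dtype=float) for k, v in config.items()})
    if name not in table:
        raise KeyError(f"unknown stimulation pattern {name!r}; known: {sorted(table)}")
    return SpikeTrain(pattern=name, times=np.asarray(table[name], dtype=float))


# ---------------------------------------------------------------------------
# Grid simulation and comparison
# ---------------------------------------------------------------------------

def simulate_grid(
    grid: SynapseGrid,
    train: SpikeTrain,
    params: STPParams | None = None,
) -> ResponseMap:
    """Summed normalized EPSP amplitude of every synapse in the grid."""
    params = params or STPParams()
    rows, cols = grid.shape
    out = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            series = simulate_amplitudes(train, params, grid.factors_at(r, c))
            out[r, c] = series.a_e.sum()
    return ResponseMap(group=grid.group, pattern=train.pattern, values=out)


def _paired_cohens_d(diff: np.ndarray) -> float:
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0 if diff.mean() == 0 else float(np.sign(diff.mean()) * np.inf)
    return float(diff.mean() / sd)


def compare_maps(map_a: ResponseMap, map_b: ResponseMap) -> dict[str, float]:
    """Disruption metrics between two response maps of equal shape.

    ``ed_intensity`` is the Euclidean distance between the raw maps
    (magnitude differences); ``ed_spatial`` the distance after dividing
    each map by its mean (shape differences only).  The KS test compares
    the two sets of per-synapse values, position-paired by construction,
    and ``cohens_d`` is the standardized mean of the paired differences.
    """
    a = np.asarray(map_a.values, dtype=float)
    b = np.asarray(map_b.values, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"map shapes differ: {a.shape} vs {b.shape}")
    av, bv = a.ravel(), b.ravel()
    ed_intensity = float(np.linalg.norm(av - bv))
    ed_spatial = float(np.linalg.norm(av / av.mean() - bv / bv.mean()))
    ks = _sps.ks_2samp(av, bv, method="auto")
    return {
        "ed_spatial": ed_spatial,
        "ed_intensity": ed_intensity,
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "cohens_d": _paired_cohens_d(av - bv),
        "n": av.size,
    }


def run_pattern_battery(
    grid_a: SynapseGrid,
    grid_b: SynapseGrid,
    patterns: Sequence[str] = PATTERN_NAMES,
    params: STPParams | None = None,
    pattern_config: Mapping[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Run all patterns on both grids; BH-adjust KS p-values across the battery."""
    if len(patterns) == 0:
        raise ValueError("need at least one pattern")
    params = params or STPParams()
    rows = []
    for name in patterns:
        train = build_stimulus(name, pattern_config)
        map_a = simulate_grid(grid_a, train, params)
        map_b = simulate_grid(grid_b, train, params)
        metrics = compare_maps(map_a, map_b)
        rows.append({"pattern": name, **metrics})
    table = pd.DataFrame(rows)
    table["ks_p_adj"] = bh_adjust(table["ks_p"].to_numpy())
    cols = ["pattern", "ed_spatial", "ed_intensity", "ks_stat", "ks_p", "ks_p_adj", "cohens_d", "n"]
    return table[cols]
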