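"""Synthetic activation-time data with the statistical structure the
detection method assumes.

Focal sources fire irregularly; each firing launches a wavefront that
reaches every sensor after a travel time ``distance / CV*``, where the
conduction velocity CV* is drawn per activation cycle from a truncated
normal law.  When several sources fire in one cycle the observed arrival
at a sensor is the earliest one (eikonal-style collision: the first
wavefront to arrive depolarizes the tissue, later fronts find it
refractory).  Observed LATs carry additive Gaussian noise.

A toy electrogram path is included — biphasic template pulses placed at
the LATs plus white noise — so the LAT-extraction step (time of maximum
signal change within an activation window) can be exercised end to end.
It does not attempt realistic fractionated electrogram morphology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .activation import ALL_PAIR_INDICES, ActivationMatrix

__all__ = [
    "SourceSpec",
    "CVModel",
    "NoiseModel",
    "EGMTrace",
    "generate_activation_schedule",
    "simulate_lat_matrix",
    "synthesize_egm_traces",
    "extract_lat",
    "segment_activations",
]


@dataclass(frozen=True)
class SourceSpec:
    """A focal source: a location plus an irregular firing schedule."""

    location: np.ndarray  # (3,) mm, or a mesh vertex id in mesh mode
    onset_times: np.ndarray  # ms, strictly increasing
    label: str = "abnormal"  # "normal" | "abnormal"

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onset_times, dtype=float)
        if onsets.ndim != 1 or len(onsets) == 0:
            raise ValueError("onset_times must be a non-empty 1-D sequence")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onset_times must be strictly increasing")
        object.__setattr__(self, "onset_times", onsets)
        if np.ndim(self.location) > 0:
            object.__setattr__(self, "location", np.asarray(self.location, dtype=float))


@dataclass(frozen=True)
class CVModel:
    """Conduction velocity law: CV* ~ N(mean, sd²), truncated to > 0."""

    mean_mu: float = 1.0  # mm/ms
    sd_sigma_c: float = 0.05  # mm/ms
    resample_per_activation: bool = True

    def __post_init__(self) -> None:
        if self.mean_mu <= 0:
            raise ValueError("mean conduction velocity must be positive")
        if self.sd_sigma_c < 0:
            raise ValueError("conduction-velocity sd must be nonnegative")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian LAT observation noise, sd in ms."""

    lat_sd_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.lat_sd_sigma < 0:
            raise ValueError("LAT noise sd must be nonnegative")


@dataclass(frozen=True)
class EGMTrace:
    """Multichannel synthetic electrogram."""

    sample_rate: float  # Hz
    signal: np.ndarray  # (n_channels, n_samples) mV
    duration: float  # ms

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.signal.shape[1]) * 1000.0 / self.sample_rate


def generate_activation_schedule(
    n_sources: int,
    n_activations: int,
    rate_jitter: float = 0.2,
    mean_interval_ms: float = 400.0,
    refractory_ms: float = 150.0,
    seed: int = 0,
    locations=None,
    stagger_ms: float | None = None,
) -> list[SourceSpec]:
    """Irregular firing schedules for one or two focal sources.

    Inter-onset intervals are ``mean_interval_ms`` scaled by i.i.d. factors
    ``1 + rate_jitter * U``, U uniform on (−√3, √3) (so the interval
    coefficient of variation ≈ ``rate_jitter``), floored at
    ``refractory_ms``.  Sources are staggered by ``stagger_ms`` (default:
    evenly across one mean interval) so two sources interleave rather than
    fire in lockstep.
    """
    if n_sources not in (1, 2):
        raise ValueError("n_sources must be 1 or 2")
    if n_activations < 1:
        raise ValueError("n_activations must be >= 1")
    if mean_interval_ms * (1 - rate_jitter * np.sqrt(3.0)) < refractory_ms:
        raise ValueError(
            "requested rate/jitter can violate the refractory period: "
            f"shortest interval {mean_interval_ms * (1 - rate_jitter * np.sqrt(3.0)):.1f} ms "
            f"< refractory {refractory_ms} ms"
        )
    rng = np.random.default_rng(seed)
    if stagger_ms is None:
        stagger_ms = mean_interval_ms / n_sources
    if locations is None:
        locations = [np.zeros(3) for _ in range(n_sources)]
    sources = []
    for s in range(n_sources):
        u = rng.uniform(-np.sqrt(3.0), np.sqrt(3.0), size=n_activations)
        intervals = np.maximum(mean_interval_ms * (1.0 + rate_jitter * u), refractory_ms)
        onsets = s * stagger_ms + np.cumsum(intervals)
        sources.append(SourceSpec(locations[s], onsets, label="abnormal" if s == 0 else "normal"))
    return sources


def _distances_to_sensors(source, geodesics, sensor_sites) -> np.ndarray:
    """Per-sensor travel distance for one source.

    ``geodesics`` may be a GeodesicField (mesh mode: ``sensor_sites`` are
    vertex ids) or None (planar mode: Euclidean distance between the
    source's coordinates and the sensor midpoints).
    """
    if geodesics is None:
        sites = np.asarray(sensor_sites, dtype=float)
        return np.linalg.norm(sites - np.asarray(source.location, dtype=float), axis=1)
    d = geodesics.distance_per_vertex[np.asarray(sensor_sites, dtype=int)]
    if np.isinf(d).any():
        raise ValueError("a sensor site is unreachable from the source on the mesh")
    return d


def simulate_lat_matrix(
    sources: list[SourceSpec],
    sensor_sites,
    cv: CVModel,
    noise: NoiseModel,
    seed: int = 0,
    geodesics=None,
    max_truncation_retries: int = 100,
) -> ActivationMatrix:
    """Simulate the LAT table under earliest-arrival wave collision.

    Activation cycles are defined by pooling all source onsets in time
    order and grouping onsets closer than half the median inter-onset gap
    into one cycle (simultaneous firing).  Within a cycle the arrival at
    each sensor is the minimum over firing sources of
    ``onset + distance / CV*``; CV* is drawn once per cycle (one wavefront
    speed per beat) unless ``cv.resample_per_activation`` is False, in
    which case a single draw covers the whole recording.  Gaussian noise
    N(0, σ²) is then added independently per (cycle, sensor).
    """
    if not sources:
        raise ValueError("need at least one source")
    rng = np.random.default_rng(seed)

    dist = np.stack([_distances_to_sensors(s, geodesics if geodesics is None else geodesics[k], sensor_sites) for k, s in enumerate(sources)])

    # pool onsets into activation cycles
    events = sorted((t, k) for k, s in enumerate(sources) for t in s.onset_times)
    all_t = np.array([e[0] for e in events])
    diffs = np.diff(all_t)
    positive = diffs[diffs > 1e-9]  # simultaneous firings contribute no gap
    gap = np.median(positive) if len(positive) else np.inf
    cycles: list[list[tuple[float, int]]] = []
    for t, k in events:
        if cycles and t - cycles[-1][0][0] < 0.5 * gap:
            cycles[-1].append((t, k))
        else:
            cycles.append([(t, k)])

    def draw_cv() -> float:
        for _ in range(max_truncation_retries):
            v = rng.normal(cv.mean_mu, cv.sd_sigma_c)
            if v > 0:
                return v
        raise RuntimeError(
            f"could not draw a positive conduction velocity from N({cv.mean_mu}, {cv.sd_sigma_c}²) "
            f"in {max_truncation_retries} tries"
        )

    global_cv = draw_cv() if not cv.resample_per_activation else None
    n_sensors = len(ALL_PAIR_INDICES)
    lat = np.empty((len(cycles), n_sensors))
    record = np.empty((len(cycles), n_sensors), dtype=int)
    for c, group in enumerate(cycles):
        cv_star = global_cv if global_cv is not None else draw_cv()
        arrivals = np.stack([t0 + dist[k] / cv_star for t0, k in group])  # (n_firing, n_sensors)
        winner = np.argmin(arrivals, axis=0)
        lat[c] = arrivals[winner, np.arange(n_sensors)]
        record[c] = np.array([group[w][1] for w in winner])
    lat += rng.normal(0.0, noise.lat_sd_sigma, size=lat.shape)
    return ActivationMatrix(lat, source_of_record=record)


def _biphasic_template(width_ms: float, sample_rate: float) -> np.ndarray:
    """Default pulse: Hann-windowed sine cycle.

    The window damps the edges so the steepest swing — the feature the
    LAT extractor keys on — is the central positive-to-negative zero
    crossing, at the pulse centre.
    """
    n = max(int(round(width_ms * sample_rate / 1000.0)), 4)
    t = np.linspace(0.0, 1.0, n, endpoint=False)
    pulse = np.sin(2.0 * np.pi * t) * 0.5 * (1.0 - np.cos(2.0 * np.pi * t))
    return pulse / np.abs(pulse).max()  # unit peak amplitude, so snr is amplitude-true


def synthesize_egm_traces(
    matrix: ActivationMatrix,
    sample_rate: float = 1000.0,
    snr: float = 20.0,
    pulse_width_ms: float = 20.0,
    template: np.ndarray | None = None,
    seed: int = 0,
    pad_ms: float = 50.0,
) -> EGMTrace:
    """Toy electrogram: template pulses centred at each channel's LATs plus
    white noise with the requested amplitude SNR (``snr=np.inf`` → clean)."""
    if template is None:
        template = _biphasic_template(pulse_width_ms, sample_rate)
    template = np.asarray(template, dtype=float)
    gaps = np.diff(np.sort(matrix.lat, axis=0), axis=0)
    if gaps.size and gaps.min() < pulse_width_ms:
        warnings.warn("activation spacing is below the pulse width; pulses overlap", stacklevel=2)
    duration = float(matrix.lat.max() + pad_ms)
    n_samples = int(round(duration * sample_rate / 1000.0)) + len(template)
    rng = np.random.default_rng(seed)
    n_channels = matrix.lat.shape[1]
    sig = np.zeros((n_channels, n_samples))
    half = len(template) // 2
    for ch in range(n_channels):
        for t_ms in matrix.lat[:, ch]:
            c = int(round(t_ms * sample_rate / 1000.0))
            lo = c - half
            sig[ch, lo : lo + len(template)] += template
    if np.isfinite(snr) and snr > 0:
        sig += rng.normal(0.0, 1.0 / snr, size=sig.shape)
    return EGMTrace(sample_rate=sample_rate, signal=sig, duration=duration)


def extract_lat(
    trace: EGMTrace,
    activation_windows: list[tuple[float, float]],
    smooth_samples: int = 3,
) -> ActivationMatrix:
    """LAT = time of maximum absolute first difference, per window and channel.

    The first difference is smoothed with a short centred moving average
    (``smooth_samples`` wide; 1 disables it) before taking the argmax —
    white measurement noise differentiates into spikes that would
    otherwise outvote the true activation slope.

    A window whose signal is flat on some channel yields NaN there and a
    warning; rows containing NaN are dropped from the returned matrix (a
    flat channel means no activation was observed in that window).
    """
    if not activation_windows:
        raise ValueError("need at least one activation window")
    starts = np.array([w[0] for w in activation_windows])
    ends = np.array([w[1] for w in activation_windows])
    if np.any(ends <= starts):
        raise ValueError("each window must satisfy start < end")
    order = np.argsort(starts)
    if np.any(ends[order][:-1] > starts[order][1:]):
        raise ValueError("activation windows must not overlap")
    t_ms = trace.times_ms
    rows = []
    keep = []
    for w, (a, b) in enumerate(activation_windows):
        mask = (t_ms >= a) & (t_ms <= b)
        idx = np.nonzero(mask)[0]
        if len(idx) < 2:
            raise ValueError(f"window ({a}, {b}) ms contains fewer than two samples")
        seg = trace.signal[:, idx]
        d = np.diff(seg, axis=1)
        if smooth_samples > 1 and d.shape[1] >= smooth_samples:
            kernel = np.ones(smooth_samples) / smooth_samples
            d = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, d)
        d = np.abs(d)
        row = np.empty(trace.signal.shape[0])
        flat = d.max(axis=1) <= 1e-12
        best = np.argmax(d, axis=1)
        # midpoint of the step between samples k and k+1
        row[:] = 0.5 * (t_ms[idx[best]] + t_ms[idx[np.minimum(best + 1, len(idx) - 1)]])
        if flat.any():
            warnings.warn(f"flat signal in window {w}: channels {np.nonzero(flat)[0].tolist()} flagged missing", stacklevel=2)
            row[flat] = np.nan
        rows.append(row)
        keep.append(not np.isnan(row).any())
    lat = np.stack(rows)
    lat = lat[np.array(keep, dtype=bool)]
    if len(lat) == 0:
        raise ValueError("no window produced a complete set of channel activations")
    return ActivationMatrix(lat)


def segment_activations(
    trace: EGMTrace,
    gap_ms: float = 100.0,
    amp_threshold: float = 0.2,
    min_duration_ms: float = 5.0,
) -> list[tuple[float, float]]:
    """Split a trace into activation windows at quiescent gaps.

    A sample is quiescent when every channel's |signal| is below
    ``amp_threshold``; runs of quiescence at least ``gap_ms`` long separate
    consecutive windows.  Active runs shorter than ``min_duration_ms``
    (isolated noise spikes, not activations) are discarded.
    """
    active = (np.abs(trace.signal) >= amp_threshold).any(axis=0)
    t_ms = trace.times_ms
    if not active.any():
        return []
    idx = np.nonzero(active)[0]
    breaks = np.nonzero(np.diff(t_ms[idx]) >= gap_ms)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    dt = 1000.0 / trace.sample_rate
    return [
        (t_ms[s] - dt, t_ms[e] + dt)
        for s, e in zip(starts, ends)
        if t_ms[e] - t_ms[s] >= min_duration_ms
    ]
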