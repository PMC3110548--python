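"""Synthetic rat cardiovascular data with known ground truth.

Every downstream stage of the pipeline (beat detection, AR spectral
analysis, factorial statistics) is exercised on data from this module, so
that the whole analysis is testable without animal recordings.  Three
layers are generated:

* beat series — tachograms/systograms in which the pulse interval and the
  per-beat systolic pressure carry additive LF and HF sinusoidal
  oscillations plus white Gaussian noise.  A sinusoid of amplitude ``A``
  contributes a band power of ``A**2 / 2``, so the spectral stage has an
  analytic ground truth;
* pressure waveforms — a pulsatile trace built from a beat series (linear
  systolic upstroke, exponential diastolic decay), sampled at 2 kHz by
  default, whose per-beat extrema equal the beat-series values;
* cohorts — a 2x2 factorial design (diabetes x renal denervation) of
  per-animal scalar outcomes drawn from per-group Gaussian distributions
  (log-normal for urinary albumin), with an attached beat series per
  animal.

The shipped default design parameterizes the four groups of a
streptozotocin-diabetic spontaneously hypertensive rat study (SHR, RD-SHR,
STZ-SHR, RD-STZ-SHR) with group sizes 7/6/6/5.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beats import BeatSeries, Waveform

logger = logging.getLogger("ratvar")

#: floor applied to non-positive pulse-interval draws (ms)
PI_CLIP_MS = 10.0
#: minimum systolic-diastolic separation enforced per beat (mmHg)
MIN_PULSE_PRESSURE = 1.0
#: glycemia threshold (mg/dL) defining successful diabetes induction
DIABETES_GLYCEMIA_THRESHOLD = 300.0
#: systolic upstroke duration in the simulated waveform (s)
RISE_TIME_S = 0.025
#: duration assumed for a single-beat waveform (s)
SINGLE_BEAT_DURATION_S = 0.2


@dataclass(frozen=True)
class BeatSpec:
    """Parameters of one simulated beat series.

    Pulse intervals follow
    ``PI_k = mean_pi + lf_amp*sin(2*pi*lf_freq*t_k)
    + hf_amp*sin(2*pi*hf_freq*t_k + phi) + noise`` with beat times ``t_k``
    accumulated from the successive PIs, and the systolic pressure series is
    built the same way around ``sap_mean``.  The HF phase ``phi`` is drawn
    once per series from the seeded generator.
    """

    mean_pi: float  # ms
    lf_freq: float = 0.45  # Hz
    lf_amp: float = 0.0  # ms
    hf_freq: float = 1.5  # Hz
    hf_amp: float = 0.0  # ms
    noise_sd: float = 0.0  # ms
    sap_mean: float = 160.0  # mmHg
    dap_mean: float = 120.0  # mmHg
    sap_lf_amp: float = 0.0  # mmHg
    sap_hf_amp: float = 0.0  # mmHg
    sap_noise_sd: float = 0.0  # mmHg
    n_beats: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_pi <= 0:
            raise ValueError("mean_pi must be positive")
        if not (0 < self.lf_freq < self.hf_freq):
            raise ValueError("need 0 < lf_freq < hf_freq")
        for name in ("lf_amp", "hf_amp", "noise_sd", "sap_lf_amp",
                     "sap_hf_amp", "sap_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sap_mean <= self.dap_mean:
            raise ValueError("sap_mean must exceed dap_mean")
        if self.n_beats < 1:
            raise ValueError("n_beats must be at least 1")


def simulate_beat_series(spec: BeatSpec,
                         rng: np.random.Generator | None = None) -> BeatSeries:
    """Generate a beat series from a :class:`BeatSpec`.

    Identical spec (including seed) gives identical output.  Pulse-interval
    draws that come out non-positive are clipped at 10 ms and a warning is
    logged; systolic draws that fall to or below the diastolic level are
    clipped just above it.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_beats
    phi_pi = rng.uniform(0.0, 2.0 * np.pi)
    phi_sap = rng.uniform(0.0, 2.0 * np.pi)
    pi_noise = rng.normal(0.0, spec.noise_sd, size=max(n - 1, 0)) \
        if spec.noise_sd > 0 else np.zeros(max(n - 1, 0))
    sap_noise = rng.normal(0.0, spec.sap_noise_sd, size=n) \
        if spec.sap_noise_sd > 0 else np.zeros(n)

    beat_times = np.empty(n)
    beat_times[0] = 0.0
    n_clipped = 0
    for k in range(n - 1):
        t_k = beat_times[k]
        pi_k = (spec.mean_pi
                + spec.lf_amp * np.sin(2.0 * np.pi * spec.lf_freq * t_k)
                + spec.hf_amp * np.sin(2.0 * np.pi * spec.hf_freq * t_k + phi_pi)
                + pi_noise[k])
        if pi_k <= 0:
            pi_k = PI_CLIP_MS
            n_clipped += 1
        beat_times[k + 1] = t_k + pi_k / 1000.0
    if n_clipped:
        logger.warning("clipped %d non-positive pulse intervals at %.0f ms",
                       n_clipped, PI_CLIP_MS)

    sap = (spec.sap_mean
           + spec.sap_lf_amp * np.sin(2.0 * np.pi * spec.lf_freq * beat_times)
           + spec.sap_hf_amp * np.sin(2.0 * np.pi * spec.hf_freq * beat_times
                                      + phi_sap)
           + sap_noise)
    dap = np.full(n, spec.dap_mean)
    low = dap + MIN_PULSE_PRESSURE
    if np.any(sap < low):
        logger.warning("clipped %d systolic values at DAP + %.0f mmHg",
                       int(np.sum(sap < low)), MIN_PULSE_PRESSURE)
        sap = np.maximum(sap, low)
    return BeatSeries(beat_times=beat_times, sap=sap, dap=dap)


def simulate_bp_waveform(beats: BeatSeries, sampling_rate: float = 2000.0) -> Waveform:
    """Render a beat series as a pulsatile arterial-pressure waveform.

    Each beat peaks at its systolic value exactly at its beat time, decays
    exponentially to its diastolic value, then rises linearly into the next
    beat's systolic peak over a 25 ms upstroke.  Per-beat extrema therefore
    match the beat series within one sample's interpolation error.  The last
    beat reuses the preceding pulse interval as its duration (a fixed
    duration for single-beat input).
    """
    if sampling_rate < 100.0:
        raise ValueError("sampling_rate must be at least 100 Hz")
    t_beats = beats.beat_times
    n = t_beats.size
    if np.any(np.diff(t_beats) <= 0):
        raise ValueError("beat times must be strictly increasing")
    durations = np.diff(t_beats)
    last = durations[-1] if n > 1 else SINGLE_BEAT_DURATION_S
    durations = np.append(durations, last)

    t_end = t_beats[-1] + durations[-1]
    n_samples = int(np.floor((t_end - t_beats[0]) * sampling_rate)) + 1
    t = t_beats[0] + np.arange(n_samples) / sampling_rate

    # which beat each sample belongs to
    idx = np.searchsorted(t_beats, t, side="right") - 1
    idx = np.clip(idx, 0, n - 1)
    u = t - t_beats[idx]
    dur = durations[idx]
    rise = np.minimum(RISE_TIME_S, 0.3 * dur)
    decay_span = dur - rise

    sap_k = beats.sap[idx]
    dap_k = beats.dap[idx]
    # exponential decay normalized to land exactly on DAP at the end of the
    # decay span; alpha controls the waveform convexity only
    alpha = 4.0
    v = np.clip(u / decay_span, 0.0, 1.0)
    decay = dap_k + (sap_k - dap_k) * (np.exp(-alpha * v) - np.exp(-alpha)) \
        / (1.0 - np.exp(-alpha))

    # upstroke toward the NEXT beat's systolic value
    next_sap = np.append(beats.sap[1:], beats.sap[-1])
    w = (u - decay_span) / rise
    upstroke = dap_k + (next_sap[idx] - dap_k) * np.clip(w, 0.0, 1.0)

    in_rise = (u > decay_span) & (idx < n - 1)
    samples = np.where(in_rise, upstroke, decay)
    return Waveform(samples=samples, sampling_rate=sampling_rate,
                    start_time=t_beats[0])


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlbuminSpec:
    """Log-normal urinary-albumin distribution given as median [lo-hi].

    The bracketed interval of the source summaries is ambiguous, so both
    readings are supported: ``interpretation='iqr'`` treats (lo, hi) as
    quartiles, ``'minmax'`` as an approximate full range (+-2 sigma on the
    log scale).  Moments are matched on the log scale.
    """

    median: float
    lower: float
    upper: float
    interpretation: str = "iqr"

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.median <= self.upper):
            raise ValueError("need 0 < lower <= median <= upper")
        if self.interpretation not in ("iqr", "minmax"):
            raise ValueError("interpretation must be 'iqr' or 'minmax'")

    @property
    def mu(self) -> float:
        return float(np.log(self.median))

    @property
    def sigma(self) -> float:
        span = np.log(self.upper) - np.log(self.lower)
        if self.interpretation == "iqr":
            return float(span / (2.0 * 0.6744897501960817))  # quartile z
        return float(span / 4.0)  # +-2 sigma covers the range


@dataclass
class GroupSpec:
    """One cell of the 2x2 design: factor levels, size, outcome distributions."""

    label: str
    diabetes: bool
    denervation: bool
    n_animals: int
    outcomes: dict[str, tuple[float, float]]  # name -> (mean, sd)
    albumin: AlbuminSpec | None = None
    beat_spec: BeatSpec | None = None
    hr_sd: float = 0.0  # bpm, between-animal spread of mean heart rate
    sap_sd: float = 0.0  # mmHg, between-animal spread of mean SAP
    dap_sd: float = 0.0  # mmHg, between-animal spread of mean DAP

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("each group needs at least 2 animals")
        for name, (_, sd) in self.outcomes.items():
            if sd < 0:
                raise ValueError(f"negative SD for outcome {name!r}")
        for name in ("hr_sd", "sap_sd", "dap_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CohortDesign:
    """Full 2x2 cohort: exactly four groups spanning the factor grid."""

    groups: list[GroupSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) != 4:
            raise ValueError("a 2x2 design needs exactly 4 groups")
        cells = {(g.diabetes, g.denervation) for g in self.groups}
        if len(cells) != 4:
            raise ValueError("groups must span the diabetes x denervation grid")


@dataclass
class AnimalRecord:
    """One simulated animal: factor levels, scalar outcomes, beat series."""

    id: str
    group: str
    diabetes: bool
    denervation: bool
    outcomes: dict[str, float]
    beats: BeatSeries | None = None


def simulate_cohort(design: CohortDesign, *,
                    include_beats: bool = True) -> list[AnimalRecord]:
    """Draw a cohort of animals from a :class:`CohortDesign`.

    Scalar outcomes are Gaussian per group (urinary albumin log-normal).
    For diabetic groups the initial glycemia is drawn truncated above the
    300 mg/dL induction threshold: the design describes the cohort that
    passed inclusion, so :func:`apply_inclusion` on the result is a no-op.
    Non-negative-by-definition outcomes are floored at zero.  When
    ``include_beats`` is true each animal also gets a simulated beat series
    whose mean PI, SAP and DAP are drawn around the group's hemodynamic
    means.  Fully reproducible under ``design.seed``.
    """
    records: list[AnimalRecord] = []
    for g_idx, group in enumerate(design.groups):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=design.seed, spawn_key=(g_idx,)))
        n = group.n_animals
        draws: dict[str, np.ndarray] = {}
        for name in sorted(group.outcomes):
            mean, sd = group.outcomes[name]
            values = rng.normal(mean, sd, n) if sd > 0 else np.full(n, mean)
            if group.diabetes and name == "glycemia_initial_mg_dl":
                # inclusion-conditioned draw: glycemia > threshold
                for _ in range(1000):
                    mask = values <= DIABETES_GLYCEMIA_THRESHOLD
                    if not mask.any():
                        break
                    values[mask] = rng.normal(mean, sd, int(mask.sum()))
                values = np.maximum(values, DIABETES_GLYCEMIA_THRESHOLD + 1e-6)
            draws[name] = np.maximum(values, 0.0)
        if group.albumin is not None:
            draws["urinary_albumin_mg_24h"] = rng.lognormal(
                group.albumin.mu, group.albumin.sigma, n)

        specs: list[BeatSpec | None] = [None] * n
        if group.beat_spec is not None:
            base = group.beat_spec
            hr0 = 60000.0 / base.mean_pi
            hr = rng.normal(hr0, group.hr_sd, n) if group.hr_sd > 0 \
                else np.full(n, hr0)
            hr = np.maximum(hr, 60.0)
            sap = rng.normal(base.sap_mean, group.sap_sd, n) \
                if group.sap_sd > 0 else np.full(n, base.sap_mean)
            dap = rng.normal(base.dap_mean, group.dap_sd, n) \
                if group.dap_sd > 0 else np.full(n, base.dap_mean)
            # independent SAP/DAP draws can collapse the pulse pressure;
            # keep room for the systolic oscillations plus noise
            min_pp = (base.sap_lf_amp + base.sap_hf_amp
                      + 3.0 * base.sap_noise_sd + 5.0)
            dap = np.where(sap - dap < min_pp, sap - min_pp, dap)
            draws.setdefault("hr_bpm", hr)
            for a_idx in range(n):
                specs[a_idx] = BeatSpec(
                    mean_pi=60000.0 / hr[a_idx], lf_freq=base.lf_freq,
                    lf_amp=base.lf_amp, hf_freq=base.hf_freq,
                    hf_amp=base.hf_amp, noise_sd=base.noise_sd,
                    sap_mean=float(sap[a_idx]), dap_mean=float(dap[a_idx]),
                    sap_lf_amp=base.sap_lf_amp, sap_hf_amp=base.sap_hf_amp,
                    sap_noise_sd=base.sap_noise_sd, n_beats=base.n_beats,
                    seed=base.seed)

        for a_idx in range(n):
            outcomes = {name: float(vals[a_idx])
                        for name, vals in draws.items()}
            beats = None
            if include_beats and specs[a_idx] is not None:
                beats = simulate_beat_series(specs[a_idx], rng=rng)
            records.append(AnimalRecord(
                id=f"{group.label}-{a_idx + 1:02d}", group=group.label,
                diabetes=group.diabetes, denervation=group.denervation,
                outcomes=outcomes, beats=beats))
    return records


def apply_inclusion(records: list[AnimalRecord],
                    glycemia_key: str = "glycemia_initial_mg_dl",
                    threshold: float = DIABETES_GLYCEMIA_THRESHOLD,
                    ) -> list[AnimalRecord]:
    """Apply the diabetes-induction inclusion rule.

    Diabetic-group animals whose glycemia is not strictly above the
    threshold (300 mg/dL by default) are excluded; non-diabetic animals
    pass unconditionally.  The exclusion count is logged.  Idempotent.
    """
    kept: list[AnimalRecord] = []
    excluded = 0
    for rec in records:
        if rec.diabetes and rec.outcomes.get(glycemia_key, np.inf) <= threshold:
            excluded += 1
            continue
        kept.append(rec)
    if excluded:
        logger.info("inclusion rule excluded %d diabetic animals "
                    "(glycemia <= %g mg/dL)", excluded, threshold)
    return kept


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def cohort_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    """Per-animal table: one row per animal, outcome columns."""
    rows = []
    for rec in records:
        row = {"animal_id": rec.id, "group": rec.group,
               "diabetes": rec.diabetes, "denervation": rec.denervation}
        row.update(rec.outcomes)
        rows.append(row)
    return pd.DataFrame(rows)


def beats_frame(beats: BeatSeries) -> pd.DataFrame:
    """Per-beat table with the interval following each beat (last is NaN)."""
    pi = np.append(beats.pi, np.nan)
    return pd.DataFrame({
        "beat_time_s": beats.beat_times,
        "pi_ms": pi,
        "sap_mmHg": beats.sap,
        "dap_mmHg": beats.dap,
    })


def beats_from_frame(df: pd.DataFrame) -> BeatSeries:
    """Inverse of :func:`beats_frame` (the trailing NaN PI is dropped)."""
    return BeatSeries(beat_times=df["beat_time_s"].to_numpy(),
                      sap=df["sap_mmHg"].to_numpy(),
                      dap=df["dap_mmHg"].to_numpy())


# ---------------------------------------------------------------------------
# default design
# ---------------------------------------------------------------------------

def _group_from_dict(label: str, d: dict) -> GroupSpec:
    outcomes = {name: (float(v["mean"]), float(v["sd"]))
                for name, v in d.get("outcomes", {}).items()}
    albumin = None
    if "albumin_mg_24h" in d:
        a = d["albumin_mg_24h"]
        albumin = AlbuminSpec(median=float(a["median"]),
                              lower=float(a["lower"]),
                              upper=float(a["upper"]),
                              interpretation=a.get("interpretation", "iqr"))
    beat_spec = None
    hr_sd = sap_sd = dap_sd = 0.0
    if "cardio" in d:
        c = d["cardio"]
        hr = c["hr_bpm"]
        sap = c["sap_mmhg"]
        dap = c["dap_mmhg"]
        beat_spec = BeatSpec(
            mean_pi=60000.0 / float(hr["mean"]),
            lf_freq=float(c["pi_lf"]["freq_hz"]),
            lf_amp=float(c["pi_lf"]["amp_ms"]),
            hf_freq=float(c["pi_hf"]["freq_hz"]),
            hf_amp=float(c["pi_hf"]["amp_ms"]),
            noise_sd=float(c["pi_noise_sd_ms"]),
            sap_mean=float(sap["mean"]), dap_mean=float(dap["mean"]),
            sap_lf_amp=float(c["sap_lf"]["amp_mmhg"]),
            sap_hf_amp=float(c["sap_hf"]["amp_mmhg"]),
            sap_noise_sd=float(c["sap_noise_sd_mmhg"]),
            n_beats=int(c.get("n_beats", 1000)))
        hr_sd, sap_sd, dap_sd = (float(hr["sd"]), float(sap["sd"]),
                                 float(dap["sd"]))
    return GroupSpec(label=label, diabetes=bool(d["diabetes"]),
                     denervation=bool(d["denervation"]),
                     n_animals=int(d["n_animals"]), outcomes=outcomes,
                     albumin=albumin, beat_spec=beat_spec,
                     hr_sd=hr_sd, sap_sd=sap_sd, dap_sd=dap_sd)


def design_from_dict(d: dict) -> CohortDesign:
    groups = [_group_from_dict(label, spec) for label, spec in
              d["groups"].items()]
    return CohortDesign(groups=groups, seed=int(d.get("seed", 0)))


def load_design(path: str | Path) -> CohortDesign:
    """Read a cohort design from a YAML file."""
    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


def default_design_dict() -> dict:
    """The shipped default cohort parameterization as a plain dict."""
    text = importlib.resources.files("ratvar").joinpath(
        "data/default_cohort.yaml").read_text()
    return yaml.safe_load(text)


def default_design(seed: int | None = None) -> CohortDesign:
    """The shipped default 2x2 SHR/STZ design (group sizes 7/6/6/5)."""
    d = default_design_dict()
    if seed is not None:
        d["seed"] = seed
    return design_from_dict(d)
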