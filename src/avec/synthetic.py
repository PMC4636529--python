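"""Synthetic canine RR-interval generator with labeled artifacts.

Dog heart rate at rest shows a pronounced respiratory sinus arrhythmia
(RSA): HR rises and falls with each breath, producing large natural
beat-to-beat swings that naive outlier filters mistake for error.  The
generator emulates this with a sinusoid in bpm space driven by real elapsed
time plus Gaussian beat noise:

    hr_i = baseline + A·sin(2π·f_resp·t_i + φ) + ε_i,   ε_i ~ N(0, σ²),

where t_i is the cumulative RR time up to beat i, so the breathing cycle
unfolds in seconds, not beats.  Values are clipped to the Polar device
range [15, 240] bpm.

Transmission artifacts are injected on top with ground-truth labels:

* ``spike`` — a beat replaced by baseline ± magnitude (electrode contact
  loss producing an isolated extreme value);
* ``missed_beat`` — two adjacent RR intervals merged into one (a beat the
  receiver never saw: RR ≈ doubled, series one beat shorter);
* ``extra_beat`` — one RR interval split in two (a spuriously registered
  beat: RR ≈ halved, series one beat longer).

Everything is a pure function of (config, seed): identical inputs give
identical output series and labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .io import write_csv, write_hrm
from .series import POLAR_DEVICE_RANGE, BeatSeries

__all__ = [
    "ArtifactSpec",
    "SyntheticConfig",
    "ArtifactLabel",
    "LabeledSeries",
    "generate_clean",
    "inject_artifacts",
    "generate_labeled",
    "write_fixture_files",
]

_ARTIFACT_TYPES = ("spike", "missed_beat", "extra_beat")


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact population: kind, per-beat rate, and magnitude.

    ``magnitude`` is in bpm for spikes and is ignored for missed/extra
    beats (their size is fixed by the merge/split mechanism).
    """

    kind: str
    rate: float
    magnitude: float = 60.0

    def __post_init__(self) -> None:
        if self.kind not in _ARTIFACT_TYPES:
            raise ValueError(f"kind must be one of {_ARTIFACT_TYPES}")
        if not 0.0 <= self.rate <= 0.1:
            raise ValueError(f"rate must be in [0, 0.1], got {self.rate}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be nonnegative")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic canine recording.

    Defaults describe a resting medium-size dog: baseline 90 bpm, RSA swing
    ±15 bpm at a 0.4 Hz breathing rate, 3 bpm beat-to-beat noise.
    """

    n_beats: int = 2000
    baseline_hr: float = 90.0
    rsa_amplitude: float = 15.0
    resp_freq: float = 0.4
    resp_phase: float = 0.0
    noise_sd: float = 3.0
    artifacts: Tuple[ArtifactSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beats < 1:
            raise ValueError("n_beats must be positive")
        for p, name in (
            (self.baseline_hr, "baseline_hr"),
            (self.resp_freq, "resp_freq"),
        ):
            if p <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rsa_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("rsa_amplitude and noise_sd must be nonnegative")
        object.__setattr__(self, "artifacts", tuple(self.artifacts))
        lo, hi = POLAR_DEVICE_RANGE
        if (
            self.baseline_hr - self.rsa_amplitude <= lo
            or self.baseline_hr + self.rsa_amplitude >= hi
        ):
            warnings.warn(
                "RSA swing reaches the device range; values will be clipped",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ArtifactLabel:
    index: int  # beat index in the OUTPUT (artifact-bearing) series
    kind: str


@dataclass(frozen=True)
class LabeledSeries:
    """An artifact-bearing series plus its ground truth and clean source."""

    series: BeatSeries
    truth: Tuple[ArtifactLabel, ...]
    clean: BeatSeries

    @property
    def truth_indices(self) -> Tuple[int, ...]:
        return tuple(lbl.index for lbl in self.truth)


def generate_clean(config: SyntheticConfig) -> BeatSeries:
    """Generate an artifact-free RSA series in bpm.

    The beat clock advances by each generated RR interval, so the sinusoid
    completes one cycle per 1/resp_freq seconds of simulated time.
    """
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, config.noise_sd, size=config.n_beats)
    lo, hi = POLAR_DEVICE_RANGE
    omega = 2.0 * np.pi * config.resp_freq
    values = np.empty(config.n_beats)
    t = 0.0
    for i in range(config.n_beats):
        hr = (
            config.baseline_hr
            + config.rsa_amplitude * np.sin(omega * t + config.resp_phase)
            + noise[i]
        )
        hr = min(max(hr, lo), hi)
        values[i] = hr
        t += 60.0 / hr  # RR interval in seconds
    return BeatSeries(
        values=values,
        unit="bpm",
        label=f"synthetic-seed{config.seed}",
        device_range=POLAR_DEVICE_RANGE,
    )


def _draw_positions(
    rng: np.random.Generator,
    counts: Sequence[int],
    n: int,
    margin: int = 21,
    min_gap: int = 2,
    max_tries: int = 1000,
) -> List[np.ndarray]:
    """Draw pairwise-disjoint artifact positions, redrawing on collision."""
    total = int(sum(counts))
    eligible = np.arange(margin, n - margin)
    if total * min_gap > eligible.size:
        raise ValueError(
            f"cannot place {total} disjoint artifacts in {n} beats; lower the rates"
        )
    for _ in range(max_tries):
        pos = np.sort(rng.choice(eligible, size=total, replace=False))
        if total < 2 or np.all(np.diff(pos) >= min_gap):
            shuffled = rng.permutation(pos)
            out, start = [], 0
            for c in counts:
                out.append(np.sort(shuffled[start : start + c]))
                start += c
            return out
    raise ValueError(
        "could not place disjoint artifact positions; rates are too high"
    )


def inject_artifacts(
    series: BeatSeries,
    artifacts: Sequence[ArtifactSpec],
    seed: int = 0,
) -> LabeledSeries:
    """Inject labeled transmission artifacts into a clean bpm series.

    Artifact counts are Binomial(n, rate) draws under the given seed;
    positions are uniform, pairwise disjoint (at least two beats apart, so
    a merge never consumes another artifact's beat), and away from the
    series ends.  ``truth`` records every altered beat index of the output
    series; for an extra-beat split both half-beats are labeled.
    """
    clean = series.to("bpm")
    n = len(clean)
    rng = np.random.default_rng(seed)
    specs = list(artifacts)
    counts = [int(rng.binomial(n, s.rate)) for s in specs]
    if sum(counts) == 0:
        return LabeledSeries(series=clean, truth=(), clean=clean)
    positions = _draw_positions(rng, counts, n)
    baseline = float(np.median(clean.values))
    lo, hi = POLAR_DEVICE_RANGE

    # per-input-beat actions, then one forward pass building the output
    actions = {}
    for spec, pos in zip(specs, positions):
        for p in pos:
            if spec.kind == "spike":
                sign = 1.0 if rng.random() < 0.5 else -1.0
                actions[int(p)] = ("spike", min(max(baseline + sign * spec.magnitude, lo), hi))
            else:
                actions[int(p)] = (spec.kind, None)

    rr = 60000.0 / clean.values  # work in ms for merges and splits
    out: List[float] = []
    labels: List[ArtifactLabel] = []
    i = 0
    while i < n:
        act = actions.get(i)
        if act is None:
            out.append(rr[i])
            i += 1
        elif act[0] == "spike":
            labels.append(ArtifactLabel(index=len(out), kind="spike"))
            out.append(60000.0 / act[1])
            i += 1
        elif act[0] == "missed_beat":
            labels.append(ArtifactLabel(index=len(out), kind="missed_beat"))
            out.append(rr[i] + rr[i + 1])  # receiver missed the beat between
            i += 2
        else:  # extra_beat: split one interval into two halves
            labels.append(ArtifactLabel(index=len(out), kind="extra_beat"))
            labels.append(ArtifactLabel(index=len(out) + 1, kind="extra_beat"))
            out.append(rr[i] / 2.0)
            out.append(rr[i] / 2.0)
            i += 1
    bpm_out = 60000.0 / np.asarray(out)
    noisy = BeatSeries(
        values=bpm_out,
        unit="bpm",
        label=clean.label,
        device_range=None,  # merges can fall below 15 bpm equivalent
    )
    labels.sort(key=lambda l: l.index)
    return LabeledSeries(series=noisy, truth=tuple(labels), clean=clean)


def generate_labeled(config: SyntheticConfig) -> LabeledSeries:
    """Generate a clean RSA series and inject the configured artifacts."""
    clean = generate_clean(config)
    # derive an independent stream for artifact placement from the same seed
    return inject_artifacts(clean, config.artifacts, seed=config.seed + 1_000_003)


def write_fixture_files(labeled: LabeledSeries, outdir: Path) -> dict:
    """Write series CSV + HRM and a truth CSV (index, type) for test use."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "csv": outdir / "series.csv",
        "hrm": outdir / "series.hrm",
        "clean_csv": outdir / "clean.csv",
        "truth": outdir / "truth.csv",
    }
    write_csv(labeled.series, paths["csv"])
    write_hrm(labeled.series, paths["hrm"])
    write_csv(labeled.clean, paths["clean_csv"])
    with paths["truth"].open("w") as fh:
        fh.write("index,type\n")
        for lbl in labeled.truth:
            fh.write(f"{lbl.index},{lbl.kind}\n")
    return paths
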