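"""Synthetic cohort generation for pulse-wave LVE studies.

Real upper-arm pulse recordings paired with echocardiographic left
ventricular measurements are not publicly deposited, so every downstream
stage of this package is exercised on synthetic cohorts whose statistical
structure mirrors the clinical study design: two heart-failure groups
(non-LVE and LVE) whose single-cycle waveforms are low-order Fourier sums
with group-specific harmonic-power distributions, multi-cycle recordings
with cycle-length jitter, additive noise and respiratory-like baseline
wander, and per-subject anthropometrics from which the left ventricular
diastolic diameter index (LVDdI, mm/m^2) is derived.

The generator records ground truth (cycle boundaries, per-order harmonic
powers, group membership) so that recovery of these quantities by the
analysis pipeline can be tested quantitatively.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

__all__ = [
    "GeneratorConfig",
    "PulseRecording",
    "LVDDI_THRESHOLDS",
    "synthesize_cycle",
    "generate_cohort",
    "paper_flow_fixture",
    "PAPER_FLOW_SEED",
]

# Sex-specific LVDdI thresholds (mm/m^2); LVE is a strict exceedance.
LVDDI_THRESHOLDS = {"male": 36.0, "female": 37.0}

# Per-group harmonic-power distributions (orders 1..3), mean and SD, as
# observed between the clinical non-LVE and LVE groups.
_DEFAULT_POWER_MEANS = {
    "non_lve": (3.11, 0.61, 0.13),
    "lve": (2.92, 0.69, 0.12),
}
_DEFAULT_POWER_SDS = {
    "non_lve": (0.65, 0.21, 0.10),
    "lve": (0.74, 0.35, 0.09),
}

# Per-group, per-sex LVDdI (mean, sd) in mm/m^2. Non-LVE means sit below
# the sex thresholds, LVE means above; draws are truncated at the
# threshold so the generated group membership and the threshold label
# always agree.
_DEFAULT_LVDDI_PARAMS = {
    "non_lve": {"male": (30.0, 3.0), "female": (31.0, 3.0)},
    "lve": {"male": (42.0, 4.0), "female": (43.0, 4.0)},
}

# Height (cm) / weight (kg) normals per sex — generic adult HF cohort.
_ANTHROPOMETRICS = {
    "male": {"height": (170.0, 7.0), "weight": (70.0, 12.0)},
    "female": {"height": (157.0, 6.0), "weight": (58.0, 10.0)},
}

# Built-in deterministic LVDdI map used for parameter-recovery studies:
# lvddi = intercept + c1 * power_1 + c2 * power_2. See GeneratorConfig.
_DETERMINISTIC_LVDDI_COEF = (5.0, 8.0, 10.0)


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic cohort.

    ``harmonic_power_means``/``sds`` give, per group, the (order-1,
    order-2, order-3) harmonic-power normal distributions in the
    pre-normalization amplitude units of the waveform. ``lvddi_params``
    gives per-group, per-sex (mean, sd) of LVDdI in mm/m^2.

    ``deterministic_lvddi`` replaces the stochastic LVDdI draw with a
    fixed linear function of the subject's true harmonic powers
    (``lvddi = 5 + 8*p1 + 10*p2``); used for identifiability studies
    where the regression target must be a known function of the
    waveform, at the cost of clinical realism of the group labels.
    """

    n_non_lve: int = 137
    n_lve: int = 90
    harmonic_power_means: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_POWER_MEANS))
    harmonic_power_sds: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_POWER_SDS))
    cycles_per_subject: int = 8
    samples_per_cycle_raw: int = 125
    sampling_rate_hz: float = 125.0
    cycle_jitter_fraction: float = 0.05
    noise_sd: float = 0.35
    baseline_wander_amplitude: float = 0.5
    incomplete_fraction: float = 0.0
    lvddi_params: dict = field(
        default_factory=lambda: copy.deepcopy(_DEFAULT_LVDDI_PARAMS))
    male_fraction: float = 0.55
    deterministic_lvddi: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_non_lve <= 0 or self.n_lve <= 0:
            raise ValueError("group sizes must be positive")
        if self.cycles_per_subject <= 0 or self.samples_per_cycle_raw <= 0:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.cycle_jitter_fraction <= 0.2):
            raise ValueError("cycle_jitter_fraction must be in [0, 0.2]")
        if self.noise_sd < 0 or self.baseline_wander_amplitude < 0:
            raise ValueError("noise levels must be non-negative")
        if not (0.0 <= self.incomplete_fraction < 1.0):
            raise ValueError("incomplete_fraction must be in [0, 1)")
        for group in ("non_lve", "lve"):
            sds = self.harmonic_power_sds[group]
            if any(s < 0 for s in sds):
                raise ValueError("harmonic power SDs must be non-negative")
            for sex, (mean, sd) in self.lvddi_params[group].items():
                if sd < 0:
                    raise ValueError("LVDdI SDs must be non-negative")
                thr = LVDDI_THRESHOLDS[sex]
                if group == "lve" and mean <= thr:
                    raise ValueError(
                        f"LVE LVDdI mean for {sex} must exceed {thr} mm/m^2")
                if group == "non_lve" and mean >= thr:
                    raise ValueError(
                        f"non-LVE LVDdI mean for {sex} must lie below {thr}")

    def to_yaml(self, path) -> None:
        import json
        payload = json.loads(json.dumps(asdict(self)))  # tuples -> lists
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "seed" not in raw:
            raise ValueError("generator configuration file must set a seed")
        # YAML lists -> tuples for the per-order parameter vectors
        for key in ("harmonic_power_means", "harmonic_power_sds"):
            if key in raw:
                raw[key] = {g: tuple(v) for g, v in raw[key].items()}
        if "lvddi_params" in raw:
            raw["lvddi_params"] = {
                g: {s: tuple(v) for s, v in d.items()}
                for g, d in raw["lvddi_params"].items()
            }
        return cls(**raw)


@dataclass
class PulseRecording:
    """A raw multi-cycle pulse signal plus generator ground truth.

    ``true_cycle_boundaries`` holds the cumulative start indices of each
    cycle plus the final end index (length ``n_cycles + 1``), so cycle
    ``i`` spans ``signal[b[i]:b[i+1]]``.
    """

    subject_id: str
    sampling_rate: float
    signal: np.ndarray
    true_cycle_boundaries: np.ndarray
    true_harmonic_powers: np.ndarray  # orders 1..3

    def __post_init__(self) -> None:
        b = np.asarray(self.true_cycle_boundaries)
        if np.any(np.diff(b) <= 0):
            raise ValueError("cycle boundaries must be strictly increasing")
        if b[-1] != len(self.signal):
            raise ValueError("boundaries must cover the signal exactly")


def synthesize_cycle(a0, a, b, n_points: int) -> np.ndarray:
    """Evaluate one period of a 3rd-order Fourier pulse template.

    F(t) = a0 + sum_{k=1..3} a[k-1] cos(k w t) + b[k-1] sin(k w t), with
    the fundamental angular frequency w spanning exactly one period over
    ``n_points`` equally spaced phases (t = 0 .. n_points-1, w = 2*pi /
    n_points; the right endpoint is excluded, so the series tiles
    periodically).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if n_points < 4:
        raise ValueError("n_points must be at least 4")
    coeffs = np.concatenate(([a0], a, b))
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("Fourier coefficients must be finite")
    t = np.arange(n_points)
    omega = 2.0 * np.pi / n_points
    out = np.full(n_points, float(a0))
    for k in range(1, len(a) + 1):
        out += a[k - 1] * np.cos(k * omega * t) + b[k - 1] * np.sin(k * omega * t)
    return out


def _draw_powers(rng: np.random.Generator, means, sds) -> np.ndarray:
    """Per-order harmonic powers, truncated below at a small positive value."""
    out = np.empty(len(means))
    for i, (m, s) in enumerate(zip(means, sds)):
        if s == 0:
            out[i] = m
            continue
        lo = (0.01 - m) / s
        out[i] = truncnorm.rvs(lo, np.inf, loc=m, scale=s, random_state=rng)
    return out


def _draw_lvddi(rng: np.random.Generator, group: str, sex: str, params) -> float:
    mean, sd = params[group][sex]
    thr = LVDDI_THRESHOLDS[sex]
    if sd == 0:
        return mean
    if group == "lve":
        lo, hi = (thr + 1e-6 - mean) / sd, np.inf
    else:
        lo, hi = (5.0 - mean) / sd, (thr - mean) / sd
    return float(truncnorm.rvs(lo, hi, loc=mean, scale=sd, random_state=rng))


def _subject_recording(rng, config: GeneratorConfig, subject_id: str,
                       powers: np.ndarray) -> PulseRecording:
    """Synthesize one multi-cycle recording from drawn harmonic powers."""
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    a = powers * np.cos(phases)
    b = powers * np.sin(phases)

    n_raw = config.samples_per_cycle_raw
    jit = config.cycle_jitter_fraction
    lengths = []
    for _ in range(config.cycles_per_subject):
        factor = 1.0 + rng.uniform(-jit, jit)
        lengths.append(max(8, int(round(n_raw * factor))))

    # Offset so the template minimum is >= 0 (pressure-like nonnegativity),
    # then rotate each cycle so it starts at its diastolic foot (minimum) —
    # foot-to-foot is the segmentation convention downstream.
    template_probe = synthesize_cycle(0.0, a, b, 512)
    a0 = -template_probe.min() + 0.05 * np.ptp(template_probe)

    cycles = []
    for L in lengths:
        cyc = synthesize_cycle(a0, a, b, L)
        cyc = np.roll(cyc, -int(np.argmin(cyc)))
        cycles.append(cyc)
    signal = np.concatenate(cycles)
    boundaries = np.concatenate(([0], np.cumsum(lengths)))

    n = len(signal)
    if config.baseline_wander_amplitude > 0:
        period = 10.0 * n_raw
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        signal = signal + config.baseline_wander_amplitude * np.sin(
            2.0 * np.pi * np.arange(n) / period + phi0)
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, size=n)

    return PulseRecording(
        subject_id=subject_id,
        sampling_rate=config.sampling_rate_hz,
        signal=signal,
        true_cycle_boundaries=boundaries,
        true_harmonic_powers=powers.copy(),
    )


def _incomplete_allocation(n_per_group: dict, fraction: float) -> dict:
    """Largest-remainder allocation of the incomplete-record count to groups."""
    total = sum(n_per_group.values())
    n_incomplete = int(round(total * fraction))
    quotas = {g: n * n_incomplete / total for g, n in n_per_group.items()}
    alloc = {g: int(np.floor(q)) for g, q in quotas.items()}
    short = n_incomplete - sum(alloc.values())
    by_remainder = sorted(quotas, key=lambda g: quotas[g] - alloc[g], reverse=True)
    for g in by_remainder[:short]:
        alloc[g] += 1
    return alloc


def generate_cohort(config: GeneratorConfig):
    """Generate a full synthetic cohort.

    Returns ``(subjects, recordings)`` where ``subjects`` is a DataFrame
    (one row per subject) and ``recordings`` maps subject_id ->
    :class:`PulseRecording`. Deterministic given ``config.seed``.

    Incomplete records are modeled as a missing echocardiographic LVDd
    (and hence missing LVDdI); the count is ``round(total *
    incomplete_fraction)``, allocated to the groups proportionally by
    largest remainder so the complete-group sizes are deterministic.
    """
    from .screening import compute_bsa  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    group_sizes = {"non_lve": config.n_non_lve, "lve": config.n_lve}
    incomplete_per_group = _incomplete_allocation(
        group_sizes, config.incomplete_fraction)

    rows = []
    recordings = {}
    idx = 0
    for group in ("non_lve", "lve"):
        n = group_sizes[group]
        incomplete_ids = set(
            rng.choice(n, size=incomplete_per_group[group], replace=False))
        for j in range(n):
            subject_id = f"S{idx:04d}"
            idx += 1
            sex = "male" if rng.uniform() < config.male_fraction else "female"
            age = float(np.clip(rng.normal(68.0, 12.0), 25.0, 95.0))
            h_mean, h_sd = _ANTHROPOMETRICS[sex]["height"]
            w_mean, w_sd = _ANTHROPOMETRICS[sex]["weight"]
            height = float(np.clip(rng.normal(h_mean, h_sd), 135.0, 200.0))
            weight = float(np.clip(rng.normal(w_mean, w_sd), 35.0, 140.0))
            bsa = compute_bsa(height, weight)

            powers = _draw_powers(
                rng,
                config.harmonic_power_means[group],
                config.harmonic_power_sds[group],
            )
            if config.deterministic_lvddi:
                c0, c1, c2 = _DETERMINISTIC_LVDDI_COEF
                lvddi = c0 + c1 * powers[0] + c2 * powers[1]
            else:
                lvddi = _draw_lvddi(rng, group, sex, config.lvddi_params)
            lvdd = lvddi * bsa

            complete = j not in incomplete_ids
            rec = _subject_recording(rng, config, subject_id, powers)
            recordings[subject_id] = rec

            rows.append({
                "subject_id": subject_id,
                "sex": sex,
                "age": age,
                "height_cm": height,
                "weight_kg": weight,
                "bsa_m2": bsa,
                "lvdd_mm": lvdd if complete else np.nan,
                "lvddi_mm_m2": lvddi if complete else np.nan,
                "measurement_site": "left_upper_arm",
                "n_valid_cycles": config.cycles_per_subject,
                "has_tte": complete,
                "complete": complete,
                "true_group": "lve" if group == "lve" else "non_lve",
            })

    subjects = pd.DataFrame(rows)
    return subjects, recordings


# Frozen seed of the packaged screening-flow fixture.
PAPER_FLOW_SEED = 227_137_90


def paper_flow_fixture():
    """The packaged 264-subject screening-flow cohort (fixed seed).

    264 heart-failure subjects of whom 37 carry incomplete records
    (missing echocardiographic LVDd); the 227 complete subjects split
    137 non-LVE / 90 LVE by construction of their LVDdI values relative
    to the sex-specific thresholds. 264 * 37/264 allocates 22 incomplete
    subjects to the non-LVE arm and 15 to the LVE arm by largest
    remainder, so the generated arms are 159 and 105 subjects.
    """
    config = GeneratorConfig(
        n_non_lve=159,
        n_lve=105,
        incomplete_fraction=37.0 / 264.0,
        seed=PAPER_FLOW_SEED,
    )
    return generate_cohort(config)


def write_subject_table(subjects: pd.DataFrame, path) -> None:
    subjects.to_csv(path, index=False)


def write_recordings(recordings: dict, path) -> None:
    """Write all recordings as one long-format CSV (subject_id, sample_index, amplitude)."""
    frames = []
    for sid, rec in recordings.items():
        frames.append(pd.DataFrame({
            "subject_id": sid,
            "sample_index": np.arange(len(rec.signal)),
            "amplitude": rec.signal,
            "sampling_rate_hz": rec.sampling_rate,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_recordings(path) -> dict:
    """Inverse of :func:`write_recordings` (without generator ground truth)."""
    df = pd.read_csv(path)
    out = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("sample_index")
        sig = grp["amplitude"].to_numpy()
        out[sid] = PulseRecording(
            subject_id=str(sid),
            sampling_rate=float(grp["sampling_rate_hz"].iloc[0]),
            signal=sig,
            true_cycle_boundaries=np.array([0, len(sig)]),
            true_harmonic_powers=np.full(3, np.nan),
        )
    return out
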