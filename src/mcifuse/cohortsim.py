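"""Synthetic cohort generator with the statistical structure the pipeline assumes.

The generative model is deliberately simple — a latent linear disease-severity
trajectory per subject with linear-Gaussian emissions per modality — because
that is the minimal structure that yields (a) temporally informative
longitudinal signal, (b) complementary information across modalities, and
(c) conversion events defined on the visit grid, which is what the two-stage
recurrent pipeline is built to exploit.

Per subject ``i`` in group g:

* latent severity  ``s_i(t) = a_i + b_i * t`` with
  ``a_i ~ N(mu_a[g], severity_intercept_sd)`` and
  ``b_i ~ N(mu_b[g], severity_slope_sd)`` (CN low/flat, MCI intermediate,
  AD high);
* an MCI subject converts at the first visit-grid month ``t`` (0, spacing,
  2*spacing, ...) within follow-up where ``s_i(t) >= conversion_threshold``;
  requested MCI-C / MCI-NC counts are enforced by rejection sampling;
* modality ``m`` observed at visit ``t`` emits
  ``loading[m] * s_i(t) + intercept[m] + N(0, noise_sd[m])``;
* longitudinal sequence lengths are drawn per subject from
  ``round(N(length_mean[m], length_sd[m]))`` truncated to >= 1, with visits
  at months 0, spacing, 2*spacing, ...; cross-sectional modalities always
  have one visit at month 0;
* each modality is independently present with ``modality_presence_prob[m]``
  (demographics always present, CSF scarcest by default);
* demographics are severity-independent covariates (age, sex, education)
  except an APOE-e4-like binary whose carrier frequency rises along the
  CN < MCI-NC < MCI-C ~ AD gradient.

Everything is driven by one ``numpy`` generator, so a fixed seed yields a
bit-identical cohort.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datamodel import Cohort, ModalitySequence, ModalitySpec, Subject, default_registry

__all__ = ["SimConfig", "simulate_cohort", "summarize_cohort", "converter_fraction",
           "benchmark_config", "separable_config"]


class SimulationError(RuntimeError):
    """Raised when a configuration cannot produce the requested cohort."""


def _default_length_mean() -> dict[str, float]:
    return {"cognitive": 3.7, "csf": 1.4, "demographics": 1.0, "mri": 1.0}


def _default_length_sd() -> dict[str, float]:
    return {"cognitive": 1.32, "csf": 0.5, "demographics": 0.0, "mri": 0.0}


def _default_loading() -> dict[str, list[float]]:
    # Signs follow clinical direction: cognition and brain volumes fall with
    # severity, tau species rise, amyloid falls.
    return {
        "cognitive": [-0.9, -0.7],
        "demographics": [0.0, 0.0, 0.0, 0.0],
        "csf": [-0.8, 0.7, 0.6, 0.5, -0.45],
        "mri": [-0.7, -0.55, -0.45],
    }


def _default_intercept() -> dict[str, float]:
    return {"cognitive": 0.0, "demographics": 0.0, "csf": 0.0, "mri": 0.0}


def _default_noise_sd() -> dict[str, float]:
    return {"cognitive": 0.35, "demographics": 0.0, "csf": 0.5, "mri": 0.45}


def _default_presence() -> dict[str, float]:
    return {"cognitive": 0.95, "demographics": 1.0, "csf": 0.6, "mri": 0.85}


def _default_intercept_mean() -> dict[str, float]:
    return {"CN": -2.0, "MCI": -0.4, "AD": 2.0}


def _default_slope_mean() -> dict[str, float]:
    return {"CN": 0.0, "MCI": 0.035, "AD": 0.04}


def _default_apoe_freq() -> dict[str, float]:
    # Carrier frequencies from the study's baseline demographics table
    # (>=1 e4 allele): CN 114/415, MCI-NC 233/558, MCI-C 202/307, AD 225/338.
    return {"CN": 0.275, "MCI-NC": 0.418, "MCI-C": 0.658, "AD": 0.666}


@dataclass
class SimConfig:
    """Full specification of the synthetic cohort generator.

    Defaults reproduce the study's group composition (415 CN, 307 MCI-C,
    558 MCI-NC, 338 AD) and per-modality sequence-length moments
    (cognitive 3.7 +- 1.32 visits, CSF 1.4 +- 0.5, demographics and MRI
    single-visit).
    """

    n_cn: int = 415
    n_mci_c: int = 307
    n_mci_nc: int = 558
    n_ad: int = 338
    visit_spacing_months: float = 6.0
    length_mean: dict[str, float] = field(default_factory=_default_length_mean)
    length_sd: dict[str, float] = field(default_factory=_default_length_sd)
    loading: dict[str, list[float]] = field(default_factory=_default_loading)
    emission_intercept: dict[str, float] = field(default_factory=_default_intercept)
    noise_sd: dict[str, float] = field(default_factory=_default_noise_sd)
    severity_intercept_mean_by_group: dict[str, float] = field(default_factory=_default_intercept_mean)
    severity_intercept_sd: float = 0.6
    severity_slope_mean_by_group: dict[str, float] = field(default_factory=_default_slope_mean)
    severity_slope_sd: float = 0.025
    conversion_threshold: float = 1.0
    severity_margin: float = 0.0
    modality_presence_prob: dict[str, float] = field(default_factory=_default_presence)
    followup_choices: tuple[float, ...] = (24.0, 30.0, 36.0, 42.0, 48.0)
    apoe_freq_by_group: dict[str, float] = field(default_factory=_default_apoe_freq)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cn", "n_mci_c", "n_mci_nc", "n_ad"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name, sd in self.length_sd.items():
            if sd < 0:
                raise ValueError(f"length_sd[{name}] must be >= 0")
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd[{name}] must be >= 0")
        if self.severity_intercept_sd < 0 or self.severity_slope_sd < 0:
            raise ValueError("severity sds must be >= 0")
        if self.severity_margin < 0:
            raise ValueError("severity_margin must be >= 0")
        for name, p in self.modality_presence_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"modality_presence_prob[{name}] must be in [0, 1]")
        if self.visit_spacing_months <= 0:
            raise ValueError("visit_spacing_months must be > 0")

    def registry(self) -> list[ModalitySpec]:
        return default_registry()

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "followup_choices" in data:
            data["followup_choices"] = tuple(float(x) for x in data["followup_choices"])
        return cls(**data)


def _draw_trajectory(rng: np.random.Generator, config: SimConfig, group: str):
    """Draw (intercept, slope, followup) for one subject of the given group."""
    a = rng.normal(config.severity_intercept_mean_by_group[group], config.severity_intercept_sd)
    b = rng.normal(config.severity_slope_mean_by_group[group], config.severity_slope_sd)
    followup = float(rng.choice(np.asarray(config.followup_choices, dtype=float)))
    return a, b, followup


def _conversion_month(a: float, b: float, followup: float, threshold: float, spacing: float):
    """First visit-grid month within follow-up where severity crosses threshold."""
    months = np.arange(0.0, followup + 1e-9, spacing)
    crossed = np.nonzero(a + b * months >= threshold)[0]
    return float(months[crossed[0]]) if crossed.size else None


def converter_fraction(config: SimConfig, n: int, seed: int) -> float:
    """Fraction of ``n`` raw MCI trajectory draws that convert within follow-up.

    Uses its own generator so a fixed seed fixes the trajectory pool; across a
    grid of ``conversion_threshold`` values (same seed, all else equal) the
    fraction is monotone non-increasing.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n):
        a, b, followup = _draw_trajectory(rng, config, "MCI")
        if _conversion_month(a, b, followup, config.conversion_threshold,
                             config.visit_spacing_months) is not None:
            hits += 1
    return hits / n


def _sequence_length(rng: np.random.Generator, config: SimConfig, spec: ModalitySpec) -> int:
    if not spec.longitudinal:
        return 1
    mean = config.length_mean[spec.name]
    sd = config.length_sd[spec.name]
    return max(1, int(np.rint(rng.normal(mean, sd))))


def _emit_subject(
    rng: np.random.Generator,
    config: SimConfig,
    registry: list[ModalitySpec],
    subject_id: str,
    group: str,
    a: float,
    b: float,
    followup: float,
    conversion: float | None,
    apoe_group: str,
) -> Subject:
    spacing = config.visit_spacing_months
    sequences: dict[str, ModalitySequence] = {}
    last_visit = 0.0
    for spec in registry:
        present = spec.name == "demographics" or rng.random() < config.modality_presence_prob[spec.name]
        if not present:
            continue
        length = _sequence_length(rng, config, spec)
        months = np.arange(length, dtype=float) * spacing
        last_visit = max(last_visit, months[-1])
        if spec.name == "demographics":
            age = rng.normal(73.5, 6.2)
            sex = float(rng.random() < 0.5)
            edu = rng.normal(15.9, 2.8)
            apoe = float(rng.random() < config.apoe_freq_by_group[apoe_group])
            obs = np.array([[age, sex, edu, apoe]])
        else:
            load = np.asarray(config.loading[spec.name], dtype=float)
            sev = a + b * months
            obs = sev[:, None] * load[None, :] + config.emission_intercept[spec.name]
            obs = obs + rng.normal(0.0, config.noise_sd[spec.name], size=obs.shape)
        sequences[spec.name] = ModalitySequence(spec.name, months, obs)
    return Subject(
        id=subject_id,
        baseline_group=group,
        conversion_month=conversion,
        followup_month=max(followup, last_visit),
        sequences=sequences,
    )


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate a cohort under the latent-severity model; deterministic per seed.

    MCI-C / MCI-NC counts are enforced by rejection: trajectories are drawn
    until both buckets are full, erroring out after a bounded number of draws
    if the threshold makes a requested bucket unreachable.
    """
    rng = np.random.default_rng(config.seed)
    registry = config.registry()
    subjects: list[Subject] = []

    for group, count, prefix in (("CN", config.n_cn, "CN"), ("AD", config.n_ad, "AD")):
        for i in range(count):
            a, b, followup = _draw_trajectory(rng, config, group)
            subjects.append(
                _emit_subject(rng, config, registry, f"{prefix}{i + 1:04d}", group,
                              a, b, followup, None, group)
            )

    need_c, need_nc = config.n_mci_c, config.n_mci_nc
    got_c = got_nc = 0
    max_draws = 200 * (need_c + need_nc) + 1000
    draws = 0
    while got_c < need_c or got_nc < need_nc:
        draws += 1
        if draws > max_draws:
            raise SimulationError(
                "could not realize requested MCI-C/MCI-NC counts "
                f"({got_c}/{need_c} converters, {got_nc}/{need_nc} non-converters "
                f"after {draws - 1} draws); conversion_threshold likely infeasible"
            )
        a, b, followup = _draw_trajectory(rng, config, "MCI")
        if config.severity_margin > 0:
            # ceiling-check mode: keep only trajectories whose grid severities
            # stay clear of the threshold, so every horizon label has margin
            months = np.arange(0.0, followup + 1e-9, config.visit_spacing_months)
            if np.min(np.abs(a + b * months - config.conversion_threshold)) < config.severity_margin:
                continue
        conv = _conversion_month(a, b, followup, config.conversion_threshold,
                                 config.visit_spacing_months)
        if conv is not None:
            if got_c >= need_c:
                continue
            got_c += 1
            sid = f"MCIC{got_c:04d}"
            apoe_group = "MCI-C"
        else:
            if got_nc >= need_nc:
                continue
            got_nc += 1
            sid = f"MCIN{got_nc:04d}"
            apoe_group = "MCI-NC"
        subjects.append(
            _emit_subject(rng, config, registry, sid, "MCI", a, b, followup, conv, apoe_group)
        )

    return Cohort(subjects, registry)


def summarize_cohort(cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Per-modality sequence-length moments and per-group subject counts.

    Returns ``{"modalities": DataFrame, "groups": DataFrame}`` mirroring the
    study's summary-statistics layout: modality rows carry subject count and
    the mean/sd of per-subject sequence length; group rows carry counts with
    MCI split into converters and non-converters.
    """
    mod_rows = []
    for spec in cohort.registry:
        lengths = [s.sequences[spec.name].length for s in cohort.subjects
                   if spec.name in s.sequences]
        arr = np.asarray(lengths, dtype=float)
        mod_rows.append(
            {
                "modality": spec.name,
                "n_subjects": len(lengths),
                "mean_length": float(arr.mean()) if arr.size else np.nan,
                "sd_length": float(arr.std(ddof=0)) if arr.size else np.nan,
            }
        )
    modalities = pd.DataFrame(mod_rows).set_index("modality")

    mci = cohort.subjects_in_group("MCI")
    groups = pd.DataFrame(
        {
            "n_subjects": {
                "CN": len(cohort.subjects_in_group("CN")),
                "MCI": len(mci),
                "MCI-C": sum(1 for s in mci if s.is_converter),
                "MCI-NC": sum(1 for s in mci if not s.is_converter),
                "AD": len(cohort.subjects_in_group("AD")),
            }
        }
    )
    return {"modalities": modalities, "groups": groups}


def benchmark_config(seed: int = 0) -> SimConfig:
    """Desk-scale benchmark cohort (~600 subjects) with complementary modality signal.

    Scaled-down group proportions of the study, with the severity signal
    split across modalities — every severity-driven feature has moderate
    signal-to-noise, so no single modality is sufficient — and the stock
    missingness pattern with CSF scarcest.  This is the fixed condition under
    which the expected ordering (longitudinal multi-modal fusion >=
    baseline-truncated >= each single modality) is evaluated.
    """
    return SimConfig(
        n_cn=100,
        n_mci_c=200,
        n_mci_nc=220,
        n_ad=80,
        loading={
            "cognitive": [-0.45, -0.35],
            "demographics": [0.0, 0.0, 0.0, 0.0],
            "csf": [-0.5, 0.45, 0.4, 0.35, -0.3],
            "mri": [-0.5, -0.45, -0.4],
        },
        noise_sd={"cognitive": 1.0, "demographics": 0.0, "csf": 0.4, "mri": 0.4},
        seed=seed,
    )


def separable_config(seed: int = 0, n_mci: int = 120) -> SimConfig:
    """Noise-free, fully observed, fixed-grid configuration for ceiling checks.

    All modalities are always present, emissions are exact linear functions of
    severity, every subject is followed for 36 months with cognitive visits on
    the full grid, and MCI severities keep a margin from the conversion
    threshold at every visit — so the last cognitive observation determines
    conversion status exactly with a gap, and any sane classifier should
    reach accuracy 1.0.
    """
    return SimConfig(
        n_cn=40,
        n_mci_c=n_mci // 2,
        n_mci_nc=n_mci - n_mci // 2,
        n_ad=40,
        length_mean={"cognitive": 7.0, "csf": 7.0, "demographics": 1.0, "mri": 1.0},
        length_sd={"cognitive": 0.0, "csf": 0.0, "demographics": 0.0, "mri": 0.0},
        noise_sd={"cognitive": 0.0, "demographics": 0.0, "csf": 0.0, "mri": 0.0},
        modality_presence_prob={"cognitive": 1.0, "demographics": 1.0, "csf": 1.0, "mri": 1.0},
        followup_choices=(36.0,),
        severity_slope_mean_by_group={"CN": 0.0, "MCI": 0.035, "AD": 0.04},
        severity_slope_sd=0.01,
        severity_margin=0.25,
        seed=seed,
    )
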