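"""Synthetic flowsheet-like cohorts with known ground truth.

Real ICU flowsheet corpora are not publicly shareable, so every stage of
the pipeline is exercised on generated data that mimics their structure:
per patient, a couple of dozen numeric physiological items sampled at
>1000 labeled timestamps, each item fluctuating around a patient-specific
baseline N(mu_i, sigma_i).

Per row, each feature is latently "abnormal" with some rate; an abnormal
reading is displaced by ``shift`` baseline standard deviations in a
direction fixed per feature (a blood pressure that runs high stays high).
The fixed sign is deliberate: two-sided binarization cannot tell high from
low excursions, so the generator exposes exactly the information the
binary coding loses.  The pain label is a function of the latent
abnormality bits — linear, a count threshold, or an XOR of two features
(linearly inseparable by construction) — optionally flipped with a small
label-noise probability.  Ground truth (latent bits, baselines, signs) is
returned alongside the numeric table so recovery is directly measurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticCohortConfig",
    "PatientData",
    "label_rule",
    "generate_patient",
    "generate_cohort",
    "write_patient_csv",
    "xor_cohort_config",
    "linear_cohort_config",
]

LABEL_RULES = ("linear", "xor_pair", "count_threshold")


@dataclass
class SyntheticCohortConfig:
    """Generative settings for a synthetic cohort.

    ``n_features`` and ``n_rows`` default to 25 items and 1200 labeled
    rows per patient, the scale of the flowsheet records this package
    targets.  ``abnormality_rate`` may be a scalar or one rate per
    feature; ``shift`` is the abnormal-state mean displacement in units of
    the feature's baseline sigma.  ``rule_features`` selects which latent
    bits the label rule reads (defaults: first two for ``xor_pair``,
    first four otherwise).
    """

    n_patients: int = 4
    n_features: int = 25
    n_rows: int = 1200
    abnormality_rate: float | Sequence[float] = 0.2
    shift: float = 2.0
    label_rule: str = "linear"
    rule_features: tuple[int, ...] | None = None
    rule_weights: tuple[float, ...] | None = None
    rule_cut: float = 1.5
    label_noise: float = 0.05
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_features < 1 or self.n_rows < 1:
            raise ValueError("counts must be positive")
        rates = np.atleast_1d(np.asarray(self.abnormality_rate, dtype=float))
        if rates.size not in (1, self.n_features):
            raise ValueError("abnormality_rate must be scalar or per-feature")
        if np.any((rates <= 0) | (rates >= 1)):
            raise ValueError("abnormality_rate must lie in (0, 1)")
        if self.shift <= 0:
            raise ValueError("shift must be positive")
        if self.label_rule not in LABEL_RULES:
            raise ValueError(f"unknown label rule {self.label_rule!r}")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        feats = self.resolved_rule_features()
        if max(feats) >= self.n_features:
            raise ValueError("label rule references more features than exist")
        if self.label_rule == "xor_pair" and len(feats) != 2:
            raise ValueError("xor_pair needs exactly two rule features")

    def resolved_rule_features(self) -> tuple[int, ...]:
        if self.rule_features is not None:
            return tuple(self.rule_features)
        return (0, 1) if self.label_rule == "xor_pair" else (0, 1, 2, 3)

    def rates_vector(self) -> np.ndarray:
        rates = np.atleast_1d(np.asarray(self.abnormality_rate, dtype=float))
        return np.broadcast_to(rates, (self.n_features,)).copy()


@dataclass
class PatientData:
    """One synthetic patient: numeric table plus full ground truth."""

    table: pd.DataFrame  # numeric readings, NaN where missing
    Z: np.ndarray  # latent abnormality bits, (n_rows, n_features)
    labels: np.ndarray  # pain labels after noise, (n_rows,)
    mu: np.ndarray
    sigma: np.ndarray
    signs: np.ndarray
    clean_labels: np.ndarray  # labels before noise flips
    patient_seed: int = 0


def label_rule(
    z_row,
    rule_name: str,
    rule_features: Sequence[int],
    rule_weights: Sequence[float] | None = None,
    rule_cut: float = 1.5,
) -> int:
    """Evaluate one label rule on a row of latent abnormality bits.

    ``linear``: 1 iff the weighted sum of the designated bits exceeds the
    cut.  ``xor_pair``: XOR of two designated bits.  ``count_threshold``:
    1 iff at least ``rule_cut`` designated bits are set.
    """
    z = np.asarray(z_row)
    sub = z[list(rule_features)]
    if rule_name == "linear":
        w = np.ones(len(sub)) if rule_weights is None else np.asarray(rule_weights)
        if w.size != sub.size:
            raise ValueError("rule_weights must match rule_features")
        return int(float(w @ sub) > rule_cut)
    if rule_name == "xor_pair":
        if sub.size != 2:
            raise ValueError("xor_pair needs exactly two designated features")
        return int(sub[0]) ^ int(sub[1])
    if rule_name == "count_threshold":
        return int(int(sub.sum()) >= rule_cut)
    raise ValueError(f"unknown label rule {rule_name!r}")


def _labels_for(Z: np.ndarray, config: SyntheticCohortConfig) -> np.ndarray:
    feats = list(config.resolved_rule_features())
    sub = Z[:, feats]
    if config.label_rule == "linear":
        w = (
            np.ones(len(feats))
            if config.rule_weights is None
            else np.asarray(config.rule_weights, dtype=float)
        )
        return (sub @ w > config.rule_cut).astype(int)
    if config.label_rule == "xor_pair":
        return (sub[:, 0].astype(int) ^ sub[:, 1].astype(int)).astype(int)
    return (sub.sum(axis=1) >= config.rule_cut).astype(int)


def generate_patient(config: SyntheticCohortConfig, patient_seed: int) -> PatientData:
    """Generate one patient's table and ground truth, deterministically.

    Per-patient baselines: mu_i ~ U(10, 150), sigma_i ~ U(1, 15) — loosely
    the magnitude range of common vitals (rates, pressures, saturations).
    """
    rng = np.random.default_rng(patient_seed)
    p, r = config.n_features, config.n_rows
    mu = rng.uniform(10.0, 150.0, size=p)
    sigma = rng.uniform(1.0, 15.0, size=p)
    signs = rng.choice([-1.0, 1.0], size=p)
    rates = config.rates_vector()

    Z = (rng.random((r, p)) < rates).astype(int)
    t = rng.normal(mu + signs * Z * config.shift * sigma, sigma)

    clean = _labels_for(Z, config)
    flips = rng.random(r) < config.label_noise
    labels = np.where(flips, 1 - clean, clean)

    if config.missing_rate > 0:
        miss = rng.random((r, p)) < config.missing_rate
        t = np.where(miss, np.nan, t)

    table = pd.DataFrame(t, columns=[f"item_{i:02d}" for i in range(p)])
    return PatientData(
        table=table,
        Z=Z,
        labels=labels.astype(int),
        mu=mu,
        sigma=sigma,
        signs=signs,
        clean_labels=clean,
        patient_seed=patient_seed,
    )


def generate_cohort(config: SyntheticCohortConfig) -> list[PatientData]:
    """Generate ``n_patients`` independent patients from the cohort seed.

    Patient seeds are derived from ``config.seed`` with a SeedSequence
    spawn, so the cohort is a pure function of the config.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    patients = []
    for child in children:
        seed = int(child.generate_state(1)[0] % (2**31))
        patients.append(generate_patient(config, seed))
    return patients


def write_patient_csv(
    patient: PatientData,
    path: str | Path,
    label_column: str = "pain",
    truth_path: str | Path | None = None,
) -> None:
    """Write the CSV dialect the preprocessing module reads, plus an
    optional ground-truth sidecar (latent bits, baselines, seed)."""
    df = patient.table.copy()
    df.insert(0, "timestamp", np.arange(len(df)))
    df[label_column] = patient.labels
    df.to_csv(path, index=False)
    if truth_path is not None:
        Path(truth_path).write_text(
            json.dumps(
                {
                    "patient_seed": patient.patient_seed,
                    "mu": patient.mu.tolist(),
                    "sigma": patient.sigma.tolist(),
                    "signs": patient.signs.tolist(),
                    "Z": patient.Z.tolist(),
                    "clean_labels": patient.clean_labels.tolist(),
                },
                indent=None,
            )
        )


# ---------------------------------------------------------------------------
# canonical study cohorts


def _rates_with_designated(n_features: int, designated: tuple[int, ...]) -> tuple:
    """Designated (label-relevant) features get rate 0.5 so the label is
    balanced and, for XOR, carries no linear signal; background features
    get a lower 0.2 rate so their binary variance does not swamp the
    informative directions."""
    rates = np.full(n_features, 0.2)
    rates[list(designated)] = 0.5
    return tuple(rates)


def xor_cohort_config(seed: int, **overrides) -> SyntheticCohortConfig:
    """Canonical nonlinear cohort: label = z_0 XOR z_1, balanced bits.

    By construction no linear function of the features predicts the
    label, while a model with hidden units can represent the interaction.
    """
    base = dict(
        n_features=25,
        n_rows=1200,
        label_rule="xor_pair",
        rule_features=(0, 1),
        abnormality_rate=_rates_with_designated(25, (0, 1)),
        label_noise=0.05,
        shift=2.0,
        seed=seed,
    )
    base.update(overrides)
    if "n_features" in overrides or "rule_features" in overrides:
        nf = base["n_features"]
        base.setdefault("rule_features", (0, 1))
        if "abnormality_rate" not in overrides:
            base["abnormality_rate"] = _rates_with_designated(
                nf, tuple(base["rule_features"])
            )
    return SyntheticCohortConfig(**base)


def linear_cohort_config(seed: int, **overrides) -> SyntheticCohortConfig:
    """Canonical linearly separable cohort: label = (>= 2 of 4 designated
    bits set), i.e. a majority-style rule every model family can fit."""
    base = dict(
        n_features=25,
        n_rows=1200,
        label_rule="linear",
        rule_features=(0, 1, 2, 3),
        rule_cut=1.5,
        abnormality_rate=_rates_with_designated(25, (0, 1, 2, 3)),
        label_noise=0.05,
        shift=2.0,
        seed=seed,
    )
    base.update(overrides)
    if "n_features" in overrides or "rule_features" in overrides:
        nf = base["n_features"]
        base.setdefault("rule_features", (0, 1, 2, 3))
        if "abnormality_rate" not in overrides:
            base["abnormality_rate"] = _rates_with_designated(
                nf, tuple(base["rule_features"])
            )
    return SyntheticCohortConfig(**base)
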