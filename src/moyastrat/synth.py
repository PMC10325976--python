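"""Synthetic variant-score tables and patient cohorts.

The original patient-level data are not publicly deposited, so the generators
here emulate their statistical structure from the published subgroup
parameters: a two-component score mixture per deleteriousness score (the
high-score component standing for functionally damaging missense changes),
and an 88-patient pediatric cohort with a 55/33 MMD/MMS split, 20 carriers of
(possibly) deleterious RNF213 variants allocated 17/3 to MMD/MMS, stratum
onset distributions (carriers 35.2 +/- 35.5 months vs non-carriers
65.1 +/- 46.5, truncated at 0), stratum artery-involvement and
bilaterality probabilities, and per-slot Bernoulli stroke maps matched to the
published mean ischemic burdens.

Everything is reproducible: one 64-bit seed, split into independent
per-component streams, fully determines the output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .cohort import (
    ARTERIES, SIDES, ArteryInvolvement, Patient, StrokeMap, stroke_slot_names,
)
from .variants import AnnotatedVariant

__all__ = [
    "ScoreSimConfig",
    "CohortSimConfig",
    "gen_variant_scores",
    "gen_cohort",
    "paper_default_configs",
]


class ConfigError(ValueError):
    """A simulation config violates its invariants."""


@dataclass(frozen=True)
class MixtureSpec:
    """Two-component normal mixture for one score (low, high order)."""

    weight_high: float
    mean_low: float
    mean_high: float
    sd_low: float
    sd_high: float

    def validate(self, name: str) -> None:
        if not 0.0 <= self.weight_high <= 1.0:
            raise ConfigError(f"{name}: weight_high outside [0, 1]")
        if self.sd_low <= 0 or self.sd_high <= 0:
            raise ConfigError(f"{name}: SDs must be positive")
        if self.mean_low > self.mean_high:
            raise ConfigError(f"{name}: mean_low must be <= mean_high")


@dataclass(frozen=True)
class ScoreSimConfig:
    """Variant-score simulation: shared true component drives both scores.

    The defaults place the CADD high component near the phred range where
    damaging missense variants cluster and the VIPUR high component in the
    upper half of its [0, 1] scale, with the aortic-disease group shifted
    upward on both scores (the published pattern: aortic-associated variants
    carry the highest predicted impact).
    """

    n_variants: int = 200
    cadd: MixtureSpec = field(
        default_factory=lambda: MixtureSpec(0.5, 15.0, 29.0, 4.0, 3.0)
    )
    vipur: MixtureSpec = field(
        default_factory=lambda: MixtureSpec(0.5, 0.25, 0.70, 0.10, 0.15)
    )
    vipur_missing_rate: float = 11.0 / 90.0
    # Additive (CADD, VIPUR) shifts per phenotype group; weights give the
    # group label distribution across generated variants.
    group_shifts: dict = field(default_factory=lambda: {
        "this_study": (0.0, 0.0),
        "MMA": (0.0, 0.0),
        "aortic": (4.0, 0.15),
        "other_arteriopathy": (1.0, 0.05),
    })
    group_weights: dict = field(default_factory=lambda: {
        "this_study": 0.25, "MMA": 0.40, "aortic": 0.15, "other_arteriopathy": 0.20,
    })
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 0:
            raise ConfigError("n_variants must be >= 0")
        self.cadd.validate("cadd")
        self.vipur.validate("vipur")
        if not 0.0 <= self.vipur_missing_rate <= 1.0:
            raise ConfigError("vipur_missing_rate outside [0, 1]")
        if set(self.group_shifts) != set(self.group_weights):
            raise ConfigError("group_shifts and group_weights keys differ")
        w = sum(self.group_weights.values())
        if abs(w - 1.0) > 1e-9:
            raise ConfigError("group weights must sum to 1")


@dataclass(frozen=True)
class CohortSimConfig:
    """Cohort simulation parameters; defaults are the published subgroup values."""

    n_patients: int = 88
    p_mmd: float = 55.0 / 88.0
    n_carriers: int = 20
    carrier_mmd_fraction: float = 17.0 / 20.0  # published 17/3 MMD/MMS split
    nf1_fraction_of_mms: float = 15.0 / 33.0
    incidental_rate: float = 8.0 / 88.0

    onset_mean_carrier: float = 35.2
    onset_sd_carrier: float = 35.5
    onset_mean_noncarrier: float = 65.1
    onset_sd_noncarrier: float = 46.5
    # MMD/MMS stratum values (published) kept for reference; the generator
    # draws onset by carrier stratum and lets the MMD/MMS contrast emerge
    # through the carrier allocation.
    onset_mean_mmd: float = 50.7
    onset_sd_mmd: float = 43.4
    onset_mean_mms: float = 75.7
    onset_sd_mms: float = 47.4

    # Involvement probability per artery, per stratum (carrier, non-carrier).
    p_involved: dict = field(default_factory=lambda: {
        "ACA": (0.815, 0.815),
        "MCA": (0.83, 0.83),
        "PCA": (0.615, 0.225),
    })
    # P(bilateral | involved), per stratum.
    p_bilateral_given_involved: tuple = (0.50, 0.16)

    burden_mean_carrier: float = 5.2
    burden_mean_noncarrier: float = 2.5
    burden_mean_nf1: float = 1.2

    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.n_carriers > self.n_patients:
            raise ConfigError("n_carriers exceeds n_patients")
        for name, p in [
            ("p_mmd", self.p_mmd),
            ("carrier_mmd_fraction", self.carrier_mmd_fraction),
            ("nf1_fraction_of_mms", self.nf1_fraction_of_mms),
            ("incidental_rate", self.incidental_rate),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} outside [0, 1]")
        for a, (pc, pn) in self.p_involved.items():
            if not (0.0 <= pc <= 1.0 and 0.0 <= pn <= 1.0):
                raise ConfigError(f"p_involved[{a}] outside [0, 1]")
        for p in self.p_bilateral_given_involved:
            if not 0.0 <= p <= 1.0:
                raise ConfigError("p_bilateral_given_involved outside [0, 1]")
        for sd in (self.onset_sd_carrier, self.onset_sd_noncarrier,
                   self.onset_sd_mmd, self.onset_sd_mms):
            if sd <= 0:
                raise ConfigError("onset SDs must be positive")
        for b in (self.burden_mean_carrier, self.burden_mean_noncarrier,
                  self.burden_mean_nf1):
            if not 0.0 <= b <= 20.0:
                raise ConfigError("burden means must lie in [0, 20]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def paper_default_configs() -> tuple[ScoreSimConfig, CohortSimConfig]:
    """The study conditions: configs at the published cohort parameters."""
    return ScoreSimConfig(), CohortSimConfig()


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_variant_scores(config: ScoreSimConfig) -> list[AnnotatedVariant]:
    """Draw scored variants with hidden true component labels.

    One latent low/high component per variant drives both scores (this is
    what makes CADD and VIPUR correlated in the simulated cloud); VIPUR is
    clamped to [0, 1] after the normal draw and a configured fraction of
    variants gets a missing VIPUR score.
    """
    config.validate()
    rng_comp, rng_cadd, rng_vipur, rng_miss, rng_group = _streams(config.seed, 5)
    n = config.n_variants

    labels = sorted(config.group_weights)
    gw = np.array([config.group_weights[l] for l in labels])
    groups = rng_group.choice(len(labels), size=n, p=gw / gw.sum())
    is_high = rng_comp.random(n) < config.cadd.weight_high
    missing = rng_miss.random(n) < config.vipur_missing_rate

    cadd_mu = np.where(is_high, config.cadd.mean_high, config.cadd.mean_low)
    cadd_sd = np.where(is_high, config.cadd.sd_high, config.cadd.sd_low)
    vip_mu = np.where(is_high, config.vipur.mean_high, config.vipur.mean_low)
    vip_sd = np.where(is_high, config.vipur.sd_high, config.vipur.sd_low)

    shifts = np.array([config.group_shifts[l] for l in labels])
    cadd = rng_cadd.normal(cadd_mu + shifts[groups, 0], cadd_sd)
    cadd = np.clip(cadd, 0.0, None)
    vipur = rng_vipur.normal(vip_mu + shifts[groups, 1], vip_sd)
    vipur = np.clip(vipur, 0.0, 1.0)

    out = []
    for i in range(n):
        out.append(AnnotatedVariant(
            variant_id=f"sim{i:05d}",
            gene="RNF213",
            cadd=float(cadd[i]),
            vipur=None if missing[i] else float(vipur[i]),
            phenotype_label=labels[groups[i]],
            true_component="high" if is_high[i] else "low",
        ))
    return out


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    a = (0.0 - mean) / sd  # truncate at 0: onset ages cannot be negative
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def gen_cohort(config: CohortSimConfig) -> list[Patient]:
    """Draw a synthetic pediatric Moyamoya cohort.

    Diagnosis is Bernoulli(p_mmd); carriers are allocated by exact counts,
    preferentially to MMD (carrier_mmd_fraction), so the expected
    carrier-by-diagnosis split matches the published 17/3 at the defaults.
    Incidental diagnoses (no symptom onset) are assigned among non-carriers.
    Onset is truncated-normal by carrier stratum; artery involvement and
    bilaterality are Bernoulli by stratum; each of the 20 stroke-map slots is
    Bernoulli with probability mean_burden/20 for the patient's stratum.
    """
    config.validate()
    (rng_dx, rng_carrier, rng_syn, rng_inc, rng_onset,
     rng_art, rng_stroke) = _streams(config.seed, 7)
    n = config.n_patients
    if n == 0:
        return []

    is_mmd = rng_dx.random(n) < config.p_mmd
    mmd_idx = np.flatnonzero(is_mmd)
    mms_idx = np.flatnonzero(~is_mmd)

    # exact-count carrier allocation, preferentially to MMD
    n_car_mmd = int(round(config.n_carriers * config.carrier_mmd_fraction))
    n_car_mmd = min(n_car_mmd, mmd_idx.size)
    n_car_mms = min(config.n_carriers - n_car_mmd, mms_idx.size)
    carriers = np.zeros(n, dtype=bool)
    if n_car_mmd:
        carriers[rng_carrier.choice(mmd_idx, size=n_car_mmd, replace=False)] = True
    if n_car_mms:
        carriers[rng_carrier.choice(mms_idx, size=n_car_mms, replace=False)] = True

    syndrome = np.array([None] * n, dtype=object)
    for i in mms_idx:
        if rng_syn.random() < config.nf1_fraction_of_mms:
            syndrome[i] = "NF1"
        else:
            syndrome[i] = "other_syndrome"

    incidental = np.zeros(n, dtype=bool)
    n_inc = int(round(config.incidental_rate * n))
    non_carrier_idx = np.flatnonzero(~carriers)
    n_inc = min(n_inc, non_carrier_idx.size)
    if n_inc:
        incidental[rng_inc.choice(non_carrier_idx, size=n_inc, replace=False)] = True

    onset_car = _truncated_normal(rng_onset, config.onset_mean_carrier,
                                  config.onset_sd_carrier, n)
    onset_non = _truncated_normal(rng_onset, config.onset_mean_noncarrier,
                                  config.onset_sd_noncarrier, n)

    p_bi = config.p_bilateral_given_involved
    slot_names = stroke_slot_names()

    cohort = []
    for i in range(n):
        stratum = 0 if carriers[i] else 1

        art_slots = set()
        for artery in ARTERIES:
            p_inv = config.p_involved[artery][stratum]
            if rng_art.random() < p_inv:
                if rng_art.random() < p_bi[stratum]:
                    art_slots.update({f"{artery}_L", f"{artery}_R"})
                else:
                    side = SIDES[rng_art.integers(0, 2)]
                    art_slots.add(f"{artery}_{side}")

        if carriers[i]:
            burden_mean = config.burden_mean_carrier
        elif syndrome[i] == "NF1":
            burden_mean = config.burden_mean_nf1
        else:
            burden_mean = config.burden_mean_noncarrier
        p_slot = burden_mean / 20.0
        stroke_slots = {s for s in slot_names if rng_stroke.random() < p_slot}

        onset = None
        if not incidental[i]:
            onset = float(onset_car[i] if carriers[i] else onset_non[i])

        cohort.append(Patient(
            patient_id=f"P{i:04d}",
            diagnosis="MMD" if is_mmd[i] else "MMS",
            sex="F" if rng_dx.random() < 0.5 else "M",
            syndrome=syndrome[i],
            incidental_diagnosis=bool(incidental[i]),
            age_at_onset_months=onset,
            rnf213_carrier=bool(carriers[i]),
            arteries=ArteryInvolvement(frozenset(art_slots)),
            strokes=StrokeMap(frozenset(stroke_slots)),
        ))
    return cohort
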