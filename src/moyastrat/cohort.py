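"""Patient-level cohort model and the genotype–phenotype test battery.

A pediatric Moyamoya cohort is a list of :class:`Patient` records carrying
diagnosis class (MMD = isolated disease, MMS = syndromic), syndrome label,
carrier status for (possibly) deleterious RNF213 variants, age at symptom
onset in months, per-side involvement (stenosis/occlusion) of the three large
cerebral arteries (ACA, MCA, PCA), and a 20-slot stroke map (five
compartments — three territorial, two watershed — by cortical/subcortical
depth by side).

All comparisons run on exact statistics from :mod:`moyastrat.exact_tests`:
age at onset and ischemic burden by exact Mann–Whitney, artery/territory
involvement and laterality by Fisher's exact test, with Bonferroni correction
over the structures tested in one family (laterality is tested separately and
is not part of the corrected family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exact_tests import Table2x2, TestResult, adjust_results, fisher_exact, mann_whitney_exact

__all__ = [
    "ARTERIES", "SIDES", "STROKE_COMPARTMENTS", "STROKE_DEPTHS",
    "ArteryInvolvement", "StrokeMap", "Patient",
    "read_cohort_table", "write_cohort_table",
    "eligible_for_onset", "under_age_subset",
    "compare_age_at_onset", "compare_involvement", "compare_laterality",
    "ischemic_burden_comparison",
]

ARTERIES = ("ACA", "MCA", "PCA")
SIDES = ("L", "R")
# Territorial compartments plus the two watershed zones between territories.
STROKE_COMPARTMENTS = ("ACA", "MCA", "PCA", "ACA-MCA_watershed", "MCA-PCA_watershed")
STROKE_DEPTHS = ("cortical", "subcortical")


def stroke_slot_names() -> list[str]:
    return [
        f"stroke_{c}_{d}_{s}"
        for c in STROKE_COMPARTMENTS for d in STROKE_DEPTHS for s in SIDES
    ]


def artery_slot_names() -> list[str]:
    return [f"{a}_{s}" for a in ARTERIES for s in SIDES]


@dataclass(frozen=True)
class ArteryInvolvement:
    """Stenosis/occlusion flags per artery and side (6 boolean slots)."""

    slots: frozenset[str] = frozenset()  # e.g. {"PCA_L", "MCA_R"}

    def __post_init__(self) -> None:
        bad = set(self.slots) - set(artery_slot_names())
        if bad:
            raise ValueError(f"unknown artery slots: {sorted(bad)}")

    def involved(self, artery: str) -> bool:
        """Involved on at least one side."""
        return any(f"{artery}_{s}" in self.slots for s in SIDES)

    def bilateral(self, artery: str) -> bool:
        return all(f"{artery}_{s}" in self.slots for s in SIDES)


@dataclass(frozen=True)
class StrokeMap:
    """Affected flags over 20 stroke slots (compartment x depth x side)."""

    slots: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = set(self.slots) - set(stroke_slot_names())
        if bad:
            raise ValueError(f"unknown stroke slots: {sorted(bad)}")

    @property
    def burden(self) -> int:
        """Total number of affected slots (0..20)."""
        return len(self.slots)

    def affected(self, compartment: str, depth: str) -> bool:
        """Affected in this compartment/depth on at least one side."""
        return any(f"stroke_{compartment}_{depth}_{s}" in self.slots for s in SIDES)


@dataclass(frozen=True)
class Patient:
    patient_id: str
    diagnosis: str  # MMD or MMS
    sex: Optional[str] = None
    ancestry: Optional[str] = None
    syndrome: Optional[str] = None  # e.g. NF1, trisomy21, spherocytosis
    incidental_diagnosis: bool = False
    age_at_onset_months: Optional[float] = None
    rnf213_carrier: bool = False
    arteries: ArteryInvolvement = field(default_factory=ArteryInvolvement)
    strokes: StrokeMap = field(default_factory=StrokeMap)

    def __post_init__(self) -> None:
        if self.diagnosis not in ("MMD", "MMS"):
            raise ValueError(f"{self.patient_id}: diagnosis must be MMD or MMS")
        if self.age_at_onset_months is not None and self.age_at_onset_months < 0:
            raise ValueError(f"{self.patient_id}: negative age at onset")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ValueError(f"{self.patient_id}: sex must be F or M")


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_cohort_table(cohort: Sequence[Patient], path: str | Path) -> None:
    """One row per patient; artery and stroke slots as 0/1 columns."""
    rows = []
    for p in cohort:
        row = {
            "patient_id": p.patient_id,
            "sex": p.sex or ".",
            "ancestry": p.ancestry or ".",
            "diagnosis": p.diagnosis,
            "syndrome": p.syndrome or ".",
            "incidental_diagnosis": int(p.incidental_diagnosis),
            "age_at_onset_months": (
                repr(p.age_at_onset_months) if p.age_at_onset_months is not None else "."
            ),
            "rnf213_carrier": int(p.rnf213_carrier),
        }
        for s in artery_slot_names():
            row[s] = int(s in p.arteries.slots)
        for s in stroke_slot_names():
            row[s] = int(s in p.strokes.slots)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path) -> list[Patient]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for _, r in df.iterrows():
        onset = r.get("age_at_onset_months", ".")
        art = frozenset(s for s in artery_slot_names() if r.get(s, "0") == "1")
        stk = frozenset(s for s in stroke_slot_names() if r.get(s, "0") == "1")
        out.append(Patient(
            patient_id=r["patient_id"],
            sex=None if r.get("sex", ".") in (".", "") else r["sex"],
            ancestry=None if r.get("ancestry", ".") in (".", "") else r["ancestry"],
            diagnosis=r["diagnosis"],
            syndrome=None if r.get("syndrome", ".") in (".", "") else r["syndrome"],
            incidental_diagnosis=r.get("incidental_diagnosis", "0") == "1",
            age_at_onset_months=None if onset in (".", "") else float(onset),
            rnf213_carrier=r.get("rnf213_carrier", "0") == "1",
            arteries=ArteryInvolvement(art),
            strokes=StrokeMap(stk),
        ))
    return out


# ---------------------------------------------------------------------------
# Eligibility and subsetting
# ---------------------------------------------------------------------------

def eligible_for_onset(patient: Patient, context: str = "rnf213") -> bool:
    """Whether a patient enters the age-at-onset analysis.

    Incidentally diagnosed patients (MMA found on imaging done for another
    indication) have no attributable symptom onset and are always excluded.
    In carrier-vs-rest and NF1-vs-rest contexts, symptomatic NF1 patients who
    *also* carry an RNF213 (possibly) deleterious variant are excluded: their
    group membership is ambiguous.
    """
    if patient.incidental_diagnosis:
        return False
    if context in ("rnf213", "nf1") and patient.syndrome == "NF1" and patient.rnf213_carrier:
        return False
    return True


def under_age_subset(cohort: Iterable[Patient], max_months: float = 60.0) -> list[Patient]:
    """Patients with symptom onset strictly below ``max_months`` (missing excluded)."""
    return [
        p for p in cohort
        if p.age_at_onset_months is not None and p.age_at_onset_months < max_months
    ]


def _exclude_double_carriers(cohort: Iterable[Patient]) -> list[Patient]:
    # NF1 patients with an additional RNF213 variant are removed from
    # involvement/stroke comparisons: ambiguous group membership.
    return [p for p in cohort if not (p.syndrome == "NF1" and p.rnf213_carrier)]


def _split(cohort: Sequence[Patient], grouping: Callable[[Patient], bool]):
    a = [p for p in cohort if grouping(p)]
    b = [p for p in cohort if not grouping(p)]
    return a, b


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------

def compare_age_at_onset(
    cohort: Sequence[Patient],
    grouping: Callable[[Patient], bool],
    context: str = "rnf213",
) -> TestResult:
    """Exact Mann–Whitney on age at onset between two patient groups.

    Eligibility filtering (incidental diagnoses, ambiguous double carriers)
    is applied first; group means and SDs are attached to the result.
    """
    eligible = [
        p for p in cohort
        if eligible_for_onset(p, context) and p.age_at_onset_months is not None
    ]
    ga, gb = _split(eligible, grouping)
    for name, g in (("group_a", ga), ("group_b", gb)):
        if not g:
            raise ValueError(f"{name} empty after onset eligibility filtering")
    xa = [p.age_at_onset_months for p in ga]
    xb = [p.age_at_onset_months for p in gb]
    res = mann_whitney_exact(xa, xb)
    res.label = "age_at_onset_months"
    res.extra.update({
        "mean_a": float(np.mean(xa)), "sd_a": float(np.std(xa, ddof=1)) if len(xa) > 1 else 0.0,
        "mean_b": float(np.mean(xb)), "sd_b": float(np.std(xb, ddof=1)) if len(xb) > 1 else 0.0,
    })
    return res


def compare_involvement(
    cohort: Sequence[Patient],
    grouping: Callable[[Patient], bool],
) -> list[TestResult]:
    """Fisher exact tests of structure involvement between two groups.

    One 2x2 per artery (involved on at least one side — laterality ignored)
    and one per stroke compartment/depth class, Bonferroni-corrected over the
    number of structures tested. Structures with no involvement anywhere are
    retained as p = 1 rows so the correction family size is stable.
    """
    cohort = _exclude_double_carriers(cohort)
    ga, gb = _split(cohort, grouping)
    if not ga or not gb:
        raise ValueError("grouping must yield two non-empty groups")

    results: list[TestResult] = []

    def add(label: str, in_a: int, in_b: int) -> None:
        t = Table2x2(in_a, len(ga) - in_a, in_b, len(gb) - in_b)
        r = fisher_exact(t)
        r.label = label
        r.extra.update({
            "frac_a": in_a / len(ga), "frac_b": in_b / len(gb),
            "n_a": len(ga), "n_b": len(gb),
        })
        results.append(r)

    for artery in ARTERIES:
        add(f"artery_{artery}",
            sum(p.arteries.involved(artery) for p in ga),
            sum(p.arteries.involved(artery) for p in gb))
    for comp in STROKE_COMPARTMENTS:
        for depth in STROKE_DEPTHS:
            add(f"stroke_{comp}_{depth}",
                sum(p.strokes.affected(comp, depth) for p in ga),
                sum(p.strokes.affected(comp, depth) for p in gb))

    adjust_results(results)  # m = number of structures tested
    return results


def compare_laterality(
    cohort: Sequence[Patient],
    grouping: Callable[[Patient], bool],
    artery: str,
) -> TestResult:
    """Fisher exact test of bilateral involvement of one artery between groups."""
    if artery not in ARTERIES:
        raise ValueError(f"unknown artery {artery!r}")
    cohort = _exclude_double_carriers(cohort)
    ga, gb = _split(cohort, grouping)
    if not ga or not gb:
        raise ValueError("grouping must yield two non-empty groups")
    bi_a = sum(p.arteries.bilateral(artery) for p in ga)
    bi_b = sum(p.arteries.bilateral(artery) for p in gb)
    r = fisher_exact(Table2x2(bi_a, len(ga) - bi_a, bi_b, len(gb) - bi_b))
    r.label = f"bilateral_{artery}"
    r.extra.update({"frac_a": bi_a / len(ga), "frac_b": bi_b / len(gb)})
    return r


def ischemic_burden_comparison(
    cohort: Sequence[Patient],
    grouping: Callable[[Patient], bool],
) -> TestResult:
    """Exact Mann–Whitney on total ischemic burden (affected stroke slots)."""
    cohort = _exclude_double_carriers(cohort)
    ga, gb = _split(cohort, grouping)
    if not ga or not gb:
        raise ValueError("grouping must yield two non-empty groups")
    xa = [float(p.strokes.burden) for p in ga]
    xb = [float(p.strokes.burden) for p in gb]
    res = mann_whitney_exact(xa, xb)
    res.label = "ischemic_burden"
    res.extra.update({
        "mean_a": float(np.mean(xa)), "sd_a": float(np.std(xa, ddof=1)) if len(xa) > 1 else 0.0,
        "mean_b": float(np.mean(xb)), "sd_b": float(np.std(xb, ddof=1)) if len(xb) > 1 else 0.0,
    })
    return res
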