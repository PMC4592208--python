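"""Ligand-efficiency prioritization of screening hits.

Four per-compound quantities are computed from potency (pIC50), size
(heavy-atom count HA) and lipophilicity (clogP):

    LE      = (1.37 / HA) * pIC50        ligand efficiency, ~kcal/mol per
                                         heavy atom at standard conditions
    LEScale = 0.104 + 0.65 e^(-0.037 HA) size-dependent maximal-LE reference
    LipE    = pIC50 - clogP              lipophilic efficiency (LLE)
    FQ      = LE / LEScale               fit quality; ~1 is size-optimal

Optimality conventions for lead selection: clogP < 3, LipE > 5, FQ close
to 1 (|FQ - 1| <= 0.25 by default), plus the Lipinski rule-of-five filter.

Reporting follows the 2-decimal presentation of the source table: in
reproduction mode FQ is the ratio of the *rounded* LE and LEScale, itself
rounded — the convention that reproduces published tables computed from
rounded intermediates.  Full precision is available by flag.

``published_hits()`` returns the packaged fixture of the ten prioritized
hits (C1-C10) with their printed pIC50/HA/clogP inputs and the printed
efficiency columns, two cells of which are known errata (see
``PRINTED_ERRATA``); ``check_published_consistency`` re-derives every
printed cell and reports the mismatches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .descriptors import DescriptorVector

#: |FQ - 1| tolerance for the "FQ close to 1" optimality flag.
FQ_NEAR_ONE_TOL = 0.25

#: The ten prioritized hits: id -> (pIC50, HA, clogP) as printed.
PUBLISHED_HIT_INPUTS: dict[str, tuple[float, int, float]] = {
    "C1": (6.2, 25, 2.94),
    "C2": (8.1, 25, 0.81),
    "C3": (8.0, 19, 0.27),
    "C4": (5.2, 27, 1.49),
    "C5": (6.0, 22, 4.11),
    "C6": (8.0, 19, 3.38),
    "C7": (12.5, 26, 2.23),
    "C8": (8.0, 25, 1.70),
    "C9": (6.4, 25, -0.20),
    "C10": (7.2, 23, 2.50),
}

#: Printed efficiency columns: id -> (LE, LEScale, LipE, FQ).
PUBLISHED_HIT_OUTPUTS: dict[str, tuple[float, float, float, float]] = {
    "C1": (0.34, 0.36, 3.26, 0.95),
    "C2": (0.44, 0.36, 7.29, 1.22),
    "C3": (0.58, 0.43, 7.73, 1.35),
    "C4": (0.26, 0.34, 3.71, 0.76),
    "C5": (0.37, 0.29, 1.89, 1.28),
    "C6": (0.58, 0.43, 4.62, 1.35),
    "C7": (0.66, 0.35, 10.27, 1.89),
    "C8": (0.44, 0.36, 6.30, 1.22),
    "C9": (0.35, 0.36, 6.60, 0.97),
    "C10": (0.43, 0.38, 4.70, 1.13),
}

#: Printed cells inconsistent with the defining equations, treated as errata:
#: C5 LEScale omits the 0.104 offset (0.29 printed vs 0.39 from the formula;
#: its printed FQ 1.28 = 0.37/0.29 is self-consistent with that erratum),
#: and C1 FQ prints 0.95 where both rounding conventions give 0.94.
PRINTED_ERRATA: tuple[tuple[str, str], ...] = (("C5", "le_scale"), ("C1", "fq"))


def ligand_efficiency(pic50: float, ha: int) -> float:
    """LE = (1.37/HA) * pIC50; potency normalised by molecular size."""
    if ha < 1:
        raise ValueError(f"heavy-atom count must be >= 1, got {ha}")
    return (1.37 / ha) * pic50


def lipophilic_efficiency(pic50: float, clogp: float) -> float:
    """LipE (LLE) = pIC50 - clogP."""
    return pic50 - clogp


def le_scale(ha: int) -> float:
    """Empirical size-dependent maximal-LE curve 0.104 + 0.65 e^(-0.037 HA)."""
    if ha < 1:
        raise ValueError(f"heavy-atom count must be >= 1, got {ha}")
    return 0.104 + 0.65 * math.exp(-0.037 * ha)


def fit_quality(le: float, le_scale_value: float, rounded_intermediates: bool = True) -> float:
    """FQ = LE/LEScale.

    With ``rounded_intermediates`` (reproduction mode, the default) the two
    inputs are rounded to 2 decimals before dividing and the ratio is
    rounded to 2 decimals, matching tables computed from printed columns;
    otherwise the full-precision ratio is returned.
    """
    if le_scale_value <= 0:
        raise ValueError("LEScale must be positive")
    if rounded_intermediates:
        return round(round(le, 2) / round(le_scale_value, 2), 2)
    return le / le_scale_value


@dataclass(frozen=True)
class EfficiencyProfile:
    """One row of the prioritization table, with optimality flags."""

    id: str
    pic50: float
    ha: int
    clogp: float
    le: float
    le_scale: float
    lipe: float
    fq: float
    clogp_lt_3: bool
    lipe_gt_5: bool
    fq_near_1: bool


def efficiency_table(
    compounds: list[tuple[str, float, int, float]],
    rounded_intermediates: bool = True,
    fq_near_one_tol: float = FQ_NEAR_ONE_TOL,
    le_scale_overrides: dict[str, float] | None = None,
) -> list[EfficiencyProfile]:
    """Build the full efficiency report from (id, pIC50, HA, clogP) rows.

    ``le_scale_overrides`` substitutes externally supplied LEScale values
    (e.g. published ones) before FQ is formed.  Rows that fail their
    preconditions are collected and reported together; valid rows are still
    emitted.
    """
    profiles: list[EfficiencyProfile] = []
    errors: list[str] = []
    for cid, pic50, ha, clogp in compounds:
        try:
            le = ligand_efficiency(pic50, ha)
            ls = le_scale(ha)
            if le_scale_overrides and cid in le_scale_overrides:
                ls = le_scale_overrides[cid]
            lipe = lipophilic_efficiency(pic50, clogp)
            fq = fit_quality(le, ls, rounded_intermediates=rounded_intermediates)
        except ValueError as exc:
            errors.append(f"{cid}: {exc}")
            continue
        profiles.append(
            EfficiencyProfile(
                id=cid,
                pic50=pic50,
                ha=ha,
                clogp=clogp,
                le=le,
                le_scale=ls,
                lipe=lipe,
                fq=fq,
                clogp_lt_3=clogp < 3,
                lipe_gt_5=lipe > 5,
                fq_near_1=abs(fq - 1) <= fq_near_one_tol,
            )
        )
    if errors:
        import warnings

        warnings.warn("efficiency rows skipped: " + "; ".join(errors))
    return profiles


def efficiency_frame(profiles: list[EfficiencyProfile], round_2dp: bool = True) -> pd.DataFrame:
    """Tabulate profiles in the published column order plus flag columns."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "id": p.id,
                "pic50": p.pic50,
                "ha": p.ha,
                "clogp": p.clogp,
                "le": round(p.le, 2) if round_2dp else p.le,
                "le_scale": round(p.le_scale, 2) if round_2dp else p.le_scale,
                "lipe": round(p.lipe, 2) if round_2dp else p.lipe,
                "fq": p.fq,
                "clogp_lt_3": p.clogp_lt_3,
                "lipe_gt_5": p.lipe_gt_5,
                "fq_near_1": p.fq_near_1,
            }
        )
    return pd.DataFrame(rows)


def published_hits() -> pd.DataFrame:
    """The packaged ten-hit fixture: printed inputs and efficiency columns."""
    rows = []
    for cid, (pic50, ha, clogp) in PUBLISHED_HIT_INPUTS.items():
        le, ls, lipe, fq = PUBLISHED_HIT_OUTPUTS[cid]
        rows.append(
            {
                "id": cid,
                "pic50": pic50,
                "ha": ha,
                "clogp": clogp,
                "le": le,
                "le_scale": ls,
                "lipe": lipe,
                "fq": fq,
            }
        )
    return pd.DataFrame(rows)


def check_published_consistency() -> pd.DataFrame:
    """Recompute every printed efficiency cell of the ten-hit table.

    Returns one row per (compound, column) mismatch at 2-decimal rounding;
    the expected output is exactly the two known errata."""
    mismatches = []
    for cid, (pic50, ha, clogp) in PUBLISHED_HIT_INPUTS.items():
        le_p, ls_p, lipe_p, fq_p = PUBLISHED_HIT_OUTPUTS[cid]
        computed = {
            "le": round(ligand_efficiency(pic50, ha), 2),
            "le_scale": round(le_scale(ha), 2),
            "lipe": round(lipophilic_efficiency(pic50, clogp), 2),
            # printed FQ derives from the printed LE/LEScale cells
            "fq": fit_quality(le_p, ls_p, rounded_intermediates=True),
        }
        printed = {"le": le_p, "le_scale": ls_p, "lipe": lipe_p, "fq": fq_p}
        for col in ("le", "le_scale", "lipe", "fq"):
            if computed[col] != printed[col]:
                mismatches.append(
                    {"id": cid, "column": col, "printed": printed[col], "computed": computed[col]}
                )
    return pd.DataFrame(mismatches, columns=["id", "column", "printed", "computed"])


@dataclass(frozen=True)
class RuleOfFiveResult:
    passed: bool
    violations: tuple[str, ...]


def rule_of_five(d: DescriptorVector, max_violations: int = 0) -> RuleOfFiveResult:
    """Lipinski rule-of-five filter: MW <= 500, clogP <= 5, HBD <= 5,
    HBA <= 10.  Pass requires at most ``max_violations`` breaches (default
    zero-violation convention)."""
    violations = []
    if d.mw > 500:
        violations.append(f"mw {d.mw:.1f} > 500")
    if d.logp > 5:
        violations.append(f"clogp {d.logp:.2f} > 5")
    if d.hbd > 5:
        violations.append(f"hbd {d.hbd} > 5")
    if d.hba > 10:
        violations.append(f"hba {d.hba} > 10")
    return RuleOfFiveResult(passed=len(violations) <= max_violations, violations=tuple(violations))
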