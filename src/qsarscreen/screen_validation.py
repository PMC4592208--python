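"""Virtual-screen validation statistics (Güner-Henry suite).

Given a labelled active/decoy dataset and the hit list retrieved by a
screening model, the quality of the screen is summarised by:

    sensitivity = Ha / A
    specificity = TN / (D - A)          TN = (D - A) - (Ht - Ha)
    %Y          = 100 * Ha / Ht         (percent yield of actives)
    EF          = (Ha/Ht) / (A/D)       (enrichment factor)
    GH          = [Ha (3A + Ht) / (4 Ht A)] * [1 - (Ht - Ha)/(D - A)]

where D is the dataset size, A the number of known actives, Ht the number
of hits and Ha the number of actives among the hits.  GH = 1 is a perfect
screen; retrieving everything gives GH = 0.  Quantities whose denominator
vanishes are reported as an explicit ``None`` marker, never a silent NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class ScreenCounts:
    """Confusion counts of one screening run."""

    D: int  # total compounds
    A: int  # known actives
    Ht: int  # total hits retrieved
    Ha: int  # actives among the hits

    def __post_init__(self):
        ok = (
            0 <= self.Ha <= min(self.Ht, self.A)
            and self.Ht <= self.D
            and self.A <= self.D
            and self.false_positives <= self.D - self.A
        )
        if not ok:
            raise ValueError(f"inconsistent screen counts: {self}")

    @property
    def false_positives(self) -> int:
        return self.Ht - self.Ha

    @property
    def true_negatives(self) -> int:
        return (self.D - self.A) - self.false_positives


@dataclass(frozen=True)
class ScreenMetrics:
    sensitivity: float | None
    specificity: float | None
    percent_yield: float | None
    enrichment_factor: float | None
    gh_score: float | None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def tally(labels: dict[str, str], hits: set[str] | list[str]) -> ScreenCounts:
    """Count D/A/Ht/Ha from a label map and a hit id collection."""
    hits = set(hits)
    unknown = sorted(h for h in hits if h not in labels)
    if unknown:
        raise KeyError(f"hit id(s) not in label set: {unknown}")
    actives = {cid for cid, lab in labels.items() if lab == "active"}
    return ScreenCounts(
        D=len(labels),
        A=len(actives),
        Ht=len(hits),
        Ha=len(hits & actives),
    )


def screen_metrics(c: ScreenCounts) -> ScreenMetrics:
    """Compute the Güner-Henry metric suite from screen counts."""
    sens = c.Ha / c.A if c.A > 0 else None
    spec = c.true_negatives / (c.D - c.A) if c.D > c.A else None
    if c.Ht > 0:
        pct_y = 100.0 * c.Ha / c.Ht
        ef = (c.Ha / c.Ht) / (c.A / c.D) if c.A > 0 else None
    else:
        pct_y = None
        ef = None
    if c.A > 0 and c.Ht > 0 and c.D > c.A:
        gh = (c.Ha * (3 * c.A + c.Ht) / (4 * c.Ht * c.A)) * (
            1 - (c.Ht - c.Ha) / (c.D - c.A)
        )
    else:
        gh = None
    return ScreenMetrics(
        sensitivity=sens,
        specificity=spec,
        percent_yield=pct_y,
        enrichment_factor=ef,
        gh_score=gh,
    )


def read_labels(path) -> dict[str, str]:
    """Read a labels CSV with columns compound_id, label."""
    df = pd.read_csv(path)
    missing = {"compound_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad = sorted(set(df["label"]) - {"active", "decoy"})
    if bad:
        raise ValueError(f"{path}: labels must be active/decoy, found {bad}")
    return dict(zip(df["compound_id"].astype(str), df["label"]))
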