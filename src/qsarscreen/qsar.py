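"""Activity handling and the multiple-linear-regression pIC50 model.

Covers the full QSAR workflow: IC50 -> pIC50 conversion (molar convention,
pIC50 = 9 - log10(IC50/nM)), per-compound averaging over HDAC isoforms,
the 2500 nM active/decoy split, ordinary-least-squares fitting with the
usual fit statistics, classical forward/backward/stepwise descriptor
selection, external validation with a residual flag, and the frozen
published five-descriptor model

    pIC50 = 14.48 - 0.13*polarizability + 0.06*logP + 0.17*TPSA
            - 2.54*HBA - 2.57*BalabanJ

with its reported fit statistics (n=10, R^2 0.93, adjusted 0.84, SEE 0.24,
p 0.02).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .descriptors import MODEL_DESCRIPTORS, DescriptorVector

ISOFORMS = ("HDAC1", "HDAC2", "HDAC3", "HDAC8")

#: Potency threshold separating actives from decoys, in nM.
ACTIVE_THRESHOLD_NM = 2500.0


@dataclass(frozen=True)
class ActivityRecord:
    compound_id: str
    isoform: str
    ic50_nM: float

    def __post_init__(self):
        if self.ic50_nM <= 0:
            raise ValueError(f"{self.compound_id}: IC50 must be positive, got {self.ic50_nM}")

    @property
    def pic50(self) -> float:
        return pic50_from_ic50_nM(self.ic50_nM)


def pic50_from_ic50_nM(ic50_nM: float) -> float:
    """pIC50 = -log10(IC50 in molar) = 9 - log10(IC50 in nM)."""
    if ic50_nM <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return 9.0 - math.log10(ic50_nM)


def ic50_nM_from_pic50(pic50: float) -> float:
    """Inverse conversion: IC50/nM = 10^(9 - pIC50)."""
    return 10.0 ** (9.0 - pic50)


def mean_pic50(records: list[ActivityRecord]) -> float:
    """Average pIC50 over a compound's per-isoform records (convert first,
    then average — i.e. the geometric mean on the IC50 scale)."""
    if not records:
        raise ValueError("no activity records")
    ids = {r.compound_id for r in records}
    if len(ids) > 1:
        raise ValueError(f"records mix compound ids: {sorted(ids)}")
    return float(np.mean([r.pic50 for r in records]))


def classify_activity(ic50_nM: float, threshold_nM: float = ACTIVE_THRESHOLD_NM) -> str:
    """Label a compound ``active`` (IC50 < threshold) or ``decoy``.

    The boundary value itself is a decoy (strict-active convention).
    """
    if ic50_nM <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_nM}")
    return "active" if ic50_nM < threshold_nM else "decoy"


def read_activities(path) -> list[ActivityRecord]:
    """Read an activity CSV with columns compound_id, isoform, ic50_nM."""
    df = pd.read_csv(path)
    required = {"compound_id", "isoform", "ic50_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        ActivityRecord(str(r.compound_id), str(r.isoform), float(r.ic50_nM))
        for r in df.itertuples()
    ]


@dataclass
class QSARModel:
    """A fitted (or frozen published) linear pIC50 model."""

    intercept: float
    coefficients: dict[str, float]
    intercept_se: float = float("nan")
    coefficient_se: dict[str, float] = field(default_factory=dict)
    n: int = 0
    r2: float = float("nan")
    adjusted_r2: float = float("nan")
    see: float = float("nan")
    f_stat: float = float("nan")
    p_value: float = float("nan")
    residuals: np.ndarray | None = None

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def predict_row(self, values: dict[str, float]) -> float:
        missing = [k for k in self.coefficients if k not in values]
        if missing:
            raise ValueError(f"missing descriptor(s) for prediction: {missing}")
        return self.intercept + sum(b * values[k] for k, b in self.coefficients.items())


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - p - 1)."""
    if n - p - 1 <= 0:
        raise ValueError("adjusted R^2 undefined: n <= p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def fit_mlr(X: pd.DataFrame, y: np.ndarray | pd.Series) -> QSARModel:
    """Ordinary least squares with intercept on a descriptor table.

    Raises on rank-deficient design, naming the offending columns.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations, got n={n}, p={p}")
    design = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # identify columns whose removal restores full rank
        offending = []
        for k, col in enumerate(X.columns):
            sub = np.delete(design, k + 1, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                offending.append(str(col))
        raise ValueError(f"rank-deficient design; collinear column(s): {offending}")
    res = sm.OLS(y, design).fit()
    see = float(np.sqrt(res.ssr / res.df_resid)) if res.df_resid > 0 else 0.0
    return QSARModel(
        intercept=float(res.params[0]),
        coefficients={str(c): float(b) for c, b in zip(X.columns, res.params[1:])},
        intercept_se=float(res.bse[0]),
        coefficient_se={str(c): float(s) for c, s in zip(X.columns, res.bse[1:])},
        n=n,
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        see=see,
        f_stat=float(res.fvalue),
        p_value=float(res.f_pvalue),
        residuals=np.asarray(res.resid),
    )


def published_model() -> QSARModel:
    """The frozen published five-descriptor pIC50 model with its printed
    standard errors and fit statistics."""
    return QSARModel(
        intercept=14.48,
        coefficients={
            "mol_polarizability": -0.13,
            "logp": 0.06,
            "tpsa": 0.17,
            "hba": -2.54,
            "balaban_j": -2.57,
        },
        intercept_se=3.8,
        coefficient_se={
            "mol_polarizability": 0.06,
            "logp": 0.04,
            "tpsa": 0.04,
            "hba": 0.5,
            "balaban_j": 1.21,
        },
        n=10,
        r2=0.93,
        adjusted_r2=0.84,
        see=0.24,
        p_value=0.02,
    )


def predict_pic50(model: QSARModel, d: DescriptorVector | dict[str, float]) -> float:
    """Predicted pIC50 = beta0 + sum_k beta_k * d_k."""
    values = d.as_dict() if isinstance(d, DescriptorVector) else dict(d)
    return model.predict_row(values)


@dataclass
class ValidationReport:
    predicted: np.ndarray
    observed: np.ndarray
    residuals: np.ndarray
    external_r2: float
    max_abs_residual: float
    flagged: list[int]  # indices with |residual| above the threshold

    def to_frame(self, ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"observed": self.observed, "predicted": self.predicted, "residual": self.residuals}
        )
        if ids is not None:
            df.insert(0, "compound_id", list(ids))
        return df


def external_validate(
    model: QSARModel,
    X: pd.DataFrame,
    y_observed: np.ndarray | pd.Series,
    residual_threshold: float = 0.5,
) -> ValidationReport:
    """Predict on a labelled set and report residuals and external R^2
    (1 - SSE/SST about the observed mean); residuals exceeding the
    threshold in absolute value are flagged."""
    X = pd.DataFrame(X)
    y = np.asarray(y_observed, dtype=float)
    if len(X) != len(y):
        raise ValueError(f"length mismatch: {len(X)} rows vs {len(y)} observations")
    pred = np.array([model.predict_row(row.to_dict()) for _, row in X.iterrows()])
    resid = y - pred
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum(resid**2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    flagged = [int(i) for i in np.flatnonzero(np.abs(resid) > residual_threshold)]
    return ValidationReport(
        predicted=pred,
        observed=y,
        residuals=resid,
        external_r2=r2,
        max_abs_residual=float(np.max(np.abs(resid))) if len(resid) else 0.0,
        flagged=flagged,
    )


def anova_significance(model: QSARModel) -> tuple[float, float]:
    """Overall regression F-test of a fitted model.

    F = MSR/MSE with (p, n-p-1) degrees of freedom; p-value from the F
    distribution.  A numerically perfect fit reports p < 1e-12.
    """
    p = len(model.coefficients)
    n = model.n
    if n - p - 1 <= 0:
        raise ValueError("degenerate degrees of freedom for ANOVA")
    if model.residuals is None:
        raise ValueError("model carries no residuals; fit it first")
    f = model.f_stat
    if not np.isfinite(f):  # perfect fit: zero residual mean square
        return float("inf"), 1e-13
    pval = float(stats.f.sf(f, p, n - p - 1))
    return float(f), max(pval, 1e-13)


def _pvalue_of_added(X: pd.DataFrame, y: np.ndarray, current: list[str], candidate: str) -> float:
    """t-test p-value of `candidate` when added to the current column set."""
    cols = current + [candidate]
    design = sm.add_constant(X[cols].to_numpy(dtype=float))
    res = sm.OLS(y, design).fit()
    return float(res.pvalues[-1])


def _coef_pvalues(X: pd.DataFrame, y: np.ndarray, cols: list[str]) -> dict[str, float]:
    design = sm.add_constant(X[cols].to_numpy(dtype=float))
    res = sm.OLS(y, design).fit()
    return {c: float(p) for c, p in zip(cols, res.pvalues[1:])}


def select_descriptors(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    method: str = "SS",
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> tuple[list[str], QSARModel]:
    """Classical p-value-driven descriptor selection.

    ``method``: ``FS`` (forward selection), ``BE`` (backward elimination)
    or ``SS`` (stepwise, i.e. forward with backward sweeps).  Deterministic:
    p-value ties are broken by column order.  If no column enters, an
    intercept-only model is returned with a warning.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    method = method.upper()
    if method not in ("FS", "BE", "SS"):
        raise ValueError(f"unknown selection method {method!r}")
    columns = [str(c) for c in X.columns]
    X = X.rename(columns=str)

    if method == "BE":
        selected = list(columns)
        while selected:
            pvals = _coef_pvalues(X, y, selected)
            worst = max(selected, key=lambda c: pvals[c])  # first-seen wins ties
            if pvals[worst] > alpha_remove:
                selected.remove(worst)
            else:
                break
    else:
        selected = []
        remaining = list(columns)
        while remaining:
            pvals = {c: _pvalue_of_added(X, y, selected, c) for c in remaining}
            best = min(remaining, key=lambda c: pvals[c])
            if pvals[best] >= alpha_enter:
                break
            selected.append(best)
            remaining.remove(best)
            if method == "SS":
                while len(selected) > 1:
                    inp = _coef_pvalues(X, y, selected)
                    worst = max(selected, key=lambda c: inp[c])
                    if inp[worst] > alpha_remove:
                        selected.remove(worst)
                        remaining.append(worst)
                    else:
                        break

    if not selected:
        warnings.warn("no descriptor passed the entry criterion; intercept-only model")
        ybar = float(np.mean(y))
        model = QSARModel(
            intercept=ybar,
            coefficients={},
            n=len(y),
            r2=0.0,
            adjusted_r2=0.0,
            see=float(np.std(y, ddof=1)),
            residuals=y - ybar,
        )
        return [], model
    return selected, fit_mlr(X[selected], y)


# --- flat key=value serialization (bit-exact round trip via float hex) ---


def save_model(model: QSARModel, path) -> None:
    lines = [f"intercept\t{model.intercept.hex()}", f"intercept_se\t{float(model.intercept_se).hex()}"]
    for name, b in model.coefficients.items():
        se = float(model.coefficient_se.get(name, float("nan")))
        lines.append(f"coef\t{name}\t{b.hex()}\t{se.hex()}")
    for stat in ("r2", "adjusted_r2", "see", "f_stat", "p_value"):
        lines.append(f"{stat}\t{float(getattr(model, stat)).hex()}")
    lines.append(f"n\t{model.n}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> QSARModel:
    coefficients: dict[str, float] = {}
    coefficient_se: dict[str, float] = {}
    scalars: dict[str, float] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "coef":
                coefficients[parts[1]] = float.fromhex(parts[2])
                coefficient_se[parts[1]] = float.fromhex(parts[3])
            elif parts[0] == "n":
                n = int(parts[1])
            else:
                scalars[parts[0]] = float.fromhex(parts[1])
    return QSARModel(
        intercept=scalars["intercept"],
        coefficients=coefficients,
        intercept_se=scalars["intercept_se"],
        coefficient_se=coefficient_se,
        n=n,
        r2=scalars["r2"],
        adjusted_r2=scalars["adjusted_r2"],
        see=scalars["see"],
        f_stat=scalars["f_stat"],
        p_value=scalars["p_value"],
    )
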