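"""Partial least squares QSAR with the classic validation battery.

The model object follows the statsmodels convention: ``PLSQSAR`` holds the
data (pIC50 vector against a wide, collinear field-descriptor matrix) and
``fit``/``fit_loo`` return a ``PLSQSARResults`` carrying coefficients,
fit statistics and diagnostics:

* Q² = 1 − PRESS/SD from leave-one-out cross-validation (SD about the
  training-fold mean), with SEP = √(PRESS/(n − c − 1));
* the optimum number of components (OPN) at maximal Q² (ties → fewer);
* R²ncv = 1 − RSS/TSS, SEE = √(RSS/(n − c − 1)),
  F = [R²/(1−R²)]·[(n − c − 1)/c] on (c, n − c − 1) degrees of freedom;
* external R²pre = (SD − PRESS)/SD on a held-out test set;
* per-field relative contributions Σ|b|·σ, normalized to 1.

The PLS flavor is NIPALS for a single response, deflating X only; X is
centered (and optionally autoscaled) inside the model, and that scaling is
recomputed inside every cross-validation fold so no information leaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fields import ColumnInfo

__all__ = ["PLSQSAR", "PLSQSARResults", "nipals_pls1", "r2_external"]


def nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS PLS1 on centered data; returns (W, P, q, B_per_component).

    ``B_per_component[c]`` are the regression coefficients (centered scale)
    using components 1..c+1, so one decomposition serves every model size.
    """
    X = Xc.copy()
    n, p = X.shape
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    q = np.zeros(n_components)
    y = yc.copy()
    for c in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            # residual orthogonal to X: stop early, repeat last column
            W, P, q = W[:, :c], P[:, :c], q[:c]
            break
        w /= norm
        t = X @ w
        tt = t @ t
        if tt < 1e-14:
            W, P, q = W[:, :c], P[:, :c], q[:c]
            break
        p_load = X.T @ t / tt
        q_c = y @ t / tt
        X = X - np.outer(t, p_load)
        y = y - q_c * t
        W[:, c], P[:, c], q[c] = w, p_load, q_c
    k = W.shape[1]
    B = np.zeros((max(k, 1), Xc.shape[1]))
    if k:
        R = W @ np.linalg.inv(np.triu(P.T @ W))  # X-weights in original basis
        for c in range(k):
            B[c] = R[:, : c + 1] @ q[: c + 1]
    return W, P, q, B


def r2_external(y_test: np.ndarray, y_pred: np.ndarray,
                y_train_mean: float) -> float:
    """External predictive coefficient (SD − PRESS)/SD, where SD is the
    squared deviation of the test activities about the training mean."""
    y_test = np.asarray(y_test, float)
    y_pred = np.asarray(y_pred, float)
    sd = ((y_test - y_train_mean) ** 2).sum()
    if sd <= 0:
        raise ValueError("degenerate test set: zero deviation about training mean")
    press = ((y_test - y_pred) ** 2).sum()
    return (sd - press) / sd


class PLSQSAR:
    """PLS regression of activity on field descriptors.

    Parameters
    ----------
    endog : array (n,)
        Activities (pIC50).
    exog : array (n, p)
        Descriptor matrix (already block-scaled by field assembly).
    columns : list of ColumnInfo, optional
        Per-column field/lattice metadata; enables field contributions and
        contour export.
    scale : bool
        Autoscale columns to unit variance inside the model (default False:
        field assembly already applies CoMFA-standard block scaling, so the
        model only centers).
    """

    def __init__(self, endog, exog, columns: list[ColumnInfo] | None = None,
                 ids: list[str] | None = None, scale: bool = False):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog/exog shape mismatch")
        self.columns = columns
        self.ids = list(ids) if ids is not None else [str(i) for i in range(len(self.endog))]
        self.scale = scale

    @classmethod
    def from_descriptor_matrix(cls, dm, activities, scale: bool = False) -> "PLSQSAR":
        """Build from a ``DescriptorMatrix`` and a list of ActivityRecord."""
        y = np.array([a.pic50 for a in activities], dtype=float)
        ids = [a.molecule_id for a in activities]
        return cls(y, dm.X, columns=dm.columns, ids=ids, scale=scale)

    # -- internal helpers -------------------------------------------------
    def _standardize(self, X: np.ndarray, y: np.ndarray):
        xm = X.mean(axis=0)
        xs = X.std(axis=0, ddof=1) if self.scale else np.ones(X.shape[1])
        xs = np.where(xs < 1e-12, 1.0, xs)
        ym = y.mean()
        return (X - xm) / xs, y - ym, xm, xs, ym

    def _fit_coefs(self, X: np.ndarray, y: np.ndarray, n_components: int):
        Xc, yc, xm, xs, ym = self._standardize(X, y)
        _, _, _, B = nipals_pls1(Xc, yc, n_components)
        b = B[-1] / xs
        intercept = ym - xm @ b
        return b, intercept, B, (xm, xs, ym)

    # -- fitting -----------------------------------------------------------
    def fit(self, n_components: int) -> "PLSQSARResults":
        """Fit with a fixed number of components (no cross-validation)."""
        n, p = self.exog.shape
        if n_components < 1:
            raise ValueError("need at least one component")
        if n < n_components + 2:
            raise ValueError("too few samples for the requested components")
        rank = np.linalg.matrix_rank(self.exog - self.exog.mean(axis=0))
        if n_components > rank:
            raise ValueError(f"n_components={n_components} exceeds rank {rank}")
        b, intercept, _, _ = self._fit_coefs(self.exog, self.endog, n_components)
        fitted = self.exog @ b + intercept
        return PLSQSARResults(self, n_components, b, intercept, fitted)

    def loo_crossvalidate(self, c_max: int) -> pd.DataFrame:
        """Leave-one-out table of (Q², SEP) for 1..c_max components.

        Every fold refits the model on n−1 samples (centering/scaling
        recomputed inside the fold).  SD is accumulated about each
        training fold's mean.
        """
        n = len(self.endog)
        if n < 5:
            raise ValueError("need at least 5 samples for LOO")
        if c_max >= n - 2:
            raise ValueError("c_max must be below n - 2")
        press = np.zeros(c_max)
        sd = 0.0
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            Xtr, ytr = self.exog[mask], self.endog[mask]
            Xc, yc, xm, xs, ym = self._standardize(Xtr, ytr)
            _, _, _, B = nipals_pls1(Xc, yc, c_max)
            xi = (self.exog[i] - xm) / xs
            sd += (self.endog[i] - ym) ** 2
            for c in range(c_max):
                bc = B[min(c, B.shape[0] - 1)]
                press[c] += (self.endog[i] - (ym + xi @ bc)) ** 2
        q2 = 1.0 - press / sd
        comps = np.arange(1, c_max + 1)
        sep = np.sqrt(press / (n - comps - 1))
        return pd.DataFrame({"components": comps, "q2": q2, "sep": sep})

    def fit_loo(self, c_max: int = 10) -> "PLSQSARResults":
        """LOO model selection then final fit at the optimum component count.

        OPN is the component count with the highest Q² (ties go to the
        smaller model, matching the smallest-SEP reading).
        """
        rank = np.linalg.matrix_rank(self.exog - self.exog.mean(axis=0))
        c_max = int(min(c_max, rank, len(self.endog) - 3))
        if c_max < 1:
            raise ValueError("dataset too small for cross-validated fitting")
        table = self.loo_crossvalidate(c_max)
        opn = int(table.loc[table["q2"].idxmax(), "components"])
        res = self.fit(opn)
        res.loo_table = table
        row = table[table["components"] == opn].iloc[0]
        res.q2, res.sep, res.opn = float(row["q2"]), float(row["sep"]), opn
        return res


@dataclass
class PLSQSARResults:
    """Fitted PLS QSAR model with the standard statistics record."""

    model: PLSQSAR
    n_components: int
    params: np.ndarray          # coefficients in original column units
    intercept: float
    fittedvalues: np.ndarray
    q2: float | None = None
    sep: float | None = None
    opn: int | None = None
    loo_table: pd.DataFrame | None = None
    _ext: dict = field(default_factory=dict)

    # -- training statistics ----------------------------------------------
    @property
    def resid(self) -> np.ndarray:
        return self.model.endog - self.fittedvalues

    @property
    def rss(self) -> float:
        return float((self.resid ** 2).sum())

    @property
    def tss(self) -> float:
        y = self.model.endog
        return float(((y - y.mean()) ** 2).sum())

    @property
    def r2_ncv(self) -> float:
        """Non-cross-validated determination coefficient."""
        return 1.0 - self.rss / self.tss

    @property
    def see(self) -> float:
        """Standard error of estimate, denominator n − c − 1."""
        n, c = len(self.model.endog), self.n_components
        return float(np.sqrt(self.rss / (n - c - 1)))

    @property
    def f_statistic(self) -> float:
        """F on (c, n − c − 1) degrees of freedom."""
        n, c = len(self.model.endog), self.n_components
        r2 = self.r2_ncv
        return (r2 / (1.0 - r2)) * (n - c - 1) / c if r2 < 1.0 else np.inf

    # -- prediction ---------------------------------------------------------
    def predict(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        return X_new @ self.params + self.intercept

    def r2_pred(self, X_test: np.ndarray, y_test: np.ndarray) -> float:
        """External R²pre = (SD − PRESS)/SD against the training mean.

        Test descriptors must be built on the training lattice with the
        training block scaling.
        """
        value = r2_external(y_test, self.predict(X_test),
                            float(self.model.endog.mean()))
        self._ext["r2_pred"] = value
        return value

    # -- interpretation ------------------------------------------------------
    def field_contributions(self) -> dict[str, float]:
        """Relative field contributions Σ|b|·σ per block, normalized to 1."""
        if self.model.columns is None:
            raise ValueError("model was built without column metadata")
        sigma = self.model.exog.std(axis=0, ddof=1)
        raw: dict[str, float] = {}
        for j, info in enumerate(self.model.columns):
            raw[info.field] = raw.get(info.field, 0.0) + abs(self.params[j]) * sigma[j]
        total = sum(raw.values())
        if total <= 0:
            return {k: 0.0 for k in raw}
        return {k: v / total for k, v in raw.items()}

    def detect_outliers(self, threshold: float = 1.5,
                        X: np.ndarray | None = None,
                        y: np.ndarray | None = None,
                        ids: list[str] | None = None) -> list[str]:
        """Ids whose |residual| exceeds ``threshold`` log units (default
        1.5); pass X/y/ids to screen an external set instead."""
        if X is None:
            res, use_ids = self.resid, self.model.ids
        else:
            res = np.asarray(y, float) - self.predict(X)
            use_ids = ids if ids is not None else [str(i) for i in range(len(res))]
        return [i for i, r in zip(use_ids, res) if abs(r) > threshold]

    def summary(self) -> str:
        n, c = len(self.model.endog), self.n_components
        lines = [
            "PLS QSAR Results",
            "=" * 40,
            f"{'No. observations':<28}{n:>12d}",
            f"{'Components':<28}{c:>12d}",
        ]
        if self.q2 is not None:
            lines += [
                f"{'Q2 (LOO)':<28}{self.q2:>12.3f}",
                f"{'SEP':<28}{self.sep:>12.3f}",
                f"{'OPN':<28}{self.opn:>12d}",
            ]
        lines += [
            f"{'R2 (non-validated)':<28}{self.r2_ncv:>12.3f}",
            f"{'SEE':<28}{self.see:>12.3f}",
            f"{'F':<28}{self.f_statistic:>12.3f}",
        ]
        if "r2_pred" in self._ext:
            lines.append(f"{'R2 (external)':<28}{self._ext['r2_pred']:>12.3f}")
        if self.model.columns is not None:
            lines.append("-" * 40)
            lines.append("Field contributions")
            for name, frac in self.field_contributions().items():
                lines.append(f"  {name:<26}{frac:>12.3f}")
        return "\n".join(lines)

    def stats_frame(self) -> pd.DataFrame:
        """One-row statistics table (mirrors the conventional report order)."""
        rec = {
            "q2": self.q2, "r2_ncv": self.r2_ncv, "see": self.see,
            "f": self.f_statistic, "r2_pre": self._ext.get("r2_pred"),
            "sep": self.sep, "opn": self.opn,
        }
        if self.model.columns is not None:
            for name, frac in self.field_contributions().items():
                rec[f"contribution_{name}"] = frac
        return pd.DataFrame([rec])
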