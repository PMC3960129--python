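"""Melting-temperature predictors: linear models on energy features.

Two modes map the four per-residue energy terms to Tm:

* ``deltaG_A`` — the conventional route: Tm regressed on the folding
  free-energy terms computed with the average-temperature potentials
  (thermal stability predicted from thermodynamic stability);
* ``deltaDeltaG`` — the temperature-dependent route: Tm regressed on the
  difference ddG = dG_M - dG_T between the meso- and thermo-derived
  energies, which isolates the interactions whose favourability changes
  with temperature.

The objective is the standard deviation sigma between predicted and
experimental Tm, here the RMS residual; for a linear-in-parameters model
the minimizer is the ordinary least-squares solution, obtained in closed
form.  Cross-validation is leave-one-out (jack-knife): each protein is
predicted by coefficients fitted on all the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MODE_DDG = "deltaDeltaG"
MODE_DGA = "deltaG_A"
MODES = (MODE_DGA, MODE_DDG)

_RCOND = 1e-10


class CollinearityError(ValueError):
    """Raised for a rank-deficient design matrix; names the columns."""


@dataclass
class TmRegressionResults:
    """Fitted coefficients, per-protein predictions and sigma statistics."""

    mode: str
    coefficients: np.ndarray      # per-feature slopes, °C per kT/residue
    intercept: float              # °C
    predictions: np.ndarray       # °C
    tm_exp: np.ndarray            # °C
    ids: list[str]
    families: list[str] | None
    feature_names: list[str]
    cross_validated: bool = False
    strict: bool = False

    @property
    def residuals(self) -> np.ndarray:
        return self.predictions - self.tm_exp

    @property
    def sigma(self) -> float:
        """RMS deviation between predicted and experimental Tm (°C)."""
        return float(np.sqrt(np.mean(self.residuals ** 2)))

    @property
    def sigma_per_family(self) -> dict[str, float]:
        if self.families is None:
            return {}
        out: dict[str, float] = {}
        fam = np.asarray(self.families)
        for f in sorted(set(self.families)):
            res = self.residuals[fam == f]
            out[f] = float(np.sqrt(np.mean(res ** 2)))
        return out

    @property
    def r_pearson(self) -> float:
        if len(self.tm_exp) < 2 or np.ptp(self.predictions) == 0:
            return float("nan")
        return float(stats.pearsonr(self.predictions, self.tm_exp)[0])

    @property
    def nobs(self) -> int:
        return len(self.tm_exp)

    def per_protein_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids,
            "family": self.families if self.families is not None else "",
            "tm_exp": self.tm_exp, "tm_pred": self.predictions,
            "residual": self.residuals,
        })

    def summary(self) -> str:
        lines = [
            f"Tm regression ({self.mode}"
            + (", jack-knife" + (" strict" if self.strict else "")
               if self.cross_validated else ", direct fit") + ")",
            f"  n proteins      {self.nobs}",
            f"  sigma           {self.sigma:8.2f} °C",
            f"  Pearson r       {self.r_pearson:8.3f}",
            f"  intercept       {self.intercept:8.2f} °C",
        ]
        for name, c in zip(self.feature_names, self.coefficients):
            lines.append(f"  coef[{name:>6s}]   {c:10.3f}")
        fams = self.sigma_per_family
        if fams:
            lines.append("  per-family sigma (°C):")
            for f, s in fams.items():
                lines.append(f"    {f:<20s} {s:6.2f}")
        return "\n".join(lines)


@dataclass
class WorstKTrace:
    """Removal trace of the iterative worst-predicted exclusion."""

    excluded_ids: list[str]
    residuals_at_removal: list[float]
    results: TmRegressionResults


class TmRegression:
    """Linear Tm model on 4 energy features, statsmodels-style.

    Parameters
    ----------
    features : (n, 4) array or DataFrame
        Energy terms per protein (ddG or dG_A features per ``mode``).
    tm : (n,) array
        Experimental melting temperatures, °C.
    ids, families : optional per-protein labels.
    """

    def __init__(self, features, tm, ids=None, families=None,
                 mode: str = MODE_DDG, feature_names=None):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        if isinstance(features, pd.DataFrame):
            feature_names = feature_names or list(features.columns)
            features = features.to_numpy(dtype=float)
        self.X = np.asarray(features, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("features must be 2-D (proteins x terms)")
        self.y = np.asarray(tm, dtype=float)
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("features/tm length mismatch")
        if n < self.X.shape[1] + 2:
            raise ValueError(
                f"need at least {self.X.shape[1] + 2} proteins, got {n}")
        self.ids = list(ids) if ids is not None else [str(i) for i in range(n)]
        self.families = list(families) if families is not None else None
        self.mode = mode
        self.feature_names = list(feature_names) if feature_names \
            else [f"x{j}" for j in range(self.X.shape[1])]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_cols: list[str],
                       tm_col: str = "tm", id_col: str = "id",
                       family_col: str | None = "family",
                       mode: str = MODE_DDG) -> "TmRegression":
        fams = df[family_col].tolist() if family_col and family_col in df \
            else None
        return cls(df[feature_cols], df[tm_col].to_numpy(),
                   ids=df[id_col].tolist(), families=fams, mode=mode,
                   feature_names=feature_cols)

    # -- fitting ------------------------------------------------------------

    def _design(self, X=None) -> np.ndarray:
        X = self.X if X is None else X
        return np.column_stack([np.ones(len(X)), X])

    def _solve(self, A: np.ndarray, y: np.ndarray) -> np.ndarray:
        """OLS on the design A = [1 | X].

        Zero-variance feature columns carry no information beyond the
        intercept; they are absorbed into it with coefficient 0.  Genuine
        collinearity among the varying columns raises an error naming them.
        """
        varying = np.ptp(A, axis=0) > 0
        varying[0] = True  # intercept column stays
        sub = A[:, varying]
        u, s, vt = np.linalg.svd(sub, full_matrices=False)
        rank = int(np.sum(s > s[0] * _RCOND))
        if rank < sub.shape[1]:
            null = vt[-1]
            cols = np.array(["intercept"] + self.feature_names)[varying]
            involved = [c for c, v in zip(cols, null) if abs(v) > 1e-6]
            raise CollinearityError(
                f"rank-deficient design: collinear columns {involved}")
        beta = np.zeros(A.shape[1])
        beta[varying] = vt.T @ ((u.T @ y) / s)
        return beta

    def fit(self) -> TmRegressionResults:
        """Closed-form OLS minimizing the RMS residual sigma."""
        beta = self._solve(self._design(), self.y)
        pred = self._design() @ beta
        return TmRegressionResults(
            mode=self.mode, coefficients=beta[1:], intercept=float(beta[0]),
            predictions=pred, tm_exp=self.y, ids=self.ids,
            families=self.families, feature_names=self.feature_names)

    # -- jack-knife ---------------------------------------------------------

    def jackknife(self, feature_provider=None) -> TmRegressionResults:
        """Leave-one-out predictions.

        By default only the coefficients are re-identified per fold, the
        features staying fixed.  For strict cross-validation pass a
        ``feature_provider(held_out_index) -> (X_train, x_test)`` that
        recomputes the features (e.g. from re-derived potentials) without
        the held-out protein; rows of ``X_train`` must align with the
        remaining proteins in order.
        """
        n = len(self.y)
        pred = np.empty(n)
        beta_sum = np.zeros(self.X.shape[1] + 1)
        for i in range(n):
            rest = np.arange(n) != i
            if feature_provider is None:
                X_tr, x_te = self.X[rest], self.X[i]
            else:
                X_tr, x_te = feature_provider(i)
                X_tr = np.asarray(X_tr, dtype=float)
                x_te = np.asarray(x_te, dtype=float)
            A = np.column_stack([np.ones(len(X_tr)), X_tr])
            beta = self._solve(A, self.y[rest])
            pred[i] = beta[0] + x_te @ beta[1:]
            beta_sum += beta
        beta_mean = beta_sum / n
        return TmRegressionResults(
            mode=self.mode, coefficients=beta_mean[1:],
            intercept=float(beta_mean[0]), predictions=pred, tm_exp=self.y,
            ids=self.ids, families=self.families,
            feature_names=self.feature_names, cross_validated=True,
            strict=feature_provider is not None)

    # -- iterative exclusion of the worst-predicted proteins ----------------

    def worst_k_exclusion(self, k: int = 6) -> WorstKTrace:
        """Remove, k times, the protein with the largest |jack-knife residual|.

        Ties are broken by lexicographic protein id.  Returns the removal
        trace and the jack-knife results on the remaining proteins.
        """
        n = len(self.y)
        if k < 0 or (k > 0 and k >= n - 6):
            raise ValueError(f"k={k} leaves too few proteins (n={n})")
        keep = np.ones(n, dtype=bool)
        excluded: list[str] = []
        resids: list[float] = []
        for _ in range(k):
            sub = self._submodel(keep)
            res = sub.jackknife()
            order = sorted(range(len(sub.y)),
                           key=lambda j: (-abs(res.residuals[j]), sub.ids[j]))
            worst_local = order[0]
            worst_global = np.flatnonzero(keep)[worst_local]
            excluded.append(self.ids[worst_global])
            resids.append(float(res.residuals[worst_local]))
            keep[worst_global] = False
        final = self._submodel(keep).jackknife()
        return WorstKTrace(excluded_ids=excluded,
                           residuals_at_removal=resids, results=final)

    def _submodel(self, mask: np.ndarray) -> "TmRegression":
        fams = [f for f, m in zip(self.families, mask) if m] \
            if self.families is not None else None
        return TmRegression(self.X[mask], self.y[mask],
                            ids=[i for i, m in zip(self.ids, mask) if m],
                            families=fams, mode=self.mode,
                            feature_names=self.feature_names)


# -- functional wrappers ----------------------------------------------------


def fit(features, tm_exp, mode: str = MODE_DDG, **kw) -> TmRegressionResults:
    return TmRegression(features, tm_exp, mode=mode, **kw).fit()


def jackknife(features, tm_exp, mode: str = MODE_DDG, feature_provider=None,
              **kw) -> TmRegressionResults:
    return TmRegression(features, tm_exp, mode=mode, **kw).jackknife(
        feature_provider=feature_provider)


def worst_k_exclusion(features, tm_exp, mode: str = MODE_DDG, k: int = 6,
                      **kw) -> WorstKTrace:
    return TmRegression(features, tm_exp, mode=mode, **kw).worst_k_exclusion(k)
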