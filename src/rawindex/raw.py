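"""The Regional Aortic Weakness (RAW) index.

Each wall patch carries three region-averaged descriptors: ILT thickness,
maximum principal strain, and TAWSS.  Each descriptor is ranked into
quartile categories 1-4 within a reference distribution; the TAWSS category
is inverted (low shear is the risk marker), and the three categories combine
into a 0-10 score::

    RAW = ((ILT_cat + STRAIN_cat + (5 - TAWSS_cat)) - 3) / 9 * 10

Categories may be plain quartile ranks (integers 1-4) or *combined*
categories — the mean of the patch's rank within its own patient and within
the population pool — which take half-integer values.  A patch with
RAW > 6 is classified as a high-weakness region.

`QuartileCategorizer` and `RawIndexModel` follow the scikit-learn estimator
protocol (``fit`` learns the reference quartiles, ``transform`` scores new
patches) and compose with sklearn pipelines; :func:`quartile_categories`,
:func:`raw_score` and friends are thin functional wrappers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

#: RAW above this marks a high-weakness region.
RAW_THRESHOLD = 6.0

DESCRIPTORS = ("ilt", "strain", "tawss")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal rounding with ties away from zero (matches hand-reported
    tables, unlike banker's rounding)."""
    scale = 10.0 ** decimals
    return float(np.floor(np.abs(x) * scale + 0.5) / scale * np.sign(x)) if x else 0.0


class QuartileCategorizer(BaseEstimator, TransformerMixin):
    """Rank values into quartile categories 1-4.

    ``fit`` learns the quartile boundaries (linear-interpolation quantiles)
    of the reference distribution, one set per column; ``transform`` assigns
    category ``k`` to values in the k-th quartile interval, lower boundary
    inclusive (a value equal to Q1 is category 1, etc.).

    Degenerate references — fewer than 4 finite values, or all values
    equal — yield category 1 everywhere, with a warning.
    """

    def __init__(self, min_reference: int = 4):
        self.min_reference = min_reference

    def fit(self, X, y=None):
        X = check_array(X, ensure_2d=False, ensure_all_finite="allow-nan", dtype=float)
        X = np.atleast_2d(X.T).T  # promote 1-D to a single column
        self.n_features_in_ = X.shape[1]
        bounds = np.full((3, X.shape[1]), np.nan)
        for j in range(X.shape[1]):
            col = X[:, j][np.isfinite(X[:, j])]
            if len(col) < self.min_reference or np.ptp(col) == 0:
                warnings.warn(
                    f"column {j}: degenerate reference distribution "
                    f"({len(col)} finite values); all categories set to 1",
                    stacklevel=2)
            else:
                bounds[:, j] = np.quantile(col, [0.25, 0.5, 0.75])
        self.quartiles_ = bounds
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "quartiles_")
        X = check_array(X, ensure_2d=False, ensure_all_finite="allow-nan", dtype=float)
        one_d = X.ndim == 1
        X = np.atleast_2d(X.T).T
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        out = np.ones_like(X)
        for j in range(X.shape[1]):
            q = self.quartiles_[:, j]
            if np.all(np.isfinite(q)):
                # lower boundary inclusive: v <= Q1 -> 1, v <= Q2 -> 2, ...
                out[:, j] = 1 + np.searchsorted(q, X[:, j], side="left")
            out[:, j][~np.isfinite(X[:, j])] = np.nan
        return out[:, 0] if one_d else out


def quartile_categories(values) -> np.ndarray:
    """Quartile categories 1-4 of a sample against its own distribution."""
    values = np.asarray(values, dtype=float)
    return QuartileCategorizer().fit(values).transform(values)


def combined_quartile(patient_category, population_category):
    """Mean of a patch's patient-specific and population quartile ranks;
    yields the half-integer categories 1, 1.5, ..., 4."""
    a = np.asarray(patient_category, dtype=float)
    b = np.asarray(population_category, dtype=float)
    for arr in (a, b):
        bad = (arr < 1) | (arr > 4)
        if np.any(bad[np.isfinite(arr)]):
            raise ValueError("categories must lie in [1, 4]")
    out = (a + b) / 2.0
    return float(out) if out.ndim == 0 else out


@dataclass
class RawScore:
    """One patch's RAW value with its risk classification."""

    raw: float
    risk_class: str
    threshold: float = RAW_THRESHOLD

    @property
    def rounded(self) -> float:
        return round_half_up(self.raw, 2)


def raw_score(ilt_category: float, strain_category: float,
              tawss_category: float, threshold: float = RAW_THRESHOLD) -> RawScore:
    """RAW = ((ILT_cat + STRAIN_cat + (5 - TAWSS_cat)) - 3) / 9 * 10.

    Categories may be integer or half-integer (combined) ranks in [1, 4];
    the TAWSS category is inverted inside the formula so that low shear
    raises the score.  The result spans [0, 10].
    """
    cats = np.asarray([ilt_category, strain_category, tawss_category], dtype=float)
    if np.any(cats < 1) or np.any(cats > 4):
        raise ValueError(f"categories must lie in [1, 4], got {cats.tolist()}")
    value = ((ilt_category + strain_category + (5.0 - tawss_category)) - 3.0) / 9.0 * 10.0
    return RawScore(raw=value, risk_class=classify(value, threshold),
                    threshold=threshold)


def raw_score_array(ilt_cat, strain_cat, tawss_cat) -> np.ndarray:
    """Vectorised RAW values (no classification)."""
    ilt_cat = np.asarray(ilt_cat, dtype=float)
    strain_cat = np.asarray(strain_cat, dtype=float)
    tawss_cat = np.asarray(tawss_cat, dtype=float)
    return ((ilt_cat + strain_cat + (5.0 - tawss_cat)) - 3.0) / 9.0 * 10.0


def classify(raw: float, threshold: float = RAW_THRESHOLD) -> str:
    """'high' weakness iff RAW > threshold (strict)."""
    return "high" if raw > threshold else "low"


class RawIndexModel(BaseEstimator, TransformerMixin):
    """End-to-end RAW scoring of patch descriptor rows.

    ``X`` is (n_patches, 3) with columns (ILT thickness mm, max principal
    strain, TAWSS Pa) in that order.  ``fit`` learns the reference quartiles
    of each descriptor from the supplied population of patches; ``transform``
    returns the RAW score of each row; ``predict`` returns ``'high'`` /
    ``'low'`` labels at the chosen threshold.

    Pass ``groups`` to ``fit_transform`` to use *combined* categories: each
    patch's category is then the mean of its rank within its own group
    (patient) and its rank within the full population.
    """

    def __init__(self, threshold: float = RAW_THRESHOLD):
        self.threshold = threshold

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite="allow-nan", dtype=float)
        if X.shape[1] != 3:
            raise ValueError("expected 3 descriptor columns (ilt, strain, tawss)")
        self.categorizer_ = QuartileCategorizer().fit(X)
        self.n_features_in_ = 3
        return self

    def categories(self, X) -> np.ndarray:
        check_is_fitted(self, "categorizer_")
        return self.categorizer_.transform(
            check_array(X, ensure_all_finite="allow-nan", dtype=float))

    def transform(self, X) -> np.ndarray:
        c = self.categories(X)
        return raw_score_array(c[:, 0], c[:, 1], c[:, 2])

    def predict(self, X) -> np.ndarray:
        scores = self.transform(X)
        return np.where(scores > self.threshold, "high", "low")

    def fit_transform(self, X, y=None, groups=None) -> np.ndarray:
        if groups is None:
            return self.fit(X).transform(X)
        return self.combined_scores(X, groups)

    def combined_scores(self, X, groups) -> np.ndarray:
        """RAW from combined (patient + population) quartile categories."""
        X = check_array(X, ensure_all_finite="allow-nan", dtype=float)
        groups = np.asarray(groups)
        if len(groups) != len(X):
            raise ValueError("groups length must match the number of rows")
        self.fit(X)
        pop = self.categories(X)
        pat = np.full_like(pop, np.nan)
        for g in np.unique(groups):
            m = groups == g
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # small patients may be degenerate
                pat[m] = QuartileCategorizer().fit(X[m]).transform(X[m])
        c = combined_quartile(pat, pop)
        return raw_score_array(c[:, 0], c[:, 1], c[:, 2])


def score_patch_table(table: pd.DataFrame, threshold: float = RAW_THRESHOLD,
                      patient_column: str | None = None) -> pd.DataFrame:
    """Categorize and score a per-patch descriptor table.

    ``table`` needs columns ``ilt_mm``, ``strain`` and ``tawss_pa``; the
    result appends single-source categories, (optionally) combined
    categories, the RAW value and the risk class.
    """
    cols = ["ilt_mm", "strain", "tawss_pa"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"patch table lacks columns: {missing}")
    X = table[cols].to_numpy(dtype=float)
    model = RawIndexModel(threshold=threshold).fit(X)
    cats = model.categories(X)
    out = table.copy()
    for i, name in enumerate(DESCRIPTORS):
        out[f"{name}_category"] = cats[:, i]
    if patient_column is not None:
        raw = model.combined_scores(X, table[patient_column].to_numpy())
    else:
        raw = raw_score_array(cats[:, 0], cats[:, 1], cats[:, 2])
    out["raw"] = raw
    out["raw_rounded"] = [round_half_up(v, 2) if np.isfinite(v) else np.nan
                          for v in raw]
    out["risk_class"] = np.where(raw > threshold, "high", "low")
    return out
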