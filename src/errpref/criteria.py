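"""Individual evaluation criteria over (energy efficiency, comfort).

Each trajectory carries two costs; the subject's accept/reject behavior (or
the ErrP decoder's posterior) defines a response over the cost plane. This
module builds 40x40 criteria maps, fits one- and two-covariate logistic
criteria models, quantifies individual customisation by transferring each
subject's classifier to every other subject (intra- vs inter-subject
accuracy, 2x2 repeated-measures ANOVA over label source x transfer
condition), and compares behavioral with ErrP-inferred maps through Pearson
correlations and a Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "CriteriaMap",
    "grid_edges",
    "build_map",
    "single_parameter_prediction",
    "CriteriaModel",
    "CriteriaResults",
    "TransferAnalysis",
    "TransferResults",
    "anova_two_way",
    "criteria_similarity",
    "SimilarityResult",
]

N_BINS = 40


@dataclass
class CriteriaMap:
    """Binned mean response over the (efficiency, comfort) plane.

    ``values`` is (n_bins, n_bins) with NaN for cells that received no
    trials (never zero-filled); ``counts`` holds per-cell trial counts.
    """

    values: np.ndarray
    counts: np.ndarray
    eff_edges: np.ndarray
    comfort_edges: np.ndarray

    @property
    def occupied(self) -> np.ndarray:
        return self.counts > 0


def grid_edges(efficiency, comfort, n_bins: int = N_BINS):
    """Linear bin edges from the ensemble min-max of each cost."""
    efficiency = np.asarray(efficiency, dtype=float)
    comfort = np.asarray(comfort, dtype=float)
    if np.ptp(efficiency) == 0 or np.ptp(comfort) == 0:
        raise ValueError("degenerate axis range: all cost values equal")
    return (np.linspace(efficiency.min(), efficiency.max(), n_bins + 1),
            np.linspace(comfort.min(), comfort.max(), n_bins + 1))


def build_map(efficiency, comfort, responses, eff_edges=None,
              comfort_edges=None, n_bins: int = N_BINS) -> CriteriaMap:
    """Bin trials into the 40x40 cost grid and average the response per cell.

    ``responses`` may be Boolean behavior (released or not) or the scalar
    ErrP posterior in [0, 1]. Grid edges default to this ensemble's min-max
    but can be shared across subjects for comparability.
    """
    efficiency = np.asarray(efficiency, dtype=float)
    comfort = np.asarray(comfort, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if efficiency.size == 0:
        raise ValueError("at least one trial required")
    if eff_edges is None or comfort_edges is None:
        eff_edges, comfort_edges = grid_edges(efficiency, comfort, n_bins)
    sums, _, _, _ = stats.binned_statistic_2d(
        efficiency, comfort, responses, statistic="sum",
        bins=[eff_edges, comfort_edges], expand_binnumbers=False)
    counts, _, _, _ = stats.binned_statistic_2d(
        efficiency, comfort, responses, statistic="count",
        bins=[eff_edges, comfort_edges])
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return CriteriaMap(values=values, counts=counts.astype(int),
                       eff_edges=np.asarray(eff_edges),
                       comfort_edges=np.asarray(comfort_edges))


def _logistic(C: float = 1e6) -> LogisticRegression:
    # effectively unregularised maximum-likelihood logistic fit
    return LogisticRegression(C=C, solver="lbfgs", max_iter=10_000)


def _scaled_logistic(C: float = 1e6):
    # standardisation only conditions the optimisation; predictions unchanged
    return make_pipeline(StandardScaler(), _logistic(C))


def single_parameter_prediction(values, labels, n_folds: int = 10,
                                random_state: int = 0) -> float:
    """10-fold CV accuracy of a one-covariate logistic regression.

    Measures how well a single cost (efficiency alone, or comfort alone)
    predicts the response.
    """
    values = np.asarray(values, dtype=float).reshape(-1, 1)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both response classes must be present")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    scores = cross_val_score(_scaled_logistic(), values, labels, cv=skf, scoring="accuracy")
    return float(np.mean(scores))


@dataclass
class CriteriaResults:
    """Fitted two-covariate logistic evaluation criterion.

    ``params`` are (intercept, w_efficiency, w_comfort); the decision
    boundary in the cost plane has slope ``-w_e / w_c`` (d comfort /
    d efficiency).
    """

    params: np.ndarray
    cv_accuracy: float
    n_trials: int
    model: "CriteriaModel"

    @property
    def boundary_slope(self) -> float:
        return -self.params[1] / self.params[2]

    def predict_proba(self, efficiency, comfort) -> np.ndarray:
        z = (self.params[0] + self.params[1] * np.asarray(efficiency)
             + self.params[2] * np.asarray(comfort))
        return 1.0 / (1.0 + np.exp(-z))

    def predict(self, efficiency, comfort) -> np.ndarray:
        return self.predict_proba(efficiency, comfort) > 0.5

    def accuracy(self, efficiency, comfort, labels) -> float:
        return float(np.mean(self.predict(efficiency, comfort)
                             == np.asarray(labels, dtype=bool)))

    def summary(self) -> str:
        lines = [
            "Evaluation-criterion logistic model",
            "=" * 42,
            f"n trials:          {self.n_trials}",
            f"intercept:         {self.params[0]:+.3f}",
            f"w(efficiency):     {self.params[1]:+.3f}",
            f"w(comfort):        {self.params[2]:+.3f}",
            f"boundary slope:    {self.boundary_slope:+.3f}  (d comfort / d efficiency)",
            f"10-fold accuracy:  {100 * self.cv_accuracy:.1f}%",
        ]
        return "\n".join(lines)


class CriteriaModel:
    """Two-covariate logistic criterion over (efficiency, comfort).

    Build from arrays or a DataFrame with columns ``efficiency``, ``comfort``
    and a label column; ``fit`` returns :class:`CriteriaResults`.
    """

    def __init__(self, efficiency, comfort, labels):
        self.efficiency = np.asarray(efficiency, dtype=float)
        self.comfort = np.asarray(comfort, dtype=float)
        self.labels = np.asarray(labels, dtype=bool)
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both response classes must be present")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "released") -> "CriteriaModel":
        return cls(df["efficiency"].to_numpy(), df["comfort"].to_numpy(),
                   df[label_col].to_numpy())

    def fit(self, n_folds: int = 10, random_state: int = 0) -> CriteriaResults:
        X = np.column_stack([self.efficiency, self.comfort])
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        Z = (X - mu) / sd  # standardised for conditioning; coefs mapped back
        clf = _logistic().fit(Z, self.labels.astype(int))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
        acc = cross_val_score(_logistic(), Z, self.labels.astype(int), cv=skf,
                              scoring="accuracy").mean()
        coef = clf.coef_[0] / sd
        intercept = clf.intercept_[0] - np.sum(clf.coef_[0] * mu / sd)
        params = np.concatenate([[intercept], coef])
        return CriteriaResults(params=params, cv_accuracy=float(acc),
                               n_trials=len(self.labels), model=self)


# ---------------------------------------------------------------------------
# Transfer analysis
# ---------------------------------------------------------------------------

def anova_two_way(values: np.ndarray):
    """Two-way repeated-measures ANOVA for a 2x2 within-subject design.

    ``values`` is (n_subjects, 2, 2) indexed (subject, factor A, factor B).
    Each effect is tested against its own effect-by-subject interaction.
    Returns a dict with F and p for 'A', 'B' and 'AxB'; zero effect *and*
    zero error sums of squares yield F = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    n, a, b = values.shape
    if (a, b) != (2, 2):
        raise ValueError("a 2x2 within-subject design is required")
    if np.any(np.isnan(values)):
        raise ValueError("missing cells are not allowed")
    grand = values.mean()
    m_s = values.mean(axis=(1, 2))
    m_a = values.mean(axis=(0, 2))
    m_b = values.mean(axis=(0, 1))
    m_sa = values.mean(axis=2)
    m_sb = values.mean(axis=1)
    m_ab = values.mean(axis=0)

    def f_p(ss_eff, df_eff, ss_err, df_err):
        if ss_eff <= 1e-300:
            return 0.0, 1.0
        F = (ss_eff / df_eff) / (ss_err / df_err)
        return float(F), float(stats.f.sf(F, df_eff, df_err))

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    resid = (values - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - grand)
    ss_abs = np.sum(resid ** 2)
    out = {}
    out["A"] = f_p(ss_a, 1, max(ss_as, 1e-300), n - 1)
    out["B"] = f_p(ss_b, 1, max(ss_bs, 1e-300), n - 1)
    out["AxB"] = f_p(ss_ab, 1, max(ss_abs, 1e-300), n - 1)
    return {k: {"F": v[0], "p": v[1]} for k, v in out.items()}


@dataclass
class TransferResults:
    """Intra- vs inter-subject transfer of individual criteria classifiers.

    ``table`` is a DataFrame indexed by subject with columns
    ('behavior'/'errp') x ('intra'/'inter') accuracies in percent.
    """

    table: pd.DataFrame
    anova: dict
    posthoc: pd.DataFrame

    def cell_mean(self, source: str, condition: str) -> float:
        return float(self.table[(source, condition)].mean())

    def cell_sem(self, source: str, condition: str) -> float:
        col = self.table[(source, condition)]
        return float(col.std(ddof=1) / np.sqrt(len(col)))

    def summary(self) -> str:
        lines = ["Criteria-classifier transfer (accuracy %, mean +/- SEM)",
                 "=" * 58]
        for source in self.table.columns.levels[0]:
            for cond in ("intra", "inter"):
                lines.append(f"{source:>9s} / {cond:<6s}: "
                             f"{self.cell_mean(source, cond):5.1f} +/- "
                             f"{self.cell_sem(source, cond):.2f}")
        lines.append("-" * 58)
        for name, key in (("label source", "A"), ("transfer", "B"),
                          ("interaction", "AxB")):
            e = self.anova[key]
            lines.append(f"ANOVA {name:<13s} F(1,{len(self.table) - 1}) = "
                         f"{e['F']:6.2f}, p = {e['p']:.4g}")
        return "\n".join(lines)


class TransferAnalysis:
    """Cross-subject transfer of individually calibrated criteria classifiers.

    ``cohort`` is a DataFrame with columns ``subject``, ``efficiency``,
    ``comfort``, ``released`` (behavioral response) and, optionally,
    ``errp_label`` (the decoder's binary output at the 0.5 threshold).

    For each subject and label source, a two-covariate logistic classifier is
    trained on that subject's labels; *intra* accuracy is 10-fold
    cross-validated on the same subject, *inter* accuracy is the mean
    accuracy of the (fully trained) classifier on every other subject.
    ErrP-trained classifiers are always scored against behavioral responses —
    the quantity of interest is how well the inferred criterion predicts what
    the person actually did.
    """

    def __init__(self, cohort: pd.DataFrame):
        if cohort["subject"].nunique() < 2:
            raise ValueError("transfer analysis needs at least two subjects")
        self.cohort = cohort.reset_index(drop=True)

    def _subject_frames(self):
        return {s: g for s, g in self.cohort.groupby("subject")}

    def fit(self, n_folds: int = 10, random_state: int = 0,
            sources: Sequence[str] = ("behavior", "errp")) -> TransferResults:
        frames = self._subject_frames()
        rows = {}
        excluded = []
        for source in sources:
            label_col = "released" if source == "behavior" else "errp_label"
            for subj, g in frames.items():
                y = g[label_col].to_numpy(dtype=bool)
                behav = g["released"].to_numpy(dtype=bool)
                X = g[["efficiency", "comfort"]].to_numpy()
                if len(np.unique(y)) < 2:
                    excluded.append((source, subj))
                    continue
                # intra: 10-fold CV, scored against behavior
                skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                      random_state=random_state)
                correct = 0
                for tr, te in skf.split(X, y):
                    clf = _scaled_logistic().fit(X[tr], y[tr])
                    correct += int(np.sum(clf.predict(X[te]).astype(bool) == behav[te]))
                intra = 100.0 * correct / len(y)
                # inter: full-data classifier on every other subject's behavior
                clf = _scaled_logistic().fit(X, y)
                accs = []
                for other, go in frames.items():
                    if other == subj:
                        continue
                    pred = clf.predict(go[["efficiency", "comfort"]].to_numpy())
                    accs.append(np.mean(pred.astype(bool)
                                        == go["released"].to_numpy(dtype=bool)))
                inter = 100.0 * float(np.mean(accs))
                rows.setdefault(subj, {})[(source, "intra")] = intra
                rows.setdefault(subj, {})[(source, "inter")] = inter
        table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        table.columns = pd.MultiIndex.from_tuples(table.columns)
        table = table.dropna()
        arr = np.stack([
            [[table[(s, "intra")].iloc[i], table[(s, "inter")].iloc[i]]
             for s in sources]
            for i in range(len(table))])
        anova = anova_two_way(arr)
        posthoc = self._posthoc(table, sources)
        return TransferResults(table=table, anova=anova, posthoc=posthoc)

    @staticmethod
    def _posthoc(table: pd.DataFrame, sources) -> pd.DataFrame:
        """Paired intra-vs-inter contrasts per label source (mean diff, SEM, p)."""
        rows = []
        for source in sources:
            d = table[(source, "intra")] - table[(source, "inter")]
            t, p = stats.ttest_rel(table[(source, "intra")], table[(source, "inter")])
            rows.append({"source": source, "difference": d.mean(),
                         "sem": d.std(ddof=1) / np.sqrt(len(d)), "p": p})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Map similarity
# ---------------------------------------------------------------------------

@dataclass
class SimilarityResult:
    """Pearson similarity between behavioral and ErrP-inferred criteria maps."""

    intra: np.ndarray          # (n_subjects,) same-subject correlations
    inter_mean: np.ndarray     # (n_subjects,) mean correlation to other subjects
    inter: np.ndarray          # (n, n) full cross matrix (NaN on skipped pairs)
    wilcoxon_p: float

    def summary(self) -> str:
        lines = [
            "Criteria-map similarity (Pearson r)",
            "=" * 42,
            f"intra-subject: {np.nanmean(self.intra):.3f} +/- "
            f"{np.nanstd(self.intra) / np.sqrt(len(self.intra)):.3f} (SEM)",
            f"inter-subject: {np.nanmean(self.inter_mean):.3f} +/- "
            f"{np.nanstd(self.inter_mean) / np.sqrt(len(self.inter_mean)):.3f} (SEM)",
            f"Wilcoxon signed-rank p = {self.wilcoxon_p:.4g}",
        ]
        return "\n".join(lines)


def _pairwise_r(a: CriteriaMap, b: CriteriaMap, min_cells: int = 3):
    joint = a.occupied & b.occupied
    if joint.sum() < min_cells:
        return np.nan
    x, y = a.values[joint], b.values[joint]
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(stats.pearsonr(x, y)[0])


def criteria_similarity(behavior_maps: Sequence[CriteriaMap],
                        inferred_maps: Sequence[CriteriaMap]) -> SimilarityResult:
    """Intra- vs inter-subject Pearson correlation of criteria maps.

    All maps must share grid edges. For subjects i, j the correlation of
    subject j's behavioral map with subject i's inferred map is computed over
    jointly occupied cells (pairs with fewer than 3 shared informative cells
    are skipped). The Wilcoxon signed-rank test compares, per subject, the
    intra correlation with the mean of that subject's inter correlations.
    """
    n = len(behavior_maps)
    if n != len(inferred_maps):
        raise ValueError("one inferred map per behavioral map required")
    r = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            r[i, j] = _pairwise_r(inferred_maps[i], behavior_maps[j])
    intra = np.diag(r).copy()
    off = r.copy()
    np.fill_diagonal(off, np.nan)
    inter_mean = np.nanmean(off, axis=1)
    valid = ~np.isnan(intra) & ~np.isnan(inter_mean)
    stat = stats.wilcoxon(intra[valid], inter_mean[valid])
    return SimilarityResult(intra=intra, inter_mean=inter_mean, inter=r,
                            wilcoxon_p=float(stat.pvalue))
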