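"""Matched-pair cohort statistics.

One-way ANOVA with Tukey HSD, paired (pair-blocked) and unpaired ANCOVA with
type-III partial F tests for diagnosis, single-pass covariate retention,
co-occurring-factor scans with Bonferroni correction, and Pearson
correlations. All linear models are fit by least squares on explicitly built
design matrices; the diagnosis effect is tested by comparing full and reduced
residual sums of squares.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .measures import is_mrna_measure, subject_means

__all__ = [
    "StatsError",
    "AnovaResult",
    "AncovaResult",
    "one_way_anova_tukey",
    "ancova",
    "retain_significant_covariates",
    "run_diagnosis_test",
    "cooccurring_factor_scan",
    "correlation",
    "fold_change",
    "PAIRED_COVARIATES",
    "UNPAIRED_COVARIATES",
]

#: candidate covariates per model (RIN appended for mRNA measures)
PAIRED_COVARIATES = ("brain_pH", "pmi", "storage")
UNPAIRED_COVARIATES = ("age", "sex", "brain_pH", "pmi", "storage")


class StatsError(ValueError):
    pass


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict
    tukey: list  # (pair, adjusted_p, significant@0.05)
    letters: dict = field(default_factory=dict)


@dataclass
class AncovaResult:
    model: str  # {"paired", "unpaired"}
    diagnosis_F: float
    diagnosis_df: tuple
    p: float
    percent_difference: float
    adjusted_means: dict
    retained_covariates: list
    coefficients: dict
    n: int


def one_way_anova_tukey(groups: dict) -> AnovaResult:
    """Classical one-way ANOVA with Tukey's HSD post hoc comparisons."""
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise StatsError(f"group {k!r} has fewer than 2 values")
    labels = list(arrays)
    F, p = stats.f_oneway(*arrays.values())
    if not np.isfinite(F):  # all groups identical -> zero between and within SS
        F, p = 0.0, 1.0
    n_total = sum(a.size for a in arrays.values())
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)

    hsd = stats.tukey_hsd(*arrays.values())
    tukey = []
    different = set()
    for i, j in itertools.combinations(range(len(labels)), 2):
        adj_p = float(hsd.pvalue[i, j])
        sig = adj_p < 0.05
        tukey.append(((labels[i], labels[j]), adj_p, sig))
        if sig:
            different.add(frozenset((labels[i], labels[j])))
    letters = _compact_letters(labels, different)
    return AnovaResult(
        F=float(F), df_between=df_between, df_within=df_within, p=float(p),
        group_means={k: float(a.mean()) for k, a in arrays.items()},
        tukey=tukey, letters=letters,
    )


def _compact_letters(labels: list, different: set) -> dict:
    """Greedy compact-letter display: groups not sharing a letter differ."""
    letter_sets: list[set] = []
    for lab in labels:
        placed = False
        for s in letter_sets:
            if all(frozenset((lab, other)) not in different for other in s):
                s.add(lab)
                placed = True
        if not placed:
            letter_sets.append({lab})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lab: "" for lab in labels}
    for letter, s in zip(alphabet, letter_sets):
        for lab in s:
            out[lab] += letter
    return out


# -- linear-model core -----------------------------------------------------


def _lstsq_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid), rank


def _partial_f(X_full: np.ndarray, y: np.ndarray, drop: np.ndarray
               ) -> tuple[float, float, int, int]:
    """Type-III partial F for the columns flagged in ``drop``."""
    _, rss_full, rank_full = _lstsq_rss(X_full, y)
    X_red = X_full[:, ~drop]
    _, rss_red, rank_red = _lstsq_rss(X_red, y)
    q = rank_full - rank_red
    df_resid = len(y) - rank_full
    if q < 1 or df_resid < 1:
        raise StatsError("degenerate design: no testable degrees of freedom")
    F = ((rss_red - rss_full) / q) / (rss_full / df_resid)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, q, df_resid))
    return float(F), p, int(q), int(df_resid)


def _build_design(subjects: pd.DataFrame, model: str, covariates: tuple
                  ) -> tuple[np.ndarray, list, np.ndarray]:
    """Design matrix, column names and the boolean diagnosis-column flag."""
    n = len(subjects)
    cols = [np.ones(n)]
    names = ["intercept"]
    diag = (subjects.diagnosis == "schizophrenia").to_numpy(float)
    cols.append(diag)
    names.append("diagnosis[schizophrenia]")
    if model == "paired":
        pair_ids = sorted(subjects.pair_id.unique())
        for pid in pair_ids[1:]:
            cols.append((subjects.pair_id == pid).to_numpy(float))
            names.append(f"pair[{pid}]")
    elif model != "unpaired":
        raise StatsError(f"unknown model {model!r}")
    for cov in covariates:
        if cov == "sex":
            x = (subjects.sex == "M").to_numpy(float)
        else:
            x = subjects[cov].to_numpy(float)
        cols.append(x - x.mean())
        names.append(cov)
    X = np.column_stack(cols)
    is_diag = np.array([nm == "diagnosis[schizophrenia]" for nm in names])
    return X, names, is_diag


def _check_rank(X: np.ndarray, names: list) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        aliased = [
            names[j] for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise StatsError(f"rank-deficient design; aliased terms: {aliased}")


def _subject_table(dataset, measure: str) -> pd.DataFrame:
    """Subjects table with the dependent variable (mean over sampled PVIs)."""
    means = subject_means(dataset.cells, measure)
    tbl = dataset.subjects.copy()
    tbl["_y"] = tbl.subject_id.map(means)
    if tbl["_y"].isna().any():
        missing = tbl.loc[tbl["_y"].isna(), "subject_id"].tolist()
        raise StatsError(f"subjects without sampled cells: {missing}")
    return tbl


def default_covariates(measure: str, model: str) -> tuple:
    base = PAIRED_COVARIATES if model == "paired" else UNPAIRED_COVARIATES
    if is_mrna_measure(measure):
        return base + ("rin",)
    return base


def ancova(dataset, measure: str, model: str = "paired",
           covariates: tuple | None = None) -> AncovaResult:
    """ANCOVA for the diagnosis effect on a subject-level dependent measure.

    paired:   y ~ diagnosis + pair(block) + covariates
    unpaired: y ~ diagnosis + covariates

    Diagnosis is tested by a type-III partial F (full vs reduced RSS). The
    percent difference comes from adjusted group means computed by averaging
    model predictions over all subjects with diagnosis toggled.
    """
    if covariates is None:
        covariates = default_covariates(measure, model)
    tbl = _subject_table(dataset, measure)
    if model == "paired":
        sizes = tbl.groupby("pair_id").size()
        if (sizes != 2).any():
            raise StatsError(f"incomplete pairs: {sizes[sizes != 2].index.tolist()}")
    y = tbl["_y"].to_numpy(float)
    X, names, is_diag = _build_design(tbl, model, covariates)
    _check_rank(X, names)
    F, p, q, df_resid = _partial_f(X, y, is_diag)

    beta, _, _ = _lstsq_rss(X, y)
    j = int(np.flatnonzero(is_diag)[0])
    X0 = X.copy(); X0[:, j] = 0.0
    X1 = X.copy(); X1[:, j] = 1.0
    adj_comp = float((X0 @ beta).mean())
    adj_sz = float((X1 @ beta).mean())
    if adj_comp <= 0:
        pct = float("nan")
    else:
        pct = 100.0 * (1.0 - adj_sz / adj_comp)
    return AncovaResult(
        model=model, diagnosis_F=F, diagnosis_df=(q, df_resid), p=p,
        percent_difference=pct,
        adjusted_means={"comparison": adj_comp, "schizophrenia": adj_sz},
        retained_covariates=list(covariates),
        coefficients=dict(zip(names, map(float, beta))),
        n=len(y),
    )


def retain_significant_covariates(dataset, measure: str, model: str = "paired",
                                  candidates: tuple | None = None) -> list:
    """Single-pass covariate retention: fit the full model once, keep the
    covariates whose partial F has p < 0.05."""
    if candidates is None:
        candidates = default_covariates(measure, model)
    if not candidates:
        return []
    tbl = _subject_table(dataset, measure)
    y = tbl["_y"].to_numpy(float)
    X, names, _ = _build_design(tbl, model, tuple(candidates))
    _check_rank(X, names)
    retained = []
    for cov in candidates:
        drop = np.array([nm == cov for nm in names])
        _, p, _, _ = _partial_f(X, y, drop)
        if p < 0.05:
            retained.append(cov)
    return retained


def run_diagnosis_test(dataset, measure: str, model: str = "paired",
                       candidates: tuple | None = None) -> AncovaResult:
    """Full reported pipeline: covariate retention, then the final ANCOVA."""
    retained = retain_significant_covariates(dataset, measure, model, candidates)
    return ancova(dataset, measure, model, covariates=tuple(retained))


def cooccurring_factor_scan(dataset, measure: str, factors: tuple,
                            correction: str = "bonferroni") -> pd.DataFrame:
    """One ANCOVA per co-occurring factor within the schizophrenia group.

    Each model: y ~ factor + sex + age + brain_pH + pmi + storage (+ rin for
    mRNA measures); p-values Bonferroni-adjusted across the scanned factors.
    """
    tbl = _subject_table(dataset, measure)
    tbl = tbl[tbl.diagnosis == "schizophrenia"].reset_index(drop=True)
    covs = ("sex", "age", "brain_pH", "pmi", "storage")
    if is_mrna_measure(measure):
        covs = covs + ("rin",)
    rows = []
    tested = []
    for factor in factors:
        vals = tbl[factor].astype(bool)
        if vals.nunique() < 2:
            warnings.warn(f"factor {factor!r} constant in schizophrenia group; skipped")
            continue
        y = tbl["_y"].to_numpy(float)
        n = len(tbl)
        cols = [np.ones(n), vals.to_numpy(float)]
        names = ["intercept", factor]
        for cov in covs:
            x = (tbl.sex == "M").to_numpy(float) if cov == "sex" else tbl[cov].to_numpy(float)
            cols.append(x - x.mean())
            names.append(cov)
        X = np.column_stack(cols)
        _check_rank(X, names)
        drop = np.array([nm == factor for nm in names])
        F, p, _, _ = _partial_f(X, y, drop)
        rows.append({"factor": factor, "F": F, "p": p})
        tested.append(factor)
    out = pd.DataFrame(rows, columns=["factor", "F", "p"])
    if len(out):
        if correction != "bonferroni":
            raise StatsError(f"unknown correction {correction!r}")
        out["p_adjusted"] = np.minimum(1.0, out["p"] * len(out))
    else:
        out["p_adjusted"] = pd.Series(dtype=float)
    return out


def correlation(x, y) -> tuple[float, float, int]:
    """Pearson correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need matched x, y with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise StatsError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), int(x.size)


def fold_change(numerator_group_mean: float, denominator_group_mean: float) -> float:
    """Ratio of two group means."""
    if denominator_group_mean <= 0:
        raise StatsError("fold change needs a positive denominator mean")
    return numerator_group_mean / denominator_group_mean
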