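"""Survival analysis of immune infiltration and CD8+ T-cell functional state.

Contents:

* Kaplan-Meier stratification of each cancer by the top/bottom fraction of a
  cell type's infiltration score (single and dual cell type), with log-rank
  test and univariate Cox hazard ratio.
* A fold-change screen for genes differing between outcome groups.
* The T-cell activation score: an inverse-variance-weighted mean of the
  expression of TCR-signaling genes, ``sum(w_i x_i) / sum(w_i)`` with
  ``w_i = 1 / Var(x_i)``.
* Dichotomization of the activation score at the cutoff maximizing the
  absolute log hazard ratio, subject to a minimum arm size.
* Age- and stage-adjusted Cox proportional-hazards regression (univariate
  fits reported alongside the multivariate model).

The hazard-ratio-maximizing cutoff is a post-selection procedure: the
log-rank p-value at the selected cutoff is anti-conservative and is reported
as-is, uncorrected (see the package methods note).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy.stats import ttest_ind

from .landscape_analysis import parse_stage

__all__ = [
    "DEFAULT_ACTIVATION_GENES",
    "GENE_ALIASES",
    "ActivationScoreModel",
    "SurvivalStratification",
    "CutoffResult",
    "CoxResult",
    "ScreenResult",
    "ResponderResult",
    "stratified_survival",
    "dual_cell_survival",
    "differential_screen",
    "activation_score",
    "optimal_cutoff",
    "cox_adjusted",
    "responder_scores",
]

#: TCR-signaling / T-cell activation gene panel used for the activation score.
DEFAULT_ACTIVATION_GENES = (
    "GRAP2",
    "CD247",
    "CD3E",
    "CD3D",
    "ZAP70",
    "CD8B",
    "CD1C",
    "TDGF1",
    "TCF7",
    "SH2D1A",
    "LCK",
    "CTSL2",
)

#: Deprecated-symbol aliases resolved when matching panel genes to a matrix.
GENE_ALIASES = {"CTSL2": "CTSV", "CTSV": "CTSL2"}


@dataclass(frozen=True)
class ActivationScoreModel:
    """Gene panel with optional frozen inverse-variance weights.

    When ``weights`` is None the weights are recomputed as the reciprocal of
    each gene's expression variance in the cohort being scored; freezing them
    from a reference cohort makes scores transferable across datasets.
    """

    genes: tuple[str, ...] = DEFAULT_ACTIVATION_GENES
    weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("activation model needs at least one gene")
        if self.weights is not None and any(w <= 0 for w in self.weights.values()):
            raise ValueError("frozen weights must be positive")


@dataclass(frozen=True)
class SurvivalStratification:
    cancer: str
    cell_type: str
    n_high: int
    n_low: int
    hazard_ratio: float | None
    ci_lower: float | None
    ci_upper: float | None
    logrank_p: float | None
    km_high: pd.DataFrame | None
    km_low: pd.DataFrame | None
    high_samples: tuple[str, ...]
    low_samples: tuple[str, ...]
    degenerate: bool = False
    reason: str = ""


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    labels: pd.Series  # sample -> True when score > cutoff
    log_hr: float
    hazard_ratio: float
    n_high: int
    n_low: int


@dataclass(frozen=True)
class CoxResult:
    """Multivariate summary plus per-covariate univariate fits.

    Each summary row: hazard_ratio, ci_lower, ci_upper, p.
    """

    multivariate: pd.DataFrame
    univariate: dict[str, pd.DataFrame]


@dataclass(frozen=True)
class ScreenResult:
    table: pd.DataFrame  # gene, mean_a, mean_b, fold_change
    up: tuple[str, ...]
    down: tuple[str, ...]
    group_a: str
    group_b: str


@dataclass(frozen=True)
class ResponderResult:
    scores: pd.Series
    group_scores: dict[str, pd.Series]
    tests: pd.DataFrame  # group_a, group_b, t_stat, p_value


# ---------------------------------------------------------------------------
# survival helpers


def _check_survival(clinical: pd.DataFrame, samples: pd.Index) -> pd.DataFrame:
    sub = clinical.reindex(samples)
    bad = sub.index[sub["os_days"].isna() | sub["os_event"].isna()].tolist()
    if bad:
        raise ValueError(f"samples with missing survival fields: {bad}")
    return sub


def _top_bottom(s: pd.Series, frac: float) -> tuple[list[str], list[str]]:
    """Top ceil(frac*n) and bottom floor(frac*n) samples by score (ties by ID)."""
    n = len(s)
    order = sorted(s.index, key=lambda i: (-s[i], i))
    k_high = math.ceil(frac * n)
    k_low = math.floor(frac * n)
    return order[:k_high], order[n - k_low :] if k_low else []


def _km_curve(times: np.ndarray, events: np.ndarray, label: str) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label=label)
    out = kmf.survival_function_.reset_index()
    out.columns = ["time", "survival"]
    return out


def _binary_cox(
    times: np.ndarray, events: np.ndarray, high: np.ndarray
) -> tuple[float, float, float]:
    """lifelines univariate Cox fit of a high/low indicator: (HR, lo, hi)."""
    df = pd.DataFrame({"T": times, "E": events, "high": high.astype(float)})
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="T", event_col="E")
    row = cph.summary.loc["high"]
    return (
        float(row["exp(coef)"]),
        float(row["exp(coef) lower 95%"]),
        float(row["exp(coef) upper 95%"]),
    )


def _stratify_arms(
    high: Sequence[str],
    low: Sequence[str],
    clinical: pd.DataFrame,
    cancer: str,
    cell_type: str,
    min_group: int,
) -> SurvivalStratification | None:
    if len(high) == 0 or len(low) == 0:
        return SurvivalStratification(
            cancer=cancer,
            cell_type=cell_type,
            n_high=len(high),
            n_low=len(low),
            hazard_ratio=None,
            ci_lower=None,
            ci_upper=None,
            logrank_p=None,
            km_high=None,
            km_low=None,
            high_samples=tuple(high),
            low_samples=tuple(low),
            degenerate=True,
            reason="empty arm",
        )
    if min(len(high), len(low)) < min_group:
        return None  # cancer dropped by the minimum-arm-size rule
    sub = _check_survival(clinical, pd.Index(list(high) + list(low)))
    t = sub["os_days"].to_numpy(dtype=float)
    e = sub["os_event"].to_numpy(dtype=float)
    is_high = np.array([s in set(high) for s in sub.index])
    lr = logrank_test(t[is_high], t[~is_high], e[is_high], e[~is_high])
    hr, lo, hi = _binary_cox(t, e, is_high)
    return SurvivalStratification(
        cancer=cancer,
        cell_type=cell_type,
        n_high=len(high),
        n_low=len(low),
        hazard_ratio=hr,
        ci_lower=lo,
        ci_upper=hi,
        logrank_p=float(lr.p_value),
        km_high=_km_curve(t[is_high], e[is_high], "high"),
        km_low=_km_curve(t[~is_high], e[~is_high], "low"),
        high_samples=tuple(high),
        low_samples=tuple(low),
    )


def stratified_survival(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    cell_type: str,
    top_frac: float = 0.2,
    min_group: int = 30,
) -> list[SurvivalStratification]:
    """Per cancer: compare the top vs bottom ``top_frac`` of samples by score.

    Cancers whose high or low arm falls below ``min_group`` are dropped.
    Each retained cancer gets Kaplan-Meier curves for both arms, the log-rank
    p-value, and the univariate Cox hazard ratio (high vs low) with 95% CI.
    """
    if not 0 < top_frac <= 0.5:
        raise ValueError("top_frac must be in (0, 0.5]")
    if cell_type not in scores.columns:
        raise KeyError(f"unknown cell type {cell_type!r}")
    cancers = clinical["cancer_type"].reindex(scores.index)
    results = []
    for cancer, idx in scores.index.groupby(cancers).items():
        s = scores.loc[pd.Index(idx), cell_type]
        high, low = _top_bottom(s, top_frac)
        res = _stratify_arms(high, low, clinical, str(cancer), cell_type, min_group)
        if res is not None:
            results.append(res)
    return results


def dual_cell_survival(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    cell_type_a: str,
    cell_type_b: str,
    top_frac: float = 0.2,
    min_group: int = 30,
) -> list[SurvivalStratification]:
    """As :func:`stratified_survival`, but arms are high (resp. low) in BOTH cell types."""
    if not 0 < top_frac <= 0.5:
        raise ValueError("top_frac must be in (0, 0.5]")
    for ct in (cell_type_a, cell_type_b):
        if ct not in scores.columns:
            raise KeyError(f"unknown cell type {ct!r}")
    cancers = clinical["cancer_type"].reindex(scores.index)
    label = f"{cell_type_a}+{cell_type_b}"
    results = []
    for cancer, idx in scores.index.groupby(cancers).items():
        idx = pd.Index(idx)
        high_a, low_a = _top_bottom(scores.loc[idx, cell_type_a], top_frac)
        high_b, low_b = _top_bottom(scores.loc[idx, cell_type_b], top_frac)
        high = sorted(set(high_a) & set(high_b))
        low = sorted(set(low_a) & set(low_b))
        res = _stratify_arms(high, low, clinical, str(cancer), label, min_group)
        if res is not None:
            results.append(res)
    return results


# ---------------------------------------------------------------------------
# differential screen


def differential_screen(
    expr: pd.DataFrame,
    group_labels: pd.Series,
    fc_min: float = 2.0,
    *,
    pseudo: float = 1.0,
    group_a: str | None = None,
    group_b: str | None = None,
) -> ScreenResult:
    """Fold-change screen between two sample groups (e.g. alive vs deceased).

    Fold change per gene is ``(mean_a + pseudo) / (mean_b + pseudo)``; genes
    with FC > ``fc_min`` are reported up, FC < 1/``fc_min`` down.  The
    pseudo-count guards against division by zero on FPKM-scale means.
    """
    labels = group_labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a group label")
    uniq = sorted(labels.unique())
    if group_a is None or group_b is None:
        if len(uniq) != 2:
            raise ValueError("specify group_a/group_b when there are not exactly 2 groups")
        group_a, group_b = uniq
    for g in (group_a, group_b):
        if (labels == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")
    if fc_min <= 1:
        raise ValueError("fc_min must be > 1")
    mean_a = expr[labels.index[labels == group_a]].mean(axis=1)
    mean_b = expr[labels.index[labels == group_b]].mean(axis=1)
    fc = (mean_a + pseudo) / (mean_b + pseudo)
    table = pd.DataFrame(
        {"gene": expr.index, "mean_a": mean_a.values, "mean_b": mean_b.values,
         "fold_change": fc.values}
    )
    up = tuple(table.loc[table["fold_change"] > fc_min, "gene"])
    down = tuple(table.loc[table["fold_change"] < 1.0 / fc_min, "gene"])
    return ScreenResult(table=table, up=up, down=down, group_a=group_a, group_b=group_b)


# ---------------------------------------------------------------------------
# activation score


def activation_score(
    expr: pd.DataFrame, model: ActivationScoreModel | None = None
) -> pd.Series:
    """Inverse-variance-weighted mean expression of the activation panel.

    Per sample: ``sum_i w_i x_i / sum_i w_i`` over the panel genes present in
    the matrix (deprecated symbols are resolved via :data:`GENE_ALIASES`).
    Unless the model carries frozen weights, ``w_i = 1 / Var(x_i)`` with the
    variance taken across the supplied cohort; zero-variance genes are
    excluded with a warning.
    """
    model = model or ActivationScoreModel()
    resolved: dict[str, str] = {}  # matrix row -> panel gene
    for g in model.genes:
        if g in expr.index:
            resolved[g] = g
        elif GENE_ALIASES.get(g) in expr.index:
            resolved[GENE_ALIASES[g]] = g
    if not resolved:
        raise ValueError("no activation panel gene found in the expression matrix")
    if len(resolved) < len(model.genes):
        missing = set(model.genes) - set(resolved.values())
        warnings.warn(
            f"activation panel genes absent from matrix: {sorted(missing)}",
            stacklevel=2,
        )
    sub = expr.loc[list(resolved)]
    if model.weights is not None:
        w = pd.Series(
            {row: float(model.weights.get(panel, np.nan)) for row, panel in resolved.items()}
        )
        w = w.dropna()
        sub = sub.loc[w.index]
    else:
        var = sub.var(axis=1, ddof=1)
        zero = var.index[var == 0].tolist()
        if zero:
            warnings.warn(f"zero-variance genes excluded from score: {zero}", stacklevel=2)
            sub = sub.drop(index=zero)
            var = var.drop(index=zero)
        if sub.empty:
            raise ValueError("all activation panel genes have zero variance")
        w = 1.0 / var
    score = sub.mul(w, axis=0).sum(axis=0) / w.sum()
    score.name = "activation_score"
    return score


# ---------------------------------------------------------------------------
# univariate Cox partial likelihood (Efron ties), used by the cutoff scan


def _cox_univariate(x: np.ndarray, time: np.ndarray, event: np.ndarray) -> tuple[float, float]:
    """Newton fit of a one-covariate Cox model; returns (beta, se).

    Efron approximation for tied event times (the same convention lifelines
    uses), so results agree with a lifelines fit to optimizer precision.
    """
    order = np.argsort(time, kind="stable")
    t, d, xs = time[order], event[order].astype(bool), np.asarray(x, float)[order]
    n = len(t)
    # event-time groups: (risk-set start index, indices of tied events)
    groups: list[tuple[int, np.ndarray]] = []
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        dead = np.arange(i, j)[d[i:j]]
        if dead.size:
            groups.append((i, dead))
        i = j
    if not groups:
        raise ValueError("no events observed")

    def quantities(beta: float) -> tuple[float, float, float]:
        th = np.exp(np.clip(beta * xs, -700, 700))
        a, b = th * xs, th * xs * xs
        c0 = np.concatenate([[0.0], np.cumsum(th)])
        c1 = np.concatenate([[0.0], np.cumsum(a)])
        c2 = np.concatenate([[0.0], np.cumsum(b)])
        tot0, tot1, tot2 = c0[-1], c1[-1], c2[-1]
        ll, grad, info = 0.0, 0.0, 0.0
        for start, dead in groups:
            s0, s1, s2 = tot0 - c0[start], tot1 - c1[start], tot2 - c2[start]
            d0, d1, d2 = th[dead].sum(), a[dead].sum(), b[dead].sum()
            m = dead.size
            ll += beta * xs[dead].sum()
            grad += xs[dead].sum()
            for l in range(m):
                f = l / m
                r0 = s0 - f * d0
                r1 = s1 - f * d1
                r2 = s2 - f * d2
                mu = r1 / r0
                ll -= math.log(r0)
                grad -= mu
                info += r2 / r0 - mu * mu
        return ll, grad, info

    beta = 0.0
    ll, grad, info = quantities(beta)
    for _ in range(60):
        if info <= 0:
            break
        step = grad / info
        step = float(np.clip(step, -5.0, 5.0))  # trust region against overshoot
        new_beta = float(np.clip(beta + step, -20.0, 20.0))
        new_ll, new_grad, new_info = quantities(new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 40:
            step /= 2.0
            new_beta = float(np.clip(beta + step, -20.0, 20.0))
            new_ll, new_grad, new_info = quantities(new_beta)
            halvings += 1
        converged = abs(new_beta - beta) < 1e-12 or (
            abs(new_beta) >= 20.0 and abs(beta) >= 20.0
        )
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if converged:
            break
    se = 1.0 / math.sqrt(info) if info > 0 else np.inf
    return beta, se


def optimal_cutoff(
    scores: pd.Series,
    clinical: pd.DataFrame,
    *,
    min_group: int | None = None,
) -> CutoffResult:
    """Dichotomize a score at the cutoff maximizing |log HR| of high vs low.

    Candidate cutoffs are the midpoints between consecutive sorted unique
    score values; a candidate is admissible when both arms contain at least
    ``min_group`` samples (default: 10% of n, at least 2).  At each
    admissible cutoff a univariate Cox model of the high/low indicator is
    fitted; the cutoff with the largest absolute log hazard ratio wins, with
    ties broken toward the more balanced split and then toward the smaller
    cutoff.  This is post-selection inference: downstream p-values at the
    selected cutoff are anti-conservative.
    """
    n = len(scores)
    if min_group is None:
        min_group = max(2, math.ceil(0.1 * n))
    if n < 2 * min_group:
        raise ValueError(f"need at least {2 * min_group} samples")
    sub = _check_survival(clinical, scores.index)
    t = sub["os_days"].to_numpy(dtype=float)
    e = sub["os_event"].to_numpy(dtype=float)
    vals = scores.to_numpy(dtype=float)
    uniq = np.unique(vals)
    if uniq.size < 2:
        raise ValueError("scores are constant; no admissible cutoff")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0

    records = []
    for c in candidates:
        high = vals > c
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_high, n_low) < min_group:
            continue
        beta, _ = _cox_univariate(high.astype(float), t, e)
        records.append((abs(beta), abs(n_high - n_low), float(c), beta, n_high, n_low, high))
    if not records:
        raise ValueError("no admissible cutoff satisfies the minimum arm size")
    best_abs = max(r[0] for r in records)
    ties = [r for r in records if r[0] >= best_abs - 1e-9]
    ties.sort(key=lambda r: (r[1], r[2]))
    _, _, cutoff, beta, n_high, n_low, high = ties[0]
    return CutoffResult(
        cutoff=cutoff,
        labels=pd.Series(high, index=scores.index, name="activation_high"),
        log_hr=float(beta),
        hazard_ratio=float(np.exp(beta)),
        n_high=n_high,
        n_low=n_low,
    )


# ---------------------------------------------------------------------------
# Cox regression


def _summary_frame(cph: CoxPHFitter) -> pd.DataFrame:
    s = cph.summary
    out = pd.DataFrame(
        {
            "hazard_ratio": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    out.index.name = "covariate"
    return out


def _fit_cox(df: pd.DataFrame) -> pd.DataFrame:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="T", event_col="E")
    except ConvergenceError as exc:
        raise RuntimeError(
            f"Cox model failed to converge (n={len(df)}, events={int(df['E'].sum())}, "
            f"covariates={[c for c in df.columns if c not in ('T', 'E')]}): {exc}"
        ) from exc
    return _summary_frame(cph)


def cox_adjusted(
    activation: pd.Series,
    clinical: pd.DataFrame,
    *,
    stage_categorical: bool = False,
    standardize: bool = True,
) -> CoxResult:
    """Cox PH regression of survival on activation, adjusted for age and stage.

    ``activation`` may be binary (high/low labels; fitted as a 0/1 indicator
    named ``activation_high``) or continuous (z-scored per SD when
    ``standardize``, named ``activation_score``).  Stage enters as an ordinal
    1-4 covariate by default, or as indicator columns with
    ``stage_categorical=True``.  Univariate fits for every covariate are
    reported alongside the multivariate model.
    """
    sub = _check_survival(clinical, activation.index)
    if len(sub) < 3:
        raise ValueError("insufficient data for Cox regression (need >= 3 samples)")
    act = activation.astype(float)
    uniq = set(act.unique())
    if uniq <= {0.0, 1.0}:
        act_name = "activation_high"
    else:
        act_name = "activation_score"
        if standardize:
            sd = act.std(ddof=0)
            if sd == 0:
                raise ValueError("activation covariate is constant")
            act = (act - act.mean()) / sd
    stage = sub["stage"].map(parse_stage)
    df = pd.DataFrame(
        {
            "T": sub["os_days"].astype(float),
            "E": sub["os_event"].astype(float),
            act_name: act,
            "age": sub["age"].astype(float),
        }
    )
    if stage_categorical:
        dummies = pd.get_dummies(stage.astype("Int64"), prefix="stage", dtype=float)
        df = pd.concat([df, dummies.iloc[:, 1:]], axis=1)
    else:
        df["stage"] = stage.astype(float)
    df = df.dropna()
    covs = [c for c in df.columns if c not in ("T", "E")]
    for c in covs:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")
    multivariate = _fit_cox(df)
    univariate = {c: _fit_cox(df[["T", "E", c]]) for c in covs}
    return CoxResult(multivariate=multivariate, univariate=univariate)


# ---------------------------------------------------------------------------
# responder comparison


def responder_scores(
    expr: pd.DataFrame,
    response_labels: pd.Series,
    model: ActivationScoreModel | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> ResponderResult:
    """Activation score per response group plus Student's t-test between groups.

    ``pairs`` restricts which group pairs are tested (default: all pairs of
    observed labels, alphabetically).  Each group needs >= 2 samples.
    """
    labels = response_labels.reindex(expr.columns)
    if labels.isna().any():
        raise ValueError("every sample needs a response label")
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 response groups")
    scores = activation_score(expr, model)
    group_scores = {g: scores[labels.index[labels == g]] for g in groups}
    for g, s in group_scores.items():
        if len(s) < 2:
            raise ValueError(f"response group {g!r} has fewer than 2 samples")
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    rows = []
    for a, b in pairs:
        t, p = ttest_ind(group_scores[a], group_scores[b], equal_var=True)
        rows.append({"group_a": a, "group_b": b, "t_stat": float(t), "p_value": float(p)})
    return ResponderResult(
        scores=scores, group_scores=group_scores, tests=pd.DataFrame(rows)
    )
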