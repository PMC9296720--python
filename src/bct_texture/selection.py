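"""Feature-selection cascade: ANOVA, rank correlation, redundancy rejection.

Three screening steps reduce the 19 texture features to a small set that
separates the four density grades and is mutually non-redundant:

1. one-way ANOVA across the four classes with Bonferroni-adjusted
   pairwise post-hoc tests; a feature survives only if *every* class pair
   differs (all six adjusted p < 0.05);
2. Spearman rank correlation against the ordinal density grade
   (a=1 ... d=4); a feature survives with p < 0.05 and at least moderate
   strength (|rho| > 0.50);
3. among surviving pairs with inter-feature |rho| >= 0.80 the member that
   is more entangled with the remaining candidates (larger mean absolute
   correlation) is rejected as redundant.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .phantom import DENSITY_CLASSES, DENSITY_ORDINAL
from .texture import FEATURE_NAMES

__all__ = [
    "AnovaResult",
    "SpearmanResult",
    "SelectionReport",
    "validate_feature_table",
    "anova_with_bonferroni",
    "spearman_vs_density",
    "correlation_strength_label",
    "feature_correlation_cluster",
    "candidates_from_adjusted_p",
    "select_features",
    "run_selection",
]

ALPHA = 0.05
MODERATE_RHO = 0.50
REDUNDANCY_RHO = 0.80


@dataclass
class AnovaResult:
    feature: str
    f_statistic: float
    p_value: float
    pairwise_adjusted_p: dict[tuple[str, str], float]
    passes: bool
    degenerate: bool = False


@dataclass
class SpearmanResult:
    feature: str
    rho: float
    p_value: float
    constant: bool = False

    @property
    def strength(self) -> str:
        return correlation_strength_label(self.rho)[0]


@dataclass
class SelectionReport:
    """Full record of the cascade, including why each feature was dropped."""

    anova: dict[str, AnovaResult]
    spearman: dict[str, SpearmanResult]
    candidates: list[str]  # ANOVA survivors
    step2_survivors: list[str]
    retained: list[str]
    rejections: dict[str, str]  # feature -> anova_fail | nonsignificant_rho | redundant_with:<name>
    correlation_matrix: pd.DataFrame | None = None
    dendrogram_order: list[str] | None = None

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "candidates": self.candidates,
            "step2_survivors": self.step2_survivors,
            "retained": self.retained,
            "rejections": self.rejections,
            "anova": {
                k: {"F": v.f_statistic, "p": v.p_value, "passes": v.passes}
                for k, v in self.anova.items()
            },
            "spearman": {
                k: {"rho": v.rho, "p": v.p_value, "strength": v.strength}
                for k, v in self.spearman.items()
            },
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=2))
        return path


def validate_feature_table(table: pd.DataFrame, features: Sequence[str] | None = None) -> None:
    features = list(features or FEATURE_NAMES)
    if "density" not in table.columns:
        raise ValueError("feature table needs a 'density' column")
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    counts = table["density"].value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 classes with >= 2 rows each")


def anova_with_bonferroni(
    table: pd.DataFrame, feature: str, welch: bool = False
) -> AnovaResult:
    """One-way ANOVA over the density classes plus pairwise post-hoc tests.

    Post-hoc comparisons are two-sample t-tests (pooled variance by
    default, Welch optionally) for all six class pairs, Bonferroni
    adjusted (p x 6, capped at 1).  A feature passes only if all six
    adjusted p-values fall below 0.05; a zero-variance (degenerate)
    feature is flagged and fails.
    """
    classes = [c for c in DENSITY_CLASSES if c in set(table["density"])]
    groups = [table.loc[table["density"] == c, feature].to_numpy(float) for c in classes]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every class needs at least 2 rows")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        pairs = {p: 1.0 for p in itertools.combinations(classes, 2)}
        return AnovaResult(feature, float("nan"), 1.0, pairs, passes=False, degenerate=True)
    f_stat, p_val = stats.f_oneway(*groups)
    n_pairs = len(classes) * (len(classes) - 1) // 2
    pairwise: dict[tuple[str, str], float] = {}
    for (ca, ga), (cb, gb) in itertools.combinations(zip(classes, groups), 2):
        if np.ptp(ga) == 0 and np.ptp(gb) == 0:
            p = 0.0 if ga[0] != gb[0] else 1.0
        else:
            p = stats.ttest_ind(ga, gb, equal_var=not welch).pvalue
        pairwise[(ca, cb)] = min(1.0, float(p) * n_pairs)
    passes = all(p < ALPHA for p in pairwise.values())
    return AnovaResult(feature, float(f_stat), float(p_val), pairwise, passes=passes)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    n = len(rx)
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    perms = itertools.permutations(range(n))
    while True:
        chunk = np.array(list(itertools.islice(perms, 50000)), dtype=np.intp)
        if chunk.size == 0:
            break
        rhos = rx[chunk] @ ry / n
        count += int(np.sum(np.abs(rhos) >= target))
        total += chunk.shape[0]
    return count / total


def spearman_vs_density(table: pd.DataFrame, feature: str) -> SpearmanResult:
    """Spearman rank correlation of one feature with the ordinal density.

    Ties get average ranks (density is heavily tied by design); the
    p-value comes from the t approximation, replaced by an exact
    permutation p for n <= 10.  A constant feature has undefined rho and
    is reported as rho 0, p 1, flagged.
    """
    y = table["density"].map(DENSITY_ORDINAL).to_numpy(float)
    x = table[feature].to_numpy(float)
    if len(x) < 3:
        raise ValueError("need at least 3 rows")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(feature, 0.0, 1.0, constant=True)
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if len(x) <= 10:
        p = _exact_spearman_p(x, y, rho)
    return SpearmanResult(feature, rho, float(p))


def correlation_strength_label(rho: float) -> tuple[str, str]:
    """Verbal strength band for a rank correlation, plus its sign.

    |rho| > 0.80 strong, 0.51-0.80 moderate, 0.11-0.50 weak, <= 0.10
    absent.  Returns ``(strength, sign)``.
    """
    if not -1.0 <= rho <= 1.0 + 1e-12:
        raise ValueError(f"rho out of range: {rho}")
    a = abs(rho)
    if a > 0.80:
        strength = "strong"
    elif a > 0.50:
        strength = "moderate"
    elif a > 0.10:
        strength = "weak"
    else:
        strength = "absent"
    sign = "negative" if rho < 0 else "positive" if rho > 0 else "zero"
    return strength, sign


def feature_correlation_cluster(
    table: pd.DataFrame, candidates: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Inter-feature Spearman matrix and average-linkage leaf order.

    Hierarchical clustering on the distance ``1 - |rho|`` groups features
    that carry the same information; the returned leaf order sorts the
    matrix so redundant blocks are adjacent.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate features")
    corr = table[candidates].corr(method="spearman")
    dist = 1.0 - corr.abs().to_numpy()
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [candidates[i] for i in leaves_list(z)]
    return corr, order


def candidates_from_adjusted_p(adjusted_p: Mapping[str, float], alpha: float = ALPHA) -> list[str]:
    """Apply the step-1 retention rule to worst-case adjusted p-values.

    ``adjusted_p`` maps feature -> the largest Bonferroni-adjusted
    pairwise p-value; a feature is a candidate iff that maximum is below
    ``alpha`` (i.e. every pairwise comparison is significant).
    """
    return [f for f in FEATURE_NAMES if f in adjusted_p and adjusted_p[f] < alpha]


def select_features(
    anova: Mapping[str, AnovaResult] | Mapping[str, bool],
    spearman: Mapping[str, SpearmanResult] | Mapping[str, tuple[float, float]],
    correlation_matrix: pd.DataFrame,
) -> tuple[list[str], dict[str, str]]:
    """The three-step cascade; returns (retained, rejection reasons).

    Step 3 resolves each redundant pair (|rho| >= 0.80, strongest pair
    first) by rejecting the member with the larger mean absolute
    correlation to the other candidates — the less independent one.  Ties
    break toward keeping the stronger density correlate, then
    alphabetically.  A rejected feature is never reinstated.
    """
    def _passes(v) -> bool:
        return v.passes if isinstance(v, AnovaResult) else bool(v)

    def _rho_p(v) -> tuple[float, float]:
        return (v.rho, v.p_value) if isinstance(v, SpearmanResult) else (float(v[0]), float(v[1]))

    rejections: dict[str, str] = {}
    order = {f: k for k, f in enumerate(FEATURE_NAMES)}
    candidates = sorted(anova, key=lambda f: (order.get(f, len(order)), f))
    step1 = []
    for f in candidates:
        if _passes(anova[f]):
            step1.append(f)
        else:
            rejections[f] = "anova_fail"

    step2 = []
    for f in step1:
        rho, p = _rho_p(spearman[f])
        if p < ALPHA and abs(rho) > MODERATE_RHO:
            step2.append(f)
        else:
            rejections[f] = "nonsignificant_rho"

    corr = correlation_matrix

    def independence_score(f: str) -> float:
        others = [g for g in step1 if g != f and g in corr.columns]
        if not others:
            return 0.0
        return float(np.mean([abs(corr.loc[f, g]) for g in others]))

    retained = sorted(step2)
    while True:
        pairs = [
            (f, g)
            for f, g in itertools.combinations(retained, 2)
            if abs(corr.loc[f, g]) >= REDUNDANCY_RHO
        ]
        if not pairs:
            break
        f, g = max(pairs, key=lambda fg: (abs(corr.loc[fg[0], fg[1]]), fg))
        sf, sg = independence_score(f), independence_score(g)
        if sf != sg:
            reject, keep = (f, g) if sf > sg else (g, f)
        else:
            rf, rg = abs(_rho_p(spearman[f])[0]), abs(_rho_p(spearman[g])[0])
            if rf != rg:
                reject, keep = (f, g) if rf < rg else (g, f)
            else:
                reject, keep = max(f, g), min(f, g)
        retained.remove(reject)
        rejections[reject] = f"redundant_with:{keep}"

    ordered = [f for f in candidates if f in retained]
    return ordered, rejections


def run_selection(table: pd.DataFrame, features: Sequence[str] | None = None) -> SelectionReport:
    """End-to-end cascade on a feature table (rows = examinations)."""
    features = list(features or FEATURE_NAMES)
    validate_feature_table(table, features)
    anova = {f: anova_with_bonferroni(table, f) for f in features}
    spearman = {f: spearman_vs_density(table, f) for f in features}
    candidates = [f for f in features if anova[f].passes]
    corr, order = (None, None)
    if len(candidates) >= 2:
        corr, order = feature_correlation_cluster(table, candidates)
    else:  # degenerate screen: fall back to the full feature set
        corr, order = feature_correlation_cluster(table, features)
    retained, rejections = select_features(anova, spearman, corr)
    step2 = [
        f
        for f in candidates
        if spearman[f].p_value < ALPHA and abs(spearman[f].rho) > MODERATE_RHO
    ]
    return SelectionReport(
        anova=anova,
        spearman=spearman,
        candidates=candidates,
        step2_survivors=step2,
        retained=retained,
        rejections=rejections,
        correlation_matrix=corr,
        dendrogram_order=order,
    )
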