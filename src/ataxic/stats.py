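"""Association statistics for heterogeneity-score analyses.

Provides the small statistical toolkit the score analyses need: Spearman
rank correlation (average ranks for ties, exact permutation p for small n),
Benjamini-Hochberg FDR adjustment, per-group correlation tables, one-tailed
Mann-Whitney U comparisons, a Shapiro-Wilk normality annotation, and the
compound-sensitivity correlation screen.

Scope of multiple-testing correction: by default BH is applied across the
tests of one analysis call (e.g. one covariate across all patient groups);
wider pooling is the caller's choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .containers import CellScoreTable
from .errors import ConstantInputError, ValidationError

EXACT_SPEARMAN_MAX_N = 9
EXACT_MW_MAX_PRODUCT = 100


def _as_vector(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} contains non-finite values")
    return x


@lru_cache(maxsize=4)
def _perm_matrix(n: int) -> np.ndarray:
    """All permutations of range(n) as an (n!, n) index array."""
    return np.array(list(permutations(range(n))), dtype=np.intp)


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    return float((rx @ ry) / denom)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  For n <= 9 the p-value comes from exact
    enumeration of all permutations of one ranking (valid under ties too);
    for larger n the large-sample t approximation is used.  Constant input
    raises :class:`ConstantInputError` — rho is undefined, and callers that
    build tables flag the record instead of storing a number.
    """
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if len(x) != len(y):
        raise ValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise ValidationError(f"Spearman needs n >= 3, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ConstantInputError("Spearman is undefined for a constant vector")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = _rank_rho(rx, ry)
    if n <= EXACT_SPEARMAN_MAX_N:
        perms = _perm_matrix(n)
        ryc = ry - ry.mean()
        rxc = rx - rx.mean()
        denom = np.sqrt((rxc @ rxc) * (ryc @ ryc))
        rhos = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        # t approximation on n-2 degrees of freedom
        with np.errstate(divide="ignore"):
            tstat = rho * np.sqrt((n - 2) / max(1.0 - rho * rho, 1e-300))
        p = float(2.0 * scipy.stats.t.sf(abs(tstat), df=n - 2))
        p = min(p, 1.0)
    return rho, p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving, capped at 1."""
    p = _as_vector(p_values, "p_values")
    if len(p) == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return p_adj


@dataclass
class CorrelationRecord:
    """Spearman result for one group: rho, raw and BH-adjusted p, n."""

    group_id: str
    rho: float
    p_raw: float
    p_adj: float
    n: int
    flag: str = ""  # non-empty when the test could not be run

    def __post_init__(self) -> None:
        if not self.flag:
            if abs(self.rho) > 1 + 1e-12:
                raise ValidationError("rho outside [-1, 1]")
            if self.p_adj < self.p_raw - 1e-12:
                raise ValidationError("adjusted p below raw p")


def correlation_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    def stars(p: float) -> str:
        if not np.isfinite(p):
            return "na"
        if p < 0.001:
            return "***"
        if p < 0.01:
            return "**"
        if p < 0.05:
            return "*"
        return "ns"

    return pd.DataFrame(
        [
            {
                "group": r.group_id,
                "n": r.n,
                "rho": r.rho,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significance": stars(r.p_adj) if not r.flag else "na",
                "flag": r.flag,
            }
            for r in records
        ]
    )


def correlate_by_group(
    scores: CellScoreTable,
    covariate: CellScoreTable,
    grouping: dict[str, str] | None = None,
    min_n: int = 3,
) -> list[CorrelationRecord]:
    """One Spearman test per group, BH-adjusted across the groups of this call.

    Cells are matched by id within each group; groups with fewer than
    ``min_n`` shared cells or a constant input are flagged and excluded from
    the adjustment.  ``grouping`` defaults to the score table's sample
    labels.
    """
    score_of = scores.score_of()
    cov_of = covariate.score_of()
    shared = [c for c in scores.cell_ids if c in cov_of]
    if not shared:
        raise ValidationError("score and covariate tables share no cells")
    if grouping is None:
        sample_of = dict(zip(scores.frame["cell_id"], scores.frame["sample_id"]))
        grouping = {c: sample_of[c] for c in shared}
    groups: dict[str, list[str]] = {}
    for c in shared:
        if c in grouping:
            groups.setdefault(grouping[c], []).append(c)
    records: list[CorrelationRecord] = []
    testable: list[tuple[int, float]] = []
    for gid in sorted(groups):
        cells = groups[gid]
        x = np.array([score_of[c] for c in cells])
        y = np.array([cov_of[c] for c in cells])
        if len(cells) < min_n:
            records.append(
                CorrelationRecord(gid, np.nan, np.nan, np.nan, len(cells),
                                  flag=f"n={len(cells)} below minimum {min_n}")
            )
            continue
        try:
            rho, p = spearman(x, y)
        except ConstantInputError:
            records.append(
                CorrelationRecord(gid, np.nan, np.nan, np.nan, len(cells),
                                  flag="constant input")
            )
            continue
        testable.append((len(records), p))
        records.append(CorrelationRecord(gid, rho, p, np.nan, len(cells)))
    if testable:
        idx, raw = zip(*testable)
        adj = bh_adjust(np.array(raw))
        for i, a in zip(idx, adj):
            records[i].p_adj = float(a)
    return records


@dataclass
class ComparisonRecord:
    """One-tailed Mann-Whitney U comparison between two groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_one_tailed: float
    direction: str  # "a_greater" | "a_less"
    method: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.u_statistic <= self.n_a * self.n_b):
            raise ValidationError("U statistic out of range")
        if not (0 <= self.p_one_tailed <= 1):
            raise ValidationError("p-value out of range")


def mann_whitney_one_tailed(
    a, b, direction: str = "a_greater",
    group_a: str = "a", group_b: str = "b",
) -> ComparisonRecord:
    """One-tailed Mann-Whitney U test of ``a`` against ``b``.

    ``direction="a_greater"`` tests the alternative that values in ``a``
    are stochastically larger.  The p-value is exact (full enumeration) when
    ``n_a * n_b <= 100`` and there are no ties; otherwise the tie-corrected
    normal approximation with continuity correction is used.
    """
    a = _as_vector(a, "a")
    b = _as_vector(b, "b")
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    if direction not in ("a_greater", "a_less"):
        raise ValidationError(f"unknown direction {direction!r}")
    alternative = "greater" if direction == "a_greater" else "less"
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    exact = (len(a) * len(b) <= EXACT_MW_MAX_PRODUCT) and not has_ties
    res = scipy.stats.mannwhitneyu(
        a, b, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return ComparisonRecord(
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        u_statistic=float(res.statistic),
        p_one_tailed=float(res.pvalue),
        direction=direction,
        method="exact" if exact else "normal_tie_corrected",
    )


def shapiro_check(x) -> tuple[float, float]:
    """Shapiro-Wilk normality statistic and p-value (annotation only).

    Score distributions are rarely Gaussian, which is why group comparisons
    use the rank-based test; this check documents that, it never switches
    methods silently.
    """
    x = _as_vector(x, "x")
    if not (3 <= len(x) <= 5000):
        raise ValidationError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {len(x)}")
    res = scipy.stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ScreenResult:
    """Per-compound correlation screen against viability, with BH FDR."""

    records: list[CorrelationRecord]
    n_significant_positive: int
    n_significant_negative: int
    fdr_threshold: float
    skipped: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return correlation_frame(self.records)


def drug_screen(
    cell_line_scores: CellScoreTable,
    viability: pd.DataFrame,
    fdr_threshold: float = 0.05,
    min_lines: int = 3,
) -> ScreenResult:
    """Correlate per-line scores with per-compound viability values.

    ``viability`` is a compound x cell-line table; missing values are
    pairwise-deleted per compound.  Compounds with fewer than ``min_lines``
    scored lines are skipped with a reason.  BH runs across all tested
    compounds; significant correlations are counted by sign at the given
    FDR threshold.  Higher viability under treatment means resistance, so a
    positive correlation links high scores to drug resistance.
    """
    score_of = cell_line_scores.score_of()
    lines = [c for c in viability.columns if c in score_of]
    if not lines:
        raise ValidationError("no cell line is shared between scores and viability")
    scores = np.array([score_of[c] for c in lines])
    records: list[CorrelationRecord] = []
    skipped: dict[str, str] = {}
    raws: list[tuple[int, float]] = []
    for compound, row in viability.loc[:, lines].iterrows():
        v = row.to_numpy(dtype=float)
        ok = np.isfinite(v)
        if ok.sum() < min_lines:
            skipped[str(compound)] = f"only {int(ok.sum())} usable lines (< {min_lines})"
            continue
        try:
            rho, p = spearman(scores[ok], v[ok])
        except ConstantInputError:
            records.append(
                CorrelationRecord(str(compound), np.nan, np.nan, np.nan,
                                  int(ok.sum()), flag="constant input")
            )
            continue
        raws.append((len(records), p))
        records.append(CorrelationRecord(str(compound), rho, p, np.nan, int(ok.sum())))
    if not raws:
        raise ValidationError("no compound has enough scored cell lines")
    idx, raw = zip(*raws)
    adj = bh_adjust(np.array(raw))
    for i, a in zip(idx, adj):
        records[i].p_adj = float(a)
    n_pos = sum(
        1 for r in records
        if not r.flag and r.p_adj < fdr_threshold and r.rho > 0
    )
    n_neg = sum(
        1 for r in records
        if not r.flag and r.p_adj < fdr_threshold and r.rho < 0
    )
    return ScreenResult(
        records=records,
        n_significant_positive=n_pos,
        n_significant_negative=n_neg,
        fdr_threshold=fdr_threshold,
        skipped=skipped,
    )
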