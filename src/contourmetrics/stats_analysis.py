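"""Nonparametric association analysis between metric panels, correction
times, and clinical covariates.

All tests are two-sided with alpha defaulting to 0.05. The Shapiro-Wilk
test is run as a logged gate for the choice of nonparametric methods; it
never branches the analysis silently. Conventions that the underlying
p-values depend on are fixed and documented so results reproduce
bit-for-bit:

* Spearman's rho is the Pearson correlation of average ranks (ties get mean
  ranks). The two-sided p-value comes from exact enumeration of all n!
  permutations for n <= 10 and from the t approximation above that.
* The Mann-Whitney U test reports U = min(U1, U2); the p-value is exact
  when n1*n2 <= 400 and the data are tie-free, otherwise the normal
  approximation with tie and continuity corrections.
* Kruskal-Wallis uses the tie-corrected H with a chi-square p-value; when
  the omnibus test is significant, all pairwise Mann-Whitney tests follow
  with Bonferroni adjustment within that post-hoc family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError

__all__ = [
    "AssociationResult",
    "shapiro_wilk",
    "spearman",
    "mann_whitney_u",
    "kruskal_wallis_with_posthoc",
    "metric_time_correlation_table",
]

ALPHA_DEFAULT = 0.05
SPEARMAN_EXACT_MAX_N = 10
MWU_EXACT_MAX_PRODUCT = 400


@dataclass(frozen=True)
class AssociationResult:
    """One statistical test outcome: statistic, p-value, and bookkeeping."""

    test_name: str
    variables: tuple[str, ...]
    statistic: float
    p_value: float
    n: int
    adjusted_p: float | None = None
    groups: tuple[str, ...] = ()
    sidedness: str = "two-sided"
    method_note: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")
        if self.adjusted_p is not None and self.adjusted_p < self.p_value - 1e-12:
            raise ValueError("adjusted p-value must be >= raw p-value")


def _clean_vector(values, name: str) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise DegenerateInputError(f"{name}: values must be finite")
    return x


def shapiro_wilk(values, variable: str = "x") -> AssociationResult:
    """Shapiro-Wilk normality test; the gate logged before choosing
    nonparametric methods. Requires 3 <= n <= 5000 and a non-constant vector."""
    x = _clean_vector(values, variable)
    n = len(x)
    if not 3 <= n <= 5000:
        raise DegenerateInputError(f"Shapiro-Wilk needs 3 <= n <= 5000, got n={n}")
    if np.ptp(x) == 0:
        raise DegenerateInputError("Shapiro-Wilk is undefined for a constant vector")
    w, p = sps.shapiro(x)
    return AssociationResult(
        test_name="shapiro_wilk", variables=(variable,), statistic=float(w),
        p_value=float(p), n=n, method_note="normality gate; nonparametric tests follow",
    )


def _spearman_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    return float((rx * ry).sum() / denom)


def _spearman_exact_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p: enumerate all n! orderings of y's
    ranks, chunked so n = 10 (3.6M permutations) stays in memory."""
    n = len(rx)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    count = 0
    total = 0
    perm_iter = itertools.permutations(range(n))
    chunk = 100_000
    thresh = abs(rho_obs) - 1e-12
    while True:
        block = np.array(list(itertools.islice(perm_iter, chunk)), dtype=np.intp)
        if block.size == 0:
            break
        rho_block = (ry[block] - ry.mean()) @ rxc / denom
        count += int((np.abs(rho_block) >= thresh).sum())
        total += block.shape[0]
    return count / total


def spearman(x, y, variables: tuple[str, str] = ("x", "y")) -> AssociationResult:
    """Spearman rank correlation with a declared exact/approximate p split."""
    xa = _clean_vector(x, variables[0])
    ya = _clean_vector(y, variables[1])
    if len(xa) != len(ya):
        raise DegenerateInputError("spearman: vectors must have equal length")
    n = len(xa)
    if n < 3:
        raise DegenerateInputError(f"spearman needs n >= 3, got n={n}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateInputError("spearman is undefined for a constant input")
    rx = sps.rankdata(xa)
    ry = sps.rankdata(ya)
    rho = _spearman_rho(rx, ry)
    if n <= SPEARMAN_EXACT_MAX_N:
        p = _spearman_exact_p(rx, ry, rho)
        note = "exact permutation enumeration"
    else:
        # t approximation; |rho| = 1 gives t = inf -> p = 0
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
        note = "t approximation"
    return AssociationResult(
        test_name="spearman", variables=tuple(variables), statistic=rho,
        p_value=min(1.0, float(p)), n=n, method_note=note,
    )


def mann_whitney_u(
    g1, g2, variables: tuple[str, ...] = ("group1", "group2")
) -> AssociationResult:
    """Two-sided Mann-Whitney U test; reports U = min(U1, U2)."""
    a = _clean_vector(g1, "g1")
    b = _clean_vector(g2, "g2")
    if len(a) == 0 or len(b) == 0:
        raise DegenerateInputError("Mann-Whitney U needs two nonempty groups")
    if len(a) + len(b) < 4:
        raise DegenerateInputError("Mann-Whitney U needs combined n >= 4")
    n1, n2 = len(a), len(b)
    has_ties = len(np.unique(np.concatenate([a, b]))) < n1 + n2
    exact = n1 * n2 <= MWU_EXACT_MAX_PRODUCT and not has_ties
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    return AssociationResult(
        test_name="mann_whitney_u", variables=tuple(variables), statistic=u,
        p_value=float(res.pvalue), n=n1 + n2,
        groups=tuple(str(v) for v in variables[-2:]),
        method_note="exact" if exact else "normal approximation, tie + continuity corrected",
    )


def kruskal_wallis_with_posthoc(
    groups: dict[str, np.ndarray] | list, alpha: float = ALPHA_DEFAULT,
    variable: str = "value",
) -> list[AssociationResult]:
    """Tie-corrected Kruskal-Wallis omnibus test over >= 3 groups; when
    significant at ``alpha``, followed by all pairwise Mann-Whitney tests
    with Bonferroni-adjusted p-values (the post-hoc family)."""
    if isinstance(groups, dict):
        labels = list(groups.keys())
        data = [_clean_vector(groups[k], str(k)) for k in labels]
    else:
        data = [_clean_vector(g, f"group{i}") for i, g in enumerate(groups)]
        labels = [f"group{i}" for i in range(len(data))]
    if len(data) < 3:
        raise DegenerateInputError(
            "Kruskal-Wallis post-hoc routing needs >= 3 groups; "
            "use mann_whitney_u for 2 groups"
        )
    if any(len(g) < 2 for g in data):
        raise DegenerateInputError("every group needs n >= 2")
    h, p = sps.kruskal(*data)
    n_total = sum(len(g) for g in data)
    results = [
        AssociationResult(
            test_name="kruskal_wallis", variables=(variable,), statistic=float(h),
            p_value=float(p), n=n_total, groups=tuple(labels),
            method_note="tie-corrected H, chi-square p",
        )
    ]
    if p < alpha:
        pairs = list(itertools.combinations(range(len(data)), 2))
        m = len(pairs)
        for i, j in pairs:
            r = mann_whitney_u(data[i], data[j], variables=(variable, labels[i], labels[j]))
            results.append(
                AssociationResult(
                    test_name=r.test_name, variables=r.variables,
                    statistic=r.statistic, p_value=r.p_value, n=r.n,
                    adjusted_p=min(1.0, r.p_value * m),
                    groups=(labels[i], labels[j]),
                    method_note=r.method_note + f"; Bonferroni m={m}",
                )
            )
    return results


def metric_time_correlation_table(
    panel: pd.DataFrame,
    cases: pd.DataFrame,
    metric_columns: list[str] | None = None,
    time_column: str = "correction_time",
) -> list[AssociationResult]:
    """Spearman correlation of every metric column against correction time,
    ranked by |rho| descending. Constant metric columns are flagged as
    undefined (statistic NaN) and excluded from the ranking but still
    reported. Joins on ``case_id`` with pairwise-complete deletion."""
    merged = panel.merge(cases[["case_id", time_column]], on="case_id", how="inner")
    if metric_columns is None:
        metric_columns = [
            c for c in panel.columns
            if c not in ("case_id", "warnings", "error") and pd.api.types.is_numeric_dtype(panel[c])
        ]
    ranked: list[AssociationResult] = []
    undefined: list[AssociationResult] = []
    for col in metric_columns:
        sub = merged[[col, time_column]].dropna()
        if len(sub) < 3:
            raise DegenerateInputError(
                f"metric {col!r}: fewer than 3 joined cases with metric and time"
            )
        try:
            r = spearman(sub[col].to_numpy(), sub[time_column].to_numpy(),
                         variables=(col, time_column))
            ranked.append(r)
        except DegenerateInputError:
            undefined.append(
                AssociationResult(
                    test_name="spearman", variables=(col, time_column),
                    statistic=float("nan"), p_value=1.0, n=len(sub),
                    method_note="undefined: constant input; excluded from ranking",
                )
            )
    ranked.sort(key=lambda r: abs(r.statistic), reverse=True)
    return ranked + undefined


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of association results."""
    return pd.DataFrame(
        {
            "test": [r.test_name for r in results],
            "variables": [" vs ".join(r.variables) for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "adjusted_p": [r.adjusted_p for r in results],
            "n": [r.n for r in results],
            "groups": ["|".join(r.groups) for r in results],
            "method": [r.method_note for r in results],
        }
    )
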