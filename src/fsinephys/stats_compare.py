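"""Paired statistical comparisons for within-cell baseline/drug designs.

Three tests cover the designs that arise in paired pharmacology experiments:

* :func:`paired_t` — two-tailed paired t test on per-cell differences
  (df = n - 1);
* :func:`wilcoxon_signed_rank` — the signed-rank test for paired data, with
  the exact null distribution for small n and a continuity-corrected normal
  approximation for larger n; zero differences are dropped per the standard
  (Wilcoxon) convention and their count is reported;
* :func:`rm_anova_treatment` — two-factor repeated-measures ANOVA
  (treatment x current step, cell as the repeated unit) returning the
  treatment main effect F with (1, n - 1) degrees of freedom.  The
  treatment effect has a single degree of freedom and is unaffected by
  sphericity; the interaction p is reported both uncorrected and
  Greenhouse-Geisser corrected.

No multiple-testing correction is applied by default; a Holm adjustment is
available as an explicit helper.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedComparison",
    "RMANOVAResult",
    "paired_t",
    "wilcoxon_signed_rank",
    "rm_anova_treatment",
    "holm_adjust",
]

EXACT_WILCOXON_MAX_N = 25


@dataclass
class PairedComparison:
    """Result of one paired test on per-cell (baseline, drug) values."""

    measure_name: str
    test: str                       # "paired_t" | "wilcoxon" | "rm_anova"
    statistic_name: str             # "t" | "W" | "F"
    statistic: float
    df: float | tuple[int, int] | None
    p_value: float
    n: int
    mean_difference: float          # mean(drug - baseline)
    baseline_mean: float = float("nan")
    drug_mean: float = float("nan")
    flags: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


def _split_pairs(pairs: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be a sequence of (baseline, drug) tuples")
    if not np.all(np.isfinite(arr)):
        raise ValueError("pairs contain non-finite values")
    return arr[:, 0], arr[:, 1]


def paired_t(
    pairs: Sequence[tuple[float, float]], measure_name: str = ""
) -> PairedComparison:
    """Classical two-tailed paired t test on drug - baseline differences."""
    base, drug = _split_pairs(pairs)
    n = base.size
    if n < 2:
        raise ValueError("paired t needs at least 2 pairs")
    diffs = drug - base
    mean_d = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    flags: list[str] = []
    if sd == 0.0:
        if mean_d == 0.0:
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, mean_d)
            p = 0.0
            flags.append("zero variance of differences with nonzero mean; t is infinite")
    else:
        t, p = sps.ttest_rel(drug, base)
        t, p = float(t), float(p)
    return PairedComparison(
        measure_name=measure_name, test="paired_t", statistic_name="t",
        statistic=t, df=n - 1, p_value=p, n=n, mean_difference=mean_d,
        baseline_mean=float(np.mean(base)), drug_mean=float(np.mean(drug)),
        flags=flags,
    )


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]], measure_name: str = ""
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on drug - baseline differences.

    Exact null distribution for n <= 25 without rank ties; otherwise the
    normal approximation with continuity correction.  Zero differences are
    dropped and counted in ``extras["n_zero_dropped"]``.
    """
    base, drug = _split_pairs(pairs)
    if base.size < 5:
        raise ValueError("Wilcoxon signed-rank needs at least 5 pairs for a meaningful p")
    diffs = drug - base
    nonzero = diffs[diffs != 0.0]
    n_zero = diffs.size - nonzero.size
    flags: list[str] = []
    if n_zero:
        flags.append(f"{n_zero} zero difference(s) dropped (Wilcoxon convention)")
    if nonzero.size == 0:
        return PairedComparison(
            measure_name=measure_name, test="wilcoxon", statistic_name="W",
            statistic=float("nan"), df=None, p_value=float("nan"),
            n=diffs.size, mean_difference=0.0,
            baseline_mean=float(np.mean(base)), drug_mean=float(np.mean(drug)),
            flags=flags + ["all differences zero; test undefined"],
            extras={"n_zero_dropped": n_zero},
        )
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    if nonzero.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        method = "exact"
        res = sps.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided",
                           method="exact")
    else:
        method = "normal approximation with continuity correction"
        res = sps.wilcoxon(nonzero, zero_method="wilcox", alternative="two-sided",
                           method="approx", correction=True)
    return PairedComparison(
        measure_name=measure_name, test="wilcoxon", statistic_name="W",
        statistic=float(res.statistic), df=None, p_value=float(res.pvalue),
        n=diffs.size, mean_difference=float(np.mean(diffs)),
        baseline_mean=float(np.mean(base)), drug_mean=float(np.mean(drug)),
        flags=flags, extras={"n_zero_dropped": n_zero, "method": method},
    )


@dataclass
class RMANOVAResult:
    """Two-way repeated-measures ANOVA decomposition (treatment x step)."""

    f_treatment: float
    df_treatment: tuple[int, int]
    p_treatment: float
    f_step: float
    df_step: tuple[int, int]
    p_step: float
    f_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float
    p_interaction_gg: float
    gg_epsilon: float
    sums_of_squares: dict[str, float]
    n_cells: int

    def as_comparison(self, measure_name: str = "") -> PairedComparison:
        return PairedComparison(
            measure_name=measure_name, test="rm_anova", statistic_name="F",
            statistic=self.f_treatment, df=self.df_treatment,
            p_value=self.p_treatment, n=self.n_cells, mean_difference=float("nan"),
            extras={
                "p_step": self.p_step, "p_interaction": self.p_interaction,
                "p_interaction_gg": self.p_interaction_gg,
                "gg_epsilon": self.gg_epsilon,
            },
        )


def _to_cube(data) -> np.ndarray:
    """Coerce input to an array of shape (cells, conditions=2, steps).

    Accepts either such an array or a long DataFrame with columns
    (cell, condition, step, value); incomplete crossed designs are rejected
    with the missing combinations listed.
    """
    if isinstance(data, pd.DataFrame):
        required = {"cell", "condition", "step", "value"}
        if not required.issubset(data.columns):
            raise ValueError(f"long table must have columns {sorted(required)}")
        pivot = data.pivot_table(
            index="cell", columns=["condition", "step"], values="value",
            aggfunc="mean", dropna=False,
        )
        if pivot.isna().any().any():
            missing = [
                f"cell={c} condition={cond} step={st}"
                for (cond, st) in pivot.columns[pivot.isna().any(axis=0)]
                for c in pivot.index[pivot[(cond, st)].isna()]
            ]
            raise ValueError("incomplete crossed design; missing: " + "; ".join(missing))
        conds = sorted(data["condition"].unique())
        steps = sorted(data["step"].unique())
        cube = np.empty((pivot.shape[0], len(conds), len(steps)))
        for i, cond in enumerate(conds):
            for j, st in enumerate(steps):
                cube[:, i, j] = pivot[(cond, st)].to_numpy()
        return cube
    cube = np.asarray(data, dtype=float)
    if cube.ndim != 3:
        raise ValueError("expected (cells, conditions, steps) array or long DataFrame")
    if np.any(~np.isfinite(cube)):
        raise ValueError("incomplete crossed design: non-finite entries present")
    return cube


def _helmert(n: int) -> np.ndarray:
    """(n-1) x n orthonormal contrast matrix."""
    h = np.zeros((n - 1, n))
    for i in range(1, n):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h


def rm_anova_treatment(data, measure_name: str = "") -> RMANOVAResult:
    """Two-factor repeated-measures ANOVA; returns the full decomposition.

    ``data`` is (cells x conditions x steps) with one rate per combination
    (or an equivalent long DataFrame).  Classical sums-of-squares
    decomposition with subject as the repeated unit; each within factor is
    tested against its own factor-by-subject interaction.
    """
    y = _to_cube(data)
    n, a, b = y.shape
    if n < 2:
        raise ValueError("repeated-measures ANOVA needs at least 2 cells")
    if a != 2:
        raise ValueError("expected exactly 2 conditions (baseline, drug)")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))          # per subject
    m_a = y.mean(axis=(0, 2))          # per condition
    m_b = y.mean(axis=(0, 1))          # per step
    m_sa = y.mean(axis=2)              # subject x condition
    m_sb = y.mean(axis=1)              # subject x step
    m_ab = y.mean(axis=0)              # condition x step

    ss_total = float(np.sum((y - grand) ** 2))
    ss_subj = a * b * float(np.sum((m_s - grand) ** 2))
    ss_a = n * b * float(np.sum((m_a - grand) ** 2))
    ss_b = n * a * float(np.sum((m_b - grand) ** 2))
    ss_as = b * float(np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2))
    ss_bs = a * float(np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2))
    ss_ab = n * float(np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2))
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_as + ss_bs + ss_ab)
    ss_abs = max(ss_abs, 0.0)

    df_a, df_b = a - 1, b - 1
    df_as, df_bs = df_a * (n - 1), df_b * (n - 1)
    df_ab, df_abs = df_a * df_b, df_a * df_b * (n - 1)

    def _f_and_p(ss_eff, df_eff, ss_err, df_err):
        ms_err = ss_err / df_err if df_err > 0 else float("nan")
        if ms_err == 0 or not math.isfinite(ms_err):
            eff = ss_eff / df_eff if df_eff else 0.0
            return (0.0, 1.0) if eff == 0 else (float("inf"), 0.0)
        f = (ss_eff / df_eff) / ms_err
        return float(f), float(sps.f.sf(f, df_eff, df_err))

    f_a, p_a = _f_and_p(ss_a, df_a, ss_as, df_as)
    f_b, p_b = _f_and_p(ss_b, df_b, ss_bs, df_bs)
    f_ab, p_ab = _f_and_p(ss_ab, df_ab, ss_abs, df_abs)

    # Greenhouse-Geisser epsilon for the interaction, from the covariance of
    # the orthonormal interaction contrast scores across subjects.
    ca, cb = _helmert(a), _helmert(b)
    z = np.einsum("pi,sij,qj->spq", ca, y, cb).reshape(n, -1)
    k = z.shape[1]
    if n > 1 and k > 0:
        sigma = np.cov(z, rowvar=False).reshape(k, k)
        tr = float(np.trace(sigma))
        tr2 = float(np.trace(sigma @ sigma))
        eps = (tr * tr) / (k * tr2) if tr2 > 0 else 1.0
        eps = min(max(eps, 1.0 / k), 1.0)
    else:
        eps = 1.0
    p_ab_gg = (
        float(sps.f.sf(f_ab, eps * df_ab, eps * df_abs))
        if math.isfinite(f_ab)
        else p_ab
    )

    return RMANOVAResult(
        f_treatment=f_a, df_treatment=(df_a, df_as), p_treatment=p_a,
        f_step=f_b, df_step=(df_b, df_bs), p_step=p_b,
        f_interaction=f_ab, df_interaction=(df_ab, df_abs),
        p_interaction=p_ab, p_interaction_gg=p_ab_gg, gg_epsilon=eps,
        sums_of_squares={
            "subject": ss_subj, "treatment": ss_a, "step": ss_b,
            "treatment_x_subject": ss_as, "step_x_subject": ss_bs,
            "treatment_x_step": ss_ab, "treatment_x_step_x_subject": ss_abs,
            "total": ss_total,
        },
        n_cells=n,
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p values (off by default in the pipeline)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj.tolist()
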