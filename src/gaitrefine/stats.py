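"""Improvement-rate statistics and report tables.

Accuracy is scored per cycle with the RMSE

    E = sqrt( (1/N) * sum_i (y_i - yhat_i)^2 ),    N = samples per cycle,

and refinement quality with the improvement rate

    Er = E_refined / E_simulator - 1,

so Er < 0 means the refined estimate beats the simulator baseline.  Each
subject contributes one Er per condition: the mean of their per-speed
values (four speeds).  Across subjects we test H0: Er = 0 with a one-sample
two-tailed t-test, report Cohen's d = (mean - mu0) / sd (sample sd,
ddof = 1) and the Student-t 95% confidence interval

    CI = mean +- t(alpha/2, n-1) * sd / sqrt(n),   alpha = 0.05,

and compare the three input patterns per muscle with Tukey's
studentized-range multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "rmse",
    "improvement_rate",
    "cohens_d",
    "confidence_interval",
    "t_test_vs_zero",
    "tukey_conditions",
    "ErSample",
    "subject_er",
    "build_eval_table",
    "significance_stars",
    "table_to_markdown",
]


def rmse(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Root mean squared error over N paired samples."""
    y = np.asarray(y, float)
    y_hat = np.asarray(y_hat, float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size < 1:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def improvement_rate(e_pro: float, e_opensim: float) -> float:
    """Er = E_refined / E_baseline - 1; negative means improvement."""
    if e_opensim <= 0:
        raise ValueError("baseline error must be positive")
    return e_pro / e_opensim - 1.0


def cohens_d(er_values: Sequence[float], mu0: float = 0.0) -> float:
    """One-sample Cohen's d: (mean - mu0) / sample sd (ddof = 1)."""
    v = np.asarray(er_values, float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return float((v.mean() - mu0) / sd)


def confidence_interval(
    er_values: Sequence[float], alpha: float = 0.05
) -> tuple[float, float]:
    """Two-tailed Student-t confidence interval on the mean."""
    v = np.asarray(er_values, float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values")
    half = sps.t.ppf(1 - alpha / 2, n - 1) * v.std(ddof=1) / np.sqrt(n)
    m = v.mean()
    return (float(m - half), float(m + half))


def t_test_vs_zero(er_values: Sequence[float]) -> tuple[float, float]:
    """One-sample two-tailed t-test of H0: mean = 0.

    Returns (t, p).  The identity t = d * sqrt(n) links the statistic to
    Cohen's d.
    """
    v = np.asarray(er_values, float)
    n = v.size
    if n < 2:
        raise ValueError("need at least 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    t = v.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return (float(t), float(p))


def tukey_conditions(
    er_by_condition: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Tukey studentized-range comparisons among input-pattern conditions.

    ``er_by_condition`` maps condition name -> per-subject Er values.
    Groups are treated as independent (no repeated-measures correction).
    Returns one row per pair with the mean difference, q statistic,
    adjusted p and significance stars.
    """
    names = list(er_by_condition)
    if len(names) < 2:
        raise ValueError("need at least 2 conditions")
    groups = [np.asarray(er_by_condition[k], float) for k in names]
    for k, g in zip(names, groups):
        if g.size < 2:
            raise ValueError(f"condition {k!r} has fewer than 2 subjects")
    k = len(groups)
    ns = np.array([g.size for g in groups])
    df_w = int(ns.sum() - k)
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            na, nb = ns[a], ns[b]
            # unequal n: Tukey-Kramer standard error
            se = np.sqrt(mse / 2 * (1 / na + 1 / nb))
            diff = groups[b].mean() - groups[a].mean()
            q = abs(diff) / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
            rows.append(
                {
                    "group_a": names[a],
                    "group_b": names[b],
                    "mean_diff": float(diff),
                    "q": float(q),
                    "p_adj": p,
                    "reject_05": p < 0.05,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)


def significance_stars(p: float) -> str:
    """'*' p<0.05, '**' p<0.01, '***' p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ErSample:
    """One subject's improvement rate for one (muscle, condition).

    ``er`` is the mean over the subject's per-speed values; the per-speed
    (refined, baseline) RMSE pairs are retained for audit.
    """

    subject_id: str
    condition: str
    muscle: str
    er: float
    speed_errors: list[tuple[float, float]] = field(default_factory=list)


def subject_er(
    speed_errors: Sequence[tuple[float, float]],
    *,
    subject_id: str = "",
    condition: str = "",
    muscle: str = "",
    expected_speeds: int | None = 4,
) -> ErSample:
    """Aggregate per-speed (refined, baseline) RMSE pairs into one Er.

    Er is computed per speed and averaged — each subject's representative
    value is the mean over their (normally four) speed conditions.
    """
    if expected_speeds is not None and len(speed_errors) != expected_speeds:
        raise ValueError(
            f"subject {subject_id!r} has {len(speed_errors)} speed conditions, "
            f"expected {expected_speeds}"
        )
    ers = [improvement_rate(ep, eo) for ep, eo in speed_errors]
    return ErSample(
        subject_id=subject_id,
        condition=condition,
        muscle=muscle,
        er=float(np.mean(ers)),
        speed_errors=list(speed_errors),
    )


def build_eval_table(
    er_samples: Sequence[ErSample], alpha: float = 0.05
) -> pd.DataFrame:
    """Per (muscle, condition) summary: mean, sd, d, CI, p, improvement flag.

    ``improved`` marks cells with a negative mean Er (the bold-cell
    semantics of the study reports).  Requires a complete set of subjects
    per cell.
    """
    if not er_samples:
        raise ValueError("no Er samples")
    frame = pd.DataFrame(
        [
            {"muscle": s.muscle, "condition": s.condition, "subject": s.subject_id, "er": s.er}
            for s in er_samples
        ]
    )
    rows = []
    for (muscle, cond), grp in frame.groupby(["muscle", "condition"], sort=True):
        v = grp["er"].to_numpy()
        if v.std(ddof=1) == 0:
            # degenerate cell: identical Er for every subject
            m = float(v.mean())
            t, p = float("nan"), (1.0 if m == 0 else 0.0)
            lo = hi = m
            d = float("nan")
        else:
            t, p = t_test_vs_zero(v)
            lo, hi = confidence_interval(v, alpha)
            d = cohens_d(v)
        rows.append(
            {
                "muscle": muscle,
                "condition": cond,
                "n": int(v.size),
                "er_mean": float(v.mean()),
                "er_sd": float(v.std(ddof=1)),
                "cohen_d": d,
                "ci_low": lo,
                "ci_high": hi,
                "t": t,
                "p": p,
                "stars": significance_stars(p),
                "improved": bool(v.mean() < 0),
            }
        )
    return pd.DataFrame(rows)


def table_to_markdown(table: pd.DataFrame) -> str:
    """Render an eval table as a Markdown report (error, 95% CI, effect size)."""
    lines = [
        "| muscle | condition | Er (p) | 95% CI | effect size d |",
        "|---|---|---|---|---|",
    ]
    for _, r in table.iterrows():
        er = f"{r.er_mean:.3f} {r.stars} (p = {r.p:.3g})"
        if r.improved:
            er = f"**{er}**"
        lines.append(
            f"| {r.muscle} | {r.condition} | {er} "
            f"| [{r.ci_low:.3f}, {r.ci_high:.3f}] | {r.cohen_d:.2f} |"
        )
    return "\n".join(lines) + "\n"
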