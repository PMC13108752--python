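"""Within-subject statistics and report assembly.

One-way repeated-measures ANOVA per keypoint group on the participant x
method matrix of mean errors, with partial eta-squared effect sizes, and
Bonferroni-corrected paired t-tests over all method pairs with 95%
confidence intervals of the mean differences.

The classical decomposition for n subjects and k within-subject levels:

    SS_total  = sum (x_ij - grand)^2
    SS_subj   = k * sum_i (rowmean_i - grand)^2
    SS_method = n * sum_j (colmean_j - grand)^2
    SS_error  = SS_total - SS_subj - SS_method

    F = (SS_method / (k-1)) / (SS_error / ((n-1)(k-1)))
    partial eta^2 = SS_method / (SS_method + SS_error)

No sphericity correction is applied by default (uncorrected degrees of
freedom df1 = k-1, df2 = (n-1)(k-1)); a Greenhouse-Geisser option is
available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import GestureCapError

__all__ = [
    "AnovaResult",
    "PairwiseResult",
    "rm_anova",
    "pairwise_bonferroni",
    "box_summary",
    "assemble_report",
]


@dataclass(frozen=True)
class AnovaResult:
    group: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    n_valid: int = 0
    gg_epsilon: Optional[float] = None


@dataclass(frozen=True)
class PairwiseResult:
    group: str
    method_a: str
    method_b: str
    mean_diff: float  # mean of (a - b)
    ci_low: float
    ci_high: float
    t: float
    p_raw: float
    p_bonferroni: float
    significant: bool
    direction: str


def _as_matrix(means) -> Tuple[np.ndarray, List[str]]:
    if isinstance(means, pd.DataFrame):
        mat = means.to_numpy(dtype=float)
        methods = [str(c) for c in means.columns]
    else:
        mat = np.asarray(means, dtype=float)
        methods = [f"m{j}" for j in range(mat.shape[1])]
    if mat.ndim != 2:
        raise GestureCapError("means must be a participants x methods matrix")
    if np.isnan(mat).any():
        raise GestureCapError("missing cells in the participant x method matrix")
    return mat, methods


def _gg_epsilon(mat: np.ndarray) -> float:
    # Greenhouse-Geisser epsilon from the double-centered covariance
    n, k = mat.shape
    S = np.cov(mat, rowvar=False, ddof=1)
    mean_all = S.mean()
    row_means = S.mean(axis=0)
    num = (k * (np.trace(S) / k - mean_all)) ** 2
    den = (k - 1) * (np.sum(S * S) - 2 * k * np.sum(row_means**2)
                     + k * k * mean_all**2)
    return float(num / den)


def rm_anova(
    means,
    *,
    group: str = "",
    n_valid: int = 0,
    greenhouse_geisser: bool = False,
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a complete n x k matrix.

    Rows are participants (the statistical unit), columns the methods.
    Raises on missing cells — the design is complete by construction.
    """
    mat, _ = _as_matrix(means)
    n, k = mat.shape
    if n < 2 or k < 2:
        raise GestureCapError("need at least 2 participants and 2 methods")
    grand = mat.mean()
    ss_total = float(np.sum((mat - grand) ** 2))
    ss_subj = float(k * np.sum((mat.mean(axis=1) - grand) ** 2))
    ss_method = float(n * np.sum((mat.mean(axis=0) - grand) ** 2))
    ss_error = ss_total - ss_subj - ss_method
    df1 = k - 1.0
    df2 = (n - 1.0) * (k - 1.0)
    eps = None
    if greenhouse_geisser:
        eps = _gg_epsilon(mat)
        df1 *= eps
        df2 *= eps
    ms_method = ss_method / df1
    ms_error = ss_error / df2
    F = ms_method / ms_error if ms_error > 0 else (0.0 if ss_method == 0 else np.inf)
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    eta = ss_method / (ss_method + ss_error) if (ss_method + ss_error) > 0 else 0.0
    return AnovaResult(group, float(F), df1, df2, p, float(eta), n_valid, eps)


def pairwise_bonferroni(
    means,
    alpha: float = 0.05,
    *,
    group: str = "",
) -> List[PairwiseResult]:
    """Paired t-tests over all method pairs with Bonferroni correction.

    Raw two-sided p-values are multiplied by the number of pairs (capped
    at 1).  The 95% CI of each mean paired difference uses the t
    distribution with n-1 degrees of freedom (unadjusted, reported per
    pair).  A zero-variance nonzero difference yields t = +/-inf, p = 0.
    """
    mat, methods = _as_matrix(means)
    n, k = mat.shape
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    m = len(pairs)
    out = []
    tcrit = sps.t.ppf(0.975, n - 1)
    for i, j in pairs:
        d = mat[:, i] - mat[:, j]
        dbar = float(d.mean())
        sd = float(d.std(ddof=1))
        se = sd / np.sqrt(n)
        if se == 0.0:
            t = 0.0 if dbar == 0.0 else np.inf * np.sign(dbar)
            p_raw = 1.0 if dbar == 0.0 else 0.0
            ci = (dbar, dbar)
        else:
            t = dbar / se
            p_raw = float(2.0 * sps.t.sf(abs(t), n - 1))
            ci = (dbar - tcrit * se, dbar + tcrit * se)
        p_bonf = min(1.0, p_raw * m)
        sig = p_bonf < alpha
        if sig:
            lo, hi = (methods[i], methods[j]) if dbar < 0 else (methods[j], methods[i])
            direction = f"{lo} < {hi}"
        else:
            direction = "n.s."
        out.append(
            PairwiseResult(
                group, methods[i], methods[j], dbar, float(ci[0]), float(ci[1]),
                float(t), p_raw, p_bonf, sig, direction,
            )
        )
    return out


def box_summary(values: np.ndarray) -> Dict[str, float]:
    """Box-plot summary: quartiles, whiskers at the furthest points within
    1.5 IQR of the box, and the outlier count."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise GestureCapError("no data for box summary")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    lo = float(in_lo.min())
    hi = float(in_hi.max())
    return {
        "mean": float(v.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": lo,
        "whisker_high": hi,
        "n_outliers": int(np.sum((v < lo) | (v > hi))),
        "n": int(v.size),
    }


def _fmt_p(p: float) -> str:
    return "<.001" if p < 0.001 else f"{p:.3f}"


def assemble_report(
    anova: Sequence[AnovaResult],
    pairwise: Sequence[PairwiseResult],
    cell_means: Optional[pd.DataFrame],
    dice_points: Optional[Sequence[Tuple[float, float]]],
    out_dir: Union[str, Path],
) -> Dict[str, Path]:
    """Write the deterministic report bundle (CSV tables + markdown).

    Emits anova.csv, pairwise.csv, errors_summary.csv (box-plot summary
    statistics of participant cell means per method and group),
    dice_curve.csv and report.md.  P-values are displayed with a <.001
    floor but stored raw in the CSVs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    anova_df = pd.DataFrame(
        [
            {
                "group": a.group,
                "N_valid": a.n_valid,
                "F": a.F,
                "df1": a.df1,
                "df2": a.df2,
                "p": a.p,
                "partial_eta_sq": a.partial_eta_sq,
            }
            for a in anova
        ]
    )
    paths["anova"] = out_dir / "anova.csv"
    anova_df.to_csv(paths["anova"], index=False)

    pw_df = pd.DataFrame([p.__dict__ for p in pairwise])
    paths["pairwise"] = out_dir / "pairwise.csv"
    pw_df.to_csv(paths["pairwise"], index=False)

    if cell_means is not None and not cell_means.empty:
        rows = []
        for (method, grp), sub in cell_means.groupby(
            ["method", "group"], observed=True
        ):
            row = {"method": method, "group": grp}
            row.update(box_summary(sub["mean_e_mm"].to_numpy()))
            rows.append(row)
        summary = pd.DataFrame(rows)
        paths["errors_summary"] = out_dir / "errors_summary.csv"
        summary.to_csv(paths["errors_summary"], index=False)

    if dice_points is not None:
        dice_df = pd.DataFrame(dice_points, columns=["voxel_mm", "dice"])
        paths["dice_curve"] = out_dir / "dice_curve.csv"
        dice_df.to_csv(paths["dice_curve"], index=False)

    lines = ["# Gesture-capture validation report", ""]
    if anova:
        lines += ["## Repeated-measures ANOVA per keypoint group", ""]
        lines.append("| group | N | F | df | p | partial eta^2 |")
        lines.append("|---|---|---|---|---|---|")
        for a in anova:
            lines.append(
                f"| {a.group} | {a.n_valid} | {a.F:.2f} | "
                f"({a.df1:g}, {a.df2:g}) | {_fmt_p(a.p)} | "
                f"{a.partial_eta_sq:.2f} |"
            )
        lines.append("")
    if pairwise:
        lines += ["## Bonferroni pairwise comparisons", ""]
        lines.append(
            "| group | pair | mean diff (mm) | 95% CI (mm) | p (Bonf.) | |"
        )
        lines.append("|---|---|---|---|---|---|")
        for p in pairwise:
            lines.append(
                f"| {p.group} | {p.method_a} vs {p.method_b} | "
                f"{p.mean_diff:.1f} | [{p.ci_low:.1f}, {p.ci_high:.1f}] | "
                f"{_fmt_p(p.p_bonferroni)} | {p.direction} |"
            )
        lines.append("")
    if dice_points:
        lines += ["## Gesture-space Dice vs voxel size", ""]
        lines.append("| voxel (mm) | Dice |")
        lines.append("|---|---|")
        for v, d in dice_points:
            lines.append(f"| {v:g} | {d:.3f} |")
        lines.append("")
    paths["report"] = out_dir / "report.md"
    paths["report"].write_text("\n".join(lines))
    return paths
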