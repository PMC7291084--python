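"""Screen-level statistics: control-normalised tests and qPCR knockdown.

Per-treatment readouts are compared against the non-silencing negative
control ("NEG") with two-sided Mann–Whitney U tests (or one-way ANOVA
plus pairwise comparisons), Bonferroni-corrected across treatments.
Knockdown efficiency is computed from qPCR cycle thresholds by the
ΔΔCt method with the treated condition normalised to NEG.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ValidationError

SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for thr, stars in SIGNIFICANCE_LEVELS:
        if p < thr:
            return stars
    return "ns"


def bonferroni(p_values: Sequence[float], n_comparisons: int | None = None) -> np.ndarray:
    """adjusted p = min(1, p × m); monotone in m by construction."""
    p = np.asarray(p_values, dtype=float)
    m = len(p) if n_comparisons is None else int(n_comparisons)
    return np.minimum(1.0, p * m)


def _mwu_pvalue(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided U statistic and p, exact for small tie-free samples."""
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (max(len(a), len(b)) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_vs_control(
    groups: Mapping[str, Sequence[float]],
    control: Sequence[float],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Each group vs the control, Bonferroni-corrected across groups.

    The exact U null distribution is used for tie-free samples of at
    most 20 per side; a continuity-corrected normal approximation
    otherwise. Returns ``treatment, n, U, p_raw, p_adj, significant,
    stars`` with one row per group.
    """
    ctrl = np.asarray(control, dtype=float)
    if ctrl.size < 2:
        raise ValidationError("control group needs >= 2 observations")
    rows = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 2:
            raise ValidationError(f"group {name!r} needs >= 2 observations")
        u, p = _mwu_pvalue(v, ctrl)
        rows.append({"treatment": name, "n": v.size, "U": u, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_adj"] = bonferroni(df["p_raw"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    df["stars"] = [significance_stars(p) for p in df["p_adj"]]
    return df


def anova_vs_control(
    groups: Mapping[str, Sequence[float]],
    control: Sequence[float],
    alpha: float = 0.05,
) -> tuple[float, pd.DataFrame]:
    """One-way ANOVA over all groups + control, then pairwise-vs-control
    t-tests with Bonferroni correction.

    Returns ``(anova_p, table)``.
    """
    ctrl = np.asarray(control, dtype=float)
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 1:
        raise ValidationError("ANOVA needs at least one non-control group")
    if any(a.size < 2 for a in arrays) or ctrl.size < 2:
        raise ValidationError("every group needs >= 2 observations")
    if all(np.var(a) == 0 for a in arrays + [ctrl]):
        raise ValidationError("zero within-group variance in every group")
    f_p = float(sps.f_oneway(ctrl, *arrays).pvalue)
    rows = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        t, p = sps.ttest_ind(v, ctrl)
        rows.append({"treatment": name, "n": v.size, "t": float(t), "p_raw": float(p)})
    df = pd.DataFrame(rows)
    df["p_adj"] = bonferroni(df["p_raw"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    df["stars"] = [significance_stars(p) for p in df["p_adj"]]
    return f_p, df


class CorrelationResult(NamedTuple):
    r: float
    p: float


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation; errors on degenerate input."""
    xv, yv = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValidationError("correlation needs matched samples with n >= 3")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValidationError("correlation inputs must be finite")
    if np.var(xv) == 0 or np.var(yv) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    res = sps.pearsonr(xv, yv)
    return CorrelationResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# qPCR knockdown
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrMeasurement:
    """One well: cycle thresholds for a target and its reference gene.

    ``ct_reference`` may be None to use the raw −ΔCt variant without a
    reference gene.
    """

    target: str
    ct_target: float
    ct_reference: float | None
    condition: str  # "treated" or "NEG"

    def delta_ct(self) -> float:
        if not np.isfinite(self.ct_target) or self.ct_target <= 0:
            raise ValidationError("Ct values must be finite and positive")
        if self.ct_reference is None:
            return self.ct_target
        if not np.isfinite(self.ct_reference) or self.ct_reference <= 0:
            raise ValidationError("Ct values must be finite and positive")
        return self.ct_target - self.ct_reference


class KnockdownResult(NamedTuple):
    target: str
    relative_expression: float
    knockdown_percent: float


def relative_expression_from_ddct(ddct: float) -> float:
    """2^−ΔΔCt."""
    return float(2.0 ** (-ddct))


def knockdown_fold_change(measurements: Sequence[QpcrMeasurement]) -> list[KnockdownResult]:
    """Per-target relative mRNA level of treated vs NEG cells.

    ΔCt = Ct_target − Ct_reference within each condition (replicates
    averaged); relative expression = 2^−(ΔCt_treated − ΔCt_NEG);
    knockdown % = (1 − relative expression) × 100. Raises when a target
    lacks a NEG counterpart.
    """
    by_target: dict[str, dict[str, list[float]]] = {}
    for m in measurements:
        cond = m.condition
        if cond not in ("treated", "NEG"):
            raise ValidationError(f"unknown qPCR condition {cond!r}")
        by_target.setdefault(m.target, {}).setdefault(cond, []).append(m.delta_ct())
    out = []
    for target, conds in by_target.items():
        if "NEG" not in conds or "treated" not in conds:
            raise ValidationError(f"target {target!r} lacks a treated/NEG pair")
        ddct = float(np.mean(conds["treated"]) - np.mean(conds["NEG"]))
        rel = relative_expression_from_ddct(ddct)
        out.append(KnockdownResult(target, rel, (1.0 - rel) * 100.0))
    return out


def simulate_null_fwer(
    n_arms: int = 21,
    n_per_group: int = 25,
    n_reps: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Family-wise error rate of the Bonferroni-corrected Mann–Whitney
    screen under the global null.

    Every arm and the control are drawn from the same distribution; a
    family error is any arm with adjusted p < alpha. With Bonferroni
    correction the returned rate should not exceed alpha. This is a
    calibration check for the screen's testing procedure, not a data
    analysis routine.
    """
    rng = np.random.default_rng(seed)
    errors = 0
    for _ in range(n_reps):
        ctrl = rng.standard_normal(n_per_group)
        p_raw = np.empty(n_arms)
        for j in range(n_arms):
            _, p_raw[j] = _mwu_pvalue(rng.standard_normal(n_per_group), ctrl)
        if (bonferroni(p_raw) < alpha).any():
            errors += 1
    return errors / n_reps


# ---------------------------------------------------------------------------
# Replicate summaries
# ---------------------------------------------------------------------------

def replicate_summary(tidy: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Mean ± s.e.m. across replicate means per treatment.

    ``tidy`` columns: treatment, replicate, and a value column. The
    s.e.m. follows the figure convention: computed over the per-
    replicate means (typically n = 3 independent experiments).
    """
    for col in ("treatment", "replicate", value):
        if col not in tidy.columns:
            raise ValidationError(f"tidy table missing column {col!r}")
    rep_means = tidy.groupby(["treatment", "replicate"])[value].mean().reset_index()
    g = rep_means.groupby("treatment")[value]
    return pd.DataFrame(
        {"mean": g.mean(), "sem": g.sem(ddof=1), "n_replicates": g.size()}
    ).reset_index()
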