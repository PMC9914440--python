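"""Statistical layer for SPT/STORM/immunocytochemistry comparisons.

Variables from SPT and STORM follow roughly log-normal distributions, so
values are divided by the control group's median and log-transformed before
comparison. Two-group tests use the Welch t-test when both groups pass a
normality check, otherwise the Mann-Whitney U test. For super-resolution
data, where cells on one coverslip vary widely, a balanced Monte-Carlo
Mann-Whitney procedure equalizes each neuron's contribution: per repetition
an equal number of observations is drawn from every neuron, values are
normalized by the per-culture control median, pooled, logged, and the U
statistic computed; the procedure is repeated (1000× by default) and a
p-value is derived from the resampled U distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

DEFAULT_N_REPS = 1000
DEFAULT_ALPHA_NORMALITY = 0.05
EXACT_MW_MAX_N = 20


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test_name: str  # "welch_t" or "mann_whitney"
    n_a: int
    n_b: int
    normality_decision: bool


@dataclass
class MCMWResult:
    u_values: np.ndarray
    summary_u: float
    p_value: float
    n_reps: int
    n_per_group: tuple[int, int]  # (treated, control) per-rep sizes
    m_per_neuron: int
    seed: int
    p_value_median_of_reps: float | None = None
    extra: dict = field(default_factory=dict)


def lognormalize(
    values: np.ndarray, condition: np.ndarray, control: str = "control"
) -> np.ndarray:
    """log(v / median of control values). Non-positive values are excluded
    (returned as NaN) with a logged count; the transformed control group has
    median exactly 0."""
    values = np.asarray(values, dtype=float)
    condition = np.asarray(condition)
    ctrl = values[(condition == control) & (values > 0)]
    if ctrl.size == 0:
        raise ValueError("empty control group")
    med = np.median(ctrl)
    n_bad = int(np.sum(values <= 0))
    if n_bad:
        logger.info("lognormalize: %d non-positive values excluded", n_bad)
    out = np.full(values.shape, np.nan)
    ok = values > 0
    out[ok] = np.log(values[ok] / med)
    return out


def mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic of sample *a* vs *b* (number of (a > b) pairs, ties ½),
    via mid-ranks: U = R_a − n_a(n_a+1)/2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0)


def mw_normal_p(u: float, n1: int, n2: int, ties_correction: float = 0.0) -> float:
    """Two-sided p for a U value under the MW null (normal approximation with
    continuity correction; optional tie variance correction term)."""
    mu = n1 * n2 / 2.0
    var = n1 * n2 * (n1 + n2 + 1) / 12.0 - ties_correction
    if var <= 0:
        return 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def choose_and_test(
    a: np.ndarray,
    b: np.ndarray,
    alpha_normality: float = DEFAULT_ALPHA_NORMALITY,
    method: str = "auto",
) -> TestResult:
    """Welch t-test when both groups pass Shapiro-Wilk normality at
    ``alpha_normality``; otherwise two-sided Mann-Whitney (exact null for
    n ≤ 20 per group without ties, continuity-corrected normal approximation
    above). Zero-variance groups fall back to Mann-Whitney. ``method`` can
    pin the branch to ``"mw"`` or ``"welch"`` instead of ``"auto"``."""
    if method not in ("auto", "mw", "welch"):
        raise ValueError("method must be 'auto', 'mw' or 'welch'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs n >= 3")

    degenerate = np.ptp(a) == 0 or np.ptp(b) == 0
    if method == "auto":
        normal = False
        if not degenerate:
            pa = sps.shapiro(a).pvalue
            pb = sps.shapiro(b).pvalue
            normal = (pa > alpha_normality) and (pb > alpha_normality)
        else:
            logger.info("zero-variance group: falling back to Mann-Whitney")
    elif method == "welch":
        if degenerate:
            logger.info("zero-variance group: falling back to Mann-Whitney")
        normal = not degenerate
    else:
        normal = False

    if normal:
        res = sps.ttest_ind(a, b, equal_var=False)
        return TestResult(
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            test_name="welch_t",
            n_a=a.size,
            n_b=b.size,
            normality_decision=True,
        )
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= EXACT_MW_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name="mann_whitney",
        n_a=a.size,
        n_b=b.size,
        normality_decision=False,
    )


def _validate_grouped(df: pd.DataFrame, control: str, treated: str) -> pd.DataFrame:
    required = {"value", "condition", "culture", "neuron"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"grouped sample lacks columns: {sorted(missing)}")
    df = df[df["value"] > 0].copy()
    n_dropped = 0
    keep = []
    for (cond, cult, neu), grp in df.groupby(["condition", "culture", "neuron"]):
        if len(grp) == 0:
            n_dropped += 1
            continue
        keep.append(grp)
    if n_dropped:
        logger.info("mc_balanced_mw: %d empty neurons excluded", n_dropped)
    df = pd.concat(keep, ignore_index=False) if keep else df.iloc[:0]
    for cond in (control, treated):
        sub = df[df["condition"] == cond]
        if sub.empty:
            raise ValueError(f"condition {cond!r} has no observations")
        if sub.groupby(["culture", "neuron"]).ngroups < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 neurons")
    return df


def mc_balanced_mw(
    sample: pd.DataFrame,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    control: str = "control",
    treated: str = "treated",
    p_mode: str = "tail_of_median_u",
) -> MCMWResult:
    """Balanced Monte-Carlo Mann-Whitney test on clustered data.

    ``sample`` is long-format with columns value, condition, culture, neuron.
    Per repetition (seeded): let m be the minimum per-neuron observation
    count across both conditions; draw m observations without replacement
    from every neuron; within each culture divide the selected values by
    that culture's selected-control median; pool cultures; apply log; compute
    the Mann-Whitney U of treated vs control. The summary U is the median of
    the per-repetition U values and the reported p-value its two-sided tail
    probability under the MW null at the balanced per-repetition sample
    sizes. The alternative aggregation — the median of per-repetition
    p-values — is always reported alongside (``p_value_median_of_reps``) and
    becomes the primary value with ``p_mode="median_p"``.
    """
    if p_mode not in ("tail_of_median_u", "median_p"):
        raise ValueError("p_mode must be 'tail_of_median_u' or 'median_p'")
    df = _validate_grouped(sample, control, treated)
    # deterministic order regardless of input row order
    df = df.sort_values(["culture", "neuron", "condition"], kind="stable").reset_index(drop=True)

    neurons = []  # (culture, condition, values array)
    for (cult, neu, cond), grp in df.groupby(["culture", "neuron", "condition"], sort=True):
        neurons.append((cult, cond, np.sort(grp["value"].to_numpy())))
    m = min(len(v) for _, _, v in neurons)
    # only cultures with control neurons can be median-normalized
    cultures_with_control = {c for c, cond, _ in neurons if cond == control}
    dropped = [c for c, cond, _ in neurons if cond == treated and c not in cultures_with_control]
    if dropped:
        logger.info(
            "mc_balanced_mw: treated neurons in cultures without controls excluded: %s",
            sorted(set(dropped)),
        )
    neurons = [n for n in neurons if n[0] in cultures_with_control]
    n_treated = sum(m for _, cond, _ in neurons if cond == treated)
    n_control = sum(m for _, cond, _ in neurons if cond == control)
    if n_treated == 0:
        raise ValueError("no treated observations share a culture with controls")

    rng = np.random.default_rng(seed)
    cultures = sorted({c for c, _, _ in neurons})
    u_values = np.empty(n_reps)
    p_values = np.empty(n_reps)
    for rep in range(n_reps):
        pooled_t, pooled_c = [], []
        for cult in cultures:
            sel_t, sel_c = [], []
            for c, cond, vals in neurons:
                if c != cult:
                    continue
                pick = vals if vals.size == m else rng.choice(vals, size=m, replace=False)
                (sel_t if cond == treated else sel_c).append(pick)
            if not sel_c:
                continue
            med = np.median(np.concatenate(sel_c))
            if sel_t:
                pooled_t.append(np.concatenate(sel_t) / med)
            pooled_c.append(np.concatenate(sel_c) / med)
        t_vals = np.log(np.concatenate(pooled_t))
        c_vals = np.log(np.concatenate(pooled_c))
        u = mann_whitney_u(t_vals, c_vals)
        u_values[rep] = u
        p_values[rep] = mw_normal_p(u, t_vals.size, c_vals.size)

    summary_u = float(np.median(u_values))
    p_tail = mw_normal_p(summary_u, n_treated, n_control)
    p_median = float(np.median(p_values))
    return MCMWResult(
        u_values=u_values,
        summary_u=summary_u,
        p_value=p_tail if p_mode == "tail_of_median_u" else p_median,
        n_reps=n_reps,
        n_per_group=(n_treated, n_control),
        m_per_neuron=m,
        seed=seed,
        p_value_median_of_reps=p_median,
        extra={"p_tail_of_median_u": p_tail},
    )
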