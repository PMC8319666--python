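"""Screen statistics: concurrent-control normalization and hit calling.

Every treated group in an RNAi screen is paired with a concurrent control
group (empty-vector animals from the same brood, assayed alongside).
Per-metric normalized values are ratios of arithmetic group means,
treated / control; two-sided pooled-variance Student's t-tests compare
per-animal percent-time values; and the family-wise error is controlled
with a Bonferroni correction whose family defaults to (number of genes)
x 2, one comparison each for dwelling and quiescence.

Because control groups spend almost no time roaming, ratios with a
near-zero control mean explode; metrics whose control mean falls below a
configurable floor are flagged "unstable" instead of being reported as
extreme ratios.

Two published hit-calling rules are provided for the normalized
quiescence value: a symmetric +/-20% band (reduced below 0.8, enhanced
above 1.2) and an asymmetric rule with cutoffs 0.6 / 1.7. The ratio class
and t-test significance are reported as separate columns, never fused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import BehaviorSummary, STATE_NAMES

PCT_METRICS = ("pct_Q", "pct_D", "pct_R")
RATE_METRICS = tuple(
    f"rate_{a}{b}" for a in STATE_NAMES for b in STATE_NAMES if a != b
)
ALL_METRICS = PCT_METRICS + RATE_METRICS

# Control-mean floors below which a ratio is flagged unstable rather than
# reported: 0.5 percentage points for percent-time metrics, 1e-4 s^-1 for
# transition rates (roaming-entry rates in controls sit near this scale).
PCT_FLOOR = 0.5
RATE_FLOOR = 1e-4


@dataclass
class GroupSummary:
    """Per-group mean and SEM of every behavioral metric."""

    group_label: str
    role: str                       # "control" | "treated"
    animals: list[BehaviorSummary]
    mean: dict[str, float] = field(init=False)
    sem: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if self.role not in ("control", "treated"):
            raise ValueError("role must be 'control' or 'treated'")
        if len(self.animals) < 1:
            raise ValueError("a group needs at least one animal")
        table = self.metric_table()
        self.mean = {}
        self.sem = {}
        for m in ALL_METRICS:
            vals = table[m].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            self.mean[m] = float(vals.mean()) if vals.size else float("nan")
            self.sem[m] = (
                float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else float("nan")
            )

    @property
    def n(self) -> int:
        return len(self.animals)

    def metric_table(self) -> pd.DataFrame:
        return pd.DataFrame([a.metric_dict() for a in self.animals])

    def values(self, metric: str) -> np.ndarray:
        return self.metric_table()[metric].to_numpy()


def group_summary(label: str, role: str, animals: list[BehaviorSummary]) -> GroupSummary:
    return GroupSummary(group_label=label, role=role, animals=animals)


@dataclass
class Normalized:
    value: float        # NaN when unstable/undefined
    stable: bool
    reason: str = ""


def normalize_to_control(
    treated: GroupSummary,
    control: GroupSummary,
    pct_floor: float = PCT_FLOOR,
    rate_floor: float = RATE_FLOOR,
) -> dict[str, Normalized]:
    """Per-metric normalized values: treated mean / concurrent control mean.

    A metric whose control mean is below the floor (or zero/NaN) yields a
    flagged, NaN-valued entry rather than a huge or undefined ratio.
    """
    out: dict[str, Normalized] = {}
    for m in ALL_METRICS:
        c = control.mean[m]
        t = treated.mean[m]
        floor = pct_floor if m in PCT_METRICS else rate_floor
        if not np.isfinite(c) or not np.isfinite(t):
            out[m] = Normalized(float("nan"), False, "group mean undefined")
        elif abs(c) < floor:
            out[m] = Normalized(float("nan"), False, f"control mean {c:.3g} below floor {floor:g}")
        else:
            out[m] = Normalized(t / c, True)
    return out


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def two_sample_t_test(treated: np.ndarray, control: np.ndarray) -> TTestResult:
    """Classical pooled-variance two-sample Student's t-test, two-sided.

    Degenerate inputs (zero pooled variance) give p = 1 for equal means
    and p = 0, flagged, for unequal means.
    """
    a = np.asarray(treated, dtype=float)
    b = np.asarray(control, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 finite values")
    df = a.size + b.size - 2
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, df=df, p=1.0)
        return TTestResult(t=float("inf"), df=df, p=0.0, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


@dataclass
class BonferroniThreshold:
    """Per-comparison significance threshold alpha / m.

    ``exact`` keeps full precision; ``display`` is rounded to 4 decimals
    for reports (0.05 / 56 displays as 0.0009).
    """

    alpha: float
    m: int
    exact: float = field(init=False)
    display: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not isinstance(self.m, (int, np.integer)) or self.m < 1:
            raise ValueError("m must be a positive integer")
        self.exact = self.alpha / self.m
        self.display = round(self.exact, 4)


def bonferroni_threshold(alpha: float, m: int) -> BonferroniThreshold:
    return BonferroniThreshold(alpha=alpha, m=m)


def classify_quiescence(
    normalized_q: float,
    rule: str = "ratio_band",
    band: float = 0.20,
    cutoffs: tuple[float, float] = (0.6, 1.7),
) -> str:
    """Ratio-based hit class for the normalized quiescence value.

    ``ratio_band``: reduced below 1 - band, enhanced above 1 + band
    (default +/-20%). ``ratio_asym``: reduced at or below the low cutoff,
    enhanced at or above the high one (defaults 0.6 and 1.7). A missing
    normalized value is "unresolved".
    """
    if normalized_q is None or not np.isfinite(normalized_q):
        return "unresolved"
    if rule == "ratio_band":
        if normalized_q < 1.0 - band:
            return "reduced"
        if normalized_q > 1.0 + band:
            return "enhanced"
        return "neutral"
    if rule == "ratio_asym":
        lo, hi = cutoffs
        if normalized_q <= lo:
            return "reduced"
        if normalized_q >= hi:
            return "enhanced"
        return "neutral"
    raise ValueError(f"unknown rule {rule!r}")


@dataclass
class ScreenResult:
    """One gene's normalized metrics, p-values and classification."""

    gene_label: str
    normalized: dict[str, Normalized]
    p_values: dict[str, float]
    alpha_corrected: BonferroniThreshold
    classification: str
    significant_q: bool
    n_control: int
    n_treated: int


def screen_report(
    gene_groups: list[tuple[str, GroupSummary, GroupSummary]],
    alpha: float = 0.05,
    family_size: int | None = None,
    rule: str = "ratio_band",
    band: float = 0.20,
    cutoffs: tuple[float, float] = (0.6, 1.7),
    pct_floor: float = PCT_FLOOR,
    rate_floor: float = RATE_FLOOR,
) -> tuple[pd.DataFrame, list[ScreenResult]]:
    """Build the screen table: one row per gene, in manifest order.

    ``gene_groups`` pairs each gene label with its (treated, control)
    group summaries; a treated group without a concurrent control is a
    caller error upstream. The Bonferroni family defaults to
    (number of genes) x 2, one comparison per gene for each of dwelling
    and quiescence; p-values are reported unadjusted alongside the
    corrected threshold.
    """
    if not gene_groups:
        raise ValueError("no genes to report")
    for gene, treated, control in gene_groups:
        if treated is None or control is None:
            raise ValueError(f"gene {gene!r} lacks a treated/concurrent-control pairing")
    m = family_size if family_size is not None else 2 * len(gene_groups)
    thr = bonferroni_threshold(alpha, int(m))

    results: list[ScreenResult] = []
    rows = []
    for gene, treated, control in gene_groups:
        norm = normalize_to_control(treated, control, pct_floor, rate_floor)
        p_values = {}
        for metric in PCT_METRICS:
            tv, cv = treated.values(metric), control.values(metric)
            if tv.size >= 2 and cv.size >= 2:
                p_values[metric] = two_sample_t_test(tv, cv).p
            else:
                p_values[metric] = float("nan")
        cls = classify_quiescence(norm["pct_Q"].value, rule=rule, band=band, cutoffs=cutoffs)
        sig = bool(np.isfinite(p_values["pct_Q"]) and p_values["pct_Q"] < thr.exact)
        res = ScreenResult(
            gene_label=gene,
            normalized=norm,
            p_values=p_values,
            alpha_corrected=thr,
            classification=cls,
            significant_q=sig,
            n_control=control.n,
            n_treated=treated.n,
        )
        results.append(res)
        row = {
            "gene": gene,
            "norm_R": norm["pct_R"].value,
            "norm_D": norm["pct_D"].value,
            "norm_Q": norm["pct_Q"].value,
        }
        for metric in RATE_METRICS:
            row[f"norm_{metric}"] = norm[metric].value
        row.update(
            {
                "p_D": p_values["pct_D"],
                "p_Q": p_values["pct_Q"],
                "alpha_corrected": thr.display,
                "classification": cls,
                "significant_Q": sig,
                "unstable_metrics": ";".join(k for k, v in norm.items() if not v.stable),
                "n_control": control.n,
                "n_treated": treated.n,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows), results
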