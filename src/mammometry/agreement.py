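"""Method-agreement statistics: paired t-test and Bland-Altman analysis.

For paired measurements (x = reference, e.g. a physical tape
measurement; y = comparator, e.g. the photometric value) the per-pair
difference is d = x - y, i.e. reference minus comparator: a positive
bias means the comparator under-reads.  The Bland-Altman summary is

    bias = mean(d),  LoA = bias +/- 1.96 * sd(d)

with the sample (n-1) standard deviation and the conventional fixed
1.96 multiplier.  Proportional bias is quantified by ordinary least
squares of d on the per-pair mean (x + y)/2; its coefficient of
determination r^2 says how much of the disagreement grows with the
magnitude being measured.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

ALPHA = 0.05
LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedSample:
    """Paired reference/comparator measurements in cm."""

    x: np.ndarray  # reference
    y: np.ndarray  # comparator
    labels: tuple = ()

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(x) < 3:
            raise ValueError(f"need at least 3 pairs, got {len(x)}")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite measurement values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if self.labels and len(self.labels) != len(x):
            raise ValueError("labels length mismatch")

    @property
    def diffs(self) -> np.ndarray:
        return self.x - self.y

    @property
    def means(self) -> np.ndarray:
        return 0.5 * (self.x + self.y)


def paired_t(sample: PairedSample):
    """Paired t-test on d = x - y; returns (t, df, two-sided p).

    Zero-variance differences are degenerate: p is reported as 1 when
    the mean difference is 0 and as 0 otherwise, with a warning.
    """
    d = sample.diffs
    n = len(d)
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate paired sample: zero-variance differences")
        return (0.0, df, 1.0) if d.mean() == 0 else (np.inf * np.sign(d.mean()), df, 0.0)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


@dataclass(frozen=True)
class ProportionalBias:
    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False


def proportional_bias(sample: PairedSample) -> ProportionalBias:
    """OLS of the difference on the per-pair mean."""
    means, diffs = sample.means, sample.diffs
    if means.var() == 0:
        warnings.warn("degenerate regressor: all per-pair means equal")
        return ProportionalBias(float("nan"), float("nan"), float("nan"), degenerate=True)
    if diffs.var() == 0:
        # flat differences: perfectly agreeing spread, no proportional trend
        return ProportionalBias(0.0, float(diffs.mean()), 0.0)
    res = stats.linregress(means, diffs)
    return ProportionalBias(float(res.slope), float(res.intercept), float(res.rvalue ** 2))


@dataclass(frozen=True)
class AgreementResult:
    n: int
    bias: float
    sd_diff: float
    loa_upper: float
    loa_lower: float
    t_stat: float
    df: int
    p_value: float
    r_squared: float
    slope: float = float("nan")
    intercept: float = float("nan")
    degenerate: bool = False
    means: np.ndarray = field(default=None, repr=False)
    diffs: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n", "bias", "sd_diff", "loa_upper", "loa_lower",
                 "t_stat", "df", "p_value", "r_squared", "slope",
                 "intercept", "degenerate")}


def bland_altman(sample: PairedSample) -> AgreementResult:
    """Full agreement summary plus the per-pair (mean, diff) points."""
    d = sample.diffs
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    t, df, p = paired_t(sample)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prop = proportional_bias(sample)
    return AgreementResult(
        n=len(d), bias=bias, sd_diff=sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        t_stat=t, df=df, p_value=p,
        r_squared=prop.r_squared, slope=prop.slope, intercept=prop.intercept,
        degenerate=(sd == 0) or prop.degenerate,
        means=sample.means, diffs=d,
    )


def render_bland_altman(result: AgreementResult, out_path, title: str = "") -> None:
    """Scatter of (mean, diff) with bias and LoA lines, written as PNG.

    A sidecar JSON (``<out_path>.json``) records the plotted line
    positions so the figure content is machine-checkable.
    """
    if result.means is None or len(result.means) == 0:
        raise ValueError("agreement result carries no data points to plot")
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.2))
    ax.scatter(result.means, result.diffs, s=18, alpha=0.7, edgecolor="none")
    for value, style, label in (
        (result.bias, "-", f"bias = {result.bias:.2f}"),
        (result.loa_upper, "--", f"+1.96 SD = {result.loa_upper:.2f}"),
        (result.loa_lower, "--", f"-1.96 SD = {result.loa_lower:.2f}"),
    ):
        ax.axhline(value, linestyle=style, color="crimson" if style == "-" else "gray")
        ax.annotate(label, xy=(1.0, value), xycoords=("axes fraction", "data"),
                    xytext=(4, 0), textcoords="offset points", fontsize=8, va="center")
    ax.set_xlabel("mean of methods (cm)")
    ax.set_ylabel("reference - comparator (cm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=110)
    plt.close(fig)
    sidecar = {"bias": result.bias, "loa_upper": result.loa_upper,
               "loa_lower": result.loa_lower, "n": result.n}
    Path(str(out_path) + ".json").write_text(json.dumps(sidecar, indent=2))
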