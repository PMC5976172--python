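"""Distance-dependent attenuation models and the extra-sum-of-squares F test.

Back-propagating action potentials attenuate with distance x from the
soma; their amplitude follows a two-parameter exponential decay
y = A * exp(-b * x) and their half-width an exponential growth
y = A * exp(b * x).  The length constant lambda = 1 / b is the distance
over which the signal falls to 1/e of its somatic value.

Group comparisons use the extra sum-of-squares F test for nested curve
models: the null model fits one curve to the pooled data (2 parameters),
the alternative fits one curve per group (4 parameters), and

    F = ((RSS_pooled - RSS_sep) / (df_pooled - df_sep)) / (RSS_sep / df_sep)

is referred to the F(df_pooled - df_sep, df_sep) upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .core import ValidationError

DECAY = "decay"
GROWTH = "growth"

#: response name -> (dataset column, default model sign)
RESPONSES = {
    "amplitude": ("amplitude_mV", DECAY),
    "half_width": ("halfwidth_ms", GROWTH),
}

_B_FLOOR = 1e-8  # per um; fits driven below this are flagged flat

DATASET_COLUMNS = ["cell_id", "group", "distance_um", "amplitude_mV", "halfwidth_ms"]


@dataclass
class AttenuationDataset:
    """One record per cell: (cell_id, group, distance, amplitude, half-width)."""

    records: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in DATASET_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"dataset missing columns: {missing}")
        if (self.records["distance_um"] < 0).any():
            raise ValidationError("distances must be >= 0")
        self.records = self.records.reset_index(drop=True)

    @property
    def groups(self) -> list:
        return sorted(self.records["group"].unique())

    def xy(self, response: str, group=None) -> tuple[np.ndarray, np.ndarray]:
        col, _ = RESPONSES[response]
        df = self.records
        if group is not None:
            df = df[df["group"] == group]
        return df["distance_um"].to_numpy(float), df[col].to_numpy(float)


@dataclass
class ExpFit:
    """A fitted single-exponent distance model y = a * exp(+/- b x).

    ``lam`` is the length constant 1/b in the units of x.  ``flat`` flags
    fits where b collapsed to zero (no distance dependence resolvable).
    """

    a: float
    b: float
    sign: str
    lam: float
    r2: float
    rss: float
    n: int
    df: int
    a_se: float = float("nan")
    b_se: float = float("nan")
    converged: bool = True
    flat: bool = False

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        s = -1.0 if self.sign == DECAY else 1.0
        return self.a * np.exp(s * self.b * np.asarray(x, dtype=float))


@dataclass
class FTestResult:
    """Pooled-vs-separate nested curve comparison."""

    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    pooled: ExpFit
    per_group: dict
    limit_case: bool = False  # RSS_sep == 0; p computed in the limit


def _fit_exp(x: np.ndarray, y: np.ndarray, sign: str):
    """Nonlinear LS on the original scale, log-linear initialization.

    Returns (a, b, a_se, b_se, converged).  Zero responses (clipped
    noisy data) are allowed in the fit; the log-linear initializer uses
    the positive subset only.
    """
    s = -1.0 if sign == DECAY else 1.0

    def model(x_, a_, b_):
        return a_ * np.exp(s * b_ * x_)

    pos = y > 0
    slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
    b0 = max(s * slope, _B_FLOOR)
    a0 = float(np.exp(intercept))
    try:
        popt, pcov = curve_fit(
            model,
            x,
            y,
            p0=[a0, b0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=10000,
        )
        ses = np.sqrt(np.diag(pcov))
        return float(popt[0]), float(popt[1]), float(ses[0]), float(ses[1]), True
    except (RuntimeError, ValueError):
        return a0, b0, float("nan"), float("nan"), False


def fit_exponential_model(
    x, y, sign: str = DECAY
) -> ExpFit:
    """Fit y = a * exp(-b x) (decay) or y = a * exp(b x) (growth).

    Unweighted nonlinear least squares on the original scale; the
    log-linear regression of ln(y) on x only seeds the optimizer (using
    the positive responses).  Requires >= 3 points, >= 3 of them
    strictly positive; zeros (clipped noisy measurements) may enter the
    least-squares objective.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError(f"need >= 3 points to fit, got {x.size}")
    if (y < 0).any():
        raise ValidationError("responses must be non-negative")
    if (y > 0).sum() < 3:
        raise ValidationError("need >= 3 strictly positive responses")
    if sign not in (DECAY, GROWTH):
        raise ValidationError(f"sign must be '{DECAY}' or '{GROWTH}'")
    a, b, a_se, b_se, converged = _fit_exp(x, y, sign)
    flat = b <= _B_FLOOR
    s = -1.0 if sign == DECAY else 1.0
    resid = y - a * np.exp(s * b * x)
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    lam = 1.0 / b if b > 0 else float("inf")
    return ExpFit(
        a=a,
        b=b,
        sign=sign,
        lam=lam,
        r2=float(np.clip(r2, 0.0, 1.0)) if tss > 0 else r2,
        rss=rss,
        n=int(x.size),
        df=int(x.size - 2),
        a_se=a_se,
        b_se=b_se,
        converged=converged,
        flat=flat,
    )


def length_constant(fit) -> float:
    """Length constant 1/b in um (for x in um).

    Accepts an :class:`ExpFit` or a bare rate parameter b.  Raises for
    b <= 0.  Reporting layers round to one decimal.
    """
    b = fit.b if isinstance(fit, ExpFit) else float(fit)
    if not b > 0:
        raise ValidationError(f"rate parameter must be > 0, got {b}")
    return 1.0 / b


def extra_ss_f_test(
    data: AttenuationDataset,
    response: str = "amplitude",
    sign: str | None = None,
) -> FTestResult:
    """Do two groups need separate attenuation curves?

    Fits one pooled curve (2 parameters) and one curve per group
    (4 parameters total) and compares them with the extra sum-of-squares
    F statistic.  Requires exactly two groups with >= 3 points each.
    """
    if response not in RESPONSES:
        raise ValidationError(f"response must be one of {sorted(RESPONSES)}")
    if sign is None:
        sign = RESPONSES[response][1]
    groups = data.groups
    if len(groups) != 2:
        raise ValidationError(f"exactly 2 groups required, got {groups}")
    per_group = {}
    rss_sep = 0.0
    n_total = 0
    for g in groups:
        xg, yg = data.xy(response, g)
        if xg.size < 3:
            raise ValidationError(f"group {g!r} has {xg.size} points; need >= 3")
        fit = fit_exponential_model(xg, yg, sign)
        per_group[g] = fit
        rss_sep += fit.rss
        n_total += fit.n
    x_all, y_all = data.xy(response)
    pooled = fit_exponential_model(x_all, y_all, sign)
    df_pooled = n_total - 2
    df_sep = n_total - 4
    df_num = df_pooled - df_sep
    limit_case = rss_sep == 0.0
    if limit_case:
        f_stat = float("inf")
        p = 0.0 if pooled.rss > 0 else 1.0
    else:
        f_stat = max(0.0, (pooled.rss - rss_sep) / df_num / (rss_sep / df_sep))
        p = float(stats.f.sf(f_stat, df_num, df_sep))
    return FTestResult(
        f_stat=f_stat,
        df_num=df_num,
        df_den=df_sep,
        p_value=p,
        pooled=pooled,
        per_group=per_group,
        limit_case=limit_case,
    )
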