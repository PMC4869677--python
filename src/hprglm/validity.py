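"""Predictive validity: AIC of condition-predicting models, and contrasts.

The question asked of every analysis parameter (a model amplitude or an
operational peak-scoring index) is: how well does this single number
separate known experimental conditions across participants?  The answer is
quantified by the Akaike information criterion (AIC) of a univariate
logistic model predicting the (two-class) condition from the standardized
parameter:

    AIC = -2 log L + 2 k,    k = 2 (intercept + slope).

Because k is identical for every tested parameter, AIC ranking reduces to
likelihood ranking.  An absolute AIC difference > 3 is treated as decisive,
by the analogy exp(-3) ~ 0.0498 < .05 with a classic rejection threshold.

The slope of the logistic model is estimated by (bounded) maximum
likelihood with ``scipy.optimize``; under perfect separation the slope is
capped at magnitude 10 on the standardized scale and the entry flagged, so
AIC stays finite and comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ArgumentError

#: Absolute AIC difference regarded as decisive evidence.
DECISIVE_DELTA_AIC = 3.0
#: Cap on the standardized logistic slope under (near-)perfect separation.
SLOPE_CAP = 10.0


@dataclass(frozen=True)
class PredictiveEntry:
    """AIC record of one parameter for one contrast."""

    log_likelihood: float
    k: int
    aic: float
    null_log_likelihood: float
    null_aic: float
    delta_aic_vs_null: float  # aic - null_aic; negative favours the parameter
    slope: float
    separation_flagged: bool

    @property
    def decisive_vs_null(self) -> bool:
        return abs(self.delta_aic_vs_null) > DECISIVE_DELTA_AIC


def _binomial_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def predictive_aic(
    values: np.ndarray,
    labels: np.ndarray,
    contrast: tuple[object, object] | None = None,
) -> PredictiveEntry:
    """AIC of predicting a two-class condition from one parameter.

    Parameters
    ----------
    values:
        Per-participant parameter values.
    labels:
        Condition label per participant.
    contrast:
        Optional pair of labels (or label collections) selecting and
        defining the two classes; required when more than two labels occur.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ArgumentError("values and labels must align")
    if contrast is not None:
        side_a, side_b = (
            set(c) if isinstance(c, (set, list, tuple)) else {c} for c in contrast
        )
        mask = np.isin(labels, list(side_a | side_b))
        values, labels = values[mask], labels[mask]
        y = np.isin(labels, list(side_b)).astype(float)
    else:
        classes = np.unique(labels)
        if classes.size != 2:
            raise ArgumentError(
                f"need exactly 2 classes (got {classes.size}); pass a contrast"
            )
        y = (labels == classes[1]).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ArgumentError("need at least 2 participants per side")

    sd = values.std(ddof=0)
    x = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)

    p_null = y.mean()
    b0_null = float(np.log(p_null / (1.0 - p_null)))
    ll_null = _binomial_loglik(y, np.full_like(y, b0_null))

    def nll(params):
        b0, b1 = params
        return -_binomial_loglik(y, b0 + b1 * x)

    res = optimize.minimize(
        nll,
        x0=np.array([b0_null, 0.0]),
        method="L-BFGS-B",
        bounds=[(None, None), (-SLOPE_CAP, SLOPE_CAP)],
    )
    b0, b1 = res.x
    ll = -float(res.fun)
    # The bounded optimum can never be worse than the null (slope 0).
    ll = max(ll, ll_null)
    k, k_null = 2, 1
    aic = -2.0 * ll + 2.0 * k
    null_aic = -2.0 * ll_null + 2.0 * k_null
    return PredictiveEntry(
        log_likelihood=ll,
        k=k,
        aic=aic,
        null_log_likelihood=ll_null,
        null_aic=null_aic,
        delta_aic_vs_null=aic - null_aic,
        slope=float(b1),
        separation_flagged=bool(abs(b1) >= SLOPE_CAP - 1e-6),
    )


def compare_parameters(
    parameters: dict[str, np.ndarray],
    labels: np.ndarray,
    contrast: tuple[object, object] | None = None,
) -> pd.DataFrame:
    """AIC table over several parameters for one contrast.

    Returns a frame with one row per parameter (AIC, log-likelihood, slope,
    delta vs null, decisiveness) plus pairwise AIC differences against the
    best parameter.
    """
    rows = {}
    for name, values in parameters.items():
        entry = predictive_aic(np.asarray(values), labels, contrast)
        rows[name] = {
            "aic": entry.aic,
            "log_likelihood": entry.log_likelihood,
            "k": entry.k,
            "delta_aic_vs_null": entry.delta_aic_vs_null,
            "slope": entry.slope,
            "separation_flagged": entry.separation_flagged,
        }
    frame = pd.DataFrame(rows).T.sort_values("aic")
    frame["delta_aic_vs_best"] = frame["aic"] - frame["aic"].min()
    frame["decisive_vs_best"] = frame["delta_aic_vs_best"] > DECISIVE_DELTA_AIC
    return frame


def contrast_tests(
    groups: dict[str, np.ndarray],
    design: str = "between",
    contrast: tuple[str, str] | None = None,
) -> dict:
    """Classic qualification statistics for grouped parameter estimates.

    ``between``
        One-way between-subjects ANOVA across all groups plus Tukey HSD
        pairwise post-hoc comparisons.
    ``within``
        Paired t test on the planned ``contrast`` pair; the two groups must
        contain the same participants in the same order.

    No multiple-comparison correction is applied: contrasts are assumed to
    be pre-specified.
    """
    arrays = {name: np.asarray(v, dtype=float) for name, v in groups.items()}
    if any(v.size == 0 for v in arrays.values()):
        raise ArgumentError("all groups must be non-empty")
    if design == "between":
        names = list(arrays)
        f_stat, p = stats.f_oneway(*arrays.values())
        if f_stat < 0 and f_stat > -1e-12:
            # Catastrophic cancellation for a between-group SS of zero.
            f_stat = 0.0
        if not np.isfinite(p) and f_stat == 0.0:
            dfb = len(names) - 1
            dfw = sum(v.size for v in arrays.values()) - len(names)
            p = float(stats.f.sf(0.0, dfb, dfw))
        hsd = stats.tukey_hsd(*arrays.values())
        pairwise = {
            (names[i], names[j]): {
                "statistic": float(hsd.statistic[i, j]),
                "p": float(hsd.pvalue[i, j]),
            }
            for i in range(len(names))
            for j in range(i + 1, len(names))
        }
        return {
            "design": "between",
            "F": float(f_stat),
            "p": float(p),
            "df_between": len(names) - 1,
            "df_within": int(sum(v.size for v in arrays.values()) - len(names)),
            "pairwise": pairwise,
        }
    if design == "within":
        if contrast is None or len(contrast) != 2:
            raise ArgumentError("within-subjects design needs a contrast pair")
        a, b = (arrays[c] for c in contrast)
        if a.shape != b.shape:
            raise ArgumentError(
                "within-subjects contrast requires matched participants"
            )
        t_stat, p = stats.ttest_rel(a, b)
        return {
            "design": "within",
            "contrast": tuple(contrast),
            "t": float(t_stat),
            "p": float(p),
            "df": int(a.size - 1),
            "mean_1": float(a.mean()),
            "mean_2": float(b.mean()),
        }
    raise ArgumentError(f"unknown design {design!r}; use 'between' or 'within'")
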