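"""Statistical summaries: bootstrap median CIs and the limb mixed model.

Group medians get percentile-bootstrap 95% confidence intervals (stride-level
resampling by default; cow-level cluster resampling by flag).  Differences
between limbs or limb pairs are evaluated with a linear mixed model — group
as fixed effect, deviation from the median stride duration as covariate
(omitted for speed-normalized responses, which are already duty factors),
and a random intercept per cow.  Inference is reported as group-level
estimates with 95% CIs plus a pairwise CI non-overlap flag; no p-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("cowgait")


@dataclass
class IntervalEstimate:
    parameter: str
    group: str
    estimate: float
    ci_low: float
    ci_high: float
    n_strides: int
    method: str  # 'bootstrap' or 'mixed_model'

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ci_high):
            raise ValueError("ci_low must not exceed ci_high")
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")


def bootstrap_median_ci(
    values,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    ci_level: float = 0.95,
    parameter: str = "",
    group: str = "",
) -> IntervalEstimate:
    """Percentile bootstrap CI of the median; deterministic given the seed."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise ValueError("bootstrap_median_ci needs at least 2 values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(medians, [alpha / 2, 1.0 - alpha / 2])
    return IntervalEstimate(
        parameter=parameter,
        group=group,
        estimate=float(np.median(values)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_strides=int(values.size),
        method="bootstrap",
    )


def group_bootstrap_summaries(
    df: pd.DataFrame,
    value_col: str,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
    cluster_by_cow: bool = False,
) -> list[IntervalEstimate]:
    """Bootstrap median CI per (parameter, group) over included records."""
    out = []
    rng = np.random.default_rng(seed)
    inc = df[df["included"].astype(bool) & np.isfinite(df[value_col])]
    for (param, group), sub in inc.groupby(["parameter", "group"], sort=True):
        vals = sub[value_col].to_numpy()
        if vals.size < 2:
            continue
        if cluster_by_cow and sub["cow_id"].nunique() > 1:
            est = _cluster_bootstrap(sub, value_col, n_boot, rng, ci_level, param, group)
        else:
            est = bootstrap_median_ci(
                vals, n_boot, rng, ci_level, parameter=param, group=group
            )
        out.append(est)
    return out


def _cluster_bootstrap(sub, value_col, n_boot, rng, ci_level, param, group):
    cows = sub["cow_id"].unique()
    by_cow = [sub.loc[sub["cow_id"] == c, value_col].to_numpy() for c in cows]
    medians = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, len(by_cow), size=len(by_cow))
        medians[b] = np.median(np.concatenate([by_cow[i] for i in pick]))
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(medians, [alpha / 2, 1.0 - alpha / 2])
    return IntervalEstimate(
        parameter=param,
        group=group,
        estimate=float(sub[value_col].median()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_strides=int(len(sub)),
        method="bootstrap",
    )


@dataclass
class MixedModelResult:
    estimates: list[IntervalEstimate]
    nonoverlap: dict[tuple[str, str], bool]     # pairwise CI non-overlap flags
    residuals: np.ndarray
    random_effects: dict
    method: str                                  # 'mixed_model' or fallback note


def fit_limb_model(
    df: pd.DataFrame,
    value_col: str = "duration",
    use_covariate: bool = True,
    ci_level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> MixedModelResult:
    """Linear mixed model of one temporal parameter across groups.

    ``df`` needs columns group, cow_id, the response ``value_col`` and — when
    ``use_covariate`` — stride_dev (stride duration minus its median).  The
    model is ``value ~ 0 + group (+ stride_dev)`` with a random intercept per
    cow, fitted by REML, so the group coefficients are the group-level
    estimated means at the median stride duration.  A singular fit or a
    single-cow data set falls back to group-wise bootstrap medians, with the
    method recorded.
    """
    data = df[df["included"].astype(bool) & np.isfinite(df[value_col])].copy()
    if data["group"].nunique() < 2:
        raise ValueError("fit_limb_model needs at least 2 groups")
    data = data.rename(columns={value_col: "value"})
    fallback_reason = None
    if data["cow_id"].nunique() < 2:
        fallback_reason = "single cow"
    result = None
    if fallback_reason is None:
        import statsmodels.formula.api as smf

        formula = "value ~ 0 + C(group)"
        if use_covariate:
            if "stride_dev" not in data.columns:
                raise ValueError("use_covariate requires a stride_dev column")
            formula += " + stride_dev"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(formula, data, groups=data["cow_id"])
                result = model.fit(reml=True)
            if not np.all(np.isfinite(result.bse_fe)):
                fallback_reason = "singular fit"
        except Exception as exc:  # convergence/singularity
            fallback_reason = f"fit failed ({exc.__class__.__name__})"

    if fallback_reason is not None:
        log.warning("mixed model fallback to bootstrap: %s", fallback_reason)
        ests = group_bootstrap_summaries(
            df.assign(parameter="model"), value_col, n_boot, seed, ci_level
        )
        non = _nonoverlap_flags(ests)
        return MixedModelResult(
            estimates=ests,
            nonoverlap=non,
            residuals=np.array([]),
            random_effects={},
            method=f"bootstrap fallback: {fallback_reason}",
        )

    ci = result.conf_int(alpha=1.0 - ci_level)
    ests = []
    counts = data.groupby("group").size()
    for name in result.fe_params.index:
        if not name.startswith("C(group)"):
            continue
        group = name[len("C(group)["):].rstrip("]")
        if group.startswith("T."):
            group = group[2:]
        ests.append(
            IntervalEstimate(
                parameter="model",
                group=group,
                estimate=float(result.fe_params[name]),
                ci_low=float(ci.loc[name, 0]),
                ci_high=float(ci.loc[name, 1]),
                n_strides=int(counts.get(group, 1)),
                method="mixed_model",
            )
        )
    non = _nonoverlap_flags(ests)
    return MixedModelResult(
        estimates=ests,
        nonoverlap=non,
        residuals=np.asarray(result.resid),
        random_effects={k: float(v.iloc[0]) for k, v in result.random_effects.items()},
        method="mixed_model",
    )


def _nonoverlap_flags(ests: list[IntervalEstimate]) -> dict[tuple[str, str], bool]:
    out = {}
    for i, a in enumerate(ests):
        for b in ests[i + 1:]:
            key = (a.group, b.group)
            out[key] = a.ci_low > b.ci_high or b.ci_low > a.ci_high
    return out
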