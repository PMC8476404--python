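"""Difference-in-difference estimation for binary outcomes.

A linear probability model

    E[y] = b0 + b1 * intervention + b2 * post + b3 * intervention x post

is fit by OLS so coefficients read directly as percentage-point effects;
``b3`` is the DiD estimate.  Standard errors are cluster-robust over
facilities with the CR1 small-sample factor (G/(G-1) x (n-1)/(n-k)) and
two-sided p-values use a t reference distribution with G-1 degrees of
freedom, the convention of Stata's ``cluster`` option.  In the saturated
(unadjusted) model the interaction equals the four-cell closed form

    (p_I,post - p_I,pre) - (p_C,post - p_C,pre)

exactly; a facility-type adjustment is available as a sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DesignError, InferenceError
from .records import EXPOSURE_GROUPS


@dataclass
class DiDResult:
    """Interaction estimate for one binary outcome."""

    outcome_name: str
    beta_interaction: float      # on the proportion scale (x100 = pp)
    se_clustered: float
    p_value: float
    n_obs: int
    n_clusters: int
    adjusted_for_facility_type: bool
    group_means: dict            # (arm, period) -> cell proportion

    @property
    def beta_pp(self) -> float:
        """Interaction in percentage points."""
        return 100.0 * self.beta_interaction


def closed_form_did(group_means: dict) -> float:
    """Four-cell difference-in-difference on proportions."""
    return ((group_means[("intervention", "post")] - group_means[("intervention", "pre")])
            - (group_means[("control", "post")] - group_means[("control", "pre")]))


def did_fit(rows: pd.DataFrame, outcome: str = "outcome",
            adjust: bool = False, outcome_name: str | None = None) -> DiDResult:
    """Fit the DiD linear probability model on one binary outcome.

    ``rows`` needs columns ``outcome`` (0/1 or bool; missing rows dropped
    listwise), ``arm``, ``period``, ``facility_id`` and — when ``adjust`` —
    ``facility_type``.  Raises :class:`DesignError` when an exposure cell is
    empty and :class:`InferenceError` with fewer than two clusters.
    """
    need = {outcome, "arm", "period", "facility_id"} | ({"facility_type"} if adjust else set())
    missing = need - set(rows.columns)
    if missing:
        raise DesignError(f"missing column(s) {sorted(missing)}")
    df = rows.dropna(subset=[outcome]).copy()
    y = df[outcome].astype(float)
    if not y.isin([0.0, 1.0]).all():
        raise DesignError(f"outcome {outcome!r} must be binary 0/1")

    interv = (df["arm"] == "intervention").astype(float)
    post = (df["period"] == "post").astype(float)
    cells = {g: ((interv == (g[0] == "intervention")) & (post == (g[1] == "post")))
             for g in EXPOSURE_GROUPS}
    for g, mask in cells.items():
        if not mask.any():
            raise DesignError(f"empty exposure cell {g}")
    group_means = {g: float(y[mask].mean()) for g, mask in cells.items()}

    groups = df["facility_id"].astype(str)
    n_clusters = groups.nunique()
    if n_clusters < 2:
        raise InferenceError("cluster-robust inference needs >= 2 facilities")

    X = pd.DataFrame({
        "const": 1.0,
        "intervention": interv,
        "post": post,
        "intervention_x_post": interv * post,
    })
    if adjust:
        X["hospital"] = (df["facility_type"] == "hospital").astype(float)

    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit(
        cov_type="cluster",
        cov_kwds={"groups": groups.to_numpy(), "use_correction": True},
    )
    k = list(X.columns).index("intervention_x_post")
    beta = float(fit.params[k])
    # near-saturated designs can leave tiny negative round-off on unused
    # covariance diagonal entries; only the interaction's SE is consumed
    with np.errstate(invalid="ignore"):
        se = float(fit.bse[k])
    # t reference with G-1 df, pinned here rather than relying on library
    # defaults; a degenerate (constant-outcome) fit has no defined p-value
    if se > 0:
        p = 2.0 * stats.t.sf(abs(beta / se), df=n_clusters - 1)
    else:
        p = float("nan")

    return DiDResult(
        outcome_name=outcome_name or outcome,
        beta_interaction=beta,
        se_clustered=se,
        p_value=float(p),
        n_obs=int(len(df)),
        n_clusters=int(n_clusters),
        adjusted_for_facility_type=adjust,
        group_means=group_means,
    )


def did_summary(results: Iterable[DiDResult]) -> pd.DataFrame:
    """Delimited-friendly summary table, one row per outcome."""
    rows = []
    for r in results:
        rows.append({
            "outcome": r.outcome_name,
            "beta_pp": r.beta_pp,
            "se_pp": 100.0 * r.se_clustered,
            "p_value": r.p_value,
            "n_obs": r.n_obs,
            "n_clusters": r.n_clusters,
            "adjusted_for_facility_type": r.adjusted_for_facility_type,
        })
    return pd.DataFrame(rows)
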