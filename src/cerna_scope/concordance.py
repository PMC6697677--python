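"""Contingency statistics for "relevant dysregulation" of downstream targets.

The ceRNA (sponge) model predicts the direction of downstream coupling:

* miRNA -> mRNA: a miRNA represses its targets, so the relevant downstream
  change is the *inverse* of the upstream one;
* circRNA -> miRNA: sequestration need not change miRNA abundance, but if it
  did the relevant direction would again be the inverse;
* circRNA -> mRNA (via a bridging miRNA): sponging disinhibits, so the
  relevant downstream change has the *same* direction as the circRNA.

Each analysis is a 2x2 table over a downstream feature universe —
targeted-by-a-dysregulated-upstream-feature against relevantly-dysregulated —
scored with the odds ratio, the Woolf (log-OR normal approximation) 95% CI
and Pearson's chi-square without continuity correction.  A logistic model
with both the circRNA-targeted and the miRNA-targeted indicator gives the
miRNA-adjusted circRNA odds ratio.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .targets import TargetMap

logger = logging.getLogger(__name__)

#: default relevant-direction rule per relation
DIRECTION_RULES: dict[str, str] = {
    "miRNA->mRNA": "inverse",
    "circRNA->miRNA": "inverse",
    "circRNA->mRNA": "same",
}

_FLIP = {"up": "down", "down": "up"}


def relevant_direction(upstream_direction: str, relation: str,
                       rules: dict[str, str] = DIRECTION_RULES) -> str:
    """Direction of downstream dysregulation predicted by the sponge model."""
    if upstream_direction not in _FLIP:
        raise ValueError("upstream direction must be 'up' or 'down'")
    rule = rules[relation]
    return upstream_direction if rule == "same" else _FLIP[upstream_direction]


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: (targeted?, relevantly dysregulated?) over a universe.

    ``a``: targeted & dysregulated, ``b``: targeted & not, ``c``: not
    targeted & dysregulated, ``d``: neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.universe_size < 1:
            raise ValueError("empty table")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """True when a row or column margin is zero (OR undefined)."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclasses.dataclass(frozen=True)
class OddsResult:
    """Odds ratio with 95% CI and p-value, plus provenance flags."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    correction_applied: bool = False
    undefined: bool = False
    method: str = "chi2"


def build_contingency(
    targeted,
    downstream_de: pd.DataFrame,
    relevant_dir: str,
    universe=None,
) -> ContingencyTable:
    """Cross-classify a downstream universe by targeted status and relevant DE.

    ``targeted`` is the id set of downstream features targeted by at least
    one dysregulated upstream feature (compute it with the target-map joins);
    ``relevant_dir`` is the downstream direction that counts as relevant
    (see :func:`relevant_direction`).  ``universe`` defaults to every feature
    in ``downstream_de``.  Degenerate margins are allowed here and flagged by
    :func:`odds_ratio_test`.
    """
    if relevant_dir not in _FLIP:
        raise ValueError("relevant_dir must be 'up' or 'down'")
    if universe is None:
        universe = set(downstream_de["feature_id"])
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    targeted = set(targeted) & universe
    in_universe = downstream_de["feature_id"].isin(universe)
    dysreg = set(
        downstream_de.loc[in_universe & (downstream_de["direction"] == relevant_dir), "feature_id"]
    )
    a = len(targeted & dysreg)
    b = len(targeted) - a
    c = len(dysreg - targeted)
    d = len(universe) - a - b - c
    table = ContingencyTable(a, b, c, d)
    if table.degenerate:
        logger.info("build_contingency: degenerate margins (a,b,c,d)=(%d,%d,%d,%d)", a, b, c, d)
    return table


def targeted_set(upstream_dysreg_ids, target_map: TargetMap) -> set[str]:
    """Downstream ids targeted by at least one upstream dysregulated feature."""
    adj = target_map.adjacency()
    out: set[str] = set()
    for u in upstream_dysreg_ids:
        out |= adj.get(u, set())
    return out


def _pearson_chi2_p(table: ContingencyTable) -> float:
    """Pearson chi-square p (1 df, no continuity correction) via closed form."""
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return 1.0
    stat = n * (a * d - b * c) ** 2 / denom
    return float(stats.chi2.sf(stat, df=1))


def odds_ratio_test(table: ContingencyTable) -> OddsResult:
    """Odds ratio, Woolf 95% CI and Pearson chi-square p for a 2x2 table.

    OR = ad/bc with CI exp(ln OR +/- 1.96*sqrt(1/a+1/b+1/c+1/d)).  When a
    cell (but no full margin) is zero, the Haldane-Anscombe +0.5 correction
    is applied to all cells for the OR/CI (flagged); the p-value always comes
    from the uncorrected chi-square.  A zero row or column margin yields an
    undefined OR with p = 1.
    """
    p = _pearson_chi2_p(table)
    if table.degenerate:
        return OddsResult(np.nan, np.nan, np.nan, 1.0, undefined=True)
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    corrected = bool((cells == 0).any())
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = np.sqrt((1.0 / cells).sum())
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return OddsResult(float(or_), float(lo), float(hi), p, correction_applied=corrected)


# --------------------------------------------------------------------------
# miRNA-adjusted logistic model


def adjusted_logistic(
    downstream_de: pd.DataFrame,
    relevant_dir: str,
    circ_targeted,
    mirna_targeted,
    universe=None,
) -> OddsResult:
    """Adjusted odds ratio of the circRNA-targeted indicator.

    Fits ``P(relevantly dysregulated) ~ targeted-by-dysregulated-circRNA +
    targeted-by-dysregulated-miRNA`` by maximum-likelihood logistic
    regression over the downstream universe and returns the exponentiated
    circRNA coefficient with its Wald 95% CI and p.  A constant miRNA
    indicator is dropped (the fit then reduces to the univariate model); on
    (quasi-)separation a Firth-penalized fit is used and flagged.
    """
    if relevant_dir not in _FLIP:
        raise ValueError("relevant_dir must be 'up' or 'down'")
    if universe is None:
        universe = set(downstream_de["feature_id"])
    universe = sorted(set(universe))
    if not universe:
        raise ValueError("empty universe")
    de = downstream_de.set_index("feature_id").reindex(universe)
    y = (de["direction"] == relevant_dir).to_numpy(dtype=float)
    circ_targeted = set(circ_targeted)
    mirna_targeted = set(mirna_targeted)
    x_circ = np.array([fid in circ_targeted for fid in universe], dtype=float)
    x_mir = np.array([fid in mirna_targeted for fid in universe], dtype=float)

    if x_circ.std() == 0:
        logger.warning("adjusted_logistic: circRNA indicator is constant; OR undefined")
        return OddsResult(np.nan, np.nan, np.nan, 1.0, undefined=True, method="logit")

    cols = [x_circ]
    if x_mir.std() > 0:
        cols.append(x_mir)
    else:
        logger.info("adjusted_logistic: miRNA indicator constant, dropped")
    X = sm.add_constant(np.column_stack(cols))
    circ_idx = 1  # column after the intercept

    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", False))
        beta = fit.params
        cov = fit.cov_params()
        if not converged or not np.all(np.isfinite(np.sqrt(np.diag(cov)))) or np.abs(beta).max() > 15:
            raise _SeparationError
        method = "logit"
    except (_SeparationError, PerfectSeparationError, np.linalg.LinAlgError):
        logger.info("adjusted_logistic: falling back to Firth-penalized fit")
        beta, cov = _firth_logistic(X, y)
        method = "firth"

    se = float(np.sqrt(cov[circ_idx, circ_idx]))
    b = float(beta[circ_idx])
    z = b / se if se > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(z)))
    return OddsResult(
        float(np.exp(b)),
        float(np.exp(b - 1.96 * se)),
        float(np.exp(b + 1.96 * se)),
        p,
        method=method,
    )


class _SeparationError(Exception):
    pass


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-8):
    """Firth-penalized logistic regression (Jeffreys-prior bias reduction).

    Newton iterations on the penalized score U*(b) = X'(y - p + h(0.5 - p))
    where h are the hats of W^{1/2} X (X'WX)^{-1} X' W^{1/2}.  Returns the
    coefficient vector and the inverse Fisher information as covariance.
    """
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        p = expit(X @ beta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        XW = X * w[:, None]
        info = X.T @ XW
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    p = expit(X @ beta)
    w = np.clip(p * (1.0 - p), 1e-12, None)
    info = X.T @ (X * w[:, None])
    return beta, np.linalg.pinv(info)


# --------------------------------------------------------------------------
# tabulation helper


def results_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble contingency/logistic results into a flat table.

    Each row dict should contain ``analysis``, ``time``, ``direction``, a
    :class:`ContingencyTable` under ``table``, an :class:`OddsResult` under
    ``odds`` and optionally another under ``adjusted``.
    """
    out = []
    for r in rows:
        t: ContingencyTable = r["table"]
        o: OddsResult = r["odds"]
        rec = {
            "analysis": r["analysis"],
            "time": r.get("time", ""),
            "direction": r["direction"],
            "a": t.a,
            "b": t.b,
            "c": t.c,
            "d": t.d,
            "odds_ratio": o.odds_ratio,
            "ci_low": o.ci_low,
            "ci_high": o.ci_high,
            "p_value": o.p_value,
            "or_undefined": o.undefined,
            "haldane_correction": o.correction_applied,
        }
        adj = r.get("adjusted")
        if adj is not None:
            rec.update(
                adjusted_or=adj.odds_ratio,
                adjusted_ci_low=adj.ci_low,
                adjusted_ci_high=adj.ci_high,
                adjusted_p=adj.p_value,
                adjusted_method=adj.method,
            )
        out.append(rec)
    return pd.DataFrame(out)
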