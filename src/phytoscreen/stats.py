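"""Hit-calling statistics for the screening campaign.

Dunnett's many-to-one comparison
--------------------------------
Each plate carries its own stress control; all treatment groups sharing
that control form one family. With group means m_i, control mean m_0 and
the pooled one-way-ANOVA within-group variance MSE (df = N - G), the
statistics

    t_i = (m_i - m_0) / sqrt(MSE * (1/n_i + 1/n_0))

are jointly multivariate t with the product correlation structure
corr(T_i, T_j) = lam_i * lam_j, lam_i = sqrt(n_i / (n_i + n_0)). The
two-sided adjusted p-value P(max_j |T_j| >= |t_i|) is evaluated by
deterministic 2-D quadrature: conditioning on the shared scale
S = chi_df / sqrt(df) and the common factor Z_0,

    P(max |T| <= t) = E[ prod_j ( Phi((tS + lam_j Z0)/c_j)
                                - Phi((-tS + lam_j Z0)/c_j) ) ],

with c_j = sqrt(1 - lam_j^2); Z_0 is integrated by Gauss-Hermite and S by
Gauss-Legendre against the chi density. This handles unbalanced designs
through the per-group lam_j. With a single treatment group the procedure
reduces exactly to the ordinary pooled two-sided t-test.

Selectivity classification
--------------------------
Extracts are labelled on the normalized (stress control = 100%) scale,
in strict rule order: dual when both NO and ROS are below 60%;
NO-selective when NO is significantly decreased while ROS stays above
90%; ROS-selective symmetrically; otherwise unclassified. Extracts that
failed the viability gate on an endpoint required by the rule are
"excluded". The classes partition every gated extract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateVarianceError,
    InsufficientDataError,
    UndefinedCorrelationError,
)

DEFAULT_ALPHA = 0.05
#: Normalized-level thresholds of the selectivity rules (percent).
DUAL_THRESHOLD = 60.0
SELECTIVE_THRESHOLD = 90.0
#: "Reduced by at least 30%" on the normalized scale.
REDUCTION30_THRESHOLD = 70.0


@dataclass(frozen=True)
class HitCall:
    """Significance call of one extract on one endpoint."""

    sample_id: str
    endpoint: str  # "ros" or "no"
    mean_pct: float
    p_adj: float
    direction: str  # decrease / increase / none
    reduction30: bool


@dataclass(frozen=True)
class SelectivityCall:
    sample_id: str
    selectivity: str  # dual / no_selective / ros_selective / unclassified / excluded


@dataclass(frozen=True)
class CorrelationResult:
    pair: tuple[str, str]
    r_s: float
    p_value: float
    n: int


def _gauss_hermite(n: int) -> tuple[np.ndarray, np.ndarray]:
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


def _chi_nodes(df: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    chi = sps.chi(df)
    lo, hi = chi.ppf(1e-12), chi.ppf(1 - 1e-12)
    x, w = np.polynomial.legendre.leggauss(n)
    q = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    wq = 0.5 * (hi - lo) * w * chi.pdf(q)
    return q / np.sqrt(df), wq  # nodes of S = chi_df / sqrt(df)


def max_abs_t_cdf(
    t: np.ndarray | float,
    lambdas: Sequence[float],
    df: int,
    n_nodes: tuple[int, int] = (64, 64),
) -> np.ndarray:
    """P(max_j |T_j| <= t) for the Dunnett product-correlation null.

    Vectorized over ``t``. ``lambdas`` are sqrt(n_j/(n_j+n0)) per
    treatment group; ``df`` the pooled-variance degrees of freedom.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    lam = np.asarray(lambdas, dtype=float)
    if df < 1:
        raise DegenerateVarianceError("pooled variance has no degrees of freedom")
    z, wz = _gauss_hermite(n_nodes[0])
    s, ws = _chi_nodes(df, n_nodes[1])
    ts = t[:, None, None] * s[None, :, None]  # (m, ns, 1)
    zz = z[None, None, :]  # (1, 1, nz)
    c = np.sqrt(1.0 - lam**2)
    if np.allclose(lam, lam[0]):
        inner = sps.norm.cdf((ts + lam[0] * zz) / c[0]) - sps.norm.cdf(
            (-ts + lam[0] * zz) / c[0]
        )
        prod = np.clip(inner, 0.0, 1.0) ** len(lam)
    else:
        prod = np.ones((t.size, s.size, z.size))
        for lj, cj in zip(lam, c):
            inner = sps.norm.cdf((ts + lj * zz) / cj) - sps.norm.cdf(
                (-ts + lj * zz) / cj
            )
            prod *= np.clip(inner, 0.0, 1.0)
    cdf = np.einsum("msz,s,z->m", prod, ws, wz)
    cdf = np.clip(cdf, 0.0, 1.0)
    cdf[t <= 0] = 0.0
    return cdf


def dunnett_test(
    control_reps: Sequence[float],
    treatment_reps: Mapping[str, Sequence[float]],
    n_nodes: tuple[int, int] = (64, 64),
) -> dict[str, float]:
    """Dunnett-adjusted two-sided p-values of each treatment vs the control.

    ``treatment_reps`` maps sample id to its replicate values; the control
    and every treatment need at least two replicates. Returns a mapping of
    sample id to adjusted p.

    Raises
    ------
    DegenerateVarianceError
        All replicates identical within every group (MSE = 0).
    InsufficientDataError
        A group with fewer than two replicates, or no treatment group.
    """
    ctrl = np.asarray(control_reps, dtype=float)
    if ctrl.size < 2:
        raise InsufficientDataError("control needs >= 2 replicates")
    if not treatment_reps:
        raise InsufficientDataError("no treatment groups")
    names = list(treatment_reps)
    groups = [np.asarray(treatment_reps[k], dtype=float) for k in names]
    for name, g in zip(names, groups):
        if g.size < 2:
            raise InsufficientDataError(f"group {name!r} needs >= 2 replicates")

    all_groups = [ctrl] + groups
    n_total = sum(g.size for g in all_groups)
    df = n_total - len(all_groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in all_groups)
    if ss_within == 0.0:
        raise DegenerateVarianceError("zero pooled within-group variance")
    mse = ss_within / df

    n0 = ctrl.size
    m0 = ctrl.mean()
    t_stats = np.array(
        [(g.mean() - m0) / np.sqrt(mse * (1.0 / g.size + 1.0 / n0)) for g in groups]
    )
    lambdas = np.array([np.sqrt(g.size / (g.size + n0)) for g in groups])
    cdf = max_abs_t_cdf(np.abs(t_stats), lambdas, df, n_nodes=n_nodes)
    p_adj = 1.0 - cdf
    return {name: float(p) for name, p in zip(names, p_adj)}


def call_hits(
    mean_pcts: Mapping[str, float],
    p_adj: Mapping[str, float],
    endpoint: str,
    alpha: float = DEFAULT_ALPHA,
) -> dict[str, HitCall]:
    """Combine normalized means and adjusted p-values into hit calls.

    Direction is "decrease" when p_adj < alpha and the mean is below the
    100% stress anchor, "increase" when above it, else "none". The
    >= 30%-reduction flag (mean <= 70%) is independent of significance
    but reported together.
    """
    calls: dict[str, HitCall] = {}
    for sid, mean in mean_pcts.items():
        p = float(p_adj[sid])
        if p < alpha and mean < 100.0:
            direction = "decrease"
        elif p < alpha and mean > 100.0:
            direction = "increase"
        else:
            direction = "none"
        calls[sid] = HitCall(
            sample_id=sid,
            endpoint=endpoint,
            mean_pct=float(mean),
            p_adj=p,
            direction=direction,
            reduction30=bool(mean <= REDUCTION30_THRESHOLD),
        )
    return calls


def classify_selectivity(
    sample_id: str,
    no_pct: float | None,
    ros_pct: float | None,
    no_call: HitCall | None,
    ros_call: HitCall | None,
    excluded_no: bool = False,
    excluded_ros: bool = False,
) -> SelectivityCall:
    """Assign one selectivity class per extract, in strict rule order.

    1. excluded — the viability gate removed an endpoint the rules need;
    2. dual — NO and ROS both below 60%;
    3. no_selective — significant NO decrease with ROS above 90%;
    4. ros_selective — significant ROS decrease with NO above 90%;
    5. unclassified.
    """
    if excluded_no or excluded_ros or no_pct is None or ros_pct is None:
        return SelectivityCall(sample_id, "excluded")
    if no_pct < DUAL_THRESHOLD and ros_pct < DUAL_THRESHOLD:
        return SelectivityCall(sample_id, "dual")
    if (
        no_call is not None
        and no_call.direction == "decrease"
        and ros_pct > SELECTIVE_THRESHOLD
    ):
        return SelectivityCall(sample_id, "no_selective")
    if (
        ros_call is not None
        and ros_call.direction == "decrease"
        and no_pct > SELECTIVE_THRESHOLD
    ):
        return SelectivityCall(sample_id, "ros_selective")
    return SelectivityCall(sample_id, "unclassified")


def spearman(
    x: Sequence[float], y: Sequence[float], pair: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Spearman rank correlation on pairwise-complete observations.

    Ties receive average (mid) ranks; the two-sided p-value comes from
    the t approximation t = r_s * sqrt((n-2)/(1-r_s^2)) on n-2 degrees of
    freedom. Perfect correlation reports p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = int(x.size)
    if n < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError("correlation undefined for constant vector")
    res = sps.spearmanr(x, y)
    return CorrelationResult(
        pair=pair, r_s=float(res.statistic), p_value=float(res.pvalue), n=n
    )
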