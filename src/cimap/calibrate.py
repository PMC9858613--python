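"""Calibration of joint distributions to mutual-information targets.

The synthetic-cohort generator needs conditional probability tables whose
induced pairwise mutual information (MI, in bits) matches published edge
strengths while the marginal prevalences match published cohort
frequencies. For a 2x2 joint with both margins fixed there is a single free
parameter (the (1,1) cell); plug-in MI is monotone in that parameter on the
positive-association side of independence, so each target is solved by
bracketed root-finding. Categorical edges (e.g. a 5-level means-of-self-harm
variable) are calibrated by exponentially tilting the child's base
distribution along a score matrix until the joint hits the MI target.
Two-parent binary nodes — forced by triangles in the published structure —
use a logistic link whose three coefficients are solved so the child's
marginal and both parent-child MI values are attained simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares
from scipy.special import expit, logit, rel_entr
from scipy.stats import norm

from .errors import CalibrationError, DomainError, InfeasibleTargetError

_LN2 = np.log(2.0)


def mutual_information_from_joint(joint) -> float:
    """Plug-in MI in bits of a joint probability array (any 2-D shape).

    Cells with zero probability contribute zero (0*log 0 == 0).
    """
    p = np.asarray(joint, dtype=float)
    if p.ndim != 2:
        raise DomainError("joint must be 2-dimensional")
    if p.min() < -1e-12:
        raise DomainError("joint probabilities must be non-negative")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise DomainError(f"joint must sum to 1, got {total}")
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    return float(rel_entr(p, px * py).sum() / _LN2)


@dataclass(frozen=True)
class PairwiseJoint:
    """Joint distribution of two binary variables (cells sum to 1)."""

    p11: float
    p10: float
    p01: float
    p00: float

    def __post_init__(self):
        cells = self.cells
        if cells.min() < -1e-12:
            raise DomainError("joint cells must be non-negative")
        if abs(cells.sum() - 1.0) > 1e-12:
            raise DomainError("joint cells must sum to 1")

    @property
    def cells(self) -> np.ndarray:
        """2x2 array indexed [x, y]."""
        return np.array([[self.p00, self.p01], [self.p10, self.p11]])

    @property
    def marginal_x(self) -> float:
        return self.p11 + self.p10

    @property
    def marginal_y(self) -> float:
        return self.p11 + self.p01

    @property
    def mi(self) -> float:
        return mutual_information_from_joint(self.cells)

    def conditional_child_given_parent(self) -> np.ndarray:
        """P(y | x) as a (2, 2) row-stochastic array indexed [x, y]."""
        px = self.marginal_x
        c1 = self.p11 / px if px > 0 else 0.5
        c0 = self.p01 / (1.0 - px) if px < 1 else 0.5
        return np.array([[1.0 - c0, c0], [1.0 - c1, c1]])


def _mi_2x2(p11: float, px: float, py: float) -> float:
    cells = np.array(
        [[1.0 - px - py + p11, py - p11], [px - p11, p11]]
    )
    cells = np.clip(cells, 0.0, 1.0)
    cells /= cells.sum()
    return mutual_information_from_joint(cells)


def max_mi_2x2(marginal_x: float, marginal_y: float) -> float:
    """Maximum MI attainable with fixed margins on the positive side."""
    return _mi_2x2(min(marginal_x, marginal_y), marginal_x, marginal_y)


def calibrate_pairwise_joint(
    target_mi: float, marginal_x: float, marginal_y: float
) -> PairwiseJoint:
    """Solve the 2x2 joint with given margins whose plug-in MI equals a target.

    The free cell p11 runs from independence (px*py, MI 0) up to
    min(px, py) where MI is maximal for positive association; MI is
    continuous and strictly increasing on that bracket, so Brent's method
    converges to far better than the 1e-6-bit contract.

    Raises
    ------
    InfeasibleTargetError
        If the target exceeds the margin-constrained maximum (message
        states the maximum).
    """
    if not (0.0 < marginal_x < 1.0 and 0.0 < marginal_y < 1.0):
        raise DomainError("marginals must lie strictly between 0 and 1")
    if target_mi < 0:
        raise DomainError("target MI must be non-negative")
    lo = marginal_x * marginal_y
    hi = min(marginal_x, marginal_y)
    mi_max = _mi_2x2(hi, marginal_x, marginal_y)
    if target_mi > mi_max + 1e-12:
        raise InfeasibleTargetError(
            f"target MI {target_mi} bits exceeds the maximum {mi_max:.6f} bits "
            f"attainable with marginals ({marginal_x}, {marginal_y})",
            maximum=mi_max,
        )
    if target_mi <= 1e-15:
        p11 = lo
    elif target_mi >= mi_max - 1e-12:
        p11 = hi
    else:
        p11 = brentq(
            lambda t: _mi_2x2(t, marginal_x, marginal_y) - target_mi,
            lo,
            hi,
            xtol=1e-16,
            rtol=8.9e-16,
        )
    return PairwiseJoint(
        p11=p11,
        p10=marginal_x - p11,
        p01=marginal_y - p11,
        p00=1.0 - marginal_x - marginal_y + p11,
    )


def calibrate_conditional_matrix(
    parent_marginal,
    child_base,
    score,
    target_mi: float,
    t_max: float = 64.0,
) -> np.ndarray:
    """Row-stochastic P(child | parent) hitting an MI target, categorical case.

    Rows are exponential tilts of the child's base distribution,
    ``p_t(y|x) ∝ base(y) * exp(t * score[x, y])``; t = 0 is independence and
    MI grows monotonically with t for a fixed score pattern. The tilt
    parameter is found by bracketed root-finding on the plug-in MI of the
    induced joint. The child's marginal may drift from ``child_base``;
    downstream calibrations should use the induced marginal.
    """
    pm = np.asarray(parent_marginal, dtype=float)
    base = np.asarray(child_base, dtype=float)
    sc = np.asarray(score, dtype=float)
    if sc.shape != (pm.size, base.size):
        raise DomainError("score matrix shape must be (parent levels, child levels)")
    if target_mi < 0:
        raise DomainError("target MI must be non-negative")

    def cond(t):
        w = base[None, :] * np.exp(t * sc)
        return w / w.sum(axis=1, keepdims=True)

    def mi(t):
        return mutual_information_from_joint(pm[:, None] * cond(t))

    if target_mi <= 1e-15:
        return cond(0.0)
    t_hi = 1.0
    while mi(t_hi) < target_mi and t_hi < t_max:
        t_hi *= 2.0
    if mi(t_hi) < target_mi:
        raise InfeasibleTargetError(
            f"target MI {target_mi} bits unreachable with this score pattern "
            f"(max {mi(t_hi):.6f} bits at tilt {t_hi})",
            maximum=mi(t_hi),
        )
    t = brentq(lambda u: mi(u) - target_mi, 0.0, t_hi, xtol=1e-13, rtol=8.9e-16)
    return cond(t)


def calibrate_two_parent_cpt(
    parent_joint,
    child_marginal: float,
    target_mi_a: float,
    target_mi_b: float,
) -> np.ndarray:
    """CPT of a binary child with two binary parents matching three targets.

    ``P(c=1 | a, b) = expit(alpha + beta_a*a + beta_b*b)``; the coefficients
    are solved (scipy least_squares) so the child marginal equals
    ``child_marginal`` and MI(child, a), MI(child, b) equal their targets,
    all computed against the supplied joint distribution of the parents.

    Returns an array of shape (2, 2, 2): axes (a, b, child level).
    """
    pj = np.asarray(parent_joint, dtype=float)
    if pj.shape != (2, 2) or abs(pj.sum() - 1.0) > 1e-9 or pj.min() < -1e-12:
        raise DomainError("parent_joint must be a 2x2 probability array")
    if not (0.0 < child_marginal < 1.0):
        raise DomainError("child marginal must lie strictly between 0 and 1")
    a_grid = np.array([[0.0, 0.0], [1.0, 1.0]])
    b_grid = np.array([[0.0, 1.0], [0.0, 1.0]])

    def child_prob(theta):
        a0, ba, bb = theta
        return expit(a0 + ba * a_grid + bb * b_grid)

    def residuals(theta):
        pc1 = child_prob(theta)
        marg = float((pj * pc1).sum())
        # joint of (parent a, child)
        pa_c1 = (pj * pc1).sum(axis=1)
        pa = pj.sum(axis=1)
        joint_a = np.stack([pa - pa_c1, pa_c1], axis=1)
        pb_c1 = (pj * pc1).sum(axis=0)
        pb = pj.sum(axis=0)
        joint_b = np.stack([pb - pb_c1, pb_c1], axis=1)
        return [
            marg - child_marginal,
            mutual_information_from_joint(joint_a) - target_mi_a,
            mutual_information_from_joint(joint_b) - target_mi_b,
        ]

    best = None
    for ba0, bb0 in [(1.0, 1.0), (2.0, 2.0), (0.5, 2.0), (2.0, 0.5), (3.0, 3.0)]:
        sol = least_squares(
            residuals,
            x0=[float(logit(child_marginal)), ba0, bb0],
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        err = float(np.max(np.abs(sol.fun)))
        if best is None or err < best[0]:
            best = (err, sol.x)
        if err < 1e-10:
            break
    err, theta = best
    if err > 1e-8:
        raise CalibrationError(
            f"two-parent CPT calibration residual {err:.2e} exceeds tolerance"
        )
    pc1 = child_prob(theta)
    return np.stack([1.0 - pc1, pc1], axis=-1)


def discretised_age_distribution(
    mean: float, sd: float, lo: int, hi: int
) -> tuple[np.ndarray, np.ndarray]:
    """Integer age distribution on [lo, hi] with a prescribed mean.

    Bins a normal density into unit-width integer bins truncated to the
    range, then root-finds the location parameter so the *discretised*
    distribution's mean equals ``mean`` exactly (truncation alone would bias
    the mean away from the nominal location). Returns (ages, probabilities).
    """
    ks = np.arange(lo, hi + 1)

    def pmf(mu):
        p = norm.cdf((ks + 0.5 - mu) / sd) - norm.cdf((ks - 0.5 - mu) / sd)
        return p / p.sum()

    def mean_err(mu):
        return float((pmf(mu) * ks).sum() - mean)

    if not (lo < mean < hi):
        raise DomainError("mean must lie inside the integer range")
    mu = brentq(mean_err, lo - 2.0, hi + 2.0, xtol=1e-12)
    return ks, pmf(mu)
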