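"""Fin-body coordination: robust lift~rotation slopes per speed bin.

Climbing fish couple trunk rotations (which redirect thrust) with fin
movements (which generate lift).  Coordination is summarized, within each
peak-speed bin, as the slope of a robust linear fit of lift [mm] against
upward rotation [deg]; only bouts with positive upward rotation and positive
lift qualify.  The fit is iteratively reweighted least squares with Tukey
bisquare weights (tuning constant 4.685, the conventional 95%-efficiency
value).  Slope and R^2 uncertainty come from a 100-draw bootstrap, and the
group comparison computes a p-value from the overlap of the two groups'
bootstrap slope distributions.  Speed dependence of the lift/rotation ratio
is tested with Spearman rank correlation, and correlations are compared
across groups via Fisher's z-transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator, RegressorMixin

from .kinematics import SPEED_BIN_NAMES

logger = logging.getLogger(__name__)

BISQUARE_C = 4.685
MAX_ITER = 50
CONV_TOL = 1e-8
N_BOOT = 100
MIN_BOUTS_PER_BIN = 10


class LiftRotationRegression(BaseEstimator, RegressorMixin):
    """Robust (Tukey bisquare) simple linear regression of lift on rotation.

    Parameters
    ----------
    c : float
        Bisquare tuning constant (4.685 gives 95% efficiency at the normal).
    max_iter, tol : IRLS iteration cap and coefficient-change convergence
        tolerance.
    weighted_r2 : bool
        If False (default) R^2 is the plain 1 - SSres/SStot on all points;
        if True, residuals and total variation are robust-weighted.

    Attributes
    ----------
    slope_, intercept_ : fitted coefficients (mm/deg, mm).
    r2_ : goodness of fit of the robust line.
    n_obs_ : number of fitted points.
    """

    def __init__(
        self,
        c: float = BISQUARE_C,
        max_iter: int = MAX_ITER,
        tol: float = CONV_TOL,
        weighted_r2: bool = False,
    ):
        self.c = c
        self.max_iter = max_iter
        self.tol = tol
        self.weighted_r2 = weighted_r2

    def fit(self, X, y) -> "LiftRotationRegression":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != 1:
            raise ValueError("exactly one predictor (upward rotation) is expected")
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        if X.shape[0] < 3:
            raise ValueError("need at least 3 points")
        if np.ptp(X) == 0.0:
            raise ValueError("degenerate design: all rotations identical")
        x = X[:, 0]
        design = sm.add_constant(x)
        ols = sm.OLS(y, design).fit()
        resid = y - ols.fittedvalues
        scale = max(np.max(np.abs(y)), 1.0)
        if np.max(np.abs(resid)) <= 1e-12 * scale:
            # exact line: IRLS scale estimate degenerates, OLS is already exact
            intercept, slope = ols.params
            weights = np.ones_like(y)
        else:
            rlm = sm.RLM(y, design, M=sm.robust.norms.TukeyBiweight(c=self.c))
            res = rlm.fit(maxiter=self.max_iter, tol=self.tol, conv="coefs")
            intercept, slope = res.params
            weights = np.asarray(res.weights, dtype=float)
        self.intercept_ = float(intercept)
        self.slope_ = float(slope)
        self.n_obs_ = int(y.size)
        self.n_features_in_ = 1
        fitted = self.intercept_ + self.slope_ * x
        if self.weighted_r2:
            w = weights
            ss_res = np.sum(w * (y - fitted) ** 2)
            ybar = np.average(y, weights=w)
            ss_tot = np.sum(w * (y - ybar) ** 2)
        else:
            ss_res = np.sum((y - fitted) ** 2)
            ss_tot = np.sum((y - np.mean(y)) ** 2)
        self.r2_ = float(1.0 - ss_res / ss_tot) if ss_tot > 0 else 1.0
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + self.slope_ * X[:, 0]


@dataclass
class SlopeFit:
    """Robust lift~rotation fit for one speed bin, with bootstrap draws."""

    speed_bin: str
    slope: float
    intercept: float
    r2: float
    n_bouts: int
    bootstrap_slopes: np.ndarray = field(default_factory=lambda: np.empty(0))
    bootstrap_r2: np.ndarray = field(default_factory=lambda: np.empty(0))

    def summary(self) -> dict:
        """Median and 25th/75th percentiles of the bootstrapped variables."""
        out = {
            "speed_bin": self.speed_bin,
            "slope": self.slope,
            "r2": self.r2,
            "n_bouts": self.n_bouts,
        }
        if self.bootstrap_slopes.size:
            q = np.percentile(self.bootstrap_slopes, [25, 50, 75])
            out.update(slope_boot_q25=q[0], slope_boot_median=q[1], slope_boot_q75=q[2])
            q = np.percentile(self.bootstrap_r2, [25, 50, 75])
            out.update(r2_boot_q25=q[0], r2_boot_median=q[1], r2_boot_q75=q[2])
        return out


def qualifying_mask(rotation: np.ndarray, lift: np.ndarray) -> np.ndarray:
    """Bouts entering the coordination fit: rotation > 0 and lift > 0."""
    return (np.asarray(rotation) > 0) & (np.asarray(lift) > 0)


def fit_lift_rotation(
    rotation: np.ndarray,
    lift: np.ndarray,
    speed_bin: str = "",
    min_n: int = MIN_BOUTS_PER_BIN,
    weighted_r2: bool = False,
) -> SlopeFit | None:
    """Fit the robust lift~rotation line for one speed bin.

    Inputs are pre-binned; non-qualifying bouts (rotation <= 0 or lift <= 0)
    are filtered here.  Returns None (bin absent, never extrapolated) when
    fewer than ``min_n`` qualifying bouts remain.
    """
    rotation = np.asarray(rotation, dtype=float)
    lift = np.asarray(lift, dtype=float)
    mask = qualifying_mask(rotation, lift)
    x, y = rotation[mask], lift[mask]
    if x.size < min_n:
        logger.info(
            "speed bin %s: %d qualifying bouts < floor %d; bin absent",
            speed_bin, x.size, min_n,
        )
        return None
    reg = LiftRotationRegression(weighted_r2=weighted_r2).fit(x, y)
    return SlopeFit(
        speed_bin=speed_bin,
        slope=reg.slope_,
        intercept=reg.intercept_,
        r2=reg.r2_,
        n_bouts=int(x.size),
    )


def bootstrap_fit(
    rotation: np.ndarray,
    lift: np.ndarray,
    n_boot: int = N_BOOT,
    seed: int = 0,
    max_retries: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap the slope and R^2 by resampling qualifying bouts.

    Draws ``n_boot`` resamples with replacement and refits.  A degenerate
    resample (all rotations identical) is redrawn, up to ``max_retries``
    times, and logged.
    """
    rotation = np.asarray(rotation, dtype=float)
    lift = np.asarray(lift, dtype=float)
    mask = qualifying_mask(rotation, lift)
    x, y = rotation[mask], lift[mask]
    if x.size < 3:
        raise ValueError("too few qualifying bouts to bootstrap")
    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    r2s = np.empty(n_boot)
    for b in range(n_boot):
        for attempt in range(max_retries + 1):
            idx = rng.integers(0, x.size, size=x.size)
            if np.ptp(x[idx]) > 0:
                break
            logger.warning("degenerate bootstrap resample; redrawing (%d)", attempt + 1)
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        reg = LiftRotationRegression().fit(x[idx], y[idx])
        slopes[b] = reg.slope_
        r2s[b] = reg.r2_
    return slopes, r2s


def fit_speed_bins(
    kin: pd.DataFrame,
    n_boot: int = N_BOOT,
    seed: int = 0,
    min_n: int = MIN_BOUTS_PER_BIN,
) -> dict[str, SlopeFit]:
    """Per-speed-bin robust fits with bootstrap, from a kinematics table."""
    fits: dict[str, SlopeFit] = {}
    for i, name in enumerate(SPEED_BIN_NAMES):
        sub = kin[kin["speed_bin"] == name]
        fit = fit_lift_rotation(
            sub["upward_rotation"].to_numpy(), sub["lift"].to_numpy(),
            speed_bin=name, min_n=min_n,
        )
        if fit is None:
            continue
        fit.bootstrap_slopes, fit.bootstrap_r2 = bootstrap_fit(
            sub["upward_rotation"].to_numpy(), sub["lift"].to_numpy(),
            n_boot=n_boot, seed=seed + i,
        )
        fits[name] = fit
    return fits


def slope_group_pvalue(
    boot_control: np.ndarray, boot_condition: np.ndarray
) -> float:
    """Two-sided p from the overlap of two bootstrap slope distributions.

    All pairwise differences between the two resampled distributions are
    formed; the one-sided tail is the (add-one corrected) fraction of pairs
    on the rarer side of zero, doubled and capped at 1.  Fully separated
    distributions therefore give the minimum attainable p for the number of
    draws rather than 0.
    """
    a = np.asarray(boot_control, dtype=float)
    b = np.asarray(boot_condition, dtype=float)
    diff = a[:, None] - b[None, :]
    n_pairs = diff.size
    n_le = int(np.sum(diff <= 0))
    n_ge = int(np.sum(diff >= 0))
    p = 2.0 * (min(n_le, n_ge) + 1) / (n_pairs + 1)
    return float(min(1.0, p))


@dataclass
class SpeedCorrelation:
    rho: float
    p: float
    n: int


def speed_ratio_correlation(kin: pd.DataFrame) -> SpeedCorrelation:
    """Spearman correlation of the lift/rotation ratio against peak speed.

    Only qualifying bouts (positive lift and rotation) enter; ties get
    average ranks (scipy's convention).
    """
    mask = qualifying_mask(
        kin["upward_rotation"].to_numpy(), kin["lift"].to_numpy()
    )
    sub = kin[mask]
    if len(sub) < 3:
        raise ValueError("need at least 3 qualifying bouts")
    ratio = sub["lift"].to_numpy() / sub["upward_rotation"].to_numpy()
    rho, p = sps.spearmanr(ratio, sub["peak_speed"].to_numpy())
    return SpeedCorrelation(rho=float(rho), p=float(p), n=int(len(sub)))


def compare_correlations(
    rho1: float, n1: int, rho2: float, n2: int
) -> tuple[float, float]:
    """Compare two correlation coefficients via Fisher's z-transform.

    z = (atanh(rho1) - atanh(rho2)) / sqrt(1/(n1-3) + 1/(n2-3)),
    with a two-sided normal p-value.
    """
    for rho, n in ((rho1, n1), (rho2, n2)):
        if abs(rho) >= 1.0:
            raise ValueError("|rho| must be < 1 for the Fisher z-transform")
        if n <= 3:
            raise ValueError("n must exceed 3")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(rho1) - np.arctanh(rho2)) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)
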