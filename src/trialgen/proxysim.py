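"""Confounding-proxy simulations: can adjusting for a PGS remove bias?

A PGS is at best an imperfect proxy of the confounder it predicts. These
simulations quantify the residual bias in the treatment-effect estimate when
the regression conditions on the PGS instead of the (unobserved) confounder
itself, under two structural models:

Model 1 — the PGS causes the confounder directly:

    PGS ~ N(0,1)
    C   = r·PGS + √(1−r²)·ε_C
    X   = b_CX·C + √(1−b_CX²)·ε_X
    Y   = X + b_CY·C

Model 2 — PGS and confounder share a common cause G*, and an extra component
G′ feeds the PGS (and possibly X, Y) but not the confounder:

    G*, G′ ~ N(0,1) independent
    PGS = b_G*PGS·G* + √(1−b²_G*PGS)·G′
    C   = b_G*C·G*  + √(1−b²_G*C)·ε_C,   b_G*C = r / b_G*PGS
    X   = b_G′X·G′ + b_CX·C + √(1−b²_G′X−b²_CX)·ε_X
    Y   = X + b_G′Y·G′ + b_CY·C

All noise terms are independent standard normal, so PGS, C and X each have
unit variance by construction and the true unconfounded effect of X on Y is
exactly 1. The observed effect is the coefficient of X in the ordinary
least-squares fit of Y on (X, PGS); bias is reported as a percentage of the
true effect, i.e. 100·(β̂_X − 1).

Because everything is jointly Gaussian, the expected OLS coefficients are a
closed-form function of the model covariance matrix; ``analytic_bias_model1``
and ``analytic_bias_model2`` provide that exact oracle for the Monte-Carlo
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import child_rng

__all__ = [
    "ProxyModel1Params",
    "ProxyModel2Params",
    "BiasResult",
    "b_cy_for_variance_fraction",
    "simulate_model1",
    "simulate_model2",
    "estimate_bias",
    "analytic_bias_model1",
    "analytic_bias_model2",
    "run_grid",
    "default_grid_model1",
]


def b_cy_for_variance_fraction(frac: float, b_cx: float) -> float:
    """Solve for b_CY so that Var(b_CY·C)/Var(Y) equals ``frac``.

    With Var(X)=Var(C)=1 and Y = X + b_CY·C,
    Var(Y) = 1 + b_CY² + 2·b_CY·Cov(X,C) and Cov(X,C) = b_CX, giving the
    quadratic (1−frac)·b_CY² − 2·frac·b_CX·b_CY − frac = 0 whose positive
    root is returned.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("variance fraction must be in (0, 1)")
    disc = frac * frac * b_cx * b_cx + frac * (1.0 - frac)
    return (frac * b_cx + np.sqrt(disc)) / (1.0 - frac)


@dataclass(frozen=True)
class ProxyModel1Params:
    """Parameters of the direct PGS→confounder proxy model (model 1)."""

    r: float
    b_cx: float
    b_cy: float
    n: int = 100_000
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r must lie in [-1, 1]")
        if self.b_cx**2 > 1.0:
            raise ValueError("b_cx² must not exceed 1 (Var(X)=1 is unachievable)")
        if self.n < 3 or self.iterations < 1:
            raise ValueError("n must be ≥ 3 and iterations ≥ 1")

    @classmethod
    def from_fractions(
        cls, r2: float, conf_frac: float, n: int = 100_000,
        iterations: int = 100, seed: int = 0,
    ) -> "ProxyModel1Params":
        """Parameterize by PGS–confounder r² and the confounding variance
        fraction b_CX²/Var(X) = Var(b_CY·C)/Var(Y) = ``conf_frac``."""
        b_cx = float(np.sqrt(conf_frac))
        return cls(
            r=float(np.sqrt(r2)),
            b_cx=b_cx,
            b_cy=b_cy_for_variance_fraction(conf_frac, b_cx),
            n=n, iterations=iterations, seed=seed,
        )


@dataclass(frozen=True)
class ProxyModel2Params:
    """Parameters of the shared-cause proxy model (model 2)."""

    b2_gstar_pgs: float = 0.8
    r2: float = 0.3
    conf_frac: float = 0.3
    b_gprime_x: float = -0.3
    b_gprime_y: float = 0.0
    n: int = 100_000
    iterations: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.b2_gstar_pgs <= 1.0:
            raise ValueError("b2_gstar_pgs must lie in (0, 1]")
        if self.r2 > self.b2_gstar_pgs:
            raise ValueError("r2 may not exceed b2_gstar_pgs (b_G*C would exceed 1)")
        if self.b_gprime_x**2 + self.conf_frac > 1.0:
            raise ValueError("b_gprime_x² + b_cx² must not exceed 1")

    @property
    def b_gstar_pgs(self) -> float:
        return float(np.sqrt(self.b2_gstar_pgs))

    @property
    def b_gstar_c(self) -> float:
        return float(np.sqrt(self.r2) / self.b_gstar_pgs)

    @property
    def b_cx(self) -> float:
        return float(np.sqrt(self.conf_frac))

    @property
    def b_cy(self) -> float:
        return b_cy_for_variance_fraction(self.conf_frac, self.b_cx)


def simulate_model1(params: ProxyModel1Params, iteration: int = 0) -> pd.DataFrame:
    """One draw of (PGS, C, X, Y) under model 1."""
    rng = child_rng(params.seed, "proxysim", "model1", iteration)
    n, r, bcx, bcy = params.n, params.r, params.b_cx, params.b_cy
    pgs = rng.standard_normal(n)
    c = r * pgs + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    x = bcx * c + np.sqrt(1.0 - bcx * bcx) * rng.standard_normal(n)
    y = x + bcy * c
    return pd.DataFrame({"pgs": pgs, "c": c, "x": x, "y": y})


def simulate_model2(params: ProxyModel2Params, iteration: int = 0) -> pd.DataFrame:
    """One draw of (G*, G′, PGS, C, X, Y) under model 2."""
    rng = child_rng(params.seed, "proxysim", "model2", iteration)
    n = params.n
    a, b = params.b_gstar_pgs, params.b_gstar_c
    bgx, bgy = params.b_gprime_x, params.b_gprime_y
    bcx, bcy = params.b_cx, params.b_cy
    gstar = rng.standard_normal(n)
    gprime = rng.standard_normal(n)
    pgs = a * gstar + np.sqrt(1.0 - a * a) * gprime
    c = b * gstar + np.sqrt(1.0 - b * b) * rng.standard_normal(n)
    x = bgx * gprime + bcx * c + np.sqrt(1.0 - bgx * bgx - bcx * bcx) * rng.standard_normal(n)
    y = x + bgy * gprime + bcy * c
    return pd.DataFrame({"gstar": gstar, "gprime": gprime, "pgs": pgs, "c": c, "x": x, "y": y})


def estimate_bias(dataset: pd.DataFrame) -> float:
    """Bias (%) of the X coefficient in OLS of Y on (X, PGS) with intercept."""
    x = dataset["x"].to_numpy()
    pgs = dataset["pgs"].to_numpy()
    y = dataset["y"].to_numpy()
    design = np.column_stack([np.ones_like(x), x, pgs])
    gram = design.T @ design
    if np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError("X and PGS are (near-)collinear; OLS is not identified")
    coef = np.linalg.solve(gram, design.T @ y)
    return 100.0 * (coef[1] - 1.0)


def _bias_from_covariance(cov: np.ndarray) -> float:
    """Expected bias (%) from the population covariance of (X, PGS, Y)."""
    gram = cov[:2, :2]
    if abs(np.linalg.det(gram)) < 1e-12:
        raise np.linalg.LinAlgError("degenerate moment matrix: X and PGS collinear")
    beta = np.linalg.solve(gram, cov[:2, 2])
    return 100.0 * (beta[0] - 1.0)


def analytic_bias_model1(r: float, b_cx: float, b_cy: float) -> float:
    """Closed-form expected bias (%) of lm(Y ~ X + PGS) under model 1.

    The population covariance of (X, PGS, Y) follows from the structural
    equations: Var(X)=Var(PGS)=1, Cov(X,PGS)=b_CX·r,
    Cov(X,Y)=1+b_CX·b_CY, Cov(PGS,Y)=r·(b_CX+b_CY).
    """
    var_y = 1.0 + b_cy * b_cy + 2.0 * b_cx * b_cy
    cov = np.array(
        [
            [1.0, b_cx * r, 1.0 + b_cx * b_cy],
            [b_cx * r, 1.0, r * (b_cx + b_cy)],
            [1.0 + b_cx * b_cy, r * (b_cx + b_cy), var_y],
        ]
    )
    return _bias_from_covariance(cov)


def analytic_bias_model2(params: ProxyModel2Params) -> float:
    """Closed-form expected bias (%) under model 2 (covariance algebra)."""
    a, b = params.b_gstar_pgs, params.b_gstar_c
    bgx, bgy = params.b_gprime_x, params.b_gprime_y
    bcx, bcy = params.b_cx, params.b_cy
    sq = np.sqrt(1.0 - a * a)
    # covariances with the independent sources (G*, G′) propagate linearly
    cov_pgs_c = a * b
    cov_x_pgs = bgx * sq + bcx * cov_pgs_c
    cov_x_c = bcx  # G′ ⫫ C
    var_y = 1.0 + bgy**2 + bcy**2 + 2.0 * (bgy * bgx + bcy * cov_x_c + bgy * bcy * 0.0)
    cov_x_y = 1.0 + bgy * bgx + bcy * cov_x_c
    cov_pgs_y = cov_x_pgs + bgy * sq + bcy * cov_pgs_c
    cov = np.array(
        [
            [1.0, cov_x_pgs, cov_x_y],
            [cov_x_pgs, 1.0, cov_pgs_y],
            [cov_x_y, cov_pgs_y, var_y],
        ]
    )
    return _bias_from_covariance(cov)


@dataclass(frozen=True)
class BiasResult:
    """Monte-Carlo bias summary for one simulation condition."""

    params: ProxyModel1Params | ProxyModel2Params
    mean_bias_pct: float
    tolerance_low: float
    tolerance_high: float
    analytic_bias_pct: float
    sd_bias_pct: float
    per_iteration: np.ndarray = field(repr=False, compare=False, default=None)

    @property
    def mc_se(self) -> float:
        return self.sd_bias_pct / np.sqrt(len(self.per_iteration))


def _run_condition(params: ProxyModel1Params | ProxyModel2Params) -> BiasResult:
    simulate = simulate_model1 if isinstance(params, ProxyModel1Params) else simulate_model2
    biases = np.array([estimate_bias(simulate(params, it)) for it in range(params.iterations)])
    mean = float(biases.mean())
    sd = float(biases.std(ddof=1)) if params.iterations > 1 else 0.0
    if isinstance(params, ProxyModel1Params):
        analytic = analytic_bias_model1(params.r, params.b_cx, params.b_cy)
    else:
        analytic = analytic_bias_model2(params)
    return BiasResult(
        params=params,
        mean_bias_pct=mean,
        tolerance_low=mean - 1.96 * sd,
        tolerance_high=mean + 1.96 * sd,
        analytic_bias_pct=analytic,
        sd_bias_pct=sd,
        per_iteration=biases,
    )


def default_grid_model1(
    r2_values: tuple[float, ...] = (0.01, 0.05, 0.1, 0.2, 0.3, 0.5),
    conf_fracs: tuple[float, ...] = (0.1, 0.2, 0.3, 0.5),
    n: int = 100_000,
    iterations: int = 100,
    seed: int = 0,
) -> list[ProxyModel1Params]:
    """The default model-1 condition grid: PGS–confounder r² crossed with the
    confounding variance fraction (0.1 small, 0.2 small-medium, 0.3
    medium-large, 0.5 large)."""
    return [
        ProxyModel1Params.from_fractions(r2, f, n=n, iterations=iterations, seed=seed)
        for f in conf_fracs
        for r2 in r2_values
    ]


def run_grid(
    conditions: list[ProxyModel1Params] | list[ProxyModel2Params],
) -> list[BiasResult]:
    """Monte-Carlo bias with ±1.96·sd tolerance interval per condition.

    Deterministic for a given seed: each condition's iterations draw from
    streams keyed by (seed, model, iteration).
    """
    if not conditions:
        raise ValueError("condition grid is empty")
    return [_run_condition(p) for p in conditions]


def grid_to_frame(results: list[BiasResult]) -> pd.DataFrame:
    """Flatten grid results to a table (one row per condition)."""
    rows = []
    for res in results:
        p = res.params
        row = {
            "model": 1 if isinstance(p, ProxyModel1Params) else 2,
            "n": p.n,
            "iterations": p.iterations,
            "mean_bias_pct": res.mean_bias_pct,
            "tolerance_low": res.tolerance_low,
            "tolerance_high": res.tolerance_high,
            "analytic_bias_pct": res.analytic_bias_pct,
            "mc_se": res.mc_se,
        }
        if isinstance(p, ProxyModel1Params):
            row.update(r=p.r, r2=p.r**2, b_cx=p.b_cx, b_cy=p.b_cy)
        else:
            row.update(
                b2_gstar_pgs=p.b2_gstar_pgs, r2=p.r2, conf_frac=p.conf_frac,
                b_gprime_x=p.b_gprime_x, b_gprime_y=p.b_gprime_y,
            )
        rows.append(row)
    return pd.DataFrame(rows)
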