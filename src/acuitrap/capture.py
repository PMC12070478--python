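"""Synthetic trap-capture experiments and count-model analysis.

Two experiment designs are simulated:

* **lab choice arena** — batches of insects released at the centre of a cage
  with one trap of each pattern size at a common distance; the trap whose
  design distance matches the release distance has a higher expected catch
  than the mismatched traps.  Counts are Poisson, thinned so a trial never
  catches more insects than were released (under-dispersed binomial
  sampling when ``dispersion < 1``).

* **polytunnel (no-choice)** — traps hung above the crop canopy; the
  expected catch follows a quadratic log-link response in the maximum
  horizontal range ``x`` over which the trap pattern is resolvable:
  ``log mu = b0 + b1*x + b2*x**2 + u_tunnel + u_row``, with
  negative-binomial noise, structural zeros and grouped random offsets.

Fitting uses log-link Poisson regression (IRLS via statsmodels) with a
quasi-likelihood dispersion correction (``Var = phi * mu``, phi estimated
by Pearson chi-square over residual degrees of freedom).  Nested models are
compared by deviance; quasi fits use the F approximation (deviance
difference / (df * phi) against F(df, df_resid)).  The quadratic-range
model absorbs tunnel and row grouping as jointly estimated fixed offsets —
a deliberate, self-contained simplification of a mixed model — and the
peak of the quadratic response, ``-b1 / (2*b2)``, is reported with a
parametric-bootstrap confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .geometry import TrapPlacement, visibility_table

__all__ = [
    "SimConfig",
    "CountModelFit",
    "LRTestResult",
    "PeakEstimate",
    "paper_lab_config",
    "paper_polytunnel_config",
    "paper_field_placements",
    "simulate_lab_choice",
    "simulate_polytunnel",
    "fit_count_model",
    "lr_test",
    "fit_quadratic_range_model",
    "peak_range",
    "write_dataset",
    "read_dataset",
]

DATASET_COLUMNS = [
    "design",
    "trial",
    "size_class",
    "distance_or_height_cm",
    "max_resolvable_range_cm",
    "tunnel_id",
    "row_id",
    "count",
]

#: Lab design: size class -> design (and release) distance in cm.
LAB_DISTANCES = {"small": 5.0, "medium": 10.0, "large": 20.0}
#: Polytunnel design: size class -> design distance (cm); traps are hung at
#: each of the three heights.
FIELD_DESIGN_DISTANCES = {"small": 15.0, "medium": 30.0, "large": 50.0}
FIELD_HEIGHTS = (15.0, 30.0, 50.0)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic capture experiments.

    ``dispersion`` is the variance-to-mean ratio phi: 1 gives Poisson
    counts, values below 1 under-dispersed binomial counts (lab), values
    above 1 negative-binomial counts (polytunnel).  The quadratic response
    is parameterised by its peak location and curvature:
    ``b2 = -curvature`` and ``b1 = 2 * curvature * peak_range_cm``, with
    ``b0 = log(baseline_mean)`` the log expected catch of an unresolvable
    trap.
    """

    n_thrips_per_trial: int = 50
    n_trials: int = 15
    mean_matched: float | Mapping[float, float] = 2.0
    mean_mismatched: float = 0.65
    allocation: str = "independent"  # or "multinomial"
    peak_range_cm: float = 26.0
    curvature: float = 0.0019231
    baseline_mean: float = 0.85
    dispersion: float = 1.0
    zero_inflation: float = 0.0
    random_effect_sd_tunnel: float = 0.0
    random_effect_sd_row: float = 0.0
    n_tunnels: int = 3
    n_rows_per_tunnel: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError(
                f"zero_inflation must lie in [0, 1], got {self.zero_inflation}"
            )
        for name in ("random_effect_sd_tunnel", "random_effect_sd_row"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.allocation not in ("independent", "multinomial"):
            raise ValueError(f"unknown allocation mode {self.allocation!r}")

    def matched_mean(self, distance_cm: float) -> float:
        if isinstance(self.mean_matched, Mapping):
            return float(self.mean_matched[distance_cm])
        return float(self.mean_matched)


def paper_lab_config() -> SimConfig:
    """Lab-arena conditions: ~50 insects per trial, 15 trials per distance,
    matched-cell mean catches near 2.0/1.7/2.1 at 5/10/20 cm and mismatched
    means near 0.65."""
    return SimConfig(
        n_thrips_per_trial=50,
        n_trials=15,
        mean_matched={5.0: 2.0, 10.0: 1.7, 20.0: 2.1},
        mean_mismatched=0.65,
        dispersion=1.0,
    )


def paper_polytunnel_config() -> SimConfig:
    """Polytunnel conditions: 3 tunnels x 4 rows of 9 traps, a quadratic
    log-link response peaking at a 26 cm resolvable range, moderate
    overdispersion, structural zeros and tunnel/row heterogeneity."""
    return SimConfig(
        peak_range_cm=26.0,
        curvature=0.0019231,
        baseline_mean=0.85,
        dispersion=2.0,
        zero_inflation=0.1,
        random_effect_sd_tunnel=0.2,
        random_effect_sd_row=0.15,
        n_tunnels=3,
        n_rows_per_tunnel=4,
    )


def paper_field_placements(vs=None) -> pd.DataFrame:
    """The nine size x height placements of the polytunnel design, with the
    maximum horizontal range over which each pattern is resolvable
    (0 when resolvable only from directly below, or not at all)."""
    from .acuity import WFT

    vs = vs or WFT
    rows = []
    for size_class, d_design in FIELD_DESIGN_DISTANCES.items():
        for height in FIELD_HEIGHTS:
            placement = TrapPlacement(
                height_above_canopy_cm=height,
                element_resolvable_distance_cm=d_design,
            )
            tbl = visibility_table([placement]).iloc[0]
            x = tbl["horizontal_range_cm"]
            rows.append(
                {
                    "size_class": size_class,
                    "distance_or_height_cm": height,
                    "max_resolvable_range_cm": 0.0 if math.isnan(x) else float(x),
                }
            )
    return pd.DataFrame(rows)


def _draw_counts(rng: np.random.Generator, means: np.ndarray, phi: float) -> np.ndarray:
    """Counts with variance ``phi * mean`` (phi <= 1; phi == 1 is Poisson)."""
    if phi >= 1.0:
        return rng.poisson(means)
    out = np.empty(means.shape, dtype=np.int64)
    for i, mu in np.ndenumerate(means):
        if mu <= 0:
            out[i] = 0
            continue
        n = max(1, math.ceil(mu / (1.0 - phi)))
        out[i] = rng.binomial(n, mu / n)
    return out


def simulate_lab_choice(cfg: SimConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate the choice-arena experiment.

    For every release distance and trial, one trap of each size class is
    present; the trap whose design distance equals the release distance has
    expectation ``mean_matched`` and the other two ``mean_mismatched``.
    Per-trial totals never exceed the released pool (hypergeometric
    thinning of the joint draw).  Deterministic for a given seed: each
    trial consumes its own child stream of the seed sequence.
    """
    seed = cfg.seed if seed is None else seed
    sizes = list(LAB_DISTANCES)
    distances = sorted(set(LAB_DISTANCES.values()))
    max_matched = max(cfg.matched_mean(d) for d in distances)
    if (
        cfg.n_thrips_per_trial > 0
        and cfg.allocation == "independent"
        and 3 * max_matched > cfg.n_thrips_per_trial
    ):
        raise ValueError(
            "expected catch exceeds the released pool: "
            f"3 x {max_matched} > {cfg.n_thrips_per_trial}"
        )
    streams = np.random.SeedSequence(seed).spawn(len(distances) * cfg.n_trials)
    records = []
    k = 0
    for d in distances:
        for trial in range(1, cfg.n_trials + 1):
            rng = np.random.default_rng(streams[k])
            k += 1
            means = np.array(
                [
                    cfg.matched_mean(d)
                    if LAB_DISTANCES[s] == d
                    else cfg.mean_mismatched
                    for s in sizes
                ]
            )
            if cfg.n_thrips_per_trial == 0:
                counts = np.zeros(3, dtype=np.int64)
            elif cfg.allocation == "multinomial":
                p = means / cfg.n_thrips_per_trial
                probs = np.append(p, 1.0 - p.sum())
                counts = rng.multinomial(cfg.n_thrips_per_trial, probs)[:3]
            else:
                counts = _draw_counts(rng, means, min(cfg.dispersion, 1.0))
                total = int(counts.sum())
                if total > cfg.n_thrips_per_trial:
                    counts = rng.multivariate_hypergeometric(
                        counts, cfg.n_thrips_per_trial
                    )
            for s, c in zip(sizes, counts):
                records.append(
                    {
                        "design": "lab_choice",
                        "trial": trial,
                        "size_class": s,
                        "distance_or_height_cm": d,
                        "max_resolvable_range_cm": np.nan,
                        "tunnel_id": "",
                        "row_id": "",
                        "count": int(c),
                    }
                )
    return pd.DataFrame(records, columns=DATASET_COLUMNS)


def simulate_polytunnel(
    cfg: SimConfig,
    placements: pd.DataFrame | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the polytunnel experiment over a placement table.

    ``placements`` needs columns ``size_class``, ``distance_or_height_cm``
    and ``max_resolvable_range_cm``; the nine-trap published layout is the
    default.  Each tunnel/row combination receives one replicate of every
    placement.  Counts are negative-binomial around the quadratic log-link
    response with tunnel and row log-normal offsets and structural zeros.
    """
    seed = cfg.seed if seed is None else seed
    if cfg.curvature <= 0:
        raise ValueError(
            "curvature must be > 0 for an interior peak of the quadratic response"
        )
    if placements is None:
        placements = paper_field_placements()
    b2 = -cfg.curvature
    b1 = 2.0 * cfg.curvature * cfg.peak_range_cm
    b0 = math.log(cfg.baseline_mean)

    root = np.random.SeedSequence(seed)
    re_rng = np.random.default_rng(root.spawn(1)[0])
    u_tunnel = re_rng.normal(0.0, cfg.random_effect_sd_tunnel, cfg.n_tunnels)
    u_row = re_rng.normal(
        0.0, cfg.random_effect_sd_row, (cfg.n_tunnels, cfg.n_rows_per_tunnel)
    )
    n_groups = cfg.n_tunnels * cfg.n_rows_per_tunnel
    streams = root.spawn(n_groups)

    records = []
    g = 0
    for t in range(cfg.n_tunnels):
        for r in range(cfg.n_rows_per_tunnel):
            rng = np.random.default_rng(streams[g])
            g += 1
            for _, p in placements.iterrows():
                x = float(p["max_resolvable_range_cm"])
                mu = math.exp(b0 + b1 * x + b2 * x * x + u_tunnel[t] + u_row[t, r])
                phi = cfg.dispersion
                if phi > 1.0:
                    # gamma-Poisson mixture with Var = phi * mu
                    lam = rng.gamma(mu / (phi - 1.0), phi - 1.0)
                    count = int(rng.poisson(lam))
                else:
                    count = int(rng.poisson(mu))
                if cfg.zero_inflation > 0 and rng.random() < cfg.zero_inflation:
                    count = 0
                records.append(
                    {
                        "design": "polytunnel",
                        "trial": r + 1,
                        "size_class": p["size_class"],
                        "distance_or_height_cm": float(p["distance_or_height_cm"]),
                        "max_resolvable_range_cm": x,
                        "tunnel_id": f"T{t + 1}",
                        "row_id": f"R{r + 1}",
                        "count": count,
                    }
                )
    return pd.DataFrame(records, columns=DATASET_COLUMNS)


@dataclass
class CountModelFit:
    """A fitted log-link count regression with quasi dispersion."""

    params: pd.Series
    cov: pd.DataFrame
    dispersion_phi: float
    loglik: float
    deviance: float
    df_resid: int
    nobs: int
    converged: bool
    quasi: bool
    formula: str

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def summary_frame(self) -> pd.DataFrame:
        se = self.bse
        z = self.params / se
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": se,
                "z": z,
                "p": 2.0 * st.norm.sf(np.abs(z)),
            }
        )


def _check_cells(data: pd.DataFrame, terms: str) -> None:
    # an interaction of the two design factors with an empty cell is not
    # estimable; fail with the offending cell named
    if "*" in terms and "size_class" in terms and "distance_or_height_cm" in terms:
        tab = pd.crosstab(data["size_class"], data["distance_or_height_cm"])
        empties = [
            (i, j) for i in tab.index for j in tab.columns if tab.loc[i, j] == 0
        ]
        if empties:
            raise ValueError(f"empty design cells: {empties}")


def fit_count_model(
    data: pd.DataFrame, terms: str = "C(size_class) * C(distance_or_height_cm)",
    quasi: bool = True,
) -> CountModelFit:
    """Fit a log-link Poisson regression of ``count`` on ``terms``.

    Fitting is by IRLS.  With ``quasi`` (default), the dispersion phi is
    estimated as Pearson chi-square over residual degrees of freedom and
    the coefficient covariance (hence standard errors) is scaled by phi —
    the ``Var = phi * mu`` quasi-likelihood correction, valid for both
    under- and over-dispersed counts.  Non-convergence is flagged on the
    returned fit, not raised.
    """
    if len(data) == 0:
        raise ValueError("no observations")
    _check_cells(data, terms)
    formula = f"count ~ {terms}"
    model = smf.glm(formula, data=data, family=sm.families.Poisson())
    exog = model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("design matrix is rank deficient (empty or aliased cells)")
    res = model.fit(maxiter=100, tol=1e-8)
    df_resid = int(res.df_resid)
    phi = float(res.pearson_chi2 / df_resid) if df_resid > 0 else float("nan")
    cov = pd.DataFrame(
        np.asarray(res.cov_params()), index=res.params.index, columns=res.params.index
    )
    if quasi and df_resid > 0:
        cov = cov * phi
    return CountModelFit(
        params=res.params,
        cov=cov,
        dispersion_phi=phi,
        loglik=float(res.llf),
        deviance=float(res.deviance),
        df_resid=df_resid,
        nobs=int(res.nobs),
        converged=bool(getattr(res, "converged", True)),
        quasi=quasi,
        formula=formula,
    )


@dataclass(frozen=True)
class LRTestResult:
    statistic: float
    df: int
    pvalue: float
    method: str


def lr_test(fit_full: CountModelFit, fit_reduced: CountModelFit) -> LRTestResult:
    """Compare nested count models.

    For plain Poisson fits the deviance difference (twice the log-likelihood
    ratio) is referred to chi-square.  For quasi fits the scaled statistic
    ``(delta deviance / delta df) / phi_full`` is referred to
    F(delta df, df_resid_full) — the standard quasi-likelihood
    F approximation.
    """
    if fit_full.nobs != fit_reduced.nobs:
        raise ValueError("models were fitted to different data")
    if not set(fit_reduced.params.index) <= set(fit_full.params.index):
        raise ValueError("models are not nested")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("the first argument must be the full model")
    delta = fit_reduced.deviance - fit_full.deviance
    if df == 0:
        return LRTestResult(0.0, 0, 1.0, "identical")
    if fit_full.quasi:
        fstat = (delta / df) / fit_full.dispersion_phi
        p = float(st.f.sf(fstat, df, fit_full.df_resid))
        return LRTestResult(float(fstat), df, p, "quasi-F")
    p = float(st.chi2.sf(delta, df))
    return LRTestResult(float(delta), df, p, "chi2")


QUADRATIC_TERMS = (
    "max_resolvable_range_cm + I(max_resolvable_range_cm ** 2)"
    " + C(tunnel_id) + C(tunnel_id):C(row_id)"
)


def fit_quadratic_range_model(
    data: pd.DataFrame, group_offsets: bool = True, quasi: bool = True
) -> CountModelFit:
    """Log-link count regression on the maximum resolvable range and its
    square, with tunnel and row-within-tunnel fixed offsets."""
    x = data["max_resolvable_range_cm"]
    if x.nunique() < 3:
        raise ValueError(
            f"need >= 3 distinct resolvable-range values, got {x.nunique()}"
        )
    terms = QUADRATIC_TERMS if group_offsets else (
        "max_resolvable_range_cm + I(max_resolvable_range_cm ** 2)"
    )
    return fit_count_model(data, terms, quasi=quasi)


@dataclass(frozen=True)
class PeakEstimate:
    peak_cm: float
    ci_low_cm: float
    ci_high_cm: float
    level: float
    n_boot: int
    n_valid: int


_X1 = "max_resolvable_range_cm"
_X2 = "I(max_resolvable_range_cm ** 2)"


def peak_range(
    fit: CountModelFit,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
) -> PeakEstimate:
    """Location of the quadratic response's maximum, ``-b1 / (2*b2)``, with
    a parametric-bootstrap percentile CI drawn from the (quasi-scaled)
    coefficient covariance.  Draws without a concave quadratic are dropped
    (their count is reported)."""
    names = list(fit.params.index)
    try:
        i1, i2 = names.index(_X1), names.index(_X2)
    except ValueError as exc:
        raise ValueError(
            "fit does not contain linear and quadratic range terms"
        ) from exc
    b1, b2 = float(fit.params.iloc[i1]), float(fit.params.iloc[i2])
    if b2 >= 0:
        raise ValueError("no interior maximum: quadratic coefficient is >= 0")
    peak = -b1 / (2.0 * b2)
    cov = fit.cov.to_numpy()[np.ix_([i1, i2], [i1, i2])]
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal([b1, b2], cov, size=n_boot)
    valid = draws[:, 1] < 0
    peaks = -draws[valid, 0] / (2.0 * draws[valid, 1])
    if peaks.size < 2:
        raise ValueError("bootstrap produced no concave draws")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(peaks, [alpha, 1.0 - alpha])
    return PeakEstimate(
        peak_cm=peak,
        ci_low_cm=float(lo),
        ci_high_cm=float(hi),
        level=level,
        n_boot=n_boot,
        n_valid=int(valid.sum()),
    )


def write_dataset(data: pd.DataFrame, path: str | Path) -> None:
    """Write a capture dataset as tidy CSV with a fixed column order."""
    data.loc[:, DATASET_COLUMNS].to_csv(path, index=False)


def read_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    for col in ("tunnel_id", "row_id"):
        df[col] = df[col].fillna("")
    return df
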