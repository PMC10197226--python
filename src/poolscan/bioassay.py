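"""Probit dose-mortality analysis: binomial GLM with a probit link on log10
dose, lethal-dose estimation by the delta method, strain comparison, and
resistance ratios (higher LD95 over lower LD95)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

log = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """Complete separation: mortality jumps 0 -> 1 between doses; the fit is
    unbounded.  Revise the dose range."""


@dataclass
class ProbitFit:
    strain: str
    intercept: float
    slope: float
    cov: np.ndarray  # covariance of (intercept, slope)
    deviance: float
    n_doses: int
    control_mortality: float = 0.0

    @property
    def valid(self) -> bool:
        return self.slope > 0


@dataclass
class LdEstimate:
    level: float
    ld: float  # dose units (ng per insect)
    se_log10: float  # standard error of log10 LD (delta method)

    @property
    def ci95(self) -> tuple[float, float]:
        lo = np.log10(self.ld) - 1.959963984540054 * self.se_log10
        hi = np.log10(self.ld) + 1.959963984540054 * self.se_log10
        return 10**lo, 10**hi


def fit_probit(table: pd.DataFrame, strain: str) -> ProbitFit:
    """Maximum-likelihood probit fit of mortality on log10 dose.

    Control (dose 0) mortality, when present and non-zero, is applied as
    Abbott's correction to the treated proportions before fitting.
    """
    sub = table[table["strain"] == strain]
    ctrl = sub[sub["dose"] == 0]
    trt = sub[sub["dose"] > 0].copy()
    doses = trt["dose"].unique()
    if len(doses) < 3:
        raise ValueError(f"strain {strain}: need >= 3 non-control doses")
    c = float(ctrl["n_dead"].sum() / ctrl["n_exposed"].sum()) if len(ctrl) else 0.0
    p_obs = trt["n_dead"] / trt["n_exposed"]
    if c > 0:
        p_obs = np.clip((p_obs - c) / (1.0 - c), 0.0, 1.0)

    by_dose = trt.assign(p=p_obs).groupby("dose")["p"].mean()
    if (by_dose.min() >= 1.0) or (by_dose.max() <= 0.0):
        raise SeparationError(
            f"strain {strain}: all-dead or all-alive at every dose; "
            "revise the dose range")
    x = np.log10(trt["dose"].to_numpy(dtype=float))
    X = sm.add_constant(x)
    model = sm.GLM(p_obs.to_numpy(), X, family=sm.families.Binomial(
        sm.families.links.Probit()), freq_weights=trt["n_exposed"].to_numpy())
    try:
        res = model.fit(tol=1e-9)
    except Exception as exc:  # perfect separation raises inside IRLS
        raise SeparationError(f"strain {strain}: {exc}") from exc
    a, b = res.params
    fit = ProbitFit(strain, float(a), float(b), np.asarray(res.cov_params()),
                    float(res.deviance), len(doses), c)
    if not fit.valid:
        log.warning("strain %s: non-positive probit slope %.3f, fit invalid",
                    strain, fit.slope)
    return fit


def ld(fit: ProbitFit, p: float = 0.95) -> LdEstimate:
    """Lethal dose for a mortality level p: log10 LD_p = (z_p - a)/b with a
    delta-method standard error from the (a, b) covariance."""
    if not fit.valid:
        raise ValueError(f"strain {fit.strain}: invalid fit (slope <= 0)")
    z = stats.norm.ppf(p)
    log_ld = (z - fit.intercept) / fit.slope
    grad = np.array([-1.0 / fit.slope, -(z - fit.intercept) / fit.slope**2])
    se = float(np.sqrt(grad @ fit.cov @ grad))
    return LdEstimate(p, float(10**log_ld), se)


def ld_ratio_test(fit_a: ProbitFit, fit_b: ProbitFit, p: float = 0.95
                  ) -> tuple[float, float]:
    """z-test on the difference of log10 lethal doses; two-sided normal p."""
    la, lb = ld(fit_a, p), ld(fit_b, p)
    se = np.sqrt(la.se_log10**2 + lb.se_log10**2)
    if se == 0:
        return 0.0, 1.0
    z = (np.log10(la.ld) - np.log10(lb.ld)) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "*"
    return ""


def resistance_ratio(ld_a: float, ld_b: float) -> tuple[float, int]:
    """Higher lethal dose over lower; returned raw and rounded to the nearest
    integer (the conventional 'x-fold resistance')."""
    if ld_a <= 0 or ld_b <= 0:
        raise ValueError("lethal doses must be positive")
    raw = max(ld_a, ld_b) / min(ld_a, ld_b)
    return raw, int(round(raw))


def strain_comparison_table(table: pd.DataFrame, p: float = 0.95) -> pd.DataFrame:
    """Pairwise LD comparison across strains: ratio test, stars, RR."""
    strains = list(table.loc[table["dose"] > 0, "strain"].unique())
    fits = {s: fit_probit(table, s) for s in strains}
    lds = {s: ld(fits[s], p) for s in strains}
    rows = []
    for i, a in enumerate(strains):
        for b in strains[i + 1:]:
            z, pv = ld_ratio_test(fits[a], fits[b], p)
            rr_raw, rr = resistance_ratio(lds[a].ld, lds[b].ld)
            rows.append({"strain_a": a, "strain_b": b,
                         "ld_a": lds[a].ld, "ld_b": lds[b].ld,
                         "se_log10_a": lds[a].se_log10, "se_log10_b": lds[b].se_log10,
                         "z": z, "p_value": pv, "stars": significance_stars(pv),
                         "resistance_ratio": rr_raw, "resistance_ratio_rounded": rr})
    return pd.DataFrame(rows)
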