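"""Synthetic VTG cohorts and packaged measured data.

The evaluations all start from a table of per-fish plasma VTG
concentrations.  This module provides

* :func:`load_fixture` — the packaged measured plasma VTG table from a
  21-day ketoconazole reproduction study (5 treatments x 4 replicate tanks
  of up to 4 females; 74 fish with measurements, a few cells missing);
* :func:`generate_cohort` — synthetic cohorts with the same structure:
  control fish drawn from a lognormal tuned by maximum likelihood to the
  fixture's control column (mean ~0.086 nmol uL^-1, observed span roughly
  0.02-0.21), and exposed treatments modelled as a multiplicative
  depression of the control distribution, mimicking how steroidogenesis
  inhibitors suppress VTG production;
* :func:`fit_truncated_lognormal` — ML recovery of truncated-lognormal
  parameters, used by the parameter-recovery test suite.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "TreatmentSpec",
    "generate_cohort",
    "load_fixture",
    "control_vtg_lognormal",
    "fit_truncated_lognormal",
]

_FIXTURES = {"ketoconazole_table2": "ketoconazole_table2.csv"}


@functools.lru_cache(maxsize=None)
def _fixture_frame(filename: str) -> pd.DataFrame:
    with resources.files("ogdm.data").joinpath(filename).open() as handle:
        return pd.read_csv(handle)


def load_fixture(name: str) -> pd.DataFrame:
    """Packaged measured-VTG table in the standard input-table layout.

    Columns: ``fish_id``, ``group_id``, ``treatment``, ``c_vtg_exposure``.
    Group ids encode the replicate tank (e.g. ``ktc6_r2``); treatments are
    the nominal water concentrations in ug L^-1 as strings.
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}")
    raw = _fixture_frame(_FIXTURES[name])
    table = pd.DataFrame(
        {
            "fish_id": [
                f"ktc{t}_r{r}_f{f}"
                for t, r, f in zip(raw.treatment_ug_per_L, raw.replicate, raw.fish)
            ],
            "group_id": [f"ktc{t}_r{r}" for t, r in zip(raw.treatment_ug_per_L, raw.replicate)],
            "treatment": raw.treatment_ug_per_L.astype(str),
            "c_vtg_exposure": raw.c_vtg_nmol_per_uL.astype(float),
        }
    )
    return table


def control_vtg_lognormal(fixture: str = "ketoconazole_table2") -> tuple[float, float]:
    """(mu, sigma) of a lognormal ML-fitted to the fixture's control column."""
    table = load_fixture(fixture)
    log_values = np.log(table.loc[table.treatment == "0", "c_vtg_exposure"].to_numpy())
    return float(log_values.mean()), float(log_values.std(ddof=0))


@dataclass(frozen=True)
class TreatmentSpec:
    """One treatment arm: either explicit lognormal VTG parameters or a
    multiplicative depression of the control distribution."""

    label: str
    depression: float = 1.0  # multiplies control draws; 0 = complete suppression
    mu: float | None = None  # explicit log-scale location, overrides depression
    sigma: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.depression <= 1.0:
            raise ValueError(f"{self.label}: depression factor must be in [0, 1]")
        if (self.mu is None) != (self.sigma is None):
            raise ValueError(f"{self.label}: give both mu and sigma or neither")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError(f"{self.label}: sigma must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Structure of a synthetic study: groups of females per treatment arm."""

    n_groups: int = 3
    females_per_group: int = 4
    treatments: tuple[TreatmentSpec, ...] = (TreatmentSpec("control"),)
    control_mu: float | None = None  # default: fitted to the packaged control data
    control_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.females_per_group < 1:
            raise ValueError("n_groups and females_per_group must be >= 1")
        if not self.treatments:
            raise ValueError("at least one treatment arm required")


def generate_cohort(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw a synthetic per-fish VTG input table with the given structure.

    Control concentrations are lognormal with parameters fitted to the
    packaged measured control data; a treatment with ``depression = d``
    scales each control draw by ``d`` (VTG suppression acts
    multiplicatively on plasma concentration).  Explicit (mu, sigma) on a
    treatment replace the scaled control distribution.
    """
    mu0, sigma0 = spec.control_mu, spec.control_sigma
    if mu0 is None or sigma0 is None:
        fitted_mu, fitted_sigma = control_vtg_lognormal()
        mu0 = fitted_mu if mu0 is None else mu0
        sigma0 = fitted_sigma if sigma0 is None else sigma0
    rows = []
    for treatment in spec.treatments:
        for g in range(1, spec.n_groups + 1):
            for f in range(1, spec.females_per_group + 1):
                if treatment.mu is not None:
                    c = float(rng.lognormal(treatment.mu, treatment.sigma))
                else:
                    c = treatment.depression * float(rng.lognormal(mu0, sigma0))
                rows.append(
                    {
                        "fish_id": f"{treatment.label}_g{g}_f{f}",
                        "group_id": f"{treatment.label}_g{g}",
                        "treatment": treatment.label,
                        "c_vtg_exposure": c,
                    }
                )
    return pd.DataFrame(rows)


def fit_truncated_lognormal(
    samples,
    bounds: tuple[float, float],
) -> tuple[float, float]:
    """Maximum-likelihood (mu, sigma) of a lognormal truncated to ``bounds``.

    The log-likelihood is the untruncated lognormal term minus
    ``n * log(F(upper) - F(lower))``; maximised numerically from the
    untruncated ML estimate.  Requires at least 30 in-bounds samples and
    rejects degenerate (zero-spread) data.
    """
    from scipy.optimize import minimize
    from scipy.stats import norm

    x = np.asarray(samples, dtype=float)
    lower, upper = bounds
    if not 0 < lower < upper:
        raise ValueError("bounds must satisfy 0 < lower < upper")
    if x.size < 30:
        raise ValueError(f"need at least 30 samples, got {x.size}")
    if np.any((x < lower) | (x > upper)):
        raise ValueError("samples outside the truncation bounds")
    logx = np.log(x)
    if logx.std() < 1e-12:
        raise ValueError("degenerate sample: zero spread on the log scale")

    log_lo, log_hi = math.log(lower), math.log(upper)

    def negative_log_likelihood(theta):
        mu, log_sigma = theta
        sigma = math.exp(log_sigma)
        z = (logx - mu) / sigma
        ll = -logx.size * math.log(sigma) - 0.5 * np.sum(z**2)
        mass = norm.cdf((log_hi - mu) / sigma) - norm.cdf((log_lo - mu) / sigma)
        if mass <= 0:
            return np.inf
        return -(ll - logx.size * math.log(mass))

    start = np.array([logx.mean(), math.log(logx.std())])
    res = minimize(negative_log_likelihood, start, method="Nelder-Mead")
    mu_hat, log_sigma_hat = res.x
    return float(mu_hat), float(math.exp(log_sigma_hat))
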