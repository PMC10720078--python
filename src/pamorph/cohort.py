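"""Synthetic two-group patient cohorts for pulmonary hypertension statistics.

Generates patient tables with the structure of a CTPA + right-heart-
catheterization study: per-patient pressures (mPAP, SPAP, DPAP in mmHg), the
nine CTPA measurements (D/A/V for MPA, RPA, LPA), a PH label defined by the
hemodynamic rule mPAP > 20 mmHg (strict), and optional categorical findings.

Sampling model
--------------
* Patients are drawn from two arms sized like the study groups (18 non-PH,
  41 PH by default).  Pressures printed as median (IQR) are modelled as
  lognormal matched to median and IQR (those variables were non-normally
  distributed); pressures printed as mean +- SD as normal truncated at zero.
* SPAP and DPAP are drawn jointly with mPAP through a Gaussian copula, and
  draws violating SPAP >= mPAP >= DPAP are conditionally resampled (mPAP is
  never touched, so its marginal is exact).  Note the published PH-group
  summaries (mPAP median 26 vs DPAP mean 27.85) are mutually inconsistent
  with that ordering, so the enforced constraint necessarily biases the
  PH-arm DPAP downward; the measurement linkage runs off mPAP and is
  unaffected.
* Each measurement is linear in mPAP within its arm,
  ``m = alpha_g + beta_g * mPAP + eps``, with the within-arm link strength
  solved so that (a) per-arm means and SDs equal the configured group values
  exactly in expectation and (b) the whole-cohort Pearson correlation with
  mPAP equals the configured target.
* The PH label is then re-derived from the strict mPAP > 20 rule, so a few
  patients cross arms; the sampling arm is kept in an ``arm`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps


class CohortConfigError(ValueError):
    pass


PH_THRESHOLD_MMHG = 20.0  # strict: PH iff mPAP > 20

MEASUREMENT_COLUMNS = (
    "D_MPA",
    "A_MPA",
    "V_MPA",
    "D_RPA",
    "A_RPA",
    "V_RPA",
    "D_LPA",
    "A_LPA",
    "V_LPA",
)
SCHEMA_COLUMNS = ("mPAP", "SPAP", "DPAP") + MEASUREMENT_COLUMNS + ("group",)

_Z75 = sps.norm.ppf(0.75)  # 0.6745: quartile z-score used for IQR -> SD


@dataclass(frozen=True)
class PressureSpec:
    """Marginal distribution of one pressure in one arm.

    ``kind='lognormal'`` is parameterized by median and quartiles;
    ``kind='normal'`` by mean and SD, truncated at zero.
    """

    kind: str
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    mean: float | None = None
    sd: float | None = None

    def _lognorm_params(self) -> tuple[float, float]:
        mu = np.log(self.median)
        sigma = (np.log(self.q3) - np.log(self.q1)) / (2.0 * _Z75)
        return mu, sigma

    def ppf(self, u: np.ndarray) -> np.ndarray:
        if self.kind == "lognormal":
            mu, sigma = self._lognorm_params()
            return np.exp(mu + sigma * sps.norm.ppf(u))
        a = (0.0 - self.mean) / self.sd
        return sps.truncnorm.ppf(u, a, np.inf, loc=self.mean, scale=self.sd)

    def moments(self) -> tuple[float, float]:
        """Exact (mean, sd) of the marginal."""
        if self.kind == "lognormal":
            mu, sigma = self._lognorm_params()
            m = float(np.exp(mu + sigma**2 / 2.0))
            s = float(m * np.sqrt(np.exp(sigma**2) - 1.0))
            return m, s
        a = (0.0 - self.mean) / self.sd
        m, v = sps.truncnorm.stats(a, np.inf, loc=self.mean, scale=self.sd, moments="mv")
        return float(m), float(np.sqrt(v))


def _default_pressures() -> dict:
    # non-PH pressures printed as median (IQR); PH SPAP/DPAP as mean +- SD,
    # PH mPAP converted from its printed median (IQR) under normality.
    return {
        "non-PH": {
            "SPAP": PressureSpec("lognormal", median=26.0, q1=24.0, q3=29.0),
            "mPAP": PressureSpec("lognormal", median=18.0, q1=16.0, q3=19.0),
            "DPAP": PressureSpec("lognormal", median=10.0, q1=8.5, q3=11.0),
        },
        "PH": {
            "SPAP": PressureSpec("normal", mean=72.22, sd=19.73),
            "mPAP": PressureSpec("normal", mean=26.0, sd=(35.0 - 20.0) / (2.0 * _Z75)),
            "DPAP": PressureSpec("normal", mean=27.85, sd=10.77),
        },
    }


def _default_measurements() -> dict:
    # per-arm (mean, sd); the one value printed as median (IQR) is converted
    # under normality (mean = median, sd = IQR width / 1.349)
    return {
        "D_MPA": {"non-PH": (25.93, 4.68), "PH": (36.01, 6.36)},
        "A_MPA": {"non-PH": (601.57, 184.37), "PH": (1046.88, 278.94)},
        "V_MPA": {"non-PH": (25751.64, 7154.24), "PH": (55557.10, 18449.48)},
        "D_RPA": {"non-PH": (19.37, 3.32), "PH": (24.37, 4.15)},
        "A_RPA": {"non-PH": (348.58, 114.38), "PH": (536.47, 176.59)},
        "V_RPA": {
            "non-PH": (15594.91, (29474.24 - 12662.13) / (2.0 * _Z75)),
            "PH": (48454.73, 19118.22),
        },
        "D_LPA": {"non-PH": (17.51, 3.47), "PH": (21.68, 4.36)},
        "A_LPA": {"non-PH": (314.36, 75.18), "PH": (459.79, 182.64)},
        "V_LPA": {"non-PH": (23118.99, 13552.82), "PH": (37963.42, 16972.93)},
    }


def _default_target_r() -> dict:
    # whole-cohort Pearson targets vs mPAP.  V_MPA's 0.744 is the reported
    # value; the others sit inside the reported per-artery ranges
    # (0.586-0.752 MPA, 0.527-0.640 RPA, 0.302-0.495 LPA, 3D lowest for LPA).
    return {
        "D_MPA": 0.586,
        "A_MPA": 0.650,
        "V_MPA": 0.744,
        "D_RPA": 0.527,
        "A_RPA": 0.560,
        "V_RPA": 0.640,
        "D_LPA": 0.450,
        "A_LPA": 0.495,
        "V_LPA": 0.302,
    }


def default_categorical_rates() -> dict:
    # observed per-group proportions (counts over group sizes)
    return {
        "sex_male": (7 / 18, 10 / 41),
        "dyspnea": (4 / 18, 36 / 41),
        "congenital_heart_disease": (12 / 18, 10 / 41),
    }


@dataclass
class CohortConfig:
    """Cohort size, per-arm distributions, linkage targets, seed."""

    n_nonph: int = 18
    n_ph: int = 41
    pressures: dict = field(default_factory=_default_pressures)
    measurements: dict = field(default_factory=_default_measurements)
    target_r: dict = field(default_factory=_default_target_r)
    noise_override: dict = field(default_factory=dict)  # name -> eps SD (0 => deterministic link)
    pressure_copula_rho: float = 0.7
    seed: int = 20231213

    def __post_init__(self) -> None:
        if self.n_nonph < 2 or self.n_ph < 2:
            raise CohortConfigError("need at least 2 patients per arm")
        for name, r in self.target_r.items():
            if not (-1.0 < r < 1.0):
                raise CohortConfigError(f"target correlation for {name} must lie in (-1, 1)")
        for name, sd in self.noise_override.items():
            if sd < 0:
                raise CohortConfigError(f"noise override for {name} must be >= 0")

    def with_total(self, total: int) -> "CohortConfig":
        """Scale both arms proportionally to a new total size."""
        n0 = int(round(total * self.n_nonph / (self.n_nonph + self.n_ph)))
        return replace(self, n_nonph=n0, n_ph=total - n0)


def _mixture_link_strength(config: CohortConfig, name: str) -> float:
    """Solve the within-arm correlation rho_w that yields the configured
    whole-cohort Pearson correlation between measurement ``name`` and mPAP."""
    w = np.array([config.n_nonph, config.n_ph], dtype=float)
    w /= w.sum()
    arms = ("non-PH", "PH")
    pm = np.array([config.pressures[g]["mPAP"].moments() for g in arms])  # (2, [mean, sd])
    mm = np.array([config.measurements[name][g] for g in arms])
    p_bar = float(w @ pm[:, 0])
    m_bar = float(w @ mm[:, 0])
    var_p = float(w @ (pm[:, 1] ** 2 + (pm[:, 0] - p_bar) ** 2))
    var_m = float(w @ (mm[:, 1] ** 2 + (mm[:, 0] - m_bar) ** 2))
    a_coef = float(w @ (mm[:, 1] * pm[:, 1]))  # within-arm covariance per unit rho_w
    b_coef = float(w @ ((pm[:, 0] - p_bar) * (mm[:, 0] - m_bar)))  # between-arm covariance
    r_target = config.target_r[name]
    rho_w = (r_target * np.sqrt(var_p * var_m) - b_coef) / a_coef
    if not (-1.0 < rho_w < 1.0):
        raise CohortConfigError(
            f"target correlation {r_target} for {name} is infeasible given the "
            f"configured group means/SDs (needs within-arm correlation {rho_w:.3f})"
        )
    return float(rho_w)


def _draw_pressures(rng: np.random.Generator, config: CohortConfig, arm: str, n: int) -> pd.DataFrame:
    specs = config.pressures[arm]
    rho = config.pressure_copula_rho
    z_m = rng.standard_normal(n)
    mpap = specs["mPAP"].ppf(sps.norm.cdf(z_m))

    def conditional(spec: PressureSpec) -> np.ndarray:
        z = rho * z_m + np.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        return spec.ppf(sps.norm.cdf(z))

    spap = conditional(specs["SPAP"])
    dpap = conditional(specs["DPAP"])
    # conditionally resample SPAP/DPAP where the pressure ordering fails;
    # mPAP stays fixed so its marginal is exact
    for _ in range(50):
        bad_s = spap < mpap
        bad_d = dpap > mpap
        if not (bad_s.any() or bad_d.any()):
            break
        if bad_s.any():
            z = rho * z_m[bad_s] + np.sqrt(1.0 - rho**2) * rng.standard_normal(int(bad_s.sum()))
            spap[bad_s] = specs["SPAP"].ppf(sps.norm.cdf(z))
        if bad_d.any():
            z = rho * z_m[bad_d] + np.sqrt(1.0 - rho**2) * rng.standard_normal(int(bad_d.sum()))
            dpap[bad_d] = specs["DPAP"].ppf(sps.norm.cdf(z))
    np.maximum(spap, mpap, out=spap)
    np.minimum(dpap, mpap, out=dpap)
    return pd.DataFrame({"mPAP": mpap, "SPAP": spap, "DPAP": dpap, "arm": arm})


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Generate one cohort table.

    Columns: mPAP, SPAP, DPAP, the nine measurements, ``group`` (the strict
    mPAP > 20 label) and ``arm`` (the sampling arm).  Same config and seed
    give identical tables.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    parts = [
        _draw_pressures(rng, config, "non-PH", config.n_nonph),
        _draw_pressures(rng, config, "PH", config.n_ph),
    ]
    df = pd.concat(parts, ignore_index=True)

    for name in MEASUREMENT_COLUMNS:
        if name in config.noise_override and config.noise_override[name] == 0.0:
            rho_w = 1.0
        else:
            rho_w = _mixture_link_strength(config, name)
        vals = np.empty(len(df))
        for arm in ("non-PH", "PH"):
            rows = df["arm"] == arm
            mu_m, sd_m = config.measurements[name][arm]
            mu_p, sd_p = config.pressures[arm]["mPAP"].moments()
            beta = rho_w * sd_m / sd_p
            alpha = mu_m - beta * mu_p
            eps_sd = config.noise_override.get(name, sd_m * np.sqrt(max(0.0, 1.0 - rho_w**2)))
            vals[rows.to_numpy()] = (
                alpha + beta * df.loc[rows, "mPAP"].to_numpy() + rng.normal(0.0, eps_sd, int(rows.sum()))
            )
        df[name] = vals

    df["group"] = np.where(df["mPAP"] > PH_THRESHOLD_MMHG, "PH", "non-PH")
    return df[list(SCHEMA_COLUMNS) + ["arm"]]


def attach_categoricals(
    cohort: pd.DataFrame,
    rates: dict | None = None,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    by: str = "arm",
) -> pd.DataFrame:
    """Add Bernoulli categorical columns with per-group probabilities.

    ``rates`` maps variable name to ``(p_nonph, p_ph)``.  Draws are
    independent per patient and per variable, keyed on the ``by`` column
    (sampling arm by default).
    """
    rates = default_categorical_rates() if rates is None else rates
    rng = rng or np.random.default_rng(seed)
    if by not in cohort.columns:
        raise CohortConfigError(f"cohort has no {by!r} column")
    out = cohort.copy()
    for name, (p0, p1) in rates.items():
        if name in SCHEMA_COLUMNS or not str(name).isidentifier():
            raise CohortConfigError(f"invalid categorical variable name: {name!r}")
        if not (0.0 <= p0 <= 1.0 and 0.0 <= p1 <= 1.0):
            raise CohortConfigError(f"probabilities for {name!r} must lie in [0, 1]")
        p = np.where(out[by].to_numpy() == "PH", p1, p0)
        out[name] = rng.random(len(out)) < p
    return out
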