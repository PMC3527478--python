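"""Synthetic fingerprint time series with known ground truth.

The generator emulates a multi-site, multi-year community-fingerprint study:
latent per-taxon log-abundances evolve over calendar sampling dates with

* **directional turnover** — at drift rate theta (per month, log scale) the
  probability mass shifts gradually from a "resident" half of the taxon pool
  to an "incoming" half (replacement, not biomass trend, because time-lag
  analysis detects compositional turnover);
* an optional per-taxon **random walk** (``walk_sd``) for autocorrelated
  stochastic turnover;
* a shared **seasonal** sinusoid with per-taxon loadings;
* **chemistry linkage** — standardized chemistry values shift the
  log-abundance of a responsive taxon subset with a stated effect size;
* i.i.d. lognormal **replicate noise** (gel-intensity variability).

Observation applies DGGE-style censoring: only taxa whose within-sample
relative abundance exceeds ``detection_fraction`` yield a band; surviving
bands are renormalized.  With the zero-drift, zero-walk, zero-seasonal
settings the sampling dates are exchangeable, which is what the null
calibration of the permutation tests relies on.

Chemistry follows the field pattern of the emulated design: pH and clay are
static site properties (sandy sites acid, clayey sites near-neutral),
nitrate and ammonium decline within each growing season, organic matter and
moisture vary mildly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import LagbetaError
from .io import FingerprintMatrix

FULL_SITES = (
    ("B", "sandy"),
    ("V", "sandy"),
    ("D", "sandy"),
    ("W", "sandy"),
    ("K", "clayey"),
    ("S", "sandy"),
    ("G", "clayey"),
    ("L", "clayey"),
)

# three-year schedule: 4 + 3 + 4 sampling campaigns, mid-month
FULL_SCHEDULE = tuple(
    pd.Timestamp(d)
    for d in (
        "2009-04-15", "2009-06-15", "2009-09-15", "2009-11-15",
        "2010-04-15", "2010-06-15", "2010-10-15",
        "2011-02-15", "2011-04-15", "2011-07-15", "2011-09-15",
    )
)

SMALL_SITES = (("B", "sandy"), ("V", "sandy"), ("K", "clayey"))
SMALL_SCHEDULE = tuple(
    pd.Timestamp(d)
    for d in (
        "2009-04-15", "2009-09-15", "2010-04-15",
        "2010-10-15", "2011-02-15", "2011-07-15",
    )
)

DAYS_PER_MONTH = 30.44

CHEMISTRY_VARIABLES = ("pH", "nh4", "no3", "om", "clay", "moisture")


@dataclass
class SyntheticScenario:
    """Generative parameters for one simulated study.

    ``drift_rate`` is the directional replacement rate theta in log-abundance
    units per month, either one value for every site or a per-site mapping.
    ``detection_fraction`` is the relative-abundance detection limit of the
    fingerprinting method (default 1%, the upper end of the commonly cited
    0.1-1% DGGE sensitivity).
    """

    name: str = "custom"
    sites: tuple = FULL_SITES
    dates: tuple = FULL_SCHEDULE
    n_replicates: int = 4
    n_taxa: int = 120
    drift_rate: float | dict = 0.03
    walk_sd: float = 0.0
    noise_sd: float = 0.5
    seasonal_amplitude: float = 0.4
    detection_fraction: float = 0.01
    chemistry_linkage: dict = field(default_factory=dict)
    linked_taxa_fraction: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_taxa < 1 or len(self.dates) < 1:
            raise LagbetaError("counts (sites, dates, replicates, taxa) must be >= 1")
        if not 0 < self.detection_fraction <= 1:
            raise LagbetaError("detection_fraction must be in (0, 1]")
        for theta in self.site_drift().values():
            if theta < 0:
                raise LagbetaError("drift_rate must be >= 0")

    def site_drift(self) -> dict[str, float]:
        sites = [s for s, _ in self.sites]
        if isinstance(self.drift_rate, dict):
            missing = set(sites) - set(self.drift_rate)
            if missing:
                raise LagbetaError(f"drift_rate mapping missing sites: {sorted(missing)}")
            return {s: float(self.drift_rate[s]) for s in sites}
        return {s: float(self.drift_rate) for s in sites}

    @property
    def n_samples(self) -> int:
        return len(self.sites) * len(self.dates) * self.n_replicates


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline is asked to recover."""

    site_drift: dict[str, float]
    directions: np.ndarray  # +1 incoming / -1 resident per taxon
    chemistry_linkage: dict[str, float]
    linked_taxa: dict[str, tuple[np.ndarray, np.ndarray]]  # var -> (indices, signs)
    latent_log_abundance: dict[str, np.ndarray]  # site -> (n_dates, n_taxa)
    chemistry: pd.DataFrame  # per (site, date)
    detection_fraction: float
    flagged_samples: list[str] = field(default_factory=list)


def _months_since_start(dates) -> np.ndarray:
    days = pd.DatetimeIndex(dates).to_julian_date().to_numpy()
    return (days - days[0]) / DAYS_PER_MONTH


def _seasonal_phase(dates) -> np.ndarray:
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy()
    return np.sin(2 * np.pi * (doy - 105) / 365.25 + np.pi / 2)  # peaks mid-April


def _simulate_chem_values(scenario: SyntheticScenario, rng: np.random.Generator) -> pd.DataFrame:
    """Per-(site, date) chemistry: static pH/clay, seasonal N species."""
    season = _seasonal_phase(scenario.dates)
    rows = []
    for site, texture in scenario.sites:
        if texture == "sandy":
            ph = rng.normal(4.9, 0.15)
            clay = rng.uniform(3.0, 8.0)
        else:
            ph = rng.normal(7.3, 0.10)
            clay = rng.uniform(20.0, 35.0)
        om_base = float(np.exp(rng.normal(np.log(4.5), 0.35)))
        no3_scale = float(np.exp(rng.normal(0.0, 0.3)))
        nh4_scale = float(np.exp(rng.normal(0.0, 0.3)))
        for date, s in zip(scenario.dates, season):
            no3 = max(0.3, no3_scale * (50.0 + 25.0 * s) * np.exp(rng.normal(0, 0.15)))
            nh4 = max(0.04, nh4_scale * (7.0 + 5.0 * s) * np.exp(rng.normal(0, 0.15)))
            om = float(np.clip(om_base * np.exp(rng.normal(0, 0.05)), 0.2, 60.0))
            moisture = float(np.clip(20.0 - 6.0 * s + rng.normal(0, 1.5), 1.0, 60.0))
            rows.append(
                {
                    "site": site,
                    "date": date,
                    "pH": round(float(np.clip(ph, 3.0, 9.0)), 3),
                    "nh4": round(nh4, 3),
                    "no3": round(no3, 3),
                    "om": round(om, 3),
                    "clay": round(clay, 3),
                    "moisture": round(moisture, 3),
                }
            )
    return pd.DataFrame(rows)


def censor_profile(rel: np.ndarray, detection_fraction: float) -> np.ndarray:
    """Apply detection censoring to one relative-abundance profile.

    Taxa at or below the detection fraction are zeroed; the survivors are
    renormalized.  Returns an all-zero profile if nothing is detected.
    Censoring never promotes a taxon above another in rank.
    """
    rel = np.asarray(rel, dtype=float)
    observed = np.where(rel > detection_fraction, rel, 0.0)
    total = observed.sum()
    return observed / total if total > 0 else observed


def simulate_series(
    scenario: SyntheticScenario,
) -> tuple[FingerprintMatrix, pd.DataFrame, GroundTruth]:
    """Generate (fingerprint matrix, sample metadata, ground truth).

    Bit-identical output for the same scenario (including seed).  Samples in
    which censoring removes every band are regenerated with fresh replicate
    noise and flagged in the ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    months = _months_since_start(scenario.dates)
    t_centered = months - months.mean()
    season = _seasonal_phase(scenario.dates)
    n_dates, n_taxa = len(scenario.dates), scenario.n_taxa

    drift = scenario.site_drift()
    directions = np.where(rng.random(n_taxa) < 0.5, 1.0, -1.0)
    seasonal_loading = rng.uniform(-1.0, 1.0, size=n_taxa)

    chem = _simulate_chem_values(scenario, rng)
    linked_taxa: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chem_z: dict[str, pd.Series] = {}
    for var, effect in scenario.chemistry_linkage.items():
        if var not in chem.columns:
            raise LagbetaError(f"chemistry linkage refers to unknown variable {var!r}")
        k = max(1, int(round(scenario.linked_taxa_fraction * n_taxa)))
        idx = rng.choice(n_taxa, size=k, replace=False)
        signs = np.where(rng.random(k) < 0.5, 1.0, -1.0)
        linked_taxa[var] = (idx, signs)
        values = chem.set_index(["site", "date"])[var]
        chem_z[var] = (values - values.mean()) / (values.std(ddof=0) or 1.0)

    sample_rows: list[np.ndarray] = []
    meta_rows: list[dict] = []
    latent: dict[str, np.ndarray] = {}
    flagged: list[str] = []

    for site, texture in scenario.sites:
        base = rng.normal(0.0, 1.2, size=n_taxa)
        theta = drift[site]
        walk = np.zeros((n_dates, n_taxa))
        if scenario.walk_sd > 0:
            steps = rng.normal(0.0, 1.0, size=(n_dates - 1, n_taxa))
            dt = np.sqrt(np.diff(months))
            walk[1:] = np.cumsum(steps * (scenario.walk_sd * dt)[:, None], axis=0)
        lam = (
            base[None, :]
            + theta * t_centered[:, None] * directions[None, :]
            + scenario.seasonal_amplitude * season[:, None] * seasonal_loading[None, :]
            + walk
        )
        for var, effect in scenario.chemistry_linkage.items():
            idx, signs = linked_taxa[var]
            z = np.array([chem_z[var][(site, d)] for d in scenario.dates])
            lam[:, idx] += effect * z[:, None] * signs[None, :]
        latent[site] = lam

        for d_i, date in enumerate(scenario.dates):
            for rep in range(1, scenario.n_replicates + 1):
                sid = f"{site}_{date:%Y%m%d}_r{rep}"
                for attempt in range(25):
                    noisy = lam[d_i] + rng.normal(0.0, scenario.noise_sd, size=n_taxa)
                    abundance = np.exp(noisy - noisy.max())
                    rel = abundance / abundance.sum()
                    detected = rel > scenario.detection_fraction
                    if detected.any():
                        break
                    if attempt == 0:
                        flagged.append(sid)
                        warnings.warn(
                            f"sample {sid}: censoring removed every band; regenerating",
                            stacklevel=2,
                        )
                else:
                    raise LagbetaError(
                        f"sample {sid}: no band exceeds detection_fraction="
                        f"{scenario.detection_fraction}"
                    )
                sample_rows.append(censor_profile(rel, scenario.detection_fraction))
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "site": site,
                        "date": date,
                        "replicate": rep,
                        "texture": texture,
                    }
                )

    data = np.asarray(sample_rows)
    ever_detected = data.sum(axis=0) > 0
    band_ids = [f"b{k:03d}" for k in np.flatnonzero(ever_detected)]
    fp = FingerprintMatrix(
        pd.DataFrame(
            data[:, ever_detected],
            index=[m["sample_id"] for m in meta_rows],
            columns=band_ids,
        ),
        normalized=True,
    )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = GroundTruth(
        site_drift=drift,
        directions=directions,
        chemistry_linkage=dict(scenario.chemistry_linkage),
        linked_taxa=linked_taxa,
        latent_log_abundance=latent,
        chemistry=chem,
        detection_fraction=scenario.detection_fraction,
        flagged_samples=flagged,
    )
    return fp, metadata, truth


def simulate_chemistry(
    scenario: SyntheticScenario,
    metadata: pd.DataFrame,
    ground_truth: GroundTruth | None = None,
) -> pd.DataFrame:
    """Chemistry table per (site, date) consistent with a simulated series.

    When the ground truth from :func:`simulate_series` is given, the values
    returned are exactly those the linkage acted on; otherwise a fresh
    (composition-independent) table is drawn.
    """
    if ground_truth is not None:
        chem = ground_truth.chemistry
    else:
        rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
        chem = _simulate_chem_values(scenario, rng)
    keys = metadata[["site", "date"]].drop_duplicates()
    merged = keys.merge(chem, on=["site", "date"], how="left")
    if merged[list(CHEMISTRY_VARIABLES)].isna().any().any():
        raise LagbetaError("metadata contains (site, date) keys absent from the scenario")
    return merged.reset_index(drop=True)


def scenario_presets() -> dict[str, SyntheticScenario]:
    """Named scenarios spanning the emulated study's regimes.

    * ``full-scale`` — the full design: 8 sites x 11 dates x 4 replicates,
      modest directional drift everywhere, nitrate-linked composition.
    * ``desk-small`` — 3 sites x 6 dates x 2 replicates, same dynamics.
    * ``null`` — desk-small geometry, exchangeable dates (no drift, no walk,
      no seasonality): the permutation-test calibration regime.
    * ``directional`` — desk-small geometry with a per-site drift grid.
    * ``seasonal-only`` — no drift, strong seasonality.
    """
    return {
        "full-scale": SyntheticScenario(
            name="full-scale",
            sites=FULL_SITES,
            dates=FULL_SCHEDULE,
            n_replicates=4,
            drift_rate=0.03,
            seasonal_amplitude=0.4,
            chemistry_linkage={"no3": 0.8},
        ),
        "desk-small": SyntheticScenario(
            name="desk-small",
            sites=SMALL_SITES,
            dates=SMALL_SCHEDULE,
            n_replicates=2,
            drift_rate=0.03,
            seasonal_amplitude=0.4,
            chemistry_linkage={"no3": 0.8},
        ),
        "null": SyntheticScenario(
            name="null",
            sites=SMALL_SITES,
            dates=SMALL_SCHEDULE,
            n_replicates=2,
            drift_rate=0.0,
            walk_sd=0.0,
            seasonal_amplitude=0.0,
            chemistry_linkage={},
        ),
        "directional": SyntheticScenario(
            name="directional",
            sites=SMALL_SITES,
            dates=SMALL_SCHEDULE,
            n_replicates=2,
            drift_rate={"B": 0.02, "V": 0.05, "K": 0.08},
            seasonal_amplitude=0.0,
            chemistry_linkage={},
        ),
        "seasonal-only": SyntheticScenario(
            name="seasonal-only",
            sites=SMALL_SITES,
            dates=SMALL_SCHEDULE,
            n_replicates=2,
            drift_rate=0.0,
            seasonal_amplitude=0.8,
            chemistry_linkage={},
        ),
    }


def preset(name: str, seed: int | None = None, **overrides) -> SyntheticScenario:
    """Fetch a preset by name, optionally overriding fields (seed included)."""
    presets = scenario_presets()
    if name not in presets:
        raise LagbetaError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return replace(presets[name], seed=seed, **overrides)
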