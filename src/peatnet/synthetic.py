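"""Synthetic pore-water scenarios with planted, recoverable structure.

The generator emulates the statistical shape of a seasonal peatland
pore-water survey: three monthly groups of samples, seven environmental
covariates drawn from per-month Gaussian profiles, an OTU count table with

* a log-normal baseline abundance distribution,
* planted correlation modules — blocks of OTUs sharing a latent Gaussian
  factor (pairwise latent correlation = ``module_correlation``), optionally
  coupled to one environmental covariate,
* planted indicator OTUs enriched ``indicator_fold``-fold in their own group
  and suppressed by the same factor elsewhere,
* multinomial sampling at a Poisson read depth around ``depth_mean``,

plus a random bifurcating phylogeny and Biolog plate time courses with
logistic colour kinetics (lag to ~24 h, rapid rise to ~72 h, plateau beyond
~168 h) whose amplitude increases with the sample's pore-water temperature.
Ground truth (module membership, indicator identities, kinetic parameters)
is returned alongside for recovery scoring.

Every generator is a deterministic function of its config and seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from peatnet.diversity import OtuTable
from peatnet.ecoplate import (
    N_WELLS,
    PlateSeries,
    standard_ecoplate_layout,
    well_label,
)

ENV_VARS = ("DOC", "DO", "ORP", "EC", "pH", "PWT", "WT")

# Per-month covariate profiles (mean, sd): DOC/DO mg/L, ORP mV, EC uS/cm,
# pH, pore-water temperature degC, water table cm relative to peat surface.
DEFAULT_ENV_PROFILES: dict[str, dict[str, tuple[float, float]]] = {
    "May": {
        "DOC": (15.23, 4.28), "DO": (0.34, 0.14), "ORP": (84.77, 24.46),
        "EC": (16.67, 5.36), "pH": (4.53, 0.41), "PWT": (22.78, 3.49),
        "WT": (1.0, 5.0),
    },
    "August": {
        "DOC": (14.24, 1.85), "DO": (1.34, 0.38), "ORP": (147.63, 20.26),
        "EC": (18.14, 5.19), "pH": (5.18, 0.24), "PWT": (23.55, 1.78),
        "WT": (-2.0, 4.0),
    },
    "November": {
        "DOC": (10.14, 3.58), "DO": (2.75, 0.89), "ORP": (224.45, 41.19),
        "EC": (18.34, 3.80), "pH": (5.35, 0.24), "PWT": (7.98, 0.36),
        "WT": (-7.0, 5.0),
    },
}

# Plateau colour (OD units) per guild; ordering mirrors the typical substrate
# preference (esters/amino acids/amines > carbohydrates/acids > alcohols) and
# the amplitudes put warm-season 72-h AWCD near 1 OD and McIntosh U near 6.
DEFAULT_GUILD_CMAX: dict[str, float] = {
    "ester": 3.1, "amino_acid": 2.7, "amine": 2.5,
    "carbohydrate": 2.0, "carboxylic_acid": 1.7, "alcohol": 1.0,
}


@dataclass
class ScenarioConfig:
    n_groups: int = 3
    samples_per_group: int = 12
    n_otus: int = 600
    depth_mean: int = 40205
    n_modules: int = 5
    module_size: int = 8
    module_correlation: float = 0.9
    module_effect_sd: float = 1.2
    n_indicators_per_group: int = 5
    indicator_fold: float = 8.0
    baseline_log_sd: float = 1.5
    otu_noise_sd: float = 0.6
    env_profiles: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {g: dict(v) for g, v in DEFAULT_ENV_PROFILES.items()}
    )
    env_linked_covariate: str | None = "WT"  # couples module 1 to this covariate
    env_link_weight: float = 0.7
    plate_lag_h: float = 24.0
    plate_plateau_h: float = 168.0
    plate_noise_sd: float = 0.01
    plate_read_interval_h: float = 12.0
    plate_total_h: float = 240.0
    guild_cmax: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GUILD_CMAX)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_groups, self.samples_per_group, self.n_otus,
               self.depth_mean) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_modules * self.module_size > self.n_otus:
            raise ValueError("module_size * n_modules exceeds n_otus")
        if not 0 < self.module_correlation < 1:
            raise ValueError("module_correlation must be in (0, 1)")
        if self.indicator_fold <= 1:
            raise ValueError("indicator_fold must be > 1")
        if self.plate_plateau_h <= self.plate_lag_h:
            raise ValueError("plate_plateau_h must exceed plate_lag_h")
        for g, prof in self.env_profiles.items():
            for v, (_, sd) in prof.items():
                if sd < 0:
                    raise ValueError(f"negative sd for {v} in group {g}")

    @property
    def group_names(self) -> list[str]:
        names = list(self.env_profiles)
        if len(names) >= self.n_groups:
            return names[: self.n_groups]
        return names + [f"group{i + 1}" for i in range(len(names), self.n_groups)]


@dataclass
class GroundTruth:
    module_of_otu: dict[str, int]
    indicator_otus: dict[str, set[str]]
    env_effect_loadings: dict[int, str]
    plate_params: dict[str, dict[str, float]] = field(default_factory=dict)

    def indicator_set(self) -> set[str]:
        return set().union(*self.indicator_otus.values()) if self.indicator_otus else set()


def _rng(cfg_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg_seed, stream])


def gen_metadata(cfg: ScenarioConfig) -> pd.DataFrame:
    """Sample metadata: group label plus Gaussian draws of the seven covariates."""
    rng = _rng(cfg.seed, 0)
    rows = []
    for g in cfg.group_names:
        prof = cfg.env_profiles.get(g, {})
        for i in range(cfg.samples_per_group):
            row = {"sample_id": f"{g}_{i + 1:02d}", "group": g}
            for v in ENV_VARS:
                mean, sd = prof.get(v, (0.0, 1.0))
                row[v] = mean + sd * rng.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def gen_otu_table(
    cfg: ScenarioConfig, meta: pd.DataFrame
) -> tuple[OtuTable, GroundTruth]:
    """OTU counts with planted correlation modules and indicator OTUs."""
    rng = _rng(cfg.seed, 1)
    n_samples = len(meta)
    n = cfg.n_otus
    otu_ids = [f"OTU_{i + 1:04d}" for i in range(n)]
    groups = meta["group"].to_numpy()

    n_module_otus = cfg.n_modules * cfg.module_size
    n_ind = cfg.n_indicators_per_group * cfg.n_groups
    if n_module_otus + n_ind > n:
        raise ValueError("planted OTUs exceed n_otus")

    base = rng.normal(0.0, cfg.baseline_log_sd, size=n)
    # planted OTUs get an elevated baseline so they survive abundance filtering
    base[:n_module_otus] = rng.normal(1.5, 0.3, size=n_module_otus)
    base[n_module_otus:n_module_otus + n_ind] = rng.normal(1.2, 0.3, size=n_ind)

    log_ab = np.tile(base, (n_samples, 1))
    rho = cfg.module_correlation
    lam = cfg.module_effect_sd
    module_of: dict[str, int] = {}
    env_loadings: dict[int, str] = {}
    for m in range(cfg.n_modules):
        factor = rng.standard_normal(n_samples)
        if m == 0 and cfg.env_linked_covariate is not None:
            cov = meta[cfg.env_linked_covariate].to_numpy()
            z = (cov - cov.mean()) / cov.std()
            w = cfg.env_link_weight
            factor = w * z + np.sqrt(1 - w**2) * factor
            env_loadings[m + 1] = cfg.env_linked_covariate
        lo = m * cfg.module_size
        for j in range(lo, lo + cfg.module_size):
            noise = rng.standard_normal(n_samples)
            log_ab[:, j] = base[j] + lam * (
                np.sqrt(rho) * factor + np.sqrt(1 - rho) * noise
            )
            module_of[otu_ids[j]] = m + 1

    indicator_otus: dict[str, set[str]] = {g: set() for g in cfg.group_names}
    log_fold = np.log(cfg.indicator_fold) if np.isfinite(cfg.indicator_fold) else None
    idx = n_module_otus
    for g in cfg.group_names:
        own = groups == g
        for _ in range(cfg.n_indicators_per_group):
            noise = 0.4 * rng.standard_normal(n_samples)
            if log_fold is None:  # infinite fold: present only in its own group
                log_ab[:, idx] = np.where(own, base[idx] + noise, -np.inf)
            else:
                log_ab[:, idx] = base[idx] + np.where(own, log_fold, -log_fold) + noise
            indicator_otus[g].add(otu_ids[idx])
            idx += 1

    rest = np.arange(n) >= n_module_otus + n_ind
    log_ab[:, rest] = base[rest] + cfg.otu_noise_sd * rng.standard_normal(
        (n_samples, int(rest.sum()))
    )

    counts = np.zeros((n_samples, n), dtype=np.int64)
    for s in range(n_samples):
        a = np.exp(log_ab[s])
        p = a / a.sum()
        depth = max(1, int(rng.poisson(cfg.depth_mean)))
        counts[s] = rng.multinomial(depth, p)
    table = OtuTable(pd.DataFrame(counts, index=meta.index, columns=otu_ids))
    truth = GroundTruth(module_of, indicator_otus, env_loadings)
    return table, truth


def gen_tree(otu_ids: list[str], seed: int = 0) -> TreeNode:
    """Random rooted bifurcating tree over the OTUs, exponential branch lengths."""
    if len(otu_ids) < 2:
        raise ValueError("need >= 2 OTUs")
    if len(set(otu_ids)) != len(otu_ids):
        raise ValueError("duplicate OTU ids")
    rng = np.random.default_rng(seed)
    nodes = list(otu_ids)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b1, b2 = rng.exponential(0.1, size=2)
        merged = f"({nodes[i]}:{b1:.6f},{nodes[j]}:{b2:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return TreeNode.read(io.StringIO(nodes[0] + ";"), convert_underscores=False)


def _logistic_color(t: np.ndarray, cmax: float, rate: float, t_mid: float) -> np.ndarray:
    return cmax / (1.0 + np.exp(-rate * (t - t_mid)))


def pwt_rate_scale(pwt: float) -> float:
    """Amplitude multiplier for colour development, increasing in temperature."""
    return 0.5 + 0.5 / (1.0 + np.exp(-(pwt - 15.0) / 4.0))


def gen_plate_series(cfg: ScenarioConfig, meta: pd.DataFrame) -> list[PlateSeries]:
    """Logistic plate kinetics per sample; amplitude scales with the sample's PWT."""
    rng = _rng(cfg.seed, 2)
    layout = standard_ecoplate_layout()
    times = np.arange(0.0, cfg.plate_total_h + 1e-9, cfg.plate_read_interval_h)
    # colour reaches ~5% of Cmax at the end of the lag and ~95% well before
    # the stated plateau, putting the steep rise between lag and ~3x lag
    t_mid = cfg.plate_lag_h + (cfg.plate_plateau_h - cfg.plate_lag_h) / 3.0
    rate = 3.0 / (t_mid - cfg.plate_lag_h)
    base590, base750 = 0.08, 0.04
    series = []
    for sid, row in meta.iterrows():
        scale = pwt_rate_scale(float(row["PWT"]))
        readings = np.zeros((len(times), 2, N_WELLS))
        readings[:, 0, :] = base590
        readings[:, 1, :] = base750
        for s in layout.non_control:
            cmax = cfg.guild_cmax[s.guild.value] * scale * rng.lognormal(0.0, 0.15)
            curve = _logistic_color(times, cmax, rate, t_mid)
            for w in s.well_positions:
                readings[:, 0, w] += curve
        if cfg.plate_noise_sd > 0:
            readings += rng.normal(0.0, cfg.plate_noise_sd, size=readings.shape)
        readings = np.clip(readings, 0.0, None)
        series.append(PlateSeries(str(sid), times, readings, layout))
    return series


def write_plate_csv(series: PlateSeries, path: str | Path) -> None:
    """Write one plate series in the long CSV format read_plate_series expects."""
    rows = []
    for ti, t in enumerate(series.times):
        for wi, wl in enumerate((590, 750)):
            for c in range(N_WELLS):
                rows.append(
                    (series.sample_id, float(t), wl, well_label(c),
                     round(float(series.readings[ti, wi, c]), 5))
                )
    pd.DataFrame(
        rows, columns=["sample_id", "time_h", "wavelength", "well", "od"]
    ).to_csv(path, index=False)
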