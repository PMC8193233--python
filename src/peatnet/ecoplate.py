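"""Community-level physiological profiling (CLPP) from Biolog EcoMicroplates.

A Biolog EcoPlate carries 31 sole-carbon-source substrates plus a water
control, each in triplicate, read at 590 nm (dye + turbidity) and 750 nm
(turbidity only) over an incubation course.  The colour response of a
substrate well is the blank-corrected differential absorbance

    c_i = mean_wells(A590 - A750)_substrate - mean_wells(A590 - A750)_water

clamped at zero (a well paler than the water control carries no metabolic
signal).  From the clamped response vector the module computes

* AWCD       = (1/n) * sum_i c_i            — average well-colour development,
* McIntosh U = sqrt(sum_i c_i^2)            — Euclidean-norm diversity,
* Shannon H' = -sum_i p_i ln p_i,  p_i = c_i / sum_j c_j,
* Rsi        = c_i / AWCD                   — AWCD-normalised response used
  for ordination (removes inoculum-density differences between samples).

Substrates belong to six functional guilds (carbohydrates, amino acids,
amines, esters, carboxylic acids, alcohols); guild profiles are per-guild
means of the clamped responses so guilds of unequal size stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

N_WELLS = 96
N_COLS = 12
WAVELENGTHS = (590, 750)


class Guild(str, Enum):
    CARBOHYDRATE = "carbohydrate"
    AMINO_ACID = "amino_acid"
    AMINE = "amine"
    ESTER = "ester"
    CARBOXYLIC_ACID = "carboxylic_acid"
    ALCOHOL = "alcohol"


def well_index(label: str | int) -> int:
    """Normalise a well label ('A1'..'H12' or 0..95) to a 0-based row-major index."""
    if isinstance(label, (int, np.integer)):
        idx = int(label)
    else:
        s = str(label).strip()
        if s.isdigit() or (s.startswith("-") and s[1:].isdigit()):
            idx = int(s)
        else:
            row = ord(s[0].upper()) - ord("A")
            col = int(s[1:]) - 1
            if not (0 <= row < 8 and 0 <= col < N_COLS):
                raise ValueError(f"well label out of range: {label!r}")
            idx = row * N_COLS + col
    if not 0 <= idx < N_WELLS:
        raise ValueError(f"well index out of range: {label!r}")
    return idx


def well_label(idx: int) -> str:
    return f"{chr(ord('A') + idx // N_COLS)}{idx % N_COLS + 1}"


@dataclass(frozen=True)
class Substrate:
    substrate_id: str
    guild: Guild | None  # None for the water control
    well_positions: tuple[int, ...]
    is_control: bool = False


@dataclass(frozen=True)
class SubstrateLayout:
    """Mapping of plate wells to substrates and guilds."""

    substrates: tuple[Substrate, ...]

    def __post_init__(self) -> None:
        controls = [s for s in self.substrates if s.is_control]
        if len(controls) != 1:
            raise ValueError("layout must contain exactly one control substrate")
        non_control = self.non_control
        seen: set[int] = set()
        for s in self.substrates:
            if not s.well_positions:
                raise ValueError(f"substrate {s.substrate_id} has no wells")
            for w in s.well_positions:
                if not 0 <= w < N_WELLS:
                    raise ValueError(f"well index {w} out of plate")
                if w in seen:
                    raise ValueError(f"well {w} assigned twice")
                seen.add(w)
        n_rep = len(controls[0].well_positions)
        if any(len(s.well_positions) != n_rep for s in non_control):
            raise ValueError("control and substrates must have equal replicate counts")

    @property
    def non_control(self) -> tuple[Substrate, ...]:
        return tuple(s for s in self.substrates if not s.is_control)

    @property
    def control(self) -> Substrate:
        return next(s for s in self.substrates if s.is_control)

    @property
    def n_substrates(self) -> int:
        return len(self.non_control)

    def guild_members(self) -> dict[Guild, list[str]]:
        out: dict[Guild, list[str]] = {}
        for s in self.non_control:
            out.setdefault(s.guild, []).append(s.substrate_id)
        return out


# EcoPlate geometry: three replicate blocks of 4 columns; within a block the
# 32 positions run A..H down rows, 1..4 across the block's columns.
_ECOPLATE_BLOCK: list[tuple[str, str | None]] = [
    # (substrate, guild); row-major within a 8x4 block, A1 first
    ("water", None),
    ("beta-methyl-D-glucoside", "carbohydrate"),
    ("D-galactonic acid gamma-lactone", "ester"),
    ("L-arginine", "amino_acid"),
    ("pyruvic acid methyl ester", "ester"),
    ("D-xylose", "carbohydrate"),
    ("D-galacturonic acid", "carboxylic_acid"),
    ("L-asparagine", "amino_acid"),
    ("Tween 40", "ester"),
    ("i-erythritol", "alcohol"),
    ("2-hydroxybenzoic acid", "carboxylic_acid"),
    ("L-phenylalanine", "amino_acid"),
    ("Tween 80", "ester"),
    ("D-mannitol", "alcohol"),
    ("4-hydroxybenzoic acid", "carboxylic_acid"),
    ("L-serine", "amino_acid"),
    ("alpha-cyclodextrin", "carbohydrate"),
    ("N-acetyl-D-glucosamine", "carbohydrate"),
    ("gamma-hydroxybutyric acid", "carboxylic_acid"),
    ("L-threonine", "amino_acid"),
    ("glycogen", "carbohydrate"),
    ("D-glucosaminic acid", "carboxylic_acid"),
    ("itaconic acid", "carboxylic_acid"),
    ("glycyl-L-glutamic acid", "amino_acid"),
    ("D-cellobiose", "carbohydrate"),
    ("glucose-1-phosphate", "carbohydrate"),
    ("alpha-ketobutyric acid", "carboxylic_acid"),
    ("phenylethylamine", "amine"),
    ("alpha-D-lactose", "carbohydrate"),
    ("D,L-alpha-glycerol phosphate", "alcohol"),
    ("D-malic acid", "carboxylic_acid"),
    ("putrescine", "amine"),
]


def standard_ecoplate_layout() -> SubstrateLayout:
    """The standard 31-substrate + water EcoPlate layout, triplicate blocks."""
    subs = []
    for pos, (name, guild) in enumerate(_ECOPLATE_BLOCK):
        row, col = divmod(pos, 4)
        wells = tuple(row * N_COLS + col + 4 * block for block in range(3))
        subs.append(
            Substrate(name, Guild(guild) if guild else None, wells, is_control=guild is None)
        )
    return SubstrateLayout(tuple(subs))


def read_layout(path: str | Path) -> SubstrateLayout:
    """Read a layout TSV: substrate_id, guild, wells (';'-separated), is_control."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    subs = []
    for _, r in df.iterrows():
        ctrl = str(r["is_control"]).strip().lower() in {"1", "true", "yes"}
        wells = tuple(well_index(w) for w in str(r["wells"]).split(";"))
        guild = None if ctrl else Guild(str(r["guild"]).strip())
        subs.append(Substrate(str(r["substrate_id"]), guild, wells, ctrl))
    return SubstrateLayout(tuple(subs))


@dataclass
class PlateSeries:
    """Absorbance time course of one sample's plate at 590 and 750 nm."""

    sample_id: str
    times: np.ndarray  # hours, strictly increasing
    readings: np.ndarray  # (n_times, 2, 96); axis 1 ordered as WAVELENGTHS
    layout: SubstrateLayout

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times < 0):
            raise ValueError("times must be nonnegative")
        if self.readings.shape != (len(self.times), 2, N_WELLS):
            raise ValueError(f"readings must have shape (n_times, 2, {N_WELLS})")
        if not np.all(np.isfinite(self.readings)):
            raise ValueError("absorbances must be finite")
        if np.any(self.readings < 0):
            t, w, c = np.argwhere(self.readings < 0)[0]
            raise ValueError(
                f"negative absorbance at t={self.times[t]} h, "
                f"{WAVELENGTHS[w]} nm, well {well_label(int(c))}"
            )


def read_plate_series(path: str | Path, layout: SubstrateLayout | None = None) -> PlateSeries:
    """Read one sample's plate CSV (long format: sample_id,time_h,wavelength,well,od)."""
    layout = layout or standard_ecoplate_layout()
    df = pd.read_csv(path)
    required = {"sample_id", "time_h", "wavelength", "well", "od"}
    if not required.issubset(df.columns):
        raise ValueError(f"plate file missing columns: {sorted(required - set(df.columns))}")
    samples = df["sample_id"].unique()
    if len(samples) != 1:
        raise ValueError(f"plate file must contain one sample, found {len(samples)}")
    times = np.sort(df["time_h"].unique().astype(float))
    readings = np.full((len(times), 2, N_WELLS), np.nan)
    t_index = {t: i for i, t in enumerate(times)}
    w_index = {w: i for i, w in enumerate(WAVELENGTHS)}
    for _, r in df.iterrows():
        wl = int(r["wavelength"])
        if wl not in w_index:
            raise ValueError(f"unknown wavelength {wl}")
        od = float(r["od"])
        if od < 0:
            raise ValueError(
                f"negative absorbance for sample {r['sample_id']} at "
                f"t={r['time_h']} h, {wl} nm, well {r['well']}"
            )
        readings[t_index[float(r["time_h"])], w_index[wl], well_index(r["well"])] = od
    if np.isnan(readings).any():
        t, w, _ = np.argwhere(np.isnan(readings))[0]
        raise ValueError(
            f"incomplete plate: missing {WAVELENGTHS[w]} nm reading at t={times[t]} h"
        )
    return PlateSeries(str(samples[0]), times, readings, layout)


@dataclass
class ColorResponse:
    """Blank-corrected, clamped per-substrate responses of one plate at one time."""

    sample_id: str
    time_h: float
    values: dict[str, float]  # clamped max(Ci - R, 0)
    n: int
    control_value: float  # R, replicate-mean control response
    raw_ci: dict[str, float]  # Ci before control subtraction

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def _snapshot_readings(
    series: PlateSeries, time_h: float, *, interpolate: bool, tolerance_h: float
) -> np.ndarray:
    """Differential (A590 - A750) per well at the requested time."""
    diff = series.readings[:, 0, :] - series.readings[:, 1, :]
    exact = np.nonzero(np.isclose(series.times, time_h))[0]
    if exact.size:
        return diff[exact[0]]
    if interpolate:
        if not (series.times[0] <= time_h <= series.times[-1]):
            raise ValueError(f"t={time_h} h outside the sampled range")
        return np.array(
            [np.interp(time_h, series.times, diff[:, w]) for w in range(N_WELLS)]
        )
    nearest = int(np.argmin(np.abs(series.times - time_h)))
    if abs(series.times[nearest] - time_h) <= tolerance_h:
        return diff[nearest]
    raise ValueError(
        f"no reading within {tolerance_h} h of t={time_h} h "
        f"(available: {series.times.tolist()})"
    )


def blank_corrected_response(
    series: PlateSeries,
    time_h: float = 72.0,
    *,
    interpolate: bool = False,
    tolerance_h: float = 6.0,
    average_replicates: bool = True,
) -> ColorResponse:
    """Per-substrate clamped colour response c_i = max(Ci - R, 0) at one snapshot.

    Ci is the replicate-mean (A590 - A750) of a substrate's wells; R the same
    for the water-control wells.  With ``average_replicates=False`` each
    replicate well is treated as its own substrate entry (suffix ``#k``).
    """
    diff = _snapshot_readings(
        series, time_h, interpolate=interpolate, tolerance_h=tolerance_h
    )
    layout = series.layout
    control_value = float(np.mean(diff[list(layout.control.well_positions)]))
    raw_ci: dict[str, float] = {}
    values: dict[str, float] = {}
    for s in layout.non_control:
        if average_replicates:
            ci = float(np.mean(diff[list(s.well_positions)]))
            raw_ci[s.substrate_id] = ci
            values[s.substrate_id] = max(ci - control_value, 0.0)
        else:
            for k, w in enumerate(s.well_positions):
                key = f"{s.substrate_id}#{k + 1}"
                ci = float(diff[w])
                raw_ci[key] = ci
                values[key] = max(ci - control_value, 0.0)
    return ColorResponse(
        sample_id=series.sample_id,
        time_h=time_h,
        values=values,
        n=len(values),
        control_value=control_value,
        raw_ci=raw_ci,
    )


def awcd(resp: ColorResponse) -> float:
    """Average well-colour development: mean of the clamped responses."""
    if resp.n == 0:
        raise ValueError("response has no substrates")
    return float(resp.as_array().mean())


def mcintosh_u(resp: ColorResponse) -> float:
    """McIntosh index U: Euclidean norm of the clamped response vector."""
    return float(np.linalg.norm(resp.as_array()))


def shannon_h(resp: ColorResponse) -> float:
    """Shannon functional diversity H' over positive wells (0 ln 0 := 0)."""
    v = resp.as_array()
    total = v.sum()
    if total <= 0:
        raise ValueError(f"degenerate plate for {resp.sample_id}: all responses zero")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


def normalize_rsi(resp: ColorResponse) -> dict[str, float]:
    """AWCD-normalised responses Rsi = c_i / AWCD; they sum to n."""
    a = awcd(resp)
    if a == 0:
        raise ValueError(f"degenerate plate for {resp.sample_id}: AWCD is zero")
    return {s: v / a for s, v in resp.values.items()}


@dataclass
class ClppMetrics:
    sample_id: str
    time_h: float
    awcd: float
    mcintosh_u: float
    shannon_h: float
    rsi: dict[str, float]


def clpp_metrics(resp: ColorResponse) -> ClppMetrics:
    """All scalar CLPP metrics plus the Rsi vector for one plate snapshot."""
    return ClppMetrics(
        sample_id=resp.sample_id,
        time_h=resp.time_h,
        awcd=awcd(resp),
        mcintosh_u=mcintosh_u(resp),
        shannon_h=shannon_h(resp),
        rsi=normalize_rsi(resp),
    )


def awcd_curve(series: PlateSeries) -> list[tuple[float, float]]:
    """AWCD at every sampled timepoint, in time order."""
    return [
        (float(t), awcd(blank_corrected_response(series, float(t))))
        for t in series.times
    ]


def guild_profile(
    resp: ColorResponse, layout: SubstrateLayout | None = None
) -> dict[Guild, float]:
    """Per-guild mean of the clamped substrate responses."""
    layout = layout or standard_ecoplate_layout()
    out: dict[Guild, float] = {}
    for guild, members in layout.guild_members().items():
        vals = [resp.values[m] for m in members if m in resp.values]
        if not vals:
            continue
        out[guild] = float(np.mean(vals))
    return out


def clpp_pca(
    rsi_matrix: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the samples x substrates Rsi matrix (column-centred, unscaled).

    Returns (scores, loadings, explained_variance_fractions).  Scores are the
    sample coordinates on the principal axes; loadings the substrate weights,
    orderable to report top contributors per axis.
    """
    X = np.asarray(rsi_matrix, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 substrates")
    if np.isnan(X).any():
        raise ValueError("PCA input contains missing values")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix: zero variance")
    # SVD of the centred matrix == eigendecomposition of the covariance
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = n_components or min(Xc.shape)
    k = min(k, len(s))
    var = s**2 / (X.shape[0] - 1)
    frac = var / var.sum()
    axes = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U[:, :k] * s[:k], index=rsi_matrix.index, columns=axes)
    loadings = pd.DataFrame(Vt[:k].T, index=rsi_matrix.columns, columns=axes)
    return scores, loadings, frac[:k]
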