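"""Synthetic multi-herd milk-spectra datasets with known ground truth.

The generator emulates the statistical structure the downstream pipeline
assumes, without attempting real FTIR physics:

* several herds of unequal size, each cow contributing repeated test-day
  records; parity sampled up to 6 and pooled into classes 1..4+ downstream;
* milk yield following a Wood lactation curve a * DIM^b * exp(-c * DIM)
  scaled by parity, plus noise;
* bodyweight = parity-class baseline + herd effect + cow effect + an
  early-lactation dip -L * exp(-DIM/tau) + a slow within-lactation gain +
  a spectrally carried component + residual noise;
* spectra built from smooth Gaussian peaks on the wavenumber grid. Peaks
  centered in a few contiguous "informative" zones have amplitudes linear in
  a latent milk-composition variable correlated with bodyweight (and weakly
  with milk yield and stage of lactation); the rest carry record-specific
  but bodyweight-independent variation. Smooth autocorrelated noise (white
  noise convolved with a Gaussian kernel) plus a little white noise is added,
  which reproduces the strong correlation between adjacent spectral points.

Random streams are partitioned per entity (herd, cow, record) via seed
spawn keys, so adding herds leaves existing ones bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .dataset import Dataset, WavenumberGrid, make_canonical_grid, parity_class

DEFAULT_PARITY_PROBS = (0.32, 0.25, 0.18, 0.12, 0.08, 0.05)
#: parity-class bodyweight ranges (kg) used by the range filter; mean +- sd
#: magnitudes typical of Holstein test-day data
DEFAULT_BW_INTERVALS = {1: (376.0, 705.0), 2: (449.0, 767.0), 3: (487.0, 838.0), 4: (492.0, 875.0)}


@dataclass(frozen=True)
class GeneratorConfig:
    """All generator knobs, in physical units where they have them."""

    n_herds: int = 9
    cows_per_herd: tuple[int, int] = (10, 45)
    records_per_cow: tuple[int, int] = (2, 8)
    parity_probs: tuple[float, ...] = DEFAULT_PARITY_PROBS
    dim_range: tuple[int, int] = (5, 305)
    grid: WavenumberGrid = field(default_factory=make_canonical_grid)
    # spectral signal geometry
    n_informative_zones: int = 3
    zone_width: float = 15.0  # cm^-1
    signal_to_noise: float = 5.0  # informative amplitude sd / per-point noise sd
    zone_bw_weight: float = 0.8  # share of zone latent loading on the BW latent
    # bodyweight variance components (kg)
    herd_sd: float = 12.0
    cow_sd: float = 20.0
    resid_sd: float = 12.0
    bw_latent_kg: float = 35.0  # kg per unit of the spectral latent
    parity_base: tuple[float, float, float, float] = (560.0, 615.0, 650.0, 670.0)
    dip_kg: float = 25.0
    dip_tau: float = 45.0
    gain_kg_per_day: float = 0.10
    # milk yield (Wood curve, kg/day)
    wood_a: float = 16.0
    wood_b: float = 0.22
    wood_c: float = 0.004
    my_parity_scale: tuple[float, float, float, float] = (0.85, 1.0, 1.08, 1.10)
    my_sd: float = 2.5
    # spectral construction (absorbance-like arbitrary units)
    n_peaks: int = 40
    peak_width: float = 25.0  # cm^-1, gaussian sigma
    peak_amp: float = 0.15
    peak_amp_jitter: float = 0.10  # relative per-record amplitude variation
    smooth_noise_sd: float = 0.006
    smooth_noise_width: float = 5.0  # grid steps of the smoothing kernel
    white_noise_sd: float = 0.0012
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.parity_probs) - 1.0) > 1e-9:
            raise ValueError("parity_probs must sum to 1")
        for name in ("n_herds", "n_informative_zones", "n_peaks"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.signal_to_noise < 0:
            raise ValueError("signal_to_noise must be >= 0")
        if self.cows_per_herd[0] < 1 or self.records_per_cow[0] < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SyntheticTruth:
    """Everything the generator knew: the key to parameter-recovery tests."""

    informative_indices: list[int]  # grid indices carrying BW signal
    zone_centers: list[float]  # cm^-1
    zone_effects: list[float]  # amplitude per unit latent, per zone
    herd_effects: dict[str, float]  # kg
    cow_effects: dict[str, float]  # kg
    outlier_ids: dict[str, str] = field(default_factory=dict)  # record_id -> kind
    noise_floor_rmse: float = 0.0  # kg: sd of BW components no predictor carries

    def informative_columns(self, dataset: Dataset) -> list[str]:
        cols = dataset.spectral_columns
        return [cols[i] for i in self.informative_indices if i < len(cols)]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _zone_centers(cfg: GeneratorConfig) -> np.ndarray:
    """Deterministic zone placement in the lower (fingerprint-like) third of
    the grid, clear of the edges."""
    g = cfg.grid
    lo = g.start + 0.05 * (g.end - g.start)
    hi = g.start + 0.45 * (g.end - g.start)
    centers = np.linspace(lo, hi, cfg.n_informative_zones + 2)[1:-1]
    if np.any(centers - cfg.zone_width / 2 < g.start) or np.any(
        centers + cfg.zone_width / 2 > g.end
    ):
        raise ValueError("informative zone centers fall outside the grid range")
    return centers


def _wood_my(dim: np.ndarray, pc: np.ndarray, cfg: GeneratorConfig) -> np.ndarray:
    scale = np.asarray(cfg.my_parity_scale)[pc - 1]
    return scale * cfg.wood_a * dim**cfg.wood_b * np.exp(-cfg.wood_c * dim)


def _my_reference_moments(cfg: GeneratorConfig) -> tuple[float, float]:
    """Mean and sd of milk yield implied by the config (uniform DIM, the
    parity mix, and the Wood curve), independent of any sampled records."""
    dims = np.arange(cfg.dim_range[0], cfg.dim_range[1] + 1, dtype=float)
    class_probs = np.zeros(4)
    for parity, prob in enumerate(cfg.parity_probs, start=1):
        class_probs[parity_class(parity) - 1] += prob
    means = np.zeros(4)
    second = np.zeros(4)
    for c in range(4):
        curve = _wood_my(dims, np.full(dims.size, c + 1, dtype=int), cfg)
        means[c] = curve.mean()
        second[c] = (curve**2).mean()
    mu = float(class_probs @ means)
    var = float(class_probs @ second) - mu**2 + cfg.my_sd**2
    return mu, max(np.sqrt(var), 1e-12)


def generate(config: GeneratorConfig) -> tuple[Dataset, SyntheticTruth]:
    """Draw a full multi-herd dataset plus its generating truth.

    Identical config (including seed) gives byte-identical output.
    """
    cfg = config
    grid = cfg.grid
    gv = grid.values
    step = grid.step

    zone_centers = _zone_centers(cfg)
    informative = sorted(
        set(
            int(i)
            for c in zone_centers
            for i in np.flatnonzero(np.abs(gv - c) <= cfg.zone_width / 2)
        )
    )
    if not informative:
        raise ValueError("zone_width too small: no grid point in any zone")

    rng_global = _rng(cfg.seed, 0)
    # fixed peak landscape shared by all records
    peak_centers = np.sort(
        rng_global.uniform(gv[0] + 2 * step, gv[-1] - 2 * step, cfg.n_peaks)
    )
    peak_base = cfg.peak_amp * (0.4 + rng_global.uniform(0, 1.2, cfg.n_peaks))
    peak_shapes = np.exp(
        -0.5 * ((gv[None, :] - peak_centers[:, None]) / cfg.peak_width) ** 2
    )  # (n_peaks, n_points)

    # one informative peak per zone, narrow enough to stay inside the zone
    zone_sigma = max(cfg.zone_width / 3.0, step)
    zone_shapes = np.exp(-0.5 * ((gv[None, :] - zone_centers[:, None]) / zone_sigma) ** 2)

    # per-zone loadings on (BW latent, MY, DIM); BW latent dominates
    w_bw = cfg.zone_bw_weight
    w_other = np.sqrt(max(0.0, 1.0 - w_bw**2) / 2.0)
    noise_pt_sd = float(np.hypot(cfg.smooth_noise_sd, cfg.white_noise_sd))
    zone_amp = cfg.signal_to_noise * noise_pt_sd  # amplitude sd per unit latent mix

    rows: list[dict] = []
    herd_effects: dict[str, float] = {}
    cow_effects: dict[str, float] = {}
    n_parity = len(cfg.parity_probs)
    rec_counter = 0
    for h in range(cfg.n_herds):
        hrng = _rng(cfg.seed, 1, h)
        herd_id = f"h{h + 1:02d}"
        herd_eff = float(hrng.normal(0, cfg.herd_sd))
        herd_effects[herd_id] = herd_eff
        n_cows = int(hrng.integers(cfg.cows_per_herd[0], cfg.cows_per_herd[1] + 1))
        for c in range(n_cows):
            crng = _rng(cfg.seed, 2, h, c)
            cow_id = f"{herd_id}c{c + 1:03d}"
            cow_eff = float(crng.normal(0, cfg.cow_sd))
            cow_effects[cow_id] = cow_eff
            parity = int(crng.choice(n_parity, p=cfg.parity_probs)) + 1
            pc = parity_class(parity)
            n_rec = int(crng.integers(cfg.records_per_cow[0], cfg.records_per_cow[1] + 1))
            dims = np.sort(crng.integers(cfg.dim_range[0], cfg.dim_range[1] + 1, n_rec))
            for k in range(n_rec):
                rows.append(
                    dict(
                        herd_id=herd_id,
                        cow_id=cow_id,
                        parity=parity,
                        parity_class=pc,
                        dim=int(dims[k]),
                        herd_eff=herd_eff,
                        cow_eff=cow_eff,
                        rec_key=(h, c, k),
                    )
                )
                rec_counter += 1

    n = len(rows)
    meta = pd.DataFrame(rows)
    meta["record_id"] = [f"r{i + 1:06d}" for i in range(n)]
    pc_arr = meta["parity_class"].to_numpy()
    dim_arr = meta["dim"].to_numpy(dtype=float)

    # per-record draws from record-keyed streams
    u = np.empty(n)
    my_noise = np.empty(n)
    bw_noise = np.empty(n)
    spec_noise = np.empty((n, grid.n_points))
    amp_jit = np.empty((n, cfg.n_peaks))
    for i, key in enumerate(meta["rec_key"]):
        rrng = _rng(cfg.seed, 3, *key)
        u[i] = rrng.normal()
        my_noise[i] = rrng.normal(0, cfg.my_sd)
        bw_noise[i] = rrng.normal(0, cfg.resid_sd)
        amp_jit[i] = rrng.normal(0, cfg.peak_amp_jitter, cfg.n_peaks)
        white = rrng.normal(0, 1.0, grid.n_points)
        smooth = gaussian_filter1d(rrng.normal(0, 1.0, grid.n_points), cfg.smooth_noise_width, mode="nearest")
        smooth_sd = max(float(smooth.std()), 1e-12)
        spec_noise[i] = cfg.smooth_noise_sd * smooth / smooth_sd + cfg.white_noise_sd * white

    my = _wood_my(dim_arr, pc_arr, cfg) + my_noise
    my = np.maximum(my, 0.5)

    base = np.asarray(cfg.parity_base)[pc_arr - 1]
    bw = (
        base
        + meta["herd_eff"].to_numpy()
        + meta["cow_eff"].to_numpy()
        - cfg.dip_kg * np.exp(-dim_arr / cfg.dip_tau)
        + cfg.gain_kg_per_day * dim_arr
        + cfg.bw_latent_kg * u
        + bw_noise
    )

    # standardized companions for the zone latents, using deterministic
    # config-implied moments so herd streams stay independent of each other
    my_mu, my_sigma = _my_reference_moments(cfg)
    dim_mu = 0.5 * (cfg.dim_range[0] + cfg.dim_range[1])
    dim_sigma = max((cfg.dim_range[1] - cfg.dim_range[0]) / np.sqrt(12.0), 1e-12)
    my_z = (my - my_mu) / my_sigma
    dim_z = (dim_arr - dim_mu) / dim_sigma
    latent_mix = w_bw * u[:, None] + w_other * my_z[:, None] + w_other * dim_z[:, None]
    # alternate signs across zones so zones are not mutually redundant copies
    zone_signs = np.where(np.arange(cfg.n_informative_zones) % 2 == 0, 1.0, -1.0)
    zone_eff = zone_amp * zone_signs

    spectra = (
        (peak_base[None, :] * (1.0 + amp_jit)) @ peak_shapes
        + (latent_mix * zone_eff[None, :]) @ zone_shapes
        + spec_noise
    )

    df = meta.drop(columns=["herd_eff", "cow_eff", "rec_key"]).copy()
    df["my"] = my
    df["bw"] = bw
    spec_df = pd.DataFrame(spectra, columns=grid.column_names())
    df = pd.concat([df, spec_df], axis=1)
    order = ["record_id", "herd_id", "cow_id", "parity", "parity_class", "dim", "my", "bw"]
    df = df[order + grid.column_names()]

    truth = SyntheticTruth(
        informative_indices=informative,
        zone_centers=[float(c) for c in zone_centers],
        zone_effects=[float(e) for e in zone_eff],
        herd_effects=herd_effects,
        cow_effects=cow_effects,
        noise_floor_rmse=float(np.sqrt(cfg.herd_sd**2 + cfg.cow_sd**2 + cfg.resid_sd**2)),
    )
    return Dataset(df, grid, "raw"), truth


def inject_outliers(
    dataset: Dataset,
    truth: SyntheticTruth,
    n_spectral: int = 0,
    n_bw: int = 0,
    magnitude: float = 8.0,
    config: GeneratorConfig | None = None,
    seed: int | None = None,
) -> tuple[Dataset, SyntheticTruth]:
    """Perturb chosen records: aberrant spectral peaks and out-of-range BW.

    Spectral outliers get an additive Gaussian bump of ``magnitude`` times the
    per-point noise sd; BW outliers are pushed above their parity-class upper
    bound by at least ``magnitude`` residual sd. Affected ids are appended to
    ``truth.outlier_ids``.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    if n_spectral + n_bw > dataset.n_records:
        raise ValueError("more outliers requested than records available")
    if n_spectral + n_bw == 0:
        return dataset, truth
    cfg = config or GeneratorConfig(grid=dataset.grid or make_canonical_grid())
    rng = _rng(seed if seed is not None else cfg.seed, 4)
    df = dataset.df.copy()
    idx = rng.choice(dataset.n_records, size=n_spectral + n_bw, replace=False)
    spec_idx, bw_idx = idx[:n_spectral], idx[n_spectral:]

    new_truth = replace(truth, outlier_ids=dict(truth.outlier_ids))
    cols = dataset.spectral_columns
    wavenumbers = np.array([float(c[3:]) for c in cols])
    # scale aberrations to the observed spectral variation, not the noise
    # floor, so `magnitude` counts in typical per-point sd units
    point_sd = float(np.median(dataset.spectra().std(axis=0, ddof=1)))
    for i in spec_idx:
        center = rng.uniform(wavenumbers[0], wavenumbers[-1])
        sigma = max(cfg.zone_width, 5 * (wavenumbers[1] - wavenumbers[0]))
        bump = magnitude * point_sd * np.exp(
            -0.5 * ((wavenumbers - center) / sigma) ** 2
        )
        df.loc[df.index[i], cols] = df.loc[df.index[i], cols].to_numpy(float) + bump
        new_truth.outlier_ids[df["record_id"].iloc[i]] = "spectral"
    for i in bw_idx:
        pc = int(df["parity_class"].iloc[i])
        hi = DEFAULT_BW_INTERVALS[pc][1]
        pushed = max(
            float(df["bw"].iloc[i]) + magnitude * cfg.resid_sd, hi + 0.5
        )
        df.loc[df.index[i], "bw"] = pushed
        new_truth.outlier_ids[df["record_id"].iloc[i]] = "bw"
    return Dataset(df, dataset.grid, dataset.stage_tag), new_truth
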