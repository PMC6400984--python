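"""Seeded synthetic paddy-field scenes with known ground truth.

The generator emulates the study design the analysis pipeline assumes:
24 plots (8 nitrogen levels x 3 replicates) laid out on a grid, each
plot a 150 x 120 px rectangle (~18000 pixels), soil ridges between
plots, four uniform calibration panels (nominal reflectances 0.06,
0.24, 0.48, 1.0), and six endmembers — top/bottom-layer leaf (TL, BL),
top/bottom-layer panicle (TP, BP), dry/wet soil (DS, WS).

Construction, per plot with nitrogen index u = level/(n_levels - 1):

* panicle share p(u) = 0.005 + 0.155 u^2 (more panicle at higher
  nitrogen), soil share 0.01 inside plots, leaf share the remainder —
  population means ~0.06 panicle / ~0.93 leaf;
* a canopy-greenness latent C = 0.60 + 0.10 u + noise splits leaf
  abundance between top layer (fraction C) and bottom layer; since TL
  and BL differ in spectral shape, C is visible to vegetation indices;
* per-pixel abundances are a softmax of log plot means plus smoothed
  Gaussian fields, so they are exactly non-negative and sum-to-one
  while showing spatial heterogeneity;
* true reflectance = abundance-weighted mixture of the band-resampled
  endmember spectra (panels overwritten with their flat nominals);
* DN = (reflectance - offset)/gain + Gaussian DN noise;
* yield = beta0 + beta1 * C * (Abd_L - Abd_P) + noise, with defaults
  giving a yield population of mean ~3.6 and CV ~12% on the study's
  (unitless) yield scale.

Everything derives from one seeded generator, so a scene is a pure
function of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

from .bands import DEFAULT_BANDS, BandSet
from .calibration import DEFAULT_PANEL_REFLECTANCES, CalibrationModel, CalibrationTargetSet
from .raster import KIND_DN, KIND_REFLECTANCE, MultibandImage
from .speclib import (DEFAULT_ENDMEMBER_ORDER, ContinuousSpectrum,
                      EndmemberLibrary, build_library)
from .unmix import AbundanceMap, PlotLayout, PlotROI


class ConfigurationError(ValueError):
    pass


#: Anchor wavelengths (nm) for the parametric endmember spectra.
_ANCHOR_W = np.array([450, 490, 520, 550, 600, 650, 670, 690, 720,
                      750, 780, 800, 850, 900, 950, 1000], dtype=float)

# Anchor reflectances. Shapes encode the qualitative orderings seen in
# ground spectra: leaf blue ~0.07 vs panicle ~0.05; panicle red above
# leaf red; leaf NIR well above panicle NIR; bottom layers darker than
# top at all wavelengths with BL NIR > BP NIR; soils monotone-ish in
# wavelength. BL is not a pure scaling of TL (its NIR is relatively
# darker), so the top/bottom leaf balance moves red-edge indices.
# Panicles (green at early heading) depress absolute NIR and raise red,
# but their red-edge chromatic ratio matches the canopy mean
# (NDRE(TP) = NDRE(BP) ~ 0.45), so red-edge indices respond to the
# greenness latent rather than to panicle fraction; the panicle signal
# reaches yield through the abundance terms, which is what makes
# VI * (Abd_L - Abd_P) the correctly specified yield predictor.
_ANCHOR_R = {
    "TL": [0.050, 0.070, 0.090, 0.120, 0.080, 0.055, 0.050, 0.070, 0.180,
           0.380, 0.470, 0.500, 0.500, 0.480, 0.470, 0.460],
    "BL": [0.032, 0.045, 0.056, 0.075, 0.050, 0.035, 0.032, 0.045, 0.100,
           0.170, 0.210, 0.220, 0.220, 0.210, 0.205, 0.200],
    "TP": [0.045, 0.050, 0.060, 0.090, 0.085, 0.082, 0.080, 0.085, 0.133,
           0.280, 0.330, 0.350, 0.350, 0.340, 0.335, 0.330],
    "BP": [0.025, 0.028, 0.033, 0.050, 0.047, 0.045, 0.044, 0.047, 0.073,
           0.154, 0.182, 0.192, 0.192, 0.187, 0.184, 0.182],
    "DS": [0.120, 0.150, 0.160, 0.180, 0.200, 0.215, 0.220, 0.225, 0.240,
           0.250, 0.260, 0.270, 0.280, 0.290, 0.300, 0.310],
}
_NITROGEN_LEVELS_KG_HA = (0.0, 3.0, 5.5, 8.5, 11.0, 14.0, 16.5, 19.5)


def generate_endmember_library(seed: int,
                               band_range: tuple[float, float] = (450.0, 1000.0),
                               grid_step: float = 1.0,
                               jitter: float = 0.015) -> list[ContinuousSpectrum]:
    """Six smooth endmember spectra with seeded small-amplitude variation.

    ``band_range`` must cover 480–910 nm so every default camera band
    is resolvable. The seeded jitter is a smooth multiplicative
    perturbation of at most ~``jitter`` relative amplitude — small
    enough that the qualitative orderings between endmembers hold for
    every seed.
    """
    lo, hi = band_range
    if lo > 480.0 or hi < 910.0:
        raise ConfigurationError(
            f"band_range {band_range} must cover at least 480–910 nm")
    lo = min(lo, _ANCHOR_W[0])
    hi = max(hi, _ANCHOR_W[-1])
    rng = np.random.default_rng(seed)
    w = np.arange(lo, hi + grid_step / 2, grid_step)
    spectra = []
    base = dict(_ANCHOR_R)
    # wet soil: dry soil scaled by a wavelength-dependent factor < 1
    ws_factor = 0.52 + 0.10 * (_ANCHOR_W - 450.0) / 550.0
    base["WS"] = list(np.asarray(base["DS"]) * ws_factor)
    for name in DEFAULT_ENDMEMBER_ORDER:
        smooth = PchipInterpolator(_ANCHOR_W, base[name])(w)
        # smooth multiplicative jitter: a few broad Gaussian bumps
        bump = np.zeros_like(w)
        for _ in range(3):
            center = rng.uniform(lo, hi)
            width = rng.uniform(60.0, 150.0)
            amp = rng.uniform(-jitter, jitter)
            bump += amp * np.exp(-0.5 * ((w - center) / width) ** 2)
        spectra.append(ContinuousSpectrum(
            name=name, wavelengths=w,
            reflectance=np.clip(smooth * (1.0 + bump), 0.0, None)))
    return spectra


@dataclass
class SceneConfig:
    """All knobs of the synthetic scene; defaults are the study conditions."""

    n_nitrogen_levels: int = 8
    replicates: int = 3
    plot_rows: int = 150
    plot_cols: int = 120
    ridge: int = 8               # soil ridge width between plots, px
    panel_size: int = 40         # calibration panel edge, px
    noise_sd_dn: float = 2.0     # Gaussian DN noise
    gain: tuple[float, ...] = (0.0008, 0.0009, 0.0010, 0.0011, 0.0012, 0.0010)
    offset: tuple[float, ...] = (-0.02, -0.01, 0.0, 0.01, 0.02, 0.005)
    panel_reflectances: tuple[float, ...] = DEFAULT_PANEL_REFLECTANCES
    # abundance model
    panicle_base: float = 0.005
    panicle_span: float = 0.155      # panicle share = base + span * u^2
    soil_in_plot: float = 0.01       # DS+WS share inside plot ROIs
    greenness_base: float = 0.60
    greenness_span: float = 0.10     # C = base + span * u + N(0, greenness_noise_sd)
    greenness_noise_sd: float = 0.05
    field_noise_sd: float = 0.25     # log-abundance field sd before softmax
    field_smooth_sigma: float = 2.0  # spatial smoothing of the fields, px
    # yield model: yield = beta0 + beta1 * C * (Abd_L - Abd_P) + eps
    yield_beta0: float = -0.32
    yield_beta1: float = 7.0
    yield_noise_sd: float = 0.15
    seed: int = 0
    bands: BandSet = field(default_factory=lambda: DEFAULT_BANDS)

    def __post_init__(self) -> None:
        if self.n_nitrogen_levels < 1 or self.replicates < 1:
            raise ConfigurationError("counts must be >= 1")
        if min(self.plot_rows, self.plot_cols, self.ridge, self.panel_size) < 1:
            raise ConfigurationError("geometry sizes must be >= 1")
        if self.noise_sd_dn < 0:
            raise ConfigurationError("noise_sd_dn must be >= 0")
        if len(self.gain) != self.bands.n_bands or len(self.offset) != self.bands.n_bands:
            raise ConfigurationError("gain/offset must have one value per band")
        if any(g <= 0 for g in self.gain):
            raise ConfigurationError("gains must be positive")

    @property
    def n_plots(self) -> int:
        return self.n_nitrogen_levels * self.replicates

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["bands"] = {"centers": list(self.bands.centers), "width": self.bands.width}
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SceneConfig":
        d = json.loads(Path(path).read_text())
        b = d.pop("bands")
        for key in ("gain", "offset", "panel_reflectances"):
            d[key] = tuple(d[key])
        return cls(bands=BandSet(centers=tuple(b["centers"]), width=b["width"]), **d)


@dataclass
class SceneTruth:
    """A generated scene plus everything needed to verify the pipeline."""

    config: SceneConfig
    dn_image: MultibandImage
    reflectance_image: MultibandImage     # noise-free true mixture reflectance
    true_abundance: AbundanceMap
    layout: PlotLayout
    panel_set: CalibrationTargetSet
    true_plot_table: pd.DataFrame
    true_calibration: CalibrationModel
    spectra: list[ContinuousSpectrum]
    library: EndmemberLibrary


def _scene_geometry(cfg: SceneConfig):
    """Plot grid and panel rectangles. Returns (rows, cols, plot_rects, panel_rects)."""
    n = cfg.n_plots
    grid_rows = max(1, int(np.floor(np.sqrt(n))))
    grid_cols = int(np.ceil(n / grid_rows))
    strip = cfg.ridge + cfg.panel_size
    rows = strip + cfg.ridge + grid_rows * (cfg.plot_rows + cfg.ridge)
    cols = cfg.ridge + grid_cols * (cfg.plot_cols + cfg.ridge)
    plot_rects = []
    for k in range(n):
        i, j = divmod(k, grid_cols)
        r0 = strip + cfg.ridge + i * (cfg.plot_rows + cfg.ridge)
        c0 = cfg.ridge + j * (cfg.plot_cols + cfg.ridge)
        plot_rects.append((r0, c0, cfg.plot_rows, cfg.plot_cols))
    n_panels = len(cfg.panel_reflectances)
    gap = max(cfg.ridge, (cols - n_panels * cfg.panel_size) // (n_panels + 1))
    panel_rects = []
    for k in range(n_panels):
        c0 = gap + k * (cfg.panel_size + gap)
        c0 = min(c0, cols - cfg.panel_size)
        panel_rects.append((cfg.ridge, c0, cfg.panel_size, cfg.panel_size))
    return rows, cols, plot_rects, panel_rects


def _smooth_field(rng: np.random.Generator, shape, sigma: float, sd: float) -> np.ndarray:
    """Smoothed Gaussian field rescaled to standard deviation ``sd``."""
    g = rng.standard_normal(shape)
    g = gaussian_filter(g, sigma=sigma, mode="reflect")
    s = g.std()
    return g * (sd / s) if s > 0 else g


def _softmax_abundance(log_means: np.ndarray, fields: np.ndarray) -> np.ndarray:
    """Softmax of log means + noise fields -> non-negative, sum-to-one."""
    z = log_means[None, None, :] + np.moveaxis(fields, 0, 2)
    z -= z.max(axis=2, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=2, keepdims=True)


def generate_scene(config: SceneConfig | None = None) -> SceneTruth:
    """Generate a full synthetic scene; a pure function of the config."""
    cfg = config if config is not None else SceneConfig()
    rng = np.random.default_rng(cfg.seed)
    spectra = generate_endmember_library(int(rng.integers(2 ** 31)))
    library = build_library(spectra, cfg.bands)
    names = library.names
    n_em = library.n_endmembers
    rows, cols, plot_rects, panel_rects = _scene_geometry(cfg)

    # nitrogen levels assigned to plots in seeded random spatial order
    if cfg.n_nitrogen_levels == len(_NITROGEN_LEVELS_KG_HA):
        level_values = _NITROGEN_LEVELS_KG_HA
    else:
        level_values = tuple(np.linspace(0.0, 19.5, cfg.n_nitrogen_levels))
    level_idx = np.repeat(np.arange(cfg.n_nitrogen_levels), cfg.replicates)
    rng.shuffle(level_idx)

    # background (ridges): soil-dominated mixture
    bg_mean = np.array([0.01, 0.03, 0.005, 0.005, 0.55, 0.40])
    fields = np.stack([_smooth_field(rng, (rows, cols), cfg.field_smooth_sigma,
                                     cfg.field_noise_sd) for _ in range(n_em)])
    abund = _softmax_abundance(np.log(bg_mean), fields)

    denom = max(cfg.n_nitrogen_levels - 1, 1)
    plot_records = []
    layout_plots = []
    for k, (rect, lv) in enumerate(zip(plot_rects, level_idx)):
        u = lv / denom
        p_share = cfg.panicle_base + cfg.panicle_span * u ** 2
        leaf_share = 1.0 - p_share - cfg.soil_in_plot
        greenness = float(np.clip(
            cfg.greenness_base + cfg.greenness_span * u
            + rng.normal(0.0, cfg.greenness_noise_sd), 0.40, 0.90))
        mean_vec = np.array([
            greenness * leaf_share,            # TL
            (1.0 - greenness) * leaf_share,    # BL
            0.7 * p_share,                     # TP
            0.3 * p_share,                     # BP
            0.6 * cfg.soil_in_plot,            # DS
            0.4 * cfg.soil_in_plot,            # WS
        ])
        r0, c0, nr, nc = rect
        plot_fields = np.stack([
            _smooth_field(rng, (nr, nc), cfg.field_smooth_sigma, cfg.field_noise_sd)
            for _ in range(n_em)])
        abund[r0:r0 + nr, c0:c0 + nc, :] = _softmax_abundance(
            np.log(mean_vec), plot_fields)
        plot_id = f"P{k + 1:02d}"
        layout_plots.append(PlotROI(plot_id=plot_id,
                                    nitrogen=float(level_values[lv]), rect=rect))
        plot_records.append({"plot_id": plot_id, "nitrogen": float(level_values[lv]),
                             "nitrogen_level": int(lv), "greenness": greenness,
                             "rect": rect})

    # true mixture reflectance, then uniform panels
    refl = abund @ library.matrix
    panel_set = CalibrationTargetSet(
        panels=[(nom, rect) for nom, rect in zip(cfg.panel_reflectances, panel_rects)])
    for nom, (r0, c0, nr, nc) in panel_set.panels:
        refl[r0:r0 + nr, c0:c0 + nc, :] = nom

    gain = np.asarray(cfg.gain)
    offset = np.asarray(cfg.offset)
    dn = (refl - offset) / gain
    if cfg.noise_sd_dn > 0:
        dn = dn + rng.normal(0.0, cfg.noise_sd_dn, size=dn.shape)

    # truth table: per-plot abundance means, latent greenness, yield
    table_rows = []
    for rec in plot_records:
        r0, c0, nr, nc = rec["rect"]
        means = abund[r0:r0 + nr, c0:c0 + nc, :].reshape(-1, n_em).mean(axis=0)
        row = {"plot_id": rec["plot_id"], "nitrogen": rec["nitrogen"],
               "nitrogen_level": rec["nitrogen_level"],
               "greenness": rec["greenness"]}
        row.update(dict(zip(names, means)))
        row["Abd_L"] = row["TL"] + row["BL"]
        row["Abd_P"] = row["TP"] + row["BP"]
        row["Abd_L-P"] = row["Abd_L"] - row["Abd_P"]
        row["true_predictor"] = rec["greenness"] * row["Abd_L-P"]
        table_rows.append(row)
    table = pd.DataFrame.from_records(table_rows)
    eps = rng.normal(0.0, cfg.yield_noise_sd, size=len(table)) \
        if cfg.yield_noise_sd > 0 else np.zeros(len(table))
    table["yield"] = (cfg.yield_beta0
                      + cfg.yield_beta1 * table["true_predictor"].to_numpy() + eps)

    residual = np.zeros((rows, cols))
    return SceneTruth(
        config=cfg,
        dn_image=MultibandImage(values=dn, bands=cfg.bands, kind=KIND_DN),
        reflectance_image=MultibandImage(values=refl, bands=cfg.bands,
                                         kind=KIND_REFLECTANCE),
        true_abundance=AbundanceMap(values=abund, residual_norm=residual, names=names),
        layout=PlotLayout(plots=layout_plots),
        panel_set=panel_set,
        true_plot_table=table,
        true_calibration=CalibrationModel(gain=gain, offset=offset),
        spectra=spectra,
        library=library,
    )
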