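"""Synthetic calibration standards: design, mixture spectra, GC areas.

The generator emulates the laboratory workflow for building a PLS
calibration with no real samples: a set of aqueous standards containing
ethanol (2-10 % w/w) and four sugars — glucose, fructose, sucrose, maltose
(0-5 % w/w each) — drawn independently (uncorrelated design), measured in
the 1200-850 cm^-1 fingerprint region at 1 cm^-1 spacing (351 points) in
triplicate.

Mixture spectra follow Beer-Lambert additivity: the absorbance at each
wavenumber is the concentration-weighted sum of Gaussian-band pure-component
spectra, plus optional smooth polynomial baseline drift (per replicate) and
i.i.d. Gaussian instrument noise.  Band positions are literature-informed;
widths and amplitudes are documented synthetic fixtures (see
``data/default_bands.yaml``) with deliberate sugar-ethanol overlap at
1000-1100 cm^-1 — the interference that motivates multivariate rather than
single-wavenumber calibration.

All randomness flows from the single ``SimConfig.seed``: identical configs
give bit-identical datasets.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .exceptions import DomainError
from .gc_calibration import CalibrationCurve
from .spectra_io import SpectrumSet, WavenumberGrid

COMPONENTS = ("ethanol", "glucose", "fructose", "sucrose", "maltose")

#: Composition ranges (% w/w) of the design space.
ETHANOL_RANGE = (2.0, 10.0)
SUGAR_RANGE = (0.0, 5.0)


@dataclass(frozen=True)
class MixtureComposition:
    """Five-component standard, concentrations in % w/w."""

    ethanol: float
    glucose: float
    fructose: float
    sucrose: float
    maltose: float

    def __post_init__(self) -> None:
        for name in COMPONENTS:
            if getattr(self, name) < 0:
                raise DomainError(f"{name} concentration must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in COMPONENTS])


BandModel = dict[str, list[dict]]  # component -> [{center, width, amplitude}, ...]


def default_band_model() -> BandModel:
    """Load the packaged synthetic band model."""
    ref = importlib.resources.files("mirpls").joinpath("data/default_bands.yaml")
    model = yaml.safe_load(ref.read_text())
    validate_band_model(model)
    return model


def load_band_model(path) -> BandModel:
    with open(path) as fh:
        model = yaml.safe_load(fh)
    validate_band_model(model)
    return model


def validate_band_model(model: BandModel) -> None:
    for component, bands in model.items():
        if not bands:
            raise DomainError(f"{component}: empty band list")
        for band in bands:
            if band["width"] <= 0 or band["amplitude"] < 0:
                raise DomainError(f"{component}: bands need width > 0, amplitude >= 0")


@dataclass
class SimConfig:
    """Study conditions for one simulated calibration campaign."""

    n_standards: int = 25
    grid_low: float = 850.0
    grid_high: float = 1200.0
    grid_spacing: float = 1.0
    noise_sigma: float = 5e-4          # AU, i.i.d. per point
    baseline_amplitude: float = 0.0    # AU, quadratic drift per replicate
    replicate_count: int = 3
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_standards < 3:
            raise DomainError("need at least 3 standards")
        if self.noise_sigma < 0 or self.baseline_amplitude < 0:
            raise DomainError("noise and baseline amplitudes must be >= 0")
        if self.replicate_count < 1:
            raise DomainError("replicate_count must be >= 1")

    def grid(self) -> WavenumberGrid:
        return WavenumberGrid.from_range(self.grid_low, self.grid_high, self.grid_spacing)


def generate_design(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the standard compositions: uniform, independent per component.

    Ethanol is uniform on [2, 10] % w/w, each sugar uniform on [0, 5];
    independence makes the design uncorrelated by construction.  Returns a
    DataFrame with a ``standard_id`` index and one column per component.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_standards
    data = {"ethanol": rng.uniform(*ETHANOL_RANGE, size=n)}
    for sugar in COMPONENTS[1:]:
        data[sugar] = rng.uniform(*SUGAR_RANGE, size=n)
    ids = [f"std{i + 1:02d}" for i in range(n)]
    return pd.DataFrame(data, index=pd.Index(ids, name="standard_id"))


def design_correlations(design: pd.DataFrame) -> pd.DataFrame:
    """Pairwise sample correlations of the design (diagnostic)."""
    return design.corr()


def pure_component_spectrum(
    component: str, grid: WavenumberGrid, band_model: BandModel | None = None
) -> np.ndarray:
    """Absorbance spectrum of one component at 1 % w/w (sum of Gaussians)."""
    if band_model is None:
        band_model = default_band_model()
    if component not in band_model:
        raise DomainError(
            f"unknown component {component!r}; band model has {sorted(band_model)}"
        )
    nu = grid.values
    spectrum = np.zeros_like(nu)
    for band in band_model[component]:
        spectrum += band["amplitude"] * np.exp(
            -((nu - band["center"]) ** 2) / (2.0 * band["width"] ** 2)
        )
    return spectrum


def simulate_dataset(
    config: SimConfig | None = None,
    band_model: BandModel | None = None,
    design: pd.DataFrame | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Simulate a replicated calibration campaign.

    Returns (spectra, design).  Each standard appears ``replicate_count``
    times with ids ``stdNN_rK`` and a ``replicate_of`` mapping back to
    ``stdNN``; replicates share the composition and the noiseless mixture
    spectrum but get independent noise (and, when enabled, an independent
    smooth quadratic baseline emulating between-measurement drift).
    """
    if config is None:
        config = SimConfig()
    if band_model is None:
        band_model = default_band_model()
    rng = np.random.default_rng(config.seed)
    if design is None:
        design = generate_design(config, rng=rng)
    grid = config.grid()
    pures = np.vstack(
        [pure_component_spectrum(c, grid, band_model) for c in COMPONENTS]
    )  # (5, p)
    clean = design[list(COMPONENTS)].to_numpy() @ pures  # (n, p)

    n_rep = config.replicate_count
    ids: list[str] = []
    replicate_of: dict[str, str] = {}
    rows = []
    u = np.linspace(-1.0, 1.0, len(grid))
    for i, std_id in enumerate(design.index):
        for r in range(n_rep):
            sid = f"{std_id}_r{r + 1}" if n_rep > 1 else str(std_id)
            spectrum = clean[i].copy()
            if config.baseline_amplitude > 0:
                b0, b1, b2 = rng.uniform(
                    -config.baseline_amplitude, config.baseline_amplitude, size=3
                )
                spectrum = spectrum + b0 + b1 * u + b2 * u**2
            if config.noise_sigma > 0:
                spectrum = spectrum + rng.normal(0.0, config.noise_sigma, size=len(grid))
            ids.append(sid)
            replicate_of[sid] = str(std_id)
            rows.append(spectrum)
    sset = SpectrumSet(
        grid=grid,
        absorbance=np.vstack(rows),
        sample_ids=ids,
        replicate_of=replicate_of,
    )
    return sset, design


def simulate_gc_areas(
    concentrations,
    curve: CalibrationCurve,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Peak-area ratios from a calibration line plus Gaussian noise."""
    x = np.asarray(concentrations, dtype=float).ravel()
    ratios = curve.slope * x + curve.intercept
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        ratios = ratios + rng.normal(0.0, noise_sigma, size=x.size)
    return ratios
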