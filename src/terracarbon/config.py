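"""Configuration objects for the synthetic world and the pipeline.

All stochastic components are driven by an explicit integer seed carried in
the configuration; no global random state is used anywhere in the package.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml


@dataclass(frozen=True)
class DeltaSocModel:
    """Linear model mapping aridity index (AI = MAP/PET) to expected ΔSOC (%).

    Expected site-level change is ``intercept + slope * ai`` with Gaussian
    site-to-site noise of standard deviation ``site_sd``.  The defaults place
    the arid end of the gradient near zero-to-negative change and the humid
    end strongly positive, with enough scatter that the AI regression
    explains roughly 60 % of site variance.
    """

    slope: float = 57.0  # % per AI unit
    intercept: float = -38.0  # %
    site_sd: float = 18.0  # %

    def __post_init__(self) -> None:
        if self.site_sd < 0:
            raise ValueError("site_sd must be >= 0")

    def expected(self, ai: float) -> float:
        return self.intercept + self.slope * ai


@dataclass(frozen=True)
class BiasParams:
    """Linear bias linking gridded-product ΔSOC to field ΔSOC.

    field = alpha + beta * gridded + N(0, sigma) by construction.
    """

    alpha: float = 5.0  # intercept, %
    beta: float = 0.8  # slope, dimensionless
    sigma: float = 10.0  # residual SD, %

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.beta == 0:
            raise ValueError("beta must be nonzero")


@dataclass(frozen=True)
class WorldConfig:
    """Full parameterization of a synthetic terracing study.

    Defaults emulate the field campaign the analysis was designed for:
    14 terrace sites along a European aridity gradient (AI 0.32-2.17),
    cut/fill/control soil profiles excavated to ~1 m in 10 cm slices, a
    gridded control product biased against field measurements, and FTIR /
    phenology / literature side-channels.
    """

    n_sites: int = 14
    ai_range: tuple[float, float] = (0.32, 2.17)
    delta_soc_model: DeltaSocModel = field(default_factory=DeltaSocModel)
    bias: BiasParams = field(default_factory=BiasParams)
    n_profiles_per_position: int = 1
    depth_max: float = 100.0  # cm
    layer_thickness: float = 10.0  # cm
    seed: int = 0

    # profile shape
    soc_surface_base: float = 0.8  # % at AI=0
    soc_surface_per_ai: float = 1.2  # % per AI unit
    soc_efold_depth: float = 35.0  # cm, e-folding depth of SOC decay
    fill_bump_rel: float = 0.30  # buried-topsoil bump height / surface SOC
    fill_bump_center: float = 50.0  # cm
    fill_bump_width: float = 12.0  # cm (Gaussian SD)
    cut_depletion_arid: float = 0.45  # surface SOC loss fraction, arid end
    cut_depletion_humid: float = 0.10  # surface SOC loss fraction, humid end

    # noise levels
    soc_noise_sd: float = 0.12  # lognormal sigma on SOC per horizon
    geochem_noise_sd: float = 0.25  # lognormal sigma on covariates
    bd_noise_sd: float = 0.08  # g cm^-3, additive on measured BD
    profile_corr_sd: float = 0.0  # within-site profile random effect (knob)

    # gridded product
    n_pixels: int = 10
    pixel_sd: float = 8.0  # % ΔSOC, pixel-to-pixel spread
    n_measured_sites: int = 9  # sites with field control profiles

    # bulk density ground truth (pedotransfer target)
    bd_coefs: tuple[float, float, float, float] = (-0.1, 0.002, 0.001, 1.4)
    frac_sites_bd_measured: float = 0.45

    def __post_init__(self) -> None:
        if self.n_sites < 3:
            raise ValueError("n_sites must be >= 3")
        lo, hi = self.ai_range
        if not (0 < lo < hi):
            raise ValueError("ai_range must satisfy 0 < lo < hi")
        if lo < 0.2:
            raise ValueError(
                "ai_range lower bound < 0.2: extremely arid sites are out of scope"
            )
        if self.depth_max <= 0:
            raise ValueError("depth_max must be > 0")
        n_layers = self.depth_max / self.layer_thickness
        if abs(n_layers - round(n_layers)) > 1e-9:
            raise ValueError("layer_thickness must divide depth_max")
        for name in ("soc_noise_sd", "geochem_noise_sd", "bd_noise_sd",
                     "profile_corr_sd", "pixel_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_measured_sites > self.n_sites:
            object.__setattr__(self, "n_measured_sites", self.n_sites)

    def with_seed(self, seed: int) -> "WorldConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _config_from_mapping(data: dict[str, Any]) -> WorldConfig:
    data = dict(data)
    if "delta_soc_model" in data and isinstance(data["delta_soc_model"], dict):
        data["delta_soc_model"] = DeltaSocModel(**data["delta_soc_model"])
    if "bias" in data and isinstance(data["bias"], dict):
        data["bias"] = BiasParams(**data["bias"])
    if "ai_range" in data:
        data["ai_range"] = tuple(data["ai_range"])
    if "bd_coefs" in data:
        data["bd_coefs"] = tuple(data["bd_coefs"])
    known = WorldConfig.__dataclass_fields__.keys()
    unknown = sorted(set(data) - set(known))
    if unknown:
        raise ValueError(f"unknown configuration keys: {unknown}")
    return WorldConfig(**data)


def load_config(path: str | Path) -> "PipelineConfig":
    """Load a pipeline configuration from YAML.

    Schema (all keys optional)::

        seed: 0
        outdir: runs/demo
        world: { n_sites: 14, ai_range: [0.32, 2.17], ... }
        imputation: { m_draws: 1000, n_rep: 1000, exclusions: [] }
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    errors = []
    world = raw.get("world", {})
    try:
        world_cfg = _config_from_mapping(world) if world else WorldConfig()
    except (TypeError, ValueError) as exc:
        errors.append(f"world: {exc}")
        world_cfg = WorldConfig()
    imput = raw.get("imputation", {})
    known_imp = {"m_draws", "n_rep", "exclusions"}
    bad = sorted(set(imput) - known_imp)
    if bad:
        errors.append(f"imputation: unknown keys {bad}")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))
    seed = int(raw.get("seed", world_cfg.seed))
    world_cfg = world_cfg.with_seed(seed)
    return PipelineConfig(
        seed=seed,
        outdir=Path(raw.get("outdir", "runs/latest")),
        world=world_cfg,
        m_draws=int(imput.get("m_draws", 1000)),
        n_rep=int(imput.get("n_rep", 1000)),
        exclusions=tuple(imput.get("exclusions", ())),
    )


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: Path = Path("runs/latest")
    world: WorldConfig = field(default_factory=WorldConfig)
    m_draws: int = 1000
    n_rep: int = 1000
    exclusions: tuple[str, ...] = ()
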