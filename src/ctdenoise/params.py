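"""Parameter containers for the two filtering stages and the pipeline.

Defaults reproduce the published operating point of the method:
patch half-width ``P = 5``, search half-width ``K = 3``, filtering
strength ``h = 0.15`` for the non-local means stage, and amplitude
threshold ``t = 0.15``, size coefficient ``s_size = 3`` px, contrast
coefficient ``c = 1.2`` for the morphological residual stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

from .errors import ParameterError

BoundaryMode = Literal["symmetric", "periodic"]
Connectivity = Literal[4, 8]


@dataclass(frozen=True)
class NLMParams:
    """Non-local means parameters.

    Attributes
    ----------
    K : int
        Search-window half-width; the window holds ``(2K+1)**2`` translations.
    P : int
        Patch half-width; similarity is measured over ``(2P+1)**2`` pixels.
    h : float
        Filtering strength of the rational kernel ``g_h(x) = 1/(1 + x**2/h**2)``.
    boundary : {"symmetric", "periodic"}
        How the image is extended before filtering.  ``symmetric`` replicates
        edges by mirror reflection; ``periodic`` wraps around.
    """

    K: int = 3
    P: int = 5
    h: float = 0.15
    boundary: BoundaryMode = "symmetric"

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ParameterError(f"K must be >= 0, got {self.K}")
        if self.P < 0:
            raise ParameterError(f"P must be >= 0, got {self.P}")
        if not (self.h > 0):
            raise ParameterError(f"h must be > 0, got {self.h}")
        if self.boundary not in ("symmetric", "periodic"):
            raise ParameterError(f"unknown boundary mode {self.boundary!r}")

    @property
    def margin(self) -> int:
        """Boundary extension required so every patch in the search window exists."""
        return self.K + self.P


@dataclass(frozen=True)
class MorphParams:
    """Morphological residual-processing parameters.

    ``t`` is the amplitude threshold on the residual (intensity units on the
    [0, 1] scale), ``s_size`` the minimum connected-component area in pixels
    kept by the area opening, ``c`` the contrast coefficient multiplying the
    restored residual, ``lowpass_sigma`` the Gaussian lowpass width in pixels
    (kernel truncated at radius ``ceil(3*sigma)``), and ``connectivity`` the
    pixel adjacency (4 or 8) used by both the area opening and the
    reconstruction.
    """

    t: float = 0.15
    s_size: int = 3
    c: float = 1.2
    lowpass_sigma: float = 1.5
    connectivity: Connectivity = 8

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ParameterError(f"t must be >= 0, got {self.t}")
        if self.s_size < 1:
            raise ParameterError(f"s_size must be >= 1, got {self.s_size}")
        if self.c < 0:
            raise ParameterError(f"c must be >= 0, got {self.c}")
        if not (self.lowpass_sigma > 0):
            raise ParameterError(f"lowpass_sigma must be > 0, got {self.lowpass_sigma}")
        if self.connectivity not in (4, 8):
            raise ParameterError(f"connectivity must be 4 or 8, got {self.connectivity}")

    @property
    def lowpass_radius(self) -> int:
        """Truncation radius of the Gaussian lowpass kernel, in pixels."""
        return math.ceil(3 * self.lowpass_sigma)


@dataclass(frozen=True)
class TileSpec:
    """Tiling of the linear stages (NLM + lowpass) for parallel-style evaluation.

    ``halo`` pixels of context are read around every tile; it must cover the
    full receptive field of the tiled stages.  ``halo=None`` means "use the
    minimum valid halo" for the pipeline at hand.
    """

    size: int
    halo: int | None = None

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ParameterError(f"tile size must be >= 1, got {self.size}")
        if self.halo is not None and self.halo < 0:
            raise ParameterError(f"halo must be >= 0, got {self.halo}")


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of the two-stage denoising pipeline."""

    nlm: NLMParams = field(default_factory=NLMParams)
    morph: MorphParams = field(default_factory=MorphParams)
    tile: TileSpec | None = None
    seed: int = 0

    # flat key <-> attribute map used by (de)serialization and the CLI
    _FLAT_KEYS = (
        ("K", "nlm", "K"),
        ("P", "nlm", "P"),
        ("h", "nlm", "h"),
        ("boundary", "nlm", "boundary"),
        ("t", "morph", "t"),
        ("s", "morph", "s_size"),
        ("c", "morph", "c"),
        ("lowpass_sigma", "morph", "lowpass_sigma"),
        ("connectivity", "morph", "connectivity"),
    )

    def min_halo(self) -> int:
        """Smallest halo that keeps tiled linear stages exactly equivalent."""
        return self.nlm.margin + self.morph.lowpass_radius

    def to_flat_dict(self) -> dict:
        d: dict = {}
        for key, group, attr in self._FLAT_KEYS:
            d[key] = getattr(getattr(self, group), attr)
        if self.tile is not None:
            d["tile"] = self.tile.size
            d["halo"] = self.tile.halo if self.tile.halo is not None else self.min_halo()
        d["seed"] = self.seed
        return d

    @classmethod
    def from_flat_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        nlm_kw: dict = {}
        morph_kw: dict = {}
        for key, group, attr in cls._FLAT_KEYS:
            if key in d:
                (nlm_kw if group == "nlm" else morph_kw)[attr] = d.pop(key)
        tile = None
        if "tile" in d:
            tile = TileSpec(size=int(d.pop("tile")), halo=d.pop("halo", None))
        seed = int(d.pop("seed", 0))
        if d:
            raise ParameterError(f"unknown config keys: {sorted(d)}")
        return cls(nlm=NLMParams(**nlm_kw), morph=MorphParams(**morph_kw), tile=tile, seed=seed)

    def to_toml(self) -> str:
        """Serialize as a flat TOML document (round-trips via :meth:`from_toml`)."""
        lines = []
        for key, value in self.to_flat_dict().items():
            if isinstance(value, str):
                lines.append(f'{key} = "{value}"')
            elif isinstance(value, bool):
                lines.append(f"{key} = {str(value).lower()}")
            else:
                lines.append(f"{key} = {value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_toml(cls, text: str) -> "PipelineConfig":
        import tomllib

        return cls.from_flat_dict(tomllib.loads(text))

    def with_overrides(self, **flat: object) -> "PipelineConfig":
        """Return a config with the given flat keys replaced (None values ignored)."""
        d = self.to_flat_dict()
        if self.tile is None:
            d.pop("tile", None)
            d.pop("halo", None)
        for k, v in flat.items():
            if v is not None:
                d[k] = v
        return self.from_flat_dict(d)


def default_config() -> PipelineConfig:
    return PipelineConfig()


__all__ = [
    "NLMParams",
    "MorphParams",
    "TileSpec",
    "PipelineConfig",
    "BoundaryMode",
    "Connectivity",
    "default_config",
    "replace",
]
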