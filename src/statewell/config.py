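"""Model parameter sets and their flat key-value config format.

A parameter set pins down the Langevin model: well depth ``h``, separation
endpoints ``d1``/``d2`` and tilt endpoints ``a1``/``a2`` of the latent map,
noise intensity ``D`` and integration step ``dt``.  Two published
configurations are shipped as module constants: ``FISH_A`` (a sedentary
individual; both tilt and separation are modulated by the latent variable)
and ``FISH_B`` (an active individual; only the tilt is modulated, the
separation is constant).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

from .latent import LatentTrajectory
from .potential import LatentMap

__all__ = ["ModelParams", "FISH_A", "FISH_B", "read_params", "write_params"]

_KEYS = ("h", "d1", "d2", "a1", "a2", "D", "dt")


@dataclass(frozen=True)
class ModelParams:
    h: float
    d1: float
    d2: float
    a1: float
    a2: float
    D: float
    dt: float = 0.01

    def latent_map(self, latent: LatentTrajectory) -> LatentMap:
        """Latent map anchored to the trajectory's observed extrema."""
        return LatentMap(
            s_min=latent.s_min,
            s_max=latent.s_max,
            a1=self.a1,
            a2=self.a2,
            d1=self.d1,
            d2=self.d2,
        )

    @property
    def mid_tilt(self) -> float:
        return 0.5 * (self.a1 + self.a2)

    @property
    def mid_separation(self) -> float:
        return 0.5 * (self.d1 + self.d2)


#: Sedentary individual: latent-coupled separation (d1 != d2), low noise.
FISH_A = ModelParams(h=-0.08, d1=0.3, d2=0.6, a1=0.12, a2=-0.1, D=0.02)

#: Active individual: constant separation, higher noise.
FISH_B = ModelParams(h=-0.32, d1=0.5, d2=0.5, a1=0.07, a2=-0.1, D=0.1)


def read_params(path: str | Path) -> ModelParams:
    """Read a flat ``key = value`` config file with keys h, d1, d2, a1, a2, D, dt.

    Lines starting with '#' are comments.  Unknown keys are rejected.
    """
    values: dict[str, float] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value', got {line!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _KEYS:
            raise ValueError(f"{path}:{ln}: unknown parameter {key!r}")
        if key in values:
            raise ValueError(f"{path}:{ln}: duplicate parameter {key!r}")
        values[key] = float(val)
    missing = [k for k in _KEYS if k not in values and k != "dt"]
    if missing:
        raise ValueError(f"{path}: missing parameters {missing}")
    return ModelParams(**values)


def write_params(params: ModelParams, path: str | Path) -> None:
    lines = [f"{k} = {v!r}" for k, v in asdict(params).items()]
    Path(path).write_text("\n".join(lines) + "\n")
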