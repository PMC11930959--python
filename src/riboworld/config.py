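"""Run configuration: every model parameter plus seeding and output cadence."""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .chemistry import ChemistryParams
from .surface import MCRSParams
from .transition import TransitionParams
from .vesicles import SCMParams

__all__ = ["RunConfig"]

log = logging.getLogger("riboworld")

#: documented ranges of the headline parameters; values outside are
#: accepted with a logged warning
_RANGES = {
    "A": (3, 10),
    "Z": (2, 1000),
    "N_met": (1, 161),
    "N_rep": (1, 161),
    "D": (0, 4),
    "N": (1, 1000),
    "S": (2, 100),
}


@dataclass
class RunConfig:
    """Complete, YAML-round-trippable description of one run."""

    A: int = 7
    seed: int = 0
    generations: int = 1000        # MCRS generations or SCM timesteps
    record_every: int = 10
    backend: str = "auto"          # folding backend: auto | vienna | nussinov
    pool_size: int = 10_000
    lam: float = 45.0              # Poisson length parameter of random pools
    fill_fraction: float = 0.8
    enrich_target: float = 0.8
    chemistry: ChemistryParams = field(default_factory=ChemistryParams)
    mcrs: MCRSParams = field(default_factory=MCRSParams)
    scm: SCMParams = field(default_factory=SCMParams)
    transition: TransitionParams = field(default_factory=TransitionParams)

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            value = self._lookup(name)
            if value is not None and not lo <= value <= hi:
                warnings.warn(
                    f"parameter {name}={value} outside the documented range "
                    f"[{lo}, {hi}]; proceeding with the override",
                    stacklevel=2,
                )

    def _lookup(self, name: str):
        if hasattr(self, name):
            return getattr(self, name)
        for block in (self.mcrs, self.scm):
            if hasattr(block, name):
                return getattr(block, name)
        return None

    # -- YAML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        kwargs = {}
        for name, sub in (
            ("chemistry", ChemistryParams),
            ("mcrs", MCRSParams),
            ("scm", SCMParams),
            ("transition", TransitionParams),
        ):
            if name in data:
                kwargs[name] = sub(**data.pop(name))
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
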