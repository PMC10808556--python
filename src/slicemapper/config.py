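"""Run configuration: the tunable operating point of the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

from .blockmatch import BlockMatchConfig
from .imaging import ContractError
from .similarity import HistogramSpec

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Global pipeline configuration.

    working_pixel_size: registration/similarity resolution in µm (default
    25, a compromise between registration time and retained detail);
    w: rigid-affine weighting (default 0.5, the robust mid-point; strongly
    stained brightfield modalities often favour w = 1);
    s_star: slice count from which a study would support 3D reconstruction
    (None = never, reconstruction is out of scope);
    seed: seed for any stochastic tooling built on top (the pipeline proper
    is deterministic).
    """

    working_pixel_size: float = 25.0
    w: float = 0.5
    similarity: HistogramSpec = field(default_factory=HistogramSpec)
    blockmatch: BlockMatchConfig = field(default_factory=BlockMatchConfig)
    n_workers: int = 1
    seed: int = 0
    s_star: int | None = None
    output_dir: str = "runs"

    def __post_init__(self):
        if self.working_pixel_size <= 0:
            raise ContractError("working_pixel_size must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ContractError("w must be in [0, 1]")
        if self.n_workers < 1:
            raise ContractError("n_workers must be >= 1")

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["similarity"] = asdict(self.similarity)
        d["blockmatch"] = asdict(self.blockmatch)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "similarity" in d and isinstance(d["similarity"], dict):
            d["similarity"] = HistogramSpec(**d["similarity"])
        if "blockmatch" in d and isinstance(d["blockmatch"], dict):
            d["blockmatch"] = BlockMatchConfig(**d["blockmatch"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
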