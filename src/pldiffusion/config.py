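"""Run configuration: validated, YAML round-trippable, unknown keys rejected."""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, model_validator
import yaml

__all__ = ["RunConfig", "load_config", "dump_config", "TINY"]


class RunConfig(BaseModel):
    """All tunables of the model, diffusion process and training loop.

    Attention head width ``sra_head_dim`` (65), head count ``sra_heads`` (4)
    and outer-product hidden width ``opu_hidden`` (32) default to the
    published values; every dimension is configurable.
    """

    model_config = ConfigDict(extra="forbid")

    # representation widths
    c_m: int = Field(64, gt=0, description="single-representation channels")
    c_z: int = Field(32, gt=0, description="pair-representation channels")
    sra_head_dim: int = Field(65, gt=0)
    sra_heads: int = Field(4, gt=0)
    opu_hidden: int = Field(32, gt=0)
    triangle_hidden: int | None = Field(None, description="defaults to c_z")
    n_blocks: int = Field(4, ge=0)

    # featurization
    r_max: int = Field(32, gt=0, description="relative-position clip")
    n_rbf: int = Field(16, gt=0)
    rbf_min: float = 0.0
    rbf_max: float = 20.0
    time_dim: int = Field(16, gt=0, description="sinusoidal time-embedding width (even)")
    embedder_dim: int = Field(32, gt=0, description="per-residue embedder output width")
    weight_mlp_hidden: int = Field(32, gt=0, description="pair-to-weight MLP hidden width")

    # diffusion
    T: int = Field(64, ge=1)
    schedule: str = "cosine"

    # masking / training
    mask_ratio: float = Field(0.15, ge=0.0, le=1.0)
    learning_rate: float = Field(1e-2, gt=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.time_dim % 2 != 0:
            raise ValueError("time_dim must be even (sin/cos halves)")
        if self.rbf_max <= self.rbf_min:
            raise ValueError("rbf_max must exceed rbf_min")
        return self

    @property
    def tri_hidden(self) -> int:
        return self.triangle_hidden if self.triangle_hidden is not None else self.c_z


#: a small configuration used for quick desk-scale runs and examples
TINY = dict(
    c_m=16, c_z=8, sra_head_dim=8, sra_heads=2, opu_hidden=4,
    n_blocks=1, n_rbf=8, time_dim=8, embedder_dim=8, weight_mlp_hidden=16,
)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
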