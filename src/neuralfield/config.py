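"""Validated run configuration (YAML) for reproducible simulations.

A run is fully described by a single structured file: domain, mesh source,
model parameters, initial condition, integration settings, distance backend
and seed.  Unknown keys are rejected so typos fail before any computation.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .geometry import PlaneDomain, TorusDomain
from .model import NeuralFieldParams, PatchSpec


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DomainConfig(_Strict):
    kind: Literal["plane", "torus", "mesh"] = "plane"
    L: float = Field(7.5, gt=0)
    R: float = Field(4.5, gt=0)
    r: float = Field(2.0, gt=0)

    def build(self):
        if self.kind == "plane":
            return PlaneDomain(self.L)
        if self.kind == "torus":
            return TorusDomain(self.R, self.r)
        return None


class MeshConfig(_Strict):
    builtin: Optional[Literal["cartesian", "torus", "irregular"]] = None
    path: Optional[str] = None
    points_per_side: int = Field(33, ge=2)
    n_theta: int = Field(18, ge=3)
    n_phi: int = Field(36, ge=3)
    target_nodes: int = Field(500, ge=10)
    refine: int = Field(0, ge=0)


class KernelConfig(_Strict):
    c2: float = Field(0.17, gt=0, lt=1)
    gamma: float = Field(0.2, gt=0, lt=1)


class ModelConfig(_Strict):
    A: float = 2.0
    B: float = 0.4
    h: float = 0.8
    tau: float = Field(3.0, gt=0)
    beta: float = Field(5.0, gt=0)
    kernel: KernelConfig = KernelConfig()

    def params(self) -> NeuralFieldParams:
        return NeuralFieldParams(
            A=self.A, B=self.B, h=self.h, tau=self.tau, beta=self.beta,
            kernel_c2=self.kernel.c2, kernel_gamma=self.kernel.gamma,
        )


class InitConfig(_Strict):
    kind: Literal["plane", "torus", "nodes"] = "plane"
    u_center: Tuple[float, float] = (0.0, 0.0)
    u_extent: Tuple[float, float] = (2.0, 2.0)
    u_level: float = 1.0
    a_center: Tuple[float, float] = (2.0, 0.0)
    a_extent: Tuple[float, float] = (2.0, 2.0)
    a_level: float = 1.5
    u_node: int = 0
    a_node: int = 0
    fraction: float = Field(0.01, gt=0, le=1)

    def patch(self) -> PatchSpec:
        return PatchSpec(
            kind=self.kind,
            u_center=self.u_center, u_extent=self.u_extent, u_level=self.u_level,
            a_center=self.a_center, a_extent=self.a_extent, a_level=self.a_level,
            u_node=self.u_node, a_node=self.a_node, fraction=self.fraction,
        )


class IntegrationConfig(_Strict):
    T: float = Field(100.0, gt=0)
    rtol: float = Field(1e-6, gt=0)
    atol: float = Field(1e-6, gt=0)
    output_stride: float = Field(1.0, gt=0)
    snapshot_stride: int = Field(50, ge=1)


class DistancesConfig(_Strict):
    backend: Literal["fast_marching", "edge_dijkstra", "exact_plugin"] = "fast_marching"
    cache: Optional[str] = None


class RunConfig(_Strict):
    """Complete, schema-validated description of one simulation run."""

    domain: DomainConfig = DomainConfig()
    mesh: MeshConfig = MeshConfig()
    model: ModelConfig = ModelConfig()
    init: InitConfig = InitConfig()
    integration: IntegrationConfig = IntegrationConfig()
    distances: DistancesConfig = DistancesConfig()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha1(
            yaml.safe_dump(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]
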