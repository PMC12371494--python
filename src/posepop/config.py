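"""Run configuration: one validated document, defaults at the analysis's
canonical values (5 Å bound criterion, 60 % triage cutoff, 1 ns subsampling
of the [100, 200] ns window, k = 2 mixture components, 3 nM probe with K_d
5/7/5 nM for DF2/DC2/DC1), all randomness flowing from one root seed."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ClusteringConfig", "SimulateConfig", "AssayConfig", "TriageConfig"]


@dataclass
class SimulateConfig:
    n_replicates: int = 8
    n_frames_per_replicate: int = 200
    frame_interval: float = 1.0      # ns
    pose_weight_A: float = 0.55
    positional_noise_sd: float = 0.3  # Å
    unbound_fraction: float = 0.1
    unbound_offset: float = 3.0       # Å
    n_docking_poses: int = 20
    planted_binders: int = 5
    assay_true_ic50: float = 1e-5     # M
    assay_noise_cv: float = 0.02
    assay_n_replicates: int = 4


@dataclass
class ClusteringConfig:
    t_start: float | None = None      # ns; default = half the span
    t_end: float | None = None        # ns; default = full span
    interval: float = 1.0             # ns
    threshold: float = 5.0            # Å, strict bound-frame criterion
    k: int = 2


@dataclass
class AssayConfig:
    triage_cutoff: float = 60.0       # % residual signal, strict
    probe_concentration: float = 3e-9  # M
    probe_kd: dict = field(default_factory=lambda: {"DF2": 5e-9, "DC2": 7e-9, "DC1": 5e-9})
    temperature: float = 300.0        # K, for ligand efficiency
    fix_hill: float | None = None


@dataclass
class TriageConfig:
    top_n: int = 50
    max_donor_acceptor_distance: float = 3.5   # Å
    min_angle_at_hydrogen: float = 120.0       # degrees
    heavy_atom_fallback_distance: float = 3.5  # Å


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "posepop_out"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    assay: AssayConfig = field(default_factory=AssayConfig)
    triage: TriageConfig = field(default_factory=TriageConfig)

    def validate(self) -> None:
        checks = [
            (self.seed >= 0, "seed"),
            (self.simulate.n_replicates >= 1, "simulate.n_replicates"),
            (self.simulate.n_frames_per_replicate >= 1, "simulate.n_frames_per_replicate"),
            (self.simulate.frame_interval > 0, "simulate.frame_interval"),
            (0 <= self.simulate.pose_weight_A <= 1, "simulate.pose_weight_A"),
            (self.simulate.positional_noise_sd >= 0, "simulate.positional_noise_sd"),
            (0 <= self.simulate.unbound_fraction < 1, "simulate.unbound_fraction"),
            (self.simulate.planted_binders <= self.simulate.n_docking_poses,
             "simulate.planted_binders"),
            (self.clustering.interval > 0, "clustering.interval"),
            (self.clustering.threshold > 0, "clustering.threshold"),
            (self.clustering.k >= 1, "clustering.k"),
            (self.assay.triage_cutoff > 0, "assay.triage_cutoff"),
            (self.assay.probe_concentration > 0, "assay.probe_concentration"),
            (all(v > 0 for v in self.assay.probe_kd.values()), "assay.probe_kd"),
            (self.triage.top_n >= 1, "triage.top_n"),
        ]
        for ok, name in checks:
            if not ok:
                raise ValueError(f"invalid configuration value for field {name!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        cfg = cls(
            seed=doc.get("seed", 0),
            out_dir=doc.get("out_dir", "posepop_out"),
            simulate=SimulateConfig(**doc.get("simulate", {})),
            clustering=ClusteringConfig(**doc.get("clustering", {})),
            assay=AssayConfig(**doc.get("assay", {})),
            triage=TriageConfig(**doc.get("triage", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ValueError("configuration file must contain a mapping")
        return cls.from_dict(doc)
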