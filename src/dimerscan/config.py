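"""Run configuration: defaults, YAML loading, and pre-flight validation."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import yaml

from .clustering import ClusterParams


@dataclass
class DatasetDecl:
    """One declared input dataset: a name, its specificity kind, and the BED
    files of its replicates (merged before analysis)."""

    name: str
    kind: str  # strong | weak
    bed_paths: list[str]

    def validate(self) -> list[str]:
        problems = []
        if self.kind not in ("strong", "weak"):
            problems.append(f"dataset {self.name!r}: kind must be strong or weak")
        if not self.bed_paths:
            problems.append(f"dataset {self.name!r}: no BED files declared")
        for p in self.bed_paths:
            if not os.path.exists(p):
                problems.append(f"dataset {self.name!r}: missing BED file {p}")
        return problems


@dataclass
class RunConfig:
    """Everything a run needs; validated before any computation starts."""

    genome: str = ""
    motif_files: list[tuple[str, str]] = field(default_factory=list)  # (path, format)
    datasets: list[DatasetDecl] = field(default_factory=list)
    scope: str = "all-pairs"            # all-pairs | fixed-motif | fixed-pair
    fixed_motifs: list[str] = field(default_factory=list)
    fixed_pairs: list[tuple[str, str]] = field(default_factory=list)
    min_spacing: int | None = None      # None -> -(min(L1, L2) - 1) per pair
    max_spacing: int = 50
    sensitivity: float = 0.8
    pseudocount: float = 0.25
    cluster_alpha: float = 0.05
    cluster_beta: float = 0.5
    cluster_gamma: float = 0.5
    significance_alpha: float = 0.05
    min_support: int = 5
    ic_trim_cutoff: float = 0.25
    threads: int = 1
    seed: int = 0
    output_dir: str = "dimerscan_out"

    @property
    def cluster_params(self) -> ClusterParams:
        return ClusterParams(self.cluster_alpha, self.cluster_beta, self.cluster_gamma)

    def validate(self, motif_ids: list[str] | None = None) -> list[str]:
        """Collect every problem found (empty list means the config is valid)."""
        problems: list[str] = []
        if not self.genome or not os.path.exists(self.genome):
            problems.append(f"genome FASTA not found: {self.genome!r}")
        for path, fmt in self.motif_files:
            if not os.path.exists(path):
                problems.append(f"missing motif file {path}")
            if fmt.lower() not in ("transfac", "jaspar", "swissregulon", "meme"):
                problems.append(f"unknown motif format {fmt!r} for {path}")
        if not self.datasets:
            problems.append("no datasets declared")
        for d in self.datasets:
            problems.extend(d.validate())
        if self.scope not in ("all-pairs", "fixed-motif", "fixed-pair"):
            problems.append(f"unknown scope {self.scope!r}")
        if self.scope == "fixed-motif" and not self.fixed_motifs:
            problems.append("scope fixed-motif requires fixed_motifs")
        if self.scope == "fixed-pair" and not self.fixed_pairs:
            problems.append("scope fixed-pair requires fixed_pairs")
        if motif_ids is not None:
            known = set(motif_ids)
            for mid in self.fixed_motifs:
                if mid not in known:
                    problems.append(f"fixed motif {mid!r} not in the motif library")
            for a, b in self.fixed_pairs:
                for mid in (a, b):
                    if mid not in known:
                        problems.append(f"fixed-pair motif {mid!r} not in the library")
        if not 0 < self.sensitivity <= 1:
            problems.append("sensitivity must lie in (0, 1]")
        if self.min_spacing is not None and self.min_spacing > self.max_spacing:
            problems.append("min_spacing exceeds max_spacing")
        if self.min_support < 1:
            problems.append("min_support must be >= 1")
        if not 0 < self.significance_alpha <= 1:
            problems.append("significance_alpha must lie in (0, 1]")
        return problems

    def to_yaml(self) -> str:
        d = asdict(self)
        d["datasets"] = [asdict(ds) for ds in self.datasets]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        datasets = [DatasetDecl(**d) if isinstance(d, dict) else d
                    for d in raw.pop("datasets", [])]
        motif_files = [tuple(x) for x in raw.pop("motif_files", [])]
        fixed_pairs = [tuple(x) for x in raw.pop("fixed_pairs", [])]
        return cls(datasets=datasets, motif_files=motif_files,
                   fixed_pairs=fixed_pairs, **raw)
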