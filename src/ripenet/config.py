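"""Pipeline configuration: one plain YAML file drives every stage.

Flags on the command line override config-file keys.  ``validate_config``
returns a report of violations instead of raising, so a config can be
checked as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .synthetic import GeneGroupSpec, SimulationSpec

FLOOR_MODES = ("clamp", "median_filter")
FDR_FAMILIES = ("pooled", "per_query")
BACKGROUNDS = ("expressed_annotated", "annotated")


@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run.

    Defaults are the pipeline constants of the target analysis: rho threshold
    0.3 (inclusive), RPKM floor 3, metabolite tree cut k=3, gene tree cut
    k=4, FDR 10%, top-5 categories per representative metabolite.
    """

    output_dir: str = "ripenet_out"
    # inputs: either a synthetic spec or explicit file paths
    synthetic: Optional[SimulationSpec] = None
    trait_replicates: Optional[str] = None
    parental_values: Optional[str] = None
    expression: Optional[str] = None
    annotation: Optional[str] = None
    bin2ec: Optional[str] = None
    # stage tunables
    rho_threshold: float = 0.3
    threshold_inclusive: bool = True
    rpkm_floor: float = 3.0
    floor_mode: str = "clamp"
    k_metabolites: int = 3
    k_genes: int = 4
    fdr_q: float = 0.10
    fdr_family: str = "pooled"
    background: str = "expressed_annotated"
    top_k: int = 5
    collapse_redundant: bool = False
    representative_trait_ids: list[str] = field(default_factory=list)
    skew_threshold: float = 1.0
    h2_line_mean_basis: bool = False
    distance: str = "one_minus_correlation"
    linkage: str = "average"
    rng_seed: int = 0

    def to_dict(self) -> dict:
        data = asdict(self)
        if self.synthetic is not None:
            data["synthetic"] = asdict(self.synthetic)
            data["synthetic"]["gene_groups"] = [
                asdict(g) for g in self.synthetic.gene_groups
            ]
        return data

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        syn = data.pop("synthetic", None)
        cfg = cls(**data)
        if syn is not None:
            syn = dict(syn)
            groups = syn.pop("gene_groups", None)
            if groups is not None:
                syn["gene_groups"] = tuple(GeneGroupSpec(**g) for g in groups)
            for key in ("trait_cluster_labels", "planted_enriched_bins"):
                if syn.get(key) is not None:
                    syn[key] = tuple(
                        tuple(v) if isinstance(v, list) else v for v in syn[key]
                    )
            if isinstance(syn.get("n_replicates"), list):
                syn["n_replicates"] = tuple(syn["n_replicates"])
            cfg.synthetic = SimulationSpec(**syn)
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def validate_config(config: PipelineConfig) -> list[str]:
    """Range / path / cross-field checks; returns a list of violations."""
    problems: list[str] = []
    if not 0 < config.rho_threshold < 1:
        problems.append(f"rho_threshold {config.rho_threshold} outside (0, 1)")
    if config.rpkm_floor < 0:
        problems.append("rpkm_floor must be >= 0")
    if not 0 < config.fdr_q < 1:
        problems.append(f"fdr_q {config.fdr_q} outside (0, 1)")
    if config.k_metabolites < 1 or config.k_genes < 1:
        problems.append("tree cuts k must be >= 1")
    if config.top_k < 1:
        problems.append("top_k must be >= 1")
    if config.floor_mode not in FLOOR_MODES:
        problems.append(f"floor_mode must be one of {FLOOR_MODES}")
    if config.fdr_family not in FDR_FAMILIES:
        problems.append(f"fdr_family must be one of {FDR_FAMILIES}")
    if config.background not in BACKGROUNDS:
        problems.append(f"background must be one of {BACKGROUNDS}")
    if config.synthetic is None:
        for key in ("trait_replicates", "expression", "annotation"):
            path = getattr(config, key)
            if path is None:
                problems.append(f"no synthetic spec and no {key} input path")
            elif not Path(path).exists():
                problems.append(f"{key} path does not exist: {path}")
        if config.representative_trait_ids and config.trait_replicates:
            try:
                import pandas as pd

                traits = set(
                    pd.read_csv(
                        config.trait_replicates, sep="\t", usecols=["trait"], dtype=str
                    )["trait"]
                )
                for rid in config.representative_trait_ids:
                    if rid not in traits:
                        problems.append(f"representative trait absent from table: {rid}")
            except Exception as exc:  # unreadable table is itself a violation
                problems.append(f"cannot read trait_replicates: {exc}")
    else:
        try:
            config.synthetic.validate()
        except Exception as exc:
            problems.append(f"synthetic spec invalid: {exc}")
        trait_ids = set(config.synthetic.trait_ids)
        for rid in config.representative_trait_ids:
            if rid not in trait_ids:
                problems.append(f"representative trait absent from table: {rid}")
    return problems
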