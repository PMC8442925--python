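"""Design configuration: one YAML document grouping every module's knobs.

Blocks map 1:1 onto the parameter dataclasses of the corresponding modules
(constraints, energy, aggregation, mc, scaffold geometry, analysis cutoffs).
Unknown keys are rejected so typos fail loudly before a run starts; parse ->
serialize -> parse is the identity on the dict representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .assembly_analysis import AnalysisParams
from .errors import ConfigurationError
from .mc_engine import MCConfig
from .scaffold_model import ScaffoldGeometry
from .scoring import AggregationParams, EnergyParams, load_contact_table
from .sequence_space import (CompositionConstraint, ResidueClassTable,
                             SequencePattern)

__all__ = ["DesignConfig", "load_config", "save_config"]

_SET_FIELDS = ("hydrophobic_set", "polar_set", "positive_set",
               "negative_set", "excluded_set")


def _build(cls, block: dict, name: str, **extra):
    block = dict(block or {})
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigurationError(
            f"unknown keys in '{name}' block: {sorted(unknown)}")
    try:
        return cls(**block, **extra)
    except TypeError as exc:
        raise ConfigurationError(f"bad '{name}' block: {exc}") from exc


@dataclass
class DesignConfig:
    pattern: SequencePattern = field(default_factory=SequencePattern)
    composition: CompositionConstraint = field(
        default_factory=CompositionConstraint)
    residue_classes: ResidueClassTable = field(
        default_factory=ResidueClassTable)
    energy: EnergyParams = field(default_factory=EnergyParams)
    aggregation: AggregationParams = field(default_factory=AggregationParams)
    mc: MCConfig = field(default_factory=MCConfig)
    geometry: ScaffoldGeometry = field(default_factory=ScaffoldGeometry)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_dict(cls, doc: dict) -> "DesignConfig":
        doc = dict(doc or {})
        known = {"pattern", "composition", "residue_classes", "energy",
                 "aggregation", "mc", "geometry", "analysis"}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config blocks: {sorted(unknown)}")
        pattern = SequencePattern(doc.get("pattern", "PPPHPHPHPPP"))
        classes_block = dict(doc.get("residue_classes") or {})
        for key in list(classes_block):
            if key in _SET_FIELDS:
                classes_block[key] = frozenset(classes_block[key])
        energy_block = dict(doc.get("energy") or {})
        table_csv = energy_block.pop("contact_table_csv", None)
        extra = {}
        if table_csv:
            extra["contact_table"] = load_contact_table(table_csv)
        return cls(
            pattern=pattern,
            composition=_build(CompositionConstraint,
                               doc.get("composition"), "composition"),
            residue_classes=_build(ResidueClassTable, classes_block,
                                   "residue_classes"),
            energy=_build(EnergyParams, energy_block, "energy", **extra),
            aggregation=_build(AggregationParams, doc.get("aggregation"),
                               "aggregation"),
            mc=_build(MCConfig, doc.get("mc"), "mc"),
            geometry=_build(ScaffoldGeometry, doc.get("geometry"), "geometry"),
            analysis=_build(AnalysisParams, doc.get("analysis"), "analysis"),
        )

    def to_dict(self) -> dict:
        """Scalar dict representation (array/table defaults are omitted)."""

        def block(obj, skip=()):
            out = {}
            for f in fields(obj):
                if f.name in skip:
                    continue
                value = getattr(obj, f.name)
                if isinstance(value, frozenset):
                    value = sorted(value)
                elif isinstance(value, tuple):
                    value = list(value)
                out[f.name] = value
            return out

        return {
            "pattern": self.pattern.pattern,
            "composition": block(self.composition),
            "residue_classes": block(self.residue_classes),
            "energy": block(self.energy,
                            skip=("contact_table", "dielectric_by_class",
                                  "centroid_distances"))
            | {"dielectric_by_class": dict(self.energy.dielectric_by_class)},
            "aggregation": block(self.aggregation,
                                 skip=("hydropathy_scale",
                                       "beta_propensity_scale")),
            "mc": block(self.mc),
            "geometry": block(self.geometry),
            "analysis": block(self.analysis),
        }


def load_config(path) -> DesignConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return DesignConfig.from_dict(doc)


def save_config(config: DesignConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    return path
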