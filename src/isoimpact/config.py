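"""Run configuration: one place for every tunable parameter group.

Precedence is flags > config file > documented defaults; unknown keys in a
config file are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import yaml

from .align import AlignParams
from .clustering import ClusterParams
from .events import EventParams
from .model import ValidationError
from .network import NetworkFilters
from .ora import OraParams
from .overlay import DEFilterParams

# config-file keys per group -> dataclass field
_GROUPS = {
    "clustering": {
        "identity_threshold": ("cluster_params", "identity_threshold"),
        "canonical_override": ("canonical_override", None),
    },
    "align": {
        "matrix": ("align_params", "matrix_name"),
        "gap_open": ("align_params", "gap_open"),
        "gap_extend": ("align_params", "gap_extend"),
    },
    "events": {
        "min_divergent_run": ("event_params", "min_divergent_run"),
        "merge_gap": ("event_params", "merge_gap"),
    },
    "network": {
        "min_mi_score": ("network_filters", "min_mi_score"),
        "allowed_types": ("network_filters", "allowed_types"),
        "max_isoform_specific": ("network_filters", "max_isoform_specific"),
    },
    "ora": {
        "alpha": ("ora_params", "alpha"),
        "background": ("ora_params", "background"),
    },
    "de": {
        "ppde_threshold": ("de_params", "ppde_threshold"),
        "strict": ("de_params", "strict"),
    },
}


@dataclass
class RunConfig:
    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    align_params: AlignParams = field(default_factory=AlignParams)
    event_params: EventParams = field(default_factory=EventParams)
    network_filters: NetworkFilters = field(default_factory=NetworkFilters)
    ora_params: OraParams = field(default_factory=OraParams)
    de_params: DEFilterParams = field(default_factory=DEFilterParams)
    canonical_override: Optional[str] = None

    def resolved(self) -> dict[str, Any]:
        """The fully resolved parameter set, embedded in every report."""
        return {
            "clustering": {
                "identity_threshold": self.cluster_params.identity_threshold,
                "canonical_override": self.canonical_override,
            },
            "align": {
                "matrix": self.align_params.matrix_name,
                "gap_open": self.align_params.gap_open,
                "gap_extend": self.align_params.gap_extend,
            },
            "events": {
                "min_divergent_run": self.event_params.min_divergent_run,
                "merge_gap": self.event_params.merge_gap,
            },
            "network": {
                "min_mi_score": self.network_filters.min_mi_score,
                "allowed_types": sorted(self.network_filters.allowed_types),
                "max_isoform_specific": self.network_filters.max_isoform_specific,
            },
            "ora": {
                "alpha": self.ora_params.alpha,
                "background": sorted(self.ora_params.background)
                if self.ora_params.background
                else "genesets",
            },
            "de": {
                "ppde_threshold": self.de_params.ppde_threshold,
                "strict": self.de_params.strict,
            },
        }


def _apply(cfg_kwargs: dict, group: str, key: str, value: Any) -> None:
    if group not in _GROUPS:
        raise ValidationError(f"unknown config section {group!r}")
    if key not in _GROUPS[group]:
        raise ValidationError(f"unknown config key {group}.{key}")
    target, attr = _GROUPS[group][key]
    if attr is None:
        cfg_kwargs[target] = value
    else:
        cfg_kwargs.setdefault(target, {})[attr] = value


def load_config(path=None, overrides: Optional[dict[tuple[str, str], Any]] = None) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus flag overrides.

    overrides maps (section, key) -> value and wins over the file.
    """
    cfg_kwargs: dict[str, Any] = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        for group, entries in data.items():
            if not isinstance(entries, dict):
                raise ValidationError(f"{path}: section {group!r} must be a mapping")
            for key, value in entries.items():
                _apply(cfg_kwargs, group, key, value)
    for (group, key), value in (overrides or {}).items():
        _apply(cfg_kwargs, group, key, value)

    canonical_override = cfg_kwargs.pop("canonical_override", None)
    if "network_filters" in cfg_kwargs:
        nf = cfg_kwargs["network_filters"]
        if "allowed_types" in nf:
            nf["allowed_types"] = frozenset(nf["allowed_types"])
    if "ora_params" in cfg_kwargs:
        op = cfg_kwargs["ora_params"]
        if op.get("background") in (None, "genesets"):
            op["background"] = None
        elif isinstance(op["background"], str):
            op["background"] = frozenset(
                Path(op["background"]).read_text().split()
            )
        else:
            op["background"] = frozenset(op["background"])

    groups = {f.name: f for f in fields(RunConfig)}
    init: dict[str, Any] = {"canonical_override": canonical_override}
    for name, f in groups.items():
        if name == "canonical_override":
            continue
        kwargs = cfg_kwargs.get(name, {})
        init[name] = f.default_factory(**kwargs) if kwargs else f.default_factory()
    return RunConfig(**init)
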