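"""Feature-name manifest: the ordered list of MRI measures and their kind.

The default manifest carries 34 cortical-thickness means and 21 subcortical
volumes (left/right averaged), mirroring the standard FreeSurfer
aparc/aseg outputs used for this style of analysis. The manifest is
configuration, not code: an alternative ordered list can be loaded from a
YAML or JSON file with the same structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .exceptions import ValidationError

THICKNESS = "thickness"
VOLUME = "volume"
_KINDS = (THICKNESS, VOLUME)


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered feature names, each tagged as thickness or volume."""

    names: tuple[str, ...]
    kinds: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.kinds):
            raise ValidationError("names and kinds must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("feature names must be unique")
        bad = [k for k in self.kinds if k not in _KINDS]
        if bad:
            raise ValidationError(f"unknown feature kinds: {sorted(set(bad))}")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def thickness_names(self) -> tuple[str, ...]:
        return tuple(n for n, k in zip(self.names, self.kinds) if k == THICKNESS)

    @property
    def volume_names(self) -> tuple[str, ...]:
        return tuple(n for n, k in zip(self.names, self.kinds) if k == VOLUME)

    def kind_of(self, name: str) -> str:
        return self.kinds[self.names.index(name)]

    def to_dict(self) -> dict:
        return {
            "features": [
                {"name": n, "kind": k} for n, k in zip(self.names, self.kinds)
            ]
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FeatureManifest":
        feats = payload["features"]
        return cls(
            names=tuple(f["name"] for f in feats),
            kinds=tuple(f["kind"] for f in feats),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "FeatureManifest":
        path = Path(path)
        text = path.read_text()
        payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(payload)


def default_manifest() -> FeatureManifest:
    """The packaged 55-measure manifest (34 thickness + 21 volume)."""
    ref = resources.files("oplsage").joinpath("data/default_manifest.yaml")
    return FeatureManifest.from_dict(yaml.safe_load(ref.read_text()))
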