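"""Provenance-bearing JSON result documents.

Every computed property can be serialized as a :class:`PropertyDocument`:
the payload (values + uncertainties), the inputs that produced it (paths,
selections, parameters), an ordered provenance chain of step records, the
seeds and replicate number of the underlying run, the package version, a
creation timestamp, and free-form user tags.  Serialization is lossless:
``from_json(to_json(doc))`` reproduces the document exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Union

from . import __version__
from .errors import ValidationError


@dataclass
class ProvenanceStep:
    """One step in the chain that produced a property."""

    step_id: str
    operation: str
    parameters: Dict[str, Any] = field(default_factory=dict)
    depends_on: List[str] = field(default_factory=list)


@dataclass
class PropertyDocument:
    """JSON-serializable record of one computed property."""

    property_name: str
    payload: Dict[str, Any]
    inputs: Dict[str, Any] = field(default_factory=dict)
    provenance: List[ProvenanceStep] = field(default_factory=list)
    seeds: List[int] = field(default_factory=list)
    replicate: int = 0
    version: str = __version__
    created: str = ""
    tags: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.created:
            self.created = datetime.now(timezone.utc).isoformat()
        ids = [s.step_id for s in self.provenance]
        if len(set(ids)) != len(ids):
            raise ValidationError("provenance step ids must be unique")
        known = set(ids)
        for s in self.provenance:
            for dep in s.depends_on:
                if dep not in known:
                    raise ValidationError(
                        f"provenance step {s.step_id!r} depends on undefined id {dep!r}"
                    )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PropertyDocument":
        d = dict(d)
        d["provenance"] = [ProvenanceStep(**s) for s in d.get("provenance", [])]
        return cls(**d)

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonable)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PropertyDocument":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _jsonable(obj: Any):
    import numpy as np

    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def write_property_doc(
    property_name: str,
    payload: Dict[str, Any],
    dest: Optional[Union[str, Path]] = None,
    inputs: Optional[Dict[str, Any]] = None,
    steps: Optional[Sequence[ProvenanceStep]] = None,
    seeds: Sequence[int] = (),
    replicate: int = 0,
    tags: Optional[Dict[str, Any]] = None,
) -> PropertyDocument:
    """Assemble (and optionally write) a :class:`PropertyDocument`."""
    doc = PropertyDocument(
        property_name=property_name,
        payload=_clean(payload),
        inputs=_clean(inputs or {}),
        provenance=list(steps or []),
        seeds=list(seeds),
        replicate=replicate,
        tags=dict(tags or {}),
    )
    if dest is not None:
        doc.to_json(dest)
    return doc


def _clean(d: Dict[str, Any]) -> Dict[str, Any]:
    """Round-trip values through the JSON encoder so the doc is plain data."""
    return json.loads(json.dumps(d, default=_jsonable))
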