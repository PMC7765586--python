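"""Gene/domain configuration: protein lengths and domain intervals.

The bundled ``data/domains.yaml`` pins the human reference lengths the
published residue totals depend on (MRE11 708, RAD50 1312, NBN 754) and
approximate domain intervals used to annotate positional outputs.  Users
can point the loader at their own YAML with the same shape.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .spectrum import DomainMap

__all__ = ["load_domain_maps", "default_domain_maps"]


def _parse(doc: dict) -> dict[str, DomainMap]:
    maps: dict[str, DomainMap] = {}
    for gene, spec in doc["genes"].items():
        domains = tuple(
            (d["name"], int(d["start"]), int(d["end"]))
            for d in spec.get("domains", ())
        )
        maps[gene] = DomainMap(gene=gene, length=int(spec["length"]),
                               domains=domains)
    return maps


def load_domain_maps(path: str | Path) -> dict[str, DomainMap]:
    """Load a domain configuration YAML into DomainMap objects."""
    with open(path) as fh:
        return _parse(yaml.safe_load(fh))


def default_domain_maps() -> dict[str, DomainMap]:
    """The bundled MRN + CtIP/RBBP8 configuration."""
    ref = resources.files("mrnspec.data").joinpath("domains.yaml")
    return _parse(yaml.safe_load(ref.read_text()))
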