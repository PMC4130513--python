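"""Readers and writers: the line-oriented quartet format and Newick trees.

Quartet format, one record per line::

    a,b|c,d        # weight 1
    a,b|c,d 3      # weight 3
    # comments and blank lines are ignored

Taxon names are any non-whitespace characters excluding ``,`` and ``|``.
Trees are standard Newick with unrooted semantics: a rooted (bifurcating
basal) input is unrooted by suppressing the degree-2 root on read.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Union

import dendropy

from .phylo_core import Quartet, QuartetSet
from .recursion import BASE_CASE_SIZE

__all__ = [
    "QuartetParseError",
    "RunConfig",
    "read_quartets",
    "write_quartets",
    "read_tree",
    "write_tree",
]

Pathlike = Union[str, Path]


class QuartetParseError(ValueError):
    """Malformed quartet file; carries the offending line number."""

    def __init__(self, path: Pathlike, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


@dataclass
class RunConfig:
    """Plain-text-serializable run settings; CLI flags override file values."""

    score: str = "diff"
    base_case_size: int = BASE_CASE_SIZE
    seed: Optional[int] = None
    quartets: Optional[str] = None
    output: Optional[str] = None
    verbosity: str = "INFO"

    def to_json(self, path: Pathlike) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Pathlike) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in data.items() if k in known})


def read_quartets(path: Pathlike) -> QuartetSet:
    """Parse a quartet file, aggregating canonically equal records."""
    out = QuartetSet()
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) > 2:
                raise QuartetParseError(
                    path, line_no, f"expected 'a,b|c,d [weight]', got {line!r}")
            weight = 1.0
            if len(parts) == 2:
                try:
                    weight = float(parts[1])
                except ValueError:
                    raise QuartetParseError(
                        path, line_no, f"non-numeric weight {parts[1]!r}")
                if weight < 0:
                    raise QuartetParseError(path, line_no, "negative weight")
            try:
                q = Quartet.parse(parts[0], weight)
            except ValueError as exc:
                raise QuartetParseError(path, line_no, str(exc))
            out.add(q)
    return out


def write_quartets(quartets: QuartetSet, path: Pathlike) -> None:
    with open(path, "w") as fh:
        for q, w in sorted(quartets.items(), key=lambda it: str(it[0])):
            if w == 1.0:
                fh.write(f"{q}\n")
            else:
                fh.write(f"{q} {w:g}\n")


def read_tree(path: Pathlike,
              taxon_namespace: Optional[dendropy.TaxonNamespace] = None
              ) -> dendropy.Tree:
    """Read one Newick tree with unrooted semantics.

    A degree-2 root (rooted input) is suppressed so that every internal
    node has degree >= 3.
    """
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             taxon_namespace=taxon_namespace,
                             preserve_underscores=True)
    if len(tree.seed_node.child_nodes()) == 2:
        tree.deroot()
    tree.is_rooted = False
    return tree


def write_tree(tree: dendropy.Tree, path: Pathlike) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               preserve_spaces=True)
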