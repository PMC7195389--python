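"""Domain partitions: named residue-range segments plus linkers.

A partition maps domain labels to lists of closed residue-number intervals in
the structure's own (gene) numbering.  A domain may own several discontiguous
ranges — SurA's core domain is the N-terminal plus C-terminal regions of the
chain, with the two PPIase domains (P1, P2) in between.  Residues covered by
no domain are linkers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "DomainPartition",
    "PartitionError",
    "assign_domains",
    "load_partition",
    "default_sura_partition",
    "LINKER",
]

LINKER = "linker"


class PartitionError(ValueError):
    pass


@dataclass
class DomainPartition:
    """Map from domain label to ordered list of closed residue ranges."""

    segments: dict[str, list[tuple[int, int]]]

    def __post_init__(self) -> None:
        clean: dict[str, list[tuple[int, int]]] = {}
        for label, ranges in self.segments.items():
            rs = [(int(a), int(b)) for a, b in ranges]
            for a, b in rs:
                if a > b:
                    raise PartitionError(f"{label}: range {a}-{b} has start > end")
            clean[label] = sorted(rs)
        self.segments = clean
        self._check_disjoint()

    def _check_disjoint(self) -> None:
        flat = [
            (a, b, label) for label, ranges in self.segments.items() for a, b in ranges
        ]
        flat.sort()
        for (a1, b1, l1), (a2, b2, l2) in zip(flat, flat[1:]):
            if a2 <= b1:
                raise PartitionError(
                    f"overlapping ranges: {l1} {a1}-{b1} collides with {l2} {a2}-{b2}"
                )

    def label_of(self, resnum: int) -> str:
        for label, ranges in self.segments.items():
            for a, b in ranges:
                if a <= resnum <= b:
                    return label
        return LINKER

    @property
    def labels(self) -> list[str]:
        return list(self.segments)


@dataclass
class PartitionAssignment:
    """Per-residue labels for one structure under one partition."""

    labels: dict[int, str]
    partition: DomainPartition

    def relation(self, res_a: int, res_b: int) -> str:
        """``"intra-domain"`` if both residues share a domain label, else ``"inter-domain"``.

        Pairs touching a linker residue are inter-domain.
        """
        la, lb = self.labels[res_a], self.labels[res_b]
        if la == lb and la != LINKER:
            return "intra-domain"
        return "inter-domain"

    def pair_label(self, res_a: int, res_b: int) -> str:
        """Canonical sorted pair label, e.g. ``"core-P1"`` or ``"core-core"``."""
        return "-".join(sorted([self.labels[res_a], self.labels[res_b]]))

    def domain_residues(self, label: str) -> list[int]:
        return [r for r, l in self.labels.items() if l == label]


def assign_domains(structure, partition: DomainPartition) -> PartitionAssignment:
    """Label every modelled residue with a domain or ``"linker"``.

    Total over the structure's residues; raises if any partition range falls
    outside the modelled residue span.
    """
    res = structure.residues()
    lo, hi = int(res.min()), int(res.max())
    for label, ranges in partition.segments.items():
        for a, b in ranges:
            if b < lo or a > hi:
                raise PartitionError(
                    f"{label} range {a}-{b} lies outside modelled span {lo}-{hi}"
                )
    labels = {int(r): partition.label_of(int(r)) for r in res}
    return PartitionAssignment(labels=labels, partition=partition)


def load_partition(text_or_path) -> DomainPartition:
    """Load a partition from YAML: ``{label: ["start-end", ...], ...}``."""
    import os

    if isinstance(text_or_path, (str, os.PathLike)) and os.path.exists(str(text_or_path)):
        with open(text_or_path) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(text_or_path)
    if not isinstance(raw, dict):
        raise PartitionError("partition config must be a mapping of label -> ranges")
    segments = {}
    for label, ranges in raw.items():
        if isinstance(ranges, str):
            ranges = [ranges]
        parsed = []
        for r in ranges:
            try:
                a, b = str(r).split("-")
                parsed.append((int(a), int(b)))
            except ValueError as exc:
                raise PartitionError(f"{label}: cannot parse range {r!r} (want 'start-end')") from exc
        segments[str(label)] = parsed
    return DomainPartition(segments)


def default_sura_partition() -> DomainPartition:
    """The shipped approximate SurA partition (gene numbering).

    core = N-terminal (21-170) + C-terminal (390-428) regions; P1 = 171-280;
    P2 = 281-389.  Boundaries are approximate and configurable; the structural
    literature does not pin exact linker residues.
    """
    with resources.files("interdom").joinpath("data/sura_domains.yaml").open() as fh:
        return load_partition(fh.read())
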