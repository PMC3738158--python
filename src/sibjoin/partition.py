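"""Maternal/paternal half-sib partitions and their TSV serialization.

A half-sib reconstruction is a pair of partitions of the same individuals:
the maternal partition M and the paternal partition P.  Because
microsatellites carry no information about which parent is which, the labels
"maternal"/"paternal" are a convention; accuracy metrics treat them as
exchangeable.  The implied full-sib families are the non-empty intersections
of a maternal with a paternal block.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


def _freeze(blocks: Iterable[Iterable[str]]) -> tuple[frozenset[str], ...]:
    out = tuple(frozenset(b) for b in blocks)
    if any(not b for b in out):
        raise ValueError("empty block")
    return out


@dataclass(frozen=True)
class SibPartition:
    """A maternal and a paternal partition over the same individuals."""

    maternal: tuple[frozenset[str], ...]
    paternal: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        for side in (self.maternal, self.paternal):
            seen: set[str] = set()
            for block in side:
                if seen & block:
                    raise ValueError("overlapping blocks within one side")
                seen |= block
        if self._universe(self.maternal) != self._universe(self.paternal):
            raise ValueError("maternal and paternal sides cover different individuals")

    @staticmethod
    def _universe(side: tuple[frozenset[str], ...]) -> frozenset[str]:
        u: set[str] = set()
        for b in side:
            u |= b
        return frozenset(u)

    @property
    def universe(self) -> frozenset[str]:
        return self._universe(self.maternal)

    @property
    def n(self) -> int:
        return len(self.universe)

    def full_families(self) -> list[frozenset[str]]:
        """Non-empty intersections M ∩ P: the implied full-sib families."""
        fams = []
        for mb in self.maternal:
            for pb in self.paternal:
                inter = mb & pb
                if inter:
                    fams.append(inter)
        return fams

    def swapped(self) -> "SibPartition":
        return SibPartition(self.paternal, self.maternal)


def make_partition(
    maternal: Iterable[Iterable[str]], paternal: Iterable[Iterable[str]]
) -> SibPartition:
    return SibPartition(_freeze(maternal), _freeze(paternal))


def write_partition(part: SibPartition, path: str | Path) -> None:
    """TSV with columns id, maternal_cluster, paternal_cluster."""
    m_of = {iid: f"M{j}" for j, b in enumerate(part.maternal) for iid in b}
    p_of = {iid: f"P{j}" for j, b in enumerate(part.paternal) for iid in b}
    with Path(path).open("w") as fh:
        fh.write("id\tmaternal_cluster\tpaternal_cluster\n")
        for iid in sorted(part.universe):
            fh.write(f"{iid}\t{m_of[iid]}\t{p_of[iid]}\n")


def read_partition(path: str | Path) -> SibPartition:
    """Inverse of :func:`write_partition` (cluster labels are arbitrary)."""
    maternal: dict[str, set[str]] = {}
    paternal: dict[str, set[str]] = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", "maternal_cluster", "paternal_cluster"]:
            raise ValueError(f"{path}: unexpected header {header}")
        for line in fh:
            if not line.strip():
                continue
            iid, mc, pc = line.rstrip("\n").split("\t")
            maternal.setdefault(mc, set()).add(iid)
            paternal.setdefault(pc, set()).add(iid)
    return make_partition(
        (maternal[k] for k in sorted(maternal)),
        (paternal[k] for k in sorted(paternal)),
    )
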