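"""Reference-genome definitions.

A :class:`GenomeDef` fixes the coordinate space every statistic is computed
on: an ordered set of chromosomes with lengths, and the total genome size
``G`` that enters the Forbes colocalization coefficient and expected-overlap
calculations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable


class GenomeError(ValueError):
    """Raised for invalid genome definitions or genome mismatches."""


@dataclass(frozen=True)
class GenomeDef:
    """An ordered list of chromosomes with lengths.

    Parameters
    ----------
    name
        Text label for the build, e.g. ``"hg19"``, ``"mm10"`` or a toy name.
    chroms
        Ordered ``(chromosome name, length in bp)`` pairs. Order is
        significant: it defines the left-to-right concatenation used for
        genome-wide plots.
    """

    name: str
    chroms: tuple[tuple[str, int], ...]
    _lengths: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        chroms = tuple((str(c), int(l)) for c, l in self.chroms)
        object.__setattr__(self, "chroms", chroms)
        names = [c for c, _ in chroms]
        if len(set(names)) != len(names):
            raise GenomeError(f"duplicate chromosome names in genome {self.name!r}")
        for c, l in chroms:
            if l <= 0:
                raise GenomeError(f"chromosome {c!r} has non-positive length {l}")
        object.__setattr__(self, "_lengths", dict(chroms))

    @property
    def G(self) -> int:
        """Total genome length in bp."""
        return sum(l for _, l in self.chroms)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chroms)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise GenomeError(f"unknown chromosome {chrom!r} in genome {self.name!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def offsets(self) -> dict[str, int]:
        """bp offset of each chromosome start when chromosomes are
        concatenated in declared order (used for genome-wide coordinates)."""
        out, acc = {}, 0
        for c, l in self.chroms:
            out[c] = acc
            acc += l
        return out

    @classmethod
    def from_chrom_sizes(cls, path: str | Path, name: str | None = None) -> "GenomeDef":
        """Read a two-column ``chrom.sizes`` file (chromosome, length)."""
        path = Path(path)
        chroms: list[tuple[str, int]] = []
        for i, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise GenomeError(f"{path}:{i}: expected 'chrom<TAB>length'")
            chroms.append((parts[0], int(parts[1])))
        if not chroms:
            raise GenomeError(f"{path}: empty chrom.sizes file")
        return cls(name=name or path.stem, chroms=tuple(chroms))

    def to_chrom_sizes(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{c}\t{l}\n" for c, l in self.chroms))


def toy_genome(name: str = "toy1",
               lengths: Iterable[int] = (10_000, 8_000, 5_000)) -> GenomeDef:
    """Small genome used by the synthetic fixtures (chr1, chr2, ...)."""
    return GenomeDef(name, tuple((f"chr{i + 1}", l) for i, l in enumerate(lengths)))
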