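"""Ordered ensembles of potential grids with optional timestamps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from .grid import GridError, PotentialGrid


@dataclass
class EnsembleManifest:
    """An ordered list of grids (in memory or on disk) with timestamps (ns).

    Entries are ``(source, time_ns)`` pairs where ``source`` is either a
    :class:`PotentialGrid` or a file path; timestamps, when present, must be
    strictly increasing.
    """

    entries: list = field(default_factory=list)
    alignment_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise GridError("manifest needs at least one entry")
        times = [t for _, t in self.entries if t is not None]
        if times and any(b <= a for a, b in zip(times, times[1:])):
            raise GridError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def timestamps(self) -> list:
        return [t for _, t in self.entries]

    def grids(self) -> Iterator[PotentialGrid]:
        """Yield grids one at a time (streaming: paths loaded lazily)."""
        for source, _ in self.entries:
            yield _load(source)

    def grid(self, i: int) -> PotentialGrid:
        return _load(self.entries[i][0])

    @classmethod
    def from_grids(cls, grids: Sequence[PotentialGrid],
                   times: Sequence[float] | None = None,
                   alignment_tag: str = "") -> "EnsembleManifest":
        if times is None:
            times = [None] * len(grids)
        return cls(entries=[(g, t) for g, t in zip(grids, times)],
                   alignment_tag=alignment_tag)

    @classmethod
    def read(cls, path: str) -> "EnsembleManifest":
        """Read a manifest file: one ``grid-path [time-ns]`` pair per line."""
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                entries.append((parts[0], float(parts[1]) if len(parts) > 1 else None))
        return cls(entries=entries)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            for source, t in self.entries:
                if not isinstance(source, str):
                    raise GridError("only path-backed manifests can be written")
                fh.write(source if t is None else f"{source}\t{t:g}")
                fh.write("\n")


def _load(source) -> PotentialGrid:
    if isinstance(source, PotentialGrid):
        return source
    from . import dx, uhbd

    if str(source).endswith(".dx"):
        return dx.read_dx_grid(source)
    return uhbd.read_uhbd_grid(source)
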