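"""Ranked polyadenylation-signal (PAS) hexamer table and sequence primitives.

Cleavage and polyadenylation of pre-mRNA is directed by a short A-rich
hexamer — canonically AATAAA at the DNA level — located roughly 20 nt
upstream of the cleavage site.  Genome-wide atlases annotate a small fixed
inventory of such hexamers and their occurrence counts; the *rank* of a
hexamer in that inventory (1 = most abundant) is what downstream consequence
classification compares when a variant rewrites a signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "PasMotif",
    "MotifTable",
    "load_motif_table",
    "derive_motif_table_from_atlas",
    "revcomp",
    "DEFAULT_TABLE_NAME",
]

DEFAULT_TABLE_NAME = "mouse-polyasite"

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _check_hexamer(hexamer: str) -> str:
    hexamer = hexamer.upper()
    if len(hexamer) != 6 or not set(hexamer) <= _VALID_BASES:
        raise ValueError(f"not a DNA hexamer: {hexamer!r}")
    return hexamer


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (alphabet ACGTN, case-folded)."""
    seq = seq.upper()
    if not set(seq) <= set("ACGTN"):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"non-DNA characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PasMotif:
    """One PAS hexamer with its genome-wide occurrence count."""

    hexamer: str
    count: int
    relative_abundance: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "hexamer", _check_hexamer(self.hexamer))
        if self.count < 0:
            raise ValueError(f"negative count for {self.hexamer}: {self.count}")
        if not 0.0 <= self.relative_abundance <= 1.0:
            raise ValueError(
                f"relative abundance outside [0, 1]: {self.relative_abundance}"
            )


@dataclass
class MotifTable:
    """Ordered PAS inventory with rank lookup (rank 1 = most abundant).

    Motifs are stored in rank order; ranks are dense 1..N with counts
    non-increasing.  Count ties are broken lexicographically on the hexamer
    so that ranks are deterministic.
    """

    motifs: list[PasMotif] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        prev_count: Optional[int] = None
        for m in self.motifs:
            if m.hexamer in seen:
                raise ValueError(f"duplicate hexamer in motif table: {m.hexamer}")
            seen.add(m.hexamer)
            if prev_count is not None and m.count > prev_count:
                raise ValueError("motif counts must be non-increasing in rank order")
            prev_count = m.count
        total_abundance = sum(m.relative_abundance for m in self.motifs)
        if total_abundance > 1.0 + 1e-9:
            raise ValueError(f"relative abundances sum to {total_abundance} > 1")
        self._rank = {m.hexamer: i + 1 for i, m in enumerate(self.motifs)}
        self._count = {m.hexamer: m.count for m in self.motifs}

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, hexamer: str) -> bool:
        return _check_hexamer(hexamer) in self._rank

    @property
    def hexamers(self) -> list[str]:
        return [m.hexamer for m in self.motifs]

    def rank_of(self, hexamer: str) -> Optional[int]:
        """Rank of ``hexamer`` (1 = most abundant), or None if not a signal."""
        return self._rank.get(_check_hexamer(hexamer))

    def count_of(self, hexamer: str) -> Optional[int]:
        return self._count.get(_check_hexamer(hexamer))


def _build_table(rows: Iterable[tuple[str, int, Optional[float]]]) -> MotifTable:
    rows = list(rows)
    if not rows:
        raise ValueError("motif table is empty")
    total = sum(count for _, count, _ in rows)
    motifs = []
    for hexamer, count, abundance in sorted(rows, key=lambda r: (-r[1], r[0])):
        if abundance is None:
            abundance = count / total if total else 0.0
        motifs.append(PasMotif(hexamer, count, abundance))
    return MotifTable(motifs)


def load_motif_table(source: str | Path = DEFAULT_TABLE_NAME) -> MotifTable:
    """Load a PAS motif table from a TSV file or by built-in name.

    The file format is ``hexamer<TAB>count[<TAB>abundance]`` with ``#``
    comment lines.  The packaged default (``"mouse-polyasite"``) is the
    18-hexamer inventory of the PolyASite 2.0 mouse atlas with AATAAA ranked
    first and ATTAAA second.
    """
    if isinstance(source, str) and source == DEFAULT_TABLE_NAME:
        ref = resources.files("passcan.data").joinpath("pas_motifs_mouse.tsv")
        text = ref.read_text()
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"no such motif table: {path}")
        text = path.read_text()

    rows: list[tuple[str, int, Optional[float]]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise ValueError(f"line {lineno}: expected 2 or 3 columns, got {len(parts)}")
        hexamer = _check_hexamer(parts[0])
        if hexamer in seen:
            raise ValueError(f"line {lineno}: duplicate hexamer {hexamer}")
        seen.add(hexamer)
        count = int(parts[1])
        if count < 0:
            raise ValueError(f"line {lineno}: negative count for {hexamer}")
        abundance = float(parts[2]) if len(parts) == 3 else None
        rows.append((hexamer, count, abundance))
    return _build_table(rows)


def derive_motif_table_from_atlas(sites: Iterable) -> MotifTable:
    """Tally signal hexamers over atlas sites into a ranked motif table.

    Counts each annotated signal occurrence across ``sites`` (objects with a
    ``signals`` attribute of items exposing ``hexamer``); ranks by descending
    count with lexicographic tie-break; relative abundance is count / total.
    """
    counts: dict[str, int] = {}
    for site in sites:
        for signal in site.signals:
            hexamer = _check_hexamer(signal.hexamer)
            counts[hexamer] = counts.get(hexamer, 0) + 1
    if not counts:
        raise ValueError("no PAS signals present in any atlas site")
    return _build_table((h, c, None) for h, c in counts.items())
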