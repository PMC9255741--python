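"""Reading and writing SWC neuronal reconstruction files.

The SWC format stores a neuron as one whitespace-delimited record per
sample point::

    id  type  x  y  z  radius  parent_id

with ``#``-prefixed comment lines.  Structure type codes follow the
NeuroMorpho convention: 1 soma, 2 axon, 3 basal dendrite, 4 apical
dendrite, >=5 custom.  ``parent_id`` is -1 for a root sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Sequence

__all__ = [
    "SwcRecord",
    "SwcParseError",
    "SwcFormatError",
    "SwcConnectivityError",
    "DEFAULT_FILTER_TYPES",
    "read_swc",
    "write_swc",
]

SOMA = 1
AXON = 2
BASAL_DENDRITE = 3
APICAL_DENDRITE = 4

#: Soma plus dendrites; axons are excluded from dendritic morphometry.
DEFAULT_FILTER_TYPES = frozenset({SOMA, BASAL_DENDRITE, APICAL_DENDRITE})


class SwcParseError(ValueError):
    """A line could not be parsed as an SWC record."""


class SwcFormatError(ValueError):
    """Records violate SWC structural invariants (e.g. duplicate ids)."""


class SwcConnectivityError(ValueError):
    """Parent links are missing, filtered away, or cyclic."""


@dataclass(frozen=True)
class SwcRecord:
    """One sample point of an SWC reconstruction."""

    sample_id: int
    structure_type: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    def __post_init__(self) -> None:
        if self.sample_id <= 0:
            raise SwcFormatError(f"sample_id must be positive, got {self.sample_id}")
        if self.radius < 0:
            raise SwcFormatError(
                f"radius must be nonnegative, got {self.radius} (sample {self.sample_id})"
            )


def _parse_line(line: str, lineno: int) -> SwcRecord:
    parts = line.split()
    if len(parts) != 7:
        raise SwcParseError(
            f"line {lineno}: expected 7 columns, got {len(parts)}: {line!r}"
        )
    try:
        return SwcRecord(
            sample_id=int(parts[0]),
            structure_type=int(parts[1]),
            x=float(parts[2]),
            y=float(parts[3]),
            z=float(parts[4]),
            radius=float(parts[5]),
            parent_id=int(parts[6]),
        )
    except SwcFormatError:
        raise
    except ValueError as exc:
        raise SwcParseError(f"line {lineno}: non-numeric field ({exc})") from None


def read_swc(
    source: IO[str] | str | Iterable[str],
    filter_types: Iterable[int] | None = DEFAULT_FILTER_TYPES,
) -> list[SwcRecord]:
    """Parse SWC text into records, keeping soma samples plus ``filter_types``.

    Parameters
    ----------
    source
        Text stream, string of SWC text, or iterable of lines.
    filter_types
        Structure-type codes to keep.  Soma records (type 1) are always
        kept.  ``None`` keeps everything.

    Returns
    -------
    list of :class:`SwcRecord` in file order.

    Raises
    ------
    SwcParseError, SwcFormatError, SwcConnectivityError
    """
    if isinstance(source, str):
        lines: Iterable[tuple[int, str]] = enumerate(source.splitlines(), start=1)
    else:
        lines = enumerate(source, start=1)

    keep: frozenset[int] | None = None
    if filter_types is not None:
        keep = frozenset(filter_types) | {SOMA}

    records: list[SwcRecord] = []
    seen: dict[int, SwcRecord] = {}
    dropped: set[int] = set()
    for lineno, raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        rec = _parse_line(line, lineno)
        if rec.sample_id in seen or rec.sample_id in dropped:
            raise SwcFormatError(f"line {lineno}: duplicate sample_id {rec.sample_id}")
        if keep is not None and rec.structure_type not in keep:
            dropped.add(rec.sample_id)
            continue
        if rec.parent_id != -1:
            if rec.parent_id == rec.sample_id:
                raise SwcConnectivityError(
                    f"line {lineno}: sample {rec.sample_id} is its own parent"
                )
            parent = seen.get(rec.parent_id)
            if parent is None:
                if rec.parent_id in dropped:
                    raise SwcConnectivityError(
                        f"line {lineno}: parent {rec.parent_id} of sample "
                        f"{rec.sample_id} was removed by the structure-type filter"
                    )
                raise SwcConnectivityError(
                    f"line {lineno}: parent {rec.parent_id} of sample "
                    f"{rec.sample_id} not declared before use"
                )
        seen[rec.sample_id] = rec
        records.append(rec)
    return records


def write_swc(
    records: Sequence[SwcRecord],
    header: str | None = None,
) -> str:
    """Serialize records to SWC text.

    A comment header names the generator; extra ``header`` lines (e.g.
    the seed of a synthetic neuron) are included verbatim.  Validates
    record invariants by re-parsing its own output contract: duplicate
    ids or dangling parents refuse to serialize.
    """
    seen: set[int] = set()
    for rec in records:
        if rec.sample_id in seen:
            raise SwcFormatError(f"duplicate sample_id {rec.sample_id}")
        if rec.parent_id != -1 and rec.parent_id not in seen:
            raise SwcConnectivityError(
                f"parent {rec.parent_id} of sample {rec.sample_id} "
                "not declared before use"
            )
        seen.add(rec.sample_id)

    out = ["# generated by shollkit"]
    if header:
        out.extend("# " + ln for ln in header.splitlines())
    out.append("# id type x y z radius parent")
    for rec in records:
        out.append(
            f"{rec.sample_id} {rec.structure_type} "
            f"{rec.x:.17g} {rec.y:.17g} {rec.z:.17g} {rec.radius:.17g} "
            f"{rec.parent_id}"
        )
    return "\n".join(out) + "\n"
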