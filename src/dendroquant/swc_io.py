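"""Reading and writing SWC reconstructions, including a multi-signal dialect.

Standard SWC is a whitespace-delimited text format with seven columns per
node: ``id type x y z radius parent`` (parent ``-1`` marks the root).  This
module additionally understands an extended dialect in which each node row
carries, after the seven standard columns, one ``(fraction, intensity)``
column pair per fluorescence channel:

    id type x y z radius parent  f1 asi1  [f2 asi2 ...]

``fraction`` is the fraction of the compartment volume occupied by the
channel's signal (dimensionless, in [0, 1]) and ``intensity`` is the average
signal intensity over the compartment (arbitrary units, >= 0).  An optional
comment header ``# channels: name1,name2`` names the channels in column
order.  A file with no extra columns parses as a plain reconstruction with
zero channels, so any standard SWC file is accepted unchanged.

The extended layout is this package's own documented convention: deposited
multi-signal reconstructions referenced by published work are distributed in
archive-specific layouts, and this dialect is a stand-in that degrades
gracefully to standard SWC.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np

__all__ = [
    "SwcRecord",
    "Reconstruction",
    "SwcParseError",
    "read_swc",
    "write_swc",
    "validate",
]

SOMA = 1
DENDRITE = 3

#: significant digits used when writing floats; round-trips are exact to this
WRITE_PRECISION = 6


class SwcParseError(ValueError):
    """A structural problem in an SWC file; carries the offending line number."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class SwcRecord:
    """One node of a reconstruction.

    Coordinates and radius are in micrometres. ``signal`` holds one
    ``(fraction, intensity)`` pair per channel; its length must equal the
    reconstruction's channel count.
    """

    node_id: int
    structure_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int
    signal: tuple[tuple[float, float], ...] = ()

    @property
    def diameter(self) -> float:
        """Local thickness D, taken as the node diameter (2 x radius)."""
        return 2.0 * self.radius


@dataclass
class Reconstruction:
    """A neuron reconstruction: an ordered list of SWC records plus metadata.

    The parent links must induce a single rooted tree; ``validate`` checks
    this and the per-record invariants without raising.
    """

    records: list[SwcRecord]
    channel_names: list[str] = field(default_factory=list)
    neuron_id: str = ""
    condition: str = ""
    neuron_class: str = ""
    subtype: str = ""

    @property
    def n_channels(self) -> int:
        return len(self.records[0].signal) if self.records else 0

    @property
    def root_id(self) -> int:
        roots = [r.node_id for r in self.records if r.parent_id == -1]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        return roots[0]

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, int):
            if not 0 <= channel < self.n_channels:
                raise KeyError(f"channel index {channel} out of range")
            return channel
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None


def _parse_line(
    line: str, line_no: int, n_channels: int | None
) -> tuple[SwcRecord, int]:
    fields = line.split()
    n_extra = len(fields) - 7
    if n_extra < 0 or n_extra % 2 != 0:
        raise SwcParseError(
            f"expected 7 + 2C whitespace-delimited columns, got {len(fields)}",
            line_no,
        )
    c = n_extra // 2
    if n_channels is not None and c != n_channels:
        raise SwcParseError(
            f"ragged column count: {c} signal channels here, {n_channels} elsewhere",
            line_no,
        )
    try:
        node_id = int(fields[0])
        structure = int(fields[1])
        x, y, z, radius = (float(v) for v in fields[2:6])
        parent = int(fields[6])
        extras = [float(v) for v in fields[7:]]
    except ValueError as exc:
        raise SwcParseError(f"malformed numeric field ({exc})", line_no) from None
    if node_id <= 0:
        raise SwcParseError(f"node id must be positive, got {node_id}", line_no)
    if radius <= 0:
        raise SwcParseError(f"radius must be > 0, got {radius}", line_no)
    signal = []
    for ch in range(c):
        frac, asi = extras[2 * ch], extras[2 * ch + 1]
        if not 0.0 <= frac <= 1.0:
            raise SwcParseError(
                f"channel {ch + 1} fraction {frac} outside [0, 1]", line_no
            )
        if asi < 0:
            raise SwcParseError(
                f"channel {ch + 1} intensity {asi} is negative", line_no
            )
        signal.append((frac, asi))
    return SwcRecord(node_id, structure, x, y, z, radius, parent, tuple(signal)), c


def read_swc(
    stream: IO[str] | str, expected_channels: int | None = None
) -> Reconstruction:
    """Parse an SWC or multi-signal SWC stream into a ``Reconstruction``.

    Parameters
    ----------
    stream
        A text stream, or a string holding the file contents.
    expected_channels
        If given, the file must carry exactly this many signal channels.

    Raises
    ------
    SwcParseError
        On duplicate node ids, dangling parents, non-positive radii,
        out-of-range fractions, or ragged column counts; the message names
        the offending line.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[SwcRecord] = []
    channel_names: list[str] = []
    n_channels: int | None = expected_channels
    seen: dict[int, int] = {}
    for line_no, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.lower().startswith("channels:"):
                names = body.split(":", 1)[1]
                channel_names = [n.strip() for n in names.split(",") if n.strip()]
            continue
        rec, c = _parse_line(line, line_no, n_channels)
        n_channels = c
        if rec.node_id in seen:
            raise SwcParseError(
                f"duplicate node id {rec.node_id} (first seen on line "
                f"{seen[rec.node_id]})",
                line_no,
            )
        seen[rec.node_id] = line_no
        records.append(rec)
    if not records:
        raise SwcParseError("no records in stream")
    # parents may appear after children; resolve after the full pass
    ids = {r.node_id for r in records}
    n_roots = 0
    for rec in records:
        if rec.parent_id == -1:
            n_roots += 1
        elif rec.parent_id not in ids:
            raise SwcParseError(
                f"dangling parent id {rec.parent_id} for node {rec.node_id}",
                seen[rec.node_id],
            )
    if n_roots != 1:
        raise SwcParseError(f"expected exactly one root (parent -1), found {n_roots}")
    c = n_channels or 0
    if channel_names and len(channel_names) != c:
        raise SwcParseError(
            f"header names {len(channel_names)} channels but records carry {c}"
        )
    if not channel_names:
        channel_names = [f"ch{i + 1}" for i in range(c)]
    return Reconstruction(records=records, channel_names=channel_names)


def _fmt(v: float) -> str:
    return f"{v:.{WRITE_PRECISION}g}"


def write_swc(recon: Reconstruction, stream: IO[str]) -> None:
    """Write ``recon`` in the dialect understood by :func:`read_swc`.

    Floats are written at 6 significant digits; a read/write round trip
    reproduces the reconstruction to that precision and the topology exactly.
    """
    if recon.neuron_id:
        stream.write(f"# neuron: {recon.neuron_id}\n")
    meta = [recon.condition, recon.neuron_class, recon.subtype]
    if any(meta):
        stream.write(f"# condition: {meta[0]} class: {meta[1]} subtype: {meta[2]}\n")
    if recon.n_channels:
        stream.write(f"# channels: {','.join(recon.channel_names)}\n")
    for r in recon.records:
        cols = [
            str(r.node_id),
            str(r.structure_code),
            _fmt(r.x),
            _fmt(r.y),
            _fmt(r.z),
            _fmt(r.radius),
            str(r.parent_id),
        ]
        for frac, asi in r.signal:
            cols.append(_fmt(frac))
            cols.append(_fmt(asi))
        stream.write(" ".join(cols) + "\n")


def dumps(recon: Reconstruction) -> str:
    """Serialize a reconstruction to a string (convenience over write_swc)."""
    buf = io.StringIO()
    write_swc(recon, buf)
    return buf.getvalue()


def validate(recon: Reconstruction) -> list[str]:
    """Check structural invariants; returns a list of violations (empty = valid).

    Checks: unique node ids, a single root, no dangling parents, acyclicity
    and connectedness of the parent graph, positive radii, signal fractions
    in [0, 1], intensities >= 0, and a uniform channel count.
    """
    issues: list[str] = []
    ids = [r.node_id for r in recon.records]
    if len(ids) != len(set(ids)):
        issues.append("duplicate node ids")
    by_id = {r.node_id: r for r in recon.records}
    roots = [r for r in recon.records if r.parent_id == -1]
    if len(roots) == 0:
        issues.append("no root (no record with parent -1)")
    elif len(roots) > 1:
        issues.append(f"multiple roots: {len(roots)} records with parent -1")
    for r in recon.records:
        if r.parent_id != -1 and r.parent_id not in by_id:
            issues.append(f"node {r.node_id}: dangling parent {r.parent_id}")
        if r.radius <= 0:
            issues.append(f"node {r.node_id}: non-positive radius {r.radius}")
        for ch, (frac, asi) in enumerate(r.signal):
            if not 0.0 <= frac <= 1.0:
                issues.append(
                    f"node {r.node_id}: channel {ch + 1} fraction {frac} "
                    "out of range [0, 1]"
                )
            if asi < 0:
                issues.append(
                    f"node {r.node_id}: channel {ch + 1} intensity {asi} negative"
                )
    counts = {len(r.signal) for r in recon.records}
    if len(counts) > 1:
        issues.append(f"inconsistent channel counts across records: {sorted(counts)}")
    # cycle / connectivity check by walking each node to the root
    if len(roots) == 1 and not any("dangling" in i for i in issues):
        root = roots[0].node_id
        state: dict[int, bool] = {}  # node -> reaches root
        for r in recon.records:
            path = []
            cur = r.node_id
            while cur not in state and cur != root:
                path.append(cur)
                nxt = by_id[cur].parent_id
                if nxt in path or nxt == cur:
                    issues.append(f"cycle through node {cur}")
                    for p in path:
                        state[p] = False
                    break
                cur = nxt
            else:
                ok = True if cur == root else state[cur]
                for p in path:
                    state[p] = ok
                if not ok and path:
                    issues.append(f"node {r.node_id} disconnected from root")
    return issues
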