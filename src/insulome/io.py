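"""Readers and writers for the text/image formats the pipeline consumes.

All genomic coordinates are 0-based half-open (BED convention). narrowPeak
summits are stored as an offset from the interval start; -1 in the file means
"no summit".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


class ParseError(ValueError):
    """A line could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates an invariant (coordinates, overlap, shape)."""


# ---------------------------------------------------------------------------
# genomic data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional summit and score."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")
        if self.summit_offset is not None:
            if not (0 <= self.summit_offset < self.end - self.start):
                raise ValidationError(
                    f"summit offset {self.summit_offset} outside interval "
                    f"{self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def center(self) -> int:
        """Summit position when defined, else interval midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return self.midpoint

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True)
class ContactRecord:
    """One paired-end contact (e.g. a ChIA-PET PET) between two anchors."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    count: int = 1

    def __post_init__(self) -> None:
        for c, s, e in ((self.chrom_a, self.start_a, self.end_a),
                        (self.chrom_b, self.start_b, self.end_b)):
            if s < 0 or e <= s:
                raise ValidationError(f"invalid anchor {c}:{s}-{e}")
        if self.count < 1:
            raise ValidationError(f"count must be >= 1, got {self.count}")

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom_a == self.chrom_b


class SignalTrack:
    """Sorted, non-overlapping per-chrom step function (bedGraph semantics).

    Stored as per-chromosome (starts, ends, values) arrays.  Positions not
    covered by any interval have value 0.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int, float]],
                 mapped_read_count: int | None = None):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if end <= start:
                raise ValidationError(f"invalid interval {chrom}:{start}-{end}")
            if not np.isfinite(value):
                raise ValidationError(f"non-finite value at {chrom}:{start}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        if mapped_read_count is not None and mapped_read_count <= 0:
            raise ValidationError("mapped_read_count must be positive")
        self.mapped_read_count = mapped_read_count
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            values = np.array([r[2] for r in rows], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1]))
                raise ValidationError(
                    f"overlapping intervals on {chrom} near position "
                    f"{int(starts[i + 1])}")
            self._data[chrom] = (starts, ends, values)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def __len__(self) -> int:
        return sum(len(v[0]) for v in self._data.values())

    def __iter__(self):
        for chrom in self.chroms:
            starts, ends, values = self._data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def chrom_arrays(self, chrom: str):
        """(starts, ends, values) for one chromosome; empty arrays if absent."""
        if chrom not in self._data:
            z = np.empty(0, dtype=np.int64)
            return z, z.copy(), np.empty(0, dtype=float)
        return self._data[chrom]

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Coverage-weighted mean value over [start, end); gaps count as 0."""
        if end <= start:
            raise ValidationError("empty query interval")
        starts, ends, values = self.chrom_arrays(chrom)
        if len(starts) == 0:
            return 0.0
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        s = np.maximum(starts[lo:hi], start)
        e = np.minimum(ends[lo:hi], end)
        return float(np.sum((e - s) * values[lo:hi]) / (end - start))

    def scale(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            ((c, s, e, v * factor) for c, s, e, v in self),
            mapped_read_count=self.mapped_read_count)


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts of a binding motif (JASPAR PFM)."""

    motif_id: str
    counts: np.ndarray  # L x 4, columns A,C,G,T

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValidationError("PFM counts must be L x 4")
        if self.counts.shape[0] < 1:
            raise ValidationError("PFM must have at least one position")
        if np.any(self.counts < 0):
            raise ValidationError("PFM counts must be non-negative")
        if np.any(self.counts.sum(axis=1) <= 0):
            raise ValidationError("every PFM position needs a positive row sum")

    def __len__(self) -> int:
        return self.counts.shape[0]


@dataclass
class ImageStack:
    """Greyscale voxel data, Z x Y x X, with physical pixel sizes in microns."""

    data: np.ndarray
    pixel_size_um: float = 1.0
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None, :, :]
        if self.data.ndim != 3:
            raise ValidationError("stack must be 2D or 3D greyscale")
        if np.any(self.data < 0):
            raise ValidationError("intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


# ---------------------------------------------------------------------------
# interval / contact / track readers and writers
# ---------------------------------------------------------------------------

BASES = "ACGT"


def _fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


def read_intervals(path: str | Path, dialect: str = "bed") -> list[GenomicInterval]:
    """Read BED or ENCODE narrowPeak intervals, preserving file order."""
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 3:
                raise ParseError(f"{path}:{ln}: expected >=3 columns")
            if dialect == "narrowPeak" and len(f) != 10:
                raise ParseError(f"{path}:{ln}: narrowPeak needs 10 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-integer coordinates") from exc
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = None
            if len(f) > 4 and f[4] not in (".", ""):
                score = float(f[4])
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
            summit = None
            if dialect == "narrowPeak":
                peak_col = int(f[9])
                if peak_col >= 0:
                    summit = peak_col
            try:
                out.append(GenomicInterval(f[0], start, end, name=name,
                                           score=score, strand=strand,
                                           summit_offset=summit))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{ln}: {exc}") from exc
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path,
                    dialect: str = "bed") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end),
                    iv.name or ".",
                    "0" if iv.score is None else f"{iv.score:g}",
                    iv.strand]
            if dialect == "narrowPeak":
                cols += ["0", "-1", "-1",
                         "-1" if iv.summit_offset is None else str(iv.summit_offset)]
            fh.write("\t".join(cols) + "\n")


def read_contacts(path: str | Path) -> list[ContactRecord]:
    """Read BEDPE contacts; optional column 8 is the PET count (default 1)."""
    out: list[ContactRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line)
            if len(f) < 6:
                raise ParseError(f"{path}:{ln}: BEDPE needs >=6 columns")
            try:
                count = int(f[7]) if len(f) >= 8 and f[7] not in (".", "") else 1
                rec = ContactRecord(f[0], int(f[1]), int(f[2]),
                                    f[3], int(f[4]), int(f[5]), count=count)
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            out.append(rec)
    return out


def write_contacts(contacts: Sequence[ContactRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in contacts:
            fh.write("\t".join(map(str, (c.chrom_a, c.start_a, c.end_a,
                                         c.chrom_b, c.start_b, c.end_b,
                                         ".", c.count))) + "\n")


def read_track(path: str | Path,
               mapped_read_count: int | None = None) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack."""
    rows: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 4:
                raise ParseError(f"{path}:{ln}: bedGraph needs 4 columns")
            try:
                rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-numeric field") from exc
    return SignalTrack(rows, mapped_read_count=mapped_read_count)


def write_track(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track:
            fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# JASPAR PFM
# ---------------------------------------------------------------------------

def read_pfm(path: str | Path) -> PositionFrequencyMatrix:
    """Parse a JASPAR-format PFM (header + four bracketed A/C/G/T rows)."""
    motif_id = Path(path).stem
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                motif_id = line[1:].split()[0]
                continue
            base = line[0].upper()
            if base not in BASES:
                raise ParseError(f"unexpected PFM row label {line[0]!r}")
            body = line[1:].replace("[", " ").replace("]", " ")
            rows[base] = [float(x) for x in body.split()]
    missing = [b for b in BASES if b not in rows]
    if missing:
        raise ValidationError(f"PFM missing rows for {','.join(missing)}")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise ValidationError("PFM rows have unequal lengths")
    counts = np.column_stack([rows[b] for b in BASES])
    return PositionFrequencyMatrix(motif_id=motif_id, counts=counts)


def write_pfm(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pfm.motif_id}\n")
        for j, base in enumerate(BASES):
            vals = " ".join(f"{v:g}" for v in pfm.counts[:, j])
            fh.write(f"{base} [ {vals} ]\n")


def load_ctcf_pfm() -> PositionFrequencyMatrix:
    """The bundled JASPAR CTCF matrix MA0139.1 (19 positions)."""
    return read_pfm(Path(__file__).parent / "data" / "MA0139.1.jaspar")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValidationError(f"duplicate FASTA record {name!r}")
                seqs[name] = []
            else:
                if name is None:
                    raise ParseError("sequence before first FASTA header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# TIFF stacks and CSV tables
# ---------------------------------------------------------------------------

def read_stack(path: str | Path, pixel_size_um: float = 1.0,
               z_step_um: float = 1.0) -> ImageStack:
    """Read a greyscale (multi-page) TIFF into an ImageStack."""
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[0] not in (3, 4):
        raise ValidationError("RGB images are not supported; greyscale only")
    if data.ndim not in (2, 3):
        raise ValidationError(f"unsupported TIFF dimensionality {data.ndim}")
    return ImageStack(data=data, pixel_size_um=pixel_size_um, z_step_um=z_step_um)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), stack.data)


def read_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a headered CSV into {column: float array}; '#' lines are skipped."""
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    reader = csv.reader(lines)
    header = next(reader)
    cols: dict[str, list[float]] = {h: [] for h in header}
    for row in reader:
        if len(row) != len(header):
            raise ParseError(f"{path}: ragged CSV row {row}")
        for h, v in zip(header, row):
            cols[h].append(float(v))
    return {h: np.asarray(v, dtype=float) for h, v in cols.items()}


def write_table(cols: dict[str, Sequence[float]], path: str | Path) -> None:
    header = list(cols)
    n = len(cols[header[0]])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for i in range(n):
            w.writerow([f"{cols[h][i]:.10g}" for h in header])


def read_matrix_csv(path: str | Path) -> np.ndarray:
    """Read a headerless numeric CSV matrix ('#' comment lines allowed)."""
    with open(path) as fh:
        rows = [[float(x) for x in ln.strip().split(",")]
                for ln in fh if ln.strip() and not ln.startswith("#")]
    if not rows:
        return np.empty((0, 0))
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise ParseError(f"{path}: ragged matrix CSV")
    return np.asarray(rows, dtype=float)


def write_matrix_csv(matrix: np.ndarray, path: str | Path,
                     comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        for row in np.asarray(matrix):
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")
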