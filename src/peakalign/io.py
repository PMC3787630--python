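"""Reading and writing the peak-table CSV dialect and companion files.

Peak table: UTF-8 CSV with header ``rt1,rt2,area,label,spectrum``; the
spectrum cell is space-separated ``mz:intensity`` tokens with integer m/z
and nonnegative decimal intensity; '.' decimal separator.  Lines starting
with ``#`` are comments (used to record the seed/preset of simulated data).

True-pair file: CSV with header ``ref_index,target_index``, 0-based indices
into the merged lists.

Alignment output: CSV with header ``target_index,ref_index,score,method``;
unmatched targets are omitted.
"""

from __future__ import annotations

import csv
import math
from pathlib import Path
from typing import Iterable

from .model import MassSpectrum, Peak, PeakList, TruePairSet

__all__ = [
    "PeakTableFormatError",
    "read_peak_table",
    "write_peak_table",
    "read_true_pairs",
    "write_true_pairs",
    "read_matches",
    "write_matches",
]

REQUIRED_COLUMNS = ("rt1", "rt2", "area", "label", "spectrum")


class PeakTableFormatError(ValueError):
    """A peak table violates the dialect (missing column, malformed row)."""


def _parse_float(cell: str, column: str, row: int) -> float:
    try:
        v = float(cell)
    except ValueError:
        raise PeakTableFormatError(
            f"row {row}: column {column!r} is not a number: {cell!r}"
        ) from None
    if not math.isfinite(v):
        raise PeakTableFormatError(f"row {row}: column {column!r} is not finite")
    return v


def parse_spectrum_cell(cell: str, row: int = 0) -> MassSpectrum:
    """Parse a space-separated ``mz:intensity`` token list."""
    tokens = cell.split()
    if not tokens:
        raise PeakTableFormatError(f"row {row}: empty spectrum cell")
    mzs: list[int] = []
    intens: list[float] = []
    for tok in tokens:
        head, sep, tail = tok.partition(":")
        if not sep:
            raise PeakTableFormatError(
                f"row {row}: malformed spectrum token {tok!r} (expected mz:intensity)"
            )
        try:
            mz = int(head)
        except ValueError:
            raise PeakTableFormatError(
                f"row {row}: non-integer m/z in token {tok!r}"
            ) from None
        try:
            inten = float(tail)
        except ValueError:
            raise PeakTableFormatError(
                f"row {row}: bad intensity in token {tok!r}"
            ) from None
        if inten < 0:
            raise PeakTableFormatError(
                f"row {row}: negative intensity in token {tok!r}"
            )
        mzs.append(mz)
        intens.append(inten)
    if len(set(mzs)) != len(mzs):
        raise PeakTableFormatError(f"row {row}: duplicate m/z in spectrum cell")
    order = sorted(range(len(mzs)), key=mzs.__getitem__)
    try:
        return MassSpectrum([mzs[i] for i in order], [intens[i] for i in order])
    except ValueError as exc:
        raise PeakTableFormatError(f"row {row}: {exc}") from None


def format_spectrum_cell(spectrum: MassSpectrum) -> str:
    return " ".join(
        f"{int(mz)}:{inten:.8g}"
        for mz, inten in zip(spectrum.mz_grid, spectrum.intensities)
    )


def read_peak_table(
    path: str | Path, run_id: str | None = None, role: str = ""
) -> PeakList:
    """Read a peak-table CSV; malformed rows raise, they are never dropped."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise PeakTableFormatError(f"{path}: empty peak table")
    header = [c.strip() for c in rows[0]]
    for col in REQUIRED_COLUMNS:
        if col not in header:
            raise PeakTableFormatError(f"{path}: missing required column {col!r}")
    idx = {c: header.index(c) for c in REQUIRED_COLUMNS}
    peaks = []
    for rownum, row in enumerate(rows[1:], start=1):
        if len(row) < len(header):
            raise PeakTableFormatError(f"row {rownum}: expected {len(header)} cells")
        label = row[idx["label"]].strip()
        try:
            peak = Peak(
                rt1=_parse_float(row[idx["rt1"]], "rt1", rownum),
                rt2=_parse_float(row[idx["rt2"]], "rt2", rownum),
                area=_parse_float(row[idx["area"]], "area", rownum),
                spectrum=parse_spectrum_cell(row[idx["spectrum"]], rownum),
                label=label or None,
            )
        except ValueError as exc:
            if isinstance(exc, PeakTableFormatError):
                raise
            raise PeakTableFormatError(f"row {rownum}: {exc}") from None
        peaks.append(peak)
    return PeakList(peaks, run_id=run_id if run_id is not None else path.stem, role=role)


def write_peak_table(
    pl: PeakList, path: str | Path, header_comment: str | None = None
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(REQUIRED_COLUMNS)
        for p in pl:
            writer.writerow(
                [
                    f"{p.rt1:.8g}",
                    f"{p.rt2:.8g}",
                    f"{p.area:.8g}",
                    p.label if p.label is not None else "",
                    format_spectrum_cell(p.spectrum),
                ]
            )


def read_true_pairs(path: str | Path) -> TruePairSet:
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise PeakTableFormatError(f"{path}: empty true-pair file")
    header = [c.strip() for c in rows[0]]
    for col in ("ref_index", "target_index"):
        if col not in header:
            raise PeakTableFormatError(f"{path}: missing required column {col!r}")
    ri, ti = header.index("ref_index"), header.index("target_index")
    try:
        return TruePairSet((int(r[ri]), int(r[ti])) for r in rows[1:])
    except ValueError as exc:
        raise PeakTableFormatError(f"{path}: {exc}") from None


def write_true_pairs(
    truth: TruePairSet, path: str | Path, header_comment: str | None = None
) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(["ref_index", "target_index"])
        for r, t in sorted(truth.pairs):
            writer.writerow([r, t])


def write_matches(result, path: str | Path, header_comment: str | None = None) -> None:
    """Write an AlignmentResult as ``target_index,ref_index,score,method``."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        writer = csv.writer(fh)
        writer.writerow(["target_index", "ref_index", "score", "method"])
        for t, r, score in sorted(result.matches):
            writer.writerow([t, r, f"{score:.10g}", result.method])


def read_matches(path: str | Path):
    """Read an alignment CSV back into an AlignmentResult."""
    from .align import AlignmentResult

    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].lstrip().startswith("#")]
    if not rows:
        raise PeakTableFormatError(f"{path}: empty match file")
    header = [c.strip() for c in rows[0]]
    for col in ("target_index", "ref_index", "score"):
        if col not in header:
            raise PeakTableFormatError(f"{path}: missing required column {col!r}")
    ti, ri, si = (header.index(c) for c in ("target_index", "ref_index", "score"))
    mi = header.index("method") if "method" in header else None
    matches = [(int(r[ti]), int(r[ri]), float(r[si])) for r in rows[1:]]
    method = rows[1][mi] if (mi is not None and len(rows) > 1) else "unknown"
    return AlignmentResult(matches=tuple(matches), method=method, params={})
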