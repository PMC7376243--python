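"""Data model and plain-text I/O for GC-IMS sample matrices.

A GC-IMS instrument separates volatiles first by gas-chromatograph
retention time (seconds) and then by ion-mobility drift time
(milliseconds); one sample is a dense 2D intensity matrix over that
grid.  Proprietary vendor files are out of scope: this module defines a
minimal, diffable text dialect instead —

    # sample_id: S001
    <TAB>d_1<TAB>d_2 ... d_m          (header: drift times, ms)
    r_1<TAB>v_11<TAB>v_12 ... v_1m    (one line per retention time, s)
    ...

'#'-prefixed lines carry metadata, the first non-comment line is the
drift axis, and every following line is a retention time followed by its
row of intensities, all tab-separated.  Values round-trip exactly
(written with full ``repr`` precision).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["IMSSpectrum", "SpectrumFormatError", "read_spectrum", "write_spectrum"]


class SpectrumFormatError(ValueError):
    """A spectrum file violates the text dialect (names the offending line)."""


@dataclass(frozen=True)
class IMSSpectrum:
    """One GC-IMS sample: intensities on a retention × drift grid.

    Parameters
    ----------
    sample_id
        Identifier linking the spectrum to a swab record.
    retention_axis
        Strictly increasing GC retention times, seconds.
    drift_axis
        Strictly increasing IMS drift times, milliseconds.
    intensities
        Real matrix, one row per retention time, one column per drift
        time.  Must be finite.
    """

    sample_id: str
    retention_axis: np.ndarray
    drift_axis: np.ndarray
    intensities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "retention_axis", np.asarray(self.retention_axis, dtype=float))
        object.__setattr__(self, "drift_axis", np.asarray(self.drift_axis, dtype=float))
        object.__setattr__(self, "intensities", np.asarray(self.intensities, dtype=float))
        r, d, m = self.retention_axis, self.drift_axis, self.intensities
        if r.ndim != 1 or d.ndim != 1 or r.size < 1 or d.size < 1:
            raise ValueError("axes must be 1-D with length >= 1")
        if m.shape != (r.size, d.size):
            raise ValueError(
                f"intensities shape {m.shape} does not match axes ({r.size}, {d.size})"
            )
        if not (np.all(np.diff(r) > 0) and np.all(np.diff(d) > 0)):
            raise ValueError("axes must be strictly increasing")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(d)) and np.all(np.isfinite(m))):
            raise ValueError("spectrum contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    def equals(self, other: "IMSSpectrum") -> bool:
        """Exact (bitwise value) equality of axes and intensities."""
        return (
            self.sample_id == other.sample_id
            and np.array_equal(self.retention_axis, other.retention_axis)
            and np.array_equal(self.drift_axis, other.drift_axis)
            and np.array_equal(self.intensities, other.intensities)
        )


def _parse_floats(cells: list[str], lineno: int) -> np.ndarray:
    try:
        return np.array([float(c) for c in cells], dtype=float)
    except ValueError as exc:
        raise SpectrumFormatError(f"line {lineno}: non-numeric cell ({exc})") from None


def read_spectrum(path: str | Path) -> IMSSpectrum:
    """Read a spectrum from the text dialect.

    Raises ``FileNotFoundError`` for a missing file and
    :class:`SpectrumFormatError` (naming the line number) for ragged
    rows, non-numeric cells or non-monotone axes.
    """
    path = Path(path)
    sample_id = path.stem
    drift: np.ndarray | None = None
    retention: list[float] = []
    rows: list[np.ndarray] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                if key.strip() == "sample_id":
                    sample_id = value.strip()
                continue
            cells = line.split("\t")
            if drift is None:
                # header: leading empty cell (corner) is tolerated
                if cells and cells[0].strip() == "":
                    cells = cells[1:]
                drift = _parse_floats(cells, lineno)
                if drift.size < 1:
                    raise SpectrumFormatError(f"line {lineno}: empty drift-time header")
                if not np.all(np.diff(drift) > 0):
                    raise SpectrumFormatError(
                        f"line {lineno}: drift axis not strictly increasing"
                    )
                continue
            values = _parse_floats(cells, lineno)
            if values.size != drift.size + 1:
                raise SpectrumFormatError(
                    f"line {lineno}: expected {drift.size + 1} values "
                    f"(retention + {drift.size} intensities), got {values.size}"
                )
            if retention and values[0] <= retention[-1]:
                raise SpectrumFormatError(
                    f"line {lineno}: retention axis not strictly increasing"
                )
            retention.append(values[0])
            rows.append(values[1:])
    if drift is None or not rows:
        raise SpectrumFormatError("line 1: file contains no data rows")
    try:
        return IMSSpectrum(sample_id, np.array(retention), drift, np.vstack(rows))
    except ValueError as exc:  # residual invariant violations (e.g. NaN cells)
        raise SpectrumFormatError(f"line 1: {exc}") from None


def write_spectrum(spectrum: IMSSpectrum, path: str | Path) -> None:
    """Write ``spectrum`` so that :func:`read_spectrum` reproduces it exactly."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_id: {spectrum.sample_id}\n")
        fh.write("# retention_unit: s\n# drift_unit: ms\n")
        fh.write("\t".join(repr(float(v)) for v in spectrum.drift_axis) + "\n")
        for r, row in zip(spectrum.retention_axis, spectrum.intensities):
            cells = [repr(float(r))] + [repr(float(v)) for v in row]
            fh.write("\t".join(cells) + "\n")
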