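"""Spectrum container and file I/O.

A :class:`SpectrumSet` holds a shared wavenumber grid (cm^-1, stored
strictly descending as instruments export it), an ``n_samples x
n_wavenumbers`` intensity matrix, the intensity mode, and per-sample
metadata.  Readers exist for wide CSV tables and simple single-block
JCAMP-DX files; transmittance spectra convert to absorbance via
``A = -log10(T/100)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Recognised intensity modes.
MODES = ("percent_transmittance", "absorbance", "derivative")

AGE_CLASSES = ("5yr", "6yr")
PARTS = ("tap_root", "rhizome", "lateral_root")

METADATA_COLUMNS = ["sample_id", "plant_id", "age_class", "part", "replicate_index"]


class SpectrumError(ValueError):
    """Raised for malformed spectra or invariant violations."""


@dataclass
class SpectrumSet:
    """Wavenumber grid + intensity matrix + mode + per-sample metadata.

    Parameters
    ----------
    wavenumbers
        Strictly decreasing cm^-1 grid, length equals the number of
        intensity columns.
    intensities
        ``(n_samples, n_wavenumbers)`` float matrix.
    mode
        One of ``percent_transmittance``, ``absorbance``, ``derivative``.
    metadata
        DataFrame with one row per sample; must contain a unique
        ``sample_id`` column.  ``plant_id``, ``age_class``, ``part`` and
        ``replicate_index`` are optional but required by downstream tasks
        that stratify on them.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    mode: str
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.mode not in MODES:
            raise SpectrumError(f"unknown intensity mode {self.mode!r}")
        self.validate()

    # -- invariants ---------------------------------------------------

    def validate(self) -> None:
        wn = self.wavenumbers
        if wn.ndim != 1 or wn.size == 0:
            raise SpectrumError("wavenumber grid must be a non-empty 1-D array")
        if np.any(np.diff(wn) >= 0):
            raise SpectrumError("wavenumbers must be strictly decreasing (no duplicates)")
        n, p = self.intensities.shape
        if p != wn.size:
            raise SpectrumError(
                f"intensity matrix has {p} columns but grid has {wn.size} points"
            )
        if not isinstance(self.metadata, pd.DataFrame) or "sample_id" not in self.metadata:
            raise SpectrumError("metadata must be a DataFrame with a sample_id column")
        if len(self.metadata) != n:
            raise SpectrumError(
                f"metadata has {len(self.metadata)} rows but intensity matrix has {n}"
            )
        ids = self.metadata["sample_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].tolist()
            raise SpectrumError(f"duplicate sample_id values: {dupes}")
        if self.mode == "percent_transmittance" and np.any(self.intensities <= 0):
            i, j = np.argwhere(self.intensities <= 0)[0]
            raise SpectrumError(
                "percent transmittance must be positive; offending sample "
                f"{ids.iloc[i]!r} at {wn[j]:g} cm^-1"
            )

    # -- conveniences -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.wavenumbers.size

    @property
    def sample_ids(self) -> list[str]:
        return self.metadata["sample_id"].tolist()

    def with_intensities(self, intensities: np.ndarray, mode: str | None = None,
                         wavenumbers: np.ndarray | None = None) -> "SpectrumSet":
        """Return a copy with new intensities (and optionally mode/grid)."""
        return SpectrumSet(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            intensities=intensities,
            mode=self.mode if mode is None else mode,
            metadata=self.metadata.reset_index(drop=True).copy(),
        )

    def select_samples(self, mask: Sequence[bool] | np.ndarray) -> "SpectrumSet":
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            raise SpectrumError("sample selection is empty")
        return SpectrumSet(
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities[mask],
            mode=self.mode,
            metadata=self.metadata.loc[mask].reset_index(drop=True).copy(),
        )


def _default_metadata(sample_ids: Iterable[str]) -> pd.DataFrame:
    ids = list(sample_ids)
    return pd.DataFrame({
        "sample_id": ids,
        "plant_id": pd.array([None] * len(ids), dtype=object),
        "age_class": pd.array([None] * len(ids), dtype=object),
        "part": pd.array([None] * len(ids), dtype=object),
        "replicate_index": pd.array([None] * len(ids), dtype=object),
    })


def to_absorbance(s: SpectrumSet) -> SpectrumSet:
    """Convert percent transmittance to absorbance, A = -log10(T/100).

    Already-absorbance sets pass through unchanged; derivative sets are
    rejected.
    """
    if s.mode == "absorbance":
        return s
    if s.mode != "percent_transmittance":
        raise SpectrumError(f"cannot convert mode {s.mode!r} to absorbance")
    # positivity enforced by the SpectrumSet invariant
    a = -np.log10(s.intensities / 100.0)
    return s.with_intensities(a, mode="absorbance")


# ---------------------------------------------------------------------------
# CSV wide format: "wavenumber,<sample_id>,..." + metadata sidecar
# ---------------------------------------------------------------------------

def _metadata_path(path: Path) -> Path:
    return path.with_name(path.stem + ".metadata.csv")


def write_spectra(s: SpectrumSet, path: str | Path, format: str = "csv_wide") -> Path:
    """Write a SpectrumSet as a wide CSV (wavenumber first column) plus a
    ``<stem>.metadata.csv`` sidecar; returns the spectra path."""
    if format != "csv_wide":
        raise ValueError(f"unsupported output format {format!r}")
    if s.n_samples == 0:
        raise SpectrumError("refusing to write an empty sample set")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wide = pd.DataFrame(s.intensities.T, columns=s.sample_ids)
    wide.insert(0, "wavenumber", s.wavenumbers)
    wide.to_csv(path, index=False, float_format="%.17g")
    meta = s.metadata.reindex(columns=METADATA_COLUMNS)
    # comment line records the intensity mode so a round trip needs no argument
    with open(_metadata_path(path), "w") as fh:
        fh.write(f"# mode={s.mode}\n")
        meta.to_csv(fh, index=False)
    return path


def read_spectra(path: str | Path, format: str = "csv_wide",
                 mode: str | None = None) -> SpectrumSet:
    """Read spectra from ``csv_wide`` or ``jcamp_dx``.

    For ``csv_wide``, ``path`` is the wide table; a ``<stem>.metadata.csv``
    sidecar (if present) supplies sample metadata and the stored intensity
    mode.  For ``jcamp_dx``, ``path`` may be a single file or a list of
    files, one spectrum each, which must share an identical grid.
    """
    if format == "csv_wide":
        return _read_csv_wide(Path(path), mode)
    if format == "jcamp_dx":
        paths = [Path(p) for p in (path if isinstance(path, (list, tuple)) else [path])]
        return _read_jcamp(paths, mode)
    raise ValueError(f"unsupported input format {format!r}")


def _read_csv_wide(path: Path, mode: str | None) -> SpectrumSet:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        wide = pd.read_csv(path)
    except Exception as exc:  # surface the parser's line information
        raise SpectrumError(f"unparseable CSV {path}: {exc}") from exc
    if wide.shape[1] < 2 or wide.columns[0] != "wavenumber":
        raise SpectrumError(
            f"{path}: expected header 'wavenumber,<sample_id>,...' "
            f"(line 1), got {list(wide.columns)[:3]}"
        )
    wn = wide["wavenumber"].to_numpy(float)
    if pd.Series(wn).duplicated().any():
        dup = wn[pd.Series(wn).duplicated()][0]
        raise SpectrumError(f"{path}: duplicated wavenumber {dup:g}")
    order = np.argsort(wn)[::-1]  # store descending
    sample_ids = [str(c) for c in wide.columns[1:]]
    intens = wide.iloc[:, 1:].to_numpy(float).T[:, order]

    meta_path = _metadata_path(path)
    stored_mode = None
    if meta_path.exists():
        with open(meta_path) as fh:
            first = fh.readline()
            m = re.match(r"#\s*mode=(\w+)", first)
            if m:
                stored_mode = m.group(1)
            else:
                fh.seek(0)
            meta = pd.read_csv(fh, dtype={"sample_id": str, "plant_id": str,
                                          "age_class": str, "part": str})
        meta = meta.set_index("sample_id").reindex(sample_ids).reset_index()
        if "replicate_index" in meta:
            meta["replicate_index"] = meta["replicate_index"].astype("Int64")
    else:
        meta = _default_metadata(sample_ids)
    use_mode = mode or stored_mode or "absorbance"
    return SpectrumSet(wn[order], intens, use_mode, meta)


# ---------------------------------------------------------------------------
# Minimal JCAMP-DX reader: single-block ##XYDATA=(X++(Y..Y)) or ##XYPOINTS,
# with SQZ/DIF/DUP decompression.  Multi-block (##BLOCKS) files rejected.
# ---------------------------------------------------------------------------

_SQZ = {c: i for i, c in enumerate("@ABCDEFGHI")}
_SQZ.update({c: -(i + 1) for i, c in enumerate("abcdefghi")})
_DIF = {c: i for i, c in enumerate("%JKLMNOPQR")}
_DIF.update({c: -(i + 1) for i, c in enumerate("jklmnopqr")})
_DUP = {c: i + 1 for i, c in enumerate("STUVWXYZs")}

_TOKEN = re.compile(r"[+-]?\d+\.?\d*(?:[eE][+-]?\d+)?|[@A-Ia-i%J-Rj-rS-Zs]\d*\.?\d*")


def _decode_asdf_line(line: str):
    """Decode one ASDF data line into (x_start, y_values, last_was_dif)."""
    toks = _TOKEN.findall(line)
    if not toks:
        return None
    x_start = float(toks[0])
    ys: list[float] = []
    last_dif = False
    last_delta = 0.0
    for tok in toks[1:]:
        head, rest = tok[0], tok[1:]
        if head in _SQZ:
            digit = _SQZ[head]
            sign = -1.0 if digit < 0 else 1.0
            ys.append(sign * float(f"{abs(digit)}{rest}"))
            last_dif = False
        elif head in _DIF:
            sign = -1.0 if _DIF[head] < 0 else 1.0
            delta = sign * float(f"{abs(_DIF[head])}{rest}") if rest \
                else float(_DIF[head])
            if not ys:
                raise SpectrumError("DIF token with no preceding value")
            ys.append(ys[-1] + delta)
            last_dif, last_delta = True, delta
        elif head in _DUP:
            count = int(str(_DUP[head]) + rest) if rest else _DUP[head]
            if not ys:
                raise SpectrumError("DUP token with no preceding value")
            for _ in range(count - 1):
                # DUP re-applies the previous token: a difference in DIF
                # form, a plain repeat otherwise
                ys.append(ys[-1] + (last_delta if last_dif else 0.0))
        else:
            ys.append(float(tok))
            last_dif = False
    return x_start, ys, last_dif


def _read_one_jcamp(path: Path) -> tuple[np.ndarray, np.ndarray, str | None]:
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if re.search(r"##BLOCKS\s*=", text, re.I):
        raise SpectrumError(f"{path}: multi-block JCAMP-DX files are not supported")

    def header(key: str, default=None):
        m = re.search(rf"^##\s*{key}\s*=\s*(.+)$", text, re.M | re.I)
        return m.group(1).strip() if m else default

    xfactor = float(header("XFACTOR", "1") or 1)
    yfactor = float(header("YFACTOR", "1") or 1)
    yunits = (header("YUNITS") or "").upper()
    mode = None
    if "TRANSMITTANCE" in yunits:
        mode = "percent_transmittance"
    elif "ABSORBANCE" in yunits:
        mode = "absorbance"

    m = re.search(r"##\s*(XYDATA|XYPOINTS)\s*=\s*([^\n]*)\n(.*?)(?=##|\Z)",
                  text, re.S | re.I)
    if m is None:
        raise SpectrumError(f"{path}: no ##XYDATA or ##XYPOINTS block found")
    kind, form, body = m.group(1).upper(), m.group(2), m.group(3)

    xs: list[float] = []
    ys: list[float] = []
    if kind == "XYPOINTS" or "XY..XY" in form.upper().replace(" ", ""):
        for ln_no, line in enumerate(body.strip().splitlines(), 1):
            for pair in re.split(r"[;\s]+", line.strip()):
                if not pair:
                    continue
                try:
                    x_str, y_str = re.split(r",", pair)
                    xs.append(float(x_str))
                    ys.append(float(y_str))
                except ValueError as exc:
                    raise SpectrumError(
                        f"{path}: bad XY pair {pair!r} on data line {ln_no}") from exc
    else:  # (X++(Y..Y)) ASDF
        prev_pts = None
        last_dif_prev = False
        for ln_no, line in enumerate(body.strip().splitlines(), 1):
            decoded = _decode_asdf_line(line.strip())
            if decoded is None:
                continue
            x_start, yvals, last_dif = decoded
            if prev_pts is not None and last_dif_prev:
                # Y-value check line: first y duplicates the previous line's last
                if yvals and abs(yvals[0] - prev_pts) > 1e-6 * max(1, abs(prev_pts)):
                    raise SpectrumError(
                        f"{path}: DIF checkpoint mismatch on data line {ln_no}")
                yvals = yvals[1:] if yvals else yvals
            if not xs:
                x0 = x_start
            ys.extend(yvals)
            prev_pts = ys[-1] if ys else None
            last_dif_prev = last_dif
        first_x = float(header("FIRSTX", x0 if ys else 0))
        last_x = float(header("LASTX", first_x))
        npts = int(float(header("NPOINTS", len(ys))))
        if npts != len(ys):
            raise SpectrumError(
                f"{path}: NPOINTS={npts} but decoded {len(ys)} values")
        xs = list(np.linspace(first_x, last_x, npts))
        xfactor = 1.0  # FIRSTX/LASTX already in real units

    x = np.asarray(xs, float) * xfactor
    y = np.asarray(ys, float) * yfactor
    return x, y, mode


def _read_jcamp(paths: list[Path], mode: str | None) -> SpectrumSet:
    grids, rows, modes = [], [], []
    for p in paths:
        x, y, m = _read_one_jcamp(p)
        order = np.argsort(x)[::-1]
        grids.append(x[order])
        rows.append(y[order])
        modes.append(m)
    ref = grids[0]
    for p, g in zip(paths[1:], grids[1:]):
        if g.shape != ref.shape or not np.allclose(g, ref, atol=1e-6):
            raise SpectrumError(
                f"grid mismatch: {p} does not share the grid of {paths[0]} "
                "(no silent interpolation)")
    use_mode = mode or next((m for m in modes if m), None) or "absorbance"
    ids = [p.stem for p in paths]
    if len(set(ids)) != len(ids):
        ids = [f"{p.stem}_{i}" for i, p in enumerate(paths)]
    return SpectrumSet(ref, np.vstack(rows), use_mode, _default_metadata(ids))
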