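"""Acquisition-geometry and signal-table I/O.

Handles the two-file whitespace gradient-table dialect (one line of b-values,
three lines of direction components), the grouping of acquisition volumes into
b-shells, and long-format per-ROI signal tables stored as delimited text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BTable",
    "Shell",
    "ShellTable",
    "ROISignalTable",
    "read_btable",
    "write_btable",
    "group_shells",
    "read_roi_signals",
    "write_roi_signals",
    "SIGNAL_COLUMNS",
]

#: required columns of a long-format ROI signal table
SIGNAL_COLUMNS = ("subject", "roi", "volume", "bval", "signal")

_DIRECTION_NORM_TOL = 1e-3


@dataclass(frozen=True)
class BTable:
    """Per-volume acquisition geometry: diffusion weighting and gradient direction.

    Parameters
    ----------
    b_values : (n,) array
        Diffusion weightings in s/mm²; all non-negative.
    directions : (n, 3) array
        Unit gradient directions. Volumes with b = 0 may carry zero-vectors.
    """

    b_values: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        d = np.asarray(self.directions, dtype=float)
        if d.ndim != 2 or d.shape[1] != 3:
            raise ValidationError(f"directions must be (n, 3); got shape {d.shape}")
        if b.shape[0] != d.shape[0]:
            raise ValidationError(
                f"b_values has {b.shape[0]} entries but directions has {d.shape[0]} rows"
            )
        if np.any(b < 0):
            raise ValidationError("b-values must be non-negative")
        norms = np.linalg.norm(d, axis=1)
        weighted = b > 0
        bad = weighted & (np.abs(norms - 1.0) > _DIRECTION_NORM_TOL)
        if np.any(bad):
            idx = int(np.flatnonzero(bad)[0])
            raise ValidationError(
                f"direction of weighted volume {idx} has norm {norms[idx]:.6f}, expected 1"
            )
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", d)

    @property
    def n_volumes(self) -> int:
        return int(self.b_values.shape[0])

    def __len__(self) -> int:
        return self.n_volumes


@dataclass(frozen=True)
class Shell:
    """One b-shell: its center b-value and the volume indices it contains."""

    b: float
    volumes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "volumes", np.asarray(self.volumes, dtype=int))

    @property
    def n_volumes(self) -> int:
        return int(self.volumes.shape[0])


@dataclass(frozen=True)
class ShellTable:
    """Ordered partition of acquisition volumes into b-shells.

    Shell centers are strictly increasing; if a b = 0 shell exists it is first.
    Every volume index appears in exactly one shell.
    """

    shells: tuple[Shell, ...]

    def __post_init__(self) -> None:
        shells = tuple(self.shells)
        centers = [s.b for s in shells]
        if any(b2 <= b1 for b1, b2 in zip(centers, centers[1:])):
            raise ValidationError("shell centers must be strictly increasing")
        all_idx = np.concatenate([s.volumes for s in shells]) if shells else np.array([], int)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValidationError("a volume index appears in more than one shell")
        object.__setattr__(self, "shells", shells)

    @property
    def b_values(self) -> np.ndarray:
        """Shell center b-values, ascending."""
        return np.array([s.b for s in self.shells])

    @property
    def n_volumes(self) -> int:
        return int(sum(s.n_volumes for s in self.shells))

    def __len__(self) -> int:
        return len(self.shells)

    def __iter__(self):
        return iter(self.shells)


def _parse_numeric_line(line: str, lineno: int, path: str) -> list[float]:
    out = []
    for col, tok in enumerate(line.split()):
        try:
            out.append(float(tok))
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric token {tok!r} at line {lineno}, column {col + 1}"
            ) from None
    return out


def read_btable(bval_path: str | Path, bvec_path: str | Path) -> BTable:
    """Read a gradient table from the two-file whitespace dialect.

    The b-value file holds one whitespace-separated numeric line; the direction
    file holds three such lines (x, y, z components), each with as many entries
    as there are b-values.
    """
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    blines = [ln for ln in bval_path.read_text().splitlines() if ln.strip()]
    if len(blines) != 1:
        raise FormatError(f"{bval_path}: expected one numeric line, found {len(blines)}")
    bvals = _parse_numeric_line(blines[0], 1, str(bval_path))

    vlines = [ln for ln in bvec_path.read_text().splitlines() if ln.strip()]
    if len(vlines) != 3:
        raise FormatError(f"{bvec_path}: expected three numeric lines, found {len(vlines)}")
    rows = [_parse_numeric_line(ln, i + 1, str(bvec_path)) for i, ln in enumerate(vlines)]
    counts = {len(r) for r in rows}
    if len(counts) != 1 or counts != {len(bvals)}:
        raise FormatError(
            f"gradient table length mismatch: {bval_path} has {len(bvals)} b-values but "
            f"{bvec_path} has rows of length {sorted(len(r) for r in rows)}"
        )
    directions = np.array(rows, dtype=float).T
    return BTable(b_values=np.array(bvals), directions=directions)


def write_btable(btable: BTable, bval_path: str | Path, bvec_path: str | Path) -> None:
    """Write a gradient table in the two-file whitespace dialect (read_btable inverse)."""
    fmt = lambda x: format(float(x), ".17g")
    Path(bval_path).write_text(" ".join(fmt(b) for b in btable.b_values) + "\n")
    lines = [" ".join(fmt(v) for v in btable.directions[:, k]) for k in range(3)]
    Path(bvec_path).write_text("\n".join(lines) + "\n")


def group_shells(btable: BTable, tolerance: float = 25.0) -> ShellTable:
    """Partition volumes into b-shells by clustering b-values.

    Volumes are clustered greedily in ascending b order: a volume joins the
    current shell while its b-value is within `tolerance` of the shell's running
    mean, else it starts a new shell. Centers are the mean b within each group.
    """
    if tolerance < 0:
        raise ValidationError("tolerance must be non-negative")
    b = btable.b_values
    order = np.argsort(b, kind="stable")
    shells: list[tuple[list[int], float]] = []  # (member indices, running sum)
    for idx in order:
        bi = b[idx]
        if shells:
            members, total = shells[-1]
            center = total / len(members)
            if bi - center <= tolerance:
                members.append(int(idx))
                shells[-1] = (members, total + bi)
                continue
        shells.append(([int(idx)], float(bi)))
    out = []
    for members, total in shells:
        vals = b[members]
        if vals.max() - vals.min() > tolerance:
            logger.warning(
                "shell centered at %.1f s/mm² spans %.1f s/mm², wider than tolerance %.1f",
                total / len(members), vals.max() - vals.min(), tolerance,
            )
        out.append(Shell(b=total / len(members), volumes=np.array(sorted(members))))
    return ShellTable(shells=tuple(out))


@dataclass(frozen=True)
class ROISignalTable:
    """Long-format per-ROI signal table.

    One row per (subject, ROI, volume) with the volume's b-value and the
    non-negative magnitude signal in arbitrary units.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"signal table missing required columns: {missing}")
        df = df.loc[:, list(SIGNAL_COLUMNS)].copy()
        df["volume"] = df["volume"].astype(int)
        df["bval"] = df["bval"].astype(float)
        df["signal"] = df["signal"].astype(float)
        if (df["signal"] < 0).any():
            bad = df.loc[df["signal"] < 0].iloc[0]
            raise ValidationError(
                f"negative signal {bad['signal']} for subject={bad['subject']!r} "
                f"roi={bad['roi']!r} volume={int(bad['volume'])}"
            )
        if df.duplicated(subset=["subject", "roi", "volume"]).any():
            bad = df.loc[df.duplicated(subset=["subject", "roi", "volume"])].iloc[0]
            raise ValidationError(
                f"duplicate (subject, roi, volume) = "
                f"({bad['subject']!r}, {bad['roi']!r}, {int(bad['volume'])})"
            )
        # b-values must be consistent with a single gradient table per subject
        nb = df.groupby(["subject", "volume"])["bval"].nunique()
        if (nb > 1).any():
            subj, vol = nb[nb > 1].index[0]
            raise ValidationError(
                f"subject {subj!r} volume {vol} carries inconsistent b-values across ROIs"
            )
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.frame["subject"]))

    @property
    def rois(self) -> list:
        return list(pd.unique(self.frame["roi"]))

    def signals_for(self, subject, roi) -> np.ndarray:
        """Per-volume signal vector for one (subject, ROI), ordered by volume index."""
        sel = self.frame[(self.frame["subject"] == subject) & (self.frame["roi"] == roi)]
        sel = sel.sort_values("volume")
        n = int(sel["volume"].max()) + 1 if len(sel) else 0
        out = np.full(n, np.nan)
        out[sel["volume"].to_numpy()] = sel["signal"].to_numpy()
        return out


def read_roi_signals(path: str | Path) -> ROISignalTable:
    """Read a long-format ROI signal table from comma-delimited text with header."""
    df = pd.read_csv(path)
    return ROISignalTable(frame=df)


def write_roi_signals(table: ROISignalTable, path: str | Path) -> None:
    """Write an ROI signal table as comma-delimited text (read_roi_signals inverse)."""
    df = table.frame.copy()
    df.to_csv(path, index=False, float_format="%.17g")
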