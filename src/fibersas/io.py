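"""Reduced-curve file I/O and flat config handling.

Curves travel as whitespace-delimited ASCII with 3 columns (Q, I, sigma)
or 4 (plus dQ); ``#`` starts a comment.  Header comments are preserved in
the curve metadata, and ``key: value`` comments written by this package
round-trip as typed metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


@dataclass
class ScatteringCurve:
    """A reduced 1-D scattering dataset.

    ``q`` in 1/A strictly increasing, ``intensity`` and ``sigma`` in 1/cm
    with sigma > 0, optional resolution column ``dq``; free-form
    ``metadata`` (radiation, f_d2o, temperature, label, ...).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    dq: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.dq is not None:
            self.dq = np.asarray(self.dq, dtype=float)
        n = self.q.size
        if self.intensity.size != n or self.sigma.size != n:
            raise ValueError("q, intensity and sigma lengths differ")
        if self.dq is not None and self.dq.size != n:
            raise ValueError("dq length differs from q")
        if n == 0:
            raise ValueError("empty curve")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")

    def __len__(self) -> int:
        return int(self.q.size)


def read_curve(path: str | Path) -> ScatteringCurve:
    """Read a 3/4-column ASCII curve; malformed rows raise with line numbers."""
    path = Path(path)
    rows: list[list[float]] = []
    comments: list[str] = []
    metadata: dict = {}
    ncols: int | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                text = line.lstrip("#").strip()
                if ":" in text:
                    key, _, val = text.partition(":")
                    if key.strip() and " " not in key.strip():
                        try:
                            metadata[key.strip()] = yaml.safe_load(val.strip())
                            continue
                        except yaml.YAMLError:
                            pass
                comments.append(text)
                continue
            parts = line.split()
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if len(values) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns, got {len(values)}")
            if ncols is None:
                ncols = len(values)
            elif len(values) != ncols:
                raise ValueError(
                    f"{path}:{lineno}: inconsistent column count ({len(values)} vs {ncols})"
                )
            rows.append(values[:4])
    if not rows:
        raise ValueError(f"{path}: no data rows")
    data = np.asarray(rows, dtype=float)
    if comments:
        metadata.setdefault("comments", comments)
    dq = data[:, 3] if data.shape[1] >= 4 and ncols and ncols >= 4 else None
    try:
        return ScatteringCurve(data[:, 0], data[:, 1], data[:, 2], dq=dq, metadata=metadata)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_curve(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve with metadata as ``# key: value`` header comments."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# columns: Q(1/A) I(1/cm) sigma(1/cm)")
        if curve.dq is not None:
            fh.write(" dQ(1/A)")
        fh.write("\n")
        for key, val in curve.metadata.items():
            if key in ("comments", "columns"):
                continue
            fh.write(f"# {key}: {val}\n")
        for comment in curve.metadata.get("comments", []):
            fh.write(f"# {comment}\n")
        cols = [curve.q, curve.intensity, curve.sigma]
        if curve.dq is not None:
            cols.append(curve.dq)
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.8e}" for v in row) + "\n")


def read_config(path: str | Path) -> dict:
    """Read a flat key: value config (sections as nested mappings)."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
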