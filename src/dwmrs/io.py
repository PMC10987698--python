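"""Plain-text interchange formats tying the pipeline stages together.

Every file is versioned: CSV files start with a ``# dwmrs.<kind>/<v>``
comment line, JSON documents carry a ``"schema"`` field. Readers check the
version and validate the column contract, reporting malformed rows with
their line number, so no stage ever has to peek into another stage's
internals.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSIONS = {
    "shots": 1,
    "spectra": 1,
    "quant": 1,
    "curves": 1,
    "fits": 1,
    "stats": 1,
    "protocol": 1,
    "truth": 1,
    "config": 1,
    "report": 1,
}

_CSV_COLUMNS = {
    "shots": ["b_value", "shot_index", "point_index", "real", "imag"],
    "spectra": ["animal", "week", "b_value", "point_index", "real", "imag"],
    "quant": ["animal", "week", "b_value", "metabolite", "amplitude", "crlb_pct"],
    "curves": ["animal", "week", "metabolite", "b_value", "s_norm"],
}


def _schema_tag(kind: str) -> str:
    return f"dwmrs.{kind}/{SCHEMA_VERSIONS[kind]}"


def write_csv(df: pd.DataFrame, path: str | Path, kind: str) -> Path:
    path = Path(path)
    cols = _CSV_COLUMNS[kind]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{kind} table missing columns {sorted(missing)}")
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# {_schema_tag(kind)}\n")
        df[cols].to_csv(fh, index=False, lineterminator="\n")
    return path


def read_csv(path: str | Path, kind: str) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        expected = f"# {_schema_tag(kind)}"
        if header != expected:
            raise ValueError(
                f"{path}: unknown or missing schema line {header!r}; expected {expected!r}"
            )
        df = pd.read_csv(fh)
    cols = _CSV_COLUMNS[kind]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    numeric = [c for c in cols if c not in ("animal", "week", "metabolite")]
    for c in numeric:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            # +3: 1-based, schema line, column header
            raise ValueError(
                f"{path}: malformed value in column {c!r} at line {bad[0] + 3}"
            )
        df[c] = vals
    return df


def write_json(obj: dict, path: str | Path, kind: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"schema": _schema_tag(kind), **obj}
    path.write_text(json.dumps(_plain(doc), indent=1, sort_keys=True) + "\n")
    return path


def read_json(path: str | Path, kind: str) -> dict:
    path = Path(path)
    doc = json.loads(path.read_text())
    tag = doc.get("schema")
    if tag != _schema_tag(kind):
        raise ValueError(
            f"{path}: unknown schema {tag!r}; expected {_schema_tag(kind)!r}"
        )
    doc.pop("schema")
    return doc


def _plain(obj):
    """JSON-serializable copy: dataclasses → dicts, ndarrays → lists."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# -- shot-level container ----------------------------------------------------


def shots_to_frame(spectra_by_b: dict[float, np.ndarray]) -> pd.DataFrame:
    """Flatten a {b: (n_shots, n_points) complex spectra} mapping into the
    documented long format."""
    frames = []
    for b, arr in spectra_by_b.items():
        n_shots, n_points = arr.shape
        frames.append(
            pd.DataFrame(
                {
                    "b_value": np.repeat(b, n_shots * n_points),
                    "shot_index": np.repeat(np.arange(n_shots), n_points),
                    "point_index": np.tile(np.arange(n_points), n_shots),
                    "real": arr.real.ravel(),
                    "imag": arr.imag.ravel(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_shots(df: pd.DataFrame) -> dict[float, np.ndarray]:
    """Inverse of :func:`shots_to_frame`."""
    out: dict[float, np.ndarray] = {}
    for b, grp in df.groupby("b_value"):
        n_shots = int(grp["shot_index"].max()) + 1
        n_points = int(grp["point_index"].max()) + 1
        if len(grp) != n_shots * n_points:
            raise ValueError(f"ragged shot table at b={b}")
        grp = grp.sort_values(["shot_index", "point_index"])
        arr = (grp["real"].to_numpy() + 1j * grp["imag"].to_numpy()).reshape(
            n_shots, n_points
        )
        out[float(b)] = arr
    return out
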