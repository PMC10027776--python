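"""CSV readers/writers, packaged fixtures, report rendering, and run logging.

CSV (comma, header row, UTF-8) is the single tabular dialect.  Item tables
are persons x items with a header of item labels; covariance matrices are
labeled square CSVs (first row and column hold variable labels) checked for
symmetry to 1e-8 and then symmetrized exactly.

The packaged fixtures are the 3x3 covariance matrices of the verbal and
speed test triads from the classic Holzinger-Swineford cognitive battery
(scaled scores), plus the published per-test reliabilities, so the whole
reliability pipeline runs with no external data.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import __version__
from .cfa import SampleMoments
from .composites import ItemMatrix
from .errors import InputError
from .reliability import ComponentReliabilities, ReliabilityReport

__all__ = [
    "read_item_table",
    "write_scores",
    "read_cov_matrix",
    "read_reliabilities",
    "render_report",
    "RunLog",
    "load_verbal_moments",
    "load_speed_moments",
    "load_test_reliabilities",
]


def read_item_table(path) -> ItemMatrix:
    """Read a persons x items CSV (header row of item labels).

    Empty cells and the token ``NA`` are treated as missing; any other
    non-numeric cell is a parse error naming its row and column.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise InputError(
                f"non-numeric value {df[col].iloc[row]!r} at row {row}, column '{col}'"
            )
        values[:, j] = coerced.to_numpy(dtype=float)
    return ItemMatrix(values, list(df.columns))


def write_scores(scores, path, columns=None) -> None:
    """Write per-person scores as a CSV keyed by row index."""
    arr = np.asarray(scores, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if columns is None:
        columns = ["score"] if arr.shape[1] == 1 else [
            f"score{g + 1}" for g in range(arr.shape[1])]
    pd.DataFrame(arr, columns=columns).to_csv(path, index_label="row")


def read_cov_matrix(path, n: int = None, means=None) -> SampleMoments:
    """Read a labeled square covariance CSV into :class:`SampleMoments`.

    Symmetry is enforced to 1e-8 and the matrix then symmetrized exactly,
    so a transposed file reads identically.  ``n`` and ``means`` are
    optional companion facts not stored in the matrix file.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise InputError(f"covariance CSV is {df.shape[0]}x{df.shape[1]}, not square")
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise InputError("row labels do not match column labels")
    return SampleMoments(df.to_numpy(dtype=float), labels=list(df.columns),
                         means=means, n=n)


def read_reliabilities(path, labels=None) -> ComponentReliabilities:
    """Read per-variable reliabilities from a 2-column CSV (variable, r_xx)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise InputError("reliability CSV needs columns: variable, r_xx")
    df = df.set_index(df.columns[0])
    series = df[df.columns[0]].astype(float)
    if labels is not None:
        missing = [v for v in labels if v not in series.index]
        if missing:
            raise InputError(f"reliabilities missing for: {missing}")
        series = series.loc[list(labels)]
    return ComponentReliabilities(series.to_numpy())


# ---------------------------------------------------------------------------
# Packaged fixtures (Holzinger-Swineford verbal & speed triads, scaled scores)
# ---------------------------------------------------------------------------

def _fixture(name: str):
    return resources.files("cttkit.data").joinpath(name)


def load_verbal_moments() -> SampleMoments:
    """3x3 covariance matrix of the verbal tests (x06, x07, x09)."""
    with resources.as_file(_fixture("holzinger_verbal_cov.csv")) as p:
        return read_cov_matrix(p)


def load_speed_moments() -> SampleMoments:
    """3x3 covariance matrix of the speed tests (x10, x12, x13)."""
    with resources.as_file(_fixture("holzinger_speed_cov.csv")) as p:
        return read_cov_matrix(p)


def load_test_reliabilities(labels=None) -> ComponentReliabilities:
    """Published reliabilities of the six tests (school-average values)."""
    with resources.as_file(_fixture("holzinger_test_reliabilities.csv")) as p:
        return read_reliabilities(p, labels=labels)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _round(obj, nd=3):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, nd) for v in obj]
    return obj


def render_report(results, format: str = "json", warnings=None) -> str:
    """Render an analysis result as machine-stable JSON or an aligned text block.

    Values are carried at full precision internally; rounding to 3 decimals
    happens only here, at render time.  An empty warning list produces no
    warnings section.
    """
    if hasattr(results, "to_dict"):
        payload = results.to_dict()
    elif isinstance(results, dict):
        payload = dict(results)
    else:
        raise InputError(f"cannot render object of type {type(results).__name__}")
    warnings = list(warnings or []) + list(payload.pop("warnings", []) or [])

    if format == "json":
        if warnings:
            payload["warnings"] = warnings
        return json.dumps(payload, indent=2, default=_json_default)
    if format != "text":
        raise InputError(f"unknown report format {format!r}")

    lines = []
    if isinstance(results, ReliabilityReport):
        lines.append("Reliability report")
        lines.append("-" * 34)
        label = {
            "alpha": "coefficient alpha",
            "omega_total": "omega_T",
            "fs_reliability": "factor-score reliability",
            "sum_reliability": "sum-score reliability",
            "fs_sum_correlation": "r(factor score, sum score)",
            "composite_reliability": "composite reliability",
        }
        for key, name in label.items():
            val = payload.get(key)
            if val is not None:
                nd = 4 if key == "fs_sum_correlation" else 3
                lines.append(f"{name:<28s}{val:>{6 + nd}.{nd}f}")
    else:
        lines.append(type(results).__name__ if not isinstance(results, dict)
                     else "Report")
        lines.append("-" * 34)
        lines.extend(_text_lines(_round(payload)))
    if warnings:
        lines.append("")
        lines.append("Warnings:")
        lines.extend(f"  - {w}" for w in warnings)
    return "\n".join(lines) + "\n"


def _text_lines(obj, indent=0):
    pad = "  " * indent
    out = []
    if isinstance(obj, dict):
        for k, v in obj.items():
            if isinstance(v, (dict, list)):
                out.append(f"{pad}{k}:")
                out.extend(_text_lines(v, indent + 1))
            else:
                out.append(f"{pad}{k}: {v}")
    elif isinstance(obj, list):
        for v in obj:
            out.append(f"{pad}- {v}")
    else:
        out.append(f"{pad}{obj}")
    return out


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Run log
# ---------------------------------------------------------------------------

@dataclass
class RunLog:
    """Timestamped record of one analysis run: steps, warnings, seeds."""

    steps: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)
    version: str = __version__

    def step(self, message: str) -> None:
        stamp = datetime.datetime.now(datetime.timezone.utc).isoformat(
            timespec="seconds")
        self.steps.append(f"{stamp} {message}")

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def record_seed(self, name: str, seed) -> None:
        if seed is not None:
            self.seeds[name] = int(seed)

    def to_dict(self) -> dict:
        return {
            "software_version": self.version,
            "steps": list(self.steps),
            "warnings": list(self.warnings),
            "seeds": dict(self.seeds),
        }
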