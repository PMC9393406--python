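"""Assemble the non-negative stacked multimodal NMF input.

Each MRI metric arrives as a vertex x subject table. The fixed pipeline is

    mask -> scanner residualization -> per-vertex z-scoring
         -> metric-wise stacking -> global min-shift

which yields one non-negative matrix of shape
(n_valid_vertices, n_subjects * n_metrics) ready for NMF.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from cortexlv.errors import SchemaError, TableParseError

#: Canonical metric stacking order: structural metrics first, then the
#: diffusion metrics sampled at the cortical mid-surface.
METRICS = ("CT", "SA", "MD", "FA", "RD")

#: Metrics that are physically non-negative (diffusivities / anisotropy).
DIFFUSION_METRICS = ("MD", "FA", "RD")


@dataclass
class VertexMetricMatrix:
    """One metric's vertex x subject values with mask and scanner labels.

    ``values[i, j]`` is the metric value at masked-in vertex ``mask[i]``
    for subject ``subject_ids[j]``.
    """

    metric_name: str
    values: np.ndarray
    subject_ids: list[str]
    scanner_labels: list[str]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=int)
        if self.metric_name not in METRICS:
            raise SchemaError(
                f"unknown metric {self.metric_name!r}; expected one of {METRICS}"
            )
        if self.values.ndim != 2:
            raise SchemaError("values must be 2-D (vertices x subjects)")
        if np.isnan(self.values).any():
            raise TableParseError(f"{self.metric_name}: values contain NaN")
        if len(self.subject_ids) != self.values.shape[1]:
            raise SchemaError("subject_ids length does not match column count")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise SchemaError("subject_ids are not unique")
        if len(self.scanner_labels) != len(self.subject_ids):
            raise SchemaError("scanner_labels length does not match subject_ids")
        if len(self.mask) != self.values.shape[0]:
            raise SchemaError("mask length does not match row count")
        if len(self.mask) > 1 and not np.all(np.diff(self.mask) > 0):
            raise SchemaError("mask indices must be strictly increasing")

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]


@dataclass
class StackedInput:
    """The fused non-negative NMF input matrix.

    ``column_index[j] == (subject_id, metric_name)`` maps columns back to
    their origin; ``shift`` is the (non-positive) global minimum that was
    subtracted so the matrix minimum is exactly zero.
    """

    matrix: np.ndarray
    shift: float
    column_index: list[tuple[str, str]]
    mask: np.ndarray
    scanner_labels: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if len(self.column_index) != self.matrix.shape[1]:
            raise SchemaError("column_index does not cover all columns")
        if len(set(self.column_index)) != len(self.column_index):
            raise SchemaError("column_index is not a bijection")
        gmin = float(self.matrix.min())
        if gmin < -1e-12:
            raise SchemaError("stacked matrix must be non-negative")
        if self.shift < 0 and abs(gmin) > 1e-12:
            # a shift was applied, so the minimum must sit exactly at zero
            raise SchemaError("shifted matrix minimum must be 0")

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for sid, _ in self.column_index:
            seen.setdefault(sid)
        return list(seen)

    def columns_for_subject(self, subject_id: str) -> list[int]:
        return [
            j for j, (sid, _) in enumerate(self.column_index) if sid == subject_id
        ]

    def unstack(self) -> dict[str, np.ndarray]:
        """Recover the per-metric blocks (shift added back)."""
        out: dict[str, np.ndarray] = {}
        for metric in METRICS:
            cols = [j for j, (_, m) in enumerate(self.column_index) if m == metric]
            if cols:
                out[metric] = self.matrix[:, cols] + self.shift
        return out


# ---------------------------------------------------------------------------
# readers / writers


def write_vertex_table(m: VertexMetricMatrix, path: str | Path) -> None:
    """Write a metric table as TSV: first column vertex index, header = IDs."""
    df = pd.DataFrame(m.values, index=m.mask, columns=m.subject_ids)
    df.index.name = "vertex"
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    Path(path).write_text("".join(f"{int(v)}\n" for v in mask))


def read_mask(path: str | Path) -> np.ndarray:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    mask = np.array([int(ln) for ln in lines], dtype=int)
    if len(mask) > 1 and not np.all(np.diff(mask) > 0):
        raise SchemaError(f"mask file {path}: indices must be strictly increasing")
    return mask


def read_subjects(path: str | Path) -> pd.DataFrame:
    """Read the subject sidecar CSV with columns subject_id, scanner."""
    df = pd.read_csv(path, dtype={"subject_id": str, "scanner": str})
    for col in ("subject_id", "scanner"):
        if col not in df.columns:
            raise SchemaError(f"subjects file {path} lacks column {col!r}")
    return df


def load_vertex_table(
    path: str | Path,
    mask_path: str | Path,
    metric_name: str,
    subjects_file: str | Path,
) -> VertexMetricMatrix:
    """Read one metric's TSV, restrict to masked-in vertices in mask order."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    subjects = read_subjects(subjects_file)
    expected = list(subjects["subject_id"])
    header = [str(c) for c in df.columns]
    if header != expected:
        raise SchemaError(
            f"{path}: header subject IDs do not match subjects file "
            f"({header[:3]}... vs {expected[:3]}...)"
        )
    if df.isna().any().any():
        rows, cols = np.nonzero(df.isna().to_numpy())
        vertex = df.index[rows[0]]
        subject = header[cols[0]]
        raise TableParseError(
            f"{path}: missing value at vertex {vertex}, subject {subject}"
        )
    mask = read_mask(mask_path)
    missing = set(mask.tolist()) - set(int(i) for i in df.index)
    if missing:
        raise SchemaError(f"{path}: mask vertices absent from table: {sorted(missing)[:5]}")
    values = df.loc[mask].to_numpy(dtype=float)
    return VertexMetricMatrix(
        metric_name=metric_name,
        values=values,
        subject_ids=expected,
        scanner_labels=list(subjects["scanner"]),
        mask=mask,
    )


# ---------------------------------------------------------------------------
# pipeline stages


def residualize_scanner(m: VertexMetricMatrix) -> VertexMetricMatrix:
    """Regress scanner out of every vertex row.

    OLS of value on scanner indicators is equivalent to subtracting the
    per-scanner mean at each vertex, leaving per-scanner vertex means at 0.
    A scanner level with a single subject forms its own group, so its
    residuals are exactly 0 (a warning is emitted: that subject carries no
    interindividual information after residualization).
    """
    labels = np.asarray(m.scanner_labels)
    values = m.values.copy()
    levels, counts = np.unique(labels, return_counts=True)
    for level, count in zip(levels, counts):
        if count == 1 and len(levels) > 1:
            warnings.warn(
                f"scanner level {level!r} has a single subject; its residuals are 0",
                stacklevel=2,
            )
        sel = labels == level
        values[:, sel] -= values[:, sel].mean(axis=1, keepdims=True)
    return replace(m, values=values)


def zscore_vertices(m: VertexMetricMatrix) -> VertexMetricMatrix:
    """Z-score each vertex row (sample SD, divisor n-1)."""
    mean = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    zero = np.nonzero(sd.ravel() == 0)[0]
    if zero.size:
        bad = [int(m.mask[i]) for i in zero[:10]]
        raise SchemaError(
            f"{m.metric_name}: zero-variance vertices {bad}"
            f"{'...' if zero.size > 10 else ''}; drop them via the mask"
        )
    return replace(m, values=(m.values - mean) / sd)


def stack_and_shift(metrics: list[VertexMetricMatrix]) -> StackedInput:
    """Stack metric blocks side by side (CT, SA, MD, FA, RD) and min-shift."""
    by_name = {m.metric_name: m for m in metrics}
    if set(by_name) != set(METRICS):
        raise SchemaError(f"expected metrics {METRICS}, got {sorted(by_name)}")
    ref = by_name[METRICS[0]]
    for m in metrics:
        if not np.array_equal(m.mask, ref.mask):
            raise SchemaError(f"{m.metric_name}: mask differs from {ref.metric_name}")
        if m.subject_ids != ref.subject_ids:
            raise SchemaError(f"{m.metric_name}: subject order differs")
        if m.scanner_labels != ref.scanner_labels:
            raise SchemaError(f"{m.metric_name}: scanner labels differ")
    blocks = [by_name[name].values for name in METRICS]
    matrix = np.hstack(blocks)
    gmin = float(matrix.min())
    shift = min(gmin, 0.0)
    matrix = matrix - shift
    column_index = [
        (sid, name) for name in METRICS for sid in ref.subject_ids
    ]
    prov = {
        "zscore_ddof": 1,
        "metric_order": list(METRICS),
        "n_subjects": ref.n_subjects,
        "n_vertices": ref.n_vertices,
    }
    prov["config_hash"] = hashlib.sha256(
        json.dumps(prov, sort_keys=True).encode()
    ).hexdigest()[:16]
    return StackedInput(
        matrix=matrix,
        shift=shift,
        column_index=column_index,
        mask=ref.mask.copy(),
        scanner_labels=list(ref.scanner_labels),
        provenance=prov,
    )


def assemble(metrics: list[VertexMetricMatrix]) -> StackedInput:
    """Full pipeline on already-masked tables: residualize, z-score, stack."""
    processed = [zscore_vertices(residualize_scanner(m)) for m in metrics]
    return stack_and_shift(processed)


def save_stacked(stacked: StackedInput, path: str | Path) -> None:
    """Persist a StackedInput as a .npz container."""
    np.savez_compressed(
        path,
        matrix=stacked.matrix,
        shift=stacked.shift,
        subjects=np.array([s for s, _ in stacked.column_index]),
        metrics=np.array([m for _, m in stacked.column_index]),
        mask=stacked.mask,
        scanners=np.array(stacked.scanner_labels),
        provenance=json.dumps(stacked.provenance),
    )


def load_stacked(path: str | Path) -> StackedInput:
    with np.load(path, allow_pickle=False) as z:
        column_index = list(zip(z["subjects"].tolist(), z["metrics"].tolist()))
        return StackedInput(
            matrix=z["matrix"],
            shift=float(z["shift"]),
            column_index=column_index,
            mask=z["mask"],
            scanner_labels=z["scanners"].tolist(),
            provenance=json.loads(str(z["provenance"])),
        )
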