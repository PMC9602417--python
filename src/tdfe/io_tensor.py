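"""Reading per-timepoint expression tables and assembling the 4-way tensor.

The analysis operates on a fourth-order tensor ``x[i, j, k, l]`` indexing
gene *i*, biological replicate *j*, timepoint *k* (postnatal day, PND) and
exposure group *l*.  This module reads one delimited expression table per
timepoint (rows = genes, columns = samples), intersects the gene universes
of the files, and places each sample's expression column at its
``(replicate, timepoint, exposure)`` slot according to a sample map.

Axis conventions
----------------
* Exposure axis: index 1 = exposed ("non-control"), index 2 = control.
  This matches the regression design where exposed samples come first.
* Replicate index within a ``(timepoint, exposure)`` cell follows the order
  samples are listed in the :class:`SampleMap`; replicates carry no
  biological pairing across timepoints.
* Gene matching is exact, case-sensitive string equality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMap",
    "ExpressionTensor",
    "read_expression_table",
    "intersect_genes",
    "build_tensor",
]


class ExpressionParseError(ValueError):
    """Raised when an expression table violates the input contract."""


@dataclass
class ExpressionMatrix:
    """One timepoint's genes x samples table of non-negative expression values.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (length = number of rows).
    values
        2-D float array, genes x samples; finite and >= 0.
    sample_ids
        Ordered, unique sample identifiers (length = number of columns).
    timepoint_label
        Postnatal day of this table, in integer days.
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_ids: list[str]
    timepoint_label: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ExpressionParseError("values must be a 2-D genes x samples array")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ExpressionParseError(
                f"{len(self.gene_ids)} gene ids for {n} rows of values"
            )
        if len(self.sample_ids) != m or m < 1:
            raise ExpressionParseError(
                f"{len(self.sample_ids)} sample ids for {m} columns (need >= 1)"
            )
        dup = _first_duplicate(self.gene_ids)
        if dup is not None:
            raise ExpressionParseError(f"duplicate gene id {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ExpressionParseError(f"duplicate sample id {dup!r}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ExpressionParseError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ExpressionParseError(
                f"negative expression at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path, gene_column: str = "gene_id") -> None:
        frame = self.to_frame()
        frame.index.name = gene_column
        frame.to_csv(path, sep="\t")


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclass
class SampleMap:
    """Assignment of sample ids to (replicate j, timepoint k, exposure l) slots.

    ``entries`` holds ``(sample_id, j, k, l)`` tuples with 1-based indices.
    The triples must tile the full M x K x L grid exactly once, and each
    sample id must occur once.  ``exposure_labels[0]`` names l = 1 (the
    exposed / "non-control" group) and ``exposure_labels[1]`` names l = 2.
    """

    entries: list[tuple[str, int, int, int]]
    timepoint_labels: list[int]
    exposure_labels: list[str] = field(default_factory=lambda: ["exposed", "control"])

    def __post_init__(self) -> None:
        self.entries = [(str(s), int(j), int(k), int(l)) for s, j, k, l in self.entries]
        M, K, L = self.dims
        triples = [(j, k, l) for _, j, k, l in self.entries]
        expected = {
            (j, k, l)
            for j in range(1, M + 1)
            for k in range(1, K + 1)
            for l in range(1, L + 1)
        }
        missing = sorted(expected - set(triples))
        if missing:
            j, k, l = missing[0]
            raise ValueError(f"sample map is missing slot (j={j}, k={k}, l={l})")
        if len(triples) != len(set(triples)) or len(self.entries) != M * K * L:
            raise ValueError(
                "sample map must cover every (replicate, timepoint, exposure) "
                f"slot of the {M}x{K}x{L} grid exactly once"
            )
        ids = [s for s, *_ in self.entries]
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ValueError(f"sample id {dup!r} mapped more than once")
        if len(self.timepoint_labels) != K:
            raise ValueError("timepoint_labels length must equal the number of timepoints")
        if len(self.exposure_labels) != L:
            raise ValueError("exposure_labels length must equal the number of groups")

    @property
    def dims(self) -> tuple[int, int, int]:
        """(M replicates, K timepoints, L exposure groups)."""
        M = max(j for _, j, _, _ in self.entries)
        K = max(k for _, _, k, _ in self.entries)
        L = max(l for _, _, _, l in self.entries)
        return M, K, L

    def to_json(self) -> str:
        return json.dumps(
            {
                "entries": self.entries,
                "timepoint_labels": self.timepoint_labels,
                "exposure_labels": self.exposure_labels,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SampleMap":
        obj = json.loads(text)
        return cls(
            entries=[tuple(e) for e in obj["entries"]],
            timepoint_labels=obj["timepoint_labels"],
            exposure_labels=obj["exposure_labels"],
        )

    @classmethod
    def from_columns(
        cls,
        columns_per_timepoint: Sequence[Sequence[str]],
        timepoint_labels: Sequence[int],
        n_replicates: int,
        exposure_labels: Sequence[str] = ("exposed", "control"),
    ) -> "SampleMap":
        """Build a map from per-timepoint column listings.

        Each listing must contain the exposed replicates first, then the
        control replicates (``n_replicates`` of each), mirroring how the
        study's sample ids are ordered within each timepoint file.
        """
        entries: list[tuple[str, int, int, int]] = []
        for k, cols in enumerate(columns_per_timepoint, start=1):
            if len(cols) != 2 * n_replicates:
                raise ValueError(
                    f"timepoint {k}: expected {2 * n_replicates} sample ids, got {len(cols)}"
                )
            for idx, sid in enumerate(cols):
                l = 1 if idx < n_replicates else 2
                j = idx % n_replicates + 1
                entries.append((sid, j, k, l))
        return cls(
            entries=entries,
            timepoint_labels=list(timepoint_labels),
            exposure_labels=list(exposure_labels),
        )


@dataclass
class ExpressionTensor:
    """The assembled 4-way array x[i, j, k, l] with axis metadata."""

    values: np.ndarray
    gene_ids: list[str]
    timepoint_days: list[int]
    exposure_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("expression tensor must be 4-way (gene, replicate, time, exposure)")
        N, M, K, L = self.values.shape
        if len(self.gene_ids) != N:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {N} tensor rows")
        if len(self.timepoint_days) != K:
            raise ValueError("timepoint_days length must equal the time extent")
        if list(self.timepoint_days) != sorted(set(self.timepoint_days)):
            raise ValueError("timepoint_days must be strictly increasing")
        if len(self.exposure_labels) != L:
            raise ValueError("exposure_labels length must equal the exposure extent")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("tensor entries must be finite")

    @property
    def dims(self) -> tuple[int, int, int, int]:
        return self.values.shape

    def save(self, directory: str | Path) -> Path:
        """Persist as an array file plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "tensor.npy", self.values)
        meta = {
            "dims": list(self.dims),
            "axis_order": ["gene", "replicate", "timepoint", "exposure"],
            "gene_ids": self.gene_ids,
            "timepoint_days": self.timepoint_days,
            "exposure_labels": self.exposure_labels,
        }
        (directory / "tensor_meta.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "ExpressionTensor":
        directory = Path(directory)
        values = np.load(directory / "tensor.npy")
        meta = json.loads((directory / "tensor_meta.json").read_text())
        return cls(
            values=values,
            gene_ids=meta["gene_ids"],
            timepoint_days=meta["timepoint_days"],
            exposure_labels=meta["exposure_labels"],
        )


def read_expression_table(
    path: str | Path,
    sep: str | None = None,
    gene_column: str | None = None,
    timepoint_label: int | None = None,
) -> ExpressionMatrix:
    """Read a delimited genes x samples expression table.

    The delimiter is auto-detected (tab vs comma) unless ``sep`` is given.
    The gene-identifier column is the first column unless ``gene_column``
    names one.  Every other column must parse to finite non-negative
    numbers; violations raise :class:`ExpressionParseError` naming the
    offending row and column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression table not found: {path}")
    if sep is None:
        header = path.open().readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if frame.shape[1] < 2:
        raise ExpressionParseError(
            f"{path.name}: need a gene-id column plus >= 1 sample column"
        )
    if gene_column is None:
        gene_column = frame.columns[0]
    elif gene_column not in frame.columns:
        raise ExpressionParseError(f"{path.name}: no column named {gene_column!r}")
    gene_ids = frame[gene_column].astype(str).tolist()
    dup = _first_duplicate(gene_ids)
    if dup is not None:
        raise ExpressionParseError(f"{path.name}: duplicate gene id {dup!r}")
    data = frame.drop(columns=[gene_column])
    numeric = data.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | ~np.isfinite(numeric.to_numpy(dtype=float, na_value=np.nan))
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ExpressionParseError(
            f"{path.name}: non-numeric cell {data.iat[i, j]!r} at gene "
            f"{gene_ids[i]!r}, column {data.columns[j]!r}"
        )
    return ExpressionMatrix(
        gene_ids=gene_ids,
        values=numeric.to_numpy(dtype=float),
        sample_ids=list(data.columns),
        timepoint_label=timepoint_label,
    )


def intersect_genes(matrices: Sequence[ExpressionMatrix]) -> list[str]:
    """Genes present in every matrix, ordered as in the first matrix.

    Mirrors the study's restriction to the genes whose expression was
    consistently measured in all per-timepoint files.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    ordered = [g for g in matrices[0].gene_ids if g in common]
    if not ordered:
        raise ValueError("gene intersection across files is empty; cannot proceed")
    return ordered


def build_tensor(
    matrices: Sequence[ExpressionMatrix],
    sample_map: SampleMap,
    genes: Sequence[str] | None = None,
) -> ExpressionTensor:
    """Assemble x[i, j, k, l] by looking each mapped sample up in the tables.

    Every ``(j, k, l)`` slot of the map must resolve to exactly one sample
    column in exactly one matrix, and every requested gene must be present
    in every matrix that contributes a sample.
    """
    if genes is None:
        genes = intersect_genes(matrices) if len(matrices) > 1 else list(matrices[0].gene_ids)
    genes = list(genes)
    M, K, L = sample_map.dims
    # sample_id -> (matrix index, column index)
    location: dict[str, tuple[int, int]] = {}
    for mi, mat in enumerate(matrices):
        for ci, sid in enumerate(mat.sample_ids):
            if sid in location:
                raise ValueError(f"sample id {sid!r} appears in more than one matrix")
            location[sid] = (mi, ci)
    row_index: list[dict[str, int]] = [
        {g: i for i, g in enumerate(mat.gene_ids)} for mat in matrices
    ]
    values = np.empty((len(genes), M, K, L), dtype=float)
    for sid, j, k, l in sample_map.entries:
        if sid not in location:
            raise ValueError(
                f"slot (j={j}, k={k}, l={l}): sample {sid!r} not found in any matrix"
            )
        mi, ci = location[sid]
        rows = row_index[mi]
        try:
            idx = [rows[g] for g in genes]
        except KeyError as exc:
            raise ValueError(
                f"gene {exc.args[0]!r} missing from the matrix holding sample {sid!r}"
            ) from None
        values[:, j - 1, k - 1, l - 1] = matrices[mi].values[idx, ci]
    return ExpressionTensor(
        values=values,
        gene_ids=genes,
        timepoint_days=list(sample_map.timepoint_labels),
        exposure_labels=list(sample_map.exposure_labels),
    )
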