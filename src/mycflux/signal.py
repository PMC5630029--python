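"""Shared containers for per-gene time-course signal.

A :class:`SignalTable` holds one assay's quantification — ChIP-seq reads in a
window, or exonic/intronic RNA-seq signal — as a genes x timepoints x
replicates array with per-library sizes, the shape every downstream stage
(share statistics, RNA kinetics, RNAPII modeling, clustering) consumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ASSAYS",
    "TimeGrid",
    "SignalTable",
    "normalize",
    "replicate_average",
    "response_matrix",
    "ResponseMatrix",
]

ASSAYS = (
    "MYC",
    "ZBTB17",
    "RNAPII_promoter",
    "RNAPII_genebody",
    "RNAPII_tes",
    "total_exon",
    "total_intron",
    "nascent_exon",
    "nascent_intron",
)

#: default sampling times in hours: untreated, 10 min, 30 min, 1 h, 2 h, 4 h
DEFAULT_TIMES = (0.0, 1.0 / 6.0, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class TimeGrid:
    """Sampling times of the activation time course, in hours.

    ``times[0]`` is the untreated reference.  ``labeling_duration`` is the
    length of the metabolic-labeling pulse applied before each collection
    (default 10 min), used to convert nascent signal into synthesis rates.
    """

    times: tuple = DEFAULT_TIMES
    labeling_duration: float = 1.0 / 6.0

    def __post_init__(self):
        t = tuple(float(x) for x in self.times)
        object.__setattr__(self, "times", t)
        if len(t) < 2:
            raise ValueError("need at least two timepoints")
        if t[0] != 0.0:
            raise ValueError("first timepoint must be 0 (untreated)")
        diffs = np.diff(t)
        if np.any(diffs <= 0):
            raise ValueError("times must be strictly increasing")
        if not (0.0 < self.labeling_duration <= float(diffs.min())):
            raise ValueError(
                "labeling_duration must be positive and no longer than the "
                "smallest inter-timepoint gap"
            )

    @property
    def n_times(self) -> int:
        return len(self.times)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.times, float)


@dataclass
class SignalTable:
    """Genes x timepoints x replicates signal for one assay.

    ``values`` are non-negative (raw or normalized counts); ``library_sizes``
    is a (timepoints, replicates) array of sequencing depths used for
    counts-per-million scaling.  ``normalized`` records whether CPM scaling
    has been applied; ``pseudocount`` is carried along for downstream log
    operations.
    """

    assay: str
    gene_ids: np.ndarray
    values: np.ndarray
    grid: TimeGrid
    library_sizes: np.ndarray | None = None
    normalized: bool = False
    pseudocount: float = 0.0

    def __post_init__(self):
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.values = np.asarray(self.values, float)
        if self.values.ndim == 2:
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError("values must be (genes, timepoints, replicates)")
        g, t, r = self.values.shape
        if g != self.gene_ids.size:
            raise ValueError("gene_ids length does not match values")
        if t != self.grid.n_times:
            raise ValueError("timepoint axis does not match TimeGrid")
        if np.any(self.values < 0):
            raise ValueError("signal values must be non-negative")
        if self.library_sizes is not None:
            self.library_sizes = np.broadcast_to(
                np.asarray(self.library_sizes, float), (t, r)
            ).copy()
            if np.any(self.library_sizes <= 0):
                raise ValueError("library sizes must be positive")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[2]

    def copy_with(self, **kw) -> "SignalTable":
        return dataclasses.replace(self, **kw)

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path) -> None:
        """Write the table as TSV plus a ``.meta.yaml`` sidecar.

        Columns are ``t<time>_r<rep>``; values are written with 17
        significant digits so a round trip is lossless to float precision.
        """
        path = Path(path)
        t_arr = self.grid.as_array()
        cols, data = [], []
        for ti, t in enumerate(t_arr):
            for ri in range(self.n_replicates):
                cols.append(f"t{t:g}_r{ri + 1}")
                data.append(self.values[:, ti, ri])
        df = pd.DataFrame(
            np.column_stack(data), columns=cols, index=pd.Index(self.gene_ids, name="gene_id")
        )
        df.to_csv(path, sep="\t", float_format="%.17g")
        meta = {
            "assay": self.assay,
            "times": [float(t) for t in t_arr],
            "labeling_duration": float(self.grid.labeling_duration),
            "n_replicates": int(self.n_replicates),
            "normalized": bool(self.normalized),
            "pseudocount": float(self.pseudocount),
        }
        if self.library_sizes is not None:
            meta["library_sizes"] = self.library_sizes.tolist()
        with open(path.with_suffix(path.suffix + ".meta.yaml").with_name(
            path.stem + ".meta.yaml"
        ), "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def from_tsv(cls, path) -> "SignalTable":
        path = Path(path)
        meta_path = path.with_name(path.stem + ".meta.yaml")
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh)
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        grid = TimeGrid(tuple(meta["times"]), meta["labeling_duration"])
        n_rep = int(meta["n_replicates"])
        values = np.empty((df.shape[0], grid.n_times, n_rep))
        for ti, t in enumerate(grid.times):
            for ri in range(n_rep):
                values[:, ti, ri] = df[f"t{t:g}_r{ri + 1}"].to_numpy()
        lib = meta.get("library_sizes")
        return cls(
            assay=meta["assay"],
            gene_ids=df.index.to_numpy(dtype=object),
            values=values,
            grid=grid,
            library_sizes=None if lib is None else np.asarray(lib, float),
            normalized=bool(meta.get("normalized", False)),
            pseudocount=float(meta.get("pseudocount", 0.0)),
        )


def normalize(table: SignalTable, pseudocount: float = 1.0) -> SignalTable:
    """Scale each library to counts per million of its sequencing depth.

    The pseudocount is not added here; it is recorded on the table and
    applied by downstream log-ratio operations.
    """
    if table.library_sizes is None:
        raise ValueError("library_sizes must be set before normalization")
    if np.any(table.library_sizes <= 0):
        raise ValueError("zero or negative library size")
    scale = 1e6 / table.library_sizes  # (T, R)
    values = table.values * scale[None, :, :]
    return table.copy_with(values=values, normalized=True, pseudocount=float(pseudocount))


def replicate_average(table: SignalTable) -> SignalTable:
    """Average the replicate axis (keeping a singleton replicate dim)."""
    values = table.values.mean(axis=2, keepdims=True)
    lib = None
    if table.library_sizes is not None:
        lib = table.library_sizes.mean(axis=1, keepdims=True)
    return table.copy_with(values=values, library_sizes=lib)


@dataclass
class ResponseMatrix:
    """Genes x features matrix of log2 ratios to the untreated condition."""

    gene_ids: np.ndarray
    values: np.ndarray  # (genes, features)
    feature_labels: list
    pseudocount: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.feature_labels,
        )


def response_matrix(
    tables: list[SignalTable],
    pseudocount: float = 1.0,
    include_t0: bool = False,
) -> ResponseMatrix:
    """Log2 response of each assay/timepoint to the untreated condition.

    Each entry is ``log2((x_t + pc) / (x_0 + pc))`` computed on
    replicate-averaged values (tables are expected normalized; raw tables
    are accepted but mixed normalization across tables is the caller's
    responsibility).
    """
    if not tables:
        raise ValueError("no tables given")
    ref = tables[0].gene_ids
    for t in tables[1:]:
        if t.gene_ids.shape != ref.shape or np.any(t.gene_ids != ref):
            raise ValueError("tables must share an identical gene list")
    blocks, labels = [], []
    for t in tables:
        avg = t.values.mean(axis=2)  # (G, T)
        x0 = avg[:, [0]]
        with np.errstate(divide="ignore", invalid="ignore"):
            lfc = np.log2(avg + pseudocount) - np.log2(x0 + pseudocount)
        t_arr = t.grid.as_array()
        start = 0 if include_t0 else 1
        blocks.append(lfc[:, start:])
        labels.extend(f"{t.assay}_t{tt:g}" for tt in t_arr[start:])
    values = np.concatenate(blocks, axis=1)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite response values; use a positive pseudocount")
    return ResponseMatrix(ref.copy(), values, labels, float(pseudocount))
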