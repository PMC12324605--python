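"""Expression containers, file I/O, normalization, and split regimes.

The :class:`ExpressionDataset` is the carrier passed between every stage:
a cells × features nonnegative matrix with ordered identifiers, a per-cell
dataset (batch) index, optional cell-type labels, and optional 2-D spot
coordinates for spatial assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "ExpressionDataset",
    "SplitSpec",
    "read_expression",
    "write_expression",
    "normalize",
    "make_split",
    "intersect_features",
]


@dataclass
class ExpressionDataset:
    """Annotated cells × features expression matrix.

    Parameters
    ----------
    values
        Nonnegative matrix, one row per cell (raw counts or normalized
        intensities).
    feature_ids, cell_ids
        Ordered identifier lists matching the matrix axes.
    modality
        ``"rna"`` or ``"protein"``.
    batch_id
        Per-cell integer dataset index (contiguous range).
    cell_type
        Optional per-cell categorical labels.
    coords
        Optional per-cell 2-D coordinates (spatial assays).
    normalized
        Whether :func:`normalize` has been applied.
    """

    values: np.ndarray
    feature_ids: list[str]
    cell_ids: list[str]
    modality: str = "rna"
    batch_id: np.ndarray | None = None
    cell_type: np.ndarray | None = None
    coords: np.ndarray | None = None
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.modality not in ("rna", "protein"):
            raise ValueError(f"unknown modality {self.modality!r}")
        n, p = self.values.shape
        if n != len(self.cell_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells × {len(self.feature_ids)} features"
            )
        if self.values.size and self.values.min() < 0:
            raise ValueError("expression values must be nonnegative")
        if self.batch_id is None:
            self.batch_id = np.zeros(n, dtype=np.int64)
        else:
            self.batch_id = np.asarray(self.batch_id, dtype=np.int64)
            if self.batch_id.shape != (n,):
                raise ValueError("batch_id must have one entry per cell")
            if n:
                uniq = np.unique(self.batch_id)
                expected = np.arange(uniq.min(), uniq.min() + len(uniq))
                if not np.array_equal(uniq, expected):
                    raise ValueError("batch_id values must form a contiguous range")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
            if self.cell_type.shape != (n,):
                raise ValueError("cell_type must have one entry per cell")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=np.float64)
            if self.coords.shape != (n, 2):
                raise ValueError("coords must be (n_cells, 2)")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, index: np.ndarray) -> "ExpressionDataset":
        index = np.asarray(index)
        return replace(
            self,
            values=self.values[index],
            cell_ids=[self.cell_ids[i] for i in index],
            batch_id=self.batch_id[index],
            cell_type=None if self.cell_type is None else self.cell_type[index],
            coords=None if self.coords is None else self.coords[index],
        )

    def subset_features(self, feature_ids: list[str]) -> "ExpressionDataset":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return replace(self, values=self.values[:, idx], feature_ids=list(feature_ids))


@dataclass
class SplitSpec:
    """Train/test split regime.

    ``random`` splits uniformly; ``few_shot`` keeps only
    ``train_fraction`` of cells for training; ``ood`` moves every cell
    whose type is in ``held_out_labels`` to the test set; ``zero_shot``
    puts every cell in the test set (training happens on another assay).
    """

    regime: str = "random"
    train_fraction: float = 0.8
    held_out_labels: frozenset = field(default_factory=frozenset)
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("random", "few_shot", "ood", "zero_shot"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if not (0 < self.train_fraction <= 1):
            raise ValueError("train_fraction must be in (0, 1]")
        if self.regime == "few_shot" and self.train_fraction >= 1:
            raise ValueError("few_shot requires train_fraction < 1")
        self.held_out_labels = frozenset(self.held_out_labels)
        if self.regime == "ood" and not self.held_out_labels:
            raise ValueError("ood requires non-empty held_out_labels")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression(path, format: str = "delimited", modality: str = "rna",
                    sep: str = "\t") -> ExpressionDataset:
    """Read an expression matrix from disk.

    ``delimited``: header row of feature IDs, first column cell IDs.
    ``matrix_market``: ``.mtx`` triplets (1-based on disk, features × cells
    or cells × features resolved by the sidecar lengths) with
    ``features.tsv`` / ``barcodes.tsv`` sidecars in the same directory.
    ``hdf5_container``: the annotated layout written by
    :func:`write_expression`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        try:
            df = pd.read_csv(path, sep=sep, index_col=0)
        except Exception as exc:
            raise ValueError(f"could not parse delimited file {path}: {exc}") from exc
        return ExpressionDataset(
            values=df.to_numpy(dtype=np.float64),
            feature_ids=[str(c) for c in df.columns],
            cell_ids=[str(i) for i in df.index],
            modality=modality,
        )
    if format == "matrix_market":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:
            raise ValueError(f"could not parse matrix-market file {path}: {exc}") from exc
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat,
                         dtype=np.float64)
        feats = _read_id_file(path.parent / "features.tsv")
        cells = _read_id_file(path.parent / "barcodes.tsv")
        if mat.shape == (len(cells), len(feats)):
            pass
        elif mat.shape == (len(feats), len(cells)):
            mat = mat.T
        else:
            raise ValueError(
                f"matrix shape {mat.shape} matches neither {len(cells)} barcodes "
                f"× {len(feats)} features nor its transpose"
            )
        return ExpressionDataset(values=mat, feature_ids=feats, cell_ids=cells,
                                 modality=modality)
    if format == "hdf5_container":
        with h5py.File(path, "r") as f:
            ds = ExpressionDataset(
                values=f["values"][...],
                feature_ids=[s.decode() for s in f["feature_ids"][...]],
                cell_ids=[s.decode() for s in f["cell_ids"][...]],
                modality=f.attrs.get("modality", modality),
                batch_id=f["batch_id"][...] if "batch_id" in f else None,
                cell_type=(np.array([s.decode() for s in f["cell_type"][...]],
                                    dtype=object) if "cell_type" in f else None),
                coords=f["coords"][...] if "coords" in f else None,
                normalized=bool(f.attrs.get("normalized", False)),
            )
        return ds
    raise ValueError(f"unknown format {format!r}")


def _read_id_file(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"missing sidecar {path}")
    with open(path) as fh:
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def write_expression(ds: ExpressionDataset, path, format: str = "hdf5_container",
                     sep: str = "\t") -> None:
    """Write a dataset in one of the formats :func:`read_expression` reads."""
    path = Path(path)
    if format == "delimited":
        pd.DataFrame(ds.values, index=ds.cell_ids, columns=ds.feature_ids).to_csv(
            path, sep=sep)
        return
    if format == "matrix_market":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(ds.values))
        with open(path.parent / "features.tsv", "w") as fh:
            fh.write("\n".join(ds.feature_ids) + "\n")
        with open(path.parent / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(ds.cell_ids) + "\n")
        return
    if format == "hdf5_container":
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=ds.values)
            f.create_dataset("feature_ids",
                             data=np.array(ds.feature_ids, dtype="S"))
            f.create_dataset("cell_ids", data=np.array(ds.cell_ids, dtype="S"))
            f.create_dataset("batch_id", data=ds.batch_id)
            if ds.cell_type is not None:
                f.create_dataset("cell_type",
                                 data=np.array([str(t) for t in ds.cell_type],
                                               dtype="S"))
            if ds.coords is not None:
                f.create_dataset("coords", data=ds.coords)
            f.attrs["modality"] = ds.modality
            f.attrs["normalized"] = ds.normalized
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize(ds: ExpressionDataset, target_sum: float = 1e4) -> ExpressionDataset:
    """Library-size normalize, log1p, then per-feature min-max scale to [0, 1].

    The three steps run in exactly that order. Constant feature columns
    (including all-zero ones) map to all zeros.
    """
    if ds.normalized:
        raise ValueError("dataset is already normalized")
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    totals = ds.values.sum(axis=1)
    zero = np.where(totals == 0)[0]
    if zero.size:
        raise ValueError(
            f"all-zero cell(s) cannot be normalized: {[ds.cell_ids[i] for i in zero[:5]]}"
        )
    x = ds.values * (target_sum / totals)[:, None]
    x = np.log1p(x)
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
    return replace(ds, values=x, normalized=True)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def make_split(ds: ExpressionDataset, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return disjoint, exhaustive (train, test) index arrays for a regime."""
    n = ds.n_cells
    rng = np.random.default_rng(spec.seed)
    if spec.regime == "zero_shot":
        return np.array([], dtype=np.int64), np.arange(n, dtype=np.int64)
    if spec.regime == "ood":
        if ds.cell_type is None:
            raise ValueError("ood regime requires cell_type labels")
        labels = set(map(str, ds.cell_type))
        missing = set(spec.held_out_labels) - labels
        if missing:
            raise ValueError(f"held-out label(s) absent from data: {sorted(missing)}")
        held = np.array([str(t) in spec.held_out_labels for t in ds.cell_type])
        train = np.where(~held)[0]
        test = np.where(held)[0]
        return train.astype(np.int64), test.astype(np.int64)
    perm = rng.permutation(n)
    n_train = max(1, _round_half_up(spec.train_fraction * n))
    if spec.regime == "few_shot" or spec.regime == "random":
        n_train = min(n_train, n - 1) if spec.train_fraction < 1 else n
    train = np.sort(perm[:n_train])
    test = np.sort(perm[n_train:])
    return train.astype(np.int64), test.astype(np.int64)


def intersect_features(
    a: ExpressionDataset, b: ExpressionDataset
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Restrict both datasets to their shared features, in ``a``'s order."""
    shared = [f for f in a.feature_ids if f in set(b.feature_ids)]
    if not shared:
        warnings.warn("feature vocabularies are disjoint; returning 0-feature datasets")
    return a.subset_features(shared), b.subset_features(shared)
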