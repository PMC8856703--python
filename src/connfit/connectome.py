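"""Structural connectome containers, validation, and consensus thresholding.

A structural connectome couples a nonnegative symmetric weight matrix
(streamline fractions ``C_ij``), a tract-length matrix in millimetres
(``D_ij``), and a region table flagging cortical versus subcortical regions.
Weights from probabilistic tractography are directionless, so directed
estimates are averaged (``symmetrize``), and spurious connections are removed
by zeroing any edge absent from a stated fraction of a comparison cohort
(``consensus_mask`` / ``apply_mask``).
"""

from __future__ import annotations

import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConnectomeValidationError",
    "Connectome",
    "read_connectome",
    "write_connectome",
    "symmetrize",
    "consensus_mask",
    "apply_mask",
]

#: relative tolerance below which input asymmetry is treated as numeric noise
ASYMMETRY_RTOL = 1e-8

REGION_COLUMNS = ["region_id", "label", "hemisphere", "is_subcortical"]

# fixed member names inside a .zip connectome bundle
BUNDLE_WEIGHTS = "weights.txt"
BUNDLE_LENGTHS = "tract_lengths.txt"
BUNDLE_REGIONS = "regions.tsv"


class ConnectomeValidationError(ValueError):
    """Raised when a connectome violates its structural invariants."""


def _validate_region_table(regions: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REGION_COLUMNS if c not in regions.columns]
    if missing:
        raise ConnectomeValidationError(f"region table missing columns {missing}")
    n = len(regions)
    if n < 2:
        raise ConnectomeValidationError("region table needs at least 2 regions")
    ids = regions["region_id"].to_numpy()
    if not np.array_equal(np.sort(ids), np.arange(n)):
        raise ConnectomeValidationError(
            "region_id values must be the contiguous range 0..n-1"
        )
    bad = set(regions["hemisphere"]) - {"left", "right"}
    if bad:
        raise ConnectomeValidationError(f"unknown hemisphere labels: {sorted(bad)}")
    out = regions.copy()
    out["is_subcortical"] = out["is_subcortical"].astype(bool)
    return out.sort_values("region_id").reset_index(drop=True)


@dataclass(frozen=True)
class Connectome:
    """Validated structural connectome.

    Parameters
    ----------
    weights : (n, n) ndarray
        Symmetric nonnegative connection weights with zero diagonal
        (unitless streamline fractions).
    lengths : (n, n) ndarray
        Symmetric nonnegative tract lengths in mm; positive wherever a
        weight is positive.
    regions : pandas.DataFrame
        Region metadata with columns region_id, label, hemisphere,
        is_subcortical.
    """

    weights: np.ndarray
    lengths: np.ndarray
    regions: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        d = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "lengths", d)
        object.__setattr__(self, "regions", _validate_region_table(self.regions))
        n = len(self.regions)
        for name, m in (("weights", w), ("lengths", d)):
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ConnectomeValidationError(f"{name} matrix is not square: {m.shape}")
            if m.shape[0] != n:
                raise ConnectomeValidationError(
                    f"{name} is {m.shape[0]}x{m.shape[0]} but region table has {n} rows"
                )
            neg = np.argwhere(m < 0)
            if neg.size:
                i, j = neg[0]
                raise ConnectomeValidationError(
                    f"{name}[{i},{j}] = {m[i, j]} is negative"
                )
            scale = max(np.abs(m).max(), 1.0)
            asym = np.argwhere(np.abs(m - m.T) > ASYMMETRY_RTOL * scale)
            if asym.size:
                i, j = asym[0]
                raise ConnectomeValidationError(
                    f"{name} asymmetric at [{i},{j}]: {m[i, j]} vs {m[j, i]}; "
                    "call symmetrize() first if the input is directed"
                )
        nz_diag = np.argwhere(np.abs(np.diag(w)) > 0)
        if nz_diag.size:
            i = int(nz_diag[0][0])
            raise ConnectomeValidationError(f"weights[{i},{i}] = {w[i, i]} is nonzero")
        missing_len = np.argwhere((w > 0) & (d <= 0))
        if missing_len.size:
            i, j = missing_len[0]
            raise ConnectomeValidationError(
                f"weights[{i},{j}] > 0 but lengths[{i},{j}] = {d[i, j]} is not positive"
            )

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    @property
    def cortical_mask(self) -> np.ndarray:
        """Boolean n-vector, True where the region is cortical."""
        return ~self.regions["is_subcortical"].to_numpy()


def symmetrize(matrix: np.ndarray) -> np.ndarray:
    """Average a directed matrix with its transpose.

    Directed tractography estimates A->B and B->A are merged as their mean,
    the standard symmetrization for undirected structural connectomes.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    return (m + m.T) / 2.0


def consensus_mask(
    weight_matrices: Sequence[np.ndarray], presence_fraction: float = 0.5
) -> np.ndarray:
    """Boolean mask of edges present in at least ``presence_fraction`` of subjects.

    Presence of edge (i, j) in a subject means a strictly positive entry. The
    comparison is inclusive ("at least"), so an edge present in exactly the
    threshold fraction is retained.
    """
    if len(weight_matrices) == 0:
        raise ValueError("need at least one weight matrix")
    if not 0 < presence_fraction <= 1:
        raise ValueError("presence_fraction must lie in (0, 1]")
    mats = [np.asarray(m, dtype=float) for m in weight_matrices]
    shape = mats[0].shape
    for k, m in enumerate(mats):
        if m.shape != shape:
            raise ValueError(f"matrix {k} has shape {m.shape}, expected {shape}")
    presence = np.mean([m > 0 for m in mats], axis=0)
    return presence >= presence_fraction


def apply_mask(connectome: Connectome, mask: np.ndarray) -> Connectome:
    """Zero weights where ``mask`` is False; tract lengths are retained.

    Lengths are inert wherever the weight is zero, so they are kept unchanged
    (they stay available if a different mask is applied later).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != connectome.weights.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match weights {connectome.weights.shape}"
        )
    return replace(connectome, weights=np.where(mask, connectome.weights, 0.0))


def _read_matrix(path: Path) -> np.ndarray:
    # whitespace- or comma-delimited numeric matrix without header
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    return np.loadtxt(path, delimiter=delimiter, ndmin=2)


def read_connectome(
    weights_path: str | Path,
    lengths_path: str | Path | None = None,
    regions_path: str | Path | None = None,
    *,
    symmetrize_input: bool = False,
) -> Connectome:
    """Read a connectome from three delimited-text files or a .zip bundle.

    If ``weights_path`` ends in ``.zip`` it is read as a bundle containing
    ``weights.txt``, ``tract_lengths.txt`` and ``regions.tsv``; otherwise all
    three paths are required. Set ``symmetrize_input`` to accept directed
    matrices (they are averaged with their transpose before validation).
    """
    weights_path = Path(weights_path)
    if weights_path.suffix == ".zip":
        import io

        with zipfile.ZipFile(weights_path) as zf:
            with zf.open(BUNDLE_WEIGHTS) as f:
                w = np.loadtxt(io.TextIOWrapper(f), ndmin=2)
            with zf.open(BUNDLE_LENGTHS) as f:
                d = np.loadtxt(io.TextIOWrapper(f), ndmin=2)
            with zf.open(BUNDLE_REGIONS) as f:
                regions = pd.read_csv(f, sep="\t")
    else:
        if lengths_path is None or regions_path is None:
            raise ValueError("lengths_path and regions_path are required")
        w = _read_matrix(weights_path)
        d = _read_matrix(Path(lengths_path))
        regions = pd.read_csv(regions_path, sep="\t")
    if w.shape != d.shape:
        raise ConnectomeValidationError(
            f"weights shape {w.shape} does not match lengths shape {d.shape}"
        )
    if symmetrize_input:
        w, d = symmetrize(w), symmetrize(d)
        np.fill_diagonal(w, 0.0)
    return Connectome(weights=w, lengths=d, regions=regions)


def write_connectome(
    connectome: Connectome,
    weights_path: str | Path,
    lengths_path: str | Path | None = None,
    regions_path: str | Path | None = None,
) -> None:
    """Write a connectome to three text files or to a single .zip bundle."""
    weights_path = Path(weights_path)
    fmt = "%.17g"
    if weights_path.suffix == ".zip":
        import io

        with zipfile.ZipFile(weights_path, "w") as zf:

            def _dump(arr: np.ndarray) -> str:
                buf = io.StringIO()
                np.savetxt(buf, arr, fmt=fmt)
                return buf.getvalue()

            zf.writestr(BUNDLE_WEIGHTS, _dump(connectome.weights))
            zf.writestr(BUNDLE_LENGTHS, _dump(connectome.lengths))
            zf.writestr(
                BUNDLE_REGIONS, connectome.regions.to_csv(sep="\t", index=False)
            )
    else:
        if lengths_path is None or regions_path is None:
            raise ValueError("lengths_path and regions_path are required")
        np.savetxt(weights_path, connectome.weights, fmt=fmt)
        np.savetxt(lengths_path, connectome.lengths, fmt=fmt)
        connectome.regions.to_csv(regions_path, sep="\t", index=False)
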