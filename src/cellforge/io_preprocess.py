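"""Count-matrix I/O and library-size normalization.

Cells are rows and genes are columns everywhere in this package.  Three
on-disk dialects are supported: Matrix Market triplets with ``barcodes.tsv``
/ ``features.tsv`` companions, dense CSV (header row = gene ids, first
column = cell ids), and the h5ad single-cell container, where per-cell
labels live in the cell annotation table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)

#: target per-cell total after library-size scaling
SCALE_TOTAL = 1.0e4

#: store counts sparse when fewer than half the entries are nonzero
_SPARSE_DENSITY_CUTOFF = 0.5


class FormatError(ValueError):
    """A file did not parse in its declared dialect."""


class ValidationError(ValueError):
    """Parsed data violates an ExpressionMatrix invariant."""


def _as_2d(a) -> np.ndarray:
    out = np.asarray(a, dtype=float)
    if out.ndim != 2:
        raise ValidationError(f"expected a 2-D matrix, got ndim={out.ndim}")
    return out


@dataclass
class ExpressionMatrix:
    """Cells x genes nonnegative count matrix with per-cell categorical labels.

    ``counts`` may be a dense ndarray or a scipy sparse matrix; it is kept
    sparse when density is below 50% and densified only where a model needs
    contiguous batches.  ``labels`` maps attribute name -> length-n_cells
    array of categorical values (zero or more attributes).
    """

    counts: np.ndarray | sp.spmatrix
    cell_ids: list[str]
    gene_ids: list[str]
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sp.issparse(self.counts):
            self.counts = self.counts.tocsr()
            if self.counts.nnz and self.counts.data.min() < 0:
                raise ValidationError("negative count in matrix")
        else:
            self.counts = _as_2d(self.counts)
            if self.counts.size and self.counts.min() < 0:
                raise ValidationError("negative count in matrix")
        n, m = self.counts.shape
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.cell_ids) != n:
            raise ValidationError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != m:
            raise ValidationError(f"{len(self.gene_ids)} gene ids for {m} columns")
        if len(set(self.cell_ids)) != n:
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != m:
            raise ValidationError("duplicate gene ids")
        self.labels = {k: np.asarray(v) for k, v in self.labels.items()}
        for name, vals in self.labels.items():
            if len(vals) != n:
                raise ValidationError(
                    f"label '{name}' covers {len(vals)} of {n} cells"
                )
        self._maybe_sparsify()

    def _maybe_sparsify(self) -> None:
        if sp.issparse(self.counts):
            return
        if self.counts.size == 0:
            return
        density = np.count_nonzero(self.counts) / self.counts.size
        if density < _SPARSE_DENSITY_CUTOFF:
            self.counts = sp.csr_matrix(self.counts)

    # -- convenience -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense float array (copy if stored sparse)."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)

    def combined_labels(self, sep: str = "_") -> np.ndarray:
        """Per-cell joint label: attribute values joined in attribute order.

        Matches the combined-condition convention (e.g. 'fibroblast_Bladder')
        used when a dataset carries more than one categorical attribute.
        """
        if not self.labels:
            return np.array([""] * self.n_cells)
        cols = [np.asarray(v).astype(str) for v in self.labels.values()]
        out = cols[0]
        for c in cols[1:]:
            out = np.char.add(np.char.add(out, sep), c)
        return out


@dataclass
class NormalizedMatrix:
    """Log-normalized expression: v_ij = ln(1e4 * x_ij / sum_j x_ij + 1)."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _as_2d(self.values)
        self.labels = {k: np.asarray(v) for k, v in self.labels.items()}

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def combined_labels(self, sep: str = "_") -> np.ndarray:
        return ExpressionMatrix.combined_labels(self, sep)  # type: ignore[arg-type]


def normalize(m: ExpressionMatrix) -> NormalizedMatrix:
    """Library-size normalize and log-transform a count matrix.

    Each cell's total count is scaled to 10 000, an offset of 1 is added and
    the natural logarithm is taken.  Cells with zero total counts map to
    all-zero rows (a warning is logged) rather than producing NaNs.
    """
    x = m.dense()
    totals = x.sum(axis=1, keepdims=True)
    zero_cells = totals[:, 0] == 0
    if zero_cells.any():
        log.warning("%d all-zero cell(s) normalized to all-zero rows", zero_cells.sum())
    safe = np.where(zero_cells[:, None], 1.0, totals)
    v = np.log1p(SCALE_TOTAL * x / safe)
    v[zero_cells] = 0.0
    return NormalizedMatrix(v, list(m.cell_ids), list(m.gene_ids),
                            {k: v2.copy() for k, v2 in m.labels.items()})


def denormalize_counts(
    values: np.ndarray,
    library_sizes: np.ndarray,
    rng: np.random.Generator | None = None,
    renormalize: bool = True,
) -> np.ndarray:
    """Invert the log-normalization back to integer counts.

    ``exp(v_ij) - 1`` recovers each gene's share of the scaled total; by
    default the shares are renormalized per cell so the expected total
    equals the given library size ``L_i`` (a no-op when the input exactly
    satisfies the exp-sum constraint, but robust to scale drift in model
    output; with ``renormalize=False`` the raw ``(exp(v)-1) * L / 1e4`` is
    used).  Fractional counts are resolved by stochastic rounding
    (floor + Bernoulli) so per-gene expected counts are preserved, or
    round-half-even if no rng is given.  Negative inputs clip to zero.
    """
    v = np.clip(_as_2d(values), 0.0, None)
    lib = np.asarray(library_sizes, dtype=float).reshape(-1, 1)
    if lib.shape[0] != v.shape[0]:
        raise ValidationError("one library size per cell required")
    shares = np.expm1(v)
    if renormalize:
        tot = shares.sum(axis=1, keepdims=True)
        tot[tot == 0] = 1.0
        x = shares / tot * lib
    else:
        x = shares * lib / SCALE_TOTAL
    if rng is None:
        return np.rint(x)
    lo = np.floor(x)
    frac = x - lo
    return lo + (rng.random(x.shape) < frac)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FORMATS = ("mtx", "csv", "h5ad")


def read_counts(path: str | Path, fmt: str) -> ExpressionMatrix:
    """Read a count matrix in one of the supported dialects.

    For ``mtx`` the path is the ``.mtx`` file; ``<stem>.barcodes.tsv`` and
    ``<stem>.features.tsv`` next to it hold cell and gene ids (extra
    tab-separated columns in the barcodes file become labels).
    """
    path = Path(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown format '{fmt}'; expected one of {_FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if fmt == "mtx":
            return _read_mtx(path)
        if fmt == "csv":
            return _read_csv(path)
        return _read_h5ad(path)
    except (ValidationError, FileNotFoundError):
        raise
    except Exception as exc:  # normalize third-party parse failures
        raise FormatError(f"could not parse {path} as {fmt}: {exc}") from exc


def write_counts(m: ExpressionMatrix, path: str | Path, fmt: str) -> None:
    """Write a count matrix so that :func:`read_counts` round-trips it."""
    path = Path(path)
    if fmt not in _FORMATS:
        raise FormatError(f"unknown format '{fmt}'; expected one of {_FORMATS}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "mtx":
        _write_mtx(m, path)
    elif fmt == "csv":
        _write_csv(m, path)
    else:
        _write_h5ad(m, path)


def _companions(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return (stem.with_suffix(".barcodes.tsv"), stem.with_suffix(".features.tsv"))


def _read_mtx(path: Path) -> ExpressionMatrix:
    import scipy.io

    mat = scipy.io.mmread(path)
    counts = sp.csr_matrix(mat)
    bc_path, ft_path = _companions(path)
    if not bc_path.exists() or not ft_path.exists():
        raise FormatError(f"missing companion files {bc_path.name} / {ft_path.name}")
    bc = pd.read_csv(bc_path, sep="\t", header=0, dtype=str)
    ft = pd.read_csv(ft_path, sep="\t", header=0, dtype=str)
    cell_ids = bc.iloc[:, 0].tolist()
    labels = {c: bc[c].to_numpy() for c in bc.columns[1:]}
    return ExpressionMatrix(counts, cell_ids, ft.iloc[:, 0].tolist(), labels)


def _write_mtx(m: ExpressionMatrix, path: Path) -> None:
    import scipy.io

    counts = m.counts if sp.issparse(m.counts) else sp.csr_matrix(m.counts)
    # integral counts are written as an integer field when exact
    data = counts.data
    field_kind = "integer" if np.all(data == np.rint(data)) else "real"
    if field_kind == "integer":
        counts = counts.astype(np.int64)
    scipy.io.mmwrite(str(path), counts.tocoo(), field=field_kind)
    bc_path, ft_path = _companions(path)
    bc = pd.DataFrame({"cell_id": m.cell_ids})
    for name, vals in m.labels.items():
        bc[name] = np.asarray(vals).astype(str)
    bc.to_csv(bc_path, sep="\t", index=False)
    pd.DataFrame({"gene_id": m.gene_ids}).to_csv(ft_path, sep="\t", index=False)


_LABEL_PREFIX = "label:"


def _read_csv(path: Path) -> ExpressionMatrix:
    df = pd.read_csv(path, header=0, index_col=0)
    label_cols = [c for c in df.columns if str(c).startswith(_LABEL_PREFIX)]
    labels = {str(c)[len(_LABEL_PREFIX):]: df[c].to_numpy().astype(str)
              for c in label_cols}
    data = df.drop(columns=label_cols)
    counts = data.to_numpy(dtype=float)
    return ExpressionMatrix(counts, [str(i) for i in df.index],
                            [str(c) for c in data.columns], labels)


def _write_csv(m: ExpressionMatrix, path: Path) -> None:
    df = pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.gene_ids)
    if np.all(df.to_numpy() == np.rint(df.to_numpy())):
        df = df.astype(np.int64)
    for name, vals in m.labels.items():
        df[_LABEL_PREFIX + name] = np.asarray(vals).astype(str)
    df.to_csv(path, index_label="cell_id")


def _read_h5ad(path: Path) -> ExpressionMatrix:
    import anndata as ad

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        adata = ad.read_h5ad(path)
    counts = adata.X
    if sp.issparse(counts):
        counts = counts.tocsr()
    else:
        counts = np.asarray(counts, dtype=float)
    labels = {c: adata.obs[c].to_numpy().astype(str) for c in adata.obs.columns}
    return ExpressionMatrix(counts, [str(i) for i in adata.obs_names],
                            [str(g) for g in adata.var_names], labels)


def _write_h5ad(m: ExpressionMatrix, path: Path) -> None:
    import anndata as ad

    obs = pd.DataFrame(index=pd.Index(m.cell_ids, name="cell_id"))
    for name, vals in m.labels.items():
        obs[name] = pd.Categorical(np.asarray(vals).astype(str))
    X = m.counts if sp.issparse(m.counts) else np.asarray(m.counts)
    adata = ad.AnnData(X=X.copy(), obs=obs,
                       var=pd.DataFrame(index=pd.Index(m.gene_ids, name="gene_id")))
    adata.write_h5ad(path)
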